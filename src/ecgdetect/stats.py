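"""Per-class statistical descriptor panel for embedded ECG epochs.

Nine descriptors: mean, standard deviation, variance, skewness, excess
kurtosis, Pearson correlation coefficient, approximate entropy, Rényi
entropy and permutation entropy.  Entropies are reported in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats as sps


@dataclass
class EntropyConfig:
    """Parameters of the three entropy descriptors.

    apen_m/apen_r: approximate-entropy embedding dimension and tolerance
    as a multiple of the sequence standard deviation (field-standard
    m=2, r=0.2*sigma).  renyi_alpha/renyi_bins: Rényi order and number of
    equal-width histogram bins.  peen_order/peen_delay: permutation-
    entropy ordinal pattern order and delay.
    """

    apen_m: int = 2
    apen_r: float = 0.2
    renyi_alpha: float = 2.0
    renyi_bins: int = 16
    peen_order: int = 3
    peen_delay: int = 1


@dataclass
class StatSummary:
    mu: float
    sigma: float
    sigma2: float
    skew: float
    C: float            # excess kurtosis
    PCC: float
    ApEn: float
    ReEn: float
    PeEn: float
    config: EntropyConfig = field(default_factory=EntropyConfig)

    def as_dict(self) -> dict[str, float]:
        return {
            "mu": self.mu, "sigma": self.sigma, "sigma2": self.sigma2,
            "skew": self.skew, "C": self.C, "PCC": self.PCC,
            "ApEn": self.ApEn, "ReEn": self.ReEn, "PeEn": self.PeEn,
        }


def renyi_entropy(probabilities: np.ndarray, alpha: float) -> float:
    """Rényi entropy of order ``alpha``: (1/(1-alpha)) * ln sum p_i^alpha."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    s = p.sum()
    if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"probabilities sum to {s}, not 1")
    if alpha <= 0 or alpha == 1:
        raise ValueError("alpha must be > 0 and != 1")
    p = p[p > 0]
    return float(np.log(np.sum(p ** alpha)) / (1.0 - alpha))


def approximate_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) with self-matches counted, Chebyshev distance.

    ``r`` defaults to 0.2 times the sample standard deviation; a constant
    sequence has ApEn 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < m + 1:
        raise ValueError(f"ApEn needs at least m+1={m + 1} samples, got {n}")
    if r is None:
        r = 0.2 * x.std()
    if r == 0:
        # constant sequence: every template matches every other exactly
        return 0.0

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distances between all template pairs
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        c = (d <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def permutation_entropy(values: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of ordinal patterns of the given order."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x) - (order - 1) * delay
    if n < 1:
        raise ValueError(
            f"PeEn order {order} (delay {delay}) needs at least "
            f"{(order - 1) * delay + 1} samples, got {len(x)}"
        )
    emb = np.empty((n, order))
    for k in range(order):
        emb[:, k] = x[k * delay: k * delay + n]
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = {p: i for i, p in enumerate(permutations(range(order)))}
    idx = np.array([codes[tuple(row)] for row in patterns])
    counts = np.bincount(idx, minlength=len(codes)).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _renyi_of_sequence(x: np.ndarray, alpha: float, bins: int) -> float:
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    return renyi_entropy(counts / counts.sum(), alpha)


def describe(
    values: np.ndarray,
    config: EntropyConfig | None = None,
    pcc_pair: np.ndarray | None = None,
) -> StatSummary:
    """All nine descriptors of one real sequence.

    PCC is the Pearson correlation between the sequence and ``pcc_pair``
    when given, otherwise the lag-1 autocorrelation of the sequence (one
    sequence defines no pair on its own).
    """
    cfg = config or EntropyConfig()
    x = np.asarray(values, dtype=float).ravel()
    need = max(cfg.apen_m + 1, (cfg.peen_order - 1) * cfg.peen_delay + 1, 3)
    if len(x) < need:
        raise ValueError(
            f"sequence of {len(x)} values is too short for the descriptor "
            f"panel (ApEn needs {cfg.apen_m + 1}, PeEn needs "
            f"{(cfg.peen_order - 1) * cfg.peen_delay + 1})"
        )
    mu = float(x.mean())
    sigma = float(x.std())
    if sigma == 0:
        skew = 0.0
        kurt = 0.0
        pcc = 0.0
    else:
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x))  # excess kurtosis
        if pcc_pair is not None:
            y = np.asarray(pcc_pair, dtype=float).ravel()
            pcc = float(np.corrcoef(x, y)[0, 1]) if y.std() > 0 else 0.0
        else:
            a, b = x[:-1], x[1:]
            pcc = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
    return StatSummary(
        mu=mu,
        sigma=sigma,
        sigma2=sigma ** 2,
        skew=skew,
        C=kurt,
        PCC=pcc,
        ApEn=approximate_entropy(x, cfg.apen_m, cfg.apen_r * sigma if sigma > 0 else None),
        ReEn=_renyi_of_sequence(x, cfg.renyi_alpha, cfg.renyi_bins),
        PeEn=permutation_entropy(x, cfg.peen_order, cfg.peen_delay),
        config=cfg,
    )


def describe_per_class(
    coords: np.ndarray, labels: np.ndarray, config: EntropyConfig | None = None
) -> dict[str, StatSummary]:
    """Descriptor panel per class over flattened embedding coordinates.

    PCC for a class is the mean Pearson correlation between consecutive
    epochs' feature vectors within that class.
    """
    cfg = config or EntropyConfig()
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, StatSummary] = {}
    for lab in dict.fromkeys(labels):  # preserve first-seen order
        rows = coords[labels == lab]
        summ = describe(rows.ravel(), cfg)
        rs = []
        for a, b in zip(rows[:-1], rows[1:]):
            if a.std() > 0 and b.std() > 0:
                rs.append(np.corrcoef(a, b)[0, 1])
        summ.PCC = float(np.mean(rs)) if rs else 0.0
        out[str(lab)] = summ
    return out
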