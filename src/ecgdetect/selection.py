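"""Metaheuristic epoch selection over embedded epochs.

Cuckoo search with Lévy flights and harmony search act as subset
selectors: a continuous position in [0,1]^n encodes an inclusion score
per candidate epoch, the optimizer maximizes Fisher class separability
of the retained subset, and the top-scoring ``target_count`` epochs per
class are kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ecgdetect.embedding import EmbeddingResult


@dataclass
class CuckooConfig:
    """Cuckoo-search settings.

    fa: probability that a host discovers (abandons) a nest per
    generation; gamma: Lévy step-size scale; beta: Lévy tail exponent.
    The default beta=0.2 follows the source method's trial-and-error
    choice and sits below the usual Mantegna range (0.3, 2) — a warning
    is emitted because the implied flight variance is extreme.
    """

    n_nests: int = 25
    fa: float = 0.25
    gamma: float = 1.0
    beta: float = 0.2
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fa <= 1:
            raise ValueError("fa must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.n_nests < 2:
            raise ValueError("n_nests must be >= 2")


@dataclass
class HarmonyConfig:
    """Harmony-search settings (memory size HS, memory considering rate
    HCR, pitch adjusting rate PAR, bandwidth bw, improvisation budget
    Vmax, per-variable bounds)."""

    HS: int = 20
    HCR: float = 0.9
    PAR: float = 0.3
    bw: float = 0.05
    Vmax: int = 2000
    lower: float = 0.0
    upper: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.HS < 2:
            raise ValueError("HS must be >= 2")
        if not (0 <= self.HCR <= 1 and 0 <= self.PAR <= 1):
            raise ValueError("HCR and PAR must be in [0, 1]")
        if self.bw <= 0:
            raise ValueError("bw must be > 0")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class SelectedFeatures:
    kept_ids: np.ndarray
    fitness_trace: np.ndarray
    selector: str
    config: object
    target_counts: dict = field(default_factory=dict)


def levy_step(beta: float, size, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Lévy-flight steps via the Mantegna scheme.

    step = u / |v|^(1/beta) with u ~ N(0, sigma_u^2), v ~ N(0, 1).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if not 0.3 < beta < 2.0:
        warnings.warn(
            f"Levy exponent beta={beta} is outside the usual Mantegna "
            "range (0.3, 2); steps will be extremely heavy-tailed",
            RuntimeWarning,
            stacklevel=2,
        )
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma_u = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size)
    v = rng.normal(0.0, 1.0, size)
    return u / np.abs(v) ** (1 / beta)


def _check_finite(val: float, pos: np.ndarray) -> float:
    if not np.isfinite(val):
        raise ValueError(f"objective returned non-finite value {val} at {pos}")
    return float(val)


def cuckoo_search_minimize(objective, config: CuckooConfig, dim: int):
    """Minimize ``objective`` over [0,1]^dim by cuckoo search.

    Per generation: every nest proposes a Lévy-flight move toward a
    random nest's replacement slot (greedy accept), then a fraction
    ``fa`` of the worst nests is abandoned and re-seeded at random.
    Returns (best_position, best_value, trace); the best-so-far trace is
    non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    nests = rng.uniform(0.0, 1.0, (config.n_nests, dim))
    fitness = np.array([_check_finite(objective(p), p) for p in nests])
    best_i = int(np.argmin(fitness))
    best_pos, best_val = nests[best_i].copy(), float(fitness[best_i])
    trace = [best_val]
    n_abandon = int(round(config.fa * config.n_nests))
    for _ in range(config.max_iter):
        for i in range(config.n_nests):
            step = config.gamma * levy_step(config.beta, dim, rng) * 0.01
            cand = np.clip(nests[i] + step * (nests[i] - best_pos + 1e-12), 0.0, 1.0)
            val = _check_finite(objective(cand), cand)
            j = rng.integers(config.n_nests)
            if val < fitness[j]:
                nests[j], fitness[j] = cand, val
        if n_abandon:
            worst = np.argsort(fitness)[-n_abandon:]
            nests[worst] = rng.uniform(0.0, 1.0, (n_abandon, dim))
            fitness[worst] = [
                _check_finite(objective(p), p) for p in nests[worst]
            ]
        i = int(np.argmin(fitness))
        if fitness[i] < best_val:
            best_pos, best_val = nests[i].copy(), float(fitness[i])
        trace.append(best_val)
    return best_pos, best_val, np.array(trace)


def harmony_search_minimize(objective, config: HarmonyConfig, dim: int):
    """Minimize ``objective`` over [lower, upper]^dim by harmony search.

    Each improvisation draws every variable from harmony memory with
    probability HCR (pitch-adjusted by +-bw*r with probability PAR) or
    uniformly at random otherwise; the new harmony replaces the worst
    memory member only if better.  Returns (best_position, best_value,
    trace of best-so-far per improvisation).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    hm = rng.uniform(lo, hi, (config.HS, dim))
    fit = np.array([_check_finite(objective(p), p) for p in hm])
    trace = [float(fit.min())]
    for _ in range(config.Vmax):
        new = np.empty(dim)
        for j in range(dim):
            if rng.uniform() < config.HCR:
                new[j] = hm[rng.integers(config.HS), j]
                if rng.uniform() < config.PAR:
                    new[j] += config.bw * rng.uniform(-1.0, 1.0)
            else:
                new[j] = rng.uniform(lo, hi)
        new = np.clip(new, lo, hi)
        val = _check_finite(objective(new), new)
        worst = int(np.argmax(fit))
        if val < fit[worst]:
            hm[worst], fit[worst] = new, val
        trace.append(float(fit.min()))
    best = int(np.argmin(fit))
    return hm[best].copy(), float(fit[best]), np.array(trace)


def fisher_separability(coords: np.ndarray, labels: np.ndarray) -> float:
    """Between-class variance of class means over mean within-class
    variance, summed across embedding coordinates.  Higher = better
    separated; returns 0 when only one class is present."""
    labs = np.unique(labels)
    if len(labs) < 2:
        return 0.0
    overall = coords.mean(axis=0)
    between = np.zeros(coords.shape[1])
    within = np.zeros(coords.shape[1])
    for lab in labs:
        rows = coords[labels == lab]
        between += len(rows) * (rows.mean(axis=0) - overall) ** 2
        within += ((rows - rows.mean(axis=0)) ** 2).sum(axis=0)
    within = np.maximum(within, 1e-12)
    return float(np.sum(between / within))


def _mask_to_subset(position, class_idx, target_counts, labels):
    """Top-``target_count`` positions per class; ties broken by lower index."""
    kept = []
    for lab, idx in class_idx.items():
        k = target_counts[lab]
        scores = position[idx]
        # stable sort on -score gives lowest-index-first tie-breaking
        order = np.argsort(-scores, kind="stable")
        kept.append(idx[order[:k]])
    return np.sort(np.concatenate(kept))


def select_epochs(
    embedding: EmbeddingResult,
    labels: np.ndarray | None,
    selector: str,
    target_counts: dict,
    config=None,
    fitness=None,
) -> SelectedFeatures:
    """Select a fixed number of epochs per class by metaheuristic search.

    The optimizer works on a continuous inclusion-score vector in
    [0,1]^n; the retained subset is the per-class top-``target_count``
    scores, and the objective is the negated Fisher separability of that
    subset (a custom ``fitness(coords, labels)`` to *maximize* can be
    supplied instead).
    """
    labels = np.asarray(labels if labels is not None else embedding.labels)
    coords = embedding.coords
    n = coords.shape[0]
    class_idx = {
        lab: np.flatnonzero(labels == lab) for lab in dict.fromkeys(labels)
    }
    for lab, k in target_counts.items():
        if lab not in class_idx:
            raise ValueError(f"target count given for absent class {lab!r}")
        if not 1 <= k <= len(class_idx[lab]):
            raise ValueError(
                f"target count {k} for class {lab!r} is infeasible "
                f"({len(class_idx[lab])} candidates)"
            )
    score = fitness or fisher_separability

    def objective(position: np.ndarray) -> float:
        sub = _mask_to_subset(position, class_idx, target_counts, labels)
        return -score(coords[sub], labels[sub])

    key = selector.upper()
    if key == "CS":
        cfg = config or CuckooConfig()
        pos, _, trace = cuckoo_search_minimize(objective, cfg, n)
    elif key == "HSO":
        cfg = config or HarmonyConfig()
        pos, _, trace = harmony_search_minimize(objective, cfg, n)
    else:
        raise ValueError(f"unknown selector {selector!r}; expected CS or HSO")
    kept = _mask_to_subset(pos, class_idx, target_counts, labels)
    return SelectedFeatures(
        kept_ids=kept,
        fitness_trace=trace,
        selector=key,
        config=cfg,
        target_counts=dict(target_counts),
    )
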