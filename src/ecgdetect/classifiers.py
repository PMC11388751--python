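"""Seven two-class decision rules with a uniform fit/predict contract.

Families: Gaussian mixture model (GMM), expectation-maximization density
classifier (EM), nonlinear regression (NLR), logistic regression (LR),
Bayesian discriminant linear classifier (BDLC), detrended fluctuation
analysis (DFA) and firefly.  Every classifier is trained on feature rows
with binary labels (1 = arrhythmia, 0 = normal sinus rhythm), returns a
real-valued score per row, and assigns the positive class when the score
is greater than or equal to the family threshold (ties break toward the
arrhythmia class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("gmm", "em", "nlr", "lr", "bdlc", "dfa", "firefly")


def _validate_training_input(features: np.ndarray, labels: np.ndarray):
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    y = y.astype(int)
    classes = np.unique(y)
    if set(classes) - {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training data")
    return x, y


@dataclass
class TrainedClassifier:
    """Uniform prediction contract over all seven families.

    ``scores`` are family-specific (log-likelihood ratio, fitted
    probability or discriminant value); ``threshold`` is the hard-label
    cut, with score >= threshold mapped to the positive class.
    """

    family: str
    threshold: float
    n_features: int
    model: object

    def predict(self, features: np.ndarray):
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match the "
                f"{self.n_features} dimensions seen in training"
            )
        scores = self.model.score(x)
        return scores, (scores >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# GMM: one diagonal-covariance Gaussian mixture per class, own EM loop


@dataclass
class GMMConfig:
    n_components: int = 2
    max_iter: int = 100
    tol: float = 1e-6
    reg_covar: float = 1e-6
    seed: int = 0
    # tuned post-fit multipliers, each in [0, 1] (1 = fitted values)
    weight_scale: float = 1.0
    mean_scale: float = 1.0
    cov_scale: float = 1.0


class _DiagonalMixture:
    """Diagonal-covariance Gaussian mixture fitted by EM."""

    def __init__(self, n_components, max_iter, tol, reg, rng):
        self.k = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.rng = rng
        self.loglik_trace: list[float] = []

    def fit(self, x: np.ndarray) -> "_DiagonalMixture":
        n, d = x.shape
        k = min(self.k, n)
        pick = self.rng.choice(n, size=k, replace=False)
        self.means = x[pick].copy()
        self.covs = np.tile(x.var(axis=0) + self.reg, (k, 1))
        self.weights = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(self.max_iter):
            logp = self._component_logpdf(x)  # (n, k)
            tot = _logsumexp(logp + np.log(self.weights), axis=1)
            self.loglik_trace.append(float(tot.sum()))
            resp = np.exp(logp + np.log(self.weights) - tot[:, None])
            nk = resp.sum(axis=0) + 1e-12
            self.weights = nk / nk.sum()
            self.means = (resp.T @ x) / nk[:, None]
            self.covs = (resp.T @ (x ** 2)) / nk[:, None] - self.means ** 2
            self.covs = np.maximum(self.covs, self.reg)
            if self.loglik_trace[-1] - prev < self.tol * max(1.0, abs(prev)):
                break
            prev = self.loglik_trace[-1]
        return self

    def _component_logpdf(self, x):
        diff = x[:, None, :] - self.means[None, :, :]
        return -0.5 * (
            (diff ** 2 / self.covs[None]).sum(axis=2)
            + np.log(2 * np.pi * self.covs).sum(axis=1)[None, :]
        )

    def logpdf(self, x):
        return _logsumexp(
            self._component_logpdf(x) + np.log(self.weights), axis=1
        )

    def apply_scales(self, weight_scale, mean_scale, cov_scale):
        """Tuned scalar multipliers reshape the fitted parameters:
        weights are tempered by the exponent, means shrunk toward the
        mixture grand mean, covariances multiplied (floored away from 0)."""
        w = self.weights ** max(weight_scale, 1e-6)
        self.weights = w / w.sum()
        grand = (self.weights[:, None] * self.means).sum(axis=0)
        self.means = grand + mean_scale * (self.means - grand)
        self.covs = self.covs * max(cov_scale, 1e-3)


def _logsumexp(a, axis):
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


class _TwoClassDensityModel:
    """Classify by class-conditional log-likelihood plus log-prior."""

    def __init__(self, pos, neg, log_prior_pos, log_prior_neg):
        self.pos, self.neg = pos, neg
        self.lp_pos, self.lp_neg = log_prior_pos, log_prior_neg

    def score(self, x):
        return (self.pos.logpdf(x) + self.lp_pos) - (
            self.neg.logpdf(x) + self.lp_neg
        )


def fit_gmm(features, labels, config: GMMConfig | None = None) -> TrainedClassifier:
    cfg = config or GMMConfig()
    x, y = _validate_training_input(features, labels)
    rng = np.random.default_rng(cfg.seed)
    parts = {}
    for cls in (1, 0):
        mix = _DiagonalMixture(
            cfg.n_components, cfg.max_iter, cfg.tol, cfg.reg_covar, rng
        ).fit(x[y == cls])
        mix.apply_scales(cfg.weight_scale, cfg.mean_scale, cfg.cov_scale)
        parts[cls] = mix
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    model = _TwoClassDensityModel(
        parts[1], parts[0], np.log(priors[1]), np.log(priors[0])
    )
    model.mixtures = parts
    return TrainedClassifier("gmm", 0.0, x.shape[1], model)


# ---------------------------------------------------------------------------
# EM density classifier: per-class diagonal Gaussian fitted by EM with
# support for missing feature entries (NaN)


@dataclass
class EMConfig:
    max_iter: int = 50
    tol: float = 1e-8
    reg_covar: float = 1e-6
    cov_scale: float = 1.0  # tuned multiplier in [0, 1]


class _EMGaussian:
    """Single diagonal Gaussian; missing entries handled by EM
    (expected sufficient statistics under the current fit).  With no
    missing data the first M-step is the closed-form fit."""

    def __init__(self, max_iter, tol, reg):
        self.max_iter, self.tol, self.reg = max_iter, tol, reg
        self.loglik_trace: list[float] = []

    def fit(self, x: np.ndarray) -> "_EMGaussian":
        miss = np.isnan(x)
        d = x.shape[1]
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        self.mean = col_mean.copy()
        var = np.nanvar(x, axis=0)
        self.var = np.where(np.isfinite(var), var, 1.0) + self.reg
        if not miss.any():
            self.loglik_trace.append(self._observed_loglik(x, miss))
            return self
        prev = -np.inf
        for _ in range(self.max_iter):
            # E-step: expected values and second moments of missing entries
            xe = np.where(miss, self.mean[None, :], x)
            second = xe ** 2 + np.where(miss, self.var[None, :], 0.0)
            # M-step
            self.mean = xe.mean(axis=0)
            self.var = np.maximum(second.mean(axis=0) - self.mean ** 2, self.reg)
            ll = self._observed_loglik(x, miss)
            self.loglik_trace.append(ll)
            if ll - prev < self.tol * max(1.0, abs(prev)):
                break
            prev = ll
        return self

    def _observed_loglik(self, x, miss):
        obs = ~miss
        z = np.where(obs, (x - self.mean[None, :]) ** 2 / self.var[None, :], 0.0)
        logdet = np.where(obs, np.log(2 * np.pi * self.var[None, :]), 0.0)
        return float(-0.5 * (z + logdet).sum())

    def logpdf(self, x):
        z = (x - self.mean[None, :]) ** 2 / self.var[None, :]
        return -0.5 * (z + np.log(2 * np.pi * self.var)[None, :]).sum(axis=1)


def fit_em(features, labels, config: EMConfig | None = None) -> TrainedClassifier:
    cfg = config or EMConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training data")
    if np.isinf(x).any():
        raise ValueError("features contain infinite values")
    parts = {}
    for cls in (1, 0):
        g = _EMGaussian(cfg.max_iter, cfg.tol, cfg.reg_covar).fit(x[y == cls])
        g.var = g.var * max(cfg.cov_scale, 1e-3)
        parts[cls] = g
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    model = _TwoClassDensityModel(
        parts[1], parts[0], np.log(priors[1]), np.log(priors[0])
    )
    model.gaussians = parts
    return TrainedClassifier("em", 0.0, x.shape[1], model)


# ---------------------------------------------------------------------------
# NLR: saturation model g(a; g1, g2) = g1 * a / (g2 + a) on a scalar
# discriminant projection of the features


@dataclass
class NLRConfig:
    max_iter: int = 200
    threshold: float = 0.5


class _NLRModel:
    def __init__(self, direction, offset, scale, g1, g2, sigma2):
        self.direction, self.offset, self.scale = direction, offset, scale
        self.g1, self.g2, self.sigma2 = g1, g2, sigma2

    def project(self, x):
        a = x @ self.direction
        return np.clip((a - self.offset) / self.scale, 0.0, 1.0)

    def score(self, x):
        a = self.project(x)
        return self.g1 * a / (self.g2 + a)


def fit_nlr(features, labels, config: NLRConfig | None = None) -> TrainedClassifier:
    """Least-squares fit of the saturation response to 0/1 labels.

    The multivariate features are first projected onto the pooled-
    variance-scaled difference of class means and min-max mapped to
    [0, 1], so larger a means more arrhythmia-like.
    """
    from scipy.optimize import least_squares

    cfg = config or NLRConfig()
    x, y = _validate_training_input(features, labels)
    pooled = x.var(axis=0) + 1e-9
    direction = (x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0)) / pooled
    a_raw = x @ direction
    offset, span = a_raw.min(), a_raw.max() - a_raw.min()
    span = span if span > 0 else 1.0
    a = (a_raw - offset) / span

    def resid(p):
        return p[0] * a / (p[1] + a) - y

    sol = least_squares(
        resid, x0=[1.0, 0.5], bounds=([-10.0, 1e-6], [10.0, 10.0]),
        max_nfev=cfg.max_iter * 10,
    )
    g1, g2 = sol.x
    sigma2 = float(np.mean(resid(sol.x) ** 2))
    model = _NLRModel(direction, offset, span, float(g1), float(g2), sigma2)
    return TrainedClassifier("nlr", cfg.threshold, x.shape[1], model)


# ---------------------------------------------------------------------------
# LR: ridge-penalized logistic regression by IRLS with step halving


@dataclass
class LRConfig:
    alpha: float = 0.01
    max_iter: int = 100
    tol: float = 1e-8
    threshold: float = 0.5


class _LRModel:
    def __init__(self, coef, intercept):
        self.coef, self.intercept = coef, intercept

    def score(self, x):
        eta = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def _penalized_deviance(eta, y, beta, alpha):
    # -2 * penalized log-likelihood
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return float(-2.0 * (ll - 0.5 * alpha * np.sum(beta[1:] ** 2)))


def fit_lr(features, labels, config: LRConfig | None = None) -> TrainedClassifier:
    cfg = config or LRConfig()
    x, y = _validate_training_input(features, labels)
    n, d = x.shape
    f = np.hstack([np.ones((n, 1)), x])  # intercept column, unpenalized
    beta = np.zeros(d + 1)
    pen = np.diag([0.0] + [cfg.alpha] * d)
    dev_trace = [_penalized_deviance(f @ beta, y, beta, cfg.alpha)]
    for _ in range(cfg.max_iter):
        eta = f @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = f.T @ (y - p) - pen @ beta
        hess = (f * w[:, None]).T @ f + pen
        step = np.linalg.solve(hess, grad)
        # Newton step with halving until the penalized deviance decreases
        t = 1.0
        while t > 1e-8:
            cand = beta + t * step
            dev = _penalized_deviance(f @ cand, y, cand, cfg.alpha)
            if dev < dev_trace[-1]:
                break
            t /= 2.0
        else:
            break
        beta = cand
        dev_trace.append(dev)
        if dev_trace[-2] - dev_trace[-1] < cfg.tol * max(1.0, abs(dev_trace[-1])):
            break
    model = _LRModel(beta[1:], float(beta[0]))
    model.deviance_trace = dev_trace
    model.deviance = dev_trace[-1]
    # observed-information standard errors at the optimum
    eta = f @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.maximum(p * (1 - p), 1e-10)
    cov = np.linalg.inv((f * w[:, None]).T @ f + pen)
    model.standard_errors = np.sqrt(np.diag(cov))
    return TrainedClassifier("lr", cfg.threshold, d, model)


# ---------------------------------------------------------------------------
# BDLC: linear discriminant from pooled covariance, thresholded at M


@dataclass
class BDLCConfig:
    threshold_M: float = 0.0
    priors: tuple[float, float] | None = None  # (negative, positive)
    reg: float = 1e-6
    # tuned multipliers in [0, 1]
    mean_scale: float = 1.0
    cov_scale: float = 1.0


class _BDLCModel:
    def __init__(self, mu_pos, mu_neg, cov_inv, log_prior_pos, log_prior_neg):
        self.mu_pos, self.mu_neg = mu_pos, mu_neg
        self.cov_inv = cov_inv
        self.lp_pos, self.lp_neg = log_prior_pos, log_prior_neg

    def _disc(self, x, mu, lp):
        diff = x - mu[None, :]
        return -0.5 * np.einsum("ij,jk,ik->i", diff, self.cov_inv, diff) + lp

    def score(self, x):
        return self._disc(x, self.mu_pos, self.lp_pos) - self._disc(
            x, self.mu_neg, self.lp_neg
        )


def fit_bdlc(features, labels, config: BDLCConfig | None = None) -> TrainedClassifier:
    cfg = config or BDLCConfig()
    x, y = _validate_training_input(features, labels)
    mu_pos = x[y == 1].mean(axis=0)
    mu_neg = x[y == 0].mean(axis=0)
    grand = x.mean(axis=0)
    mu_pos = grand + cfg.mean_scale * (mu_pos - grand)
    mu_neg = grand + cfg.mean_scale * (mu_neg - grand)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    cov = (
        (x[y == 1] - mu_pos).T @ (x[y == 1] - mu_pos)
        + (x[y == 0] - mu_neg).T @ (x[y == 0] - mu_neg)
    ) / (n_pos + n_neg - 2)
    cov = cov * max(cfg.cov_scale, 1e-3) + cfg.reg * np.eye(x.shape[1])
    if cfg.priors is None:
        priors = (n_neg / len(y), n_pos / len(y))
    else:
        priors = cfg.priors
    model = _BDLCModel(
        mu_pos, mu_neg, np.linalg.inv(cov), np.log(priors[1]), np.log(priors[0])
    )
    return TrainedClassifier("bdlc", cfg.threshold_M, x.shape[1], model)


# ---------------------------------------------------------------------------
# DFA: scaling exponent of the detrended cumulative profile


def default_scales(n: int, order: int = 1, n_scales: int = 8) -> np.ndarray:
    """Log-spaced window sizes from order+2 up to n//4."""
    lo, hi = order + 2, max(n // 4, order + 3)
    s = np.unique(np.round(np.geomspace(lo, hi, n_scales)).astype(int))
    return s


def dfa_exponent(series: np.ndarray, scales=None, order: int = 1,
                 return_fluctuations: bool = False):
    """Detrended-fluctuation scaling exponent of one series.

    Builds the cumulative profile, detrends non-overlapping windows of
    each scale with an order-``order`` polynomial, takes the root-mean-
    square fluctuation per scale, and returns the slope of log
    fluctuation against log scale (about 0.5 for white noise, 1.5 for a
    random walk).
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if scales is None:
        scales = default_scales(n, order)
    scales = np.asarray(scales, dtype=int)
    if len(scales) < 4:
        raise ValueError("need at least 4 scales for the log-log fit")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    if scales[0] < order + 2:
        raise ValueError(f"smallest scale must be >= order+2 = {order + 2}")
    if scales[-1] > n:
        raise ValueError(f"scale {scales[-1]} exceeds series length {n}")
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(len(scales))
    for si, u in enumerate(scales):
        q = n // u
        seg = profile[: q * u].reshape(q, u)
        t = np.arange(u)
        # least-squares polynomial detrending per window
        coeffs = np.polynomial.polynomial.polyfit(t, seg.T, order)
        trend = np.polynomial.polynomial.polyval(t, coeffs)
        flucts[si] = np.sqrt(np.mean((seg - trend) ** 2))
    slope = np.polyfit(np.log(scales), np.log(np.maximum(flucts, 1e-300)), 1)[0]
    if return_fluctuations:
        return float(slope), scales, flucts
    return float(slope)


@dataclass
class DFAConfig:
    order: int = 1
    scales: np.ndarray | None = None


class _DFAModel:
    def __init__(self, order, scales, threshold_sign):
        self.order, self.scales = order, scales
        self.sign = threshold_sign  # +1 if arrhythmia exponents are larger

    def exponents(self, x):
        return np.array([dfa_exponent(row, self.scales, self.order) for row in x])

    def score(self, x):
        return self.sign * self.exponents(x)


def fit_dfa(features, labels, config: DFAConfig | None = None) -> TrainedClassifier:
    """Threshold the per-epoch scaling exponent at the midpoint of the
    class-mean exponents from training."""
    cfg = config or DFAConfig()
    x, y = _validate_training_input(features, labels)
    model = _DFAModel(cfg.order, cfg.scales, +1)
    exps = model.exponents(x)
    mean_pos, mean_neg = exps[y == 1].mean(), exps[y == 0].mean()
    mid = 0.5 * (mean_pos + mean_neg)
    if mean_pos >= mean_neg:
        return TrainedClassifier("dfa", mid, x.shape[1], model)
    model.sign = -1
    return TrainedClassifier("dfa", -mid, x.shape[1], model)


# ---------------------------------------------------------------------------
# Firefly: swarm optimizer plus a centroid-pair decision rule


@dataclass
class FireflyConfig:
    population: int = 40
    max_iter: int = 1000
    beta_absorption: float = 1.0
    alpha0: float = 1.0
    alpha_min: float = 0.0
    gamma_rand: float = 0.2
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.alpha_min <= self.alpha0:
            raise ValueError("need 0 <= alpha_min <= alpha0")


def attractiveness(p, alpha0: float, beta: float, alpha_min: float = 0.0):
    """alpha(p) = alpha_min + (alpha0 - alpha_min) * exp(-beta p^2)."""
    return alpha_min + (alpha0 - alpha_min) * np.exp(-beta * np.asarray(p) ** 2)


def firefly_optimize(objective, config: FireflyConfig, dim: int,
                     lower=0.0, upper=1.0):
    """Minimize ``objective`` over a box by the firefly algorithm.

    Brightness is the negated objective; per generation each firefly
    moves toward every brighter one with coefficient ``attractiveness``
    of their distance plus a uniform randomization term
    gamma*(rand - 1/2)*scale.  Returns (best_position, best_value,
    best-so-far trace).
    """
    rng = np.random.default_rng(config.seed)
    lower = np.broadcast_to(np.asarray(lower, dtype=float), dim).copy()
    upper = np.broadcast_to(np.asarray(upper, dtype=float), dim).copy()
    z = rng.uniform(lower, upper, (config.population, dim))
    vals = np.array([_check_finite_ff(objective(p), p) for p in z])
    best_i = int(np.argmin(vals))
    best_pos, best_val = z[best_i].copy(), float(vals[best_i])
    trace = [best_val]
    span = upper - lower
    for it in range(config.max_iter):
        # cool the randomization over iterations for convergence
        jitter = config.gamma_rand * (0.97 ** it)
        order = np.argsort(vals)
        for m in range(config.population):
            moved = z[m].copy()
            for nidx in order:
                if vals[nidx] < vals[m]:
                    p = np.linalg.norm(z[nidx] - moved)
                    a = attractiveness(
                        p, config.alpha0, config.beta_absorption, config.alpha_min
                    )
                    moved = (
                        moved
                        + a * (z[nidx] - moved)
                        + jitter * (rng.uniform(0, 1, dim) - 0.5) * config.scale * span
                    )
            moved = np.clip(moved, lower, upper)
            val = _check_finite_ff(objective(moved), moved)
            z[m], vals[m] = moved, val
            if val < best_val:
                best_pos, best_val = moved.copy(), float(val)
        trace.append(best_val)
    return best_pos, best_val, np.array(trace)


def _check_finite_ff(val, pos):
    if not np.isfinite(val):
        raise ValueError(f"objective returned non-finite value {val} at {pos}")
    return float(val)


class _FireflyModel:
    def __init__(self, c_pos, c_neg, threshold):
        self.c_pos, self.c_neg = c_pos, c_neg
        self.threshold = threshold

    def score(self, x):
        d_pos = np.linalg.norm(x - self.c_pos[None, :], axis=1)
        d_neg = np.linalg.norm(x - self.c_neg[None, :], axis=1)
        return d_neg - d_pos - self.threshold


def fit_firefly(features, labels, config: FireflyConfig | None = None) -> TrainedClassifier:
    """Firefly-optimized decision rule: a centroid pair plus threshold
    minimizing the training error rate."""
    cfg = config or FireflyConfig()
    x, y = _validate_training_input(features, labels)
    d = x.shape[1]
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    radius = float(np.linalg.norm(span))
    lower = np.concatenate([lo, lo, [-radius]])
    upper = np.concatenate([hi, hi, [radius]])

    def objective(pos):
        model = _FireflyModel(pos[:d], pos[d: 2 * d], pos[-1])
        pred = (model.score(x) >= 0).astype(int)
        return float((pred != y).mean())

    best, best_val, trace = firefly_optimize(
        objective, cfg, 2 * d + 1, lower, upper
    )
    model = _FireflyModel(best[:d], best[d: 2 * d], best[-1])
    model.training_error = best_val
    model.trace = trace
    return TrainedClassifier("firefly", 0.0, d, model)


# ---------------------------------------------------------------------------

_FITTERS = {
    "gmm": fit_gmm,
    "em": fit_em,
    "nlr": fit_nlr,
    "lr": fit_lr,
    "bdlc": fit_bdlc,
    "dfa": fit_dfa,
    "firefly": fit_firefly,
}

DEFAULT_CONFIGS = {
    "gmm": GMMConfig,
    "em": EMConfig,
    "nlr": NLRConfig,
    "lr": LRConfig,
    "bdlc": BDLCConfig,
    "dfa": DFAConfig,
    "firefly": FireflyConfig,
}


def fit(features, labels, family: str, config=None) -> TrainedClassifier:
    """Train one of the seven families on binary-labelled feature rows."""
    key = family.lower()
    if key not in _FITTERS:
        raise ValueError(f"unknown classifier family {family!r}; expected one of {FAMILIES}")
    return _FITTERS[key](features, labels, config)


def predict(model: TrainedClassifier, features):
    """Scores and hard labels for feature rows (see TrainedClassifier)."""
    return model.predict(features)
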