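"""Indirect reference-interval estimation from a mixed laboratory distribution.

The estimator assumes the post-filter values are a mixture of a dominant
healthy component and residual pathological contamination, and composes:

1. outlier removal with a medcouple-adjusted (skewness-aware) boxplot;
2. transform selection (identity or Box-Cox on a coarse lambda grid) gated
   on sample skewness and excess kurtosis;
3. Gaussian mixture deconvolution on the transformed scale by EM with BIC
   component selection;
4. kernel-density mode/antimode detection;
5. a truncation window around the healthy component where its posterior
   responsibility stays >= 0.5, with flanking antimodes overriding the
   responsibility boundaries when they fall inside them;
6. nonparametric percentiles (CLSI rank r = p(n+1), linear interpolation)
   of the raw values inside the window; and
7. seeded percentile-bootstrap 90% confidence intervals for both bounds.

With a single mixture component the window is the full data range and the
estimate reduces exactly to plain nonparametric percentiles of the
outlier-cleaned sample.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.stats.stattools import medcouple

logger = logging.getLogger(__name__)

__all__ = [
    "RIConfig", "TransformSpec", "MixtureModel", "ModesInfo",
    "TruncationWindow", "ReferenceIntervalEstimate",
    "detect_outliers", "select_transform", "fit_mixture",
    "find_modes_antimodes", "choose_truncation", "estimate_percentile_ri",
    "bootstrap_ci", "run_indirect_ri",
]


@dataclass(frozen=True)
class RIConfig:
    """Tunables of the indirect pipeline (defaults are the study settings)."""

    # outlier fences: Tukey multiplier and medcouple exponents
    fence_multiplier: float = 1.5
    medcouple_max_n: int = 5000
    # transform gating
    skewness_gate: float = 0.5
    kurtosis_gate: float = 1.0
    boxcox_grid: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    # mixture fit
    k_max: int = 4
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    n_restarts: int = 5
    # density scan
    kde_gridsize: int = 512
    # truncation
    responsibility_threshold: float = 0.5
    # percentiles and CIs
    probs: tuple = (0.025, 0.975)
    min_n_window: int = 120       # CLSI minimum reference sample size
    ci_level: float = 0.90
    n_boot: int = 1000


DEFAULT_CONFIG = RIConfig()


# ---------------------------------------------------------------------------
# transforms

@dataclass(frozen=True)
class TransformSpec:
    """A monotone symmetrizing transform: identity or Box-Cox(lambda)."""

    family: str = "identity"           # {"identity", "box_cox"}
    lam: float | None = None
    offset: float = 0.0                # added before the transform

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "identity":
            return x
        y = x + self.offset
        if self.lam == 0.0:
            return np.log(y)
        return (np.power(y, self.lam) - 1.0) / self.lam

    def invert(self, y):
        y = np.asarray(y, dtype=float)
        if self.family == "identity":
            return y
        if self.lam == 0.0:
            return np.exp(y) - self.offset
        return np.power(self.lam * y + 1.0, 1.0 / self.lam) - self.offset

    def to_dict(self) -> dict:
        return {"family": self.family, "lam": self.lam, "offset": self.offset}


# ---------------------------------------------------------------------------
# outliers

def detect_outliers(values, config: RIConfig = DEFAULT_CONFIG):
    """Medcouple-adjusted boxplot outlier removal on the raw scale.

    Fences are Tukey's 1.5*IQR stretched asymmetrically by the medcouple MC
    (a robust skewness measure): for MC >= 0 the fences are
    ``[Q1 - 1.5 exp(-4 MC) IQR, Q3 + 1.5 exp(3 MC) IQR]`` and mirrored for
    MC < 0, so a clean right-skewed sample is not mass-deleted. For n above
    ``medcouple_max_n`` the medcouple is computed on that many evenly spaced
    order statistics (the full pairwise kernel is quadratic in n).

    Returns ``(kept, removed)`` arrays partitioning the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError(f"need at least 20 values for outlier detection, got {x.size}")
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        return x.copy(), np.array([], dtype=float)
    if xs.size > config.medcouple_max_n:
        idx = np.linspace(0, xs.size - 1, config.medcouple_max_n).round().astype(int)
        mc = float(medcouple(xs[idx]))
    else:
        mc = float(medcouple(xs))
    q1, q3 = np.quantile(xs, [0.25, 0.75])
    iqr = q3 - q1
    c = config.fence_multiplier
    if mc >= 0:
        lo = q1 - c * math.exp(-4.0 * mc) * iqr
        hi = q3 + c * math.exp(3.0 * mc) * iqr
    else:
        lo = q1 - c * math.exp(-3.0 * mc) * iqr
        hi = q3 + c * math.exp(4.0 * mc) * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


# ---------------------------------------------------------------------------
# transform selection

def select_transform(values, config: RIConfig = DEFAULT_CONFIG) -> TransformSpec:
    """Pick identity or a Box-Cox transform after skewness/kurtosis analysis.

    Identity when |skewness| <= skewness_gate and |excess kurtosis| <=
    kurtosis_gate; otherwise the Box-Cox lambda from ``boxcox_grid``
    minimizing the absolute skewness of the transformed sample. An offset
    is applied first when any value is <= 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or np.ptp(x) == 0.0:
        warnings.warn("degenerate (constant) sample; using identity transform")
        return TransformSpec()
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x))
    if abs(skew) <= config.skewness_gate and abs(kurt) <= config.kurtosis_gate:
        return TransformSpec()
    offset = 0.0
    if x.min() <= 0:
        offset = -float(x.min()) + 1e-6 * float(np.ptp(x))
    best_lam, best_skew = None, math.inf
    for lam in config.boxcox_grid:
        t = TransformSpec("box_cox", lam, offset).apply(x)
        s = abs(float(stats.skew(t)))
        if s < best_skew:
            best_lam, best_skew = lam, s
    return TransformSpec("box_cox", float(best_lam), offset)


# ---------------------------------------------------------------------------
# Gaussian mixture EM

@dataclass
class MixtureModel:
    """A k-component Gaussian mixture on the transformed scale."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be positive")

    def log_component_densities(self, x) -> np.ndarray:
        """(k, n) matrix of log(w_j * phi_j(x))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[None, :] - self.means[:, None]) / self.sds[:, None]
        return (np.log(self.weights)[:, None]
                - 0.5 * z * z - np.log(self.sds)[:, None]
                - 0.5 * math.log(2.0 * math.pi))
    def pdf(self, x) -> np.ndarray:
        return np.exp(logsumexp(self.log_component_densities(x), axis=0))

    def responsibility(self, x, component) -> np.ndarray:
        """Posterior probability that x belongs to ``component``.

        ``component`` may be an index or a sequence of indices; a sequence
        gives the summed (cluster) responsibility.
        """
        lcd = self.log_component_densities(x)
        idx = np.atleast_1d(component)
        return np.exp(logsumexp(lcd[idx], axis=0) - logsumexp(lcd, axis=0))

    def to_dict(self) -> dict:
        return {
            "k": self.k, "weights": self.weights.tolist(),
            "means": self.means.tolist(), "sds": self.sds.tolist(),
            "loglik": self.loglik, "bic": self.bic,
            "converged": self.converged, "n_iter": self.n_iter,
        }


def _em_once(x: np.ndarray, k: int, rng: np.random.Generator, jitter: bool,
             config: RIConfig):
    """One EM run from a quantile-spread initialization.

    Returns (weights, means, sds, loglik, n_iter, converged). The
    log-likelihood is monotone non-decreasing across iterations (asserted
    in debug mode).
    """
    n = x.size
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    means = np.array([b.mean() for b in blocks])
    overall_sd = max(float(x.std()), 1e-12)
    sds = np.array([max(float(b.std()), 0.05 * overall_sd) for b in blocks])
    if jitter:
        means = means + 0.25 * sds * rng.standard_normal(k)
    weights = np.full(k, 1.0 / k)
    sd_floor = max(1e-8 * (xs[-1] - xs[0]), 1e-12)

    loglik = -math.inf
    converged = False
    it = 0
    for it in range(1, config.em_max_iter + 1):
        z = (x[None, :] - means[:, None]) / sds[:, None]
        log_dens = (np.log(weights)[:, None] - 0.5 * z * z
                    - np.log(sds)[:, None] - 0.5 * math.log(2.0 * math.pi))
        log_norm = logsumexp(log_dens, axis=0)
        new_loglik = float(log_norm.sum())
        assert new_loglik >= loglik - 1e-6 * abs(loglik), \
            "EM log-likelihood decreased"
        resp = np.exp(log_dens - log_norm[None, :])
        nj = resp.sum(axis=1)
        nj = np.maximum(nj, 1e-10)
        weights = nj / nj.sum()
        means = resp @ x / nj
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nj
        sds = np.maximum(np.sqrt(var), sd_floor)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= config.em_tol * abs(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return weights, means, sds, loglik, it, converged


def fit_mixture(values_transformed, k_max: int | None = None, seed=0,
                config: RIConfig = DEFAULT_CONFIG) -> MixtureModel:
    """Fit Gaussian mixtures for k = 1..k_max by EM; return the BIC minimizer.

    Each k uses ``n_restarts`` seeded restarts from quantile-spread
    initializations (the first unjittered). k = 1 is the closed-form
    normal fit. BIC = -2 loglik + (3k - 1) log n.
    """
    x = np.asarray(values_transformed, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 values to fit a mixture, got {x.size}")
    k_max = k_max if k_max is not None else config.k_max
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = x.size
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    for k in range(1, k_max + 1):
        if k == 1:
            mu, sd = float(x.mean()), max(float(x.std()), 1e-12)
            ll = float(stats.norm.logpdf(x, mu, sd).sum())
            cand = (np.array([1.0]), np.array([mu]), np.array([sd]), ll, 0, True)
        else:
            cand = None
            for r in range(config.n_restarts):
                try:
                    run = _em_once(x, k, rng, jitter=(r > 0), config=config)
                except FloatingPointError:  # pragma: no cover - defensive
                    continue
                if cand is None or run[3] > cand[3]:
                    cand = run
        if cand is None:  # pragma: no cover - defensive
            continue
        weights, means, sds, ll, n_iter, converged = cand
        bic = -2.0 * ll + (3 * k - 1) * math.log(n)
        model = MixtureModel(k=k, weights=weights, means=means, sds=sds,
                             loglik=ll, bic=bic, converged=converged,
                             n_iter=n_iter)
        logger.debug("k=%d loglik=%.3f bic=%.3f iter=%d converged=%s",
                     k, ll, bic, n_iter, converged)
        if best is None or model.bic < best.bic:
            best = model
    if not best.converged:
        warnings.warn("EM did not converge on any restart; returning best fit")
    return best


# ---------------------------------------------------------------------------
# modes and antimodes

@dataclass
class ModesInfo:
    """Kernel-density modes/antimodes on the transformed scale."""

    modes: np.ndarray
    antimodes: np.ndarray
    grid: np.ndarray
    density: np.ndarray

    @property
    def global_mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def find_modes_antimodes(values_transformed,
                         config: RIConfig = DEFAULT_CONFIG) -> ModesInfo:
    """Locate modes and antimodes of a Gaussian-KDE density estimate.

    Silverman-bandwidth KDE evaluated on a ``kde_gridsize``-point grid;
    modes are interior local maxima, antimodes interior local minima
    strictly between the outermost modes, so the two strictly interleave.
    """
    x = np.asarray(values_transformed, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 values for mode detection, got {x.size}")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), config.kde_gridsize)
    dens = kde(grid)
    d = np.diff(dens)
    rising, falling = d > 0, d < 0
    maxima = np.where(rising[:-1] & falling[1:])[0] + 1
    minima = np.where(falling[:-1] & rising[1:])[0] + 1
    if maxima.size == 0:  # monotone density on the grid: take the boundary max
        maxima = np.array([int(np.argmax(dens))])
    modes = grid[maxima]
    antimodes = np.array([
        grid[i] for i in minima if modes.min() < grid[i] < modes.max()
    ])
    return ModesInfo(modes=modes, antimodes=antimodes, grid=grid, density=dens)


# ---------------------------------------------------------------------------
# truncation

@dataclass
class TruncationWindow:
    """Raw-scale interval isolating the presumed-healthy subpopulation."""

    lower: float
    upper: float
    lower_source: str   # {"posterior_responsibility", "antimode", "data_extreme"}
    upper_source: str
    healthy_component: int = 0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("truncation window must satisfy lower < upper")

    @property
    def source(self) -> str:
        return (self.lower_source if self.lower_source == self.upper_source
                else f"{self.lower_source}/{self.upper_source}")

    def to_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper,
                "lower_source": self.lower_source,
                "upper_source": self.upper_source,
                "healthy_component": self.healthy_component}


def _healthy_component(mixture: MixtureModel, modes_info: ModesInfo) -> int:
    """Representative healthy component: heaviest component of the
    heaviest mode basin.

    Antimodes partition the axis into basins; each component is assigned to
    the basin holding its mean. The healthy basin is the one carrying the
    greatest total mixture weight — the indirect method's premise that the
    dominant subpopulation is the physiological one — and the component
    with maximum weight inside it is the representative.
    """
    basins = np.searchsorted(np.sort(modes_info.antimodes), mixture.means)
    totals = np.bincount(basins, weights=mixture.weights)
    healthy_basin = int(np.argmax(totals))
    members = np.where(basins == healthy_basin)[0]
    return int(members[np.argmax(mixture.weights[members])])


def choose_truncation(mixture: MixtureModel, modes_info: ModesInfo,
                      transform: TransformSpec, values,
                      config: RIConfig = DEFAULT_CONFIG) -> TruncationWindow:
    """Determine the truncation window for the healthy component.

    Combines the mixture fit with the mode/antimode scan. The antimodes of
    the kernel density partition the transformed axis into mode basins;
    mixture components whose means share the basin of the healthy
    component describe the same population (a skewed or platykurtic
    healthy distribution fitted by several overlapping Gaussians) and are
    merged, so the truncation uses the *cluster* posterior responsibility.
    With well-separated components — each in its own basin — this reduces
    to the single-component responsibility rule.

    The window is the contiguous transformed-scale interval around the
    healthy component's mean where the cluster responsibility stays at or
    above the threshold (0.5). A side where responsibility never drops
    below the threshold ends at the data extreme. Flanking antimodes
    override responsibility boundaries when they lie strictly inside them.
    The window is returned on the raw scale and always contains the healthy
    component's back-transformed mean.
    """
    x = np.asarray(values, dtype=float)
    raw_lo, raw_hi = float(x.min()), float(x.max())
    if mixture.k == 1:
        return TruncationWindow(raw_lo, raw_hi, "data_extreme", "data_extreme", 0)

    t = transform.apply(x)
    t_lo, t_hi = float(t.min()), float(t.max())
    h = _healthy_component(mixture, modes_info)
    mu_h = float(mixture.means[h])
    thr = config.responsibility_threshold

    basins = np.searchsorted(np.sort(modes_info.antimodes), mixture.means)
    cluster = np.where(basins == basins[h])[0]

    def resp(u):
        return float(mixture.responsibility(u, cluster)[0])

    grid = np.linspace(t_lo, t_hi, 2048)
    rr = mixture.responsibility(grid, cluster)
    anchor = int(np.clip(np.searchsorted(grid, mu_h), 0, grid.size - 1))
    if rr[anchor] < thr:  # fall back to the most responsible point
        anchor = int(np.argmax(rr))
    above = rr >= thr

    # walk out from the anchor to the edges of its contiguous above-threshold run
    i = anchor
    while i > 0 and above[i - 1]:
        i -= 1
    j = anchor
    while j < grid.size - 1 and above[j + 1]:
        j += 1

    if i == 0:
        lo_t, lo_src = t_lo, "data_extreme"
    else:
        lo_t = float(optimize.brentq(lambda u: resp(u) - thr, grid[i - 1], grid[i]))
        lo_src = "posterior_responsibility"
    if j == grid.size - 1:
        hi_t, hi_src = t_hi, "data_extreme"
    else:
        hi_t = float(optimize.brentq(lambda u: resp(u) - thr, grid[j], grid[j + 1]))
        hi_src = "posterior_responsibility"

    flank_lo = modes_info.antimodes[modes_info.antimodes < mu_h]
    if flank_lo.size and float(flank_lo.max()) > lo_t:
        lo_t, lo_src = float(flank_lo.max()), "antimode"
    flank_hi = modes_info.antimodes[modes_info.antimodes > mu_h]
    if flank_hi.size and float(flank_hi.min()) < hi_t:
        hi_t, hi_src = float(flank_hi.min()), "antimode"

    lower = raw_lo if lo_src == "data_extreme" else float(transform.invert(lo_t))
    upper = raw_hi if hi_src == "data_extreme" else float(transform.invert(hi_t))
    mean_raw = float(transform.invert(mu_h))
    if not (lower <= mean_raw <= upper):  # pragma: no cover - defensive
        raise RuntimeError("truncation window does not contain the healthy mean")
    return TruncationWindow(lower, upper, lo_src, hi_src, h)


# ---------------------------------------------------------------------------
# percentiles and bootstrap

def _in_window(values, window: TruncationWindow) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[(x >= window.lower) & (x <= window.upper)]


def estimate_percentile_ri(values, window: TruncationWindow,
                           probs=(0.025, 0.975),
                           config: RIConfig = DEFAULT_CONFIG):
    """Nonparametric percentiles of the within-window values.

    Uses the CLSI rank convention r = p(n+1) with linear interpolation
    between order statistics, clamped to [1, n] (numpy's "weibull"
    definition). Requires at least ``min_n_window`` in-window values.
    """
    inside = _in_window(values, window)
    if inside.size < config.min_n_window:
        raise ValueError(
            f"only {inside.size} values inside the truncation window; "
            f"need at least {config.min_n_window}")
    lo, hi = np.quantile(inside, probs, method="weibull")
    return float(lo), float(hi)


def bootstrap_ci(values_in_window, probs=(0.025, 0.975), level: float = 0.90,
                 n_boot: int = 1000, seed=0,
                 config: RIConfig = DEFAULT_CONFIG):
    """Seeded percentile-bootstrap CIs for each reference-interval bound.

    Resamples the in-window values ``n_boot`` times with replacement,
    recomputes both r = p(n+1) percentiles per resample, and reports the
    central ``level`` span of each bootstrap distribution.

    Returns ``(lower_ci, upper_ci)`` as (lo, hi) pairs.
    """
    x = np.asarray(values_in_window, dtype=float)
    if x.size < config.min_n_window:
        raise ValueError(
            f"need at least {config.min_n_window} in-window values, got {x.size}")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    ests = np.empty((n_boot, len(probs)))
    chunk = max(1, int(2e7 // x.size))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        res = rng.choice(x, size=(m, x.size), replace=True)
        ests[done:done + m] = np.quantile(res, probs, axis=1, method="weibull").T
        done += m
    cis = np.quantile(ests, [alpha, 1.0 - alpha], axis=0)
    return ((float(cis[0, 0]), float(cis[1, 0])),
            (float(cis[0, 1]), float(cis[1, 1])))


# ---------------------------------------------------------------------------
# the composed pipeline

@dataclass
class ReferenceIntervalEstimate:
    """A reference interval with provenance for every pipeline stage."""

    lower: float
    upper: float
    lower_ci: tuple
    upper_ci: tuple
    n_input: int
    n_after_outliers: int
    n_in_window: int
    percentiles: tuple
    transform: TransformSpec
    mixture: MixtureModel
    window: TruncationWindow
    seed: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("reference interval must satisfy lower < upper")
        if not self.n_input >= self.n_after_outliers >= self.n_in_window:
            raise ValueError("stage counts must be non-increasing")

    def to_dict(self) -> dict:
        return {
            "lower": self.lower, "upper": self.upper,
            "lower_ci": list(self.lower_ci), "upper_ci": list(self.upper_ci),
            "n_input": self.n_input,
            "n_after_outliers": self.n_after_outliers,
            "n_in_window": self.n_in_window,
            "percentiles": list(self.percentiles),
            "transform": self.transform.to_dict(),
            "mixture": self.mixture.to_dict(),
            "window": self.window.to_dict(),
            "seed": self.seed,
        }


def _staged(name: str, fn, *args, **kwargs):
    """Run one pipeline stage, prefixing any error with the stage name."""
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        if str(exc).startswith("stage "):
            raise
        try:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
        except TypeError:
            raise RuntimeError(f"stage {name!r}: {exc}") from exc


def run_indirect_ri(values, config: RIConfig = DEFAULT_CONFIG,
                    seed: int = 0) -> ReferenceIntervalEstimate:
    """Run the full indirect reference-interval pipeline on raw values.

    Composes outlier removal -> transform selection -> mixture
    deconvolution -> mode/antimode scan -> truncation -> truncated
    nonparametric percentiles -> bootstrap CIs. The point estimate is
    invariant to input order; the seed drives EM restarts and the
    bootstrap only.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 500:
        warnings.warn(f"n = {x.size} is below the recommended minimum of 500 "
                      "for indirect estimation")
    ss = np.random.SeedSequence(seed)
    em_seed, boot_seed = ss.spawn(2)

    kept, _removed = _staged("detect_outliers", detect_outliers, x, config)
    transform = _staged("select_transform", select_transform, kept, config)
    t = transform.apply(kept)
    mixture = _staged("fit_mixture", fit_mixture, t, config.k_max,
                      seed=em_seed, config=config)
    modes_info = _staged("find_modes_antimodes", find_modes_antimodes, t, config)
    window = _staged("choose_truncation", choose_truncation, mixture,
                     modes_info, transform, kept, config)
    lower, upper = _staged("estimate_percentile_ri", estimate_percentile_ri,
                           kept, window, config.probs, config)
    inside = _in_window(kept, window)
    lower_ci, upper_ci = _staged("bootstrap_ci", bootstrap_ci, inside,
                                 config.probs, config.ci_level, config.n_boot,
                                 seed=boot_seed, config=config)

    logger.info("indirect RI: n=%d kept=%d in-window=%d k=%d window=(%.4g, %.4g) "
                "RI=(%.4g, %.4g)", x.size, kept.size, inside.size, mixture.k,
                window.lower, window.upper, lower, upper)
    return ReferenceIntervalEstimate(
        lower=lower, upper=upper, lower_ci=lower_ci, upper_ci=upper_ci,
        n_input=int(x.size), n_after_outliers=int(kept.size),
        n_in_window=int(inside.size), percentiles=tuple(config.probs),
        transform=transform, mixture=mixture, window=window, seed=seed,
    )
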