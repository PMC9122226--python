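"""Causal-effect estimators and diagnostics for two-sample MR.

All estimators consume :class:`~pqtlmr.iv_selection.HarmonizedInstrument`
lists, i.e. per-variant exposure effects ``beta_X (SE_X)`` and outcome
effects ``beta_Y (SE_Y)`` expressed on a shared effect allele.

The primary estimator is the fixed-effects inverse-variance-weighted (IVW)
meta-analysis of per-variant Wald ratios ``beta_Y / beta_X``.  Sensitivity
estimators — MR-Egger regression, the weighted median, simple and weighted
mode, and a robust-adjusted-profile-score (RAPS) style maximum-likelihood
estimator — relax the assumption that every instrument is valid in
different ways.  Diagnostics cover Cochran's Q heterogeneity, the Egger
intercept test for directional pleiotropy, a Steiger directionality check,
and a PRESSO-style simulation-based global pleiotropy test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .iv_selection import HarmonizedInstrument
from .summary_stats import ValidationError

logger = logging.getLogger("pqtlmr")

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "PleiotropyResult",
    "SteigerResult",
    "InsufficientInstrumentsError",
    "ConvergenceError",
    "wald_ratio",
    "ivw_fixed",
    "cochran_q",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "steiger_test",
    "presso_global",
    "raps_mle",
    "run_methods",
]

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw_fe": "Inverse variance weighted (fixed effects)",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
    "raps": "Robust adjusted profile score",
}


class InsufficientInstrumentsError(ValueError):
    """An estimator was given fewer instruments than it needs."""


class ConvergenceError(RuntimeError):
    """Numerical optimisation failed to converge."""


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate: method, beta, SE, p-value, #IVs."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_iv: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError("MREstimate requires se > 0")


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """Egger intercept: a non-zero value signals directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pvalue: float


def _arrays(ivs: list[HarmonizedInstrument]):
    bx = np.array([iv.beta_exposure for iv in ivs], dtype=float)
    sx = np.array([iv.se_exposure for iv in ivs], dtype=float)
    by = np.array([iv.beta_outcome for iv in ivs], dtype=float)
    sy = np.array([iv.se_outcome for iv in ivs], dtype=float)
    return bx, sx, by, sy


def _ratio_arrays(ivs, second_order: bool = False):
    bx, sx, by, sy = _arrays(ivs)
    if np.any(bx == 0):
        raise ValidationError("zero exposure effect: Wald ratio undefined")
    ratio = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return ratio, se


def _norm_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


def wald_ratio(
    iv: HarmonizedInstrument, second_order_se: bool = False
) -> MREstimate:
    """Single-instrument causal estimate ``beta_Y / beta_X``.

    The default SE is the first-order delta method ``SE_Y / |beta_X|``;
    ``second_order_se`` adds the exposure-uncertainty term
    ``sqrt(SE_Y^2/beta_X^2 + beta_Y^2 SE_X^2 / beta_X^4)``.
    """
    ratio, se = _ratio_arrays([iv], second_order=second_order_se)
    b, s = float(ratio[0]), float(se[0])
    return MREstimate("wald_ratio", b, s, float(_norm_p(b / s)), 1)


def ivw_fixed(
    ivs: list[HarmonizedInstrument], second_order_se: bool = False
) -> MREstimate:
    """Fixed-effects IVW meta-analysis of per-instrument Wald ratios.

    ``beta = sum(w_i b_i)/sum(w_i)`` with ``w_i = 1/SE_i^2`` and
    ``SE = 1/sqrt(sum w_i)``; reduces exactly to :func:`wald_ratio` at k=1.
    """
    if len(ivs) < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 instrument")
    ratio, se = _ratio_arrays(ivs, second_order=second_order_se)
    w = 1.0 / se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_ivw = float(1.0 / np.sqrt(np.sum(w)))
    return MREstimate(
        "ivw_fe", beta, se_ivw, float(_norm_p(beta / se_ivw)), len(ivs)
    )


def cochran_q(estimates: list[tuple[float, float]]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test on (beta, se) pairs.

    ``Q = sum w_i (b_i - b_pooled)^2`` against chi-square with k-1 df, where
    ``b_pooled`` is the fixed-effects inverse-variance-weighted mean.
    """
    if len(estimates) < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 estimates")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValidationError("Cochran's Q requires positive SEs")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(estimates) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def mr_egger(
    ivs: list[HarmonizedInstrument],
) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    Instruments are first oriented so every beta_X is positive (flipping
    both signs leaves the Wald ratio unchanged).  Weights are 1/SE_Y^2;
    standard errors are multiplied by max(1, residual SD) so underdispersed
    fits are not anti-conservative; inference uses t with k-2 df.  The slope
    is the causal estimate and a non-zero intercept indicates directional
    pleiotropy (under the InSIDE assumption).
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {len(ivs)}"
        )
    bx, sx, by, sy = _arrays(ivs)
    flip = np.sign(bx)
    if np.any(flip == 0):
        raise ValidationError("zero exposure effect: cannot orient instrument")
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    # Weighted least squares with intercept, solved via the normal equations.
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    k = len(ivs)
    sigma2 = float(resid @ (w * resid) / (k - 2))
    cov_unscaled = np.linalg.inv(xtwx)
    infl = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * infl
    tdist = stats.t(df=k - 2)
    p = 2.0 * tdist.sf(np.abs(coef / se))
    slope = MREstimate(
        "egger", float(coef[1]), float(se[1]), float(p[1]), k,
        extras={"intercept": float(coef[0]), "residual_sd": float(np.sqrt(sigma2))},
    )
    intercept = PleiotropyResult(float(coef[0]), float(se[0]), float(p[0]))
    return slope, intercept


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation on cumulative
    standardised weights (midpoint convention)."""
    order = np.argsort(ratio)
    r, wt = ratio[order], w[order]
    cum = (np.cumsum(wt) - 0.5 * wt) / np.sum(wt)
    return float(np.interp(0.5, cum, r))


def weighted_median(
    ivs: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator: consistent if >= 50% of weight is valid.

    The point estimate is the inverse-variance-weighted median of the
    per-instrument Wald ratios; the SE comes from a parametric bootstrap
    resampling beta_X and beta_Y from their sampling distributions.
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {len(ivs)}"
        )
    ratio, se_ratio = _ratio_arrays(ivs)
    w = 1.0 / se_ratio**2
    beta = _weighted_median_point(ratio, w)
    se = _bootstrap_se(ivs, lambda r, wt: _weighted_median_point(r, wt), n_boot, seed)
    return MREstimate(
        "weighted_median", beta, se, float(_norm_p(beta / se)), len(ivs)
    )


def _bootstrap_se(ivs, point_fn, n_boot: int, seed: int | None) -> float:
    """Parametric bootstrap of a ratio-based point estimator."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(ivs)
    k = len(ivs)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        # keep the ratio defined: resampled exposure effects of exactly 0
        # have probability 0 but guard regardless
        bx_b[bx_b == 0] = np.finfo(float).tiny
        ratio_b = by_b / bx_b
        w_b = bx_b**2 / sy**2  # 1 / (sy/|bx|)^2
        draws[b] = point_fn(ratio_b, w_b)
    se = float(np.std(draws, ddof=1))
    if se == 0.0:
        se = np.finfo(float).tiny
    return se


def _normal_reference_bandwidth(x: np.ndarray, w: np.ndarray) -> float:
    """0.9 min(sd, IQR/1.349) n^(-1/5), with weighted sd/IQR."""
    wn = w / np.sum(w)
    mean = np.sum(wn * x)
    sd = np.sqrt(np.sum(wn * (x - mean) ** 2))
    order = np.argsort(x)
    cum = np.cumsum(wn[order])
    q1 = float(np.interp(0.25, cum, x[order]))
    q3 = float(np.interp(0.75, cum, x[order]))
    iqr = q3 - q1
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def _mode_point(ratio: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Mode of a weighted Gaussian kernel-density of the ratios."""
    h = phi * _normal_reference_bandwidth(ratio, w)
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: the weighted modal value
        vals, idx = np.unique(ratio, return_inverse=True)
        return float(vals[np.argmax(np.bincount(idx, weights=w))])
    lo, hi = ratio.min() - 3 * h, ratio.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    ivs: list[HarmonizedInstrument],
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator: the kernel-density mode of the Wald ratios.

    Consistent when the largest group of instruments sharing a ratio is
    valid (ZEMPA).  ``phi`` scales the normal-reference bandwidth; the
    weighted variant weights the density by inverse ratio variance.  SE by
    parametric bootstrap.
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError(
            f"mode estimator requires >= 3 instruments, got {len(ivs)}"
        )
    ratio, se_ratio = _ratio_arrays(ivs)
    w = 1.0 / se_ratio**2 if weighted else np.ones_like(ratio)
    beta = _mode_point(ratio, w, phi)
    if weighted:
        point = lambda r, wt: _mode_point(r, wt, phi)
    else:
        point = lambda r, wt: _mode_point(r, np.ones_like(r), phi)
    se = _bootstrap_se(ivs, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, float(_norm_p(beta / se)), len(ivs))


def steiger_test(ivs: list[HarmonizedInstrument]) -> SteigerResult:
    """Directionality check: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-trait r^2 is approximated from the observed Z statistics as
    ``Z^2 / (Z^2 + N - 2)`` and summed over instruments; the p-value
    compares the Fisher-transformed correlations with a normal reference.
    For binary outcomes this is the observed-scale approximation.
    """
    bx, sx, by, sy = _arrays(ivs)
    nx = np.array([iv.n_exposure for iv in ivs], dtype=float)
    ny = np.array([iv.n_outcome for iv in ivs], dtype=float)
    if np.any(~np.isfinite(nx)) or np.any(~np.isfinite(ny)) or np.any(nx <= 3) or np.any(ny <= 3):
        raise ValidationError("Steiger test requires per-instrument sample sizes > 3")
    zx, zy = bx / sx, by / sy
    r2x = float(np.sum(zx**2 / (zx**2 + nx - 2)))
    r2y = float(np.sum(zy**2 / (zy**2 + ny - 2)))
    r2x, r2y = min(r2x, 1.0), min(r2y, 1.0)
    rx, ry = np.sqrt(r2x), np.sqrt(r2y)
    n_x, n_y = float(np.mean(nx)), float(np.mean(ny))
    denom = np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    with np.errstate(divide="ignore"):
        z = (np.arctanh(min(rx, 1 - 1e-15)) - np.arctanh(min(ry, 1 - 1e-15))) / denom
    return SteigerResult(r2x, r2y, bool(r2x > r2y), float(_norm_p(z)))


def _loo_ivw(ratio: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorised."""
    sw, swb = np.sum(w), np.sum(w * ratio)
    return (swb - w * ratio) / (sw - w)


def _presso_rss(bx, sx, by, sy) -> float:
    ratio = by / bx
    w = bx**2 / sy**2
    loo = _loo_ivw(ratio, w)
    return float(np.sum((by - loo * bx) ** 2 / (sy**2 + loo**2 * sx**2)))


def presso_global(
    ivs: list[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
) -> float:
    """Simulation-based global test for horizontal pleiotropy.

    The observed residual sum of squares uses leave-one-out IVW predictions
    of each instrument's outcome effect; the null distribution is built by
    redrawing (beta_X, beta_Y) from the no-pleiotropy model and recomputing
    the statistic.  Returns the empirical upper-tail p-value (lower bound
    1/n_sim).
    """
    if len(ivs) < 4:
        raise InsufficientInstrumentsError(
            f"global pleiotropy test requires >= 4 instruments, got {len(ivs)}"
        )
    bx, sx, by, sy = _arrays(ivs)
    rss_obs = _presso_rss(bx, sx, by, sy)
    ratio = by / bx
    w = bx**2 / sy**2
    loo = _loo_ivw(ratio, w)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(loo * bx, sy)
        if _presso_rss(bx_s, sx, by_s, sy) >= rss_obs:
            exceed += 1
    return max(exceed, 1) / n_sim


def _raps_profile_nll(beta, tau2, bx, sx, by, sy):
    """Profile negative log-likelihood after eliminating the per-instrument
    true exposure effects: 0.5 * sum (by - beta bx)^2 / (sy^2 + beta^2 sx^2
    + tau^2).  No log-variance term survives the profiling, which is what
    makes the score unbiased under exposure-side sampling error."""
    v = sy**2 + beta**2 * sx**2 + tau2
    return 0.5 * np.sum((by - beta * bx) ** 2 / v)


def _raps_minimize_beta(tau2, bx, sx, by, sy, b0, max_iter):
    span = 10.0 * abs(b0) + 10.0
    res = optimize.minimize_scalar(
        lambda b: _raps_profile_nll(b, tau2, bx, sx, by, sy),
        bounds=(b0 - span, b0 + span),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError(f"RAPS did not converge: {res.message}")
    return float(res.x)


def raps_mle(
    ivs: list[HarmonizedInstrument],
    overdispersion: bool = False,
    max_iter: int = 500,
) -> MREstimate:
    """Profile-likelihood causal estimate robust to weak instruments.

    Models ``beta_X,i ~ N(gamma_i, SE_X,i^2)`` and ``beta_Y,i ~
    N(beta gamma_i, SE_Y,i^2 [+ tau^2])`` and profiles out the nuisance
    ``gamma_i``, leaving ``0.5 sum (beta_Y - beta beta_X)^2 / (SE_Y^2 +
    beta^2 SE_X^2 [+ tau^2])`` to minimise over ``beta`` — unlike IVW this
    accounts for exposure-side sampling error, removing weak-instrument
    attenuation.  With ``overdispersion`` a systematic-pleiotropy variance
    ``tau^2 >= 0`` is fitted by moment matching of the standardised
    residuals.  The SE comes from the observed information of the profile
    likelihood (numerical second derivative at the optimum).
    """
    need = 3 if overdispersion else 1
    if len(ivs) < need:
        raise InsufficientInstrumentsError(
            f"RAPS requires >= {need} instruments, got {len(ivs)}"
        )
    bx, sx, by, sy = _arrays(ivs)
    b0 = ivw_fixed(ivs).beta
    k = len(ivs)

    tau2 = 0.0
    beta_hat = _raps_minimize_beta(tau2, bx, sx, by, sy, b0, max_iter)
    if overdispersion:
        for _ in range(200):
            # moment equation: mean standardized squared residual = 1
            def excess(t2, b=beta_hat):
                v = sy**2 + b**2 * sx**2 + t2
                return float(np.sum((by - b * bx) ** 2 / v)) - k

            if excess(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.max((by - beta_hat * bx) ** 2)) + 1.0
                tau2_new = float(optimize.brentq(excess, 0.0, hi, xtol=1e-12))
            beta_new = _raps_minimize_beta(tau2_new, bx, sx, by, sy, b0, max_iter)
            done = abs(beta_new - beta_hat) < 1e-10 and abs(tau2_new - tau2) < 1e-12
            beta_hat, tau2 = beta_new, tau2_new
            if done:
                break
        else:
            raise ConvergenceError("RAPS overdispersion loop did not converge")

    h = 1e-5 * (abs(beta_hat) + 1.0)
    info = (
        _raps_profile_nll(beta_hat + h, tau2, bx, sx, by, sy)
        - 2 * _raps_profile_nll(beta_hat, tau2, bx, sx, by, sy)
        + _raps_profile_nll(beta_hat - h, tau2, bx, sx, by, sy)
    ) / h**2
    if not np.isfinite(info) or info <= 0:
        raise ConvergenceError(
            f"observed information non-positive at optimum (info={info!r})"
        )
    se = float(1.0 / np.sqrt(info))
    extras = {"tau2": tau2} if overdispersion else {}
    return MREstimate(
        "raps", beta_hat, se, float(_norm_p(beta_hat / se)), len(ivs), extras=extras
    )


def run_methods(
    ivs: list[HarmonizedInstrument],
    methods: list[str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MREstimate]:
    """Run a battery of estimators by name, skipping (with a log line) those
    with too few instruments."""
    out: list[MREstimate] = []
    for m in methods:
        try:
            if m in ("ivw", "ivw_fe"):
                out.append(ivw_fixed(ivs))
            elif m == "wald_ratio":
                if len(ivs) != 1:
                    raise InsufficientInstrumentsError("Wald ratio is single-IV")
                out.append(wald_ratio(ivs[0]))
            elif m == "egger":
                out.append(mr_egger(ivs)[0])
            elif m in ("wmedian", "weighted_median"):
                out.append(weighted_median(ivs, n_boot=n_boot, seed=seed))
            elif m in ("smode", "simple_mode"):
                out.append(mode_estimate(ivs, weighted=False, n_boot=n_boot, seed=seed))
            elif m in ("wmode", "weighted_mode"):
                out.append(mode_estimate(ivs, weighted=True, n_boot=n_boot, seed=seed))
            elif m == "raps":
                out.append(raps_mle(ivs))
            else:
                raise ValueError(f"unknown MR method {m!r}")
        except InsufficientInstrumentsError as err:
            logger.warning("skipping %s: %s", m, err)
    return out
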