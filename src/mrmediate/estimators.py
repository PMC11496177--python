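"""Two-sample MR causal-effect estimators.

Implements the Wald ratio, inverse-variance-weighted (IVW) meta-analysis,
MR-Egger regression, the weighted median, and the simple/weighted mode
estimators, all operating on a :class:`~mrmediate.instruments.HarmonizedSet`
of per-SNP exposure/outcome effect pairs (β_Xj ± σ_Xj, β_Yj ± σ_Yj).

IVW is the zero-intercept weighted least-squares fit of β_Y on β_X with
weights 1/σ_Y²; it is the primary estimator.  The default variant uses
multiplicative random effects: the standard error is inflated by the
residual scale √(Q/(k−1)), floored at 1 so it never drops below the
fixed-effect SE.  MR-Egger adds a free intercept that absorbs (and tests
for) average directional pleiotropy; its inference uses a t reference with
k−2 degrees of freedom.  Median and mode estimators obtain standard errors
by parametric bootstrap, resampling each β from a normal with its reported
SE under a caller-supplied seed.

Binary-outcome effects are log odds ratios; :func:`to_odds_ratio` fills the
OR-scale fields OR = exp(β), 95% CI = exp(β ∓ 1.96·SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .instruments import HarmonizedSet, InsufficientInstrumentsError

Z95 = 1.959963984540054  # Φ⁻¹(0.975)


@dataclass
class MREstimate:
    """One method's causal-effect estimate for an exposure/outcome pair."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    exposure_id: str = ""
    outcome_id: str = ""
    extra: dict = field(default_factory=dict)


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def to_odds_ratio(estimate: MREstimate) -> MREstimate:
    """Fill OR-scale fields: OR = exp(β), CI = exp(β ± 1.96·SE). Idempotent."""
    return replace(estimate,
                   or_=float(np.exp(estimate.beta)),
                   ci_low=float(np.exp(estimate.beta - Z95 * estimate.se)),
                   ci_high=float(np.exp(estimate.beta + Z95 * estimate.se)))


def wald_ratio(row) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with first-order delta-method SE.

    ``row`` is one row of ``HarmonizedSet.rows`` (anything with beta_exp,
    se_exp, beta_out, se_out attributes or keys).
    """
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    bx, sx = float(get("beta_exp")), float(get("se_exp"))
    by, sy = float(get("beta_out")), float(get("se_out"))
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    beta = by / bx
    se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    p = _normal_p(beta / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    return to_odds_ratio(MREstimate("wald", float(beta), float(se), p, 1))


def _wald_ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratios and their first-order delta variances."""
    bx, sx, by, sy = hset.arrays()
    ratio = by / bx
    var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4
    return ratio, var


def ivw(hset: HarmonizedSet, variant: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Zero-intercept WLS of β_Y on β_X with weights 1/σ_Y².  ``variant``
    chooses the SE model: ``"fixed"`` uses residual scale 1;
    ``"multiplicative_random"`` (default) inflates the SE by
    max(1, √(Q/(k−1))).  A single SNP delegates to :func:`wald_ratio`.
    """
    if variant not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW variant {variant!r}")
    k = hset.n_snp
    if k < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 SNP")
    if k == 1:
        est = wald_ratio(hset.rows.iloc[0])
        return replace(est, method="ivw", exposure_id=hset.exposure_id,
                       outcome_id=hset.outcome_id,
                       extra={"variant": "wald_fallback"})
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by) / sxx)
    se_fixed = np.sqrt(1.0 / sxx)
    resid = by - beta * bx
    q = float(np.sum(w * resid ** 2))
    scale = 1.0
    if variant == "multiplicative_random":
        scale = max(1.0, np.sqrt(q / (k - 1)))
    se = float(se_fixed * scale)
    est = MREstimate("ivw", beta, se, _normal_p(beta / se), k,
                     exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
                     extra={"variant": variant, "q_stat": q})
    return to_odds_ratio(est)


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: WLS of β_Y on β_X with a free intercept.

    Rows are re-oriented so every β_X ≥ 0 before fitting.  The slope is the
    causal estimate; the intercept estimates average directional pleiotropy
    and its test is stored in ``extra`` (egger_intercept, intercept_se,
    intercept_p).  SEs use residual scale max(1, σ̂); p-values come from a
    t distribution with k−2 df.
    """
    k = hset.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")
    bx, sx, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    # weighted normal equations for [intercept, slope]
    s0 = np.sum(w)
    s1 = np.sum(w * bx)
    s2 = np.sum(w * bx * bx)
    t0 = np.sum(w * by)
    t1 = np.sum(w * bx * by)
    det = s0 * s2 - s1 * s1
    intercept = (s2 * t0 - s1 * t1) / det
    slope = (s0 * t1 - s1 * t0) / det
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid ** 2) / (k - 2))
    scale2 = max(1.0, sigma2)
    var_slope = scale2 * s0 / det
    var_int = scale2 * s2 / det
    se_slope = float(np.sqrt(var_slope))
    se_int = float(np.sqrt(var_int))
    tdist = stats.t(df=k - 2)
    p_slope = float(2 * tdist.sf(abs(slope / se_slope)))
    p_int = float(2 * tdist.sf(abs(intercept / se_int)))
    est = MREstimate("egger", float(slope), se_slope, p_slope, k,
                     exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
                     extra={"egger_intercept": float(intercept),
                            "intercept_se": se_int, "intercept_p": p_int,
                            "residual_scale2": sigma2})
    return to_odds_ratio(est)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Quantile by linear interpolation across centered cumulative weights."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cum, v))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Weights are the normalized inverse variances of the ratios; the estimate
    is the weighted 50th percentile of the sorted ratios with linear
    interpolation across cumulative weights.  The SE comes from a parametric
    bootstrap (``n_boot`` draws of each β from a normal with its SE),
    deterministic under ``seed``.  Consistent when SNPs carrying ≥50% of the
    weight are valid instruments.
    """
    k = hset.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 SNPs")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    ratio, var = _wald_ratios(hset)
    beta = _weighted_quantile(ratio, 1.0 / var)
    se = _bootstrap_se(hset, n_boot, seed,
                       lambda r, v: _weighted_quantile(r, 1.0 / v))
    est = MREstimate("weighted_median", beta, se, _normal_p(beta / se), k,
                     exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
                     extra={"n_boot": n_boot, "seed": seed})
    return to_odds_ratio(est)


def _mode_bandwidth(ratio: np.ndarray, se_ratio: np.ndarray,
                    bandwidth_factor: float) -> float:
    """Modified Silverman rule on the ratio distribution (MAD-scaled)."""
    k = len(ratio)
    mad = stats.median_abs_deviation(ratio, scale="normal")
    s = min(float(np.std(ratio, ddof=1)), float(mad)) if mad > 0 else float(np.std(ratio, ddof=1))
    if s <= 0:
        s = max(float(np.mean(se_ratio)), 1e-12)
    return bandwidth_factor * 0.9 * s * k ** (-1 / 5)


def _mode_argmax(ratio: np.ndarray, weights: np.ndarray, h: float,
                 n_grid: int = 2048) -> float:
    """Argmax of the weighted normal-kernel density over a dense grid."""
    lo = ratio.min() - 3 * h
    hi = ratio.max() + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(hset: HarmonizedSet, weighted: bool = True,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MREstimate:
    """Mode-based estimate: argmax of a kernel density over Wald ratios.

    ``weighted=True`` weights each ratio by its inverse variance (weighted
    mode); ``False`` gives the simple mode.  Bandwidth is
    ``bandwidth_factor`` × a MAD-based modified-Silverman rule.  SE by
    parametric bootstrap as in :func:`weighted_median`.
    """
    k = hset.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("mode estimator requires at least 3 SNPs")
    if seed is None:
        raise ValueError("mode_estimate requires an explicit seed")
    ratio, var = _wald_ratios(hset)
    se_ratio = np.sqrt(var)
    h = _mode_bandwidth(ratio, se_ratio, bandwidth_factor)
    if h <= 0 or np.ptp(ratio) == 0:  # all ratios identical: point mass
        beta = float(ratio[0])
        est = MREstimate("weighted_mode" if weighted else "simple_mode",
                         beta, 0.0, 1.0 if beta == 0 else 0.0, k,
                         exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
                         extra={"bandwidth": 0.0, "n_boot": n_boot, "seed": seed})
        return to_odds_ratio(est)
    weights = 1.0 / var if weighted else np.ones(k)
    beta = _mode_argmax(ratio, weights, h)

    def stat(r, v):
        hh = _mode_bandwidth(r, np.sqrt(v), bandwidth_factor)
        if hh <= 0 or np.ptp(r) == 0:
            return float(r[0])
        ww = 1.0 / v if weighted else np.ones(len(r))
        return _mode_argmax(r, ww, hh, n_grid=512)

    se = _bootstrap_se(hset, n_boot, seed, stat)
    p = _normal_p(beta / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    est = MREstimate("weighted_mode" if weighted else "simple_mode",
                     beta, se, p, k,
                     exposure_id=hset.exposure_id, outcome_id=hset.outcome_id,
                     extra={"bandwidth": float(h), "n_boot": n_boot, "seed": seed})
    return to_odds_ratio(est)


def _bootstrap_se(hset: HarmonizedSet, n_boot: int, seed: int, stat) -> float:
    """Parametric-bootstrap SE: resample β_X, β_Y ~ N(β̂, SE²), recompute stat."""
    if n_boot < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(k)
        bys = by + sy * rng.standard_normal(k)
        bxs = np.where(bxs == 0, 1e-300, bxs)
        ratio = bys / bxs
        var = sy ** 2 / bxs ** 2 + bys ** 2 * sx ** 2 / bxs ** 4
        draws[b] = stat(ratio, var)
    return float(np.std(draws, ddof=1))


ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")


def run_all(hset: HarmonizedSet, seed: int, *, methods=ALL_METHODS,
            ivw_variant: str = "multiplicative_random", n_boot: int = 1000,
            bandwidth_factor: float = 1.0) -> list[MREstimate]:
    """Run the requested estimators on one harmonized set.

    Methods whose minimum SNP count is not met are silently skipped (IVW
    falls back to the Wald ratio at k = 1).  Bootstrap seeds are derived
    from ``seed`` per method so the set of methods run does not perturb any
    individual result.
    """
    out = []
    k = hset.n_snp
    ss = np.random.SeedSequence(seed)
    method_seed = {m: int(s.generate_state(1)[0] % (2 ** 31))
                   for m, s in zip(ALL_METHODS, ss.spawn(len(ALL_METHODS)))}
    for m in methods:
        if m == "ivw" and k >= 1:
            out.append(ivw(hset, ivw_variant))
        elif m == "egger" and k >= 3:
            out.append(mr_egger(hset))
        elif m == "weighted_median" and k >= 3:
            out.append(weighted_median(hset, n_boot, method_seed[m]))
        elif m == "weighted_mode" and k >= 3:
            out.append(mode_estimate(hset, True, bandwidth_factor, n_boot, method_seed[m]))
        elif m == "simple_mode" and k >= 3:
            out.append(mode_estimate(hset, False, bandwidth_factor, n_boot, method_seed[m]))
    return out
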