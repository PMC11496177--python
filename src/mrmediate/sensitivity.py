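"""Heterogeneity, pleiotropy and outlier diagnostics.

Cochran's Q measures heterogeneity of the per-SNP Wald ratios around the
fixed-effect IVW estimate and is referred to a chi-square with k−1 df; the
MR-Egger intercept tests for average directional pleiotropy; leave-one-out
refits IVW omitting each SNP in turn; and the MR-PRESSO global, per-SNP
outlier and distortion tests detect and quantify the impact of pleiotropic
outliers by comparing observed residual sums of squares against parametric
simulations under the no-pleiotropy null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger
from .instruments import HarmonizedSet, InsufficientInstrumentsError


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios.

    Q = Σ w_j (ratio_j − β_IVW,fixed)² with w_j the inverse first-order
    variance of each ratio; the p-value comes from chi-square(k−1).
    Returns ``(q_stat, q_df, q_pvalue)``.
    """
    k = hset.n_snp
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires at least 2 SNPs")
    bx, sx, by, sy = hset.arrays()
    ratio = by / bx
    w = 1.0 / (sy ** 2 / bx ** 2)  # first-order weight used by IVW
    beta = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(hset: HarmonizedSet, ivw_variant: str = "multiplicative_random"
                  ) -> list[dict]:
    """IVW refits omitting each SNP in turn.

    Returns one record per omitted SNP: ``dropped_snp_id``, ``beta``,
    ``se``, ``pvalue`` and ``sign_flag`` — True when that fit's 95% CI no
    longer supports the full-set estimate's sign conclusion.
    """
    k = hset.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 SNPs")
    def conclusion(beta: float, se: float) -> int:
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        if lo > 0:
            return 1
        if hi < 0:
            return -1
        return 0

    full = ivw(hset, ivw_variant)
    full_conclusion = conclusion(full.beta, full.se)
    out = []
    for snp in hset.rows["snp_id"]:
        est = ivw(hset.drop(snp), ivw_variant)
        out.append({"dropped_snp_id": snp, "beta": est.beta, "se": est.se,
                    "pvalue": est.pvalue,
                    "sign_flag": conclusion(est.beta, est.se) != full_conclusion})
    return out


@dataclass
class PressoRecord:
    """MR-PRESSO global/outlier/distortion results."""

    global_rss_obs: float
    global_p: float
    outlier_snp_ids: list = field(default_factory=list)
    outlier_p: dict = field(default_factory=dict)
    distortion_p: float = float("nan")
    beta_raw: float = float("nan")
    beta_outlier_corrected: float = float("nan")
    n_sim: int = 0
    seed: int = 0


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-intercept WLS slope leaving each observation out, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoRecord:
    """MR-PRESSO residual-sum-of-squares pleiotropy diagnostics.

    Global test: the observed RSS — each SNP's squared deviation of β_Y
    from the outcome effect expected under the leave-that-SNP-out IVW slope
    — is compared with ``n_sim`` parametric simulations drawn under no
    pleiotropy; ``global_p`` is the upper-tail proportion, floored at
    1/(n_sim+1).  Outlier test: each SNP's observed RSS contribution versus
    its own simulated distribution, Bonferroni-corrected at
    ``outlier_alpha``.  Distortion test: the relative difference between the
    outlier-corrected and raw IVW slopes against a permutation distribution
    built by removing random SNP subsets of the same size.  Deterministic
    under ``seed``.
    """
    k = hset.n_snp
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 SNPs")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy ** 2

    slopes_loo = _loo_slopes(bx, by, w)
    rss_contrib_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(rss_contrib_obs))

    # parametric simulations under the no-pleiotropy null
    bx_sim = bx + sx * rng.standard_normal((n_sim, k))
    by_sim = slopes_loo * bx + sy * rng.standard_normal((n_sim, k))
    contrib_sim = np.empty((n_sim, k))
    for s in range(n_sim):
        sl = _loo_slopes(bx_sim[s], by_sim[s], w)
        contrib_sim[s] = w * (by_sim[s] - sl * bx_sim[s]) ** 2
    rss_sim = contrib_sim.sum(axis=1)
    global_p = float(max(np.mean(rss_sim > rss_obs), 1.0 / (n_sim + 1)))

    record = PressoRecord(global_rss_obs=rss_obs, global_p=global_p,
                          n_sim=n_sim, seed=seed,
                          beta_raw=ivw(hset, "multiplicative_random").beta)
    if global_p >= outlier_alpha:
        return record

    # per-SNP outlier test, Bonferroni across k SNPs
    p_snp = np.maximum((contrib_sim > rss_contrib_obs[None, :]).mean(axis=0),
                       1.0 / (n_sim + 1))
    p_adj = np.minimum(p_snp * k, 1.0)
    outliers = [str(s) for s, p in zip(hset.rows["snp_id"], p_adj) if p < outlier_alpha]
    record.outlier_p = {str(s): float(p) for s, p in zip(hset.rows["snp_id"], p_adj)}
    record.outlier_snp_ids = outliers
    if not outliers:
        return record

    keep = ~hset.rows["snp_id"].isin(outliers).to_numpy()
    if keep.sum() < 2:
        return record
    corrected = ivw(hset.subset(keep), "multiplicative_random").beta
    record.beta_outlier_corrected = float(corrected)

    # distortion: observed bias vs removing random subsets of the same size
    n_out = len(outliers)
    d_obs = (record.beta_raw - corrected) / abs(corrected) if corrected != 0 else np.inf
    d_perm = np.empty(n_sim)
    idx = np.arange(k)
    for s in range(n_sim):
        drop = rng.choice(idx, size=n_out, replace=False)
        mask = np.ones(k, bool)
        mask[drop] = False
        b = ivw(hset.subset(mask), "multiplicative_random").beta
        d_perm[s] = (record.beta_raw - b) / abs(b) if b != 0 else np.inf
    record.distortion_p = float(max(np.mean(np.abs(d_perm) > abs(d_obs)),
                                    1.0 / (n_sim + 1)))
    return record


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure/outcome pair."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    loo: list
    presso: PressoRecord | None
    seed: int

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


def sensitivity_report(hset: HarmonizedSet, seed: int, *, presso_nsim: int = 1000,
                       run_presso: bool = True) -> SensitivityReport:
    """Run Q, Egger-intercept, leave-one-out and (optionally) MR-PRESSO."""
    q, df, qp = cochran_q(hset)
    eg = mr_egger(hset) if hset.n_snp >= 3 else None
    loo = leave_one_out(hset) if hset.n_snp >= 3 else []
    presso = None
    if run_presso and hset.n_snp >= 4 and presso_nsim > 0:
        presso = mr_presso(hset, n_sim=presso_nsim, seed=seed)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pvalue=qp,
        egger_intercept=eg.extra["egger_intercept"] if eg else float("nan"),
        egger_intercept_se=eg.extra["intercept_se"] if eg else float("nan"),
        egger_intercept_p=eg.extra["intercept_p"] if eg else float("nan"),
        loo=loo, presso=presso, seed=seed)
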