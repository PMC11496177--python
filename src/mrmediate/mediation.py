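"""Two-step MR mediation decomposition, FDR tiering, and power.

The two-step design estimates the exposure→mediator effect β(A) and the
mediator→outcome effect β(B) from separate MR fits (IVW by default) and
decomposes the total exposure→outcome effect as

    mediated = β(A) · β(B),    direct = total − mediated,
    proportion = 100 · mediated / total  (percent).

Confidence intervals for the product and the proportion use the first-order
delta method (the Sobel variance for the product), assuming the two legs
come from independent GWAS samples.  Multiple-testing control is
Benjamini–Hochberg; evidence is tiered as "causal" (FDR < 0.05),
"suggestive" (FDR ≥ 0.05 but p < 0.05) or "none" (p ≥ 0.05).  Statistical
power for a binary outcome follows the standard summary-data MR
approximation used by the mRnd calculator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, Z95
from .gwas_io import ConfigurationError


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one exposure→mediator→outcome path."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    total: float
    se_total: float
    mediated: float
    mediated_se: float
    mediated_ci: tuple
    mediated_p: float
    direct: float
    proportion_pct: float
    proportion_ci_pct: tuple
    inconsistent: bool
    estimator: str = "ivw"


def sobel_ci(beta_a: float, se_a: float, beta_b: float, se_b: float,
             level: float = 0.95, second_order: bool = False
             ) -> tuple[float, float, tuple, float]:
    """Delta-method (Sobel) interval for the product β(A)·β(B).

    First-order variance β_B²σ_A² + β_A²σ_B²; with ``second_order`` the
    σ_A²σ_B² term is added.  Returns ``(mediated, se, (lo, hi), p)`` with a
    normal reference.  Assumes the two estimates are independent.
    """
    mediated = beta_a * beta_b
    var = beta_b ** 2 * se_a ** 2 + beta_a ** 2 * se_b ** 2
    if second_order:
        var += se_a ** 2 * se_b ** 2
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    ci = (mediated - z * se, mediated + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(mediated / se)))
    else:
        p = 1.0 if mediated == 0 else 0.0
    return float(mediated), se, ci, p


def mediation_proportion(mediated: float, se_med: float, total: float,
                         se_total: float, level: float = 0.95
                         ) -> tuple[float, tuple, bool]:
    """Mediated proportion 100·mediated/total with a delta-method CI.

    The ratio variance assumes the numerator and denominator estimates are
    independent: (m/t)²·(σ_m²/m² + σ_t²/t²).  Returns
    ``(proportion_pct, (lo, hi), inconsistent)`` where ``inconsistent``
    flags opposite signs of mediated and total (the "proportion" is then
    negative and not interpretable as a share of the total effect).
    """
    if total == 0:
        raise ZeroDivisionError("mediation proportion undefined for total effect 0")
    prop = mediated / total
    if mediated == 0:
        se_prop = se_med / abs(total)
    else:
        se_prop = abs(prop) * np.sqrt(se_med ** 2 / mediated ** 2
                                      + se_total ** 2 / total ** 2)
    z = stats.norm.ppf(0.5 + level / 2)
    ci = (100 * (prop - z * se_prop), 100 * (prop + z * se_prop))
    inconsistent = (mediated != 0) and (np.sign(mediated) != np.sign(total))
    return float(100 * prop), ci, bool(inconsistent)


def two_step_mediation(a: MREstimate, b: MREstimate, total: MREstimate,
                       level: float = 0.95) -> MediationResult:
    """Assemble a :class:`MediationResult` from the three MR legs.

    ``a`` is the exposure→mediator fit, ``b`` the mediator→outcome fit and
    ``total`` the exposure→outcome fit, all on the log-OR/linear scale.
    The identities mediated = β(A)·β(B) and direct + mediated = total hold
    exactly.
    """
    for leg, name in ((a, "A"), (b, "B"), (total, "T")):
        if leg is None:
            raise ValueError(f"mediation requires all three legs; leg {name} missing")
    mediated, se_med, ci, p = sobel_ci(a.beta, a.se, b.beta, b.se, level)
    prop, prop_ci, inconsistent = mediation_proportion(
        mediated, se_med, total.beta, total.se, level)
    return MediationResult(
        exposure_id=a.exposure_id, mediator_id=a.outcome_id or b.exposure_id,
        outcome_id=total.outcome_id,
        beta_a=a.beta, se_a=a.se, beta_b=b.beta, se_b=b.se,
        total=total.beta, se_total=total.se,
        mediated=mediated, mediated_se=se_med, mediated_ci=ci, mediated_p=p,
        direct=total.beta - mediated,
        proportion_pct=prop, proportion_ci_pct=prop_ci,
        inconsistent=inconsistent,
        estimator=f"A:{a.method},B:{b.method},T:{total.method}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_evidence(pvalue: float, fdr: float) -> str:
    """Tier a result: ``causal`` (FDR<0.05), ``suggestive`` (p<0.05), else ``none``."""
    if fdr < 0.05:
        return "causal"
    if pvalue < 0.05:
        return "suggestive"
    return "none"


def mr_power(n: float, case_fraction: float, r2: float,
             or_hypothesized: float, alpha: float = 0.05) -> float:
    """Power of a two-sample MR test with a binary outcome.

    Uses the standard non-centrality approximation: with K the case
    fraction and R² the variance in the exposure explained by the
    instruments,

        power = Φ(−z_{1−α/2} + |log OR| · √(n·R²·K·(1−K))).
    """
    if not 0 < r2 < 1:
        raise ConfigurationError("r2 must lie in (0, 1)")
    if not 0 < case_fraction < 1:
        raise ConfigurationError("case_fraction must lie in (0, 1)")
    if n <= 0 or not 0 < alpha < 1:
        raise ConfigurationError("invalid n or alpha")
    z = stats.norm.ppf(1 - alpha / 2)
    ncp = abs(np.log(or_hypothesized)) * np.sqrt(n * r2 * case_fraction * (1 - case_fraction))
    return float(stats.norm.cdf(-z + ncp))
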