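"""Instrument selection and exposure/outcome harmonization.

Instruments for a trait are chosen by the conventional three-stage screen:
a p-value threshold on the exposure association (default 1e-5), greedy LD
clumping against a reference r² panel (default r² < 0.001 within ±10,000 kb),
and a per-SNP strength filter F = (beta/se)² ≥ 10 to guard against
weak-instrument bias.  Harmonization aligns the outcome effect to the
exposure's effect allele, flipping signs where the outcome reports the
complementary orientation and handling strand-ambiguous (palindromic A/T,
C/G) SNPs by policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import ConfigurationError, LDPanel, SummaryStatTable

logger = logging.getLogger("mrmediate")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which strand inference for palindromic SNPs is refused
PALINDROME_EAF_WINDOW = (0.42, 0.58)


class InsufficientInstrumentsError(ValueError):
    """Too few instruments survive for the requested analysis step."""

    def __init__(self, message: str, counts: dict | None = None):
        super().__init__(message)
        self.counts = counts or {}


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-SNP F statistics."""

    exposure_id: str
    records: pd.DataFrame  # canonical summary-stat columns + "f_stat"

    @property
    def n_snp(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to the exposure's effect allele."""

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame  # snp_id, beta_exp, se_exp, beta_out, se_out
    drop_counts: dict | None = None

    @property
    def n_snp(self) -> int:
        return len(self.rows)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out, snp_ids=None,
                    exposure_id: str = "exposure", outcome_id: str = "outcome"
                    ) -> "HarmonizedSet":
        """Build a set directly from effect/SE arrays (tests, simulations)."""
        beta_exp = np.asarray(beta_exp, float)
        if snp_ids is None:
            snp_ids = [f"rs{i}" for i in range(len(beta_exp))]
        df = pd.DataFrame({"snp_id": snp_ids, "beta_exp": beta_exp,
                           "se_exp": np.asarray(se_exp, float),
                           "beta_out": np.asarray(beta_out, float),
                           "se_out": np.asarray(se_out, float)})
        return cls(exposure_id, outcome_id, df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        r = self.rows
        return (r["beta_exp"].to_numpy(float), r["se_exp"].to_numpy(float),
                r["beta_out"].to_numpy(float), r["se_out"].to_numpy(float))

    def drop(self, snp_id: str) -> "HarmonizedSet":
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.rows[self.rows["snp_id"] != snp_id].reset_index(drop=True))

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.rows.loc[np.asarray(mask)].reset_index(drop=True))


def filter_by_pvalue(table: SummaryStatTable, threshold: float = 1e-5) -> SummaryStatTable:
    """Keep rows with exposure p-value strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"p-value threshold {threshold} outside (0, 1]")
    kept = table.records[table.records["pvalue"] < threshold].reset_index(drop=True)
    return SummaryStatTable(trait_id=table.trait_id, records=kept)


def ld_clump(table: SummaryStatTable, panel: LDPanel,
             r2_threshold: float = 0.001, window_kb: float = 10_000) -> SummaryStatTable:
    """Greedy p-value-ordered LD clumping.

    Repeatedly takes the remaining SNP with the smallest p-value as the index
    and discards remaining SNPs on the same chromosome within ±``window_kb``
    whose r² with the index meets ``r2_threshold``.  Ties on p-value are
    broken by position then snp_id, making the result independent of input
    row order.  SNPs absent from the panel are treated as unlinked (with a
    logged warning).
    """
    if window_kb < 0:
        raise ConfigurationError("window_kb must be non-negative")
    if not 0 <= r2_threshold <= 1:
        raise ConfigurationError("r2_threshold must lie in [0, 1]")
    df = table.records
    missing = [s for s in df["snp_id"] if s not in panel]
    if missing:
        logger.warning("ld_clump: %d SNP(s) absent from LD panel treated as unlinked",
                       len(missing))
    order = df.sort_values(["pvalue", "pos", "snp_id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    alive = dict.fromkeys(order.index, True)
    kept_idx: list = []
    for idx in order.index:
        if not alive[idx]:
            continue
        kept_idx.append(idx)
        row = df.loc[idx]
        for jdx in order.index:
            if jdx == idx or not alive[jdx]:
                continue
            other = df.loc[jdx]
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_bp:
                continue
            if panel.lookup(row["snp_id"], other["snp_id"]) >= r2_threshold:
                alive[jdx] = False
    kept = df.loc[sorted(kept_idx)].reset_index(drop=True)
    return SummaryStatTable(trait_id=table.trait_id, records=kept)


def compute_f_statistics(table: SummaryStatTable, min_f: float = 10.0) -> InstrumentSet:
    """Attach per-SNP F = (beta/se)² and drop weak instruments (F < min_f)."""
    df = table.records.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    n_weak = int((df["f_stat"] < min_f).sum())
    if n_weak:
        logger.info("compute_f_statistics(%s): %d weak instrument(s) removed (F < %g)",
                    table.trait_id, n_weak, min_f)
    df = df[df["f_stat"] >= min_f].reset_index(drop=True)
    return InstrumentSet(exposure_id=table.trait_id, records=df)


def f_from_r2(r2: float, n: int) -> float:
    """F statistic implied by instrument variance explained: R²(n−2)/(1−R²)."""
    return r2 * (n - 2) / (1.0 - r2)


def r2_from_eaf(beta: np.ndarray, eaf: np.ndarray) -> np.ndarray:
    """Per-SNP variance explained 2·MAF·(1−MAF)·β² for a standardized trait."""
    maf = np.minimum(np.asarray(eaf, float), 1.0 - np.asarray(eaf, float))
    return 2.0 * maf * (1.0 - maf) * np.asarray(beta, float) ** 2


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def select_instruments(table: SummaryStatTable, panel: LDPanel, *,
                       pvalue_threshold: float = 1e-5, r2_threshold: float = 0.001,
                       window_kb: float = 10_000, min_f: float = 10.0) -> InstrumentSet:
    """Full selection pipeline: p-value screen → LD clump → F filter."""
    screened = filter_by_pvalue(table, pvalue_threshold)
    clumped = ld_clump(screened, panel, r2_threshold, window_kb)
    return compute_f_statistics(clumped, min_f)


def harmonize(exposure: InstrumentSet, outcome: SummaryStatTable,
              palindrome_policy: str = "drop") -> HarmonizedSet:
    """Join exposure instruments with outcome records on snp_id and align alleles.

    The outcome beta is sign-flipped when the outcome's effect allele equals
    the exposure's other allele (directly or through a strand flip).
    Palindromic SNPs (A/T, C/G pairs) are dropped under policy ``"drop"``;
    under ``"infer_by_eaf"`` they are kept with strand inferred from the two
    effect-allele frequencies when both lie outside the ambiguity window
    [0.42, 0.58], and dropped otherwise.  Non-matching allele pairs are
    dropped.  Raises :class:`InsufficientInstrumentsError` if no SNP
    survives, carrying per-reason drop counts.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp = exposure.records
    out = outcome.records.set_index("snp_id")
    counts = {"absent_in_outcome": 0, "allele_mismatch": 0, "palindromic_dropped": 0,
              "kept": 0}
    rows = []
    for rec in exp.itertuples(index=False):
        if rec.snp_id not in out.index:
            counts["absent_in_outcome"] += 1
            continue
        o = out.loc[rec.snp_id]
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        palindromic = _is_palindromic(ea_x, oa_x)
        if palindromic:
            if palindrome_policy == "drop":
                counts["palindromic_dropped"] += 1
                continue
            # strand is unknowable from alleles alone; infer from frequencies
            eaf_x, eaf_y = rec.eaf, o["eaf"]
            lo, hi = PALINDROME_EAF_WINDOW
            if (pd.isna(eaf_x) or pd.isna(eaf_y)
                    or lo <= eaf_x <= hi or lo <= eaf_y <= hi):
                counts["palindromic_dropped"] += 1
                continue
            if {ea_y, oa_y} != {ea_x, oa_x}:
                counts["allele_mismatch"] += 1
                continue
            same_minor_side = (eaf_x < 0.5) == (eaf_y < 0.5)
            if ea_y == ea_x:
                flip = not same_minor_side
            else:
                flip = same_minor_side
            beta_out = -float(o["beta"]) if flip else float(o["beta"])
        elif (ea_y, oa_y) == (ea_x, oa_x):
            beta_out = float(o["beta"])
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_out = -float(o["beta"])
        elif (ea_y, oa_y) == (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x]):
            beta_out = float(o["beta"])  # opposite-strand report, same orientation
        elif (ea_y, oa_y) == (_COMPLEMENT[oa_x], _COMPLEMENT[ea_x]):
            beta_out = -float(o["beta"])
        else:
            counts["allele_mismatch"] += 1
            continue
        rows.append((rec.snp_id, float(rec.beta), float(rec.se),
                     beta_out, float(o["se"])))
        counts["kept"] += 1
    if not rows:
        raise InsufficientInstrumentsError(
            f"no instruments survive harmonization for {exposure.exposure_id} vs "
            f"{outcome.trait_id}", counts)
    dropped = sum(v for k, v in counts.items() if k != "kept")
    if dropped:
        logger.info("harmonize(%s vs %s): dropped %d SNP(s) %s",
                    exposure.exposure_id, outcome.trait_id, dropped, counts)
    df = pd.DataFrame(rows, columns=["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"])
    return HarmonizedSet(exposure_id=exposure.exposure_id, outcome_id=outcome.trait_id,
                         rows=df, drop_counts=counts)
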