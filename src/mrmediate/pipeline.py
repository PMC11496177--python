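"""Orchestration of the full two-sample, two-step MR mediation workflow.

``run_pair`` takes one exposure and one outcome summary-statistic file plus
an LD panel and produces instrument selection, harmonization, the five
estimators, and the full sensitivity report.  ``run_mediation_scan`` runs
the study-level workflow: screen every exposure against the outcome (with
Benjamini–Hochberg FDR within the exposure family), screen every mediator
the same way within its own family, test the exposure→mediator leg for
every pair of screen survivors, and assemble the mediation decomposition
for each surviving triangle.

All randomness (bootstraps, MR-PRESSO, simulation) flows from one root
seed via ``numpy.random.SeedSequence`` stream-splitting, so a single
integer reproduces an entire run; every output table carries the seed and
a hash of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import estimators as est
from .gwas_io import (LDPanel, SummaryStatTable, read_ld_panel,
                      read_summary_stats)
from .instruments import (HarmonizedSet, InsufficientInstrumentsError,
                          harmonize, select_instruments)
from .mediation import (MediationResult, bh_fdr, classify_evidence,
                        two_step_mediation)
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger("mrmediate")


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with the study's defaults."""

    iv_pvalue: float = 1e-5        # exposure-association screen for instruments
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    min_f: float = 10.0
    palindrome_policy: str = "drop"
    ivw_variant: str = "multiplicative_random"
    methods: tuple = est.ALL_METHODS
    n_boot: int = 1000
    screen_alpha: float = 0.01     # report threshold for screening steps
    fdr_alpha: float = 0.05        # "causal" tier bound
    leg_alpha: float = 0.05        # exposure->mediator leg threshold
    presso_nsim: int = 1000
    run_presso: bool = True
    direction: str = "forward"     # forward | reverse | both
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _split_seed(root: int, *labels) -> int:
    """Derive an independent 31-bit child seed from the root and a label path."""
    h = hashlib.sha256(("/".join(map(str, labels)) + f"#{root}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PairReport:
    """Result of one exposure/outcome MR analysis (or a structured skip)."""

    exposure_id: str
    outcome_id: str
    status: str                     # "ok" | "skipped"
    reason: str = ""
    n_instruments: int = 0
    estimates: list = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    hset: HarmonizedSet | None = None
    stage_counts: dict = field(default_factory=dict)

    def ivw(self) -> est.MREstimate | None:
        for e in self.estimates:
            if e.method == "ivw":
                return e
        return None


def analyze_pair(exposure: SummaryStatTable, outcome: SummaryStatTable,
                 panel: LDPanel, config: PipelineConfig) -> PairReport:
    """In-memory pair analysis: select → harmonize → estimate → diagnose.

    Never raises on thin data: any stage with too few instruments yields a
    ``status="skipped"`` report carrying the reason and stage counts.
    """
    counts = {"input": exposure.n_snp}
    inst = select_instruments(
        exposure, panel, pvalue_threshold=config.iv_pvalue,
        r2_threshold=config.clump_r2, window_kb=config.clump_kb,
        min_f=config.min_f)
    counts["instruments"] = inst.n_snp
    report = PairReport(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
                        status="ok", stage_counts=counts)
    if inst.n_snp == 0:
        return replace(report, status="skipped", reason="weak instruments")
    try:
        hset = harmonize(inst, outcome, config.palindrome_policy)
    except InsufficientInstrumentsError as err:
        counts.update(err.counts)
        return replace(report, status="skipped", reason=str(err))
    counts["harmonized"] = hset.n_snp
    seed = _split_seed(config.seed, exposure.trait_id, outcome.trait_id)
    report.hset = hset
    report.n_instruments = hset.n_snp
    report.estimates = est.run_all(
        hset, seed, methods=config.methods, ivw_variant=config.ivw_variant,
        n_boot=config.n_boot)
    if hset.n_snp >= 2:
        report.sensitivity = sensitivity_report(
            hset, _split_seed(config.seed, exposure.trait_id,
                              outcome.trait_id, "sens"),
            presso_nsim=config.presso_nsim, run_presso=config.run_presso)
    return report


def run_pair(exposure_path: str, outcome_path: str, panel_path: str,
             config: PipelineConfig) -> PairReport:
    """File-based wrapper around :func:`analyze_pair`.

    With ``config.direction == "reverse"`` the exposure and outcome tables
    are swapped (same thresholds); ``"forward"`` is the default.
    """
    exposure = read_summary_stats(exposure_path)
    outcome = read_summary_stats(outcome_path)
    panel = read_ld_panel(panel_path)
    if config.direction == "reverse":
        exposure, outcome = outcome, exposure
    return analyze_pair(exposure, outcome, panel, config)


def estimates_frame(reports: list[PairReport], config: PipelineConfig) -> pd.DataFrame:
    """Tidy per-method results table (forest-plot columns)."""
    rows = []
    for r in reports:
        if r.status != "ok":
            rows.append({"exposure": r.exposure_id, "outcome": r.outcome_id,
                         "method": "skipped", "n_snp": 0, "note": r.reason})
            continue
        for e in r.estimates:
            rows.append({"exposure": r.exposure_id, "outcome": r.outcome_id,
                         "method": e.method, "n_snp": e.n_snp, "beta": e.beta,
                         "se": e.se, "OR": e.or_, "ci_low": e.ci_low,
                         "ci_high": e.ci_high, "pvalue": e.pvalue, "note": ""})
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash()
    df.attrs["seed"] = config.seed
    return df


@dataclass
class ScanReport:
    """Study-level scan output: screens, legs, and mediation triangles."""

    exposure_screen: pd.DataFrame
    mediator_screen: pd.DataFrame
    leg_results: pd.DataFrame
    triangles: list
    stage_counts: dict
    pair_reports: dict
    config: PipelineConfig


def _screen_family(tables: list[SummaryStatTable], outcome: SummaryStatTable,
                   panel: LDPanel, config: PipelineConfig,
                   family: str) -> tuple[pd.DataFrame, dict]:
    """Screen every family member against the outcome; BH FDR within family."""
    reports = {}
    rows = []
    for tbl in sorted(tables, key=lambda t: t.trait_id):
        rep = analyze_pair(tbl, outcome, panel, config)
        reports[tbl.trait_id] = rep
        e = rep.ivw()
        rows.append({"trait_id": tbl.trait_id, "status": rep.status,
                     "n_snp": rep.n_instruments,
                     "beta": e.beta if e else np.nan,
                     "se": e.se if e else np.nan,
                     "OR": e.or_ if e else np.nan,
                     "ci_low": e.ci_low if e else np.nan,
                     "ci_high": e.ci_high if e else np.nan,
                     "pvalue": e.pvalue if e else np.nan})
    df = pd.DataFrame(rows)
    ok = df["pvalue"].notna()
    fdr = np.full(len(df), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = bh_fdr(df.loc[ok, "pvalue"].to_numpy())
    df["fdr"] = fdr
    df["tier"] = [classify_evidence(p, f) if np.isfinite(p) else "none"
                  for p, f in zip(df["pvalue"], df["fdr"].fillna(1.0))]
    df["significant"] = ok & (df["pvalue"] < config.screen_alpha)
    df.attrs["family"] = family
    return df, reports


def run_mediation_scan(exposures: list[SummaryStatTable],
                       mediators: list[SummaryStatTable],
                       outcome: SummaryStatTable, panel: LDPanel,
                       config: PipelineConfig) -> ScanReport:
    """Full two-step mediation scan over exposure and mediator families.

    Step 0: exposure→outcome screen, FDR within the exposure family.
    Step 1: mediator→outcome screen, FDR within the mediator family.
    Step 2: exposure→mediator MR for each (significant, significant) pair,
    kept at ``config.leg_alpha``.  Step 3: mediation decomposition for each
    surviving triangle.  Output is invariant to input list order.
    """
    if not exposures or not mediators:
        raise ValueError("scan requires at least one exposure and one mediator")
    exp_screen, exp_reports = _screen_family(exposures, outcome, panel, config,
                                             "exposure")
    med_screen, med_reports = _screen_family(mediators, outcome, panel, config,
                                             "mediator")
    sig_exp = sorted(exp_screen.loc[exp_screen["significant"], "trait_id"])
    sig_med = sorted(med_screen.loc[med_screen["significant"], "trait_id"])
    exp_by_id = {t.trait_id: t for t in exposures}
    med_by_id = {t.trait_id: t for t in mediators}

    leg_rows = []
    triangles: list[MediationResult] = []
    pair_reports = {**{("exposure", k): v for k, v in exp_reports.items()},
                    **{("mediator", k): v for k, v in med_reports.items()}}
    # the A legs are exploratory single tests at leg_alpha (no family FDR)
    for eid in sig_exp:
        for mid in sig_med:
            leg = analyze_pair(exp_by_id[eid], med_by_id[mid], panel, config)
            pair_reports[("leg", eid, mid)] = leg
            a = leg.ivw()
            row = {"exposure": eid, "mediator": mid,
                   "status": leg.status,
                   "beta_a": a.beta if a else np.nan,
                   "se_a": a.se if a else np.nan,
                   "pvalue": a.pvalue if a else np.nan}
            leg_rows.append(row)
            if leg.status != "ok" or a is None or a.pvalue >= config.leg_alpha:
                continue
            b = med_reports[mid].ivw()
            total = exp_reports[eid].ivw()
            triangles.append(two_step_mediation(a, b, total))
    leg_results = pd.DataFrame(
        leg_rows, columns=["exposure", "mediator", "status", "beta_a", "se_a",
                           "pvalue"])
    counts = {
        "n_exposures": len(exposures), "n_mediators": len(mediators),
        "exposures_significant": len(sig_exp),
        "mediators_significant": len(sig_med),
        "legs_tested": len(leg_rows), "triangles": len(triangles),
    }
    logger.info("scan stage counts: %s", counts)
    return ScanReport(exposure_screen=exp_screen, mediator_screen=med_screen,
                      leg_results=leg_results, triangles=triangles,
                      stage_counts=counts, pair_reports=pair_reports,
                      config=config)


def mediation_frame(triangles: list[MediationResult]) -> pd.DataFrame:
    """Mediation results in the headline-table layout."""
    rows = []
    for t in triangles:
        rows.append({
            "exposure": t.exposure_id, "mediator": t.mediator_id,
            "outcome": t.outcome_id,
            "mediated_effect": t.mediated,
            "mediated_ci_low": t.mediated_ci[0],
            "mediated_ci_high": t.mediated_ci[1],
            "pvalue": t.mediated_p,
            "proportion_pct": t.proportion_pct,
            "proportion_ci_low_pct": t.proportion_ci_pct[0],
            "proportion_ci_high_pct": t.proportion_ci_pct[1],
            "direct": t.direct, "total": t.total,
            "inconsistent": t.inconsistent,
        })
    return pd.DataFrame(rows, columns=[
        "exposure", "mediator", "outcome", "mediated_effect",
        "mediated_ci_low", "mediated_ci_high", "pvalue", "proportion_pct",
        "proportion_ci_low_pct", "proportion_ci_high_pct", "direct", "total",
        "inconsistent"])


def _provenance_header(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def write_frame(df: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    """Write a result table as TSV with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, sep="\t", index=False)


def write_scan_outputs(scan: ScanReport, out_dir: str) -> dict:
    """Write the scan's TSV outputs; returns {name: path}."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = scan.config
    paths = {}
    for name, df in (("exposure_screen", scan.exposure_screen),
                     ("mediator_screen", scan.mediator_screen),
                     ("legs", scan.leg_results),
                     ("mediation", mediation_frame(scan.triangles))):
        p = os.path.join(out_dir, f"{name}.tsv")
        write_frame(df, p, cfg)
        paths[name] = p
    loo_rows = []
    for key, rep in sorted(scan.pair_reports.items(), key=lambda kv: str(kv[0])):
        if rep.status == "ok" and rep.sensitivity is not None:
            for r in rep.sensitivity.loo:
                loo_rows.append({"pair": "/".join(key), **r})
    p = os.path.join(out_dir, "loo.tsv")
    write_frame(pd.DataFrame(loo_rows), p, cfg)
    paths["loo"] = p
    return paths
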