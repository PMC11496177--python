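"""Synthetic GWAS summary-statistic studies with known mediation structure.

Generates trio-of-trait summary statistics (exposure, mediator, outcome)
directly on the summary-data scale — no individual-level genotypes — under
the causal chain

    exposure --β(A)--> mediator --β(B)--> outcome
        \\________________direct_______________/

with total effect θ = direct + β(A)·β(B).  Exposure instruments carry true
effects γ_j ~ Normal(0, γ_sd²) truncated away from zero; the mediator has
its own instrument set δ_j of the same form; null SNPs have no effect
anywhere.  Observed effects are the true effects plus Normal(0, se²) noise
with the large-sample SE scale se = 1/√(2·maf·(1−maf)·n), additionally
divided by √(K·(1−K)) for the binary outcome with case fraction K.
Horizontal pleiotropy α_j (none, balanced, or directional) is added to the
outcome effects of the exposure instruments.

Default sample sizes and effects emulate a realistic immune-trait →
metabolite → heart-failure study: a small exposure GWAS (n ≈ 3,757), a
mid-sized mediator GWAS (n ≈ 8,299), and a large binary-outcome GWAS
(n ≈ 977,323, ~4.8% cases), with θ = 0.039 on the log-odds scale (OR ≈
1.04) of which ~19.2% is mediated.

LD is block-structured and drives clumping only: each exposure or mediator
instrument heads a block whose remaining members are null "proxy" SNPs with
a declared within-block r²; observed statistics are still drawn
independently per SNP.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import (LDPanel, SummaryStatTable, write_ld_panel,
                      write_summary_stats)

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                   ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy model for exposure instruments' outcome effects."""

    mode: str = "none"  # none | balanced | directional
    sd: float = 0.0
    mean: float = 0.0


@dataclass
class LDConfig:
    """Block LD layout: each instrument heads a block of proxy null SNPs."""

    block_size: int = 3
    within_r2: float = 0.8


@dataclass
class SimConfig:
    """Generating parameters of one synthetic mediation study."""

    n_snp: int = 30                # exposure instruments
    n_snp_med: int = 30            # mediator's own instruments
    n_null_snp: int = 120          # SNPs with no effect anywhere (incl. LD proxies)
    gamma_sd: float = 0.25         # SD of true instrument effects (SD units of trait)
    gamma_floor_frac: float = 0.6  # truncation: |gamma| >= frac * gamma_sd
    theta_total: float = 0.039    # total exposure->outcome effect (log-OR)
    beta_a: float = 0.05          # exposure->mediator
    beta_b: float = 0.15          # mediator->outcome (log-OR)
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_exp: int = 3757
    n_med: int = 8299
    n_out: int = 977_323
    case_fraction_out: float = 47_309 / 977_323
    ld: LDConfig = field(default_factory=LDConfig)
    maf_range: tuple = (0.1, 0.5)
    palindrome_fraction: float = 0.0
    shuffle_outcome_alleles: bool = True
    outlier_snp_effect: float = 0.0  # planted pleiotropic effect on one exposure instrument
    seed: int = 0

    @property
    def direct(self) -> float:
        return self.theta_total - self.beta_a * self.beta_b


@dataclass
class SimTruth:
    """Ground truth of a simulated study, for recovery tests."""

    theta_total: float
    beta_a: float
    beta_b: float
    direct: float
    true_proportion_pct: float
    gamma: np.ndarray          # exposure-instrument effects
    delta: np.ndarray          # mediator-instrument effects
    alpha: np.ndarray          # pleiotropic outcome effects of exposure instruments
    exposure_instrument_ids: list = field(default_factory=list)
    mediator_instrument_ids: list = field(default_factory=list)
    outlier_snp_id: str | None = None


def _truncated_normal(rng: np.random.Generator, n: int, sd: float,
                      floor: float) -> np.ndarray:
    """Normal(0, sd²) with |x| >= floor by rejection (deterministic per rng state)."""
    out = rng.normal(0.0, sd, n)
    bad = np.abs(out) < floor
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) < floor
    return out


def _observed(rng, true_beta, se):
    beta_hat = true_beta + se * rng.standard_normal(len(se))
    p = 2 * stats.norm.sf(np.abs(beta_hat / se))
    return beta_hat, np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_study(config: SimConfig
                   ) -> tuple[SummaryStatTable, SummaryStatTable,
                              SummaryStatTable, LDPanel, SimTruth]:
    """Generate one (exposure, mediator, outcome) summary-statistic trio.

    Returns the three :class:`SummaryStatTable` objects (sharing one SNP
    universe), the block-structured :class:`LDPanel`, and the
    :class:`SimTruth`.  Byte-for-byte deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_e, n_m, n_0 = config.n_snp, config.n_snp_med, config.n_null_snp
    n_tot = n_e + n_m + n_0
    floor = config.gamma_floor_frac * config.gamma_sd

    gamma = _truncated_normal(rng, n_e, config.gamma_sd, floor)
    delta = _truncated_normal(rng, n_m, config.gamma_sd, floor)

    alpha = np.zeros(n_e)
    mode = config.pleiotropy.mode
    if mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy.sd, n_e)
    elif mode == "directional":
        alpha = rng.normal(config.pleiotropy.mean, config.pleiotropy.sd, n_e)
    elif mode != "none":
        raise ValueError(f"unknown pleiotropy mode {mode!r}")

    # true per-SNP effects on each trait
    beta_exp = np.concatenate([gamma, np.zeros(n_m + n_0)])
    beta_med = np.concatenate([gamma * config.beta_a, delta, np.zeros(n_0)])
    beta_out = np.concatenate([gamma * config.theta_total + alpha,
                               delta * config.beta_b, np.zeros(n_0)])
    outlier_id = None
    if config.outlier_snp_effect != 0.0 and n_e > 0:
        beta_out[0] += config.outlier_snp_effect
        outlier_id = "rs0"

    maf = rng.uniform(*config.maf_range, n_tot)
    se_base = 1.0 / np.sqrt(2 * maf * (1 - maf))
    k = config.case_fraction_out
    se_exp = se_base / np.sqrt(config.n_exp)
    se_med = se_base / np.sqrt(config.n_med)
    se_out = se_base / np.sqrt(config.n_out * k * (1 - k))

    bhat_exp, p_exp = _observed(rng, beta_exp, se_exp)
    bhat_med, p_med = _observed(rng, beta_med, se_med)
    bhat_out, p_out = _observed(rng, beta_out, se_out)

    snp_ids = [f"rs{i}" for i in range(n_tot)]
    # layout: instruments (exposure then mediator) each head an LD block
    # whose proxies are drawn from the null pool; blocks are far apart.
    block_size = max(1, config.ld.block_size)
    n_blocks = n_e + n_m
    chrom = np.empty(n_tot, dtype=object)
    pos = np.empty(n_tot, dtype=np.int64)
    block_of = np.full(n_tot, -1)
    null_idx = list(range(n_e + n_m, n_tot))
    proxy_ptr = 0
    for b in range(n_blocks):
        members = [b]
        for _ in range(block_size - 1):
            if proxy_ptr < len(null_idx):
                members.append(null_idx[proxy_ptr])
                proxy_ptr += 1
        c = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 25_000_000
        for off, idx in enumerate(members):
            chrom[idx] = c
            pos[idx] = base + 1000 * off
            block_of[idx] = b
    # leftover nulls: unlinked singleton positions
    for j, idx in enumerate(null_idx[proxy_ptr:]):
        b = n_blocks + j
        chrom[idx] = str(b % 22 + 1)
        pos[idx] = 1_000_000 + (b // 22) * 25_000_000
        block_of[idx] = b

    r2 = np.zeros((n_tot, n_tot))
    np.fill_diagonal(r2, 1.0)
    for b in range(n_blocks):
        members = np.where(block_of == b)[0]
        for i in members:
            for j in members:
                if i != j:
                    r2[i, j] = config.ld.within_r2
    panel = LDPanel(snp_ids=snp_ids, r2=r2, positions=pos.copy())

    n_pal = int(round(config.palindrome_fraction * n_tot))
    pal_mask = np.zeros(n_tot, bool)
    if n_pal:
        pal_mask[rng.choice(n_tot, n_pal, replace=False)] = True
    ea = np.empty(n_tot, dtype=object)
    oa = np.empty(n_tot, dtype=object)
    for i in range(n_tot):
        pool = _PALINDROMIC if pal_mask[i] else _NONPALINDROMIC
        ea[i], oa[i] = pool[rng.integers(len(pool))]

    def table(trait_id, beta_hat, se, p, n, flip_mask=None, comp_mask=None):
        ea_t, oa_t = ea.copy(), oa.copy()
        b = beta_hat.copy()
        eaf = maf.copy()
        if flip_mask is not None:  # report the other allele as effect allele
            ea_t[flip_mask], oa_t[flip_mask] = oa[flip_mask], ea[flip_mask]
            b[flip_mask] = -b[flip_mask]
            eaf[flip_mask] = 1.0 - eaf[flip_mask]
        if comp_mask is not None:  # report on the opposite strand
            for i in np.where(comp_mask)[0]:
                ea_t[i] = _COMPLEMENT[ea_t[i]]
                oa_t[i] = _COMPLEMENT[oa_t[i]]
        df = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea_t, "other_allele": oa_t,
            "eaf": eaf, "beta": b, "se": se, "pvalue": p,
            "n": float(n),
        })
        return SummaryStatTable(trait_id=trait_id, records=df)

    flip_mask = comp_mask = None
    if config.shuffle_outcome_alleles:
        flip_mask = rng.random(n_tot) < 0.5
        comp_mask = (rng.random(n_tot) < 0.25) & ~pal_mask

    exposure = table("exposure", bhat_exp, se_exp, p_exp, config.n_exp)
    mediator = table("mediator", bhat_med, se_med, p_med, config.n_med,
                     flip_mask, comp_mask)
    outcome = table("outcome", bhat_out, se_out, p_out, config.n_out,
                    flip_mask, comp_mask)

    truth = SimTruth(
        theta_total=config.theta_total, beta_a=config.beta_a,
        beta_b=config.beta_b, direct=config.direct,
        true_proportion_pct=100 * config.beta_a * config.beta_b / config.theta_total,
        gamma=gamma, delta=delta, alpha=alpha,
        exposure_instrument_ids=snp_ids[:n_e],
        mediator_instrument_ids=snp_ids[n_e:n_e + n_m],
        outlier_snp_id=outlier_id)
    return exposure, mediator, outcome, panel, truth


def simulate_decoy_trait(config: SimConfig, trait_id: str, seed: int,
                         kind: str = "exposure") -> SummaryStatTable:
    """A trait with its own instruments but no causal link to anything.

    Shares the SNP universe of :func:`simulate_study` under the same
    ``config`` (identical ids, positions, alleles and MAFs) so it can join
    the same scan.  Its instruments sit on the null SNPs of the parent
    study, so the decoy is genuinely associated with nothing downstream.
    """
    n_e, n_m, n_0 = config.n_snp, config.n_snp_med, config.n_null_snp
    n_tot = n_e + n_m + n_0
    parent = simulate_study(config)
    meta = parent[0].records[["snp_id", "chrom", "pos", "effect_allele",
                              "other_allele", "eaf"]].copy()
    rng = np.random.default_rng(seed)
    floor = config.gamma_floor_frac * config.gamma_sd
    n_inst = min(config.n_snp, n_0)
    effects = np.zeros(n_tot)
    # instruments on a random subset of the parent study's null SNPs
    inst_idx = rng.choice(np.arange(n_e + n_m, n_tot), n_inst, replace=False)
    effects[inst_idx] = _truncated_normal(rng, n_inst, config.gamma_sd, floor)
    n = config.n_exp if kind == "exposure" else config.n_med
    maf = meta["eaf"].to_numpy()
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    beta_hat, p = _observed(rng, effects, se)
    df = meta.assign(beta=beta_hat, se=se, pvalue=p, n=float(n))
    return SummaryStatTable(trait_id=trait_id, records=df)


FIXTURES = ("clean", "directional_pleiotropy", "outlier", "weak_instruments")


def fixture_config(name: str, seed: int = 20240) -> SimConfig:
    """Canonical fixture configurations used by the test suite and docs."""
    if name == "clean":
        return SimConfig(seed=seed)
    if name == "directional_pleiotropy":
        return SimConfig(pleiotropy=PleiotropyConfig("directional", sd=0.002, mean=0.006),
                         seed=seed + 1)
    if name == "outlier":
        return SimConfig(outlier_snp_effect=0.15, seed=seed + 2)
    if name == "weak_instruments":
        return SimConfig(gamma_sd=0.05, gamma_floor_frac=0.2, seed=seed + 3)
    raise ValueError(f"unknown fixture {name!r}")


def make_fixture_suite(out_dir: str, seed: int = 20240) -> dict:
    """Write the four canonical fixture studies plus a manifest of truths.

    Each study writes ``<name>_{exposure,mediator,outcome}.tsv`` and
    ``<name>_ld.tsv``; the manifest is a flat ``key = value`` text file of
    generating truths, returned as a dict as well.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {}
    for name in FIXTURES:
        cfg = fixture_config(name, seed)
        exposure, mediator, outcome, panel, truth = simulate_study(cfg)
        for tag, tbl in (("exposure", exposure), ("mediator", mediator),
                         ("outcome", outcome)):
            write_summary_stats(tbl, os.path.join(out_dir, f"{name}_{tag}.tsv"))
        write_ld_panel(panel, os.path.join(out_dir, f"{name}_ld.tsv"))
        manifest[f"{name}.theta_total"] = truth.theta_total
        manifest[f"{name}.beta_a"] = truth.beta_a
        manifest[f"{name}.beta_b"] = truth.beta_b
        manifest[f"{name}.direct"] = truth.direct
        manifest[f"{name}.true_proportion_pct"] = truth.true_proportion_pct
        manifest[f"{name}.seed"] = cfg.seed
        if name == "weak_instruments":
            f = (exposure.records["beta"] / exposure.records["se"]) ** 2
            inst = f.iloc[:cfg.n_snp]
            manifest[f"{name}.frac_weak"] = float((inst < 10).mean())
    with open(os.path.join(out_dir, "manifest.txt"), "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} = {v}\n")
    return manifest


def read_manifest(path: str) -> dict:
    """Read a flat ``key = value`` manifest back into a dict of floats."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                out[k.strip()] = float(v)
    return out
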