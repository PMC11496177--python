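"""Instrument selection, clumping oracle equivalence, and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.gwas_io import LDPanel, SummaryStatTable
from mrmediate.instruments import (HarmonizedSet, InstrumentSet,
                                   InsufficientInstrumentsError,
                                   compute_f_statistics, filter_by_pvalue,
                                   harmonize, ld_clump, select_instruments)
from .conftest import random_table


def brute_force_clump(table, panel, r2_threshold, window_kb):
    """Independent greedy oracle over explicit candidate lists."""
    recs = table.records.to_dict("records")
    recs.sort(key=lambda r: (r["pvalue"], r["pos"], r["snp_id"]))
    kept, removed = [], set()
    for r in recs:
        if r["snp_id"] in removed:
            continue
        kept.append(r["snp_id"])
        for other in recs:
            if other["snp_id"] in removed or other["snp_id"] == r["snp_id"]:
                continue
            if (other["chrom"] == r["chrom"]
                    and abs(other["pos"] - r["pos"]) <= window_kb * 1000
                    and panel.lookup(r["snp_id"], other["snp_id"]) >= r2_threshold):
                removed.add(other["snp_id"])
    return set(kept)


def _block_panel(rng, snps, block=4, r2_in=0.5):
    k = len(snps)
    r2 = np.zeros((k, k))
    np.fill_diagonal(r2, 1.0)
    for start in range(0, k, block):
        idx = range(start, min(start + block, k))
        for i in idx:
            for j in idx:
                if i != j:
                    r2[i, j] = r2_in * rng.uniform(0.5, 1.5) % 1
    r2 = np.maximum(r2, r2.T)
    return LDPanel(snp_ids=list(snps), r2=r2)


def test_pvalue_filter_matches_bruteforce_and_keeps_order(rng):
    table = random_table(rng, n=100)
    thr = 0.3
    got = filter_by_pvalue(table, thr)
    want = [s for s, p in zip(table.records["snp_id"], table.records["pvalue"])
            if p < thr]
    assert list(got.records["snp_id"]) == want


def test_pvalue_filter_paper_threshold_strict():
    df = random_table(np.random.default_rng(0), n=2).records
    df["pvalue"] = [1e-6, 1e-4]
    table = SummaryStatTable("t", df)
    kept = filter_by_pvalue(table, 1e-5)
    assert list(kept.records["snp_id"]) == ["rs0"]
    assert filter_by_pvalue(table, 1.0).n_snp == 2


def test_clump_dominance_and_independence(rng):
    df = random_table(rng, n=2).records
    df["chrom"] = "1"
    df["pos"] = [1000, 2000]
    df["pvalue"] = [1e-8, 1e-6]
    table = SummaryStatTable("t", df)
    linked = LDPanel(["rs0", "rs1"], np.array([[1, 0.9], [0.9, 1]]))
    kept = ld_clump(table, linked, 0.001, 10_000)
    assert list(kept.records["snp_id"]) == ["rs0"]
    unlinked = LDPanel(["rs0", "rs1"], np.eye(2))
    assert ld_clump(table, unlinked, 0.001, 10_000).n_snp == 2


@pytest.mark.parametrize("seed", range(8))
def test_clump_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng, n=20)
    # cluster positions so windows genuinely overlap
    table.records["chrom"] = rng.integers(1, 4, 20).astype(str)
    table.records["pos"] = rng.integers(1, 5_000_000, 20)
    panel = _block_panel(rng, table.records["snp_id"])
    got = ld_clump(table, panel, 0.1, 2_000)
    want = brute_force_clump(table, panel, 0.1, 2_000)
    assert set(got.records["snp_id"]) == want


def test_clump_order_invariance_and_retained_pair_invariant(rng):
    table = random_table(rng, n=20)
    table.records["chrom"] = "2"
    table.records["pos"] = rng.integers(1, 3_000_000, 20)
    panel = _block_panel(rng, table.records["snp_id"])
    kept = ld_clump(table, panel, 0.1, 2_000)
    shuffled = SummaryStatTable(
        "t", table.records.sample(frac=1, random_state=7).reset_index(drop=True))
    kept2 = ld_clump(shuffled, panel, 0.1, 2_000)
    assert set(kept.records["snp_id"]) == set(kept2.records["snp_id"])
    ids = list(kept.records["snp_id"])
    pos = dict(zip(table.records["snp_id"], table.records["pos"]))
    for a in ids:
        for b in ids:
            if a < b and abs(pos[a] - pos[b]) <= 2_000_000:
                assert panel.lookup(a, b) < 0.1


def test_f_statistics_threshold_and_bruteforce(rng):
    df = random_table(rng, n=2).records
    df["beta"], df["se"] = [0.1, 0.01], [0.02, 0.02]
    inst = compute_f_statistics(SummaryStatTable("t", df))
    assert list(inst.records["snp_id"]) == ["rs0"]
    assert inst.records["f_stat"].iloc[0] == pytest.approx(25.0)

    table = random_table(rng, n=50)
    inst = compute_f_statistics(table)
    want = {s for s, b, e in zip(table.records["snp_id"], table.records["beta"],
                                 table.records["se"]) if (b / e) ** 2 >= 10}
    assert set(inst.records["snp_id"]) == want


def test_selection_pipeline_idempotent(rng):
    table = random_table(rng, n=40)
    panel = _block_panel(rng, table.records["snp_id"])
    once = select_instruments(table, panel, pvalue_threshold=0.5,
                              r2_threshold=0.1, window_kb=2000)
    twice = select_instruments(
        SummaryStatTable("t", once.records.drop(columns="f_stat")), panel,
        pvalue_threshold=0.5, r2_threshold=0.1, window_kb=2000)
    pd.testing.assert_frame_equal(once.records, twice.records)


def _one_row_tables(ea_x, oa_x, beta_x, ea_y, oa_y, beta_y,
                    eaf_x=0.3, eaf_y=0.3):
    base = dict(chrom="1", pos=100, se=0.05, pvalue=1e-8, n=1000.0)
    exp = pd.DataFrame([dict(snp_id="rs1", effect_allele=ea_x, other_allele=oa_x,
                             eaf=eaf_x, beta=beta_x, f_stat=100.0, **base)])
    out = pd.DataFrame([dict(snp_id="rs1", effect_allele=ea_y, other_allele=oa_y,
                             eaf=eaf_y, beta=beta_y, **base)])
    return (InstrumentSet("E", exp), SummaryStatTable("O", out))


@pytest.mark.parametrize("ea_y,oa_y,expected", [
    ("A", "G", 0.3),    # same orientation
    ("G", "A", -0.3),   # swapped: flip
    ("T", "C", 0.3),    # opposite strand, same orientation
    ("C", "T", -0.3),   # opposite strand, swapped
])
def test_harmonize_allele_alignment(ea_y, oa_y, expected):
    inst, out = _one_row_tables("A", "G", 0.2, ea_y, oa_y, 0.3)
    h = harmonize(inst, out)
    assert h.rows["beta_out"].iloc[0] == pytest.approx(expected)


def test_harmonize_palindrome_policies():
    # ambiguous frequency: dropped under both policies
    for policy in ("drop", "infer_by_eaf"):
        inst, out = _one_row_tables("A", "T", 0.2, "A", "T", 0.3,
                                    eaf_x=0.5, eaf_y=0.5)
        with pytest.raises(InsufficientInstrumentsError) as err:
            harmonize(inst, out, policy)
        assert err.value.counts["palindromic_dropped"] == 1
    # informative frequencies, same strand: retained with no flip
    inst, out = _one_row_tables("A", "T", 0.2, "A", "T", 0.3,
                                eaf_x=0.10, eaf_y=0.12)
    h = harmonize(inst, out, "infer_by_eaf")
    assert h.rows["beta_out"].iloc[0] == pytest.approx(0.3)
    # informative frequencies on opposite minor sides: strand flip implied
    inst, out = _one_row_tables("A", "T", 0.2, "A", "T", 0.3,
                                eaf_x=0.10, eaf_y=0.88)
    h = harmonize(inst, out, "infer_by_eaf")
    assert h.rows["beta_out"].iloc[0] == pytest.approx(-0.3)


def test_harmonize_drop_reasons_counted():
    inst, out = _one_row_tables("A", "G", 0.2, "A", "C", 0.3)
    with pytest.raises(InsufficientInstrumentsError) as err:
        harmonize(inst, out)
    assert err.value.counts["allele_mismatch"] == 1
    out_absent = SummaryStatTable("O", out.records.assign(snp_id="rs999"))
    with pytest.raises(InsufficientInstrumentsError) as err:
        harmonize(inst, out_absent)
    assert err.value.counts["absent_in_outcome"] == 1


def test_harmonize_exposure_flip_involution(clean_study):
    """Flipping every exposure allele leaves the harmonized set's science
    unchanged: beta_exp/beta_out negate together, so all ratios agree."""
    from mrmediate.pipeline import PipelineConfig, analyze_pair
    exposure, _, outcome, panel, _ = clean_study
    cfg = PipelineConfig(seed=9, methods=("ivw",), run_presso=False, n_boot=0)
    rep = analyze_pair(exposure, outcome, panel, cfg)
    flipped_records = exposure.records.assign(
        effect_allele=exposure.records["other_allele"],
        other_allele=exposure.records["effect_allele"],
        eaf=1 - exposure.records["eaf"],
        beta=-exposure.records["beta"])
    flipped = analyze_pair(
        type(exposure)(exposure.trait_id, flipped_records), outcome, panel, cfg)
    assert flipped.ivw().beta == pytest.approx(rep.ivw().beta, abs=1e-12)
    assert flipped.ivw().se == pytest.approx(rep.ivw().se, abs=1e-12)
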