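"""Reading, validation and writing of GWAS summary statistics and LD panels.

The canonical on-disk format for one trait's summary statistics is a
tab-separated table with a fixed header::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pvalue  n

``eaf`` and ``n`` may be empty.  Dialect differences (column names, comma
delimiters) are absorbed by a ``column_map`` at read time.  Coordinates are
1-based; they are used only for clump windowing.  Only biallelic SNPs with
single-base A/C/G/T alleles are accepted — indels and multi-allelic records
are dropped during validation.

LD panels are either long-format TSV triples ``snp_a  snp_b  r2`` (missing
pairs default to r² = 0) or a square matrix with a header row of SNP ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediate")

#: canonical column order of the on-disk summary-statistic table
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

_MANDATORY = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pvalue"]

_VALID_ALLELES = {"A", "C", "G", "T"}


class ConfigurationError(ValueError):
    """A parameter or file schema problem the user must fix."""


class EmptyInputError(ValueError):
    """No valid rows survived reading/validation."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SummaryStatTable:
    """Per-variant association records for a single GWAS trait.

    ``records`` is a DataFrame with the canonical columns; ``beta`` is the
    per-effect-allele estimate (log-odds for binary traits, SD units for
    continuous traits) and ``se`` its standard error.
    """

    trait_id: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CANONICAL_COLUMNS))

    def __post_init__(self) -> None:
        self.records = self.records.reindex(columns=CANONICAL_COLUMNS)

    @property
    def n_snp(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Raise if an invariant is violated (unique ids, se > 0, p in (0,1])."""
        df = self.records
        if df["snp_id"].duplicated().any():
            dupes = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise FormatError(f"duplicate snp_id values: {dupes[:5]}")
        if (df["se"] <= 0).any():
            raise FormatError("non-positive se present")
        if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
            raise FormatError("p-value outside (0, 1] present")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise FormatError("effect_allele equals other_allele for some rows")


@dataclass
class LDPanel:
    """Pairwise squared-correlation (r²) panel over a set of SNPs."""

    snp_ids: list
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise FormatError(f"r2 matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise FormatError("r2 matrix is not symmetric")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise FormatError("r2 entries outside [0, 1]")
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        """r² between two SNPs; SNPs absent from the panel are unlinked (0)."""
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return 1.0 if snp_a == snp_b else 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_summary_stats(path: str, column_map: dict[str, str] | None = None,
                       trait_id: str | None = None,
                       delimiter: str | None = None) -> SummaryStatTable:
    """Read one trait's summary statistics from a TSV/CSV file.

    Parameters
    ----------
    path:
        File with a header row; tab- or comma-delimited (sniffed unless
        ``delimiter`` is given).
    column_map:
        Mapping from file column names to canonical names, e.g.
        ``{"ES": "beta", "SE": "se", "P": "pvalue"}``.  Unmapped columns that
        already carry canonical names pass through.
    trait_id:
        Label for the trait; defaults to the file stem.

    Rows failing type or range checks (non-positive se, p outside (0,1],
    non-ACGT or identical alleles, duplicated snp_id) are dropped with a
    logged count.  Raises :class:`ConfigurationError` if a mandatory column
    is missing and :class:`EmptyInputError` if no valid rows remain.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=[""],
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].copy()

    n_in = len(df)
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

    ok = (
        df["pos"].notna()
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & ~df["snp_id"].duplicated(keep="first")
    )
    # eaf is optional but must be a frequency when present
    ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("read_summary_stats(%s): dropped %d of %d rows failing validation",
                       path, dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    if df.empty:
        raise EmptyInputError(f"no valid rows in {path}")
    return SummaryStatTable(trait_id=trait_id or _stem(path), records=df)


def _stem(path: str) -> str:
    import os
    return os.path.splitext(os.path.basename(path))[0]


def write_summary_stats(table: SummaryStatTable, path: str) -> None:
    """Write a table in the canonical tab-separated format.

    ``read_summary_stats(write(x))`` reproduces ``x`` exactly: floats are
    serialized with ``repr`` precision, optional fields as empty strings.
    """
    table.validate()
    df = table.records.reindex(columns=CANONICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_ld_panel(path: str) -> LDPanel:
    """Read an LD panel from either long-format triples or a square matrix.

    Long format: three columns ``snp_a, snp_b, r2`` (TSV/CSV, header
    optional but recommended); unmentioned pairs default to r² = 0.
    Square format: first column holds SNP ids, remaining columns one per
    SNP in header order.  Asymmetric entries differing by more than 1e-9
    raise :class:`FormatError`.
    """
    sep = _sniff_delimiter(path)
    head = pd.read_csv(path, sep=sep, nrows=1)
    if head.shape[1] == 3:
        df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str},
                         float_precision="round_trip")
        df.columns = ["snp_a", "snp_b", "r2"]
        snps = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(snps)}
        k = len(snps)
        r2 = np.zeros((k, k))
        np.fill_diagonal(r2, 1.0)
        seen: dict[tuple[int, int], float] = {}
        for a, b, v in df.itertuples(index=False):
            ia, ib = idx[a], idx[b]
            v = float(v)
            key = (min(ia, ib), max(ia, ib))
            if key in seen and abs(seen[key] - v) > 1e-9:
                raise FormatError(f"asymmetric r2 entries for pair ({a}, {b})")
            seen[key] = v
            if ia != ib:
                r2[ia, ib] = r2[ib, ia] = v
        return LDPanel(snp_ids=snps, r2=r2)
    # square-matrix format
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    snps = [str(s) for s in df.columns]
    r2 = df.to_numpy(dtype=float)
    if not np.allclose(r2, r2.T, atol=1e-9):
        raise FormatError("square LD matrix is asymmetric beyond 1e-9")
    return LDPanel(snp_ids=snps, r2=(r2 + r2.T) / 2.0)


def write_ld_panel(panel: LDPanel, path: str) -> None:
    """Write a panel as long-format TSV, omitting zero off-diagonal pairs."""
    k = len(panel.snp_ids)
    # self-pairs keep the SNP universe intact even when all off-diagonals are 0
    rows = [(s, s, 1.0) for s in panel.snp_ids]
    for i in range(k):
        for j in range(i + 1, k):
            if panel.r2[i, j] != 0.0:
                rows.append((panel.snp_ids[i], panel.snp_ids[j], panel.r2[i, j]))
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)
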