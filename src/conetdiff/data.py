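"""Core data containers and plain-text I/O.

Expression data lives in a pandas DataFrame (rows = genes/transcripts,
columns = tissue samples) carrying log-transformed FPKM-like values.
Ortholog maps are tidy tables of (transcript_id, ortholog_id, evalue)
best-hit assignments against a shared reference proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "OrthologMap",
    "load_expression",
    "write_expression",
    "load_ortholog_map",
    "write_ortholog_map",
]

#: maximum BLASTX e-value for a transcript->ortholog assignment to be kept
EVALUE_CUTOFF = 1e-5


@dataclass
class ExpressionDataset:
    """Gene-by-sample matrix of log-expression values.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene (or transcript) identifiers with
        one column per sample; column names are tissue labels.
    species_tag
        Free-text label naming the species/dataset, carried through reports.
    """

    values: pd.DataFrame
    species_tag: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample label: {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_labels(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, genes) -> "ExpressionDataset":
        """Return a new dataset restricted to ``genes`` (order preserved)."""
        return ExpressionDataset(self.values.loc[list(genes)], self.species_tag)


@dataclass
class OrthologMap:
    """Best-hit transcript -> ortholog assignments.

    ``table`` has columns ``transcript_id``, ``ortholog_id``, ``evalue``.
    Rows above the e-value cutoff are dropped on construction; only the
    single best (lowest e-value) hit per transcript is retained.
    """

    table: pd.DataFrame
    evalue_cutoff: float = field(default=EVALUE_CUTOFF)

    def __post_init__(self) -> None:
        required = {"transcript_id", "ortholog_id", "evalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ortholog map missing columns: {sorted(missing)}")
        t = self.table[self.table["evalue"] <= self.evalue_cutoff]
        t = t.sort_values(["transcript_id", "evalue", "ortholog_id"], kind="mergesort")
        self.table = t.drop_duplicates("transcript_id", keep="first").reset_index(drop=True)

    def ortholog_of(self) -> pd.Series:
        """Series mapping transcript_id -> ortholog_id."""
        return self.table.set_index("transcript_id")["ortholog_id"]


def load_expression(path) -> ExpressionDataset:
    """Read an expression TSV: header of sample names, first column gene IDs.

    Missing values are encoded as ``NA``. Duplicate gene identifiers and
    non-numeric cells raise descriptive errors naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.nonzero(df.index == dup)[0][1]) + 2  # +1 header, +1 one-based
        raise ValueError(f"duplicate gene id {dup!r} at line {line} of {path}")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                line = int(df.index.get_loc(bad.index[0])) + 2
                raise ValueError(
                    f"non-numeric value {bad.iloc[0]!r} in column {col!r} "
                    f"at line {line} of {path}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df.index.name = None
    return ExpressionDataset(df.astype(float))


def write_expression(x: ExpressionDataset, path) -> None:
    """Write a dataset as TSV with ``NA`` for missing values.

    Floating-point formatting is fixed (repr-faithful ``%.10g``) so that a
    write/read round trip and repeated runs are byte-identical.
    """
    x.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", index_label="gene_id")


def load_ortholog_map(path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t"))


def write_ortholog_map(m: OrthologMap, path) -> None:
    m.table.to_csv(path, sep="\t", index=False, float_format="%.3g")


def load_gene_sets(path) -> dict:
    """Read named gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    raise ValueError(f"malformed GMT line {i} in {path}")
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
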