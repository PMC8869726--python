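"""Core data containers and TSV input/output.

All on-disk artifacts are plain TSV with a header row, UTF-8, '.' decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised expression units
UNITS = ("counts", "fpkm")


def timepoint_order(labels) -> list:
    """Return time-point labels sorted numerically when possible.

    Labels that parse as numbers are ordered by value (0, 2, 4, ... DAP);
    otherwise the order of first appearance is kept.
    """
    uniq = list(pd.unique(pd.Series(list(labels))))
    try:
        return sorted(uniq, key=float)
    except (TypeError, ValueError):
        return uniq


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Genes (index) x samples (columns), non-negative counts or FPKM.
    samples : DataFrame
        Indexed by sample id, with columns ``timepoint`` and ``replicate``.
    unit : {"counts", "fpkm"}
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("timepoint", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        # align metadata to the column order of the matrix
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> list:
        return timepoint_order(self.samples["timepoint"])

    def samples_at(self, timepoint) -> list:
        """Sample ids belonging to one time point."""
        mask = self.samples["timepoint"] == timepoint
        if not mask.any():
            raise KeyError(f"unknown time point {timepoint!r}")
        return list(self.samples.index[mask])

    def timepoint_means(self) -> pd.DataFrame:
        """Replicate-mean expression, genes x time points (ordered)."""
        cols = {}
        for tp in self.timepoints:
            cols[tp] = self.values[self.samples_at(tp)].mean(axis=1)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# TSV I/O

_FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_counts(counts_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype={"timepoint": str})
    return ExpressionMatrix(values=values, samples=samples, unit="counts")


def read_fpkm(fpkm_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype={"timepoint": str})
    return ExpressionMatrix(values=values, samples=samples, unit="fpkm")


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_triads(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"triad_id", "gene_A", "gene_B", "gene_D"}
    if not required.issubset(df.columns):
        raise ValueError(f"triad table needs columns {sorted(required)}")
    return df.set_index("triad_id")


def read_annotation(path) -> pd.DataFrame:
    """Gene -> term map as a two-column (gene_id, term_id) frame."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    return df[["gene_id", "term_id"]]


def write_matrix(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    write_tsv(out, path, index=True)
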