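"""Expression-table input/output and per-subtype sample selection.

Expression values arrive as tab-separated tables: rows are transcripts
(genes in FPKM, miRs in reads-per-million-miR-mapped), columns are samples.
A companion two-column table maps every sample to a molecular subtype; one
bipartite network is later built per subtype, so the central operation here
is a pure column selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("gene", "miR")


@dataclass(frozen=True)
class ExpressionMatrix:
    """One expression layer: nonnegative values over named samples.

    Parameters
    ----------
    layer:
        Either ``"gene"`` or ``"miR"``.
    data:
        DataFrame with transcript ids as the index and sample ids as
        columns. Values must be finite and nonnegative.
    """

    layer: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        idx = self.data.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate transcript ids: {dupes}")
        cols = self.data.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_transcripts(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression_table(path: str | Path, layer: str) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample ids, first column = ids).

    Duplicate transcript ids, negative cells and non-numeric cells are
    errors; the offending ids are named in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate transcript ids in {path.name}: {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {path.name}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(layer=layer, data=df)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same TSV layout ``read_expression_table`` reads."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.data.to_csv(path, sep="\t", float_format="%.10g")


@dataclass(frozen=True)
class SubtypeAssignment:
    """Mapping sample id -> subtype label (each sample exactly one label)."""

    labels: Mapping[str, str]

    @property
    def subtypes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        return list(dict.fromkeys(self.labels.values()))

    def samples_for(self, subtype: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == subtype]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.labels


def read_subtype_table(path: str | Path) -> SubtypeAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"subtype table must have 2 columns, got {df.shape[1]}")
    sample_col, label_col = df.columns
    if df[sample_col].duplicated().any():
        dupes = sorted(set(df[sample_col][df[sample_col].duplicated()]))
        raise ValueError(f"samples with more than one subtype label: {dupes}")
    return SubtypeAssignment(labels=dict(zip(df[sample_col], df[label_col])))


def write_subtype_table(assign: SubtypeAssignment, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"sample_id": list(assign.labels), "subtype": list(assign.labels.values())}
    ).to_csv(path, sep="\t", index=False)


MIN_SAMPLES_PER_SUBTYPE = 4  # equal-frequency MI needs >= 2 bins of >= 2 samples


def split_by_subtype(
    expr: ExpressionMatrix, assign: SubtypeAssignment, subtype: str
) -> ExpressionMatrix:
    """Restrict columns to the samples carrying ``subtype``, order preserved.

    Samples present in the table but absent from the assignment are skipped
    with a warning. Fewer than four matching samples is an error.
    """
    if subtype not in assign.subtypes:
        raise KeyError(f"unknown subtype label: {subtype!r}")
    unassigned = [s for s in expr.sample_ids if s not in assign]
    if unassigned:
        logger.warning(
            "%d sample(s) lack a subtype label and are ignored: %s",
            len(unassigned),
            ", ".join(unassigned[:5]),
        )
    keep = [s for s in expr.sample_ids if s in assign and assign.labels[s] == subtype]
    if len(keep) < MIN_SAMPLES_PER_SUBTYPE:
        raise ValueError(
            f"subtype {subtype!r} has {len(keep)} samples; "
            f"need >= {MIN_SAMPLES_PER_SUBTYPE}"
        )
    return ExpressionMatrix(layer=expr.layer, data=expr.data[keep])


def drop_zero_variance(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Remove transcripts constant across samples (MI is degenerate for them).

    Returns the filtered matrix and the list of dropped transcript ids.
    """
    values = expr.values
    constant = (values == values[:, :1]).all(axis=1)
    dropped = [t for t, c in zip(expr.transcript_ids, constant) if c]
    if dropped:
        logger.info(
            "dropping %d zero-variance %s transcript(s): %s%s",
            len(dropped),
            expr.layer,
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    kept = expr.data.loc[~constant]
    return ExpressionMatrix(layer=expr.layer, data=kept), dropped


def common_samples(
    mir: ExpressionMatrix, gene: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Align both layers on their shared samples, in gene-table order."""
    shared = [s for s in gene.sample_ids if s in set(mir.sample_ids)]
    if len(shared) < MIN_SAMPLES_PER_SUBTYPE:
        raise ValueError(f"only {len(shared)} shared samples between layers")
    return (
        ExpressionMatrix(layer=mir.layer, data=mir.data[shared]),
        ExpressionMatrix(layer=gene.layer, data=gene.data[shared]),
    )
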