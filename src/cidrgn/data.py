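"""Expression data containers and text-format I/O.

The central container is :class:`ExpressionDataset`: a cell-line × gene
log-expression matrix with a two-level phenotype label per cell line and an
optional scalar modulator (a cell-line characteristic such as drug
sensitivity) used by the sample-specific network mode.

File formats are plain text only: expression as TSV (rows = cell lines,
first column cell-line id, second phenotype, optional third modulator), gene
sets as GMT (name, description, tab-separated gene ids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SubnetworkSpec",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
]

_RESERVED = ("cell_line", "phenotype", "modulator")


@dataclass
class SubnetworkSpec:
    """A named gene set to be scored as one subnetwork."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")


class ExpressionDataset:
    """Cell-line × gene expression matrix with phenotype labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are cell lines, columns are genes. Must be fully numeric with
        no missing values.
    phenotype : sequence of str
        One label per cell line; exactly two distinct levels.
    modulator : sequence of float, optional
        One scalar per cell line; required for sample-specific mode.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        phenotype: Sequence[str],
        modulator: Sequence[float] | None = None,
    ) -> None:
        values = pd.DataFrame(values)
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        phenotype = pd.Series(list(phenotype), index=values.index, name="phenotype")
        if len(phenotype) != len(values):
            raise ValueError("phenotype length does not match number of cell lines")
        levels = sorted(phenotype.unique().tolist())
        if len(levels) != 2:
            raise ValueError(
                f"phenotype must have exactly two levels, got {levels!r}"
            )
        if modulator is not None:
            modulator = pd.Series(
                np.asarray(list(modulator), dtype=float),
                index=values.index,
                name="modulator",
            )
            if modulator.isna().any():
                raise ValueError("modulator contains missing values")
        self.values = values.astype(float)
        self.phenotype = phenotype
        self.modulator = modulator

    # -- basic introspection -------------------------------------------------
    @property
    def n_cell_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def levels(self) -> tuple[str, str]:
        """The two phenotype levels in sorted order."""
        lv = sorted(self.phenotype.unique().tolist())
        return lv[0], lv[1]

    def mask(self, level: str) -> np.ndarray:
        """Boolean cell-line mask for one phenotype level."""
        return (self.phenotype == level).to_numpy()

    def subset(self, level: str) -> "ExpressionDataset":
        """Return the cell lines of one phenotype as a new dataset.

        The returned object keeps the two-level contract relaxed: it is a
        plain DataFrame view used internally for estimation, so this method
        returns ``(values, modulator)`` callers should not need; use
        :meth:`mask` plus ``values`` instead.
        """
        raise NotImplementedError("use mask()/values for phenotype subsets")

    def __repr__(self) -> str:  # pragma: no cover
        a, b = self.levels
        na = int(self.mask(a).sum())
        nb = int(self.mask(b).sum())
        mod = ", modulator" if self.modulator is not None else ""
        return (
            f"ExpressionDataset({self.n_cell_lines} cell lines × "
            f"{self.n_genes} genes; {a}: {na}, {b}: {nb}{mod})"
        )


# ---------------------------------------------------------------------------
# TSV expression I/O
# ---------------------------------------------------------------------------

def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as TSV: cell_line, phenotype, [modulator], genes."""
    out = pd.DataFrame({"cell_line": dataset.values.index.astype(str)})
    out["phenotype"] = dataset.phenotype.to_numpy()
    if dataset.modulator is not None:
        out["modulator"] = dataset.modulator.to_numpy()
    vals = dataset.values.reset_index(drop=True)
    out = pd.concat([out, vals], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionDataset:
    """Read an expression TSV written by :func:`write_expression`.

    Parameters
    ----------
    path : str or Path
    transpose : bool
        If True the expression block is gene-major (genes as rows) and is
        transposed after reading; the phenotype/modulator columns must still
        be cell-line-major header columns, so this flag only applies to files
        holding a bare matrix plus sidecar columns and is rarely needed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str})
    if "phenotype" not in df.columns:
        raise ValueError(f"{path}: missing required 'phenotype' column")
    if "cell_line" not in df.columns:
        raise ValueError(f"{path}: missing required 'cell_line' column")
    if df["cell_line"].duplicated().any():
        dup = df.loc[df["cell_line"].duplicated(), "cell_line"].iloc[0]
        raise ValueError(f"{path}: duplicate cell-line id {dup!r}")
    modulator = df["modulator"].tolist() if "modulator" in df.columns else None
    gene_cols = [c for c in df.columns if c not in _RESERVED]
    expr = df[gene_cols]
    bad = expr.columns[~expr.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        col = bad[0]
        row = expr[col].map(lambda v: not _is_number(v)).idxmax()
        raise ValueError(
            f"{path}: non-numeric expression cell at row {row}, column {col!r}"
        )
    if expr.isna().any().any():
        col = expr.columns[expr.isna().any()][0]
        row = int(expr[col].isna().idxmax())
        raise ValueError(f"{path}: blank expression cell at row {row}, column {col!r}")
    expr = expr.copy()
    expr.index = df["cell_line"].tolist()
    if transpose:
        expr = expr.T
    return ExpressionDataset(expr, df["phenotype"].tolist(), modulator)


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# GMT gene-set I/O
# ---------------------------------------------------------------------------

def write_gene_sets(subnetworks: Sequence[SubnetworkSpec], path: str | Path) -> None:
    """Write gene sets as GMT (name, description, tab-separated genes)."""
    with open(path, "w") as fh:
        for s in subnetworks:
            desc = s.description or "na"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


def read_gene_sets(
    path: str | Path, universe: Sequence[str] | None = None
) -> list[SubnetworkSpec]:
    """Read a GMT file; optionally filter genes to an expression universe.

    Genes absent from `universe` are dropped with a warning; a set left
    empty after filtering is skipped with a warning.
    """
    uni = set(universe) if universe is not None else None
    out: list[SubnetworkSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene)"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if uni is not None:
                known = [g for g in genes if g in uni]
                missing = [g for g in genes if g not in uni]
                if missing:
                    warnings.warn(
                        f"{name}: dropped {len(missing)} gene(s) absent from the "
                        f"expression universe (e.g. {missing[0]!r})"
                    )
                genes = known
            if not genes:
                warnings.warn(f"{name}: empty after filtering; skipped")
                continue
            out.append(SubnetworkSpec(name=name, genes=genes, description=desc))
    return out
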