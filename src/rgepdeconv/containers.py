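"""Core in-memory containers shared across the pipeline.

Expression data are kept as plain genes x columns :class:`pandas.DataFrame`
objects wrapped with a scale flag, because every operation in this package is
a dense linear-algebraic transform on at most a few thousand genes; columns
are either single cells or bulk samples depending on context.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TPM = "tpm"
LOG2 = "log2"

#: within-sample normalization target: every TPM column sums to one million
TPM_TOTAL = 1e6


class ScaleError(ValueError):
    """Raised when an operation receives data on the wrong expression scale."""


@dataclass
class ExpressionMatrix:
    """A genes x columns expression table with an explicit scale flag.

    Parameters
    ----------
    values
        Non-negative expression values, genes as rows (unique ids in the
        index), cells or samples as columns (unique ids).
    scale
        Either ``"tpm"`` (linear, columns summing to ~1e6 for full matrices)
        or ``"log2"`` (log2(TPM+1), possibly housekeeping-rescaled).
    """

    values: pd.DataFrame
    scale: str = TPM

    def __post_init__(self) -> None:
        if self.scale not in (TPM, LOG2):
            raise ScaleError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate column ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def column_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale)

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: gene rows, header row of column ids."""
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = TPM) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale)

    def to_mtx(self, out_dir: str | Path, prefix: str = "") -> None:
        """Write MatrixMarket triplet plus genes.tsv / barcodes.tsv sidecars."""
        from scipy import io as spio
        from scipy import sparse

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(out / f"{prefix}matrix.mtx", sparse.csr_matrix(self.values.to_numpy()))
        (out / f"{prefix}genes.tsv").write_text("\n".join(self.gene_ids) + "\n")
        (out / f"{prefix}barcodes.tsv").write_text("\n".join(self.column_ids) + "\n")

    @classmethod
    def from_mtx(cls, in_dir: str | Path, prefix: str = "", scale: str = TPM) -> "ExpressionMatrix":
        from scipy import io as spio

        src = Path(in_dir)
        mat = spio.mmread(src / f"{prefix}matrix.mtx").toarray()
        genes = (src / f"{prefix}genes.tsv").read_text().splitlines()
        cols = (src / f"{prefix}barcodes.tsv").read_text().splitlines()
        return cls(pd.DataFrame(mat, index=genes, columns=cols), scale)


def tpm_scale(values: pd.DataFrame | pd.Series):
    """Rescale columns of non-negative linear values to sum to 1e6.

    All-zero columns are left at zero (an empty droplet stays empty).
    """
    if isinstance(values, pd.Series):
        total = values.sum()
        return values * (TPM_TOTAL / total) if total > 0 else values
    totals = values.sum(axis=0)
    factors = np.where(totals > 0, TPM_TOTAL / np.where(totals > 0, totals, 1.0), 0.0)
    return values * factors


@dataclass
class MarkerSpec:
    """AND / OR / NOT marker-gene lists per cell type.

    AND genes are all required, a single OR gene suffices, and NOT genes are a
    negative selection criterion; the three lists must be disjoint within a
    type.
    """

    markers: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    KEYS = ("AND", "OR", "NOT")

    def __post_init__(self) -> None:
        for ctype, lists in self.markers.items():
            for key in self.KEYS:
                lists.setdefault(key, [])
            seen: set[str] = set()
            for key in self.KEYS:
                overlap = seen.intersection(lists[key])
                if overlap:
                    raise ValueError(
                        f"marker lists for {ctype!r} overlap: {sorted(overlap)}"
                    )
                seen.update(lists[key])

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def genes(self) -> list[str]:
        out: list[str] = []
        for lists in self.markers.values():
            for key in self.KEYS:
                out.extend(lists[key])
        return sorted(set(out))

    def restrict_to(self, available: pd.Index | set[str]) -> "MarkerSpec":
        """Drop marker genes absent from ``available`` (with a warning)."""
        avail = set(available)
        missing = [g for g in self.genes() if g not in avail]
        if missing:
            warnings.warn(f"dropping {len(missing)} marker genes absent from matrix: "
                          f"{missing[:5]}...", stacklevel=2)
        pruned = {
            ctype: {key: [g for g in lists[key] if g in avail] for key in self.KEYS}
            for ctype, lists in self.markers.items()
        }
        return MarkerSpec(pruned)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.markers, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerSpec":
        return cls(json.loads(Path(path).read_text()))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
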