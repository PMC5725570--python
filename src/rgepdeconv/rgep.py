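"""Pseudobulk construction and the five reference-profile configurations.

A reference gene expression profile (RGEP) matrix B holds one consensus
column per cell type, averaged over annotated single cells drawn from a
configuration-specific pool:

=======  ==========================================================
RGEP1    blood-source cells only (no tumour-associated columns)
RGEP2    cells pooled over all three tissue sources
RGEP3    cells from the target sample's source (indication-specific)
CNTR1    as RGEP3, but malignant column(s) from the target patient
CNTR2    every column from the target patient only
=======  ==========================================================

Consensus columns are cell-weighted means in log2 space by default (linear
averaging behind a flag); cells labelled "unknown" never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LOG2, TPM, ExpressionMatrix, ScaleError, tpm_scale
from .synthetic import BLOOD

CONFIGS = ("RGEP1", "RGEP2", "RGEP3", "CNTR1", "CNTR2")


@dataclass
class BulkProfile:
    values: pd.Series                # gene -> TPM-scale expression
    sample_id: str
    provenance: str = "pseudobulk"   # or "measured"

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("negative bulk expression values")


@dataclass
class SignatureMatrix:
    B: pd.DataFrame                  # genes x cell types, log2 consensus scale
    config: str
    source: str | None = None        # context for RGEP3 / CNTR1 / CNTR2
    patient: str | None = None       # context for CNTR1 / CNTR2

    def __post_init__(self):
        if self.config not in CONFIGS:
            raise ValueError(f"unknown signature config {self.config!r}")
        if (self.B.to_numpy() < 0).any():
            raise ValueError("negative signature entries")

    @property
    def cell_types(self) -> list[str]:
        return list(self.B.columns)

    def drop_types(self, types: list[str]) -> "SignatureMatrix":
        keep = [c for c in self.B.columns if c not in set(types)]
        return SignatureMatrix(self.B[keep], self.config, self.source, self.patient)

    def linear(self) -> pd.DataFrame:
        """Consensus columns back on the linear TPM-like scale."""
        return np.clip(np.exp2(self.B) - 1.0, 0, None)

    def to_tsv(self, path) -> None:
        self.B.to_csv(path, sep="\t", index_label="gene")


def build_pseudobulk(sample: ExpressionMatrix, sample_id: str = "pseudobulk") -> BulkProfile:
    """Artificial bulk profile: per-gene mean of TPM cells, rescaled to 1e6.

    Under equal per-cell depth this equals aggregating reads over all cell
    barcodes of the sample.
    """
    if sample.scale != TPM:
        raise ScaleError("pseudobulk construction expects TPM-scale cells")
    if sample.n_columns == 0:
        raise ValueError("cannot build a pseudobulk from zero cells")
    mean = sample.values.mean(axis=1)
    return BulkProfile(tpm_scale(mean), sample_id)


def _select_cells(
    ann: pd.DataFrame, ctype: str, config: str, malignant: set[str],
    source: str | None, patient: str | None,
) -> pd.Index:
    mask = ann["cell_type"] == ctype
    if config == "RGEP1":
        mask &= ann["source"] == BLOOD
    elif config == "RGEP3":
        mask &= ann["source"] == source
    elif config == "CNTR1":
        if ctype in malignant:
            mask &= ann["patient"] == patient
        else:
            mask &= ann["source"] == source
    elif config == "CNTR2":
        mask &= ann["patient"] == patient
    return ann.index[mask]


def build_rgep(
    cells: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: str,
    cell_types: list[str] | None = None,
    malignant_types: list[str] | None = None,
    source: str | None = None,
    patient: str | None = None,
    average: str = "log",
) -> SignatureMatrix:
    """Build one signature matrix from annotated, log2-normalized cells.

    ``annotation`` needs columns cell_id / cell_type / patient / source and
    must cover every column of ``cells``; "unknown" cells are skipped. Types
    with no contributing cell in the requested context are dropped with a
    warning — their mass then surfaces in the unknown fraction downstream.
    """
    if cells.scale != LOG2:
        raise ScaleError("signature construction expects log2-normalized cells")
    if config not in CONFIGS:
        raise ValueError(f"unknown signature config {config!r}")
    if config in ("RGEP3", "CNTR1", "CNTR2") and source is None:
        raise ValueError(f"{config} requires a source context")
    if config in ("CNTR1", "CNTR2") and patient is None:
        raise ValueError(f"{config} requires a patient context")
    ann = annotation.set_index("cell_id")
    missing = cells.column_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for {len(missing)} cells")
    ann = ann.loc[cells.column_ids]
    malignant = set(malignant_types or [])
    if cell_types is None:
        cell_types = sorted(set(ann["cell_type"]) - {"unknown"})

    columns, dropped = {}, []
    for ctype in cell_types:
        ids = _select_cells(ann, ctype, config, malignant, source, patient)
        if len(ids) == 0:
            dropped.append(ctype)
            continue
        sub = cells.values[ids]
        if average == "log":
            columns[ctype] = sub.mean(axis=1)
        elif average == "linear":
            lin = np.clip(np.exp2(sub) - 1.0, 0, None)
            columns[ctype] = np.log2(lin.mean(axis=1) + 1.0)
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
    if dropped:
        warnings.warn(f"{config}: no cells for type(s) {dropped}; column(s) dropped",
                      stacklevel=2)
    if not columns:
        raise ValueError(f"{config}: no cell type has contributing cells")
    return SignatureMatrix(pd.DataFrame(columns), config, source, patient)
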