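"""Expression normalization and gene-id harmonization.

The processing order is fixed: TPM -> log2(TPM+1) -> housekeeping rescaling.
Housekeeping normalization multiplies each column by H̄K/HK_i, where HK_i is
the column's mean log2 expression over the housekeeping genes and H̄K the
grand mean over all housekeeping genes and columns, so that every column ends
up with the same housekeeping level. Quantile-style alternatives (upper
quartile, median) are deliberately not offered: single-cell columns carry too
many zeros for those statistics to be stable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LOG2, TPM, ExpressionMatrix, ScaleError


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1); refuses to double-transform."""
    if m.scale != TPM:
        raise ScaleError("matrix is already log2-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), LOG2)


def unlog(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log_transform` (2**y - 1), back to the linear scale."""
    if m.scale != LOG2:
        raise ScaleError("matrix is not on the log2 scale")
    return ExpressionMatrix(np.clip(np.exp2(m.values) - 1.0, 0, None), TPM)


@dataclass
class HousekeepingSet:
    """A list of stably expressed genes used to put columns on one scale."""

    gene_ids: list[str]

    def resolve(self, m: ExpressionMatrix) -> pd.Index:
        present = m.gene_ids.intersection(self.gene_ids)
        if len(present) == 0:
            raise ValueError("no housekeeping genes present in matrix")
        return present

    def column_means(self, m: ExpressionMatrix) -> pd.Series:
        """HK_i: per-column mean log2 expression over the housekeeping genes."""
        return m.values.loc[self.resolve(m)].mean(axis=0)

    def global_mean(self, m: ExpressionMatrix) -> float:
        """H̄K: mean over all housekeeping genes and columns."""
        return float(m.values.loc[self.resolve(m)].to_numpy().mean())


def housekeeping_normalize(
    m: ExpressionMatrix,
    hk: HousekeepingSet | list[str],
    reference_mean: float | None = None,
) -> ExpressionMatrix:
    """Rescale each column so its housekeeping mean equals the global mean.

    ``reference_mean`` substitutes an external H̄K so that independently
    processed data sets (e.g. bulk profiles and the single-cell reference they
    are deconvolved against) share one scale.
    """
    if m.scale != LOG2:
        raise ScaleError("housekeeping normalization expects log2 data")
    if not isinstance(hk, HousekeepingSet):
        hk = HousekeepingSet(list(hk))
    hk_i = hk.column_means(m)
    zero = hk_i.index[hk_i <= 0]
    if len(zero):
        raise ValueError(
            f"column(s) with non-positive housekeeping mean: {list(zero[:5])}")
    hbar = hk.global_mean(m) if reference_mean is None else float(reference_mean)
    return ExpressionMatrix(m.values * (hbar / hk_i), LOG2)


# ---------------------------------------------------------------------------
# Excel date-corruption repair
# ---------------------------------------------------------------------------

# gene families historically corrupted by spreadsheet date auto-conversion
_MONTH_FAMILY = {"mar": "MARCH", "sep": "SEPT", "sept": "SEPT", "dec": "DEC"}
_MONTH_NUMBER = {3: "MARCH", 9: "SEPT", 12: "DEC"}
_VALID_MEMBERS = {
    "MARCH": set(range(1, 12)),          # MARCH1..MARCH11
    "SEPT": set(range(1, 13)) | {14},    # SEPT1..SEPT12, SEPT14
    "DEC": {1},                          # DEC1
}

_DASH_DM = re.compile(r"^(\d{1,2})-([A-Za-z]{3,5})\.?$")
_DASH_MD = re.compile(r"^([A-Za-z]{3,5})\.?-(\d{1,2})$")
_DOTTED = re.compile(r"^(\d{1,2})\.(\d{1,2})(?:\.\d{2,4})?$")


def _repair_one(gene_id: str) -> str:
    m = _DASH_DM.match(gene_id) or _DASH_MD.match(gene_id)
    if m:
        a, b = m.groups()
        day, month = (a, b) if a.isdigit() else (b, a)
        family = _MONTH_FAMILY.get(month.lower())
        if family and int(day) in _VALID_MEMBERS[family]:
            return f"{family}{int(day)}"
        return gene_id
    m = _DOTTED.match(gene_id)
    if m:
        day, month = int(m.group(1)), int(m.group(2))
        family = _MONTH_NUMBER.get(month)
        if family and day in _VALID_MEMBERS[family]:
            return f"{family}{day}"
    return gene_id


def repair_excel_gene_symbols(gene_ids) -> list[str]:
    """Map spreadsheet-date-corrupted ids ("1-Mar", "Sep-2", "1.3.2016") back
    to their gene symbols (MARCH1, SEPT2, ...); everything else is unchanged.

    Raises if the repair would create duplicate ids.
    """
    repaired = [_repair_one(g) for g in gene_ids]
    counts = pd.Series(repaired).value_counts()
    dups = sorted(counts.index[counts > 1])
    if dups:
        raise ValueError(f"symbol repair created duplicate ids: {dups[:10]}")
    return repaired


def filter_to_gene_set(
    m: ExpressionMatrix, gene_set: list[str], on_missing: str = "drop",
) -> ExpressionMatrix:
    """Restrict rows to ``gene_set`` (in its order), dropping absent genes.

    With ``on_missing="error"`` any absent gene aborts; the default mirrors
    signature-set practice, where published lists routinely contain genes not
    measured in a given data set (e.g. 496 of LM22's 547 present).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in m.gene_ids]
    missing = len(gene_set) - len(present)
    if missing and on_missing == "error":
        absent = [g for g in gene_set if g not in m.gene_ids]
        raise ValueError(f"{missing} gene(s) missing from matrix: {absent[:10]}")
    if not present:
        raise ValueError("gene set has empty intersection with matrix")
    if missing:
        warnings.warn(f"{len(present)}/{len(gene_set)} gene-set genes present; "
                      f"{missing} dropped", stacklevel=2)
    return ExpressionMatrix(m.values.loc[present], m.scale)
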