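"""Mixture-weight estimation from a bulk profile and a signature matrix.

The mixture model is m = B·w with non-negative weights summing to at most
one; the shortfall w̃ = 1 − Σw is the mass of cell types absent from the
signature. Four solvers are provided: ν-support-vector regression (the
noise-robust default, ν = 0.5, linear kernel, C = 1, on per-gene standardized
data), the pseudo-inverse least-squares solution, ordinary least squares with
an intercept, and an L2-regularized non-negative least-squares program
min ‖Bw − m‖² + λ‖w‖² s.t. w ≥ 0 (λ = 1).

Solvers operate on the linear TPM scale, where the mixture identity holds
exactly; a log-space option exists for exploratory use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.svm import NuSVR

from .containers import TPM, ExpressionMatrix
from .rgep import BulkProfile, SignatureMatrix

SOLVERS = ("nusvr", "pinv", "lm", "regnnls")


@dataclass
class CompositionEstimate:
    """Non-negative cell-type fractions plus the unknown remainder.

    Invariant: Σw + w̃ = 1 with w ≥ 0 and w̃ ≥ 0; ``raw_w`` keeps the
    solver output before clipping/renormalization.
    """

    w: pd.Series
    unknown: float
    solver: str
    raw_w: pd.Series
    sample_id: str | None = None
    intercept: float | None = None
    n_genes_used: int | None = None

    def __post_init__(self):
        if (self.w < 0).any() or self.unknown < -1e-9:
            raise ValueError("fractions must be non-negative")
        total = self.w.sum() + self.unknown
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    def fraction(self, cell_type: str) -> float:
        return float(self.w.get(cell_type, 0.0))

    def as_series(self, include_unknown: bool = True) -> pd.Series:
        out = self.w.copy()
        if include_unknown:
            out["unknown"] = self.unknown
        return out


def standardize_for_svr(B: pd.DataFrame, m: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene centre/scale of the (B | m) system by B's row mean and s.d.

    Applying the identical affine map to m keeps the mixture relation intact
    for weights summing to one. Zero-variance gene rows are dropped with a
    warning; a signature whose rows are all constant is degenerate.
    """
    mu = B.mean(axis=1)
    sd = B.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate signature: all gene rows have zero variance")
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance gene rows for SVR",
                      stacklevel=2)
    Bk, mk, muk, sdk = B.loc[keep], m.loc[keep], mu[keep], sd[keep]
    return Bk.sub(muk, axis=0).div(sdk, axis=0), (mk - muk) / sdk


def deconvolve_nusvr(B: pd.DataFrame, m: pd.Series, nu: float = 0.5, C: float = 1.0) -> pd.Series:
    """ν-SVR with a linear kernel on the standardized system; primal weights."""
    if B.shape[0] < B.shape[1]:
        raise ValueError("need at least as many genes as cell types")
    Bs, ms = standardize_for_svr(B, m)
    svr = NuSVR(kernel="linear", nu=nu, C=C)
    svr.fit(Bs.to_numpy(), ms.to_numpy())
    if svr.fit_status_ != 0:  # pragma: no cover - libsvm rarely reports failure
        raise RuntimeError(f"nu-SVR failed to converge (status {svr.fit_status_})")
    w = svr.coef_.ravel()
    # Per-gene centring puts the all-ones weight direction in the null space of
    # the standardized signature (each row of B' sums to zero), so the SVR
    # returns weights only up to a constant shift. Pin that gauge by a
    # one-parameter least-squares fit in the original scale, which restores
    # the absolute weight calibration needed for the unknown fraction.
    b1 = B.to_numpy().sum(axis=1)
    denom = b1 @ b1
    if denom > 0:
        resid = m.to_numpy() - B.to_numpy() @ w
        w = w + (resid @ b1) / denom
    return pd.Series(w, index=B.columns)


def deconvolve_pinv(B: pd.DataFrame, m: pd.Series) -> pd.Series:
    """Minimum-norm least-squares solution w = pinv(B)·m."""
    w = np.linalg.pinv(B.to_numpy()) @ m.to_numpy()
    return pd.Series(w, index=B.columns)


def deconvolve_lm_intercept(B: pd.DataFrame, m: pd.Series) -> tuple[pd.Series, float]:
    """Ordinary least squares with an intercept column; intercept returned
    separately and excluded from the weights."""
    X = np.column_stack([np.ones(B.shape[0]), B.to_numpy()])
    coef, *_ = np.linalg.lstsq(X, m.to_numpy(), rcond=None)
    return pd.Series(coef[1:], index=B.columns), float(coef[0])


def deconvolve_reg_nnls(B: pd.DataFrame, m: pd.Series, lam: float = 1.0) -> pd.Series:
    """Exact solution of min ‖Bw−m‖² + λ‖w‖² s.t. w ≥ 0 via the augmented
    NNLS system [B; √λ·I]w = [m; 0] (always feasible at w = 0)."""
    k = B.shape[1]
    A = np.vstack([B.to_numpy(), np.sqrt(lam) * np.eye(k)]) if lam > 0 else B.to_numpy()
    b = np.concatenate([m.to_numpy(), np.zeros(k)]) if lam > 0 else m.to_numpy()
    w, _ = optimize.nnls(A, b)
    return pd.Series(w, index=B.columns)


def postprocess_weights(
    raw_w: pd.Series, solver: str = "pinv", sample_id: str | None = None,
    intercept: float | None = None, n_genes_used: int | None = None,
) -> CompositionEstimate:
    """Negative weights to zero; w̃ = 1 − Σw, with renormalization if Σw > 1."""
    if not np.isfinite(raw_w.to_numpy()).all():
        raise ValueError("raw weights contain non-finite values")
    w = raw_w.clip(lower=0.0)
    total = w.sum()
    if total > 1.0:
        w = w / total
        unknown = 0.0
    else:
        unknown = 1.0 - total
    return CompositionEstimate(w, float(unknown), solver, raw_w, sample_id,
                               intercept, n_genes_used)


_SOLVER_FUNCS = {
    "nusvr": deconvolve_nusvr,
    "pinv": deconvolve_pinv,
    "regnnls": deconvolve_reg_nnls,
}


def deconvolve_sample(
    bulk: BulkProfile,
    signature: SignatureMatrix,
    gene_set: list[str] | None = None,
    solver: str = "nusvr",
    space: str = "linear",
    **solver_kwargs,
) -> CompositionEstimate:
    """Filter bulk and signature to a common gene set, solve, postprocess.

    ``space="linear"`` (default) solves on TPM-scale values, matching the
    physical mixing of transcripts; ``space="log"`` solves directly on the
    log2 consensus scale.
    """
    if solver not in SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; choose from {SOLVERS}")
    genes = signature.B.index.intersection(bulk.values.index)
    if gene_set is not None:
        order = [g for g in gene_set if g in set(genes)]
        genes = pd.Index(order)
    if len(genes) == 0:
        raise ValueError("empty gene intersection between bulk, signature and gene set")
    if space == "linear":
        B = signature.linear().loc[genes]
        m = bulk.values.loc[genes]
    elif space == "log":
        B = signature.B.loc[genes]
        m = np.log2(bulk.values.loc[genes] + 1.0)
    else:
        raise ValueError(f"unknown space {space!r}")

    intercept = None
    if solver == "lm":
        raw, intercept = deconvolve_lm_intercept(B, m)
    else:
        raw = _SOLVER_FUNCS[solver](B, m, **solver_kwargs)
    return postprocess_weights(raw, solver, bulk.sample_id, intercept, len(genes))
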