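"""Accuracy benchmarking of deconvolution across signature configurations.

For every sample the benchmark builds a pseudobulk, constructs the
configuration-appropriate signature matrix, deconvolves, and compares the
estimated composition to the generator's realized ground truth. Accuracy is
the per-cell-type Pearson correlation across samples, with bootstrap
(100 replications, resampling samples) quartiles, RMSD as an alternative
metric, T-subset ratio accuracy, and a leave-one-type-out robustness scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .deconvolve import CompositionEstimate, deconvolve_sample
from .preprocess import log_transform
from .rgep import CONFIGS, SignatureMatrix, build_pseudobulk, build_rgep
from .synthetic import Cohort

T_SUBSETS = ("Treg", "CD4 T cell", "CD8 T cell")
RATIOS = {
    "Treg/CD4": ("Treg", "CD4 T cell"),
    "CD8/Treg": ("CD8 T cell", "Treg"),
    "CD4/CD8": ("CD4 T cell", "CD8 T cell"),
}


def correlation_accuracy(est: pd.Series, truth: pd.Series) -> float:
    """Pearson ρ of estimated vs true fractions across samples.

    Returns NaN (reported as missing, not zero) when the truth is constant —
    correlation is not a meaningful accuracy measure for a type whose true
    proportion does not vary.
    """
    est, truth = est.align(truth, join="inner")
    if len(truth) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(truth.to_numpy()) == 0 or np.ptp(est.to_numpy()) == 0:
        return float("nan")
    return float(stats.pearsonr(est.to_numpy(), truth.to_numpy())[0])


def rmsd_accuracy(est: pd.Series, truth: pd.Series) -> float:
    est, truth = est.align(truth, join="inner")
    return float(np.sqrt(np.mean((est.to_numpy() - truth.to_numpy()) ** 2)))


def bootstrap_accuracy(
    est: pd.Series, truth: pd.Series, reps: int = 100, seed: int = 0,
) -> tuple[float, float, float]:
    """(median, q25, q75) of ρ over bootstrap resamples of the samples.

    Degenerate resamples (constant truth) are redrawn.
    """
    est, truth = est.align(truth, join="inner")
    n = len(truth)
    if n < 3:
        raise ValueError("need at least 3 samples to bootstrap")
    rng = np.random.default_rng(seed)
    e, t = est.to_numpy(), truth.to_numpy()
    rhos = []
    guard = 0
    while len(rhos) < reps and guard < 100 * reps:
        guard += 1
        idx = rng.integers(0, n, n)
        if np.ptp(t[idx]) == 0 or np.ptp(e[idx]) == 0:
            continue
        rhos.append(stats.pearsonr(e[idx], t[idx])[0])
    if not rhos:
        return float("nan"), float("nan"), float("nan")
    q25, med, q75 = np.percentile(rhos, [25, 50, 75])
    return float(med), float(q25), float(q75)


def aggregate_t_cells(
    fractions: pd.Series, subsets=T_SUBSETS, total_label: str = "T cell (total)",
) -> pd.Series:
    """Add the summed T-cell proportion; conserves the overall total.

    Subsets that are absent (or not estimated, NaN) contribute zero.
    """
    out = fractions.copy()
    vals = [fractions.get(s, 0.0) for s in subsets]
    out[total_label] = float(np.nansum([v for v in vals]))
    return out


def tcell_ratios(fractions: pd.Series, eps: float = 1e-4) -> dict[str, float]:
    """Treg/CD4, CD8/Treg and CD4/CD8 ratios; NaN where the denominator is
    below ``eps`` (those samples are excluded from downstream correlations)."""
    out = {}
    for name, (num, den) in RATIOS.items():
        d = float(fractions.get(den, 0.0))
        out[name] = float(fractions.get(num, 0.0)) / d if d >= eps else float("nan")
    return out


@dataclass
class BenchmarkReport:
    estimates: pd.DataFrame       # config, sample, cell_type, estimated, true
    type_stats: pd.DataFrame      # config, cell_type, rho, rho_median/q25/q75, rmsd
    ratio_stats: pd.DataFrame     # config, ratio, rho, n_samples
    solver: str
    gene_set_size: int

    def median_rho(self, config: str, cell_types: list[str] | None = None) -> float:
        sub = self.type_stats[self.type_stats["config"] == config]
        if cell_types is not None:
            sub = sub[sub["cell_type"].isin(cell_types)]
        return float(sub["rho"].dropna().median())

    def types_estimated(self, config: str) -> list[str]:
        sub = self.estimates[self.estimates["config"] == config]
        present = sub.groupby("cell_type")["estimated"].max()
        return sorted(present.index[present.notna()])

    def shared_types(self) -> list[str]:
        """Cell types estimated under every configuration in the report."""
        configs = self.estimates["config"].unique()
        shared = None
        for cfg in configs:
            types = set(self.types_estimated(cfg))
            shared = types if shared is None else shared & types
        return sorted(shared or [])

    def to_tsv(self, path) -> None:
        self.type_stats.to_csv(path, sep="\t", index=False)


def _signatures_for_config(
    cohort: Cohort, log_cells: ExpressionMatrix, annotation: pd.DataFrame,
    config: str, average: str,
) -> dict[str, SignatureMatrix]:
    """Signature per sample (cached per context: one per source / patient)."""
    cfg = cohort.config
    kwargs = dict(cell_types=cfg.type_names, malignant_types=cfg.malignant_types,
                  average=average)
    cache: dict[tuple, SignatureMatrix] = {}
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in cohort.samples:
            if config in ("RGEP1", "RGEP2"):
                key = ()
            elif config == "RGEP3":
                key = (s.source,)
            else:
                key = (s.source, s.patient)
            if key not in cache:
                cache[key] = build_rgep(log_cells, annotation, config,
                                        source=s.source, patient=s.patient, **kwargs)
            out[s.sample_id] = cache[key]
    return out


def run_benchmark(
    cohort: Cohort,
    configs: tuple[str, ...] = CONFIGS,
    gene_set: str | list[str] = "merged",
    solver: str = "nusvr",
    annotation: pd.DataFrame | None = None,
    seed: int = 0,
    bootstrap_reps: int = 100,
    average: str = "linear",
    space: str = "linear",
) -> BenchmarkReport:
    """Deconvolve every sample under each configuration and score accuracy.

    ``annotation`` defaults to the generator's true labels; pass the output
    of the classification pipeline to benchmark the full workflow.

    Consensus averaging defaults to linear here (unlike :func:`build_rgep`):
    pseudobulk aggregation is linear in transcript counts, so a patient's
    pseudobulk is exactly a mixture of linear-averaged consensus columns of
    the same cells, whereas log-space averaging adds a Jensen bias that
    penalizes precisely the configurations built from the fewest cells.
    """
    cells, true_ann = cohort.concat_cells()
    ann = annotation if annotation is not None else true_ann
    log_cells = log_transform(cells)
    genes = cohort.gene_set(gene_set) if isinstance(gene_set, str) else list(gene_set)
    truth = cohort.truth.composition
    all_types = cohort.config.type_names

    bulks = {s.sample_id: build_pseudobulk(s.expression, s.sample_id)
             for s in cohort.samples}

    rows = []
    for config in configs:
        sigs = _signatures_for_config(cohort, log_cells, ann, config, average)
        for s in cohort.samples:
            est = deconvolve_sample(bulks[s.sample_id], sigs[s.sample_id],
                                    gene_set=genes, solver=solver, space=space)
            for ctype in all_types:
                in_sig = ctype in est.w.index
                rows.append({
                    "config": config, "sample": s.sample_id, "cell_type": ctype,
                    "estimated": est.fraction(ctype) if in_sig else np.nan,
                    "true": float(truth.loc[s.sample_id, ctype]),
                })
            rows.append({"config": config, "sample": s.sample_id,
                         "cell_type": "unknown", "estimated": est.unknown,
                         "true": float(truth.loc[s.sample_id,
                                                 [t for t in all_types
                                                  if t not in est.w.index]].sum())})
    estimates = pd.DataFrame(rows)

    # per-type accuracy, T subsets individually plus their total
    stat_rows, ratio_rows = [], []
    for config in configs:
        sub = estimates[estimates["config"] == config]
        est_wide = sub.pivot(index="sample", columns="cell_type", values="estimated")
        true_wide = sub.pivot(index="sample", columns="cell_type", values="true")
        est_wide = est_wide.apply(aggregate_t_cells, axis=1)
        true_wide = true_wide.apply(aggregate_t_cells, axis=1)
        for ctype in est_wide.columns:
            e = est_wide[ctype]
            if e.isna().all():
                continue
            t = true_wide[ctype]
            rho = correlation_accuracy(e.fillna(0), t)
            med, q25, q75 = bootstrap_accuracy(e.fillna(0), t, reps=bootstrap_reps,
                                               seed=seed)
            stat_rows.append({"config": config, "cell_type": ctype, "rho": rho,
                              "rho_median": med, "rho_q25": q25, "rho_q75": q75,
                              "rmsd": rmsd_accuracy(e.fillna(0), t)})
        # T-subset ratios (only meaningful when subsets are estimated)
        if all(s in est_wide.columns and est_wide[s].notna().any() for s in T_SUBSETS):
            est_r = pd.DataFrame({i: tcell_ratios(est_wide.loc[i].fillna(0))
                                  for i in est_wide.index}).T
            true_r = pd.DataFrame({i: tcell_ratios(true_wide.loc[i])
                                   for i in true_wide.index}).T
            for ratio in RATIOS:
                ok = est_r[ratio].notna() & true_r[ratio].notna()
                if ok.sum() >= 3 and np.ptp(true_r.loc[ok, ratio].to_numpy()) > 0:
                    rho = correlation_accuracy(est_r.loc[ok, ratio], true_r.loc[ok, ratio])
                else:
                    rho = float("nan")
                ratio_rows.append({"config": config, "ratio": ratio, "rho": rho,
                                   "n_samples": int(ok.sum())})

    return BenchmarkReport(estimates, pd.DataFrame(stat_rows),
                           pd.DataFrame(ratio_rows), solver, len(genes))


def leave_one_type_out(
    cohort: Cohort,
    config: str = "RGEP3",
    gene_set: str | list[str] = "merged",
    solver: str = "nusvr",
    annotation: pd.DataFrame | None = None,
    space: str = "linear",
) -> pd.DataFrame:
    """Δρ per remaining type when one signature column at a time is removed.

    Rows: removed type; columns: evaluated type; entries: ρ(without) − ρ(full).
    The removed type's own column is NaN (its ρ is undefined without an
    estimate).
    """
    cells, true_ann = cohort.concat_cells()
    ann = annotation if annotation is not None else true_ann
    log_cells = log_transform(cells)
    genes = cohort.gene_set(gene_set) if isinstance(gene_set, str) else list(gene_set)
    truth = cohort.truth.composition
    bulks = {s.sample_id: build_pseudobulk(s.expression, s.sample_id)
             for s in cohort.samples}
    sigs = _signatures_for_config(cohort, log_cells, ann, config, "log")

    def rho_per_type(drop: str | None) -> pd.Series:
        est_rows = {}
        for s in cohort.samples:
            sig = sigs[s.sample_id]
            if drop is not None:
                sig = sig.drop_types([drop])
            est = deconvolve_sample(bulks[s.sample_id], sig, gene_set=genes,
                                    solver=solver, space=space)
            est_rows[s.sample_id] = est.as_series(False)
        est_wide = pd.DataFrame(est_rows).T
        out = {}
        for ctype in est_wide.columns:
            out[ctype] = correlation_accuracy(est_wide[ctype].fillna(0), truth[ctype])
        return pd.Series(out)

    full = rho_per_type(None)
    rows = {}
    for removed in full.index:
        delta = rho_per_type(removed) - full
        delta[removed] = np.nan
        rows[removed] = delta
    out = pd.DataFrame(rows).T.reindex(columns=full.index)
    out.index.name = "removed_type"
    return out
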