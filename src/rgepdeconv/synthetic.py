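"""Seeded synthetic single-cell cohorts for benchmarking deconvolution.

The generator emulates the statistical structure the downstream analysis
assumes: cell-type-specific expression programmes, tissue-source shifts
between blood and two tumour sites, patient-specific malignant-cell profiles,
AND/OR/NOT marker genes, and housekeeping genes with a stable shared level.
Expression is modelled log-normally in log2 space with additive Gaussian
effects; cells are rendered to the TPM scale (columns summing to 1e6) with
optional Bernoulli dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LOG2, TPM, ExpressionMatrix, MarkerSpec, tpm_scale, write_gene_list

BLOOD = "blood"
SOURCES = (BLOOD, "tumorA", "tumorB")

T_PARENT = "T cell"


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CellType:
    name: str
    is_malignant: bool = False
    tumor_associated: bool = False
    parent: str | None = None

    def __post_init__(self):
        if self.is_malignant and not self.tumor_associated:
            object.__setattr__(self, "tumor_associated", True)


def default_cell_types() -> list[CellType]:
    """Melanoma/ascites-like panel: 7 major types plus three T subsets."""
    return [
        CellType("Malignant", is_malignant=True),
        CellType("CAF", tumor_associated=True),
        CellType("Endothelial", tumor_associated=True),
        CellType("B cell"),
        CellType("NK cell"),
        CellType("Macrophage"),
        CellType("DC"),
        CellType("CD4 T cell", parent=T_PARENT),
        CellType("CD8 T cell", parent=T_PARENT),
        CellType("Treg", parent=T_PARENT),
    ]


def default_composition_alpha() -> dict[str, dict[str, float]]:
    """Dirichlet concentrations per source; tumour-associated types never in blood."""
    return {
        BLOOD: {
            "CD4 T cell": 4.0, "CD8 T cell": 3.0, "Treg": 0.7,
            "B cell": 2.0, "NK cell": 1.5, "Macrophage": 2.0, "DC": 0.5,
        },
        "tumorA": {
            "Malignant": 5.0, "CAF": 0.8, "Endothelial": 0.8,
            "B cell": 1.0, "NK cell": 0.7, "Macrophage": 1.5, "DC": 0.4,
            "CD4 T cell": 2.0, "CD8 T cell": 1.5, "Treg": 0.8,
        },
        "tumorB": {
            "Malignant": 4.0, "CAF": 1.0, "Endothelial": 0.7,
            "B cell": 0.8, "NK cell": 0.8, "Macrophage": 1.8, "DC": 0.5,
            "CD4 T cell": 1.8, "CD8 T cell": 1.6, "Treg": 0.7,
        },
    }


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the three-tissue-source design (4 blood donors, 19
    tumour-site-A patients, 4 tumour-site-B patients → 27 samples).
    """

    n_genes: int = 1000
    cell_types: list[CellType] = field(default_factory=default_cell_types)
    n_patients_per_source: dict[str, int] = field(
        default_factory=lambda: {BLOOD: 4, "tumorA": 19, "tumorB": 4})
    cells_per_sample: int = 100
    composition_alpha: dict[str, dict[str, float]] = field(
        default_factory=default_composition_alpha)
    base_expression_scale: float = 4.0   # mean log2 level of expressed genes
    marker_boost: float = 4.0            # marker genes sit this far above base
    expressed_fraction: float = 0.45     # background genes on per type
    background_sd: float = 1.5           # spread of background log2 levels
    marker_fraction: float = 0.06
    hk_fraction: float = 0.10
    source_shift_sd: float = 0.5         # per-gene log2 shift of non-blood sources
    patient_shift_sd: float = 0.4        # malignant-cell patient effect (log2)
    subset_shift_sd: float = 1.0         # T-subset perturbation of shared T base
    noise_sd: float = 0.3                # per-cell log2 noise
    dropout_rate: float = 0.05
    seed: int = 0

    # -- derived views -------------------------------------------------------
    @property
    def type_names(self) -> list[str]:
        return [t.name for t in self.cell_types]

    @property
    def tumor_associated_types(self) -> list[str]:
        return [t.name for t in self.cell_types if t.tumor_associated]

    @property
    def malignant_types(self) -> list[str]:
        return [t.name for t in self.cell_types if t.is_malignant]

    @property
    def sources(self) -> list[str]:
        return list(self.n_patients_per_source)

    def validate(self) -> None:
        for frac, name in ((self.marker_fraction, "marker_fraction"),
                           (self.hk_fraction, "hk_fraction"),
                           (self.dropout_rate, "dropout_rate"),
                           (self.expressed_fraction, "expressed_fraction")):
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name}={frac} outside [0, 1]")
        if self.marker_fraction + self.hk_fraction >= 1:
            raise ConfigError("marker_fraction + hk_fraction must be < 1")
        for sd in (self.source_shift_sd, self.patient_shift_sd, self.noise_sd):
            if sd < 0:
                raise ConfigError("shift/noise standard deviations must be >= 0")
        if self.n_genes <= 0 or self.cells_per_sample < 0:
            raise ConfigError("n_genes and cells_per_sample must be positive")
        names = self.type_names
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell type names")
        tumor = set(self.tumor_associated_types)
        for source, alpha in self.composition_alpha.items():
            for ctype, a in alpha.items():
                if ctype not in names:
                    raise ConfigError(f"alpha for unknown type {ctype!r}")
                if a <= 0:
                    raise ConfigError(f"composition_alpha[{source}][{ctype}] <= 0")
            if source == BLOOD:
                present = tumor.intersection(alpha)
                if present:
                    raise ConfigError(
                        f"tumour-associated types in blood composition: {sorted(present)}")
        for source in self.n_patients_per_source:
            if source not in self.composition_alpha:
                raise ConfigError(f"no composition_alpha for source {source!r}")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            **{k: v for k, v in self.__dict__.items() if k != "cell_types"},
            "cell_types": [t.__dict__ for t in self.cell_types],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["cell_types"] = [CellType(**t) for t in doc.get("cell_types", [])]
        return cls(**doc)


# ---------------------------------------------------------------------------
# gene panel + mean profiles
# ---------------------------------------------------------------------------

@dataclass
class GenePanel:
    """Allocation of the gene index into marker / housekeeping / background."""

    gene_ids: pd.Index
    marker_spec: MarkerSpec          # major-level: parent T entry, no subsets
    tsubset_spec: MarkerSpec         # T-subset level
    hk_genes: list[str]
    marker_genes: list[str]
    background_genes: list[str]


N_AND = 2
N_OR = 2


def _allocate_markers(config: CohortConfig) -> tuple[dict, dict, list[str]]:
    """Assign AND/OR marker gene names per major entity and T subset."""
    subsets = [t.name for t in config.cell_types if t.parent == T_PARENT]
    majors = [t.name for t in config.cell_types if t.parent is None]
    if subsets:
        majors = majors + [T_PARENT]

    def mk(entity: str, cat: str, i: int) -> str:
        return f"M_{entity.replace(' ', '')}_{cat}{i + 1}"

    own: dict[str, dict[str, list[str]]] = {}
    for entity in majors + subsets:
        own[entity] = {
            "AND": [mk(entity, "AND", i) for i in range(N_AND)],
            "OR": [mk(entity, "OR", i) for i in range(N_OR)],
        }
    # NOT lists: the first AND marker of every sibling entity
    major_spec = {
        e: {"AND": own[e]["AND"], "OR": own[e]["OR"],
            "NOT": [own[o]["AND"][0] for o in majors if o != e]}
        for e in majors
    }
    tsub_spec = {
        s: {"AND": own[s]["AND"], "OR": own[s]["OR"],
            "NOT": [own[o]["AND"][0] for o in subsets if o != s]}
        for s in subsets
    }
    all_marker_genes = sorted({g for e in own.values() for lst in e.values() for g in lst})
    return major_spec, tsub_spec, all_marker_genes


def build_gene_panel(config: CohortConfig) -> GenePanel:
    major_spec, tsub_spec, marker_genes = _allocate_markers(config)
    n_marker_budget = int(round(config.marker_fraction * config.n_genes))
    if len(marker_genes) > n_marker_budget:
        raise ConfigError(
            f"marker_fraction allows {n_marker_budget} genes but the cell-type "
            f"panel needs {len(marker_genes)}; increase n_genes or marker_fraction")
    n_hk = int(round(config.hk_fraction * config.n_genes))
    n_background = config.n_genes - len(marker_genes) - n_hk
    if n_background <= 0:
        raise ConfigError("too few genes left for background after markers + housekeeping")
    hk_genes = [f"HK{i + 1:04d}" for i in range(n_hk)]
    background = [f"G{i + 1:05d}" for i in range(n_background)]
    gene_ids = pd.Index(marker_genes + hk_genes + background, name="gene")
    return GenePanel(gene_ids, MarkerSpec(major_spec), MarkerSpec(tsub_spec),
                     hk_genes, marker_genes, background)


def generate_type_profiles(
    config: CohortConfig, rng: np.random.Generator | None = None,
    panel: GenePanel | None = None,
) -> tuple[dict[tuple[str, str], pd.Series], GenePanel]:
    """Mean log2 profile per (cell type, source), before TPM rendering.

    Marker genes follow the AND/OR/NOT structure (high in the owning type
    only), housekeeping genes share one level everywhere, non-blood sources
    add a per-gene Normal(0, source_shift_sd) shift to non-housekeeping genes,
    and T subsets are correlated perturbations of a shared T-cell base.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = build_gene_panel(config)

    n = config.n_genes
    gene_ids = panel.gene_ids
    hk_mask = gene_ids.isin(panel.hk_genes)
    bg_index = pd.Index(panel.background_genes)
    high = config.base_expression_scale + config.marker_boost

    # shared T-cell base background so subsets form a continuum
    subsets = {t.name for t in config.cell_types if t.parent == T_PARENT}
    t_base_bg: pd.Series | None = None
    if subsets:
        on = rng.random(len(bg_index)) < config.expressed_fraction
        t_base_bg = pd.Series(
            np.where(on, np.clip(rng.normal(config.base_expression_scale,
                                            config.background_sd, len(bg_index)), 0, None), 0.0),
            index=bg_index)

    def entities_of(type_name: str) -> list[str]:
        """Marker-owning entities whose AND/OR genes are high in this type."""
        ct = next(t for t in config.cell_types if t.name == type_name)
        return [ct.name] if ct.parent is None else [ct.parent, ct.name]

    marker_entities = {**panel.marker_spec.markers, **panel.tsubset_spec.markers}

    base: dict[str, pd.Series] = {}
    for ct in config.cell_types:
        prof = pd.Series(0.0, index=gene_ids)
        # background programme
        if ct.name in subsets:
            bg = t_base_bg + rng.normal(0, config.subset_shift_sd, len(bg_index))
            prof.loc[bg_index] = np.clip(bg.to_numpy(), 0, None)
        else:
            on = rng.random(len(bg_index)) < config.expressed_fraction
            prof.loc[bg_index] = np.where(
                on, np.clip(rng.normal(config.base_expression_scale,
                                       config.background_sd, len(bg_index)), 0, None), 0.0)
        # housekeeping: one shared level across all types and sources
        prof.loc[hk_mask] = config.base_expression_scale
        # markers: high in the owning entity (and, for subsets, the T parent)
        for entity in entities_of(ct.name):
            lists = marker_entities.get(entity)
            if lists:
                prof.loc[lists["AND"] + lists["OR"]] = high
        base[ct.name] = prof

    profiles: dict[tuple[str, str], pd.Series] = {}
    for ct in config.cell_types:
        for source in config.sources:
            prof = base[ct.name].copy()
            if source != BLOOD and config.source_shift_sd > 0:
                shift = rng.normal(0, config.source_shift_sd, n)
                shift[hk_mask] = 0.0
                prof = pd.Series(np.clip(prof.to_numpy() + shift, 0, None), index=gene_ids)
            profiles[(ct.name, source)] = prof
    return profiles, panel


# ---------------------------------------------------------------------------
# sample + cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleData:
    sample_id: str
    patient: str
    source: str
    expression: ExpressionMatrix          # TPM scale, genes x cells
    annotation: pd.DataFrame              # cell_id, cell_type, patient, source


@dataclass
class GroundTruth:
    """What the generator knows: realized compositions, labels, profiles."""

    composition: pd.DataFrame             # samples x cell types, rows sum to 1
    cell_labels: pd.Series                # cell_id -> true type
    type_profiles: dict[str, pd.DataFrame]  # sample_id -> genes x types, log2(TPM+1)

    def tumor_profile(self, sample_id: str, malignant_type: str = "Malignant") -> pd.Series:
        return self.type_profiles[sample_id][malignant_type]


@dataclass
class Cohort:
    config: CohortConfig
    samples: list[SampleData]
    truth: GroundTruth
    marker_spec: MarkerSpec
    tsubset_spec: MarkerSpec
    hk_genes: list[str]
    marker_genes: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleData:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def concat_cells(self) -> tuple[ExpressionMatrix, pd.DataFrame]:
        """All cells of the cohort as one TPM matrix plus true annotation."""
        mats = [s.expression.values for s in self.samples if s.expression.n_columns]
        anns = [s.annotation for s in self.samples if len(s.annotation)]
        values = pd.concat(mats, axis=1) if mats else pd.DataFrame()
        ann = pd.concat(anns, ignore_index=True) if anns else pd.DataFrame(
            columns=["cell_id", "cell_type", "patient", "source"])
        return ExpressionMatrix(values, TPM), ann

    def gene_set(self, name: str = "merged", n_extra: int = 400) -> list[str]:
        """Canonical signature gene sets.

        ``markers``: the AND/OR/NOT panel only. ``merged``: markers plus the
        ``n_extra`` most variable background genes across mean type profiles
        (the synthetic analogue of merging published signature lists with the
        classification markers). ``all``: every gene.
        """
        genes = self.samples[0].expression.gene_ids
        if name == "all":
            return list(genes)
        if name == "markers":
            return list(self.marker_genes)
        if name == "merged":
            means = [df for df in self.truth.type_profiles.values()]
            stack = pd.concat(means, axis=1)
            bg = stack.index.difference(self.marker_genes).difference(self.hk_genes)
            var = stack.loc[bg].var(axis=1).sort_values(ascending=False)
            extra = sorted(var.index[:n_extra])
            return list(self.marker_genes) + extra
        raise ValueError(f"unknown gene set {name!r}")

    def write(self, out_dir: str | Path, matrix_format: str = "tsv") -> None:
        """Persist the cohort as plain-text files (TSV or MatrixMarket)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells, ann = self.concat_cells()
        if matrix_format == "tsv":
            cells.to_tsv(out / "matrix.tsv")
        elif matrix_format == "mtx":
            cells.to_mtx(out)
        else:
            raise ValueError(f"unknown matrix format {matrix_format!r}")
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        self.marker_spec.to_json(out / "markers.json")
        self.tsubset_spec.to_json(out / "markers_tsubsets.json")
        write_gene_list(self.hk_genes, out / "housekeeping.txt")
        self.truth.composition.to_csv(out / "true_composition.tsv", sep="\t")
        self.config.to_yaml(out / "config.yaml")


def _render_cells(
    log2_profiles: pd.DataFrame, labels: list[str], cell_ids: list[str],
    config: CohortConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Render TPM cells from per-type log2(TPM+1) mean profiles."""
    n_genes = log2_profiles.shape[0]
    cols = np.empty((n_genes, len(labels)))
    for j, lab in enumerate(labels):
        x = log2_profiles[lab].to_numpy()
        if config.noise_sd > 0:
            x = x + rng.normal(0, config.noise_sd, n_genes)
        lin = np.clip(np.exp2(x) - 1.0, 0, None)
        if config.dropout_rate > 0:
            lin[rng.random(n_genes) < config.dropout_rate] = 0.0
        cols[:, j] = lin
    df = pd.DataFrame(cols, index=log2_profiles.index, columns=cell_ids)
    return tpm_scale(df)


def simulate_sample(
    profiles: dict[tuple[str, str], pd.Series],
    composition: pd.Series,
    n_cells: int,
    patient: str,
    source: str,
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str | None = None,
    patient_shifts: pd.DataFrame | None = None,
) -> tuple[SampleData, pd.Series, pd.DataFrame]:
    """Simulate one sample; returns (sample, realized composition, profiles).

    The recorded truth is the *realized* label frequency of the multinomial
    draw, not its parameter. Malignant types receive the per-patient shift in
    ``patient_shifts`` (genes x malignant types, log2 units) when provided.
    """
    if abs(composition.sum() - 1.0) > 1e-8:
        raise ConfigError(f"composition must sum to 1, got {composition.sum()}")
    malignant = set(config.malignant_types)
    if source == BLOOD and any(composition.get(t, 0) > 0 for t in malignant):
        raise ConfigError("malignant fraction must be 0 in blood samples")
    sample_id = sample_id or f"{source}_{patient}"

    # per-sample per-type log2(TPM+1) mean profiles
    cols = {}
    for ctype in composition.index:
        prof = profiles[(ctype, source)]
        if patient_shifts is not None and ctype in patient_shifts.columns:
            prof = pd.Series(
                np.clip(prof.to_numpy() + patient_shifts[ctype].to_numpy(), 0, None),
                index=prof.index)
        lin = tpm_scale(pd.Series(np.exp2(prof.to_numpy()) - 1.0, index=prof.index))
        cols[ctype] = np.log2(lin + 1.0)
    sample_profiles = pd.DataFrame(cols)

    counts = rng.multinomial(n_cells, composition.to_numpy()) if n_cells else np.zeros(
        len(composition), dtype=int)
    labels = [t for t, c in zip(composition.index, counts) for _ in range(c)]
    cell_ids = [f"{sample_id}_c{i + 1:04d}" for i in range(len(labels))]
    values = _render_cells(sample_profiles, labels, cell_ids, config, rng) if labels else \
        pd.DataFrame(index=sample_profiles.index)
    expr = ExpressionMatrix(values, TPM)
    ann = pd.DataFrame({"cell_id": cell_ids, "cell_type": labels,
                        "patient": patient, "source": source})
    realized = pd.Series(counts / n_cells if n_cells else 0.0, index=composition.index)
    return SampleData(sample_id, patient, source, expr, ann), realized, sample_profiles


@dataclass
class SamplePlan:
    sample_id: str
    patient: str
    source: str
    composition: pd.Series
    n_cells: int


def simulate_planned_cohort(config: CohortConfig, plan: list[SamplePlan]) -> Cohort:
    """Simulate a cohort from an explicit per-sample plan (compositions fixed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles, panel = generate_type_profiles(config, rng)

    # per-patient malignant shifts, one draw per patient regardless of plan order
    patients = sorted({(p.patient, p.source) for p in plan})
    shift_by_patient: dict[str, pd.DataFrame] = {}
    for patient, source in patients:
        if source == BLOOD or config.patient_shift_sd == 0:
            shift_by_patient[patient] = None
            continue
        hk_mask = panel.gene_ids.isin(panel.hk_genes)
        shifts = {}
        for mt in config.malignant_types:
            s = rng.normal(0, config.patient_shift_sd, config.n_genes)
            s[hk_mask] = 0.0
            shifts[mt] = s
        shift_by_patient[patient] = pd.DataFrame(shifts, index=panel.gene_ids) if shifts else None

    samples, rows, labels, sample_profiles = [], {}, [], {}
    all_types = config.type_names
    for p in plan:
        comp_full = pd.Series(0.0, index=all_types)
        comp_full[p.composition.index] = p.composition.to_numpy()
        sample, realized, profs = simulate_sample(
            profiles, comp_full, p.n_cells, p.patient, p.source, config, rng,
            sample_id=p.sample_id, patient_shifts=shift_by_patient.get(p.patient))
        samples.append(sample)
        rows[p.sample_id] = realized
        labels.append(sample.annotation.set_index("cell_id")["cell_type"])
        sample_profiles[p.sample_id] = profs

    composition = pd.DataFrame(rows).T.reindex(columns=all_types).fillna(0.0)
    composition.index.name = "sample"
    cell_labels = pd.concat(labels) if labels else pd.Series(dtype=object)
    truth = GroundTruth(composition, cell_labels, sample_profiles)
    return Cohort(config, samples, truth, panel.marker_spec, panel.tsubset_spec,
                  panel.hk_genes, panel.marker_genes)


def classification_fixture_config(seed: int = 0, cells_per_sample: int = 220) -> CohortConfig:
    """Well-separated single-source cohort for exercising the classifier.

    Five major populations (T cells with their three subsets, B cells, NK
    cells, macrophages, malignant cells) at balanced abundances; six samples
    give every population enough cells to form a dense map cluster.
    """
    types = [
        CellType("CD4 T cell", parent=T_PARENT),
        CellType("CD8 T cell", parent=T_PARENT),
        CellType("Treg", parent=T_PARENT),
        CellType("B cell"),
        CellType("NK cell"),
        CellType("Macrophage"),
        CellType("Malignant", is_malignant=True),
    ]
    alpha = {"tumorA": {"CD4 T cell": 3, "CD8 T cell": 3, "Treg": 3,
                        "B cell": 4, "NK cell": 4, "Macrophage": 4, "Malignant": 5}}
    return CohortConfig(cell_types=types, n_patients_per_source={"tumorA": 6},
                        composition_alpha=alpha, cells_per_sample=cells_per_sample,
                        seed=seed)


def tumor_content_sweep_plan(
    fractions, n_cells: int = 150, source: str = "tumorA",
    malignant_type: str = "Malignant",
    other_types: list[str] | None = None,
) -> list[SamplePlan]:
    """One sample per malignant fraction, the rest spread evenly over the
    non-malignant types; used to probe purification accuracy vs content."""
    others = other_types or ["CD4 T cell", "CD8 T cell", "Treg", "B cell",
                             "NK cell", "Macrophage", "DC", "CAF", "Endothelial"]
    plan = []
    for i, f in enumerate(fractions):
        comp = pd.Series((1.0 - f) / len(others), index=others)
        comp[malignant_type] = f
        plan.append(SamplePlan(f"sweep_{i}", f"{source}_p{i + 1:02d}", source,
                               comp, n_cells))
    return plan


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate the full multi-source cohort with Dirichlet compositions."""
    config = config or CohortConfig()
    config.validate()
    # compositions drawn from a dedicated stream so the plan is independent of
    # profile generation order
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    plan: list[SamplePlan] = []
    for source, n_patients in config.n_patients_per_source.items():
        alpha = config.composition_alpha[source]
        types, conc = list(alpha), np.array(list(alpha.values()))
        for i in range(n_patients):
            patient = f"{source}_p{i + 1:02d}"
            comp = pd.Series(rng.dirichlet(conc), index=types)
            plan.append(SamplePlan(f"s_{patient}", patient, source, comp,
                                   config.cells_per_sample))
    return simulate_planned_cohort(config, plan)
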