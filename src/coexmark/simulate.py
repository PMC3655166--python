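"""Seeded generator of synthetic study cohorts with planted structure.

The generator emulates the statistical shape of a multi-cohort biomarker
study: two small disease tissue expression datasets sharing planted
disease-specific co-expression modules and up-regulated genes, several
background datasets (other cancers, normal tissues) carrying generic
modules, a peripheral-blood transcriptome in which a subset of markers is
elevated, qPCR CT tables with a planted tumor cycle shift, and a
single-analyte comparator whose distributions overlap between classes.

Every downstream stage of the pipeline — network inference, topological
filtering, marker selection, ΔΔCt quantification, ensemble classification
and evaluation — is testable against the planted ground truth returned
alongside the data.

Correlated modules are generated with a single latent factor per module,

    x_g = √ρ · z_module + √(1 − ρ) · ε_g,

which gives an exact expected pairwise Pearson correlation of ρ between any
two genes of the module. Disease-specific modules receive a shared latent
factor only in the two disease tissue datasets; generic modules receive one
in every dataset (each dataset draws its own factor, so the correlation is
within-dataset, as in real co-expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CONTROL, TUMOR, CtTable, ExpressionDataset

DISEASE = "disease"
GENERIC = "generic"


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module.

    ``specificity`` is ``"disease"`` (correlated only in the two disease
    tissue datasets) or ``"generic"`` (correlated in every dataset).
    """

    size: int
    rho: float
    specificity: str = DISEASE

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"within-module correlation must be in [0,1], got {self.rho}")
        if self.size < 2:
            raise ValueError("a module needs at least 2 genes")
        if self.specificity not in (DISEASE, GENERIC):
            raise ValueError(f"unknown module specificity {self.specificity!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """A differentially expressed gene: log2 shift applied to tumor samples."""

    gene_index: int
    log2_effect: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_effect > 0 else ("down" if self.log2_effect < 0 else "flat")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study conditions the pipeline is exercised under:
    strongly correlated planted modules (ρ = 0.9), a 2-unit log2 effect for
    planted markers over σ = 0.5 residual noise, 50 samples per class in the
    expression cohorts, PCR cohorts of 130/115/120 samples, a 2-cycle tumor
    CT shift (a 4-fold expression change under perfect doubling), and a
    comparator analyte whose tumor distribution leaves about two thirds of
    tumors below the normal cutoff.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 50
    modules: tuple[PlantedModule, ...] = (
        PlantedModule(15, 0.9, DISEASE),
        PlantedModule(15, 0.9, DISEASE),
        PlantedModule(15, 0.9, DISEASE),
        PlantedModule(15, 0.9, GENERIC),
        PlantedModule(15, 0.9, GENERIC),
        PlantedModule(15, 0.9, GENERIC),
    )
    de_effect: float = 2.0           # log2 shift of disease-module genes in tumor tissue
    n_blood_markers: int = 32        # blood-elevated genes outside the modules
    blood_effect: float = 2.0        # their log2 shift in tumor blood
    blood_tissue_effect: float = 0.5  # their (smaller) shift in tumor tissue
    extra_de: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.5
    baseline_mean: float = 8.0       # log2 intensity scale of the matrices
    baseline_sd: float = 1.5
    n_background_datasets: int = 3
    # qPCR panel structure: 75 candidates -> 51 detectable -> 27 informative
    n_tissue_panel: int = 21
    n_curated_panel: int = 22
    n_undetectable: int = 24
    n_informative: int = 27
    ct_baseline: float = 27.0        # mean cycles of marker assays
    ct_group_shift: float = 2.0      # cycles by which tumor CT drops (informative genes)
    ct_noise_sd: float = 0.5         # cycle-scale Gaussian noise
    ct_cohorts: tuple[tuple[str, int, int], ...] = (
        ("train", 67, 63),
        ("validation1", 43, 72),
        ("validation2", 49, 71),
    )
    analyte_cohort: tuple[int, int] = (95, 81)   # controls, tumors
    analyte_cutoff: float = 19.0     # upper limit of normal, U/L
    analyte_overlap: float = 55 / 81  # fraction of tumors below the cutoff
    analyte_log_sd: float = 0.5
    # tumors disperse widely: a secretory analyte is absent in a fraction of
    # tumors, so the class is elevated on average yet overlaps the cutoff
    analyte_tumor_log_sd: float = 1.2
    control_false_positive_rate: float = 0.01
    reference_gene: str = "REF"
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.ct_noise_sd <= 0:
            raise ValueError("ct_noise_sd must be positive")
        if not 0.0 <= self.analyte_overlap <= 1.0:
            raise ValueError("analyte_overlap must be in [0,1]")
        module_genes = sum(m.size for m in self.modules)
        if module_genes + self.n_blood_markers > self.n_genes:
            raise ValueError("planted modules and blood markers exceed n_genes")
        for eff in self.extra_de:
            if not 0 <= eff.gene_index < self.n_genes:
                raise ValueError(f"DE gene index {eff.gene_index} out of range")
        n_panel = self.n_tissue_panel + self.n_blood_markers + self.n_curated_panel
        if self.n_undetectable >= n_panel:
            raise ValueError("cannot plant more assay failures than panel genes")
        if self.n_informative > n_panel - self.n_undetectable:
            raise ValueError("informative genes must be a subset of detectable genes")
        n_disease = sum(m.size for m in self.modules if m.specificity == DISEASE)
        if self.n_tissue_panel > n_disease:
            raise ValueError("tissue panel larger than planted disease-module gene pool")

    @property
    def n_panel(self) -> int:
        return self.n_tissue_panel + self.n_blood_markers + self.n_curated_panel


@dataclass
class GroundTruth:
    """Planted structure of a cohort, for truth-checked evaluation."""

    module_genes: dict[str, list[str]]
    module_specificity: dict[str, str]
    disease_genes: list[str]          # genes of disease-specific modules
    tissue_de: dict[str, float]       # gene -> log2 effect in tumor tissue
    blood_de: dict[str, float]        # gene -> log2 effect in tumor blood
    tissue_allowlist: list[str]       # curation stand-in for the tissue route
    blood_allowlist: list[str]
    curated_panel: list[str]
    panel_genes: list[str]            # candidate panel (tissue + blood + curated)
    detectable_genes: list[str]       # candidates whose assay amplifies (CT < 40)
    informative_genes: list[str]      # detectable genes carrying the CT group shift
    reference_gene: str


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the planted truth."""

    tissue_a: ExpressionDataset
    tissue_b: ExpressionDataset
    background: list[ExpressionDataset]
    blood: ExpressionDataset
    ct_tables: dict[str, CtTable]
    analyte_values: pd.Series
    analyte_labels: pd.Series
    truth: GroundTruth
    config: SimulationConfig

    def write_dir(self, out_dir: str | Path) -> None:
        """Export every table as TSV plus a plain-text truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ds in [self.tissue_a, self.tissue_b, self.blood, *self.background]:
            labels = out / f"{ds.name}.labels.tsv" if ds.labels is not None else None
            ds.write_tsv(out / f"{ds.name}.expr.tsv", labels)
        for name, table in self.ct_tables.items():
            table.write_tsv(out / f"ct_{name}.tsv", out / f"ct_{name}.labels.tsv")
        analyte = pd.DataFrame({"value": self.analyte_values, "class": self.analyte_labels})
        analyte.to_csv(out / "analyte.tsv", sep="\t", index_label="sample")
        with open(out / "truth.txt", "w") as fh:
            t = self.truth
            for mod, genes in t.module_genes.items():
                fh.write(f"module\t{mod}\t{t.module_specificity[mod]}\t{','.join(genes)}\n")
            for gene, eff in t.tissue_de.items():
                fh.write(f"tissue_de\t{gene}\t{eff}\n")
            for gene, eff in t.blood_de.items():
                fh.write(f"blood_de\t{gene}\t{eff}\n")
            fh.write(f"panel\t{','.join(t.panel_genes)}\n")
            fh.write(f"detectable\t{','.join(t.detectable_genes)}\n")
            fh.write(f"informative\t{','.join(t.informative_genes)}\n")
            fh.write(f"reference_gene\t{t.reference_gene}\n")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_names(prefix: str, n_control: int, n_tumor: int) -> tuple[list[str], pd.Series]:
    names = [f"{prefix}_c{i:03d}" for i in range(n_control)]
    names += [f"{prefix}_t{i:03d}" for i in range(n_tumor)]
    labels = pd.Series([CONTROL] * n_control + [TUMOR] * n_tumor, index=names)
    return names, labels


def _expression_matrix(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genes: list[str],
    samples: list[str],
    labels: pd.Series | None,
    module_blocks: dict[str, tuple[slice, PlantedModule]],
    active: set[str],
    de: dict[int, float],
    baseline_boost: dict[int, float] | None = None,
) -> pd.DataFrame:
    n_genes, n_samples = len(genes), len(samples)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_genes)
    if baseline_boost:
        for idx, boost in baseline_boost.items():
            baseline[idx] = cfg.baseline_mean + boost
    resid = rng.normal(0.0, 1.0, (n_genes, n_samples))
    for mod_id, (block, module) in module_blocks.items():
        z = rng.normal(0.0, 1.0, n_samples)
        if mod_id in active:
            resid[block] = (
                np.sqrt(module.rho) * z
                + np.sqrt(1.0 - module.rho) * resid[block]
            )
    x = baseline[:, None] + cfg.noise_sd * resid
    if de and labels is not None:
        tumor_mask = (labels.to_numpy() == TUMOR)
        for idx, eff in de.items():
            x[idx, tumor_mask] += eff
    return pd.DataFrame(x, index=genes, columns=samples)


def generate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a configuration.

    The same configuration (including its seed) always yields an identical
    cohort. ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": int(seed)})
    cfg.validate()

    genes = _gene_names(cfg.n_genes)

    # lay planted modules out in consecutive disjoint blocks
    module_blocks: dict[str, tuple[slice, PlantedModule]] = {}
    cursor = 0
    disease_counter = generic_counter = 0
    for module in cfg.modules:
        if module.specificity == DISEASE:
            disease_counter += 1
            mod_id = f"disease-{disease_counter}"
        else:
            generic_counter += 1
            mod_id = f"generic-{generic_counter}"
        module_blocks[mod_id] = (slice(cursor, cursor + module.size), module)
        cursor += module.size
    blood_marker_idx = list(range(cursor, cursor + cfg.n_blood_markers))
    cursor += cfg.n_blood_markers

    disease_idx = [
        i
        for mod_id, (block, _) in module_blocks.items()
        if mod_id.startswith("disease")
        for i in range(block.start, block.stop)
    ]
    tissue_de = {i: cfg.de_effect for i in disease_idx}
    tissue_de.update({i: cfg.blood_tissue_effect for i in blood_marker_idx})
    for eff in cfg.extra_de:
        tissue_de[eff.gene_index] = eff.log2_effect
    blood_de = {i: cfg.blood_effect for i in blood_marker_idx}

    ss = np.random.SeedSequence(cfg.seed)
    n_streams = 4 + cfg.n_background_datasets + len(cfg.ct_cohorts) + 1
    streams = [np.random.default_rng(s) for s in ss.spawn(n_streams)]
    it = iter(streams)

    disease_and_generic = set(module_blocks)
    generic_only = {m for m in module_blocks if m.startswith("generic")}

    n = cfg.n_samples_per_group
    tissue_datasets = []
    for tag in ("A", "B"):
        samples, labels = _sample_names(tag, n, n)
        values = _expression_matrix(next(it), cfg, genes, samples, labels,
                                    module_blocks, disease_and_generic, tissue_de)
        tissue_datasets.append(ExpressionDataset(values, labels, name=f"tissue_{tag}"))

    background = []
    bg_names = ["cancer_compendium_1", "cancer_compendium_2", "normal_tissues"]
    for k in range(cfg.n_background_datasets):
        tag = bg_names[k] if k < len(bg_names) else f"background_{k}"
        samples = [f"{tag}_s{i:03d}" for i in range(2 * n)]
        values = _expression_matrix(next(it), cfg, genes, samples, None,
                                    module_blocks, generic_only, {})
        background.append(ExpressionDataset(values, None, name=tag))

    samples, labels = _sample_names("blood", n, n)
    # blood markers are expressed transcripts: keep their baselines off the floor
    boost = {i: 2.0 for i in blood_marker_idx}
    values = _expression_matrix(next(it), cfg, genes, samples, labels,
                                module_blocks, generic_only, blood_de,
                                baseline_boost=boost)
    blood = ExpressionDataset(values, labels, name="blood")

    # candidate panel: tissue route (disease-module genes), blood route, curated
    tissue_panel = [genes[i] for i in disease_idx[: cfg.n_tissue_panel]]
    blood_panel = [genes[i] for i in blood_marker_idx]
    curated_panel = [genes[i] for i in range(cursor, cursor + cfg.n_curated_panel)]
    panel = tissue_panel + blood_panel + curated_panel

    # spread assay failures across the three routes, deterministically
    fail_rng = next(it)
    order = fail_rng.permutation(len(panel))
    undetectable = sorted(order[: cfg.n_undetectable])
    detectable = [g for i, g in enumerate(panel) if i not in set(undetectable)]
    # informative genes (carrying the CT shift): favor blood-elevated markers
    detectable_blood = [g for g in detectable if g in set(blood_panel)]
    others = [g for g in detectable if g not in set(detectable_blood)]
    informative = (detectable_blood + others)[: cfg.n_informative]

    ct_genes = panel + [cfg.reference_gene]
    ct_tables: dict[str, CtTable] = {}
    for name, n_control, n_tumor in cfg.ct_cohorts:
        rng = next(it)
        samples, labels = _sample_names(name, n_control, n_tumor)
        base = rng.normal(cfg.ct_baseline, 2.0, len(panel))
        ct = base[:, None] + rng.normal(0.0, cfg.ct_noise_sd, (len(panel), len(samples)))
        tumor_mask = labels.to_numpy() == TUMOR
        informative_set = set(informative)
        for row, gene in enumerate(panel):
            if gene in informative_set:
                ct[row, tumor_mask] -= cfg.ct_group_shift
        ref = 20.0 + rng.normal(0.0, cfg.ct_noise_sd, len(samples))
        table = np.vstack([ct, ref])
        df = pd.DataFrame(table, index=ct_genes, columns=samples)
        for i in undetectable:  # assay never amplifies: censored at the run limit
            df.iloc[i, :] = 40.0
        df = df.clip(upper=40.0)
        ct_tables[name] = CtTable(df, cfg.reference_gene, labels, name=name)

    # single-analyte comparator: log-normal per class, overlap set by class mean
    from scipy.stats import norm

    rng = next(it)
    n_control, n_tumor = cfg.analyte_cohort
    samples, analyte_labels = _sample_names("analyte", n_control, n_tumor)
    sd_c, sd_t = cfg.analyte_log_sd, cfg.analyte_tumor_log_sd
    mu_control = np.log(cfg.analyte_cutoff) - sd_c * norm.ppf(1.0 - cfg.control_false_positive_rate)
    mu_tumor = np.log(cfg.analyte_cutoff) - sd_t * norm.ppf(cfg.analyte_overlap)
    vals = np.concatenate([
        np.exp(rng.normal(mu_control, sd_c, n_control)),
        np.exp(rng.normal(mu_tumor, sd_t, n_tumor)),
    ])
    analyte_values = pd.Series(vals, index=samples, name="analyte")

    truth = GroundTruth(
        module_genes={m: [genes[i] for i in range(b.start, b.stop)]
                      for m, (b, _) in module_blocks.items()},
        module_specificity={m: mod.specificity for m, (_, mod) in module_blocks.items()},
        disease_genes=[genes[i] for i in disease_idx],
        tissue_de={genes[i]: e for i, e in tissue_de.items()},
        blood_de={genes[i]: e for i, e in blood_de.items()},
        tissue_allowlist=tissue_panel,
        blood_allowlist=blood_panel,
        curated_panel=curated_panel,
        panel_genes=panel,
        detectable_genes=detectable,
        informative_genes=informative,
        reference_gene=cfg.reference_gene,
    )
    return SyntheticCohort(
        tissue_a=tissue_datasets[0],
        tissue_b=tissue_datasets[1],
        background=background,
        blood=blood,
        ct_tables=ct_tables,
        analyte_values=analyte_values,
        analyte_labels=analyte_labels,
        truth=truth,
        config=cfg,
    )
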