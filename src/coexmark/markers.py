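"""Marker-panel assembly: the three selection routes and detectability screen.

Candidate diagnostic transcripts are collected along three routes and then
screened for PCR detectability in blood:

* **tissue route** — genes significantly up-regulated (BH-FDR q < 0.025,
  FC > 0) in BOTH disease tissue datasets, present in the consensus
  co-expression network, and topologically clustered (clustering
  coefficient ≥ 0.25);
* **blood route** — genes up-regulated in tumor blood (unadjusted
  p < 0.05, FC > 0), expressed above the lower 25th quantile of gene-level
  means, and with positive fold change in both tissue datasets;
* **curated route** — a user-supplied literature list, accepted verbatim.

Manual curation steps are inherently human judgment; they enter as
optional allowlist files that intersect the computed route output.
Detectability keeps genes whose assay amplified (CT below the run limit)
in a sufficient fraction of screening samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CONTROL, TUMOR, CtTable, ExpressionDataset
from .network import DOWN, FLAT, UP, CoexpressionNetwork
from .topology import NodeTopology

TISSUE, BLOOD, CURATED = "tissue", "blood", "curated"

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class DEResult:
    """Per-gene two-sample differential expression for one dataset.

    Columns: t, p_value, q_value (BH across genes), log2_fc
    (mean tumor − mean control) and direction.
    """

    table: pd.DataFrame
    source_tag: str = ""

    def up_regulated(self, q_cutoff: float | None = None,
                     p_cutoff: float | None = None) -> pd.Index:
        mask = self.table["log2_fc"] > 0
        if q_cutoff is not None:
            mask &= self.table["q_value"] < q_cutoff
        if p_cutoff is not None:
            mask &= self.table["p_value"] < p_cutoff
        return self.table.index[mask]

    def fold_change(self, gene: str) -> float:
        return float(self.table.loc[gene, "log2_fc"])


def differential_expression(dataset: ExpressionDataset,
                            equal_var: bool = False) -> DEResult:
    """Per-gene two-sample t-test (Welch by default) with BH adjustment.

    Fold change is the difference of class means on the log2 scale the
    matrices already live on.
    """
    tumor = dataset.class_columns(TUMOR).to_numpy()
    control = dataset.class_columns(CONTROL).to_numpy()
    if tumor.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    t, p = stats.ttest_ind(tumor, control, axis=1, equal_var=equal_var)
    fc = tumor.mean(axis=1) - control.mean(axis=1)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    direction = np.where(fc > 0, UP, np.where(fc < 0, DOWN, FLAT))
    table = pd.DataFrame(
        {"t": t, "p_value": p, "q_value": q, "log2_fc": fc, "direction": direction},
        index=dataset.genes)
    return DEResult(table, dataset.name)


@dataclass
class MarkerRecord:
    gene: str
    routes: list[str]
    filter_trail: list[tuple[str, bool, float | None]] = field(default_factory=list)
    detectable: bool | None = None


@dataclass
class MarkerPanel:
    """Candidate marker genes with per-gene route provenance."""

    records: dict[str, MarkerRecord]

    @property
    def genes(self) -> list[str]:
        return sorted(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def subset(self, genes: list[str]) -> "MarkerPanel":
        return MarkerPanel({g: self.records[g] for g in genes if g in self.records})

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for gene in self.genes:
            rec = self.records[gene]
            trail = ";".join(
                f"{name}:{'pass' if ok else 'fail'}"
                + (f":{value:.4g}" if value is not None else "")
                for name, ok, value in rec.filter_trail)
            rows.append({
                "gene": gene,
                "routes": ",".join(rec.routes),
                "detectable": "" if rec.detectable is None else str(rec.detectable),
                "filter_trail": trail,
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = {}
        for row in df.itertuples(index=False):
            trail = []
            if row.filter_trail:
                for item in row.filter_trail.split(";"):
                    parts = item.split(":")
                    value = float(parts[2]) if len(parts) > 2 else None
                    trail.append((parts[0], parts[1] == "pass", value))
            detectable = None if row.detectable == "" else row.detectable == "True"
            records[row.gene] = MarkerRecord(
                row.gene, row.routes.split(",") if row.routes else [],
                trail, detectable)
        return cls(records)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def load_reference_panel() -> list[str]:
    """The packaged 51-transcript blood marker panel (gene symbols)."""
    return read_gene_list(_DATA_DIR / "marker_panel_51.txt")


def tissue_route(
    de_a: DEResult,
    de_b: DEResult,
    consensus: CoexpressionNetwork,
    topo: NodeTopology,
    q_cutoff: float = 0.025,
    clustering_cutoff: float = 0.25,
    allowlist: list[str] | None = None,
) -> list[str]:
    """Tissue-derived candidates.

    Keeps genes up-regulated at FDR q < 0.025 in both disease datasets,
    present in the consensus network, with clustering coefficient ≥ 0.25.
    An optional allowlist (the curation stand-in) intersects the result.
    """
    up_a = set(de_a.up_regulated(q_cutoff=q_cutoff))
    up_b = set(de_b.up_regulated(q_cutoff=q_cutoff))
    candidates = up_a & up_b & consensus.nodes
    selected = [g for g in candidates if topo.clustering(g) >= clustering_cutoff]
    if allowlist is not None:
        selected = [g for g in selected if g in set(allowlist)]
    return sorted(selected)


def blood_route(
    blood_de: DEResult,
    de_a: DEResult,
    de_b: DEResult,
    blood_expr: ExpressionDataset,
    p_cutoff: float = 0.05,
    expression_quantile: float = 0.25,
    allowlist: list[str] | None = None,
) -> list[str]:
    """Blood-derived candidates.

    Keeps genes up-regulated in tumor blood at unadjusted p < 0.05 with
    FC > 0, whose mean blood expression sits above the lower quantile of
    gene-level means (weakly expressed transcripts excluded), and whose
    fold change is positive in both tissue datasets.
    """
    up_blood = set(blood_de.up_regulated(p_cutoff=p_cutoff))
    gene_means = blood_expr.values.mean(axis=1)
    floor = gene_means.quantile(expression_quantile)
    expressed = set(gene_means.index[gene_means > floor])
    selected = []
    for gene in up_blood & expressed:
        if gene not in de_a.table.index or gene not in de_b.table.index:
            continue
        if de_a.fold_change(gene) > 0 and de_b.fold_change(gene) > 0:
            selected.append(gene)
    if allowlist is not None:
        selected = [g for g in selected if g in set(allowlist)]
    return sorted(selected)


def assemble_panel(
    tissue: list[str],
    blood: list[str],
    curated: list[str],
) -> MarkerPanel:
    """Union of the three routes with per-gene provenance (deduplicated)."""
    records: dict[str, MarkerRecord] = {}
    for route, genes in ((TISSUE, tissue), (BLOOD, blood), (CURATED, curated)):
        if len(genes) != len(set(genes)):
            warnings.warn(f"duplicate genes within {route} route deduplicated",
                          stacklevel=2)
        for gene in dict.fromkeys(genes):
            if gene in records:
                if route not in records[gene].routes:
                    records[gene].routes.append(route)
            else:
                records[gene] = MarkerRecord(gene, [route])
    return MarkerPanel(records)


def detectability_screen(
    panel: MarkerPanel,
    ct: CtTable,
    min_fraction: float = 0.8,
) -> MarkerPanel:
    """Keep genes whose assay amplified in enough screening samples.

    A gene is detectable when CT < the run limit (default 40 cycles) in at
    least ``min_fraction`` of samples. Genes absent from the CT table are
    marked undetectable with a warning.
    """
    detected = ct.detected()
    kept = {}
    for gene in panel.genes:
        rec = panel.records[gene]
        if gene not in ct.genes:
            warnings.warn(f"panel gene {gene!r} absent from CT table; "
                          "marked undetectable", stacklevel=2)
            rec.detectable = False
            rec.filter_trail.append(("detectability", False, None))
            continue
        fraction = float(detected.loc[gene].mean())
        ok = fraction >= min_fraction
        rec.detectable = ok
        rec.filter_trail.append(("detectability", ok, fraction))
        if ok:
            kept[gene] = rec
    return MarkerPanel(kept)
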