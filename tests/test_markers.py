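"""Marker selection: DE testing, the three routes, panel assembly and the
detectability screen."""

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coexmark as cm
from coexmark.network import CoexpressionNetwork
from coexmark.topology import NodeTopology

from conftest import make_dataset


def welch_t_oracle(x, y):
    """Closed-form Welch t-test (statistic and two-sided p)."""
    from scipy.stats import t as tdist
    nx_, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx_ + vy / ny
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def bh_oracle(pvals):
    """Step-up BH adjustment, brute force."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, pvals[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


class TestDifferentialExpression:
    def _fixed_dataset(self):
        # 3 genes x 8 samples, values frozen
        values = pd.DataFrame(
            [[5.1, 4.8, 5.3, 5.0, 7.2, 6.8, 7.5, 7.0],
             [3.0, 3.2, 2.9, 3.1, 3.0, 3.1, 2.95, 3.05],
             [6.0, 6.5, 5.5, 6.2, 5.0, 4.5, 5.2, 4.8]],
            index=["up_gene", "flat_gene", "down_gene"],
            columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["control"] * 4 + ["tumor"] * 4, index=values.columns)
        return cm.ExpressionDataset(values, labels, name="fixed")

    def test_matches_closed_form_welch_oracle(self):
        ds = self._fixed_dataset()
        de = cm.differential_expression(ds)
        for gene in ds.genes:
            tum = ds.class_columns("tumor").loc[gene]
            ctl = ds.class_columns("control").loc[gene]
            t, p = welch_t_oracle(tum, ctl)
            assert de.table.loc[gene, "t"] == pytest.approx(t, rel=1e-9)
            assert de.table.loc[gene, "p_value"] == pytest.approx(p, rel=1e-9)
        assert de.table.loc["up_gene", "direction"] == "up"
        assert de.table.loc["down_gene", "direction"] == "down"

    def test_q_values_dominate_p_values(self):
        de = cm.differential_expression(self._fixed_dataset())
        assert (de.table["q_value"] >= de.table["p_value"] - 1e-12).all()

    def test_null_data_yields_no_fdr_hits(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(500, 40)),
                              index=[f"g{i}" for i in range(500)],
                              columns=[f"s{i}" for i in range(40)])
        labels = pd.Series(["control"] * 20 + ["tumor"] * 20, index=values.columns)
        de = cm.differential_expression(cm.ExpressionDataset(values, labels))
        assert len(de.up_regulated(q_cutoff=0.025)) == 0

    def test_planted_effect_recovered_with_high_power(self):
        """δ=2 against σ=0.5 at 20/group clears FDR q<0.025 essentially always."""
        rng = np.random.default_rng(6)
        n_genes, n_planted = 300, 30
        values = rng.normal(8.0, 0.5, size=(n_genes, 40))
        values[:n_planted, 20:] += 2.0
        df = pd.DataFrame(values, index=[f"g{i:03d}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(40)])
        labels = pd.Series(["control"] * 20 + ["tumor"] * 20, index=df.columns)
        de = cm.differential_expression(cm.ExpressionDataset(df, labels))
        hits = set(de.up_regulated(q_cutoff=0.025))
        planted = {f"g{i:03d}" for i in range(n_planted)}
        assert len(hits & planted) / n_planted > 0.95

    def test_single_sample_class_rejected(self):
        values = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        labels = pd.Series(["control", "tumor", "tumor"], index=values.columns)
        with pytest.raises(ValueError):
            cm.differential_expression(cm.ExpressionDataset(values, labels))


def test_bh_adjustment_matches_step_up_brute_force():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=100)
    from statsmodels.stats.multitest import multipletests
    assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(p),
                       atol=1e-12)


def _de_from_frame(rows):
    df = pd.DataFrame(rows).T
    df.columns = ["t", "p_value", "q_value", "log2_fc"]
    df["direction"] = np.where(df["log2_fc"] > 0, "up", "down")
    return cm.DEResult(df)


def _topo(values):
    df = pd.DataFrame({"degree": 5, "clustering": pd.Series(values),
                       "defined": True})
    return NodeTopology(df)


def _net_of(genes):
    g = nx.Graph()
    for i in range(len(genes) - 1):
        g.add_edge(genes[i], genes[i + 1], weight=0.9)
    return CoexpressionNetwork(g, 0.8, "toy")


class TestTissueRoute:
    def setup_method(self):
        # g1 passes everything; g2 up in A only; g3 low clustering; g4 not in net
        self.de_a = _de_from_frame({
            "g1": [5, 1e-4, 1e-3, 2.0], "g2": [5, 1e-4, 1e-3, 2.0],
            "g3": [5, 1e-4, 1e-3, 2.0], "g4": [5, 1e-4, 1e-3, 2.0]})
        self.de_b = _de_from_frame({
            "g1": [5, 1e-4, 1e-3, 2.0], "g2": [-5, 1e-4, 1e-3, -2.0],
            "g3": [5, 1e-4, 1e-3, 2.0], "g4": [5, 1e-4, 1e-3, 2.0]})
        self.net = _net_of(["g1", "g2", "g3"])
        self.topo = _topo({"g1": 0.8, "g2": 0.8, "g3": 0.2})

    def test_filters_applied(self):
        out = cm.tissue_route(self.de_a, self.de_b, self.net, self.topo)
        assert out == ["g1"]

    def test_allowlist_intersection(self):
        assert cm.tissue_route(self.de_a, self.de_b, self.net, self.topo,
                               allowlist=["g9"]) == []

    def test_numeric_filters_commute(self):
        """Order of the conjunctive filters does not change the output."""
        up_a = set(self.de_a.up_regulated(q_cutoff=0.025))
        up_b = set(self.de_b.up_regulated(q_cutoff=0.025))
        in_net = self.net.nodes
        high_c = {g for g in self.topo.table.index if self.topo.clustering(g) >= 0.25}
        import itertools
        results = set()
        for perm in itertools.permutations([up_a, up_b, in_net, high_c]):
            acc = set(self.de_a.table.index)
            for f in perm:
                acc &= f
            results.add(tuple(sorted(acc)))
        assert results == {tuple(cm.tissue_route(self.de_a, self.de_b,
                                                 self.net, self.topo))}


class TestBloodRoute:
    def _blood_expr(self, means):
        rng = np.random.default_rng(0)
        rows = {g: rng.normal(m, 0.01, 10) for g, m in means.items()}
        values = pd.DataFrame(rows).T
        values.columns = [f"s{i}" for i in range(10)]
        labels = pd.Series(["control"] * 5 + ["tumor"] * 5, index=values.columns)
        return cm.ExpressionDataset(values, labels, name="blood")

    def test_low_expression_excluded_regardless_of_p(self):
        means = {"low": 1.0, "a": 8.0, "b": 8.0, "c": 8.0}
        de_blood = _de_from_frame({g: [5, 1e-4, 1e-3, 1.0] for g in means})
        de_t = _de_from_frame({g: [5, 1e-4, 1e-3, 1.0] for g in means})
        out = cm.blood_route(de_blood, de_t, de_t, self._blood_expr(means))
        assert "low" not in out
        assert set(out) == {"a", "b", "c"}

    def test_tissue_fold_change_must_be_positive(self):
        means = {"a": 8.0, "b": 8.0, "c": 8.0, "d": 8.0}
        de_blood = _de_from_frame({g: [5, 1e-4, 1e-3, 1.0] for g in means})
        de_a = _de_from_frame({"a": [5, 1e-4, 1e-3, 1.0], "b": [-5, 1e-4, 1e-3, -1.0],
                               "c": [5, 1e-4, 1e-3, 1.0], "d": [5, 1e-4, 1e-3, 1.0]})
        de_b = _de_from_frame({g: [5, 1e-4, 1e-3, 1.0] for g in means})
        out = cm.blood_route(de_blood, de_a, de_b, self._blood_expr(means))
        assert "b" not in out

    def test_matches_independent_filter_chain_on_random_input(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:03d}" for i in range(100)]
        p = rng.uniform(size=100)
        fc_blood = rng.normal(size=100)
        fc_a = rng.normal(size=100)
        fc_b = rng.normal(size=100)
        de_blood = _de_from_frame({g: [1, p[i], p[i], fc_blood[i]]
                                   for i, g in enumerate(genes)})
        de_a = _de_from_frame({g: [1, 0.5, 0.5, fc_a[i]] for i, g in enumerate(genes)})
        de_b = _de_from_frame({g: [1, 0.5, 0.5, fc_b[i]] for i, g in enumerate(genes)})
        means = dict(zip(genes, rng.normal(8, 2, size=100)))
        expr = self._blood_expr(means)
        out = cm.blood_route(de_blood, de_a, de_b, expr)
        # independently coded sequential filter
        gene_means = expr.values.mean(axis=1)
        floor = np.quantile(gene_means, 0.25)
        expected = sorted(
            g for i, g in enumerate(genes)
            if p[i] < 0.05 and fc_blood[i] > 0 and gene_means[g] > floor
            and fc_a[i] > 0 and fc_b[i] > 0)
        assert out == expected


class TestPanelAssembly:
    def test_disjoint_routes_sum(self):
        tissue = [f"t{i}" for i in range(21)]
        blood = [f"b{i}" for i in range(32)]
        curated = [f"c{i}" for i in range(22)]
        panel = cm.assemble_panel(tissue, blood, curated)
        assert len(panel) == 75

    def test_overlap_recorded_in_provenance(self):
        panel = cm.assemble_panel(["g1", "g2"], ["g2", "g3"], [])
        assert len(panel) == 3
        assert panel.records["g2"].routes == ["tissue", "blood"]

    def test_empty_curated_list(self):
        panel = cm.assemble_panel(["g1"], ["g2"], [])
        assert panel.genes == ["g1", "g2"]

    def test_within_route_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            panel = cm.assemble_panel(["g1", "g1"], [], [])
        assert len(panel) == 1


class TestDetectabilityScreen:
    def _ct(self, rows, labels=None):
        df = pd.DataFrame(rows).T
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        df.loc["REF"] = 20.0
        labels = labels or ["control"] * df.shape[1]
        return cm.CtTable(df, "REF", pd.Series(labels, index=df.columns))

    def test_strictly_below_limit_retained(self):
        ct = self._ct({"g1": [39.0] * 5})
        panel = cm.assemble_panel(["g1"], [], [])
        out = cm.detectability_screen(panel, ct)
        assert "g1" in out
        assert out.records["g1"].detectable is True

    def test_censored_at_limit_dropped(self):
        ct = self._ct({"g1": [40.0] * 5})
        panel = cm.assemble_panel(["g1"], [], [])
        assert "g1" not in cm.detectability_screen(panel, ct)

    def test_fraction_rule(self):
        # detected in 3 of 5 samples: below the 80% default
        ct = self._ct({"g1": [30.0, 30.0, 30.0, 40.0, 40.0]})
        panel = cm.assemble_panel(["g1"], [], [])
        assert "g1" not in cm.detectability_screen(panel, ct)
        assert "g1" in cm.detectability_screen(panel, ct, min_fraction=0.6)

    def test_gene_absent_from_table_flagged_undetectable(self):
        ct = self._ct({"g1": [30.0] * 5})
        panel = cm.assemble_panel(["g1", "g2"], [], [])
        with pytest.warns(UserWarning, match="absent"):
            out = cm.detectability_screen(panel, ct)
        assert "g2" not in out

    def test_planted_cohort_reduces_75_to_51(self, cohort):
        panel = cm.assemble_panel(cohort.truth.tissue_allowlist,
                                  cohort.truth.blood_allowlist,
                                  cohort.truth.curated_panel)
        assert len(panel) == 75
        out = cm.detectability_screen(panel, cohort.ct_tables["train"])
        assert len(out) == 51
        assert sorted(out.genes) == sorted(cohort.truth.detectable_genes)


def test_panel_tsv_round_trip(tmp_path):
    panel = cm.assemble_panel(["g1", "g2"], ["g2"], ["g3"])
    panel.records["g1"].detectable = True
    panel.records["g1"].filter_trail.append(("detectability", True, 0.97))
    path = tmp_path / "panel.tsv"
    panel.write_tsv(path)
    back = cm.MarkerPanel.read_tsv(path)
    assert back.genes == panel.genes
    assert back.records["g2"].routes == ["tissue", "blood"]
    assert back.records["g1"].detectable is True
    assert back.records["g1"].filter_trail == [("detectability", True, 0.97)]


def test_reference_panel_fixture_round_trips(tmp_path):
    genes = cm.load_reference_panel()
    assert len(genes) == 51
    assert len(set(genes)) == 51
    panel = cm.assemble_panel([], [], genes)
    path = tmp_path / "panel51.tsv"
    panel.write_tsv(path)
    assert cm.MarkerPanel.read_tsv(path).genes == sorted(genes)
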