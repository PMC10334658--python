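import numpy as np
import pandas as pd
import pytest

from microrewire.cooccurrence import (CooccurrenceNetwork,
                                      condition_network,
                                      differential_network, hub_nodes,
                                      pearson_with_p, rewiring_degree)
from microrewire.feature_table import (FeatureTable, attach_metadata,
                                       to_relative)
from microrewire.synthetic_data import make_paper_like_spec, simulate


class TestPearson:
    def test_affine_dependence(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_hand_computed_r(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [1, 2, 3, 5])
        assert r == pytest.approx(6.5 / np.sqrt(43.75), abs=1e-4)

    def test_matches_scipy(self, rng):
        from scipy.stats import pearsonr
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r, p = pearson_with_p(x, y)
            ref = pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_p_uniform(self, rng):
        """Under independence the p-values are uniform (KS check)."""
        from scipy.stats import kstest
        ps = []
        for _ in range(2000):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            ps.append(pearson_with_p(x, y)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _relative_table(values, groups, taxa=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=taxa, columns=samples)
    meta = pd.DataFrame({"sample_id": samples,
                         "dataset": ["D"] * len(samples),
                         "group": groups})
    return to_relative(attach_metadata(FeatureTable(df), meta))


class TestConditionNetwork:
    def test_constructed_dependence_significant(self, rng):
        base = rng.uniform(1, 2, size=8)
        values = np.vstack([base, 2 * base, rng.uniform(1, 2, size=8)])
        ft = _relative_table(values, ["case"] * 8)
        # taxa 0 and 1 proportional in counts -> correlated proportions
        net = condition_network(ft, "case")
        edges = net.edges.set_index(["taxon_a", "taxon_b"])
        assert edges.loc[("T0", "T1"), "significant"]

    def test_condition_constant_taxon_excluded(self, rng):
        values = rng.uniform(1, 2, size=(3, 12))
        ft = _relative_table(values, ["case"] * 6 + ["control"] * 6)
        frozen = ft.data.copy()
        frozen.loc["T0", ft.samples_in_group("case")] = 0.1
        ft2 = FeatureTable(frozen, mode="relative", meta=ft.meta,
                           closed=False)
        net = condition_network(ft2, "case")
        assert "T0" not in net.nodes
        assert not ((net.edges["taxon_a"] == "T0") |
                    (net.edges["taxon_b"] == "T0")).any()

    def test_power_on_planted_pairs(self):
        """Planted |r|=0.8 latent pairs are flagged at alpha=0.05 with
        ~200 samples per condition in every replicate."""
        n_seeds = 10
        for seed in range(n_seeds):
            spec = make_paper_like_spec(0.4, seed=seed, n_modules=0,
                                        n_changed_edges=0)
            ft, truth = simulate(spec)
            rel = to_relative(ft)
            net = condition_network(rel, "control")
            sig_edges = net.significant_edges()
            sig = {tuple(sorted(p)) for p in
                   zip(sig_edges["taxon_a"], sig_edges["taxon_b"])}
            assert truth.expected_lost <= sig

    def test_too_few_samples(self, rng):
        ft = _relative_table(rng.uniform(1, 2, (3, 5)),
                             ["case"] * 3 + ["control"] * 2)
        with pytest.raises(ValueError, match="at least 4"):
            condition_network(ft, "control")


def _net(condition, edges, level="genus"):
    """edges: list of (a, b, r, significant)."""
    df = pd.DataFrame(edges, columns=["taxon_a", "taxon_b", "r",
                                      "significant"])
    df["p"] = np.where(df["significant"], 0.001, 0.5)
    df["q"] = np.nan
    nodes = sorted(set(df["taxon_a"]) | set(df["taxon_b"]))
    return CooccurrenceNetwork(condition=condition, level=level, nodes=nodes,
                               edges=df, alpha=0.05, adjust="none")


class TestDifferentialNetwork:
    def test_classification_truth_table(self):
        ctrl = _net("control", [
            ("A", "B", 0.6, True),    # lost
            ("C", "D", 0.5, True),    # changed (flips sign)
            ("E", "F", 0.5, True),    # stable same sign
            ("G", "H", 0.1, False),   # gained (case-only)
        ])
        case = _net("case", [
            ("A", "B", 0.1, False),
            ("C", "D", -0.5, True),
            ("E", "F", 0.7, True),
            ("G", "H", 0.6, True),
        ])
        dnet = differential_network(ctrl, case)
        assert dnet.edge_set("lost") == {("A", "B")}
        assert dnet.edge_set("changed_direction") == {("C", "D")}
        assert dnet.edge_set("gained") == {("G", "H")}
        assert ("E", "F") not in dnet.edge_set()

    def test_classes_partition_edge_set(self, rng):
        taxa = [f"T{i}" for i in range(8)]
        edges_c, edges_k = [], []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                edges_c.append((taxa[i], taxa[j],
                                float(rng.uniform(-1, 1)),
                                bool(rng.random() < 0.5)))
                edges_k.append((taxa[i], taxa[j],
                                float(rng.uniform(-1, 1)),
                                bool(rng.random() < 0.5)))
        dnet = differential_network(_net("control", edges_c),
                                    _net("case", edges_k))
        g, l, c = (dnet.edge_set(k) for k in
                   ("gained", "lost", "changed_direction"))
        assert not (g & l) and not (g & c) and not (l & c)
        assert g | l | c == dnet.edge_set()

    def test_swap_maps_gained_to_lost(self, rng):
        taxa = [f"T{i}" for i in range(6)]
        edges_c, edges_k = [], []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                edges_c.append((taxa[i], taxa[j],
                                float(rng.uniform(-1, 1)),
                                bool(rng.random() < 0.5)))
                edges_k.append((taxa[i], taxa[j],
                                float(rng.uniform(-1, 1)),
                                bool(rng.random() < 0.5)))
        nc, nk = _net("control", edges_c), _net("case", edges_k)
        fwd = differential_network(nc, nk)
        rev = differential_network(nk, nc)
        assert fwd.edge_set("gained") == rev.edge_set("lost")
        assert fwd.edge_set("lost") == rev.edge_set("gained")
        assert fwd.edge_set("changed_direction") == \
            rev.edge_set("changed_direction")

    def test_level_mismatch_rejected(self):
        ctrl = _net("control", [("A", "B", 0.5, True)], level="genus")
        case = _net("case", [("A", "B", 0.5, True)], level="family")
        with pytest.raises(ValueError, match="level"):
            differential_network(ctrl, case)


class TestRewiringDegree:
    def test_counts_and_handshake(self):
        ctrl = _net("control", [("A", "B", 0.5, True),
                                ("A", "C", 0.5, True),
                                ("B", "C", 0.2, False)])
        case = _net("case", [("A", "B", 0.2, False),
                             ("A", "C", 0.3, False),
                             ("B", "C", 0.6, True)])
        dnet = differential_network(ctrl, case)
        deg = rewiring_degree(dnet)
        assert deg.loc["A", "total"] == 2
        assert deg.loc["A", "lost"] == 2
        assert deg.loc["B", "gained"] == 1
        assert deg["total"].sum() == 2 * len(dnet.edges)
        # sorted by total descending
        assert list(deg["total"]) == sorted(deg["total"], reverse=True)


class TestHubNodes:
    def test_level_cutoffs(self):
        ctable = pd.DataFrame({"degree": [4, 3, 16, 15]},
                              index=["p1", "p2", "g1", "g2"])
        assert hub_nodes(ctable, "phylum") == ["p1", "g1", "g2"]
        assert hub_nodes(ctable, "genus") == ["g1"]

    def test_family_requires_cutoff(self):
        ctable = pd.DataFrame({"degree": [5]}, index=["f1"])
        with pytest.raises(ValueError, match="family"):
            hub_nodes(ctable, "family")
        assert hub_nodes(ctable, "family", family_cutoff=5) == ["f1"]
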