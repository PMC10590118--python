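"""Co-expression network, scale-free fit, Fisher enrichment, composite score,
pathway attribution, PPI confidence filter."""
import math

import numpy as np
import pandas as pd
import pytest

from quiescentome import simulate
from quiescentome.diffexpr import run_contrasts, select_deg
from quiescentome.regnet import (
    attribute_regulators_to_pathways,
    build_coexpression_network,
    choose_soft_power,
    filter_ppi_edges,
    regenrich_score,
    regulator_enrichment,
    scale_free_fit,
    top_regulators,
)
from quiescentome.types import RegulatorNetwork, ValidationError

from conftest import small_config, toy_matrix


def fisher_upper_tail_bruteforce(a, b, c, d):
    """Oracle: sum the hypergeometric pmf over every 2x2 table with the same
    margins that is at least as enriched (one-sided)."""
    n_targets, n_de, N = a + b, a + c, a + b + c + d
    total = 0.0
    for x in range(a, min(n_targets, n_de) + 1):
        total += (math.comb(n_de, x) * math.comb(N - n_de, n_targets - x)
                  / math.comb(N, n_targets))
    return total


def _net(targets, regulators=None):
    regs = regulators or sorted(targets)
    return RegulatorNetwork(edges=pd.DataFrame(), beta=1, r2=1.0,
                            edge_keep=1.0, regulators=regs,
                            targets={r: frozenset(targets.get(r, ())) for r in regs})


class TestNetworkConstruction:
    def _corr_matrix(self, seed=0, n=20, samples=10):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n, samples))
        return toy_matrix(y, ["uM", "hlf"] * (samples // 2),
                          [f"d{i}" for i in range(samples)])

    def test_top_fraction_keeps_strongest_pair(self):
        # 3 genes engineered so pairwise |r| ranks (0-1) > (0-2) > (1-2)
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.vstack([
            base,
            base + [0.01, -0.02, 0.015, -0.01, 0.02, -0.015],
            base[::-1] * 0.2 + np.array([5, 1, 4, 2, 3, 0]) * 0.8,
        ])
        m = toy_matrix(y, ["uM", "hlf"] * 3, [f"d{i}" for i in range(6)])
        net = build_coexpression_network(m, ["g0", "g1"], beta=1,
                                         edge_keep=1 / 3)
        assert len(net.edges) == 1
        assert {net.edges["gene_a"][0], net.edges["gene_b"][0]} == {"g0", "g1"}

    def test_duplicated_rows_always_retained(self):
        m = self._corr_matrix(seed=1)
        v = m.values.copy()
        v.loc["g1"] = v.loc["g0"] + 1.0      # |r| = 1 pair
        m2 = toy_matrix(v.to_numpy(), list(m.conditions),
                        list(m.samples["donor"]), genes=list(v.index))
        net = build_coexpression_network(m2, ["g0", "g1"], edge_keep=0.02)
        pairs = set(map(frozenset, zip(net.edges["gene_a"], net.edges["gene_b"])))
        assert frozenset({"g0", "g1"}) in pairs

    @pytest.mark.parametrize("edge_keep", [0.01, 0.05, 0.2, 0.5])
    def test_retained_edge_count_is_exact_ceiling(self, edge_keep):
        m = self._corr_matrix(seed=2, n=25)
        net = build_coexpression_network(m, ["g0", "g1"], edge_keep=edge_keep)
        assert len(net.edges) == math.ceil(edge_keep * math.comb(25, 2))

    def test_too_few_samples_or_regulators_rejected(self):
        m = self._corr_matrix(n=10, samples=4)
        with pytest.raises(ValidationError):
            build_coexpression_network(
                toy_matrix(m.values.iloc[:, :3].to_numpy(), ["a", "b", "c"],
                           ["d1", "d2", "d3"]), ["g0", "g1"])
        with pytest.raises(ValidationError):
            build_coexpression_network(m, ["g0"])

    def test_planted_hub_has_highest_degree(self):
        """Targets generated as regulator + noise make the hub the most
        connected node."""
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            hub = rng.normal(size=16)
            targets = hub + rng.normal(0, 0.3, size=(8, 16))
            others = rng.normal(size=(12, 16))
            y = np.vstack([hub, targets, others])
            m = toy_matrix(y, ["uM", "uM_LPS", "hlf", "hlf_LPS"] * 4,
                           sum([[f"d{i}"] * 4 for i in range(4)], []))
            net = build_coexpression_network(m, ["g0", "g15"], edge_keep=0.1)
            degree = pd.concat([net.edges["gene_a"],
                                net.edges["gene_b"]]).value_counts()
            if degree.index[0] == "g0":
                recovered += 1
        assert recovered >= 9


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        rng = np.random.default_rng(7)
        degrees = rng.zipf(2.2, size=3000).astype(float)
        degrees = degrees[degrees <= 100]
        assert scale_free_fit(degrees) > 0.9

    def test_uniform_degrees_fit_poorly(self):
        rng = np.random.default_rng(8)
        degrees = rng.uniform(1, 100, size=2000)
        assert scale_free_fit(degrees) < 0.6

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            scale_free_fit([1.0, 2.0, 3.0, 4.0])

    def test_equal_degrees_return_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert scale_free_fit([2.0] * 10) == 0.0

    def test_soft_power_prefers_smallest_passing(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(40, 12))
        corr = np.abs(np.corrcoef(y))
        np.fill_diagonal(corr, 0.0)
        beta, r2 = choose_soft_power(corr, r2_min=0.0)
        assert beta == 1                      # r2_min=0: first power passes


class TestFisherEnrichment:
    def test_perfect_overlap_exact_value(self):
        # a=5, b=0, c=0, d=95 -> p = 1 / C(100, 5)
        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(5)}
        net = _net({"R": de})
        out = regulator_enrichment(net, de, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(100, 5), rel=1e-12)
        assert bool(out["significant"].iloc[0])

    def test_disjoint_targets_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        net = _net({"R": {"g0", "g1"}})
        out = regulator_enrichment(net, {"g10", "g11"}, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_target_set_flagged(self):
        universe = {"g0", "g1"}
        net = _net({"R": set()})
        out = regulator_enrichment(net, {"g0"}, universe)
        assert out["p"].iloc[0] == 1.0
        assert out["flag"].iloc[0] == "no-targets"

    def test_bruteforce_enumeration_on_small_universes(self):
        """One-sided Fisher p equals exhaustive fixed-margin enumeration."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            N = int(rng.integers(4, 31))
            genes = [f"g{i}" for i in range(N)]
            n_t = int(rng.integers(1, N + 1))
            n_d = int(rng.integers(1, N + 1))
            targets = set(rng.choice(genes, size=n_t, replace=False))
            de = set(rng.choice(genes, size=n_d, replace=False))
            a = len(targets & de)
            b = len(targets - de)
            c = len(de - targets)
            d = N - a - b - c
            out = regulator_enrichment(_net({"R": targets}), de, set(genes))
            assert out["p"].iloc[0] == pytest.approx(
                fisher_upper_tail_bruteforce(a, b, c, d), rel=1e-10, abs=1e-12)


class TestCompositeScore:
    def test_double_winner_scores_two(self):
        out = regenrich_score([1e-8, 0.5, 0.9], [1e-6, 0.3, 0.8],
                              regulators=["a", "b", "c"])
        best = out[out["regulator"] == "a"].iloc[0]
        assert best["score"] == pytest.approx(2.0)

    def test_double_loser_scores_zero(self):
        out = regenrich_score([1e-8, 1.0], [1e-6, 1.0], regulators=["a", "b"])
        worst = out[out["regulator"] == "b"].iloc[0]
        assert worst["score"] == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        dp, ep = rng.random(15) * 0.9 + 0.05, rng.random(15) * 0.9 + 0.05
        names = [f"r{i}" for i in range(15)]
        base = regenrich_score(dp, ep, regulators=names).set_index("regulator")
        perm = rng.permutation(15)
        permuted = regenrich_score(dp[perm], ep[perm],
                                   regulators=[names[i] for i in perm]
                                   ).set_index("regulator")
        assert np.allclose(base["score"].sort_index(),
                           permuted["score"].sort_index())

    def test_monotone_transformation_invariance(self):
        rng = np.random.default_rng(14)
        dp, ep = rng.random(10) * 0.9 + 0.05, rng.random(10) * 0.9 + 0.05
        names = [f"r{i}" for i in range(10)]
        base = regenrich_score(dp, ep, regulators=names).set_index("regulator")
        transformed = regenrich_score(dp ** 3, np.sqrt(ep),
                                      regulators=names).set_index("regulator")
        assert np.allclose(base["score"].sort_index(),
                           transformed["score"].sort_index())

    def test_zero_p_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            out = regenrich_score([0.0, 0.5], [0.5, 0.5], regulators=["a", "b"])
        assert np.isfinite(out["score"]).all()

    def test_top_k_deterministic(self):
        out = regenrich_score([0.5] * 4, [0.5] * 4,
                              regulators=["d", "b", "a", "c"])
        assert list(top_regulators(out, 2)["regulator"]) == ["a", "b"]


class TestPathwayAttribution:
    def test_points_are_shared_gene_counts(self):
        adjacency = pd.DataFrame({"P": [1, 1, 0]}, index=["g1", "g2", "g3"])
        net = _net({"R": {"g1", "g2", "g9"}})
        out = attribute_regulators_to_pathways(net, adjacency)
        assert out.iloc[0]["points"] == 2

    def test_regulator_without_pathway_genes_absent(self):
        adjacency = pd.DataFrame({"P": [1]}, index=["g1"])
        net = _net({"R": {"g2"}})
        out = attribute_regulators_to_pathways(net, adjacency)
        assert out.empty

    def test_top5_matches_exhaustive_counting_with_ties(self):
        genes = [f"g{i}" for i in range(12)]
        adjacency = pd.DataFrame({
            "P1": [1] * 6 + [0] * 6,
            "P2": [0] * 4 + [1] * 8,
        }, index=genes)
        targets = {
            "r1": set(genes[:6]),         # P1: 6, P2: 2
            "r2": set(genes[:3]),         # P1: 3
            "r3": set(genes[3:9]),        # P1: 3, P2: 5  (tie with r2 on P1)
            "r4": set(genes[6:]),         # P2: 6
            "r5": set(genes[:1]),         # P1: 1
            "r6": set(genes[11:]),        # P2: 1
        }
        scores = pd.DataFrame({"regulator": list(targets),
                               "score": [0.9, 0.2, 0.8, 0.7, 0.1, 0.05]})
        net = _net(targets)
        out = attribute_regulators_to_pathways(net, adjacency, scores=scores,
                                               top_k=5)
        # exhaustive counting oracle
        for pathway in ("P1", "P2"):
            path_genes = set(adjacency.index[adjacency[pathway] == 1])
            expected = sorted(
                ((len(targets[r] & path_genes),
                  float(scores.loc[scores["regulator"] == r, "score"].iloc[0]), r)
                 for r in targets if targets[r] & path_genes),
                key=lambda t: (-t[0], -t[1], t[2]))[:5]
            got = out[out["pathway"] == pathway]
            assert list(got["regulator"]) == [r for _, _, r in expected]
            assert list(got["points"]) == [p for p, _, _ in expected]
        # tie on P1 between r2 and r3 broken by composite score (r3 > r2)
        p1 = list(out[out["pathway"] == "P1"]["regulator"])
        assert p1.index("r3") < p1.index("r2")

    def test_empty_adjacency_rejected(self):
        with pytest.raises(ValidationError):
            attribute_regulators_to_pathways(_net({"R": {"g"}}),
                                             pd.DataFrame())


class TestPPIFilter:
    def _edges(self, confs):
        return pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(len(confs))],
            "gene_b": [f"b{i}" for i in range(len(confs))],
            "channel": ["physical"] * len(confs),
            "directed": [0] * len(confs),
            "confidence": confs,
        })

    def test_inclusive_boundary(self):
        out = filter_ppi_edges(self._edges([0.900, 0.899, 0.95]))
        assert list(out["confidence"]) == [0.900, 0.95]

    def test_empty_input(self):
        assert filter_ppi_edges(self._edges([])).empty

    def test_missing_confidence_rejected(self):
        edges = self._edges([0.9]).drop(columns="confidence")
        with pytest.raises(ValidationError):
            filter_ppi_edges(edges)


def test_planted_module_regulator_in_top3_composite():
    """End-to-end hub recovery: the planted regulator ranks top-3 by the
    composite score in nearly every replicate."""
    from quiescentome import SimConfig

    hits = 0
    n_rep = 5
    for seed in range(n_rep):
        study = simulate(SimConfig(seed=300 + seed))
        res = run_contrasts(study.expression)
        deg_union = set()
        for name in ("hlf-vs-uM", "uM_LPS-vs-uM", "hlf_LPS-vs-uM_LPS"):
            deg_union |= set(select_deg(res[name])["gene"])
        regulators = set(study.annotations.loc[
            study.annotations["class"] == "regulator", "gene"])
        net = build_coexpression_network(study.expression.subset_genes(deg_union),
                                         regulators)
        primary = res["hlf-vs-uM"].table.set_index("gene")
        de_genes = set(primary.index[primary["p"] < 0.05])
        enr = regulator_enrichment(net, de_genes, set(study.expression.genes))
        dp = np.array([float(primary.loc[r, "p"]) if r in primary.index else 1.0
                       for r in enr["regulator"]])
        scores = regenrich_score(dp, enr["p"].to_numpy(),
                                 regulators=list(enr["regulator"]))
        [module_reg] = study.truth.regulator_modules
        if module_reg in set(scores["regulator"].head(3)):
            hits += 1
    assert hits >= n_rep - 1
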