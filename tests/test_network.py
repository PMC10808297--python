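import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microfoodweb.io import CommunityTable
from microfoodweb.network import (
    group_associations,
    join_kingdoms,
    network_summary,
    prevalence_filter,
    spearman_edges,
    to_graph,
)
from microfoodweb.simulate import LatentFactor, SimulationConfig, simulate_communities


def brute_force_edges(data: pd.DataFrame, r_threshold=0.6, p_threshold=0.05):
    """Independent oracle: explicit rank transform + covariance loop + t test."""
    n = len(data)
    retained = set()
    for a, b in itertools.combinations(data.columns, 2):
        xa, xb = data[a].to_numpy(), data[b].to_numpy()
        if len(set(xa)) == 1 or len(set(xb)) == 1:
            continue
        ra, rb = stats.rankdata(xa), stats.rankdata(xb)
        ma, mb = ra.mean(), rb.mean()
        cov = sa = sb = 0.0
        for i in range(n):
            cov += (ra[i] - ma) * (rb[i] - mb)
            sa += (ra[i] - ma) ** 2
            sb += (rb[i] - mb) ** 2
        rho = cov / math.sqrt(sa * sb)
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        if abs(rho) > r_threshold and p < p_threshold:
            retained.add(frozenset((a, b)))
    return retained


def _table(array, taxa=None):
    array = np.asarray(array, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(array.shape[1])]
    index = [f"S{i}" for i in range(array.shape[0])]
    return CommunityTable(pd.DataFrame(array, index=index, columns=taxa))


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        col = [1, 2, 3] + [0] * 9
        tbl = _table(np.column_stack([col, [1] * 12]), taxa=["rare", "common"])
        kept = prevalence_filter(tbl, min_samples=3)
        assert "rare" in kept.taxa

    def test_below_threshold_dropped(self):
        col = [1, 2] + [0] * 10
        tbl = _table(np.column_stack([col, [1] * 12]), taxa=["rare", "common"])
        assert prevalence_filter(tbl, min_samples=3).taxa == ["common"]

    def test_all_zero_taxon_always_dropped(self):
        tbl = _table([[0, 1], [0, 2], [0, 3]], taxa=["zero", "ok"])
        assert prevalence_filter(tbl, min_samples=1).taxa == ["ok"]

    def test_empty_result_is_error(self):
        tbl = _table([[1, 0], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="no taxon"):
            prevalence_filter(tbl, min_samples=3)


class TestSpearmanEdges:
    def test_perfect_monotone_pair_retained(self):
        x = np.arange(8)
        tbl = _table(np.column_stack([x, np.exp(x)]), taxa=["a", "b"])
        edges = spearman_edges(tbl)
        assert len(edges) == 1
        assert edges.iloc[0]["rho"] == pytest.approx(1.0, abs=1e-12)
        assert edges.iloc[0]["sign"] == "+"

    def test_antitone_pair_is_negative_edge(self):
        x = np.arange(8)
        tbl = _table(np.column_stack([x, x.max() - x]), taxa=["a", "b"])
        edges = spearman_edges(tbl)
        assert edges.iloc[0]["rho"] == pytest.approx(-1.0, abs=1e-12)
        assert edges.iloc[0]["sign"] == "-"

    def test_constant_taxon_skipped(self):
        tbl = _table([[1, 5], [1, 6], [1, 7], [1, 8]], taxa=["const", "x"])
        assert len(spearman_edges(tbl)) == 0

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(50):
            tbl = _table(rng.integers(0, 50, size=(8, 15)))
            edges = spearman_edges(tbl)
            got = set(frozenset((r.source, r.target)) for r in edges.itertuples())
            assert got == brute_force_edges(tbl.data)

    def test_invariant_to_column_order(self, rng):
        data = rng.integers(0, 30, size=(10, 8)).astype(float)
        tbl = _table(data)
        perm = list(reversed(tbl.taxa))
        shuffled = CommunityTable(tbl.data[perm])
        e1 = spearman_edges(tbl)
        e2 = spearman_edges(shuffled)
        pairs1 = set(frozenset((r.source, r.target)) for r in e1.itertuples())
        pairs2 = set(frozenset((r.source, r.target)) for r in e2.itertuples())
        assert pairs1 == pairs2

    def test_exact_p_small_n_only_perfect_rho_passes(self):
        # at n=3 any non-perfect rank order yields p >= 0.5 for both methods
        for perm in itertools.permutations([1, 2, 3]):
            tbl = _table(np.column_stack([[1, 2, 3], perm]), taxa=["a", "b"])
            for method in ("t_approx", "exact_smalln"):
                edges = spearman_edges(tbl, p_method=method)
                rho = stats.spearmanr([1, 2, 3], perm).statistic
                if abs(rho) == 1.0 and method == "t_approx":
                    assert len(edges) == 1
                else:
                    # exact p at n=3 is 2/6 = 1/3 even for |rho| = 1
                    assert len(edges) == 0

    def test_exact_enumeration_agrees_with_rank_distance_oracle(self, rng):
        """Exact p-values match full enumeration via the classical tie-free
        identity rho = 1 - 6·Σd²/(n(n²-1)) — a different formula from the
        Pearson-on-ranks route the implementation uses."""
        n = 6
        all_perms = np.array(list(itertools.permutations(range(1, n + 1))))

        def oracle_p(x, y):
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            obs = 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))
            d2 = ((all_perms - rx) ** 2).sum(axis=1)
            null = 1 - 6 * d2 / (n * (n**2 - 1))
            return (np.abs(null) >= abs(obs) - 1e-12).mean(), obs

        for _ in range(20):
            x = rng.permutation(n)
            y = rng.permutation(n)
            edges = spearman_edges(
                _table(np.column_stack([x, y]), taxa=["a", "b"]),
                r_threshold=0.0, p_threshold=1.01, p_method="exact_smalln",
            )
            p_exp, obs = oracle_p(x, y)
            if abs(obs) == 0.0:
                assert len(edges) == 0  # rho exactly 0 is not > threshold
                continue
            assert edges.iloc[0]["p"] == pytest.approx(p_exp, abs=1e-12)


class TestNetworkSummary:
    def test_hand_counted_stats(self):
        edges = pd.DataFrame(
            {
                "source": ["a", "a", "b", "c", "d"],
                "target": ["b", "c", "c", "d", "e"],
                "rho": [0.9, 0.8, 0.7, -0.9, -0.8],
                "p": [0.01] * 5,
                "sign": ["+", "+", "+", "-", "-"],
                "kingdom_source": [""] * 5,
                "kingdom_target": [""] * 5,
            }
        )
        stats_ = network_summary(edges)
        assert stats_.n_nodes == 5
        assert stats_.total_links == 5
        assert stats_.positive_links == 3 and stats_.negative_links == 2
        assert stats_.average_degree == pytest.approx(2.0)

    def test_empty_network(self):
        stats_ = network_summary(pd.DataFrame(columns=["source", "target", "sign"]))
        assert stats_.total_links == 0 and math.isnan(stats_.average_degree)

    def test_sign_conservation_on_simulated_networks(self, rng):
        for seed in range(5):
            tbl = _table(rng.integers(0, 60, size=(10, 12)))
            stats_ = network_summary(spearman_edges(tbl))
            assert stats_.positive_links + stats_.negative_links == stats_.total_links


class TestJoinAndGraph:
    def test_cross_kingdom_join_and_attributes(self):
        b = _table([[1, 2], [3, 4], [5, 6], [7, 8]], taxa=["b1", "b2"])
        f = _table([[1, 1], [2, 3], [3, 5], [4, 7]], taxa=["f1", "f2"])
        joined, kingdoms = join_kingdoms(bacteria=b, fungi=f)
        assert kingdoms == {"b1": "bacteria", "b2": "bacteria",
                            "f1": "fungi", "f2": "fungi"}
        edges = spearman_edges(joined, kingdoms=kingdoms)
        graph = to_graph(edges)
        assert all("kingdom" in graph.nodes[n] for n in graph.nodes)

    def test_duplicate_taxon_across_kingdoms_rejected(self):
        b = _table([[1], [2], [3]], taxa=["shared"])
        with pytest.raises(ValueError, match="more than one kingdom"):
            join_kingdoms(bacteria=b, fungi=b)


class TestGroupAssociations:
    def test_planted_fungal_fungivore_link_recovered(self):
        fungivores = ["Aphelenchus", "Aphelenchoides", "Ditylenchus",
                      "Filenchus", "Miculenchus"]
        members = tuple(
            [("fungi", f"Fungus_{i:03d}") for i in (1, 2, 3)]
            + [("nematodes", g) for g in fungivores]
        )
        cfg = SimulationConfig(
            treatments=("T",), replicates=12, n_bacteria=10, n_fungi=10,
            latent_factors=(LatentFactor(taxa=members, rho=0.95),),
            seed=4,
        )
        data = simulate_communities(cfg)
        out = group_associations(data.bacteria, data.fungi, data.annotated_nematodes())
        row = out[(out.group_a == "fungi") & (out.group_b == "FF")].iloc[0]
        assert row["sign"] == "+" and row["rho"] > 0.6

    def test_no_self_pairs(self, rng):
        cfg = SimulationConfig(treatments=("T",), replicates=6,
                               n_bacteria=5, n_fungi=5, seed=1)
        data = simulate_communities(cfg)
        out = group_associations(data.bacteria, data.fungi, data.annotated_nematodes())
        assert (out.group_a != out.group_b).all()
        assert len(out) == 15  # C(6,2) group pairs
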