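import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from chromdyn.motif_ensembles import (
    PWM,
    bimod_lr_test,
    build_region_motif_matrix,
    discover_ensembles,
    embed_and_graph,
    find_cluster_markers,
    louvain_cluster,
    rank_network_hubs,
    read_pwms,
    scan_pwm,
    scan_regions,
)
from chromdyn.synthetic_data import generate_motif_matrix, make_ensemble_spec

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def all_partitions(items):
    """All set partitions (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in all_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] + [first]] + p[i + 1 :]
        yield [[first]] + p


def modularity_by_hand(graph, partition, gamma=1.0):
    m = graph.number_of_edges()
    q = 0.0
    for comm in partition:
        sub = set(comm)
        intra = sum(1 for u, v in graph.edges if u in sub and v in sub)
        deg = sum(d for _, d in graph.degree(sub))
        q += intra / m - gamma * (deg / (2 * m)) ** 2
    return q


def max_modularity_exhaustive(graph, gamma=1.0):
    nodes = list(graph.nodes)
    return max(
        modularity_by_hand(graph, p, gamma) for p in all_partitions(nodes)
    )


def naive_two_part_loglik(x):
    """Independently coded zero-inflated log-likelihood (pure python)."""
    zeros = [v for v in x if v <= 0]
    pos = [v for v in x if v > 0]
    n = len(x)
    a = min(max(len(pos) / n, 1e-5), 1 - 1e-5)
    ll = len(zeros) * math.log(1 - a) + len(pos) * math.log(a)
    if pos:
        mu = sum(pos) / len(pos)
        if len(pos) >= 2:
            var = sum((v - mu) ** 2 for v in pos) / (len(pos) - 1)
            sd = math.sqrt(var) if var > 0 else 1.0
        else:
            sd = 1.0
        ll += sum(
            -0.5 * math.log(2 * math.pi * sd * sd) - (v - mu) ** 2 / (2 * sd * sd)
            for v in pos
        )
    return ll


def one_hot_pwm(consensus: str, p: float = 0.97) -> PWM:
    bases = "ACGT"
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat[bases.index(b), j] = p
    return PWM("onehot", mat)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

class TestScanPwm:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = PWM("bg", np.full((4, 6), 0.25))
        hits = scan_pwm("ACGTACGTACGT", pwm, threshold=0.0)
        assert len(hits) == 2 * (12 - 6 + 1)
        assert all(score == pytest.approx(0.0) for _, _, score in hits)

    def test_consensus_match_has_maximal_score(self):
        pwm = one_hot_pwm("ACGTAC")
        expected = 6 * np.log2(0.97 / 0.25)
        hits = scan_pwm("TTTACGTACTTT", pwm, threshold=expected - 1e-6)
        fwd = [h for h in hits if h[1] == "+"]
        assert fwd and fwd[0][0] == 3
        assert fwd[0][2] == pytest.approx(expected)

    def test_reverse_strand_motif_found(self):
        pwm = one_hot_pwm("AACCGT")
        seq = "TTTT" + "ACGGTT" + "TTTT"  # reverse complement of AACCGT
        hits = scan_pwm(seq, pwm, threshold=5.0)
        assert any(strand == "-" and pos == 4 for pos, strand, _ in hits)

    def test_n_bases_contribute_zero(self):
        pwm = one_hot_pwm("ACGT")
        full = scan_pwm("ACGT", pwm, threshold=-100)[0][2]
        with_n = scan_pwm("ACNT", pwm, threshold=-100)[0][2]
        assert with_n == pytest.approx(full - np.log2(0.97 / 0.25))

    def test_motif_longer_than_sequence_no_hits(self):
        pwm = one_hot_pwm("ACGTACGT")
        assert scan_pwm("ACG", pwm, threshold=-100) == []

    def test_matches_biopython_pssm_scores(self, rng):
        """Forward-strand scores agree with Biopython's PSSM (independent oracle)."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        mat = rng.dirichlet(np.ones(4), size=8).T  # 4 x 8 columns sum to 1
        pwm = PWM("rand", mat)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        bio = bio_motifs.Motif(
            counts={b: list(mat[i] * 1000) for i, b in enumerate("ACGT")}
        )
        pssm = bio.counts.normalize(pseudocounts=0).log_odds()
        expected = pssm.calculate(Seq(seq))
        got = scan_pwm(seq, pwm, threshold=-np.inf)
        fwd = sorted([h for h in got if h[1] == "+"])
        np.testing.assert_allclose(
            [s for _, _, s in fwd], np.asarray(expected, dtype=float), atol=1e-4
        )

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            PWM("bad", np.full((4, 6), 0.3))
        with pytest.raises(ValueError):
            PWM("short", np.full((4, 2), 0.25))

    def test_jaspar_roundtrip(self, tmp_path):
        text = (
            ">M1\n"
            "A [ 10 0 0 10 ]\n"
            "C [ 0 10 0 0 ]\n"
            "G [ 0 0 10 0 ]\n"
            "T [ 0 0 0 0 ]\n"
        )
        path = tmp_path / "m.jaspar"
        path.write_text(text)
        pwms = read_pwms(path)
        assert len(pwms) == 1 and pwms[0].motif_id == "M1"
        np.testing.assert_allclose(pwms[0].matrix[:, 0], [1, 0, 0, 0])


class TestRegionMotifMatrix:
    def test_one_hot_column(self):
        hits = pd.DataFrame(
            {"region_id": ["r1"], "motif_id": ["M1"]}
        )
        mat = build_region_motif_matrix(hits, region_ids=["r1", "r2"])
        assert mat.loc["r1", "M1"] == 1 and mat.loc["r2", "M1"] == 0

    def test_no_hits_all_zero(self):
        hits = pd.DataFrame(columns=["region_id", "motif_id"])
        mat = build_region_motif_matrix(hits, region_ids=["r1"], motif_ids=["M1"])
        assert (mat.to_numpy() == 0).all()

    def test_counts_mode(self):
        hits = pd.DataFrame({"region_id": ["r1", "r1"], "motif_id": ["M1", "M1"]})
        mat = build_region_motif_matrix(hits, binary=False)
        assert mat.loc["r1", "M1"] == 2

    def test_scanner_and_external_table_agree(self, rng):
        """The internal scanner and an imported hit table produce the same matrix."""
        pwm = one_hot_pwm("ACGTAA")
        seqs = {
            "r1": "TTTTACGTAATTTT",
            "r2": "GGGGGGGGGGGGGG",
            "r3": "ACGTAACCACGTAA",
        }
        thr = 6 * np.log2(0.97 / 0.25) - 1.0
        hits = scan_regions(seqs, [pwm], thr)
        internal = build_region_motif_matrix(hits, region_ids=list(seqs))
        external = pd.DataFrame(
            {"region_id": ["r1", "r3", "r3"], "motif_id": ["onehot"] * 3}
        )
        imported = build_region_motif_matrix(external, region_ids=list(seqs))
        pd.testing.assert_frame_equal(internal, imported)


# ---------------------------------------------------------------------------
# graph construction + Louvain
# ---------------------------------------------------------------------------

class TestEmbedAndGraph:
    def test_disjoint_blocks_have_no_cross_edges(self):
        spec = make_ensemble_spec(
            n_ensembles=2, regions_per_ensemble=20, motifs_per_ensemble=5,
            n_background_motifs=0, p_in=1.0, p_out=0.0, seed=1,
        )
        mat, labels = generate_motif_matrix(spec)
        graph = embed_and_graph(mat, k_neighbors=10)
        for u, v in graph.edges:
            assert labels[u] == labels[v]

    def test_identical_rows_complete_graph_weight_one(self):
        mat = pd.DataFrame(np.ones((8, 5)), index=[f"r{i}" for i in range(8)])
        graph = embed_and_graph(mat, k_neighbors=7)
        assert graph.number_of_edges() == 8 * 7 // 2
        assert all(d["weight"] == pytest.approx(1.0) for _, _, d in graph.edges(data=True))

    def test_k_neighbors_too_large_rejected(self):
        mat = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            embed_and_graph(mat, k_neighbors=5)


class TestLouvain:
    def _bridged_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        return g

    def test_bridged_cliques_two_communities_at_max_modularity(self):
        g = self._bridged_cliques()
        part = louvain_cluster(g, resolution=1.0, seed=1)
        assert part.nunique() == 2
        assert part[0] == part[1] == part[2] == part[3]
        assert part[4] == part[5] == part[6] == part[7]
        got_q = part.attrs["modularity"]
        assert got_q == pytest.approx(max_modularity_exhaustive(g), abs=1e-12)

    @pytest.mark.parametrize(
        "graph",
        [
            nx.complete_graph(5),
            nx.cycle_graph(6),
            nx.path_graph(7),
            nx.star_graph(6),
            nx.complete_bipartite_graph(3, 3),
            nx.barbell_graph(3, 1),
        ],
        ids=["K5", "C6", "P7", "S7", "K33", "barbell"],
    )
    def test_matches_exhaustive_modularity_on_small_graphs(self, graph):
        part = louvain_cluster(graph, resolution=1.0, seed=1)
        assert part.attrs["modularity"] == pytest.approx(
            max_modularity_exhaustive(graph), abs=1e-12
        )

    def test_single_clique_one_community(self):
        part = louvain_cluster(nx.complete_graph(6), resolution=1.0, seed=1)
        assert part.nunique() == 1

    def test_beats_trivial_partitions(self):
        g = self._bridged_cliques()
        part = louvain_cluster(g, resolution=1.0, seed=3)
        q = part.attrs["modularity"]
        singletons = [[n] for n in g.nodes]
        one_block = [list(g.nodes)]
        assert q >= modularity_by_hand(g, singletons)
        assert q >= modularity_by_hand(g, one_block)

    def test_resolution_monotone_community_count(self):
        g = self._bridged_cliques()
        counts = [
            louvain_cluster(g, resolution=r, seed=1).nunique()
            for r in (0.1, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph())


# ---------------------------------------------------------------------------
# bimod test + markers + hubs
# ---------------------------------------------------------------------------

class TestBimod:
    def test_identical_groups_lr_zero_p_one(self):
        x = np.array([0, 0, 1.0, 2, 3] * 10)
        lr, p = bimod_lr_test(x, x.copy())
        assert lr == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_all_zero_vs_all_one_closed_form(self):
        lr, p = bimod_lr_test(np.zeros(50), np.ones(50))
        # detection component alone: 2 * 2n * ln 2 (up to the proportion clamp)
        assert lr == pytest.approx(4 * 50 * math.log(2), rel=1e-4)
        assert p < 1e-6

    def test_both_groups_all_zero(self):
        lr, p = bimod_lr_test(np.zeros(20), np.zeros(30))
        assert lr == pytest.approx(0.0, abs=1e-10) and p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bimod_lr_test(np.array([]), np.ones(3))

    def test_matches_naive_two_part_oracle(self, rng):
        """100 random fixtures agree with an independently coded likelihood
        to 1e-8."""
        for _ in range(100):
            n1, n2 = rng.integers(5, 60, size=2)
            x = np.where(rng.random(n1) < 0.5, rng.normal(2, 1, n1), 0.0)
            y = np.where(rng.random(n2) < 0.3, rng.normal(1, 2, n2), 0.0)
            lr, p = bimod_lr_test(x, y)
            lr_o = 2 * (
                naive_two_part_loglik(x)
                + naive_two_part_loglik(y)
                - naive_two_part_loglik(np.concatenate([x, y]))
            )
            assert lr == pytest.approx(max(lr_o, 0.0), abs=1e-8)
            assert p == pytest.approx(stats.chi2.sf(max(lr_o, 0.0), 3), abs=1e-8)


class TestMarkers:
    def _matrix_with_planted_marker(self):
        rng = np.random.default_rng(5)
        n = 60
        mat = pd.DataFrame(
            (rng.random((n, 4)) < 0.3).astype(int),
            index=[f"r{i}" for i in range(n)],
            columns=["M_bg1", "M_bg2", "M_bg3", "M_planted"],
        )
        part = pd.Series([1] * 30 + [2] * 30, index=mat.index)
        mat.loc[part == 1, "M_planted"] = 1
        mat.loc[part == 2, "M_planted"] = 0
        return mat, part

    def test_planted_motif_is_top_marker(self):
        mat, part = self._matrix_with_planted_marker()
        markers = find_cluster_markers(mat, part)
        top = markers[markers["cluster_id"] == 1].iloc[0]
        assert top["motif_id"] == "M_planted"
        assert top["pct_in"] == 1.0 and top["pct_out"] == 0.0
        assert top["p_adj"] <= 4 * top["p"]

    def test_min_pct_filter(self):
        mat, part = self._matrix_with_planted_marker()
        mat["M_rare"] = 0
        mat.loc[mat.index[:1], "M_rare"] = 1  # 1/30 in cluster 1 < 10%
        markers = find_cluster_markers(mat, part)
        assert "M_rare" not in set(markers["motif_id"])

    def test_logfc_filter(self):
        # detection 50% vs 48% -> ln fold change ~0.04 < 0.09
        mat = pd.DataFrame(
            {"M1": [1] * 25 + [0] * 25 + [1] * 24 + [0] * 26},
            index=[f"r{i}" for i in range(100)],
        )
        part = pd.Series([1] * 50 + [2] * 50, index=mat.index)
        markers = find_cluster_markers(mat, part)
        assert len(markers) == 0

    def test_singleton_cluster_flagged(self):
        mat = pd.DataFrame(
            {"M1": [1, 0, 0, 0, 1, 1]}, index=[f"r{i}" for i in range(6)]
        )
        part = pd.Series([1, 2, 2, 2, 2, 2], index=mat.index)
        markers = find_cluster_markers(mat, part, min_pct=0.0, logfc_threshold=-10,
                                       only_pos=False)
        flagged = markers[markers["cluster_id"] == 1]
        assert flagged["low_power"].all()


class TestHubs:
    def test_star_center_ranked_first(self):
        edges = pd.DataFrame(
            {"tf_a": ["HUB"] * 4, "tf_b": ["T1", "T2", "T3", "T4"]}
        )
        out = rank_network_hubs(edges, ["HUB", "T1", "T2", "T3", "T4"])
        assert out.index[0] == "HUB" and out["central"].iloc[0]

    def test_empty_edges_zero_degrees_no_central(self):
        out = rank_network_hubs(pd.DataFrame(), ["A", "B"])
        assert (out["weighted_degree"] == 0).all()
        assert not out["central"].any()

    def test_weighted_degree_arithmetic(self):
        edges = pd.DataFrame(
            {"tf_a": ["a", "a", "b"], "tf_b": ["b", "c", "c"],
             "weight": [0.9, 0.9, 0.1]}
        )
        out = rank_network_hubs(edges, ["a", "b", "c"])
        assert out.index[0] == "a"
        assert out.loc["a", "weighted_degree"] == pytest.approx(1.8)


class TestEnsembleRecovery:
    def test_planted_ensembles_recovered(self):
        """2-4 planted ensembles: ARI >= 0.9 and defining motifs among markers."""
        for n_ens in (2, 3, 4):
            spec = make_ensemble_spec(
                n_ensembles=n_ens, regions_per_ensemble=50,
                motifs_per_ensemble=8, p_in=0.9, p_out=0.05, seed=n_ens,
            )
            mat, truth = generate_motif_matrix(spec)
            part, markers = discover_ensembles(mat, seed=1)
            ari = adjusted_rand_score(truth.values, part.reindex(truth.index).values)
            assert ari >= 0.9, f"{n_ens} ensembles: ARI {ari}"
            for k, (motifs, regions, _) in enumerate(spec.ensembles):
                cid = part.loc[truth.index[truth == k]].mode().iloc[0]
                marker_ids = set(
                    markers.loc[markers["cluster_id"] == cid, "motif_id"]
                )
                defining = {f"MOTIF{j:03d}" for j in motifs}
                assert defining <= marker_ids

    def test_deterministic_under_seed(self):
        spec = make_ensemble_spec(seed=9)
        mat, _ = generate_motif_matrix(spec)
        a, ma = discover_ensembles(mat, seed=4)
        b, mb = discover_ensembles(mat, seed=4)
        assert (a == b).all()
        pd.testing.assert_frame_equal(ma, mb)
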