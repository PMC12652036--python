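from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from periomics.networks import (
    build_commensal_network,
    build_network,
    cluster_taxa,
    expand_constellations,
    find_constellations,
    is_numeric_name,
    select_commensal,
    select_pathogenic,
)
from periomics.rmcorr import NINE_FACTORS, CorrelationScreen


def make_screen(r, p=None, taxa=None, factors=None):
    r = np.atleast_2d(np.asarray(r, float))
    taxa = taxa or [f"Taxon_{i}" for i in range(r.shape[0])]
    factors = factors or list(NINE_FACTORS)[: r.shape[1]]
    rdf = pd.DataFrame(r, index=taxa, columns=factors)
    pdf = pd.DataFrame(
        np.full_like(r, 1e-6) if p is None else np.atleast_2d(np.asarray(p, float)),
        index=taxa,
        columns=factors,
    )
    return CorrelationScreen(rdf, pdf, n_obs=100, n_subjects=10)


def sym(rng, n, low=-1.0, high=1.0):
    A = rng.uniform(low, high, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    names = [f"T{i}" for i in range(n)]
    return pd.DataFrame(A, index=names, columns=names)


class TestNumericNames:
    @pytest.mark.parametrize(
        "name,numeric",
        [
            ("GGB9342_SGB14341", True),
            ("Prevotella_sp_GGB1287_SGB1266", True),
            ("Saccharibacteria_sp_OTU512", True),
            ("Porphyromonas_gingivalis", False),
            ("Candidatus_Nanosynsacchari_sp_TM7_ANC_38_39_G1_1", False),
        ],
    )
    def test_classification(self, name, numeric):
        assert is_numeric_name(name) is numeric


class TestClusterTaxa:
    def test_separable_profiles_order_iii_to_i(self):
        sc = make_screen(
            [[1.0] * 9, [0.0] * 9, [-1.0] * 9], taxa=["hot", "mid", "cold"],
            factors=list(NINE_FACTORS),
        )
        labels = cluster_taxa(sc)
        assert labels["hot"] == "III" and labels["mid"] == "II" and labels["cold"] == "I"

    def test_duplicated_profiles_share_cluster(self):
        sc = make_screen(
            [[0.8] * 9, [0.8] * 9, [-0.5] * 9, [0.1] * 9],
            factors=list(NINE_FACTORS),
        )
        labels = cluster_taxa(sc)
        assert labels.iloc[0] == labels.iloc[1]

    def test_permutation_invariance(self, rng):
        r = rng.uniform(-1, 1, size=(10, 9))
        sc = make_screen(r, factors=list(NINE_FACTORS))
        labels = cluster_taxa(sc)
        perm = rng.permutation(10)
        sc2 = CorrelationScreen(sc.r.iloc[perm], sc.p.iloc[perm], 100, 10)
        labels2 = cluster_taxa(sc2)
        for t in sc.r.index:
            assert labels[t] == labels2[t]

    def test_matches_naive_agglomeration(self, rng):
        """Brute-force complete-linkage agglomeration oracle."""
        r = rng.uniform(-1, 1, size=(8, 4))
        sc = make_screen(r, factors=["a", "b", "c", "d"])
        labels = cluster_taxa(sc, n_clusters=3)

        # naive O(n^3) agglomeration
        clusters = [{i} for i in range(8)]
        D = np.linalg.norm(r[:, None, :] - r[None, :, :], axis=2)
        while len(clusters) > 3:
            best = None
            for i, j in combinations(range(len(clusters)), 2):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
            _, i, j = best
            clusters[i] |= clusters[j]
            del clusters[j]
        naive = {}
        for cid, members in enumerate(clusters):
            for m in members:
                naive[m] = cid
        # same partition (labels may differ)
        for i, j in combinations(range(8), 2):
            assert (labels.iloc[i] == labels.iloc[j]) == (naive[i] == naive[j])

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            cluster_taxa(make_screen([[0.5] * 9], factors=list(NINE_FACTORS)))


class TestSelectPathogenic:
    def test_separable_twenty(self, rng):
        r = np.vstack([np.full((20, 9), 0.7), np.full((15, 9), 0.2)])
        sc = make_screen(r, factors=list(NINE_FACTORS))
        taxa, thr = select_pathogenic(sc)
        assert len(taxa) == 20
        assert 0.2 < thr <= 0.7
        assert set(taxa) == {f"Taxon_{i}" for i in range(20)}

    def test_no_taxon_passes_p_filter(self):
        sc = make_screen([[0.9] * 9], p=[[0.5] * 9], factors=list(NINE_FACTORS))
        with pytest.warns(UserWarning):
            taxa, thr = select_pathogenic(sc)
        assert taxa == []

    def test_numeric_names_excluded_first(self):
        r = np.full((2, 9), 0.9)
        sc = make_screen(r, taxa=["GGB1_SGB2", "Real_species"], factors=list(NINE_FACTORS))
        taxa, _ = select_pathogenic(sc, target_n=2)
        assert taxa == ["Real_species"]

    def test_matches_grid_scan_oracle(self, rng):
        r = rng.uniform(0, 1, size=(30, 9))
        sc = make_screen(r, factors=list(NINE_FACTORS))
        taxa, thr = select_pathogenic(sc, target_n=12)
        min_r = sc.r.min(axis=1)
        best = None
        for t in np.round(np.arange(0, 1.001, 0.01), 2):
            count = int((min_r > t).sum())
            gap = abs(count - 12)
            if best is None or gap <= best[0]:
                best = (gap, float(t))
        assert thr == pytest.approx(best[1])
        assert set(taxa) == set(min_r.index[min_r > best[1]])

    def test_monotone_in_threshold(self, rng):
        r = rng.uniform(0, 1, size=(25, 9))
        sc = make_screen(r, factors=list(NINE_FACTORS))
        min_r = sc.r.min(axis=1)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            cur = set(min_r.index[min_r > thr])
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestBuildNetwork:
    def test_zero_matrix_is_edgeless(self):
        m = sym(np.random.default_rng(0), 5)
        m.values[:] = 0.0
        np.fill_diagonal(m.values, 1.0)
        net = build_network(m)
        assert net.graph.number_of_edges() == 0

    def test_boundary_r_equal_threshold_has_edge(self):
        names = ["A", "B"]
        m = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]], index=names, columns=names)
        net = build_network(m, edge_threshold=0.6)
        assert net.graph.has_edge("A", "B")

    def test_edges_match_brute_force(self, rng):
        m = sym(rng, 8)
        net = build_network(m, edge_threshold=0.3)
        for i, a in enumerate(m.index):
            for j, b in enumerate(m.index):
                if i < j:
                    assert net.graph.has_edge(a, b) == (m.iloc[i, j] >= 0.3)

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            build_network(m)


class TestConstellations:
    def test_edgeless_graph_has_none(self):
        m = sym(np.random.default_rng(0), 6)
        m.values[:] = 0.0
        np.fill_diagonal(m.values, 1.0)
        assert build_network(m).constellations == []

    def test_planted_clique_found_exactly(self):
        names = list("ABCDEF")
        m = pd.DataFrame(np.zeros((6, 6)), index=names, columns=names)
        np.fill_diagonal(m.values, 1.0)
        for a, b in combinations("ABCD", 2):
            m.loc[a, b] = m.loc[b, a] = 0.8
        net = build_network(m, edge_threshold=0.6)
        assert net.constellations == [("A", "B", "C", "D")]
        # exhaustive oracle: all subsets of size >= 4 that are cliques and maximal
        nodes = names
        cliques = []
        for size in range(6, 3, -1):
            for sub in combinations(nodes, size):
                if all(m.loc[a, b] >= 0.6 for a, b in combinations(sub, 2)):
                    if not any(set(sub) < set(c) for c in cliques):
                        cliques.append(tuple(sorted(sub)))
        assert net.constellations == sorted(cliques, key=lambda c: (-len(c), c))

    def test_audit_passes_for_reported_cliques(self, rng):
        m = sym(rng, 10, low=0, high=1)
        net = build_network(m, edge_threshold=0.5)
        assert net.audit_constellations()


class TestExpand:
    def test_boundary_inclusive(self):
        names = ["core", "halo"]
        r = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=names, columns=names)
        p = pd.DataFrame([[0.0, 0.01], [0.01, 0.0]], index=names, columns=names)
        out = expand_constellations(["core"], r, p)
        assert out["core"] == ["halo"]

    def test_no_candidates(self):
        names = ["core", "halo"]
        r = pd.DataFrame([[1.0, 0.1], [0.1, 1.0]], index=names, columns=names)
        p = pd.DataFrame([[0.0, 0.9], [0.9, 0.0]], index=names, columns=names)
        assert expand_constellations(["core"], r, p)["core"] == []

    def test_matches_brute_force(self, rng):
        n = 8
        names = [f"T{i}" for i in range(n)]
        r = sym(rng, n, 0, 1)
        p = sym(rng, n, 0, 0.2).abs()
        core = ["T0", "T1"]
        out = expand_constellations(core, r, p, 0.5, 0.05)
        for member in core:
            expected = sorted(
                t for t in names if t not in core
                and r.loc[t, member] >= 0.5 and p.loc[t, member] < 0.05
            )
            assert out[member] == expected


class TestCommensal:
    def test_boundary_count_selected(self):
        p = [[0.5] * 6 + [0.001] * 3]
        sc = make_screen([[0.1] * 9], p=p, factors=list(NINE_FACTORS))
        assert select_commensal(sc) == ["Taxon_0"]

    def test_fully_significant_taxon_excluded(self):
        sc = make_screen([[0.5] * 9], p=[[1e-5] * 9], factors=list(NINE_FACTORS))
        assert select_commensal(sc) == []

    def test_both_criteria_match_row_scan(self, rng):
        r = rng.uniform(-1, 1, size=(20, 9))
        p = rng.uniform(0, 0.2, size=(20, 9))
        sc = make_screen(r, p=p, factors=list(NINE_FACTORS))
        got_p = select_commensal(sc, "p_gt_0.05")
        got_n = select_commensal(sc, "negative_r")
        for i, taxon in enumerate(sc.taxa):
            assert (taxon in got_p) == ((p[i] > 0.05).sum() >= 6)
            assert (taxon in got_n) == ((r[i] < 0).sum() >= 6)

    def test_unknown_criterion(self):
        sc = make_screen([[0.1] * 9], factors=list(NINE_FACTORS))
        with pytest.raises(ValueError):
            select_commensal(sc, "bogus")


class TestCommensalNetwork:
    def test_boundary_exactly_point_one_is_excluded(self):
        names = ["A", "B"]
        r = pd.DataFrame([[1.0, 0.1], [0.1, 1.0]], index=names, columns=names)
        p = pd.DataFrame([[0.0, 0.001], [0.001, 0.0]], index=names, columns=names)
        net = build_commensal_network(r, p)
        assert net.graph.number_of_edges() == 0

    def test_all_nonsignificant_is_edgeless(self, rng):
        r = sym(rng, 5, -0.9, 0.9)
        p = sym(rng, 5, 0.2, 0.9).abs()
        assert build_commensal_network(r, p).graph.number_of_edges() == 0

    def test_edges_and_signs_match_brute_force(self, rng):
        r = sym(rng, 7, -1, 1)
        p = sym(rng, 7, 0, 0.3).abs()
        net = build_commensal_network(r, p, 0.1)
        for i, a in enumerate(r.index):
            for j, b in enumerate(r.index):
                if i < j:
                    expect = abs(r.iloc[i, j]) > 0.1 and p.iloc[i, j] < 0.05
                    assert net.graph.has_edge(a, b) == expect
                    if expect:
                        assert net.graph.edges[a, b]["sign"] == (
                            1 if r.iloc[i, j] > 0 else -1
                        )


@pytest.fixture(scope="module")
def analysis(default_cohort):
    from periomics.abundance import prevalence_filter
    from periomics.pipeline import condition_level_factors
    from periomics.rmcorr import rmcorr_matrix, screen

    co = default_cohort
    filtered = prevalence_filter(co.abundance, 0.10)
    taxa = filtered.to_biomass().absolute.T
    cells = pd.MultiIndex.from_frame(
        co.metadata[["subject_id", "condition", "visit_month"]]
    )
    factors = condition_level_factors(co.biomarkers, NINE_FACTORS, index=cells)
    factors.index = taxa.index
    subj = co.metadata["subject_id"].to_numpy()
    sc = screen(taxa, factors, subj)
    pathogenic, thr = select_pathogenic(sc)
    tt_r, _ = rmcorr_matrix(taxa[pathogenic], subj)
    net = build_network(tt_r, 0.6, screen=sc, include_factors=True)
    return sc, pathogenic, net


class TestOnDefaultCohort:
    """Structure recovery on the study-sized synthetic cohort."""

    def test_constellations_recover_red_and_pink_groups(self, analysis):
        _, _, net = analysis
        red = {"Porphyromonas_endodontalis", "Tannerella_forsythia",
               "Treponema_denticola", "Filifactor_alocis"}
        pink = {"Fusobacterium_nucleatum", "Dialister_invisus",
                "Treponema_socranskii",
                "Candidatus_Nanosynsacchari_sp_TM7_ANC_38_39_G1_1"}
        cliques = [set(c) for c in net.constellations]
        assert any(red <= c for c in cliques)
        assert any(pink <= c for c in cliques)
        # the two groups never co-occur in one clique
        assert not any(red <= c and pink <= c for c in cliques)

    def test_about_twenty_pathogenic_taxa(self, analysis):
        _, pathogenic, _ = analysis
        assert 14 <= len(pathogenic) <= 26

    def test_pathogens_cluster_away_from_commensals(self, analysis, default_cohort):
        sc, _, _ = analysis
        labels = cluster_taxa(sc)
        red = ["Porphyromonas_endodontalis", "Tannerella_forsythia"]
        comm = ["Rothia_mucilaginosa", "Streptococcus_mutans"]
        assert {labels[t] for t in red} == {"III"}
        assert all(labels[t] != "III" for t in comm)

    def test_commensals_selected_as_uncorrelated(self, analysis):
        sc, _, _ = analysis
        selected = set(select_commensal(sc))
        assert {"Rothia_mucilaginosa", "Streptococcus_mutans"} <= selected
        assert "Porphyromonas_endodontalis" not in selected
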