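import math

import numpy as np
import pytest

import oracles
from svaduplicon import synthetic_genome as sg
from svaduplicon.core_model import MultipleAlignment
from svaduplicon.recombination_phylo import (
    DistanceMatrix,
    bootstrap_support,
    group_monophyletic,
    k2p_distance,
    k2p_matrix,
    locate_recombination_interval,
    nj_tree,
    partition_diagnostic_sites,
    rf_distance,
    segment_concordance_test,
    split_tree_test,
    tree_from_nested,
)


class TestK2P:
    def test_identical(self):
        d, P, Q = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (d, P, Q) == (0.0, 0.0, 0.0)

    def test_single_transition(self):
        d, P, Q = k2p_distance("AAAA", "AGAA")
        assert (P, Q) == (0.25, 0.0)
        assert d == pytest.approx(-0.5 * math.log(0.5), abs=1e-5)
        assert d == pytest.approx(0.34657, abs=1e-5)

    def test_single_transversion(self):
        d, P, Q = k2p_distance("AAAA", "ACAA")
        assert (P, Q) == (0.0, 0.25)
        assert d == pytest.approx(-0.5 * math.log(0.75) - 0.25 * math.log(0.5), abs=1e-9)
        assert d == pytest.approx(0.31713, abs=1e-5)

    def test_gap_columns_excluded(self):
        d0 = k2p_distance("AAGA", "AAAA")[0]
        d1 = k2p_distance("A-AGA", "ACAAA")[0]
        assert d0 == d1

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturation"):
            k2p_distance("AAAA", "GGGG")

    def test_closed_form_agreement_random(self, rng):
        for _ in range(500):
            n = int(rng.integers(50, 300))
            a = sg.random_dna(rng, n)
            b, _ = sg.mutate_sequence(a, float(rng.uniform(0, 0.15)), 2.0, rng)
            d, P, Q = k2p_distance(a, b)
            de, Pe, Qe = oracles.k2p_closed_form(a, b)
            assert abs(d - de) <= 1e-12
            assert d >= 0
            assert (d == 0) == (P == 0 and Q == 0)


def _dm(taxa, dd):
    n = len(taxa)
    m = np.zeros((n, n))
    for (i, j), v in dd.items():
        m[i, j] = m[j, i] = v
    return DistanceMatrix(taxa=taxa, d=m, P=np.zeros((n, n)), Q=np.zeros((n, n)))


class TestNJ:
    def test_two_taxa(self):
        t = nj_tree(_dm(["A", "B"], {(0, 1): 0.3}))
        edges = list(t.edges())
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(0.3)

    def test_three_taxa_star(self):
        t = nj_tree(_dm(["A", "B", "C"], {(0, 1): 2, (0, 2): 2, (1, 2): 2}))
        lengths = sorted(ln for _, _, ln in t.edges())
        assert lengths == pytest.approx([1.0, 1.0, 1.0])

    def test_additive_four_taxon(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> distances below
        dd = {(0, 1): 3, (0, 2): 5, (0, 3): 3, (1, 2): 6, (1, 3): 4, (2, 3): 4}
        t = nj_tree(_dm(["A", "B", "C", "D"], dd))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        lengths = {}
        for u, v, ln in t.edges():
            leaf_u = t.leaf_of.get(u)
            leaf_v = t.leaf_of.get(v)
            name = leaf_u or leaf_v
            if name is not None and (leaf_u is None) != (leaf_v is None):
                lengths[name] = ln
            elif leaf_u is None and leaf_v is None:
                lengths["internal"] = ln
        assert lengths == pytest.approx(
            {"A": 1, "B": 2, "C": 3, "D": 1, "internal": 1}
        )

    def test_additive_recovery_100_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_leaves = int(rng.integers(6, 11))
            taxa = [f"t{i}" for i in range(n_leaves)]
            nested = sg.make_random_tree(taxa, rng, (0.05, 0.5))
            dists = sg.tree_path_distances(nested)
            dd = {}
            for i in range(n_leaves):
                for j in range(i + 1, n_leaves):
                    dd[(i, j)] = dists[tuple(sorted((taxa[i], taxa[j])))]
            recovered = nj_tree(_dm(taxa, dd))
            truth = tree_from_nested(nested)
            assert rf_distance(recovered, truth) == 0

    def test_single_taxon_error(self):
        with pytest.raises(ValueError):
            nj_tree(_dm(["A"], {}))


class TestRF:
    def test_identical_zero(self):
        dd = {(0, 1): 3, (0, 2): 5, (0, 3): 3, (1, 2): 6, (1, 3): 4, (2, 3): 4}
        t1 = nj_tree(_dm(["A", "B", "C", "D"], dd))
        t2 = nj_tree(_dm(["A", "B", "C", "D"], dd))
        assert rf_distance(t1, t2) == 0

    def test_conflicting_quartets(self):
        ab_cd = {(0, 1): 2, (2, 3): 2, (0, 2): 4, (0, 3): 4, (1, 2): 4, (1, 3): 4}
        ac_bd = {(0, 2): 2, (1, 3): 2, (0, 1): 4, (0, 3): 4, (1, 2): 4, (2, 3): 4}
        t1 = nj_tree(_dm(["A", "B", "C", "D"], ab_cd))
        t2 = nj_tree(_dm(["A", "B", "C", "D"], ac_bd))
        assert rf_distance(t1, t2) == 2

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(200):
            t1 = tree_from_nested(sg.make_random_tree(taxa, rng))
            t2 = tree_from_nested(sg.make_random_tree(taxa, rng))
            assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_leaf_set_mismatch(self):
        t1 = tree_from_nested(sg.make_random_tree(["a", "b", "c", "d"], np.random.default_rng(0)))
        t2 = tree_from_nested(sg.make_random_tree(["a", "b", "c", "e"], np.random.default_rng(0)))
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestBootstrap:
    def test_identical_sequences_degenerate(self):
        rows = {f"t{i}": "ACGTACGTAC" for i in range(4)}
        aln = MultipleAlignment(rows, {r: "g" for r in rows}, "t0")
        tree = bootstrap_support(aln, n_replicates=10, seed=0)
        assert tree.supports == {}

    def test_planted_clades_high_support(self, rng):
        base = sg.random_dna(rng, 400)
        rowsA, rowsB = {}, {}
        a_state = {}
        diag_cols = list(range(0, 400, 20))[:20]
        for j in diag_cols:
            a_state[j] = "A" if base[j] != "A" else "G"
        for i in range(4):
            sa = list(base)
            sb = list(base)
            for j in diag_cols:
                sa[j] = a_state[j]
            # a couple of private tip mutations for resolution
            for j in rng.integers(0, 400, 3):
                sa[j] = "C" if sa[j] != "C" else "T"
                sb[j] = "G" if sb[j] != "G" else "A"
            rowsA[f"A{i}"] = "".join(sa)
            rowsB[f"B{i}"] = "".join(sb)
        rows = {**rowsA, **rowsB}
        aln = MultipleAlignment(rows, {r: "g" for r in rows}, "A0")
        tree = bootstrap_support(aln, n_replicates=1000, seed=3)
        central = frozenset({"B0", "B1", "B2", "B3"})
        assert central in tree.supports
        assert tree.supports[central] >= 99

    def test_default_replicates_is_10000(self):
        import inspect

        sig = inspect.signature(bootstrap_support)
        assert sig.parameters["n_replicates"].default == 10_000

    def test_fixed_seed_reproducible(self, rng):
        aln, _ = sg.simulate_split_alignment(seed=5, recombinant=False, seg_len=150)
        t1 = bootstrap_support(aln, n_replicates=50, seed=9)
        t2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert t1.supports == t2.supports


def _toy_alignment():
    #           0123456789
    out_row = "AAAAAAAAAA"
    rows = {
        "A1": "CAAAAAAGAA",  # col0 A-specific, col7 shared-derived
        "A2": "CAAAAAAGAA",
        "B1": "AAAAAAAGAA",
        "B2": "AAAATAAAAA",  # col4 private (uninformative); col7 ancestral
        "OUT": out_row,
    }
    groups = {"A1": "ga", "A2": "ga", "B1": "gb", "B2": "gb", "OUT": "o"}
    return MultipleAlignment(rows, groups, "OUT")


class TestSitePartition:
    def test_hand_enumeration(self):
        part = partition_diagnostic_sites(_toy_alignment())
        assert part.column_classes[0] == "ga-specific"
        assert part.column_classes[7] == "shared-derived"
        assert part.column_classes[4] == "uninformative"
        assert part.count("ga-specific") == 1
        assert part.count("shared-derived") == 1

    def test_outgroup_identical_all_uninformative(self):
        rows = {"A1": "ACGT", "A2": "ACGT", "B1": "ACGT", "B2": "ACGT", "OUT": "ACGT"}
        groups = {"A1": "a", "A2": "a", "B1": "b", "B2": "b", "OUT": "o"}
        part = partition_diagnostic_sites(MultipleAlignment(rows, groups, "OUT"))
        assert set(part.column_classes) == {"uninformative"}

    def test_outgroup_gap_skipped(self):
        rows = {"A1": "CACG", "A2": "CACG", "B1": "AACG", "B2": "AACG", "OUT": "-ACG"}
        groups = {"A1": "a", "A2": "a", "B1": "b", "B2": "b", "OUT": "o"}
        part = partition_diagnostic_sites(MultipleAlignment(rows, groups, "OUT"))
        assert part.column_classes[0] == "skipped"
        assert part.n_skipped == 1

    def test_simulated_recombinant_has_expected_structure(self):
        aln, truth = sg.simulate_split_alignment(seed=21, recombinant=True)
        part = partition_diagnostic_sites(aln)
        spec = [j for j, c in enumerate(part.column_classes) if c == "chr16-specific"]
        shared = [j for j, c in enumerate(part.column_classes) if c == "shared-derived"]
        assert spec and shared
        # group-specific substitutions never occur on the shared 3' side
        assert max(spec) < truth["switch"]
        # the bulk of shared-derived signal sits on the 3' side (stem
        # homoplasy can produce rare early columns; bracketing ignores them)
        assert sum(1 for j in shared if j >= truth["switch"]) > 0.8 * len(shared)
        res = locate_recombination_interval(part, aln, group="chr16")
        assert res.found
        assert res.start < truth["switch"] <= res.end


class TestRecombinationInterval:
    def _planted(self, last_spec, first_shared, length=500):
        out = "A" * length
        a = list(out)
        b = list(out)
        a[last_spec] = "C"  # both A rows share it -> A-specific
        shared = first_shared
        rows = {
            "A1": "".join(a),
            "A2": "".join(a),
            "B1": out,
            "B2": out,
            "OUT": out,
        }
        for rid in ("A1", "A2", "B1"):  # B2 stays ancestral -> informative
            s = list(rows[rid])
            s[shared] = "G"
            rows[rid] = "".join(s)
        groups = {"A1": "ga", "A2": "ga", "B1": "gb", "B2": "gb", "OUT": "o"}
        return MultipleAlignment(rows, groups, "OUT")

    def test_length_306_scenario(self):
        aln = self._planted(120, 426)
        part = partition_diagnostic_sites(aln)
        res = locate_recombination_interval(part, aln, group="ga")
        assert res.found
        assert (res.start, res.end, res.length) == (120, 426, 306)

    def test_adjacent_sites_minimal_interval(self):
        aln = self._planted(100, 101)
        res = locate_recombination_interval(partition_diagnostic_sites(aln), aln)
        assert res.found and res.length == 1

    def test_no_interval_result(self):
        rows = {"A1": "ACGT", "A2": "ACGT", "B1": "ACGT", "B2": "ACGT", "OUT": "ACGT"}
        groups = {"A1": "a", "A2": "a", "B1": "b", "B2": "b", "OUT": "o"}
        aln = MultipleAlignment(rows, groups, "OUT")
        res = locate_recombination_interval(partition_diagnostic_sites(aln), aln)
        assert not res.found


class TestSplitTreeTest:
    def test_non_recombinant_concordant(self):
        aln, truth = sg.simulate_split_alignment(seed=31, recombinant=False)
        res = split_tree_test(aln, truth["switch"])
        assert res.verdict == "concordant"
        for g, (m5, m3) in res.monophyly.items():
            assert m5 and m3

    def test_recombinant_discordant(self):
        aln, truth = sg.simulate_split_alignment(seed=31, recombinant=True)
        res = split_tree_test(aln, truth["switch"])
        assert res.verdict == "discordant"

    def test_identical_halves_concordant_rf0(self):
        aln, _ = sg.simulate_split_alignment(seed=8, recombinant=False, seg_len=300)
        half = {rid: s[:300] + s[:300] for rid, s in aln.rows.items()}
        doubled = MultipleAlignment(half, aln.groups, "OUT")
        res = split_tree_test(doubled, 300)
        assert res.verdict == "concordant"
        assert res.rf == 0

    def test_split_point_bounds(self):
        aln, _ = sg.simulate_split_alignment(seed=8, recombinant=False)
        with pytest.raises(ValueError, match="split_point"):
            split_tree_test(aln, 0)

    def test_segment_too_short(self):
        aln, _ = sg.simulate_split_alignment(seed=8, recombinant=False)
        with pytest.raises(ValueError, match="too short"):
            split_tree_test(aln, 2)


class TestSegmentConcordance:
    def test_all_one_tree_not_supported(self):
        ref, _ = sg.simulate_split_alignment(seed=41, recombinant=False, seg_len=400)
        segs = [
            sg.simulate_split_alignment(seed=42, recombinant=False, seg_len=300)[0],
            sg.simulate_split_alignment(seed=43, recombinant=False, seg_len=300)[0],
        ]
        res = segment_concordance_test(ref, segs)
        assert res["overall"] == "gene conversion not supported"

    def test_swapped_segment_flagged(self):
        ref, _ = sg.simulate_split_alignment(seed=44, recombinant=False, seg_len=400)
        # a segment evolved with mixed clades has a different monophyly pattern
        bad, _ = sg.simulate_split_alignment(seed=45, recombinant=True, seg_len=10)
        bad = bad.subset_columns(range(10, 20))  # keep only the mixed-tree part
        res = segment_concordance_test(ref, [bad])
        # single-segment control warns
        assert res["segments"][0]["verdict"] == "discordant"

    def test_single_segment_warns(self):
        ref, _ = sg.simulate_split_alignment(seed=46, recombinant=False, seg_len=300)
        seg, _ = sg.simulate_split_alignment(seed=47, recombinant=False, seg_len=300)
        with pytest.warns(UserWarning, match="single-segment"):
            segment_concordance_test(ref, [seg])

    def test_taxa_mismatch_error(self):
        ref, _ = sg.simulate_split_alignment(seed=48, recombinant=False, n_per_group=3)
        seg, _ = sg.simulate_split_alignment(seed=49, recombinant=False, n_per_group=4)
        with pytest.raises(ValueError, match="taxa"):
            segment_concordance_test(ref, [seg])


class TestMonophyly:
    def test_monophyletic_group(self):
        aln, _ = sg.simulate_split_alignment(seed=51, recombinant=False)
        t = nj_tree(k2p_matrix(aln))
        a_members = {r for r, g in aln.groups.items() if g == "chr16"}
        assert group_monophyletic(t, a_members)

    def test_singleton_trivially_monophyletic(self):
        aln, _ = sg.simulate_split_alignment(seed=51, recombinant=True)
        t = nj_tree(k2p_matrix(aln))
        assert group_monophyletic(t, {"A1"})
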