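import json

import numpy as np
import pytest

from svaduplicon import synthetic_genome as sg
from svaduplicon.core_model import revcomp
from svaduplicon.junction_tsd import detect_tsd
from svaduplicon.core_model import Interval


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestElementLibrary:
    def test_zero_diagnostic_sites(self):
        lib = sg.make_element_library(seed=5, n_subfamilies=2, n_diagnostic_sites=0)
        a, b = lib.subfamilies()
        assert lib.consensus(a) == lib.consensus(b)
        assert lib.diagnostic_sites[(a, b)] == []

    def test_diagnostic_site_count_is_exact(self):
        lib = sg.make_element_library(seed=5, n_subfamilies=2, n_diagnostic_sites=20)
        a, b = lib.subfamilies()
        vntr = lib.domain(a, "VNTR")
        diffs = [
            i
            for i, (x, y) in enumerate(zip(lib.consensus(a), lib.consensus(b)))
            if x != y
        ]
        non_vntr_diffs = [i for i in diffs if not vntr[0] <= i < vntr[1]]
        assert len(non_vntr_diffs) == 20
        assert diffs == non_vntr_diffs  # none inside the VNTR
        assert len(lib.diagnostic_sites[(a, b)]) == 20

    def test_hexamer_domain_content(self):
        lib = sg.make_element_library(seed=5, hexamer_copies=4)
        a = lib.subfamilies()[0]
        h0, h1 = lib.domain(a, "hexamer")
        assert lib.consensus("base")[h0:h1] == sg.HEXAMER_UNIT * 4

    def test_domains_tile(self, library):
        for name in library.entries:
            spans = sorted(library.entries[name]["domains"].values())
            assert spans[0][0] == 0
            assert spans[-1][1] == len(library.entries[name]["seq"])
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 == s2

    def test_too_many_sites_error(self):
        with pytest.raises(ValueError, match="non-VNTR"):
            sg.make_element_library(seed=5, n_diagnostic_sites=10_000)

    def test_needs_two_subfamilies(self):
        with pytest.raises(ValueError):
            sg.make_element_library(seed=5, n_subfamilies=1)


class TestMutateSequence:
    def test_mu_zero_identity(self, rng):
        seq = sg.random_dna(rng, 500)
        out, pos = sg.mutate_sequence(seq, 0.0, 2.0, rng)
        assert out == seq and pos == []

    def test_substitution_count_distribution(self, rng):
        seq = sg.random_dna(rng, 20_000)
        out, pos = sg.mutate_sequence(seq, 0.02, 2.0, rng)
        n, p = 20_000, 0.02
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(len(pos) - n * p) <= 3 * sigma
        assert _hamming(seq, out) == len(pos)

    def test_transition_bias(self, rng):
        seq = "A" * 50_000
        out, pos = sg.mutate_sequence(seq, 0.1, 2.0, rng)
        ts = sum(1 for i in pos if out[i] == "G")
        # expect kappa/(kappa+2) = 1/2 transitions
        assert abs(ts / len(pos) - 0.5) < 0.05


class TestPlantL1Insertion:
    def test_tsd_duplicated_exactly(self, library, rng):
        genome = {"c": sg.random_dna(rng, 5000)}
        g2, ev, _ = sg.plant_l1_insertion(
            genome, library, ("c", 2500), seed=3, tsd_length=12, tsd_mismatches=0
        )
        lt, rt = ev["features"]["tsd_left"], ev["features"]["tsd_right"]
        assert lt["seq"] == rt["seq"]
        assert len(lt["seq"]) == 12
        seq = g2["c"]
        assert seq[lt["start"] : lt["end"]] == seq[rt["start"] : rt["end"]]

    def test_transduction_order(self, library, rng):
        genome = {"c": sg.random_dna(rng, 5000)}
        g2, ev, _ = sg.plant_l1_insertion(
            genome, library, ("c", 2500), with_transduction=True, seed=3,
            subfamily=library.subfamilies()[0], tsd_length=10, polya_length=15,
        )
        f = ev["features"]
        insert = f["insert"]["seq"]
        assert insert.endswith("A" * 15)
        td = library.entries[ev["subfamily"]]["transduction"]
        assert insert[: -15][-len(td):] == td
        sub = library.consensus(ev["subfamily"])
        assert insert[: len(sub)] == sub  # SINE-R 3' end precedes the TD

    def test_out_of_bounds_error(self, library):
        with pytest.raises(ValueError, match="out of bounds"):
            sg.plant_l1_insertion({"c": "ACGT" * 100}, library, ("c", 2000))

    def test_100_seeded_insertions_recovered_exactly(self, library):
        """detect_tsd recovers every planted TSD interval at mu=0."""
        master = np.random.default_rng(2024)
        for k in range(100):
            genome = {"c": sg.random_dna(master, 3000)}
            tsd_len = int(master.integers(12, 17))
            g2, ev, _ = sg.plant_l1_insertion(
                genome, library, ("c", 1500), seed=int(master.integers(2**31)),
                tsd_length=tsd_len,
            )
            f = ev["features"]
            span = Interval("c", f["insert"]["start"], f["insert"]["end"])
            call = detect_tsd(g2, span, max_window=16, min_len=5)
            assert call is not None, f"locus {k}: no TSD found"
            assert (call.left.start, call.left.end) == (f["tsd_left"]["start"], f["tsd_left"]["end"])
            assert (call.right.start, call.right.end) == (f["tsd_right"]["start"], f["tsd_right"]["end"])


class TestPlantDuplicationBlock:
    def test_mu_zero_copy_identical(self, rng):
        genome = {"anc": sg.random_dna(rng, 20_000), "c": sg.random_dna(rng, 10_000)}
        g2, ev = sg.plant_duplication_block(
            genome, ("anc", 0), 2_000, 8_000, ("c", 5_000), mu=0.0, seed=1
        )
        copy = ev["features"]["copy"]["seq"]
        expect = genome["anc"][2_000 + ev["mh5"] : 8_000 - ev["mh3"]]
        assert copy == expect
        assert ev["donor_seq"] == genome["anc"][2_000:8_000]

    def test_substitution_distribution(self, rng):
        genome = {"anc": sg.random_dna(rng, 25_000), "c": sg.random_dna(rng, 10_000)}
        g2, ev = sg.plant_duplication_block(
            genome, ("anc", 0), 1_000, 21_000, ("c", 5_000), mu=0.02, seed=1,
            kappa=2.0,
        )
        n, p = 20_000, 0.02
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(ev["n_substitutions"] - n * p) <= 3 * sigma

    def test_short_interval_error(self, rng):
        genome = {"anc": sg.random_dna(rng, 5_000), "c": sg.random_dna(rng, 5_000)}
        with pytest.raises(ValueError, match="1 kb"):
            sg.plant_duplication_block(genome, ("anc", 0), 100, 600, ("c", 2_000))

    def test_microhomology_junction_bases(self, rng):
        genome = {"anc": sg.random_dna(rng, 10_000), "c": sg.random_dna(rng, 10_000)}
        g2, ev = sg.plant_duplication_block(
            genome, ("anc", 0), 1_000, 5_000, ("c", 5_000), seed=7
        )
        seq = g2["c"]
        copy_start = ev["features"]["copy"]["start"]
        # flank suffix equals the donor copy prefix (the realized microhomology)
        assert seq[copy_start - ev["mh5"] : copy_start] == ev["junction5_bases"]


class TestPlantCircularIntegration:
    @pytest.fixture()
    def planted(self, library, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        g2, ev, annots = sg.plant_circular_integration(
            genome, library,
            donor_locus=("c", 18_000, 24_000),
            target_site=("c", 5_000),
            seed=9, tsd_length=12,
        )
        return genome, g2, ev, annots

    def test_outer_tsd_matches_preintegration_site(self, planted):
        genome, g2, ev, _ = planted
        ol = ev["features"]["outer_tsd_left"]
        assert ol["seq"] == genome["c"][5_000 : 5_012]
        assert ol["seq"] == ev["features"]["outer_tsd_right"]["seq"]

    def test_inner_tsd_matches_donor_cut(self, planted):
        genome, g2, ev, _ = planted
        il = ev["features"]["inner_tsd_left"]
        cut = 18_000 + 3_000  # donor midpoint
        assert il["seq"] == genome["c"][cut : cut + 12]
        assert il["seq"] == ev["features"]["inner_tsd_right"]["seq"]

    def test_switch_points_coincide(self, planted):
        _, _, ev, _ = planted
        assert ev["switch_point_5p"] == ev["switch_point_3p"]

    def test_chimeras_are_reciprocal(self, planted, library):
        _, g2, ev, _ = planted
        s = ev["switch_point_5p"]
        x = library.consensus(ev["outer_subfamily"])
        y = library.consensus(ev["inner_subfamily"])
        assert ev["features"]["chimera_5p"]["seq"] == x[:s] + y[s:]
        assert ev["features"]["chimera_3p"]["seq"] == y[:s] + x[s:]

    def test_end_to_end_signature_positive(self, planted, library):
        from svaduplicon.chimera_circular import (
            detect_chimera,
            detect_circular_signature,
        )

        _, g2, ev, annots = planted
        chimeras = detect_chimera(annots, g2, library)
        assert len(chimeras) == 2
        call = detect_circular_signature(g2, chimeras)
        assert call.verdict == "positive"

    def test_unknown_subfamily_error(self, library, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        with pytest.raises(ValueError, match="donor lacks"):
            sg.plant_circular_integration(
                genome, library, donor_locus=("c", 18_000, 24_000),
                target_site=("c", 5_000), inner_subfamily="SVA_Z",
            )


class TestPlantDirectRepeatSD:
    def test_identity_one_flanks_identical(self, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        g2, ev = sg.plant_direct_repeat_sd(
            genome, sg.random_dna(rng, 8_000), flank_length=4_000, identity=1.0,
            seed=2, target_site=("c", 10_000),
        )
        assert ev["features"]["left_repeat"]["seq"] == ev["features"]["right_repeat"]["seq"]
        assert len(ev["features"]["left_repeat"]["seq"]) == 4_000

    def test_identity_mismatch_distribution(self, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        g2, ev = sg.plant_direct_repeat_sd(
            genome, sg.random_dna(rng, 8_000), flank_length=4_000, identity=0.95,
            seed=2, target_site=("c", 10_000),
        )
        mism = _hamming(
            ev["features"]["left_repeat"]["seq"], ev["features"]["right_repeat"]["seq"]
        )
        n, p = 4_000, 0.05
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(mism - n * p) <= 3 * sigma

    def test_below_sd_identity_error(self, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        with pytest.raises(ValueError, match="SD definition"):
            sg.plant_direct_repeat_sd(
                genome, "ACGT" * 500, identity=0.8, target_site=("c", 10_000)
            )

    def test_never_inverted_orientation(self, rng):
        genome = {"c": sg.random_dna(rng, 30_000)}
        g2, ev = sg.plant_direct_repeat_sd(
            genome, sg.random_dna(rng, 5_000), flank_length=4_000, identity=0.98,
            seed=2, target_site=("c", 10_000),
        )
        left = ev["features"]["left_repeat"]["seq"]
        right = ev["features"]["right_repeat"]["seq"]
        assert _hamming(left, right) < 0.1 * 4_000
        assert _hamming(left, revcomp(right)) > 0.5 * 4_000


class TestComposedSimulation:
    def test_determinism_byte_identical(self, tmp_path, demo_sim):
        import filecmp

        res2 = sg.simulate(demo_sim.config)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sg.write_result(demo_sim, d1)
        sg.write_result(res2, d2)
        for name in ("genome.fasta", "truth.json", "annotations.out",
                     "annotations.bed", "library.json", "config.txt"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_audit_self_consistency(self, demo_sim):
        sg.audit_ledger(demo_sim.contigs, demo_sim.ledger)

    def test_audit_detects_corruption(self, demo_sim):
        contigs = dict(demo_sim.contigs)
        ev = demo_sim.ledger.events[0]
        f = next(iter(ev["features"].values()))
        s = contigs[f["contig"]]
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[f["start"]]]
        contigs[f["contig"]] = s[: f["start"]] + flip + s[f["start"] + 1 :]
        with pytest.raises(AssertionError):
            sg.audit_ledger(contigs, demo_sim.ledger)

    def test_all_coordinates_inside_genome(self, demo_sim):
        for ev in demo_sim.ledger.events:
            for f in ev["features"].values():
                assert 0 <= f["start"] <= f["end"] <= len(demo_sim.contigs[f["contig"]])

    def test_config_validation(self):
        with pytest.raises(ValueError, match="mu"):
            sg.SimulationConfig(seed=1, mu=0.5)
        with pytest.raises(ValueError, match="flank"):
            sg.SimulationConfig(seed=1, direct_repeat_flank_length=500)

    def test_ledger_json_roundtrip(self, tmp_path, demo_sim):
        p = tmp_path / "truth.json"
        demo_sim.ledger.to_json(p)
        back = sg.TruthLedger.from_json(p)
        assert back.events == demo_sim.ledger.events


class TestTreeSimulation:
    def test_evolve_zero_branch_lengths(self, rng):
        tree = sg.node([(sg.leaf("a"), 0.0), (sg.leaf("b"), 0.0)])
        seqs = sg.evolve_on_tree(tree, "ACGT" * 25, rng)
        assert seqs["a"] == seqs["b"] == "ACGT" * 25

    def test_path_distances_additive(self, rng):
        tree = sg.node([
            (sg.node([(sg.leaf("A"), 1.0), (sg.leaf("B"), 2.0)]), 1.0),
            (sg.node([(sg.leaf("C"), 3.0), (sg.leaf("D"), 1.0)]), 0.0),
        ])
        d = sg.tree_path_distances(tree)
        assert d[("A", "B")] == 3.0
        assert d[("A", "C")] == 5.0
        assert d[("A", "D")] == 3.0
        assert d[("B", "C")] == 6.0

    def test_random_tree_leaves(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        tree = sg.make_random_tree(taxa, rng)
        assert sorted(sg.tree_leaves(tree)) == sorted(taxa)
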