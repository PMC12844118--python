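import math

import dendropy
import numpy as np
import pytest

from ectoconv.conversion import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    classify_quartet_topology,
    delineate_tracts,
    detect_split,
    distance_matrix_from_msa,
    jc_distance,
    nj_tree,
    star_msa,
    window_contrast_test,
)
from ectoconv.homology import Alignment, global_align


class TestJcDistance:
    def test_identical(self):
        d, sat = jc_distance("ACGT" * 25, "ACGT" * 25)
        assert d == 0.0 and not sat

    def test_ten_percent_divergence_closed_form(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 100
        d, sat = jc_distance(a, b)
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), rel=1e-9)
        assert not sat

    def test_saturation_flagged(self):
        a = "A" * 20 + "C" * 80
        b = "A" * 20 + "G" * 80
        _, sat = jc_distance(a, b)
        assert sat

    def test_gap_columns_ignored(self):
        d, _ = jc_distance("AC-T", "AC-T")
        assert d == 0.0
        with pytest.raises(ValueError):
            jc_distance("--", "AA")


def _random_tree_matrix(rng, n_taxa):
    """Random binary tree with positive branch lengths -> additive matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=ns, rng=rng,
    )
    for e in tree.edges():
        if e.length is not None:
            e.length = 0.05 + rng.random() * 0.5
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in ns)
    idx = {t.label: t for t in ns}
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[i, j] = d[j, i] = pdm.distance(idx[a], idx[b])
    return tree, labels, d


def _rf_zero(tree_a: dendropy.Tree, newick_b: str, ns) -> bool:
    tb = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=ns, preserve_underscores=True)
    for t in (tree_a, tb):
        t.is_rooted = False
        t.update_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(tree_a, tb) == 0


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]])))

    def test_three_taxa_star(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float),
        )
        tree = nj_tree(dm)
        assert tree.leaf_labels() == {"a", "b", "c"}

    def test_additive_four_taxon_recovery(self):
        # ((a:1,b:2):1,(c:1,d:1)); additive distances
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 3, 3, 3],
                [3, 0, 4, 4],
                [3, 4, 0, 2],
                [3, 4, 2, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        t = tree.rooted_at("a")
        assert t.is_clade(["c", "d"])

    @pytest.mark.parametrize("trial", range(30))
    def test_additive_matrices_recover_topology(self, trial):
        import random

        rng = random.Random(trial)
        n = rng.choice([4, 5, 6])
        true_tree, labels, d = _random_tree_matrix(rng, n)
        out = nj_tree(DistanceMatrix(labels, d))
        assert _rf_zero(true_tree, out.newick, true_tree.taxon_namespace)

    def test_deterministic_output(self):
        d = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], float
        )
        t1 = nj_tree(DistanceMatrix(list("abcd"), d.copy()))
        t2 = nj_tree(DistanceMatrix(list("abcd"), d.copy()))
        assert t1.newick == t2.newick


def _tree(newick):
    return PhyloTree.from_newick(newick)


class TestTopologyClassification:
    A = ("A1", "A2")
    B = ("B1", "B2")

    def test_both_pairs_sisters(self):
        t = _tree("((A1:1,A2:1):1,(B1:1,B2:1):1,O:3);")
        verdict, _ = classify_quartet_topology(t, self.A, self.B, "O")
        assert verdict == "converted_in_both"

    def test_orthologous_pairing_is_none(self):
        t = _tree("((A1:1,B1:1):1,(A2:1,B2:1):1,O:3);")
        verdict, _ = classify_quartet_topology(t, self.A, self.B, "O")
        assert verdict == "none"

    def test_single_lineage_conversion(self):
        t = _tree("(((A1:1,A2:1):1,B1:2):1,B2:2,O:3);")
        verdict, _ = classify_quartet_topology(
            t, self.A, self.B, "O", paralog_identity_a=0.942
        )
        assert verdict == "converted_in_A"

    def test_low_identity_downgrades_to_ambiguous(self):
        t = _tree("(((A1:1,A2:1):1,B1:2):1,B2:2,O:3);")
        verdict, reason = classify_quartet_topology(
            t, self.A, self.B, "O", paralog_identity_a=0.80
        )
        assert verdict == "ambiguous"
        assert "below conversion floor" in reason

    def test_species_label_swap_maps_verdict(self):
        t = _tree("(((A1:1,A2:1):1,B1:2):1,B2:2,O:3);")
        v_ab, _ = classify_quartet_topology(t, self.A, self.B, "O")
        v_ba, _ = classify_quartet_topology(t, self.B, self.A, "O")
        assert v_ab == "converted_in_A"
        assert v_ba == "converted_in_B"

    def test_invariant_to_label_order_within_species(self):
        t = _tree("((A1:1,A2:1):1,(B1:1,B2:1):1,O:3);")
        for a in (("A1", "A2"), ("A2", "A1")):
            for b in (("B1", "B2"), ("B2", "B1")):
                v, _ = classify_quartet_topology(t, a, b, "O")
                assert v == "converted_in_both"

    def test_leaf_mismatch_rejected(self):
        t = _tree("((A1:1,A2:1):1,(B1:1,B2:1):1,O:3);")
        with pytest.raises(ValueError):
            classify_quartet_topology(t, ("A1", "AX"), self.B, "O")

    def test_unrooted_orthologous_split(self):
        t = _tree("((A1:1,B1:1):1,A2:1,B2:1);")
        v, _ = classify_quartet_topology(t, self.A, self.B, None)
        assert v == "none"


def _mutseq(rng, seq, divergence):
    out = list(seq)
    k = rng.binomial(len(seq), divergence)
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestBootstrap:
    def _msa(self, seed=0):
        rng = np.random.default_rng(seed)
        anc = "".join(rng.choice(list("ACGT"), 300))
        a_branch = _mutseq(rng, anc, 0.04)
        b_branch = _mutseq(rng, anc, 0.04)
        seqs = {
            "A1": a_branch,
            "A2": a_branch,  # homogenized paralogs in species A
            "B1": _mutseq(rng, b_branch, 0.03),
            "B2": _mutseq(rng, b_branch, 0.03),
            "O": _mutseq(rng, anc, 0.20),
        }
        return star_msa(seqs, "A1")

    def test_strong_signal_high_support(self):
        msa = self._msa()
        tree = nj_tree(distance_matrix_from_msa(msa))
        verdict, _ = classify_quartet_topology(tree, ("A1", "A2"), ("B1", "B2"), "O")
        support = bootstrap_support(msa, verdict, ("A1", "A2"), ("B1", "B2"), "O",
                                    n_reps=100, seed=0)
        assert support >= 0.95

    def test_all_identical_support_undefined_or_ambiguous(self):
        msa = {k: "ACGTACGTACGT" * 5 for k in ("A1", "A2", "B1", "B2", "O")}
        tree = nj_tree(distance_matrix_from_msa(msa))
        verdict, _ = classify_quartet_topology(tree, ("A1", "A2"), ("B1", "B2"), "O")
        assert verdict == "ambiguous"

    def test_seed_determinism(self):
        msa = self._msa()
        args = (msa, "converted_in_both", ("A1", "A2"), ("B1", "B2"), "O")
        assert bootstrap_support(*args, n_reps=30, seed=7) == bootstrap_support(
            *args, n_reps=30, seed=7
        )

    def test_too_short_alignment_undefined(self):
        msa = {k: "ACGTACG" for k in ("A1", "A2", "B1", "B2")}
        assert bootstrap_support(msa, "none", ("A1", "A2"), ("B1", "B2"), None) is None


class TestStarMsa:
    def test_columns_equal_and_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), 120))
        seqs = {
            "r": ref,
            "x": _mutseq(rng, ref, 0.1),
            "y": ref[:50] + ref[60:],  # deletion relative to the reference
        }
        msa = star_msa(seqs, "r")
        width = len(msa["r"])
        for label, s in seqs.items():
            assert len(msa[label]) == width
            assert msa[label].replace("-", "") == s


class TestTractDelineation:
    def test_constructed_signal_two_segments(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 1100))
        other = base[:1000] + _mutseq(rng, base[1000:], 0.6)
        aln = Alignment(base, other, 0)
        segs = delineate_tracts(aln)
        classes = [s.seg_class for s in segs]
        assert classes == ["converted", "mutated_flank"]
        assert abs(segs[0].end_col - 1000) <= 25

    def test_fully_identical_single_converted_segment(self):
        s = "ACGT" * 100
        segs = delineate_tracts(Alignment(s, s, 0))
        assert len(segs) == 1
        assert segs[0].seg_class == "converted"
        assert (segs[0].start_col, segs[0].end_col) == (0, 400)

    def test_window_longer_than_alignment(self):
        s = "ACGTACGTAC"
        segs = delineate_tracts(Alignment(s, s, 0), window=50)
        assert len(segs) == 1
        assert segs[0].seg_class == "converted"

    def test_deleted_segment_classified(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 600))
        aligned_a = base
        aligned_b = base[:300] + "-" * 30 + base[330:]
        segs = delineate_tracts(Alignment(aligned_a, aligned_b, 0))
        assert any(s.seg_class == "deleted" for s in segs)

    def test_segments_tile_alignment_without_overlap(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), 900))
        other = (
            _mutseq(rng, base[:150], 0.5)
            + base[150:700]
            + _mutseq(rng, base[700:], 0.4)
        )
        segs = delineate_tracts(Alignment(base, other, 0))
        assert segs[0].start_col == 0
        assert segs[-1].end_col == 900
        for prev, cur in zip(segs, segs[1:]):
            assert prev.end_col == cur.start_col


class TestWindowContrast:
    def test_identical_proportions(self):
        r = window_contrast_test(50, 50, 50, 50)
        assert r.chi2 == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.method == "chi2"

    def test_closed_form_agreement(self):
        r = window_contrast_test(100, 0, 18, 27)
        n = 145
        expected = n * (100 * 27 - 0 * 18) ** 2 / (100 * 45 * 118 * 27)
        assert r.chi2 == pytest.approx(expected, rel=1e-10)

    def test_small_expected_cells_use_fisher(self):
        r = window_contrast_test(3, 1, 1, 3)
        assert r.method == "fisher"

    def test_zero_column_segment_rejected(self):
        with pytest.raises(ValueError):
            window_contrast_test(0, 0, 5, 5)

    def test_exhaustive_small_tables_match_closed_form(self):
        from scipy import stats as ss

        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b == 0 or c + d == 0:
                            continue
                        n = a + b + c + d
                        col1, col2 = a + c, b + d
                        if col1 == 0 or col2 == 0:
                            continue
                        exp = np.outer([a + b, c + d], [col1, col2]) / n
                        if (exp < 5).any():
                            continue
                        r = window_contrast_test(a, b, c, d)
                        closed = n * (a * d - b * c) ** 2 / (
                            (a + b) * (c + d) * col1 * col2
                        )
                        assert r.chi2 == pytest.approx(closed, abs=1e-10)


def _orf(rng, n_codons):
    from ectoconv.evostats import STOP_CODONS

    sense = [c for c in
             ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
             if c not in STOP_CODONS]
    body = "".join(rng.choice(sense) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


class TestDetectSplit:
    def test_identical_target_absent(self):
        rng = np.random.default_rng(0)
        mother = _orf(rng, 300)
        assert detect_split(mother, mother) is None

    def test_two_point_stops_three_daughters(self):
        rng = np.random.default_rng(1)
        mother = _orf(rng, 300)
        target = list(mother)
        for c in (100, 200):
            target[3 * c : 3 * c + 3] = "TAA"
        ev = detect_split(mother, "".join(target))
        assert ev.stop_offsets == [100, 200]
        assert len(ev.daughters) == 3
        assert ev.mode == "point_mutation"
        assert ev.frameshift_indels == []

    def test_frameshift_deletion_reported(self):
        rng = np.random.default_rng(4)
        for attempt in range(20):
            mother = _orf(rng, 300)
            dpos = 3 * 120
            target = mother[:dpos] + mother[dpos + 4 :]
            ev = detect_split(mother, target)
            if ev is not None:
                assert any(l % 3 != 0 for _, l in ev.frameshift_indels)
                assert ev.mode == "frameshift"
                assert min(ev.stop_offsets) >= 119
                return
        pytest.fail("no frameshift split detected in 20 random mothers")

    def test_invalid_mother_rejected(self):
        with pytest.raises(ValueError):
            detect_split("CCCCCCTAA", "CCCCCCTAA")
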