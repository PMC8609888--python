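"""Alignment utilities, NJ, rooting and clade assignment."""

import numpy as np
import pytest

from tollscan.domain_scan import annotate_architecture
from tollscan.phylo import (
    Alignment, CladeAssignment, assign_clades, build_nj_tree, detect_insertion,
    extract_core_columns, gappyout_cutoff, leaf_labels, mask_region,
    nj_tree_from_distances, p_distance_matrix, read_tree, root_with_outgroup,
    trim_gappyout,
)
from tollscan.records import SequenceRecord
from tollscan.synthetic import make_tlr_sequence, simulate_alignment_with_insertion

from conftest import random_binary_tree


def _aln(*rows):
    return Alignment(tuple(rows))


def _splits(tree):
    """Non-trivial unrooted splits as frozensets of the smaller side."""
    all_tips = leaf_labels(tree.seed_node)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = leaf_labels(node)
        if 1 < len(below) < len(all_tips) - 1:
            side = min(below, all_tips - below, key=lambda s: (len(s), sorted(s)))
            out.add(frozenset(side))
    return out


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            _aln(("a", "AC-"), ("b", "AC"))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            _aln(("a", "AC"), ("a", "AC"))

    def test_gap_fractions(self):
        aln = _aln(("a", "A-C"), ("b", "--C"))
        assert aln.gap_fractions().tolist() == [0.5, 1.0, 0.0]


class TestMaskRegion:
    def test_paper_window_removes_six_columns(self):
        aln, _ = simulate_alignment_with_insertion(3, 2, 400, (349, 354), seed=0)
        masked = mask_region(aln, 349, 354)
        assert masked.n_cols == 394

    def test_arithmetic_on_inclusive_range(self):
        aln, _ = simulate_alignment_with_insertion(2, 2, 375, (10, 15), seed=0)
        assert mask_region(aln, 150, 220).n_cols == 304

    def test_first_column(self):
        aln = _aln(("a", "WAC"), ("b", "WGC"))
        masked = mask_region(aln, 1, 1)
        assert masked.rows == (("a", "AC"), ("b", "GC"))

    def test_out_of_range(self):
        aln = _aln(("a", "WAC"),)
        with pytest.raises(ValueError):
            mask_region(aln, 2, 4)

    def test_projection_preserves_column_content(self):
        aln, _ = simulate_alignment_with_insertion(4, 3, 100, (40, 45), seed=1)
        masked = mask_region(aln, 20, 30)
        cols = lambda a: ["".join(seq[c] for _, seq in a.rows) for c in range(a.n_cols)]
        original = cols(aln)
        assert cols(masked) == original[:19] + original[30:]


class TestGappyout:
    def test_gap_free_unchanged(self):
        aln = _aln(("a", "ACDEF"), ("b", "ACDEF"), ("c", "ACDEW"))
        assert trim_gappyout(aln) == aln

    def test_constructed_distribution_matches_scan_oracle(self):
        # 80 clean columns, 20 columns with 90% gaps (10 rows)
        rng = np.random.default_rng(0)
        gappy = set(rng.choice(100, size=20, replace=False))
        rows = []
        for r in range(10):
            row = "".join(
                "-" if (c in gappy and r < 9) else "A" for c in range(100)
            )
            rows.append((f"r{r}", row))
        aln = Alignment(tuple(rows))
        trimmed = trim_gappyout(aln)
        assert trimmed.n_cols == 80
        # independent exhaustive cutoff scan
        fracs = aln.gap_fractions()
        candidates = sorted(set(fracs))
        best, best_jump = candidates[-1], 0.0
        ordered = sorted(fracs)
        for a, b in zip(ordered, ordered[1:]):
            if b - a > best_jump:
                best_jump, best = b - a, a
        assert gappyout_cutoff(fracs) == best

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_rows, n_cols = int(rng.integers(4, 9)), int(rng.integers(5, 40))
            mat = rng.random((n_rows, n_cols)) < rng.uniform(0, 0.6)
            if mat.all(axis=0).all():
                continue
            rows = tuple(
                (f"r{i}", "".join("-" if mat[i, j] else "A" for j in range(n_cols)))
                for i in range(n_rows)
            )
            aln = Alignment(rows)
            fracs = aln.gap_fractions()
            ordered = sorted(fracs)
            jump, cutoff = 0.0, ordered[-1]
            for a, b in zip(ordered, ordered[1:]):
                if b - a > jump:
                    jump, cutoff = b - a, a
            expected_cols = [j for j in range(n_cols) if fracs[j] <= cutoff]
            if not expected_cols:
                continue
            assert trim_gappyout(aln) == aln.take_columns(expected_cols)

    def test_single_fully_gapped_column_removed(self):
        aln = _aln(("a", "AC-EF"), ("b", "AC-EF"), ("c", "AC-EF"))
        assert trim_gappyout(aln).rows[0][1] == "ACEF"

    def test_degenerate_alignment_error(self):
        aln = _aln(("a", "---"), ("b", "---"))
        with pytest.raises(ValueError):
            trim_gappyout(aln)


class TestDetectInsertion:
    def test_carriers_recovered_exactly(self):
        aln, truth = simulate_alignment_with_insertion(10, 5, 400, (349, 354), seed=4)
        calls = detect_insertion(aln, 349, 354)
        assert {sid for sid, v in calls.items() if v} == set(truth["carriers"])

    def test_full_window_true_gapped_false(self):
        aln = _aln(("full", "AAAAAA"), ("gapped", "------"))
        calls = detect_insertion(aln, 1, 6)
        assert calls == {"full": True, "gapped": False}

    def test_no_carriers(self):
        aln, _ = simulate_alignment_with_insertion(0, 5, 100, (40, 45), seed=2)
        assert not any(detect_insertion(aln, 40, 45).values())

    def test_monotone_in_min_nongap(self):
        aln, _ = simulate_alignment_with_insertion(6, 6, 80, (30, 35), seed=3)
        previous = None
        for k in range(0, 8):
            calls = detect_insertion(aln, 30, 35, min_nongap=k)
            if previous is not None:
                for sid in calls:
                    assert previous[sid] or not calls[sid]
            previous = calls


class TestExtractCore:
    def _core_alignment(self, seed=12, n_rows=3):
        rec, truth = make_tlr_sequence("scc", 6, seed=seed)
        rows = tuple((f"r{i}", rec.residues) for i in range(n_rows))
        archs = {f"r{i}": annotate_architecture(
            SequenceRecord(id=f"r{i}", residues=rec.residues, species="sp"))
            for i in range(n_rows)}
        return Alignment(rows), archs

    def test_core_block_extracted(self):
        aln, archs = self._core_alignment()
        core = extract_core_columns(aln, archs)
        arch = archs["r0"]
        proximal = max(h for h in arch.hits_of("LRR") if h.start < arch.tm.start)
        expected = arch.tir.end - proximal.start + 1
        assert core.n_cols == expected

    def test_idempotent_on_core(self):
        aln, archs = self._core_alignment()
        core = extract_core_columns(aln, archs)
        core_archs = {
            sid: annotate_architecture(SequenceRecord(id=sid, residues=seq, species="sp"))
            for sid, seq in core.rows
        }
        assert extract_core_columns(core, core_archs) == core

    def test_missing_tir_error(self):
        aln, archs = self._core_alignment()
        bad = dict(archs)
        import dataclasses

        bad["r0"] = dataclasses.replace(
            bad["r0"], hits=tuple(h for h in bad["r0"].hits if h.kind != "TIR"),
            has_tir=False)
        with pytest.raises(ValueError):
            extract_core_columns(aln, bad)


class TestPDistance:
    def test_pairwise_deletion(self):
        aln = _aln(("a", "AC-T"), ("b", "AG-T"), ("c", "A--A"))
        ids, d = p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(1 / 3)  # ACT vs AGT
        assert d[0, 2] == pytest.approx(1 / 2)  # A,T vs A,A
        assert (d == d.T).all()


class TestNeighborJoining:
    def test_quartet_recovers_generating_split(self):
        # additive distances for ((A,B),(C,D))
        d = np.array([
            [0, 2, 7, 7],
            [2, 0, 7, 7],
            [7, 7, 0, 2],
            [7, 7, 2, 0],
        ], dtype=float)
        tree = nj_tree_from_distances(["A", "B", "C", "D"], d)
        assert _splits(tree) == {frozenset({"A", "B"})} or \
            _splits(tree) == {frozenset({"C", "D"})}

    def test_three_taxa(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree_from_distances(["A", "B", "C"], d)
        assert leaf_labels(tree.seed_node) == {"A", "B", "C"}
        assert _splits(tree) == set()

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree_from_distances(["A", "B"], np.zeros((2, 2)))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8, 10, 12])
    def test_additive_matrix_topology_recovery(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            true_tree, _ = random_binary_tree(n_leaves, rng)
            pdm = true_tree.phylogenetic_distance_matrix()
            taxa = sorted(true_tree.taxon_namespace, key=lambda t: t.label)
            ids = [t.label for t in taxa]
            d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
            nj = nj_tree_from_distances(ids, d)
            assert _splits(nj) == _splits(true_tree)

    def test_build_from_alignment(self):
        aln = _aln(
            ("A", "AAAAAAAAAA"),
            ("B", "AAAAAAAAAC"),
            ("C", "TTTTTTTTTA"),
            ("D", "TTTTTTTTTC"),
        )
        tree = build_nj_tree(aln)
        assert frozenset({"A", "B"}) in _splits(tree) or \
            frozenset({"C", "D"}) in _splits(tree)


class TestRooting:
    def test_single_outgroup_tip(self):
        tree = read_tree("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);", is_path=False)
        rooted = root_with_outgroup(tree, {"A"})
        children = rooted.seed_node.child_nodes()
        sides = [leaf_labels(c) for c in children]
        assert frozenset({"A"}) in sides

    def test_outgroup_cherry(self):
        tree = read_tree("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);", is_path=False)
        rooted = root_with_outgroup(tree, {"A", "B"})
        sides = [leaf_labels(c) for c in rooted.seed_node.child_nodes()]
        assert frozenset({"A", "B"}) in sides

    def test_non_monophyletic_outgroup_error(self):
        tree = read_tree("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);", is_path=False)
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(tree, {"A", "C"})

    def test_missing_tip_error(self):
        tree = read_tree("((A:1,B:1):1,C:1);", is_path=False)
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(tree, {"Z"})


GENE_TREE = (
    "(OG:1,((a1:1,(cn1:1,cn2:1)90:1)85:1,"
    "((b1:1,b2:1)88:1,(g1:1,g2:1)92:1)70:1)99:1);"
)


class TestAssignClades:
    def _rooted(self, newick=GENE_TREE):
        tree = read_tree(newick, is_path=False)
        return root_with_outgroup(tree, {"OG"})

    def test_three_supported_clades_fully_labeled(self):
        asg = assign_clades(
            self._rooted(),
            {"alpha": {"cn1", "cn2"}, "beta": {"b1"}, "gamma": {"g1"}},
            outgroup_tips={"OG"},
        )
        assert asg.members("alpha") == {"a1", "cn1", "cn2"}
        assert asg.members("beta") == {"b1", "b2"}
        assert asg.members("gamma") == {"g1", "g2"}
        assert asg.members("unassigned") == set()

    def test_support_boundary_strictly_above(self):
        newick = ("(OG:1,((a1:1,(cn1:1,cn2:1)90:1)60:1,"
                  "((b1:1,b2:1)88:1,(g1:1,g2:1)92:1)70:1)99:1);")
        asg = assign_clades(
            self._rooted(newick),
            {"alpha": {"cn1", "cn2"}, "beta": {"b1"}, "gamma": {"g1"}},
            outgroup_tips={"OG"},
        )
        # the 60-support alpha stem fails the strict >60 rule; a1 unassigned
        assert asg.labels["a1"] == "unassigned"
        assert asg.members("alpha") == {"cn1", "cn2"}

    def test_tip_between_clades_unassigned(self):
        newick = ("(OG:1,(((a1:1,a2:1)90:1,stray:1)55:1,"
                  "((b1:1,b2:1)88:1,(g1:1,g2:1)92:1)70:1)99:1);")
        asg = assign_clades(
            self._rooted(newick),
            {"alpha": {"a1"}, "beta": {"b1"}, "gamma": {"g1"}},
            outgroup_tips={"OG"},
        )
        assert asg.labels["stray"] == "unassigned"

    def test_tip_order_invariance(self):
        anchors = {"alpha": {"cn1", "cn2"}, "beta": {"b1"}, "gamma": {"g1"}}
        reordered = (
            "(((g2:1,g1:1)92:1,(b2:1,b1:1)88:1)70:1,"
            "((cn2:1,cn1:1)90:1,a1:1)85:1,OG:1);"
        )
        a1 = assign_clades(self._rooted(), anchors, outgroup_tips={"OG"})
        tree2 = root_with_outgroup(read_tree(reordered, is_path=False), {"OG"})
        a2 = assign_clades(tree2, anchors, outgroup_tips={"OG"})
        assert a1.labels == a2.labels

    def test_shared_minimal_clade_error(self):
        with pytest.raises(ValueError, match="minimal clade"):
            assign_clades(
                self._rooted(),
                {"alpha": {"cn1"}, "beta": {"cn2"}, "gamma": {"g1"}},
                outgroup_tips={"OG"},
            )

    def test_counts(self):
        asg = CladeAssignment(labels={"x": "alpha", "y": "alpha", "z": "unassigned"})
        assert asg.counts["alpha"] == 2
        assert asg.counts["unassigned"] == 1
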