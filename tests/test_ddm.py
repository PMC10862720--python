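"""Distance matrices, DDMs, and helix-binned RMSDD fingerprints."""

import numpy as np
import pytest

import ddmotion as dm
from conftest import random_rigid_transform, random_trace


def brute_force_distance_matrix(coords):
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((coords[i] - coords[j]) ** 2))
    return out


def brute_force_hb(ddm_values, members):
    """Double loop over residue pairs per segment pair."""
    k = len(members)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            total = 0.0
            for i in members[a]:
                for j in members[b]:
                    total += ddm_values[i, j] ** 2
            out[a, b] = np.sqrt(total / (len(members[a]) * len(members[b])))
    return out


class TestDistanceMatrix:
    def test_three_four_five(self):
        trace = dm.CaTrace("p", "S", "A", [1, 2],
                           [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert dm.distance_matrix(trace).values[0, 1] == pytest.approx(5.0)

    def test_single_residue(self):
        trace = dm.CaTrace("p", "S", "A", [1], [[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(dm.distance_matrix(trace).values, [[0.0]])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        trace = random_trace(rng, n=6)
        np.testing.assert_allclose(
            dm.distance_matrix(trace).values,
            brute_force_distance_matrix(trace.coords),
        )


class TestDDM:
    def test_identical_traces_zero(self):
        rng = np.random.default_rng(1)
        trace = random_trace(rng)
        ddm = dm.compute_ddm(trace, trace.with_coords(trace.coords.copy()))
        np.testing.assert_array_equal(ddm.values, 0.0)

    def test_hand_computed_entry(self):
        a = dm.CaTrace("p", "A1", "A", [1, 2], [[0, 0, 0], [0, 0, 5.0]])
        b = dm.CaTrace("p", "B1", "A", [1, 2], [[0, 0, 0], [0, 0, 8.0]])
        ddm = dm.compute_ddm(a, b)
        assert ddm.values[0, 1] == pytest.approx(3.0)
        assert ddm.direction == ("A1", "B1")

    @pytest.mark.parametrize("seed", range(10))
    def test_rigid_invariance(self, seed):
        """A global rotation+translation leaves internal distances, and
        hence the DDM, at zero."""
        rng = np.random.default_rng(seed)
        trace = random_trace(rng)
        Q, t = random_rigid_transform(rng)
        moved = dm.CaTrace(trace.protein_id, "S2", "A", trace.residue_numbers,
                           trace.coords @ Q.T + t)
        ddm = dm.compute_ddm(trace, moved)
        assert np.abs(ddm.values).max() < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_trace(rng, structure_id="S1")
        b = dm.CaTrace("p", "S2", "A", a.residue_numbers,
                       rng.uniform(-20, 20, size=a.coords.shape))
        fwd = dm.compute_ddm(a, b)
        rev = dm.compute_ddm(b, a)
        np.testing.assert_array_equal(fwd.values, -rev.values)

    def test_mismatched_residues_use_intersection(self):
        a = dm.CaTrace("p", "S1", "A", [1, 2, 3],
                       [[0, 0, 0], [0, 0, 1], [0, 0, 2.0]])
        b = dm.CaTrace("p", "S2", "A", [2, 3, 4],
                       [[0, 0, 1], [0, 0, 2.0], [0, 0, 3.0]])
        ddm = dm.compute_ddm(a, b)
        np.testing.assert_array_equal(ddm.residue_numbers, [2, 3])

    def test_too_few_common_residues(self):
        a = dm.CaTrace("p", "S1", "A", [1, 2], np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])
        b = dm.CaTrace("p", "S2", "A", [2, 3], [[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            dm.compute_ddm(a, b)

    def test_different_proteins_refused(self):
        a = dm.CaTrace("p1", "S1", "A", [1, 2], [[0, 0, 0], [1, 0, 0.0]])
        b = dm.CaTrace("p2", "S2", "A", [1, 2], [[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(ValueError, match="different proteins"):
            dm.compute_ddm(a, b)


class TestHoDDM:
    def test_full_coverage_is_identity(self, toy, scheme):
        moved = dm.apply_motion(
            toy, scheme, dm.MotionScript.single(["2"], translation=(3, 0, 0)))
        ddm = dm.compute_ddm(toy, moved)
        ho = dm.ho_ddm(ddm, scheme)
        np.testing.assert_array_equal(ho.values, ddm.values)
        assert len(ho.segment_boundaries) == 14

    def test_submatrix_extraction(self):
        coords = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        a = dm.CaTrace("p", "S1", "A", np.arange(1, 11), coords)
        b = dm.CaTrace("p", "S2", "A", np.arange(1, 11), coords * 1.1)
        ddm = dm.compute_ddm(a, b)
        scheme = dm.SegmentationScheme.from_ranges("p", [("h", 1, 5)])
        ho = dm.ho_ddm(ddm, scheme)
        assert ho.values.shape == (5, 5)
        np.testing.assert_array_equal(ho.values, ddm.values[:5, :5])

    def test_row_count_equals_resolved_residues(self, scheme):
        """With some residues unresolved, the ho-DDM keeps exactly the
        resolved in-segment residues."""
        numbers = [n for n in scheme.all_residue_numbers() if n % 7 != 0]
        rng = np.random.default_rng(3)
        a = dm.CaTrace("toy", "S1", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        b = dm.CaTrace("toy", "S2", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        ho = dm.ho_ddm(dm.compute_ddm(a, b), scheme)
        assert len(ho.residue_numbers) == len(numbers)

    def test_empty_selection(self, scheme):
        a = dm.CaTrace("toy", "S1", "A", [900, 901], [[0, 0, 0], [1, 0, 0.0]])
        b = dm.CaTrace("toy", "S2", "A", [900, 901], [[0, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ValueError, match="covers none"):
            dm.ho_ddm(dm.compute_ddm(a, b), scheme)


class TestHbDDM:
    def test_zero_ddm_gives_zero_fingerprint(self, toy, scheme):
        ddm = dm.compute_ddm(toy, toy.with_coords(toy.coords.copy()))
        hb = dm.hb_ddm(ddm, scheme)
        np.testing.assert_array_equal(hb.values, 0.0)

    def test_hand_computed_block(self):
        """2×2 inter-segment block with differences {1, −1, 2, 0} →
        RMSDD = sqrt(6/4)."""
        # residues 1,2 in segment a; 3,4 in segment b; engineer the DDM
        values = np.zeros((4, 4))
        block = np.array([[1.0, -1.0], [2.0, 0.0]])
        values[0:2, 2:4] = block
        values[2:4, 0:2] = block.T
        ddm = dm.DDM(np.arange(1, 5), values, ("A", "B"))
        scheme = dm.SegmentationScheme.from_ranges("p", [("a", 1, 2), ("b", 3, 4)])
        hb = dm.hb_ddm(ddm, scheme)
        assert hb.values[0, 1] == pytest.approx(np.sqrt(6 / 4))
        assert hb.values[1, 0] == hb.values[0, 1]

    def test_constant_block_gives_absolute_value(self):
        values = np.zeros((4, 4))
        values[0:2, 2:4] = -2.5
        values[2:4, 0:2] = -2.5
        ddm = dm.DDM(np.arange(1, 5), values, ("A", "B"))
        scheme = dm.SegmentationScheme.from_ranges("p", [("a", 1, 2), ("b", 3, 4)])
        assert dm.hb_ddm(ddm, scheme).values[0, 1] == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, scheme):
        rng = np.random.default_rng(200 + seed)
        numbers = scheme.all_residue_numbers()
        a = dm.CaTrace("toy", "S1", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        b = dm.CaTrace("toy", "S2", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        ddm = dm.compute_ddm(a, b)
        hb = dm.hb_ddm(ddm, scheme)
        members = []
        for seg in scheme.segments:
            members.append([i for i, n in enumerate(ddm.residue_numbers)
                            if seg.start <= n <= seg.end])
        np.testing.assert_allclose(hb.values, brute_force_hb(ddm.values, members))

    def test_unresolved_segment_named_in_error(self, scheme):
        numbers = [n for n in scheme.all_residue_numbers()
                   if not scheme.segment("5a").contains(n)]
        rng = np.random.default_rng(5)
        a = dm.CaTrace("toy", "S1", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        b = dm.CaTrace("toy", "S2", "A", numbers,
                       rng.uniform(-20, 20, size=(len(numbers), 3)))
        with pytest.raises(ValueError, match="5a"):
            dm.hb_ddm(dm.compute_ddm(a, b), scheme)

    def test_translation_monotonicity(self):
        """Translating one point-mass segment directly away from another
        changes that pair's RMSDD by exactly the translation distance."""
        a = dm.CaTrace("p", "S1", "A", [1, 2], [[0, 0, 0], [10.0, 0, 0]])
        b = dm.CaTrace("p", "S2", "A", [1, 2], [[0, 0, 0], [13.0, 0, 0]])
        scheme = dm.SegmentationScheme.from_ranges("p", [("a", 1, 1), ("b", 2, 2)])
        hb = dm.hb_ddm(dm.compute_ddm(a, b), scheme)
        assert hb.values[0, 1] == pytest.approx(3.0)


class TestIntraVsInterSummary:
    def test_zero_matrix(self):
        hb = dm.HbDDM(("a", "b"), np.zeros((2, 2)), ("A", "B"))
        s = dm.intra_vs_inter_summary([hb])
        assert (s["intra_mean"], s["intra_sd"], s["inter_mean"], s["inter_sd"]) \
            == (0.0, 0.0, 0.0, 0.0)

    def test_separate_pools(self):
        values = np.full((3, 3), 2.0)
        np.fill_diagonal(values, 1.0)
        hb = dm.HbDDM(("a", "b", "c"), values, ("A", "B"))
        s = dm.intra_vs_inter_summary([hb])
        assert s["intra_mean"] == pytest.approx(1.0)
        assert s["inter_mean"] == pytest.approx(2.0)
        assert s["n_intra"] == 3
        assert s["n_inter"] == 3  # k(k-1)/2 unique off-diagonal values

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            dm.intra_vs_inter_summary([])
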