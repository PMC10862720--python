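"""Conformational-state clustering, label propagation, representatives."""

import numpy as np
import pytest

import ddmotion as dm
from conftest import random_rigid_transform


def make_two_groups(scheme, n_per_group=3, jitter=0.1, gap_angle=25.0, seed=0):
    """Two tight groups of structures: small within-group jitter, a large
    rigid-body motion between groups."""
    rng = np.random.default_rng(seed)
    base = dm.make_toy_protein(scheme)
    script = dm.MotionScript.single(["1a", "1b", "2"], axis=(0.0, 1.0, 0.0),
                                    angle_deg=gap_angle)
    other = dm.apply_motion(base, scheme, script)
    traces = []
    for g, anchor in enumerate((base, other)):
        for i in range(n_per_group):
            coords = anchor.coords + rng.normal(scale=jitter, size=anchor.coords.shape)
            traces.append(dm.CaTrace("toy", f"G{g}S{i}", "A",
                                     anchor.residue_numbers, coords))
    return traces


class TestPairwiseRmsdMatrix:
    def test_duplicate_structures_zero(self, toy):
        dup = dm.CaTrace("toy", "S2", "A", toy.residue_numbers, toy.coords.copy())
        m = dm.pairwise_rmsd_matrix([toy, dup])
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self, toy):
        rng = np.random.default_rng(1)
        Q, t = random_rigid_transform(rng)
        moved = dm.CaTrace("toy", "S2", "A", toy.residue_numbers,
                           toy.coords @ Q.T + t)
        m = dm.pairwise_rmsd_matrix([toy, moved])
        assert m.values[0, 1] < 1e-6

    def test_matches_kabsch_oracle(self):
        """One residue displaced by 3 Å (n=100): RMSD equals the directly
        computed post-fit RMSD."""
        rng = np.random.default_rng(2)
        coords = rng.uniform(-20, 20, size=(100, 3))
        a = dm.CaTrace("p", "S1", "A", np.arange(1, 101), coords)
        moved = coords.copy()
        moved[0] += [3.0, 0, 0]
        b = dm.CaTrace("p", "S2", "A", np.arange(1, 101), moved)
        m = dm.pairwise_rmsd_matrix([a, b])
        _, _, oracle = dm.kabsch(b.coords, a.coords)
        assert m.values[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_global_transform_of_one_input(self, scheme):
        traces = make_two_groups(scheme, n_per_group=2)
        ref = dm.pairwise_rmsd_matrix(traces).values
        rng = np.random.default_rng(3)
        Q, t = random_rigid_transform(rng)
        traces[1] = traces[1].with_coords(traces[1].coords @ Q.T + t)
        again = dm.pairwise_rmsd_matrix(traces).values
        np.testing.assert_allclose(again, ref, atol=1e-6)


class TestKmeansConformations:
    def test_two_tight_groups_split(self, scheme):
        traces = make_two_groups(scheme)
        m = dm.pairwise_rmsd_matrix(traces)
        labeling = dm.kmeans_conformations(m, k=2, seed=0)
        g0 = {labeling.cluster_of[f"G0S{i}"] for i in range(3)}
        g1 = {labeling.cluster_of[f"G1S{i}"] for i in range(3)}
        assert len(g0) == 1 and len(g1) == 1 and g0 != g1

    def test_k_equals_one(self, scheme):
        traces = make_two_groups(scheme, n_per_group=2)
        m = dm.pairwise_rmsd_matrix(traces)
        labeling = dm.kmeans_conformations(m, k=1, seed=0)
        assert set(labeling.cluster_of.values()) == {0}

    def test_identical_structures_degenerate_warns(self, toy):
        dups = [dm.CaTrace("toy", f"S{i}", "A", toy.residue_numbers,
                           toy.coords.copy()) for i in range(3)]
        m = dm.pairwise_rmsd_matrix(dups)
        with pytest.warns(UserWarning, match="degenerate"):
            dm.kmeans_conformations(m, k=2, seed=0)

    def test_k_out_of_range(self, scheme):
        traces = make_two_groups(scheme, n_per_group=1)
        m = dm.pairwise_rmsd_matrix(traces)
        with pytest.raises(ValueError, match="out of range"):
            dm.kmeans_conformations(m, k=5)

    def test_fixed_seed_reproducible(self, scheme):
        traces = make_two_groups(scheme)
        m = dm.pairwise_rmsd_matrix(traces)
        a = dm.kmeans_conformations(m, k=2, seed=3).cluster_of
        b = dm.kmeans_conformations(m, k=2, seed=3).cluster_of
        assert a == b


class TestPropagateLabels:
    @pytest.fixture()
    def clustered(self, scheme):
        traces = make_two_groups(scheme)
        m = dm.pairwise_rmsd_matrix(traces)
        return m, dm.kmeans_conformations(m, k=2, seed=0)

    def test_close_structures_inherit_label(self, clustered):
        m, labeling = clustered
        out = dm.propagate_labels(labeling, {"G0S0": "O_op", "G1S0": "I_op"}, m)
        for i in range(3):
            assert out.conformation_of(f"G0S{i}") == "O_op"
            assert out.conformation_of(f"G1S{i}") == "I_op"

    def test_distant_structure_unresolved(self, clustered):
        m, labeling = clustered
        out = dm.propagate_labels(labeling, {"G0S0": "O_op", "G1S0": "I_op"},
                                  m, threshold=1e-6)
        assert out.conformation_of("G0S1") == "unresolved"

    def test_never_labels_beyond_threshold(self, clustered):
        """Invariant: a non-anchor structure only carries a label if it is
        below the propagation threshold from an anchor of its cluster."""
        m, labeling = clustered
        anchors = {"G0S0": "O_op", "G1S0": "I_op"}
        threshold = 0.5
        out = dm.propagate_labels(labeling, anchors, m, threshold=threshold)
        for sid in out.cluster_of:
            if sid in anchors or out.conformation_of(sid) == "unresolved":
                continue
            cluster = out.cluster_of[sid]
            dists = [m.rmsd(sid, a) for a in anchors
                     if out.cluster_of[a] == cluster]
            assert min(dists) < threshold

    def test_conflicting_anchors_rejected(self, clustered):
        m, labeling = clustered
        with pytest.raises(ValueError, match="conflicting"):
            dm.propagate_labels(
                labeling, {"G0S0": "O_op", "G0S1": "O_oc"}, m)

    def test_two_agreeing_anchors(self, clustered):
        m, labeling = clustered
        out = dm.propagate_labels(
            labeling, {"G0S0": "O_oc", "G0S1": "O_oc", "G1S0": "I_op"}, m)
        assert out.conformation_of("G0S2") == "O_oc"


class TestSelectRepresentative:
    def test_resolution_priority(self):
        candidates = [
            dm.Candidate("XAAA", "E. coli", 3.0, "O_oc"),
            dm.Candidate("XBBB", "E. coli", 1.65, "O_oc"),
        ]
        chosen = dm.select_representative(candidates, "E. coli")
        assert chosen["O_oc"] == "XBBB"

    def test_organism_beats_resolution(self):
        candidates = [
            dm.Candidate("XAAA", "H. sapiens", 1.5, "I_op"),
            dm.Candidate("XBBB", "E. coli", 3.0, "I_op"),
        ]
        chosen = dm.select_representative(candidates, "E. coli")
        assert chosen["I_op"] == "XBBB"

    def test_disordered_replaced_by_next_best(self):
        candidates = [
            dm.Candidate("XAAA", "E. coli", 1.5, "I_op", disorder_flag=True),
            dm.Candidate("XBBB", "E. coli", 3.0, "I_op"),
        ]
        chosen = dm.select_representative(candidates, "E. coli")
        assert chosen["I_op"] == "XBBB"

    def test_sole_disordered_candidate_warns(self):
        candidates = [dm.Candidate("XAAA", "E. coli", 2.0, "O_op",
                                   disorder_flag=True)]
        with pytest.warns(UserWarning, match="disordered"):
            chosen = dm.select_representative(candidates, "E. coli")
        assert chosen["O_op"] == "XAAA"

    def test_tie_breaks_alphabetically(self):
        candidates = [
            dm.Candidate("XBBB", "E. coli", 2.0, "O_op"),
            dm.Candidate("XAAA", "E. coli", 2.0, "O_op"),
        ]
        assert dm.select_representative(candidates, "E. coli")["O_op"] == "XAAA"

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            dm.select_representative([], "E. coli")


def test_dispersion_scan_decreases(scheme):
    traces = make_two_groups(scheme)
    m = dm.pairwise_rmsd_matrix(traces)
    scan = dm.dispersion_scan(m, range(1, 4))
    assert scan["inertia"].is_monotonic_decreasing
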