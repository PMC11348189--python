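import numpy as np
import pytest

import capscan as cs
from capscan.errors import DataError, ValidationError
from capscan.screen import DetectionParams, OrderMatrix, StateParams


def matrix_from_strings(columns: list[str]) -> OrderMatrix:
    """Build an order matrix from one H/O/D string per member."""
    arr = np.array([list(c) for c in columns], dtype="U1").T
    return OrderMatrix(matrix=arr, member_ids=[f"m{i}" for i in range(len(columns))])


class TestBuildOrderMatrix:
    def test_ground_truth_columns(self, planted, planted_matrix):
        result, _ = planted
        m = planted_matrix.matrix
        a, b = result.spec.event_segment
        for j, label in enumerate(result.labels):
            col = m[a - 1 : b, j]
            if label == "unfolded":
                assert set(col) == {"D"}
            else:
                assert (col == "H").mean() >= 0.9
        # missing N terminus is disordered for every member
        assert set(m[:39].ravel()) == {"D"}

    def test_inconsistent_reference_lengths_rejected(self, small_ensemble):
        result, maps = small_ensemble
        bad = cs.ResidueMap(reference_length=99, positions={1: None},
                            alignment_identity=1.0, chain_id="A")
        with pytest.raises(DataError):
            cs.build_order_matrix(result.members[:2], [maps[0], bad])


class TestDetectFoldingEvents:
    def test_single_planted_event_recovered(self, planted_matrix):
        events = cs.detect_folding_events(planted_matrix)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.segment[0] - 385) <= 2 and abs(ev.segment[1] - 400) <= 2
        assert ev.helical_members == pytest.approx(0.31, abs=0.02)
        assert ev.disordered_members == pytest.approx(0.69, abs=0.02)

    def test_homogeneous_ensemble_yields_no_events(self):
        m = matrix_from_strings(["OOHHHHHOOO"] * 6)
        assert cs.detect_folding_events(m) == []

    def test_two_separated_events_stay_separate(self):
        col_h = "O" * 10 + "H" * 8 + "O" * 30 + "H" * 8 + "O" * 10
        col_d = "O" * 10 + "D" * 8 + "O" * 30 + "D" * 8 + "O" * 10
        m = matrix_from_strings([col_h, col_h, col_d, col_d])
        events = cs.detect_folding_events(m)
        assert [e.segment for e in events] == [(11, 18), (49, 56)]

    def test_nearby_runs_merge_across_small_gaps(self):
        col_h = "O" * 5 + "HHH" + "OO" + "HHH" + "O" * 5
        col_d = "O" * 5 + "DDD" + "OO" + "DDD" + "O" * 5
        m = matrix_from_strings([col_h, col_h, col_d, col_d])
        events = cs.detect_folding_events(m)
        assert [e.segment for e in events] == [(6, 13)]

    def test_raising_theta_d_never_adds_events(self, planted_matrix):
        counts = [
            len(cs.detect_folding_events(planted_matrix, DetectionParams(theta_d=t)))
            for t in (0.05, 0.15, 0.3, 0.5, 0.75, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_member_order_invariance(self, planted_matrix):
        rng = np.random.default_rng(0)
        perm = rng.permutation(planted_matrix.n_members)
        shuffled = OrderMatrix(
            matrix=planted_matrix.matrix[:, perm],
            member_ids=[planted_matrix.member_ids[i] for i in perm],
        )
        ev_a = cs.detect_folding_events(planted_matrix)
        ev_b = cs.detect_folding_events(shuffled)
        assert [e.segment for e in ev_a] == [e.segment for e in ev_b]
        assert [e.helical_members for e in ev_a] == [e.helical_members for e in ev_b]

    def test_tiny_ensembles_rejected(self):
        m = matrix_from_strings(["HHHHH"])
        with pytest.raises(ValidationError):
            cs.detect_folding_events(m)
        m3 = matrix_from_strings(["HHHHH"] * 3)
        with pytest.raises(ValidationError):
            cs.detect_folding_events(m3)
        with pytest.warns(UserWarning):
            cs.detect_folding_events(m3, DetectionParams(allow_small_ensemble=True))


class TestClassifyStates:
    def test_planted_fractions_recovered_exactly(self, planted, planted_matrix):
        result, maps = planted
        event = cs.detect_folding_events(planted_matrix)[0]
        states = cs.classify_states(result.members, maps, event)
        assert states.fractions == (0.23, 0.69, 0.08)
        assert states.labels == result.labels
        assert sum(states.fractions) == pytest.approx(1.0, abs=1e-12)

    def test_all_folded_ensemble(self):
        spec = cs.EnsembleSpec(n_members=5, chain_length=80, event_segment=(30, 45),
                               state_fractions=(1.0, 0.0, 0.0), missing_prefix=0, seed=12)
        result = cs.make_ensemble(spec)
        maps = [cs.map_to_reference(s, "A", result.reference_sequence) for s in result.members]
        ev = cs.FoldingEvent(segment=(30, 45), helical_members=1.0, disordered_members=0.0)
        states = cs.classify_states(result.members, maps, ev)
        assert states.fractions == (1.0, 0.0, 0.0)

    def test_displaced_members_never_labelled_folded(self, planted, planted_matrix):
        result, maps = planted
        event = cs.detect_folding_events(planted_matrix)[0]
        states = cs.classify_states(
            result.members, maps, event, StateParams(displacement_threshold=4.0)
        )
        for label, truth in zip(states.labels, result.labels):
            if truth == "alternative":
                assert label != "folded"


class TestPlddtDipTest:
    def test_flat_profile_is_null(self):
        prof = cs.make_plddt(cs.PlddtSpec(dip_depth=0.0, noise_sigma=0.0, seed=0), 200)
        res = cs.plddt_dip_test(prof, (90, 105), seed=1)
        assert res.delta == pytest.approx(0.0)
        assert res.p_value > 0.05

    def test_noise_free_dip_measured_exactly(self):
        prof = cs.make_plddt(
            cs.PlddtSpec(baseline=90, dip_depth=10, dip_segment=(90, 105),
                         noise_sigma=0.0, seed=0),
            200,
        )
        res = cs.plddt_dip_test(prof, (90, 105), seed=1)
        assert res.delta == pytest.approx(-10.0)
        assert res.p_value <= 0.05

    def test_deterministic_given_seed(self):
        prof = cs.make_plddt(cs.PlddtSpec(noise_sigma=2.0, seed=3), 300)
        r1 = cs.plddt_dip_test(prof, (100, 115), seed=7)
        r2 = cs.plddt_dip_test(prof, (100, 115), seed=7)
        assert (r1.delta, r1.p_value) == (r2.delta, r2.p_value)

    def test_argument_validation(self):
        prof = cs.make_plddt(cs.PlddtSpec(seed=0), 50)
        with pytest.raises(ValidationError):
            cs.plddt_dip_test(prof, (1, 49), seed=0)  # segment too long
        with pytest.raises(ValidationError):
            cs.plddt_dip_test(prof, (10, 20), n_perm=10, seed=0)


class TestActiveSiteProximity:
    def test_event_near_planted_site_coordinates(self, planted):
        result, maps = planted
        ev = cs.FoldingEvent(segment=(385, 400), helical_members=0.3, disordered_members=0.7)
        coords = maps[0].ca_coordinates(result.members[0])
        site = coords[390]  # a point on the segment itself
        cs.flag_active_site_proximity([ev], result.members[0], maps[0], site)
        assert ev.near_active_site is True
        assert ev.active_site_distance == pytest.approx(0.0, abs=1e-9)
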