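import numpy as np
import pytest

from petkit import synth
from petkit.errors import DataError
from petkit.mdgeom import Frame, classify_frame, salt_bridge_occupancy, state_fractions
from petkit.mdgeom.states import (
    STATE_IN_OXYANION,
    STATE_NEAR_ACTIVE_SITE,
    STATE_OTHER,
    STATES,
    AtomSelectionMap,
    GeometricCriteria,
    triad_competent,
)


def make_frame(d_og_c, d_n_o):
    """Frame with prescribed OG-C and N-O distances (atoms on axes)."""
    og = np.zeros(3)
    n = np.array([3.0, 0.0, 0.0])
    return Frame(
        resnums=np.array([131, 132, 500, 500]),
        resnames=np.array(["SER", "MET", "MHE", "MHE"], dtype=object),
        atom_names=np.array(["OG", "N", "C1", "O1"], dtype=object),
        coords=np.vstack([og, n, og + [0, d_og_c, 0], n + [0, 0, d_n_o]]),
    )


class TestClassifyFrame:
    def test_in_oxyanion_by_n_o_distance(self):
        assert classify_frame(make_frame(7.0, 4.2)) == STATE_IN_OXYANION

    def test_near_active_site_paper_thresholds(self):
        assert classify_frame(make_frame(5.0, 6.0)) == STATE_NEAR_ACTIVE_SITE

    def test_other_outside_both(self):
        assert classify_frame(make_frame(6.0, 8.0)) == STATE_OTHER

    def test_tie_at_five_angstrom_goes_to_near(self):
        # boundary rule: N-O exactly 5.0 is not in_oxyanion
        assert classify_frame(make_frame(4.0, 5.0)) == STATE_NEAR_ACTIVE_SITE

    def test_og_c_at_upper_bound_is_excluded(self):
        assert classify_frame(make_frame(5.5, 6.0)) == STATE_OTHER

    def test_missing_atom_named(self):
        frame = make_frame(5.0, 6.0)
        selection = AtomSelectionMap(ser_og=(999, "OG"))
        with pytest.raises(DataError, match="ser_og"):
            classify_frame(frame, selection=selection)

    def test_partition_every_frame_gets_one_label(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            label = classify_frame(make_frame(rng.uniform(2, 10), rng.uniform(2, 12)))
            assert label in STATES

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(4)
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        for args in [(5.0, 6.0), (4.0, 4.0), (8.0, 9.0)]:
            frame = make_frame(*args)
            moved = frame.transformed(q, rng.uniform(-30, 30, 3))
            assert classify_frame(frame) == classify_frame(moved)

    def test_disjointness_enforced_in_criteria(self):
        with pytest.raises(DataError, match="disjoint"):
            GeometricCriteria(d_oxyanion_in=4.5, d_oxyanion_near=(5.0, 7.5))


class TestStateFractions:
    def test_counting(self):
        frames = [make_frame(7.0, 4.0)] * 45 + [make_frame(6.0, 8.0)] * 55
        fr = state_fractions(frames)
        assert fr.in_oxyanion == pytest.approx(0.45)
        assert fr.other == pytest.approx(0.55)
        assert fr.n_frames == 100

    def test_identical_frames_unit_vector(self):
        fr = state_fractions([make_frame(5.0, 6.0)] * 10)
        assert fr.near_active_site == 1.0
        assert fr.in_oxyanion == 0.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DataError):
            state_fractions([])

    def test_generated_trajectory_classifies_back_exactly(self):
        occ = {STATE_IN_OXYANION: 0.3, STATE_NEAR_ACTIVE_SITE: 0.5, STATE_OTHER: 0.2}
        frames, labels = synth.gen_trajectory(occ, n_frames=300, seed=1)
        assert [classify_frame(f) for f in frames] == labels

    def test_occupancy_recovery_within_binomial_tolerance(self):
        occ = {STATE_IN_OXYANION: 0.45, STATE_OTHER: 0.55}
        frames, _ = synth.gen_trajectory(occ, n_frames=2000, seed=7)
        fr = state_fractions(frames)
        # binomial SE at p=0.45, n=2000 is ~0.011; +/-0.03 is ~2.7 SE
        assert fr.in_oxyanion == pytest.approx(0.45, abs=0.03)


class TestSaltBridge:
    def make_pair_frame(self, d):
        direction = np.array([1.0, 0.0, 0.0])
        return Frame(
            resnums=np.array([148, 233, 233]),
            resnames=np.array(["LYS", "ASP", "ASP"], dtype=object),
            atom_names=np.array(["NZ", "OD1", "OD2"], dtype=object),
            coords=np.vstack([np.zeros(3), d * direction, (d + 0.8) * direction]),
        )

    def test_all_contact(self):
        frames = [self.make_pair_frame(2.8)] * 20
        assert salt_bridge_occupancy(frames, 148, 233, 4.0) == 1.0

    def test_no_contact(self):
        frames = [self.make_pair_frame(8.0)] * 20
        assert salt_bridge_occupancy(frames, 148, 233, 4.0) == 0.0

    def test_minimum_over_multiple_oxygens(self):
        # OD1 at 3.5, OD2 at 4.3: the minimum decides
        frames = [self.make_pair_frame(3.5)]
        assert salt_bridge_occupancy(frames, 148, 233, 4.0) == 1.0

    def test_missing_sidechain_rejected(self):
        frame = self.make_pair_frame(3.0)
        with pytest.raises(DataError, match="nitrogen"):
            salt_bridge_occupancy([frame], 999, 233, 4.0)

    def test_generator_occupancy_exact_on_flags(self):
        frames, contacts = synth.gen_salt_bridge_trajectory(0.45, 500, seed=3)
        occ = salt_bridge_occupancy(frames, 148, 233, 4.0)
        assert occ == pytest.approx(contacts.mean())


class TestTriad:
    def make_triad_frame(self, d_ser_his, d_his_asp):
        return Frame(
            resnums=np.array([131, 209, 209, 177, 177]),
            resnames=np.array(["SER", "HIS", "HIS", "ASP", "ASP"], dtype=object),
            atom_names=np.array(["OG", "NE2", "ND1", "OD1", "OD2"], dtype=object),
            coords=np.array(
                [
                    [0.0, 0.0, 0.0],
                    [d_ser_his, 0.0, 0.0],
                    [d_ser_his + 1.4, 0.0, 0.0],
                    [d_ser_his + 1.4 + d_his_asp, 0.0, 0.0],
                    [d_ser_his + 1.4 + d_his_asp + 1.0, 0.0, 0.0],
                ]
            ),
        )

    def test_competent_and_not(self):
        assert triad_competent(self.make_triad_frame(2.8, 2.9))
        assert not triad_competent(self.make_triad_frame(5.0, 2.9))
        assert not triad_competent(self.make_triad_frame(2.8, 6.0))
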