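import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbquant import hbond
from hbquant.hbond import (
    HBCriterion,
    HBondSeries,
    LOOSE_HB,
    STRICT_HB,
    classify_hbond,
    detect_role_switches,
    hb_distance_series,
    hb_lifetimes,
    isodensity_contours,
    proton_histogram2d,
)
from hbquant.traj_io import Trajectory


def _series(d_HA, d_OO=None, d_OH=None, dt=1.0, partner=None):
    d_HA = np.asarray(d_HA, dtype=float)
    n = len(d_HA)
    d_OH = np.full(n, 1.0) if d_OH is None else np.asarray(d_OH, dtype=float)
    d_OO = d_OH + d_HA if d_OO is None else np.asarray(d_OO, dtype=float)
    s = HBondSeries(
        times=np.arange(n) * dt,
        d_OH=d_OH,
        d_HA=d_HA,
        d_OO=d_OO,
        bonded=np.zeros(n, dtype=bool),
        partner=np.zeros(n, dtype=int) if partner is None else np.asarray(partner),
    )
    s.bonded = classify_hbond(s)
    return s


class TestDistanceSeries:
    def test_collinear_geometry(self):
        pos = np.array([[[0, 0, 0], [1, 0, 0], [3, 0, 0]]], dtype=float)
        traj = Trajectory(positions=pos, elements=["O", "H", "O"], dt=1.0)
        s = hb_distance_series(traj, 0, 1, 2)
        assert s.d_OH[0] == pytest.approx(1.0)
        assert s.d_HA[0] == pytest.approx(2.0)
        assert s.d_OO[0] == pytest.approx(3.0)

    def test_minimum_image_across_boundary(self):
        pos = np.array([[[0.5, 0, 0], [9.8, 0, 0], [3.0, 0, 0]]])
        traj = Trajectory(
            positions=pos, elements=["O", "H", "O"], dt=1.0, cell=[10, 10, 10]
        )
        s = hb_distance_series(traj, 0, 1, 2)
        assert s.d_OH[0] == pytest.approx(0.7)

    def test_dimer_mean_OO_near_3A(self, dimer_traj):
        s = hb_distance_series(dimer_traj, 0, 1, 3)
        assert abs(s.d_OO.mean() - 3.0) < 0.05

    def test_donor_equals_acceptor_rejected(self, dimer_traj):
        with pytest.raises(ValueError):
            hb_distance_series(dimer_traj, 0, 1, 0)

    def test_triangle_inequality_enforced(self):
        with pytest.raises(ValueError, match="triangle"):
            HBondSeries(
                times=np.array([0.0]),
                d_OH=np.array([1.0]),
                d_HA=np.array([1.0]),
                d_OO=np.array([5.0]),
                bonded=np.array([False]),
                partner=np.array([0]),
            )


class TestClassify:
    @pytest.mark.parametrize(
        "d_ha,expected",
        [(1.8, True), (3.8, False), (2.0, True), (1.6, True), (1.59, False)],
    )
    def test_strict_criterion_closed_interval(self, d_ha, expected):
        s = _series([d_ha])
        assert classify_hbond(s, STRICT_HB)[0] == expected

    def test_oo_cutoff_applies(self):
        s = _series([1.8], d_OO=[3.6], d_OH=[2.0])
        assert classify_hbond(s, LOOSE_HB)[0] == np.False_
        assert classify_hbond(s, STRICT_HB)[0] == np.True_  # no d_OO cut

    @settings(max_examples=200, derandomize=True)
    @given(
        d=st.lists(st.floats(0.5, 5.0), min_size=1, max_size=50),
        hi1=st.floats(1.0, 3.0),
        widen=st.floats(0.0, 2.0),
    )
    def test_relaxing_dHAmax_is_monotone(self, d, hi1, widen):
        """A bonded flag never unsets when the upper cutoff is relaxed."""
        s = _series(d)
        tight = classify_hbond(s, HBCriterion(0.1, hi1))
        loose = classify_hbond(s, HBCriterion(0.1, hi1 + widen))
        assert np.all(loose[tight])


def _switch_traj(states, dt=100.0):
    """Handcrafted two-hydroxyl trajectory with a prescribed donor sequence."""
    n = len(states)
    pos = np.zeros((n, 6, 3))
    pos[:, 3, 0] = 3.0  # O_b
    pos[:, 2] = [-1.0, -1.0, 0.0]
    pos[:, 5] = [4.0, -1.0, 0.0]
    for i, s in enumerate(states):
        if s == 0:  # a donates
            pos[i, 1] = [1.0, 0.0, 0.0]
            pos[i, 4] = [3.33, 0.91, 0.0]
        else:  # b donates
            pos[i, 1] = [-0.33, 0.91, 0.0]
            pos[i, 4] = [2.0, 0.0, 0.0]
    return Trajectory(
        positions=pos, elements=["O", "H", "C", "O", "H", "C"], dt=dt
    )


class TestRoleSwitches:
    def test_generator_schedule_recovered(self, dimer_traj):
        events = detect_role_switches(dimer_traj, 0, 1, 3, 4)
        assert len(events) == 2
        assert abs(events[0] - 15.0) < 0.5
        assert abs(events[1] - 64.0) < 0.5

    def test_no_switch_gives_empty_list(self):
        traj = _switch_traj([0] * 40)
        assert detect_role_switches(traj, 0, 1, 3, 4) == []

    def test_flicker_shorter_than_hold_ignored(self):
        # 5-frame flicker (0.5 ps) < hold (1 ps = 10 frames); real switch kept
        states = [0] * 50 + [1] * 5 + [0] * 45 + [1] * 60
        traj = _switch_traj(states)
        events = detect_role_switches(traj, 0, 1, 3, 4, hold=1.0)
        # brute-force oracle over the known state sequence
        expected = []
        accepted, i = states[0], 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            if states[i] != accepted and (j - i) >= 10:
                expected.append(i * 100.0 / 1000.0)
                accepted = states[i]
            i = j
        assert events == pytest.approx(expected)
        assert len(events) == 1


def _lifetime_oracle(bonded, partner, dt, gap_tol):
    """Independent run-length scan for the lifetime statistics."""
    runs = []
    i = 0
    n = len(bonded)
    while i < n:
        if bonded[i]:
            j = i
            while j < n and bonded[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    if not runs:
        return 0.0, []
    longest = max(e - s + 1 for s, e in runs) * dt
    episodes = []
    cs, ce = runs[0]
    for s, e in runs[1:]:
        gap = (s - ce - 1) * dt
        if gap < gap_tol and partner[s] == partner[cs]:
            ce = e
        else:
            episodes.append((ce - cs + 1) * dt)
            cs, ce = s, e
    episodes.append((ce - cs + 1) * dt)
    return longest, sorted(episodes, reverse=True)


class TestLifetimes:
    def test_broken_bridge_longest_run(self):
        # bonded [0,100) ps, broken [100,110), bonded [110,300) at 1 ps/frame
        d_ha = np.full(300, 1.8)
        d_ha[100:110] = 3.0
        s = _series(d_ha, dt=1.0)
        longest, episodes = hb_lifetimes(s, gap_tolerance=0.0)
        assert longest == pytest.approx(190.0)
        assert episodes == pytest.approx([190.0, 100.0])

    def test_gap_merging_into_one_episode(self):
        d_ha = np.full(300, 1.8)
        d_ha[100:110] = 3.0
        s = _series(d_ha, dt=1.0)
        _, episodes = hb_lifetimes(s, gap_tolerance=20.0)
        assert episodes == pytest.approx([300.0])

    def test_fully_bonded_series(self):
        s = _series(np.full(250, 1.8), dt=2.0)
        longest, episodes = hb_lifetimes(s, gap_tolerance=0.0)
        assert longest == pytest.approx(500.0)
        assert episodes == pytest.approx([500.0])

    def test_partner_change_breaks_episode(self):
        d_ha = np.full(60, 1.8)
        d_ha[29:31] = 3.0
        partner = np.array([3] * 30 + [7] * 30)
        s = _series(d_ha, dt=1.0, partner=partner)
        _, episodes = hb_lifetimes(s, gap_tolerance=10.0)
        assert sorted(episodes) == pytest.approx([29.0, 29.0])

    def test_matches_bruteforce_oracle_on_random_series(self):
        """1000 random boolean series against an independent run-length scan."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            bonded = rng.random(n) < rng.uniform(0.2, 0.8)
            partner = rng.integers(0, 3, size=n)
            gap_tol = float(rng.uniform(0.0, 5.0))
            d_ha = np.where(bonded, 1.8, 3.0)
            s = _series(d_ha, dt=1.0, partner=partner)
            got = hb_lifetimes(s, gap_tolerance=gap_tol)
            want = _lifetime_oracle(bonded, partner, 1.0, gap_tol)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])


class TestProtonHistogram:
    def test_uniform_sample_density(self, rng):
        """Uniform box over the classical bridge-geometry spans."""
        n = 1_000_000
        d_oh = rng.uniform(0.92, 1.04, n)
        d_oo = rng.uniform(2.6, 3.8, n)
        s = _series(d_oo - d_oh, d_OO=d_oo, d_OH=d_oh)
        hist = proton_histogram2d(
            [s],
            bins_x=np.linspace(0.92, 1.04, 13),
            bins_y=np.linspace(2.6, 3.8, 25),
        )
        expected = 1.0 / (0.12 * 1.2)
        np.testing.assert_allclose(hist.density, expected, rtol=0.1)

    def test_normalization(self, rng):
        d_oh = rng.normal(1.0, 0.02, 5000).clip(0.8, 1.2)
        d_oo = rng.normal(3.0, 0.1, 5000).clip(2.5, 3.5)
        s = _series(d_oo - d_oh, d_OO=d_oo, d_OH=d_oh)
        hist = proton_histogram2d([s], bins_x=30, bins_y=30)
        dx = np.diff(hist.edges_x)[:, None]
        dy = np.diff(hist.edges_y)[None, :]
        assert abs((hist.density * dx * dy).sum() - 1.0) < 1e-9

    def test_pooling_invariance(self, rng):
        d_oh = rng.uniform(0.9, 1.1, 2000)
        d_oo = rng.uniform(2.7, 3.3, 2000)
        s = _series(d_oo - d_oh, d_OO=d_oo, d_OH=d_oh)
        one = proton_histogram2d([s], bins_x=20, bins_y=20)
        two = proton_histogram2d([s, s], bins_x=20, bins_y=20)
        np.testing.assert_allclose(one.density, two.density)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            proton_histogram2d([])

    def test_isocontour_encloses_uniform_support(self, rng):
        n = 200_000
        d_oh = rng.uniform(0.92, 1.04, n)
        d_oo = rng.uniform(2.6, 3.8, n)
        s = _series(d_oo - d_oh, d_OO=d_oo, d_OH=d_oh)
        hist = proton_histogram2d(
            [s], bins_x=np.linspace(0.9, 1.06, 17), bins_y=np.linspace(2.5, 3.9, 29)
        )
        contours = isodensity_contours(hist, level=1.0)
        assert contours
        verts = np.vstack(contours)
        assert verts[:, 0].min() >= 0.9 and verts[:, 0].max() <= 1.06
        assert verts[:, 1].min() >= 2.5 and verts[:, 1].max() <= 3.9
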