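import numpy as np
import pytest

from conftest import make_residue, make_structure
from reference_walker import reference_allowed_ranges
from splitscan.energetics import SplitEnergyProfile
from splitscan.geometry_annotation import LoopSegment, SurfaceAnnotation
from splitscan.sequence_conservation import ConservationProfile
from splitscan.site_selection import (AllowedRanges, Config,
                                      SplitSiteCandidate, enumerate_candidates,
                                      finalize_profile, match_experimental,
                                      profile_derivative, rank_predictions,
                                      reconstruct_allowed_ranges,
                                      select_per_loop, smooth_profile)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        v = np.full(9, 3.25)
        np.testing.assert_allclose(smooth_profile(v, 3, 7), v)

    def test_single_spike_one_pass(self):
        got = smooth_profile(np.array([0.0, 0, 3, 0, 0]), window=3, passes=1)
        np.testing.assert_allclose(got, [0, 1, 1, 1, 0])

    def test_linear_ramp_interior_unchanged(self):
        v = np.arange(10.0)
        got = smooth_profile(v, window=3, passes=1)
        np.testing.assert_allclose(got[1:-1], v[1:-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.zeros(5), window=4, passes=1)

    def test_bounds_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        got = smooth_profile(v, 3, 5)
        assert got.min() >= v.min() - 1e-12
        assert got.max() <= v.max() + 1e-12


class TestDerivative:
    def test_constant_is_zero(self):
        np.testing.assert_allclose(profile_derivative(np.full(6, 2.0)),
                                   np.zeros(6))

    def test_linear_slope_recovered(self):
        v = 1.5 * np.arange(8.0) + 3
        np.testing.assert_allclose(profile_derivative(v), np.full(8, 1.5))

    def test_hand_arithmetic_example(self):
        got = profile_derivative(np.array([0.0, 1, 4, 9]))
        np.testing.assert_allclose(got[1:-1], [2.0, 4.0])
        np.testing.assert_allclose(got[[0, -1]], [1.0, 5.0])


def make_profile(values):
    return SplitEnergyProfile(values=np.asarray(values, dtype=float))


def plateau_well_profile():
    """Plateaus at 0, wells at -20: only the middle plateau is allowed
    (terminal plateaus touch the ends; wells are minima)."""
    ramp_d = np.linspace(0, -20, 6)[1:-1]
    ramp_u = ramp_d[::-1]
    return np.concatenate([
        np.zeros(8), ramp_d, np.full(6, -20.0), ramp_u,
        np.zeros(8), ramp_d, np.full(6, -20.0), ramp_u, np.zeros(8)])


class TestAllowedRanges:
    def test_plateau_well_profile_keeps_middle_plateau(self):
        raw = plateau_well_profile()
        prof = make_profile(raw)
        cfg = Config()
        allowed = reconstruct_allowed_ranges(prof, cfg)
        expected = reference_allowed_ranges(list(raw))
        assert [tuple(iv) for iv in allowed.intervals] == expected
        assert len(allowed.intervals) == 1
        s, e = allowed.intervals[0]
        mid_lo = 8 + 4 + 6 + 4  # first plateau + ramp + well + ramp
        assert mid_lo < s < e <= mid_lo + 9
        # the global minimum cut is never allowed
        assert int(np.argmin(prof.smoothed)) + 1 not in allowed

    def test_v_profile_yields_no_ranges(self):
        k = np.arange(41.0)
        raw = np.abs(k - 20) - 20.0  # strict V, |slope| 1, min -20
        prof = make_profile(raw)
        allowed = reconstruct_allowed_ranges(prof, Config())
        assert allowed.intervals == []
        assert reference_allowed_ranges(list(raw)) == []

    def test_constant_profile_yields_no_ranges(self):
        raw = np.full(30, -5.0)
        allowed = reconstruct_allowed_ranges(make_profile(raw), Config())
        assert allowed.intervals == []
        assert reference_allowed_ranges(list(raw)) == []

    def test_e_tr_is_a_twentieth_of_the_minimum(self):
        prof = make_profile(plateau_well_profile())
        allowed = reconstruct_allowed_ranges(prof, Config())
        assert allowed.e_tr == pytest.approx(abs(allowed.e_min) / 20.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_profiles_match_reference_walker(self, seed):
        """The vectorized implementation agrees with the independent
        step-by-step walker on rough random-walk profiles."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(8, 60))
            raw = np.cumsum(rng.normal(0, 3, n))
            raw -= raw.max()  # energies non-positive like real profiles
            got = reconstruct_allowed_ranges(make_profile(raw.copy()),
                                             Config())
            expected = reference_allowed_ranges(list(raw))
            assert [tuple(iv) for iv in got.intervals] == expected

    def test_flat_set_shrinks_with_threshold(self):
        """Step B monotonicity: a stricter derivative threshold never
        adds flat cuts."""
        rng = np.random.default_rng(3)
        raw = np.cumsum(rng.normal(0, 3, 50))
        prof = make_profile(raw)
        finalize_profile(prof, Config())
        strict = np.abs(prof.derivative) < 0.25
        loose = np.abs(prof.derivative) < 0.5
        assert np.all(loose[strict])


def selection_inputs(n=12, saa=None, cons=None, loops=None, allowed=None,
                     smoothed=None):
    """Hand-assembled inputs for the candidate filter."""
    st = make_structure([make_residue(k + 1, ca=(4.0 * k, 0, 0))
                         for k in range(n)])
    prof = make_profile(np.zeros(n - 1))
    prof.smoothed = (np.asarray(smoothed, float) if smoothed is not None
                     else np.linspace(-3, -1, n - 1))
    prof.derivative = np.zeros(n - 1)
    ann = SurfaceAnnotation(
        saa=np.asarray(saa if saa is not None else np.full(n, 100.0), float),
        ss="C" * n,
        loops=loops if loops is not None else [LoopSegment(1, n)])
    consv = ConservationProfile(
        scores=np.asarray(cons if cons is not None else np.zeros(n), float),
        column_of_residue=np.arange(1, n + 1))
    alw = allowed if allowed is not None else AllowedRanges(
        intervals=[(1, n - 1)], e_min=-20.0, e_tr=1.0)
    return st, prof, ann, consv, alw


class TestCandidateFilter:
    def test_buried_residue_excludes_the_pair(self):
        # SAA 27 A^2 on one residue of the pair is below the 30 A^2 bar
        saa = np.full(12, 100.0)
        saa[4] = 27.0
        st, prof, ann, cons, alw = selection_inputs(saa=saa)
        got = {c.i for c in enumerate_candidates(st, prof, ann, cons, alw,
                                                 Config())}
        assert 4 not in got and 5 not in got
        assert 6 in got

    def test_conservation_threshold_is_strict(self):
        cons = np.zeros(12)
        cons[6] = 2.0  # exactly at the threshold: not "< 2"
        st, prof, ann, consv, alw = selection_inputs(cons=cons)
        got = {c.i for c in enumerate_candidates(st, prof, ann, consv, alw,
                                                 Config())}
        assert 6 not in got and 7 not in got

    def test_missing_conservation_excludes_pair(self):
        cons = np.zeros(12)
        cons[2] = np.nan
        st, prof, ann, consv, alw = selection_inputs(cons=cons)
        got = {c.i for c in enumerate_candidates(st, prof, ann, consv, alw,
                                                 Config())}
        assert 2 not in got and 3 not in got

    def test_loop_membership_required(self):
        loops = [LoopSegment(5, 8)]
        st, prof, ann, cons, alw = selection_inputs(loops=loops)
        got = {c.i for c in enumerate_candidates(st, prof, ann, cons, alw,
                                                 Config())}
        # pair (4,5) qualifies through residue 5; pair (1,2) does not
        assert got == {4, 5, 6, 7, 8}

    def test_passing_pair_annotated(self):
        st, prof, ann, cons, alw = selection_inputs(
            allowed=AllowedRanges(intervals=[(5, 7)], e_min=-20, e_tr=1))
        cands = enumerate_candidates(st, prof, ann, cons, alw, Config())
        by_i = {c.i: c for c in cands}
        assert by_i[6].in_allowed is True
        assert by_i[2].in_allowed is False
        assert by_i[6].se == pytest.approx(prof.smoothed[5])


def candidate(i, loop_id=0, saa=(60.0, 60.0), se=-1.0, in_allowed=True,
              tight=False):
    return SplitSiteCandidate(i=i, j=i + 1, loop_id=loop_id, saa_i=saa[0],
                              saa_j=saa[1], cons_i=0.1, cons_j=0.1, se=se,
                              in_allowed=in_allowed, tight=tight)


class TestPerLoopSelection:
    def test_close_second_site_is_dropped_not_replaced(self):
        cands = [candidate(10, saa=(60, 60)),   # sum 120, top
                 candidate(12, saa=(55, 55)),   # sum 110, 2 away: dropped
                 candidate(20, saa=(50, 50))]   # sum 100, never considered
        kept = select_per_loop(cands, Config())
        assert [c.i for c in kept] == [10]

    def test_distant_second_site_is_kept(self):
        cands = [candidate(10, saa=(60, 60)), candidate(20, saa=(55, 55))]
        kept = select_per_loop(cands, Config())
        assert sorted(c.i for c in kept) == [10, 20]

    def test_single_site_loop(self):
        kept = select_per_loop([candidate(7)], Config())
        assert [c.i for c in kept] == [7]

    def test_loops_selected_independently(self):
        cands = [candidate(5, loop_id=0), candidate(30, loop_id=1),
                 candidate(40, loop_id=1, saa=(70, 70))]
        kept = select_per_loop(cands, Config())
        assert sorted(c.i for c in kept) == [5, 30, 40]


class TestRanking:
    def test_tight_loop_precedes_higher_energy(self):
        tight_site = candidate(10, se=-2.0, tight=True)
        loose_site = candidate(30, se=-0.5, tight=False)
        ranked = rank_predictions([loose_site, tight_site], Config())
        assert [c.i for c in ranked] == [10, 30]
        assert [c.rank for c in ranked] == [1, 2]

    def test_higher_split_energy_first_within_class(self):
        a = candidate(10, se=-0.5, tight=True)
        b = candidate(30, se=-3.0, tight=True)
        ranked = rank_predictions([b, a], Config())
        assert [c.i for c in ranked] == [10, 30]

    def test_tie_broken_by_lower_index(self):
        a = candidate(40, se=-1.0)
        b = candidate(12, se=-1.0)
        ranked = rank_predictions([a, b], Config())
        assert [c.i for c in ranked] == [12, 40]

    def test_disallowed_candidates_excluded(self):
        a = candidate(10, in_allowed=False)
        b = candidate(20)
        ranked = rank_predictions([a, b], Config())
        assert [c.i for c in ranked] == [20]
        assert a.rank is None

    def test_magnitude_ordering_variant(self):
        a = candidate(10, se=-0.5, tight=True)
        b = candidate(30, se=-3.0, tight=True)
        ranked = rank_predictions([a, b], Config(rank_order="abs"))
        assert [c.i for c in ranked] == [30, 10]


class TestMatching:
    def test_predicted_pair_hits_validated_site(self):
        table = match_experimental([268, 279], [268], tolerance=2)
        assert table[0]["hit"] is True
        assert table[0]["predicted"] == 268

    @pytest.mark.parametrize("pred,expected_hit", [(266, True), (265, False)])
    def test_two_residue_tolerance_boundary(self, pred, expected_hit):
        table = match_experimental([pred], [268], tolerance=2)
        assert table[0]["hit"] is expected_hit

    def test_nearest_predicted_reported(self):
        table = match_experimental([266, 269, 300], [268], tolerance=2)
        assert table[0]["predicted"] == 269
        assert table[0]["distance"] == 1

    def test_no_predictions(self):
        table = match_experimental([], [268], tolerance=2)
        assert table[0]["hit"] is False
        assert table[0]["predicted"] is None


class TestConfig:
    def test_file_parsing_and_overrides(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("saa_threshold = 40\n# comment\nkl_threshold = 1.5\n"
                        "rank_order = abs\n")
        cfg = Config.from_file(str(path), kl_threshold=1.0)
        assert cfg.saa_threshold == 40
        assert cfg.kl_threshold == 1.0
        assert cfg.rank_order == "abs"

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("not_a_setting = 1\n")
        with pytest.raises(ValueError, match="unknown option"):
            Config.from_file(str(path))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            Config(smoothing_window=4)


# ---------------------------------------------------------------- properties

from hypothesis import given, settings
from hypothesis import strategies as hst


@settings(derandomize=True, max_examples=60, deadline=None)
@given(hst.lists(hst.floats(-50, 50), min_size=3, max_size=60))
def test_smoothing_never_leaves_value_bounds(values):
    """Repeated windowed averaging cannot overshoot the data range."""
    v = np.asarray(values, dtype=float)
    got = smooth_profile(v, 3, 5)
    assert got.min() >= v.min() - 1e-9
    assert got.max() <= v.max() + 1e-9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(hst.lists(hst.integers(1, 300), min_size=1, max_size=10),
       hst.integers(1, 300))
def test_match_hit_iff_some_prediction_within_tolerance(predicted,
                                                        experimental):
    row = match_experimental(predicted, [experimental], tolerance=2)[0]
    assert row["hit"] == any(abs(p - experimental) <= 2 for p in predicted)
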