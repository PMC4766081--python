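"""DF / ShEn / CFAE maps, area masks, overlap statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotormap import maps, tissue
from rotormap.electrogram import Electrogram
from rotormap.fixtures import EgmFixture, make_egm


def _movie_from_signal(sig, ny=8, nx=8, dt=1.0):
    frames = np.repeat(np.repeat(np.asarray(sig, np.float32)[:, None, None],
                                 ny, axis=1), nx, axis=2)
    return tissue.VoltageMovie(frames, dt, 0.0, 0.25)


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("case,expected_hz", [
    ("sine7", 7.0),
    ("ap_train_600", 1.0 / 0.6),
    ("two_tone", 9.0),
])
def test_dominant_frequency_examples(case, expected_hz):
    t = np.arange(6000) / 1000.0       # 6 s at 1 kHz
    if case == "sine7":
        sig = 30.0 * np.sin(2 * np.pi * 7.0 * t)
    elif case == "ap_train_600":
        sig = 100.0 * ((t % 0.6) < 0.2) - 80.0   # square AP train, CL 600 ms
    else:
        sig = 2.0 * np.sin(2 * np.pi * 9.0 * t) + 1.0 * np.sin(2 * np.pi * 5.0 * t)
    movie = _movie_from_signal(sig)
    dfm = maps.dominant_frequency_map(movie, window=6000.0)
    assert not dfm.undefined.any()
    np.testing.assert_allclose(dfm.values, expected_hz, atol=0.06)


def test_df_short_window_rejected():
    movie = _movie_from_signal(np.sin(np.arange(1500) / 20.0) * 30)
    with pytest.raises(maps.ResolutionError):
        maps.dominant_frequency_map(movie, window=1500.0)


def test_df_flags_quiescent_nodes():
    sig = 30 * np.sin(2 * np.pi * 7 * np.arange(6000) / 1000.0)
    movie = _movie_from_signal(sig)
    movie.frames[:, 2, 3] = -80.0        # flat node
    dfm = maps.dominant_frequency_map(movie, window=6000.0)
    assert dfm.undefined[2, 3]
    assert np.isnan(dfm.values[2, 3])


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def test_shen_constant_signal_is_zero():
    egm = Electrogram(np.zeros(6000), 1.0)
    assert maps.shannon_entropy(egm) == 0.0


def test_shen_uniform_bins_reach_log2_n():
    """Samples uniformly filling all N bins give the maximum entropy.

    With the clip range set to the spread of uniformly distributed data
    (sqrt(3) standard deviations) every bin receives equal mass."""
    n_bins = 50
    x = np.tile((np.arange(n_bins) + 0.5) / n_bins, 200)   # uniform fill
    got = maps.shannon_entropy(Electrogram(x, 1.0), bins=n_bins,
                               clip_sd=np.sqrt(3.0) * (1 + 1e-12))
    assert got == pytest.approx(np.log2(n_bins), abs=1e-6)


def test_shen_matches_brute_force_histogram_entropy():
    rng = np.random.default_rng(11)
    x = rng.normal(0.0, 2.0, 6000)
    got = maps.shannon_entropy(Electrogram(x, 1.0))
    # independent oracle: direct histogram entropy with the same binning rule
    sd, mu = x.std(), x.mean()
    lo, hi = mu - 3 * sd, mu + 3 * sd
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=50, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    expect = -(p * np.log2(p)).sum()
    assert got == pytest.approx(expect, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-50, 50))
def test_shen_invariant_to_offset_and_sign(seed, offset):
    x = np.random.default_rng(seed).normal(0, 1.5, 2000)
    e0 = maps.shannon_entropy(Electrogram(x, 1.0))
    assert maps.shannon_entropy(Electrogram(x + offset, 1.0)) == pytest.approx(e0, abs=1e-9)
    assert maps.shannon_entropy(Electrogram(-x, 1.0)) == pytest.approx(e0, abs=1e-9)


# ---------------------------------------------------------------------------
# CFAE cycle length
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("intervals,expected", [
    ((150.0,) * 39, 150.0),
    ((100.0, 200.0) * 20, 150.0),
    ((600.0,) * 9, 600.0),
])
def test_cfae_cycle_length_on_deflection_trains(intervals, expected):
    egm, truth = make_egm(EgmFixture(intervals_ms=intervals))
    window = min(6000.0, egm.signal.size * egm.dt_sample)
    got = maps.cfae_cycle_length(egm, window=window)
    # oracle: mean of the prescribed interval list inside the window
    assert got == pytest.approx(expected, abs=egm.dt_sample + 0.5)


def test_cfae_flat_signal_undefined():
    egm = Electrogram(np.zeros(6001), 1.0)
    assert np.isnan(maps.cfae_cycle_length(egm))


def test_cfae_periodic_equals_period_within_one_sample():
    egm, _ = make_egm(EgmFixture(intervals_ms=(137.0,) * 43))
    got = maps.cfae_cycle_length(egm, window=6000.0)
    assert got == pytest.approx(137.0, abs=egm.dt_sample)


# ---------------------------------------------------------------------------
# area masks
# ---------------------------------------------------------------------------

def test_threshold_mask_selects_exactly_above():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 12, (60, 60))
    smap = maps.ScalarMap(vals, "DF", 6000.0)
    am = maps.area_mask(smap, "threshold-above", 9.0)
    assert am.count == (vals > 9.0).sum()


def test_upper_percentile_mask_counts_and_order_statistic():
    rng = np.random.default_rng(6)
    vals = rng.uniform(0.0, 8.0, size=(600, 600))
    smap = maps.ScalarMap(vals, "ShEn", 6000.0)
    am = maps.area_mask(smap, "upper-percentile", 5.0)
    assert am.count == 18000                     # 5% of 360,000
    sel_min = vals[am.mask].min()
    assert sel_min >= vals[~am.mask].max() - 1e-12


def test_percentile_mask_tie_break_on_degenerate_map():
    vals = np.ones((40, 40))
    smap = maps.ScalarMap(vals, "CFAE", 6000.0)
    am = maps.area_mask(smap, "upper-percentile", 2.5)
    assert am.count == int(round(0.025 * 1600))
    # deterministic row-major tie-break: first nodes chosen
    flat = am.mask.ravel()
    assert flat[:am.count].all() and not flat[am.count:].any()


def test_percentile_mask_never_selects_undefined():
    vals = np.random.default_rng(1).uniform(50, 300, (40, 40))
    vals[:20] = np.nan
    smap = maps.ScalarMap(vals, "CFAE", 6000.0)
    am = maps.area_mask(smap, "lower-percentile", 10.0)
    assert not am.mask[:20].any()
    assert am.count > 0


def test_percentile_out_of_range_rejected():
    smap = maps.ScalarMap(np.ones((20, 20)), "DF", 6000.0)
    with pytest.raises(ValueError):
        maps.area_mask(smap, "upper-percentile", 0.0)
    with pytest.raises(ValueError):
        maps.area_mask(smap, "lower-percentile", 120.0)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_identities():
    a = np.zeros((50, 50), bool)
    a[10:30, 10:30] = True
    same = maps.overlap(a, a)
    assert same.percent == 100.0
    b = np.zeros_like(a)
    b[35:45, 35:45] = True
    assert maps.overlap(a, b).percent == 0.0
    half = np.zeros_like(a)
    half[10:30, 10:20] = True
    assert maps.overlap(a, half).percent == pytest.approx(50.0)
    assert sum(same.counts) == a.size


def test_overlap_empty_mask_flagged_undefined():
    a = np.zeros((20, 20), bool)
    b = np.ones((20, 20), bool)
    res = maps.overlap(a, b)
    assert not res.defined and np.isnan(res.percent)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_overlap_reciprocity_identity(seed):
    """|a| * P(a covered by b) == |b| * P(b covered by a) == 100 * |a & b|."""
    rng = np.random.default_rng(seed)
    a = rng.random((30, 30)) < 0.3
    b = rng.random((30, 30)) < 0.4
    if a.sum() == 0 or b.sum() == 0:
        return
    ab = maps.overlap(a, b)
    ba = maps.overlap(b, a)
    lhs = a.sum() * ab.percent
    rhs = b.sum() * ba.percent
    assert lhs == pytest.approx(rhs, rel=1e-12)
    assert lhs == pytest.approx(100.0 * (a & b).sum(), rel=1e-12)


def test_overlap_association_p_value_direction():
    rng = np.random.default_rng(9)
    a = np.zeros((60, 60), bool)
    a[:30] = True
    assoc = maps.overlap(a, a.copy())
    indep = maps.overlap(a, rng.random((60, 60)) < 0.5)
    assert assoc.p_value < 1e-10
    assert indep.p_value > 1e-4
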