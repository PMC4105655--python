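"""1-D waveguide simulation: benchmark modes, troughs, repulsion, filters."""

import numpy as np
import pytest
from scipy.signal import welch

import sweeptract as st
from sweeptract.errors import ParameterError
from sweeptract.rig import RigSpec, make_voice_fixture, tract_fir_from_tf
from sweeptract.tubes import transcendental_modes
from sweeptract.waveguide import (AreaFunction, SideBranch, WallModel,
                                  apply_filter, find_formants, find_troughs,
                                  fossae_removal_filter, repulsion_analysis,
                                  simulate_tf)
from sweeptract.deconvolve import TransferFunction


@pytest.fixture(scope="module")
def cylinder():
    return AreaFunction.uniform(142.0, 15.0)


def test_lossless_cylinder_peaks_match_transcendental_roots(cylinder,
                                                            benchmark_tube,
                                                            air5):
    """1-D simulation vs analytic roots within 1% over the plane-wave band."""
    roots = transcendental_modes(benchmark_tube, air5, 5000.0)
    tf = simulate_tf(cylinder, [], WallModel(0.0, air5),
                     np.arange(100.0, 5000.0, 1.0), flange_width_mm=2.0)
    peaks = find_formants(tf, 3.0).freqs_hz
    assert peaks.size == roots.size  # formant count equals mode count
    np.testing.assert_allclose(peaks, roots, rtol=0.01)


def test_closed_branch_carves_trough_at_quarter_wave(vowel_tfs, air5):
    """At 15 dB prominence only the fossa antiresonance survives, within 5%
    of the branch quarter-wave frequency c / 4L."""
    troughs = find_troughs(vowel_tfs["with"], 15.0)
    expected = air5.c / (4 * 19e-3)
    assert troughs.size == 1
    assert abs(troughs[0] - expected) / expected <= 0.05


def test_trough_frequency_decreases_with_branch_length(vowel_tract, air5):
    """The longer the sinus, the lower its antiresonance."""
    wall = WallModel(0.02, air5)
    grid = np.arange(50.0, 10_000.0, 2.0)
    found = []
    for L in (15.0, 19.0, 23.0):
        tf = simulate_tf(vowel_tract, [SideBranch(15.0, L, 40.0)], wall, grid)
        troughs = find_troughs(tf, 15.0)
        assert troughs.size == 1
        assert abs(troughs[0] - air5.c / (4 * L * 1e-3)) \
            / (air5.c / (4 * L * 1e-3)) <= 0.05
        found.append(troughs[0])
    assert found[0] > found[1] > found[2]


def test_branch_free_tract_has_no_deep_trough(vowel_tfs):
    """Without a side branch there is no prominent 3-6 kHz antiresonance."""
    tf = vowel_tfs["without"]
    troughs = find_troughs(tf, 15.0)
    assert not np.any((troughs > 3000.0) & (troughs < 6000.0))
    # with the fossa branch the deepest trough sits in the 3.5-5.5 kHz region
    tw = vowel_tfs["with"]
    troughs_w = find_troughs(tw, 15.0)
    deepest = troughs_w[np.argmin(np.interp(troughs_w, tw.freqs,
                                            tw.magnitude_db))]
    assert 3500.0 <= deepest <= 5500.0


def test_two_unequal_branches_give_two_troughs(vowel_tract, air5):
    wall = WallModel(0.02, air5)
    grid = np.arange(50.0, 10_000.0, 2.0)
    tf = simulate_tf(vowel_tract, [SideBranch(15.0, 15.0, 40.0),
                                   SideBranch(22.0, 22.0, 40.0)], wall, grid)
    troughs = find_troughs(tf, 12.0)
    f1, f2 = air5.c / (4 * 22e-3), air5.c / (4 * 15e-3)
    assert np.any(np.abs(troughs - f1) / f1 < 0.08)
    assert np.any(np.abs(troughs - f2) / f2 < 0.08)


def test_wall_absorption_damps_peaks_without_moving_them(cylinder, air5):
    grid = np.arange(100.0, 8000.0, 1.0)
    lossless = simulate_tf(cylinder, [], WallModel(0.0, air5), grid,
                           flange_width_mm=2.0)
    lossy = simulate_tf(cylinder, [], WallModel(0.05, air5), grid,
                        flange_width_mm=2.0)
    fa, fb = find_formants(lossless, 3.0), find_formants(lossy, 3.0)
    n = min(len(fa), len(fb))
    assert np.all(fb.magnitudes_db[:n] < fa.magnitudes_db[:n])
    assert np.max(np.abs(fb.freqs_hz[:n] - fa.freqs_hz[:n])
                  / fa.freqs_hz[:n]) < 0.01


def test_grid_refinement_convergence(vowel_tract, air5):
    """Halving the element size moves no peak by more than 0.2%."""
    wall = WallModel(0.02, air5)
    grid = np.arange(100.0, 8000.0, 2.0)
    coarse = simulate_tf(vowel_tract, [], wall, grid)
    n_req = int(np.ceil(0.175 / (air5.c / 8000.0 / 20.0)))
    fine = simulate_tf(vowel_tract, [], wall, grid, n_elements=2 * n_req)
    f1 = find_formants(coarse, 3.0).freqs_hz
    f2 = find_formants(fine, 3.0).freqs_hz
    n = min(f1.size, f2.size)
    assert np.max(np.abs(f2[:n] - f1[:n]) / f1[:n]) < 0.002


def test_underresolved_grid_is_refused(vowel_tract, air5):
    with pytest.raises(ParameterError, match=r"need at least \d+"):
        simulate_tf(vowel_tract, [], WallModel(0.02, air5),
                    np.arange(100.0, 8000.0, 2.0), n_elements=10)


def test_find_formants_on_synthetic_spectra():
    f = np.arange(0.0, 5000.0, 10.0)
    single = 30.0 / (1 + ((f - 1200) / 150) ** 2)
    fs_ = find_formants(TransferFunction(f, single, is_db=True), 6.0)
    assert len(fs_) == 1 and fs_.labels == ("F1",)
    assert fs_.freqs_hz[0] == pytest.approx(1200.0, abs=10.0)
    # two resonances closer than the grid step blur into a single peak
    two = (30.0 / (1 + ((f - 1200) / 80) ** 2)
           + 30.0 / (1 + ((f - 1207) / 80) ** 2))
    assert len(find_formants(TransferFunction(f, two, is_db=True), 6.0)) == 1


def test_formant_repulsion_sign_pattern(vowel_tfs, air5):
    """Formants below the fossa antiresonance fall, those above rise."""
    f_antires = air5.c / (4 * 19e-3)
    table = repulsion_analysis(vowel_tfs["with"], vowel_tfs["without"],
                               f_antires, prominence_db=3.0)
    below = table[table.side == "below"]
    above = table[table.side == "above"]
    step = vowel_tfs["with"].freqs[1] - vowel_tfs["with"].freqs[0]
    assert len(below) >= 3 and len(above) >= 1
    # one grid step of slack: peak positions are quantised to the grid
    assert (below.shift_hz <= step).all()
    assert (above.shift_hz >= -step).all()
    assert below.shift_hz.min() < -50.0  # the repulsion is real, not jitter
    assert above.shift_hz.max() > 50.0
    # identical spectra give identically zero shifts
    same = repulsion_analysis(vowel_tfs["with"], vowel_tfs["with"], f_antires,
                              prominence_db=3.0)
    assert (same.shift_hz == 0).all()


def test_removal_filter_identity_and_round_trip(vowel_tfs):
    fs = 48_000.0
    flat = fossae_removal_filter(vowel_tfs["with"], vowel_tfs["with"], fs)
    rng = np.random.default_rng(0)
    noise = st.SampledSignal(rng.standard_normal(48_000), fs)
    out = apply_filter(noise, flat)
    assert np.max(np.abs(out.samples - noise.samples)) \
        / np.max(np.abs(noise.samples)) < 1e-6

    filt = fossae_removal_filter(vowel_tfs["with"], vowel_tfs["without"], fs)
    longer = st.SampledSignal(rng.standard_normal(3 * 48_000), fs)
    back = apply_filter(apply_filter(longer, filt), filt.inverse())
    m = filt.taps.size  # compare the steady-state interior
    err = back.samples[m:-m] - longer.samples[m:-m]
    level = 20 * np.log10(np.linalg.norm(err)
                          / np.linalg.norm(longer.samples[m:-m]))
    assert level <= -60.0
    with pytest.raises(ParameterError):
        fossae_removal_filter(vowel_tfs["with"], vowel_tfs["without"], 8000.0)


def test_removal_filter_lifts_voice_trough(vowel_tfs):
    """Filtering a with-fossa voice matches the fossa-less voice in the
    trough region within +-1 dB."""
    fs = 48_000.0
    scale = float(np.abs(vowel_tfs["with"].values).max())
    fir_w = tract_fir_from_tf(vowel_tfs["with"], fs, 4097, scale)
    fir_o = tract_fir_from_tf(vowel_tfs["without"], fs, 4097, scale)
    rig = RigSpec(driver_ir=[1.0], distortion_coeffs=[0.0, 1.0],
                  tract_fir=[1.0], noise_snr_db=120.0, seed=4, fs=fs)
    voice_w = make_voice_fixture(103.8, fir_w, rig, 2.0)
    voice_o = make_voice_fixture(103.8, fir_o, rig, 2.0)
    filt = fossae_removal_filter(vowel_tfs["with"], vowel_tfs["without"], fs)
    filtered = apply_filter(voice_w, filt)

    f, p_f = welch(filtered.samples, fs, nperseg=16_384)
    _, p_o = welch(voice_o.samples, fs, nperseg=16_384)
    _, p_w = welch(voice_w.samples, fs, nperseg=16_384)
    f0 = fs / round(fs / 103.8)
    harmonics = np.arange(1, 60) * f0
    sel = (harmonics > 3500.0) & (harmonics < 5500.0)
    idx = np.round(harmonics[sel] / (f[1] - f[0])).astype(int)
    lifted = 10 * np.log10(p_f[idx]) - 10 * np.log10(p_o[idx])
    assert np.max(np.abs(lifted)) <= 1.0
    # sanity: the unfiltered voice really shows the trough (> 10 dB deep)
    raw = 10 * np.log10(p_w[idx]) - 10 * np.log10(p_o[idx])
    assert np.min(raw) < -10.0
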