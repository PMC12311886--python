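"""Tailored RLM filter, percentage cutoff, and consensus merging."""

import numpy as np
import pytest
import statsmodels.api as sm

from specdenoise import (
    TailoredConfig,
    consensus_spectrum,
    make_spectrum,
    percent_cutoff_denoise,
    tailored_denoise,
)


def _tailored_oracle(mz, intensity, quantile=0.75, k_sd=3.0):
    """Independent step-by-step reimplementation of the tailored filter.

    Sort by (intensity, m/z); Huber-RLM of intensity on rank over the lowest
    ceil(q*N) ranks; residual SD over the fitted subset; keep-set = peaks
    with intensity >= min intensity among ions exceeding trend + k*SD.
    """
    mz, intensity = np.asarray(mz, float), np.asarray(intensity, float)
    order = sorted(range(len(mz)), key=lambda i: (intensity[i], mz[i]))
    vals = intensity[list(order)]
    n = len(vals)
    ranks = np.arange(1, n + 1, dtype=float)
    m = int(np.ceil(quantile * n))
    X = sm.add_constant(ranks[:m])
    if np.ptp(vals[:m]) == 0:
        a, b = vals[0], 0.0
    else:
        a, b = sm.RLM(vals[:m], X, M=sm.robust.norms.HuberT()).fit().params
    resid = vals[:m] - (a + b * ranks[:m])
    sd = np.std(resid, ddof=1)
    exceeds = vals > a + b * ranks + k_sd * sd
    if not exceeds.any():
        return np.ones(len(mz), bool), 0.0
    thr = vals[exceeds].min()
    return intensity >= thr, thr


# --- tailored --------------------------------------------------------------

def test_equal_intensity_spectrum_kept_unchanged():
    s = make_spectrum(np.arange(20) + 100.0, np.full(20, 5.0))
    r = tailored_denoise(s)
    assert r.keep.all()
    assert r.threshold_intensity == 0.0


def test_fewer_than_four_peaks_passthrough():
    s = make_spectrum([100.0, 150.0, 200.0], [1.0, 50.0, 2.0])
    r = tailored_denoise(s)
    assert r.keep.all() and r.threshold_intensity == 0.0


def test_planted_fragments_over_linear_background_recovered_exactly():
    # 90 background ions whose sorted intensities lie exactly on a line of
    # slope 1, plus 10 fragments at 50x the background maximum
    rng = np.random.default_rng(5)
    bg_int = np.arange(1, 91, dtype=float)          # exact line, slope 1
    frag_int = np.full(10, 50.0 * 90.0)
    mz = np.sort(rng.uniform(50, 450, size=100))
    inten = np.concatenate([bg_int, frag_int])
    rng.shuffle(inten)
    s = make_spectrum(mz, inten)
    r = tailored_denoise(s)
    assert r.keep.sum() == 10
    assert set(s.intensity[r.keep]) == {4500.0}
    assert r.threshold_intensity == 4500.0


def test_hockey_stick_profile_matches_step_oracle():
    # hockey-stick sorted-intensity curve: dense low-intensity background
    # plus an exponential high-intensity tail, as in a gallate-ester spectrum
    rng = np.random.default_rng(17)
    bg = rng.uniform(0.5, 30.0, size=70)
    tail = 30.0 * np.exp(rng.uniform(0.5, 3.5, size=20))
    mz = np.sort(rng.uniform(50, 600, size=90))
    inten = np.concatenate([bg, tail])
    rng.shuffle(inten)
    s = make_spectrum(mz, inten, precursor_mz=650.0)
    r = tailored_denoise(s)
    keep_expected, thr_expected = _tailored_oracle(s.mz, s.intensity)
    assert np.array_equal(r.keep, keep_expected)
    assert np.isclose(r.threshold_intensity, thr_expected)


@pytest.mark.parametrize("scale", [1e-3, 1.0, 1e4])
def test_tailored_invariant_to_uniform_rescaling(scale):
    rng = np.random.default_rng(23)
    mz = np.sort(rng.uniform(50, 450, 80))
    inten = np.concatenate([rng.uniform(1, 10, 70), rng.uniform(100, 500, 10)])
    rng.shuffle(inten)
    s = make_spectrum(mz, inten)
    r1 = tailored_denoise(s)
    r2 = tailored_denoise(s.copy(intensity=s.intensity * scale))
    assert np.array_equal(r1.keep, r2.keep)


def test_tailored_always_keeps_base_peak(default_library):
    for s in default_library[:30]:
        r = tailored_denoise(s)
        assert r.keep[np.argmax(s.intensity)]


def test_non_finite_intensity_rejected():
    s = make_spectrum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    s.intensity[2] = np.nan
    with pytest.raises(ValueError):
        tailored_denoise(s)


# --- percentage cutoff -----------------------------------------------------

def test_percent_cutoff_worked_example():
    s = make_spectrum([100.0, 200.0, 300.0, 400.0], [100.0, 10.0, 4.0, 1.0])
    r = percent_cutoff_denoise(s, 0.05)
    assert r.threshold_intensity == 5.0
    assert sorted(s.intensity[r.keep]) == [10.0, 100.0]


def test_percent_cutoff_zero_is_identity(simple_spectrum):
    assert percent_cutoff_denoise(simple_spectrum, 0.0).keep.all()


def test_peak_exactly_at_threshold_is_kept():
    s = make_spectrum([100.0, 200.0], [100.0, 5.0])
    assert percent_cutoff_denoise(s, 0.05).keep.all()


def test_percent_cutoff_rejects_out_of_range(simple_spectrum):
    for pct in (-0.1, 1.5):
        with pytest.raises(ValueError):
            percent_cutoff_denoise(simple_spectrum, pct)


def test_percent_cutoff_monotone_nesting(default_library):
    for s in default_library[:10]:
        prev = None
        for pct in (0.0, 0.02, 0.05, 0.10):
            keep = percent_cutoff_denoise(s, pct).keep
            if prev is not None:
                assert np.all(prev | ~keep)  # keep(pct2) subset of keep(pct1)
            prev = keep


def test_denoised_peaks_are_subset_of_source(simple_spectrum):
    r = percent_cutoff_denoise(simple_spectrum, 0.2)
    d = r.spectrum
    assert set(d.mz) <= set(simple_spectrum.mz)
    src = dict(zip(simple_spectrum.mz, simple_spectrum.intensity))
    assert all(src[m] == i for m, i in zip(d.mz, d.intensity))


# --- consensus -------------------------------------------------------------

def _replicate(mz, inten, id):
    return make_spectrum(mz, inten, id=id, precursor_mz=500.0)


def test_consensus_of_identical_spectra_is_identity():
    reps = [_replicate([100.0, 200.0, 300.0], [5.0, 10.0, 2.0], f"r{i}")
            for i in range(3)]
    c = consensus_spectrum(reps)
    assert np.array_equal(c.mz, reps[0].mz)
    assert np.array_equal(c.intensity, reps[0].intensity)
    assert c.precursor_mz == 500.0


def test_peak_in_two_of_three_spectra_dropped():
    # 66.7% presence < 70% required
    reps = [
        _replicate([100.0, 200.0], [5.0, 1.0], "a"),
        _replicate([100.0, 200.0], [5.0, 1.0], "b"),
        _replicate([100.0], [5.0], "c"),
    ]
    c = consensus_spectrum(reps)
    assert np.array_equal(c.mz, [100.0])


def test_consensus_matches_presence_counting_oracle():
    rng = np.random.default_rng(31)
    base_mz = np.sort(rng.choice(np.arange(100.0, 400.0, 5.0), 12, replace=False))
    reps = []
    membership = rng.random((5, 12)) < 0.6
    membership[:, 0] = True  # one peak always present
    for i in range(5):
        sel = membership[i]
        reps.append(_replicate(base_mz[sel] + rng.uniform(-0.003, 0.003, sel.sum()),
                               rng.uniform(1, 10, sel.sum()), f"r{i}"))
    c = consensus_spectrum(reps, min_presence=0.7, min_n=3, mz_tol=0.01)
    expected_groups = [j for j in range(12) if membership[:, j].sum() >= 0.7 * 5]
    assert len(c.mz) == len(expected_groups)
    assert np.allclose(c.mz, base_mz[expected_groups], atol=0.01)


def test_consensus_requires_min_n_and_single_polarity():
    reps = [_replicate([100.0], [1.0], "a"), _replicate([100.0], [1.0], "b")]
    with pytest.raises(ValueError):
        consensus_spectrum(reps, min_n=3)
    reps3 = reps + [_replicate([100.0], [1.0], "c")]
    reps3[2] = reps3[2].copy(polarity="negative")
    with pytest.raises(ValueError):
        consensus_spectrum(reps3)
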