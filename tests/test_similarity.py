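"""GNPS-style similarity: peak joining, greedy assignment, score contract."""

import math

import numpy as np
import pytest

from specdenoise import (
    MatchKind,
    add_noise_ions,
    gnps_score,
    join_peaks_gnps,
    low_intensity_sum,
    make_spectrum,
)
from conftest import random_spectrum


def bruteforce_best_assignment(pairs):
    """Maximum-weight one-to-one assignment by exhaustive recursion.

    Independent of the scoring path: explores every subset of candidate
    pairs that uses each peak at most once.
    """
    pairs = [(i, j, w) for i, j, _, w in pairs]

    def rec(k, used_a, used_b):
        if k == len(pairs):
            return 0.0
        best = rec(k + 1, used_a, used_b)  # skip pair k
        i, j, w = pairs[k]
        if i not in used_a and j not in used_b:
            best = max(best, w + rec(k + 1, used_a | {i}, used_b | {j}))
        return best

    return rec(0, frozenset(), frozenset())


# --- join_peaks_gnps -------------------------------------------------------

def test_identical_spectra_direct_matches_coincide_with_shifted(simple_spectrum):
    s = simple_spectrum
    matches = join_peaks_gnps(s, s)
    diag = [(p[0], p[1]) for p in matches.pairs if p[2] == MatchKind.DIRECT]
    assert {(i, i) for i in range(len(s))} <= set(diag)
    # zero precursor difference: no separate shifted pairs survive dedup
    assert all(p[2] == MatchKind.DIRECT for p in matches.pairs)


def test_direct_match_within_tolerance():
    a = make_spectrum([100.0], [1.0], precursor_mz=200.0)
    b = make_spectrum([100.005], [1.0], precursor_mz=200.0)
    matches = join_peaks_gnps(a, b, tol=0.01)
    assert len(matches) == 1
    assert matches.pairs[0][2] == MatchKind.DIRECT


def test_neutral_loss_shifted_match():
    # water-loss arithmetic: precursor difference 18.011 equals the fragment
    # m/z difference 163.039 - 145.028
    a = make_spectrum([163.039], [1.0], precursor_mz=365.105)
    b = make_spectrum([145.028], [1.0], precursor_mz=347.094)
    matches = join_peaks_gnps(a, b, tol=0.01)
    assert len(matches) == 1
    assert matches.pairs[0][2] == MatchKind.SHIFTED


def test_pair_weights_are_products_of_unit_normalized_sqrt_intensities():
    a = make_spectrum([100.0, 200.0], [4.0, 9.0], precursor_mz=300.0)
    matches = join_peaks_gnps(a, a)
    na = np.sqrt([4.0, 9.0]) / math.sqrt(13.0)
    by_pair = {(i, j): w for i, j, _, w in matches.pairs}
    assert math.isclose(by_pair[(0, 0)], na[0] ** 2, rel_tol=1e-12)
    assert math.isclose(by_pair[(1, 1)], na[1] ** 2, rel_tol=1e-12)


def test_missing_peaks_rejected():
    a = make_spectrum([100.0], [1.0])
    empty = a.subset(np.array([False]))
    with pytest.raises(ValueError):
        join_peaks_gnps(a, empty)


# --- gnps_score ------------------------------------------------------------

def test_self_similarity_is_one(default_library):
    for s in default_library[:10]:
        assert gnps_score(s, s) == pytest.approx(1.0, abs=1e-9)


def test_disjoint_spectra_score_zero():
    a = make_spectrum([100.0, 110.0], [1.0, 2.0], precursor_mz=200.0)
    b = make_spectrum([151.0, 161.0], [1.0, 2.0], precursor_mz=300.0)
    assert gnps_score(a, b) == 0.0


def test_empty_spectrum_scores_zero():
    a = make_spectrum([100.0], [1.0])
    assert gnps_score(a, a.subset(np.array([False]))) == 0.0


def test_greedy_never_exceeds_and_usually_equals_bruteforce_optimum():
    rng = np.random.default_rng(99)
    grid = np.arange(100.0, 160.0, 5.0)
    equal = 0
    n_cases = 20
    for k in range(n_cases):
        # every 10th case uses a grid-aligned precursor offset that floods
        # the shifted channel with conflicting candidates; the rest have
        # unaligned offsets, as in real spectra
        offset = 5.0 if k % 10 == 0 else float(rng.uniform(2.0, 4.0))
        a = random_spectrum(rng, n_peaks=8, grid=grid, precursor=200.0, id="a")
        b = random_spectrum(rng, n_peaks=8, grid=grid, precursor=200.0 + offset, id="b")
        greedy = gnps_score(a, b)
        optimum = min(bruteforce_best_assignment(join_peaks_gnps(a, b).pairs), 1.0)
        assert greedy <= optimum + 1e-12
        if math.isclose(greedy, optimum, rel_tol=1e-9, abs_tol=1e-12):
            equal += 1
    assert equal >= 0.9 * n_cases


def test_optimal_assignment_flag_matches_bruteforce():
    rng = np.random.default_rng(4)
    grid = np.arange(100.0, 160.0, 5.0)
    for _ in range(5):
        a = random_spectrum(rng, n_peaks=6, grid=grid, precursor=220.0, id="a")
        b = random_spectrum(rng, n_peaks=6, grid=grid, precursor=205.0, id="b")
        expected = min(bruteforce_best_assignment(join_peaks_gnps(a, b).pairs), 1.0)
        assert gnps_score(a, b, assignment="optimal") == pytest.approx(expected)


def test_score_symmetric_and_in_range():
    rng = np.random.default_rng(12)
    grid = np.arange(100.0, 200.0, 4.0)
    for _ in range(30):
        a = random_spectrum(rng, n_peaks=10, grid=grid, id="a")
        b = random_spectrum(rng, n_peaks=10, grid=grid, id="b")
        s_ab, s_ba = gnps_score(a, b), gnps_score(b, a)
        assert 0.0 <= s_ab <= 1.0
        assert s_ab == pytest.approx(s_ba, abs=1e-12)


def test_unmatched_peaks_strictly_lower_score():
    rng = np.random.default_rng(8)
    a = random_spectrum(rng, n_peaks=10, id="a")
    base = gnps_score(a, a)
    noisy = add_noise_ions(a, 5, frac=0.05, rng=np.random.default_rng(1))
    assert gnps_score(a, noisy) < base


def test_score_invariant_to_intensity_rescaling():
    rng = np.random.default_rng(21)
    grid = np.arange(100.0, 200.0, 4.0)
    a = random_spectrum(rng, n_peaks=9, grid=grid, id="a")
    b = random_spectrum(rng, n_peaks=9, grid=grid, id="b")
    ref = gnps_score(a, b)
    assert gnps_score(a.copy(intensity=a.intensity * 137.0), b) == pytest.approx(ref)
    assert gnps_score(a, b.copy(intensity=b.intensity * 1e-3)) == pytest.approx(ref)


def test_agrees_with_matchms_modified_cosine():
    """Cross-check against the reference modified-cosine implementation.

    matchms scores raw intensities, so the square-root transform is applied
    before handing spectra over; well-separated peaks avoid assignment-order
    ambiguity between the two greedy implementations.
    """
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(3)
    grid = np.arange(100.0, 300.0, 7.0)
    sim = ModifiedCosine(tolerance=0.01)
    for k in range(10):
        a = random_spectrum(rng, n_peaks=8, grid=grid, precursor=400.0, id="a")
        b = random_spectrum(rng, n_peaks=8, grid=grid,
                            precursor=400.0 if k % 2 else 412.3, id="b")
        ma = matchms.Spectrum(mz=a.mz, intensities=np.sqrt(a.intensity),
                              metadata={"precursor_mz": a.precursor_mz},
                              metadata_harmonization=False)
        mb = matchms.Spectrum(mz=b.mz, intensities=np.sqrt(b.intensity),
                              metadata={"precursor_mz": b.precursor_mz},
                              metadata_harmonization=False)
        expected = float(sim.pair(ma, mb)["score"])
        assert gnps_score(a, b) == pytest.approx(expected, abs=1e-6)


# --- low_intensity_sum -----------------------------------------------------

def test_low_intensity_sum_single_peak_is_zero():
    assert low_intensity_sum(make_spectrum([100.0], [50.0])) == 0.0


def test_low_intensity_sum_worked_example():
    s = make_spectrum([100.0, 200.0, 300.0], [100.0, 4.0, 1.0])
    assert low_intensity_sum(s, 0.05) == pytest.approx(0.05)


def test_low_intensity_sum_invariant_to_rescaling():
    rng = np.random.default_rng(14)
    for _ in range(10):
        s = random_spectrum(rng, n_peaks=12, id="s")
        v = low_intensity_sum(s)
        scaled = s.copy(intensity=s.intensity * rng.uniform(0.01, 100.0))
        assert low_intensity_sum(scaled) == pytest.approx(v)
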