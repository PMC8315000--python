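"""MS2 annotation, isobaric discrimination and the surrogate match score."""

import itertools

import numpy as np
import pytest

from splicequant import (
    FragmentConfig,
    SpectrumSimConfig,
    Spectrum,
    Tolerance,
    annotate_spectrum,
    diagnostic_ions,
    match_score,
    rt_resolved,
    simulate_ms2,
    spectra_agreement,
    support_in_spectrum,
    theoretical_fragments,
)
from splicequant.fragments import RESIDUE_MASS, WATER, PROTON

SPLICED = "KLVVGAVGV"
NONSPLICED = "KLVVVGAVG"


def noiseless(peptide, frag_cfg, spectrum_id="clean", rt=10.0):
    return simulate_ms2(
        peptide,
        SpectrumSimConfig(
            detection_probability=1.0, mz_jitter_ppm=0.0, noise_peaks=0, seed=0
        ),
        frag_cfg,
        spectrum_id=spectrum_id,
        rt=rt,
    )


def test_annotate_noiseless_matches_everything(frag_by_z1, tol20ppm):
    sp = noiseless(SPLICED, frag_by_z1)
    ann = annotate_spectrum(sp, SPLICED, tol20ppm, frag_by_z1)
    assert ann.matched_ion_count == len(theoretical_fragments(SPLICED, frag_by_z1))
    assert ann.unmatched_ions == []
    assert ann.matched_intensity_fraction == pytest.approx(1.0)


def test_annotate_empty_spectrum(tol20ppm, frag_by_z1):
    sp = Spectrum("empty", 421.279, 2, 10.0, ())
    ann = annotate_spectrum(sp, SPLICED, tol20ppm, frag_by_z1)
    assert ann.matched_ion_count == 0
    assert ann.matched_intensity_fraction == 0.0


def test_annotate_jittered_recovery(frag_by_z1, tol20ppm):
    # 10 ppm Gaussian jitter vs 20 ppm window: P(|N(0,10)| <= 20) ~ 0.9545,
    # so across seeds >= 95% of detected ions are matched on average
    matched = total = 0
    for seed in range(300):
        sp = simulate_ms2(
            SPLICED,
            SpectrumSimConfig(
                detection_probability=1.0,
                mz_jitter_ppm=10.0,
                noise_peaks=0,
                seed=seed,
            ),
            frag_by_z1,
        )
        ann = annotate_spectrum(sp, SPLICED, tol20ppm, frag_by_z1)
        matched += ann.matched_ion_count
        total += len(sp.peaks)
    assert matched / total >= 0.93


def test_tolerance_monotonicity(frag_by_z1):
    sp = simulate_ms2(
        SPLICED,
        SpectrumSimConfig(detection_probability=1.0, mz_jitter_ppm=15.0, seed=3),
        frag_by_z1,
    )
    counts = [
        annotate_spectrum(sp, SPLICED, Tolerance("ppm", v), frag_by_z1).matched_ion_count
        for v in (5, 10, 20, 40, 80)
    ]
    assert counts == sorted(counts)


def test_agreement_identical_and_disjoint(frag_by_z1, tol20ppm):
    sp = noiseless(SPLICED, frag_by_z1)
    same = spectra_agreement(sp, sp, SPLICED, tol20ppm, frag_by_z1)
    assert same["unique_to_1"] == set() and same["unique_to_2"] == set()
    empty = Spectrum("e", 421.279, 2, 10.0, ())
    disj = spectra_agreement(sp, empty, SPLICED, tol20ppm, frag_by_z1)
    assert disj["shared_ions"] == set()
    assert disj["unique_to_1"] == same["shared_ions"]


def test_agreement_bernoulli_shared_fraction(frag_by_z1, tol20ppm):
    # two independent detections at p=0.8 share ~0.64 of the theoretical ions
    n_ions = len(theoretical_fragments(SPLICED, frag_by_z1))
    fractions = []
    for seed in range(250):
        s1 = simulate_ms2(
            SPLICED,
            SpectrumSimConfig(detection_probability=0.8, mz_jitter_ppm=0.0, noise_peaks=0, seed=2 * seed),
            frag_by_z1,
        )
        s2 = simulate_ms2(
            SPLICED,
            SpectrumSimConfig(detection_probability=0.8, mz_jitter_ppm=0.0, noise_peaks=0, seed=2 * seed + 1),
            frag_by_z1,
        )
        shared = spectra_agreement(s1, s2, SPLICED, tol20ppm, frag_by_z1)["shared_ions"]
        fractions.append(len(shared) / n_ions)
    mean = np.mean(fractions)
    sigma = np.sqrt(0.64 * 0.36 / (n_ions * len(fractions)))
    assert abs(mean - 0.64) <= 3 * sigma + 0.01


def composition_partition(a, b):
    """Composition brute-force oracle for the shared/diagnostic partition."""
    shared, diag = set(), set()
    n = len(a)
    prefixes = lambda s: {f"b{i}": sorted(s[:i]) for i in range(1, len(s))}
    suffixes = lambda s: {f"y{i}": sorted(s[-i:]) for i in range(1, len(s))}
    ions_a = {**prefixes(a), **suffixes(a)}
    ions_b = {**prefixes(b), **suffixes(b)}
    for label, comp in ions_a.items():
        series = label[0]
        if any(
            comp == other and label[0] == lab_b[0]
            for lab_b, other in ions_b.items()
        ):
            shared.add(label)
        else:
            diag.add(label)
    return shared, diag


def test_diagnostic_partition_kras_pair(frag_by_z1, tol002da):
    report = diagnostic_ions(SPLICED, NONSPLICED, frag_by_z1, tol002da)
    shared = {i.label for i in report.shared_a}
    diag = {i.label for i in report.diagnostic_a}
    assert shared == {"b1", "b2", "b3", "b4", "b7", "y2", "y5", "y6", "y7", "y8"}
    assert diag == {"b5", "b6", "b8", "y1", "y3", "y4"}
    # independent composition oracle agrees
    oracle_shared, oracle_diag = composition_partition(SPLICED, NONSPLICED)
    assert shared == oracle_shared and diag == oracle_diag
    # symmetric partition for isomeric candidates: same labels diagnostic on
    # the B side (the compositions differ at the same cut points)
    assert {i.label for i in report.diagnostic_b} == diag


def test_diagnostic_identity_and_disjoint(frag_by_z1, tol002da):
    same = diagnostic_ions(SPLICED, SPLICED, frag_by_z1, tol002da)
    assert same.diagnostic_a == [] and same.diagnostic_b == []
    far = diagnostic_ions("GK", "WW", frag_by_z1, tol002da)
    assert far.shared_a == [] and far.shared_b == []


def test_support_verdicts(frag_by_z1, tol20ppm, tol002da):
    report = diagnostic_ions(SPLICED, NONSPLICED, frag_by_z1, tol002da)
    sp = noiseless(SPLICED, frag_by_z1)
    r = support_in_spectrum(sp, report, tol20ppm)
    assert r.support_a == len(report.diagnostic_a)
    assert r.support_b == 0
    assert r.verdict == "A"
    # a spectrum holding only shared-mass peaks is ambiguous
    shared_mz = [i.mz for i in report.shared_a]
    sp_shared = Spectrum("sh", 421.279, 2, 10.0, tuple((m, 100.0) for m in shared_mz))
    r2 = support_in_spectrum(sp_shared, report, tol20ppm)
    assert r2.verdict == "ambiguous" and r2.support_a == r2.support_b == 0


def test_support_monte_carlo(frag_by_z1, tol20ppm, tol002da):
    # spectra of A at detection 0.8: verdict A in >= 99% of seeds
    report = diagnostic_ions(SPLICED, NONSPLICED, frag_by_z1, tol002da)
    wins = 0
    for seed in range(200):
        sp = simulate_ms2(
            SPLICED,
            SpectrumSimConfig(detection_probability=0.8, mz_jitter_ppm=3.0, noise_peaks=0, seed=seed),
            frag_by_z1,
        )
        if support_in_spectrum(sp, report, tol20ppm).verdict == "A":
            wins += 1
    assert wins >= 198


def test_match_score_zero_cases(tol20ppm, frag_by_z1):
    empty = Spectrum("e", 421.279, 2, 10.0, ())
    assert match_score(empty, SPLICED, tol20ppm, frag_by_z1) == 0.0
    # spectrum with no peak near any theoretical ion scores zero
    off = Spectrum("off", 421.279, 2, 10.0, ((2000.0, 5.0), (2100.0, 5.0)))
    assert match_score(off, SPLICED, tol20ppm, frag_by_z1) == 0.0


def test_match_score_true_beats_decoy(frag_by_z1, tol20ppm):
    decoy = "VKGVAVLGV"  # shuffled, same composition
    assert sorted(decoy) == sorted(SPLICED) and decoy != SPLICED
    wins = 0
    for seed in range(200):
        sp = simulate_ms2(
            SPLICED,
            SpectrumSimConfig(detection_probability=0.9, mz_jitter_ppm=3.0, noise_peaks=10, seed=seed),
            frag_by_z1,
        )
        s_true = match_score(sp, SPLICED, tol20ppm, frag_by_z1)
        s_decoy = match_score(sp, decoy, tol20ppm, frag_by_z1)
        if s_true > s_decoy:
            wins += 1
    assert wins >= 190


def test_match_score_monotone_in_matches(frag_by_z1, tol20ppm):
    # adding a matching peak never decreases the score
    ions = theoretical_fragments(SPLICED, frag_by_z1)
    base = ((100.0, 1.0), (3000.0, 1.0))  # fixes the m/z span
    scores = []
    for k in range(0, len(ions) + 1):
        peaks = base + tuple((ions[j].mz, 100.0) for j in range(k))
        sp = Spectrum("s", 421.279, 2, 10.0, peaks)
        scores.append(match_score(sp, SPLICED, tol20ppm, frag_by_z1))
    assert scores == sorted(scores)


@pytest.mark.parametrize(
    "rta,rtb,tol,expected",
    [(10.0, 10.0, 0.5, False), (10.0, 12.0, 0.5, True), (10.0, 10.5, 0.5, False)],
)
def test_rt_resolved(rta, rtb, tol, expected):
    assert rt_resolved(rta, rtb, tol) is expected
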