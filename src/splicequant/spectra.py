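"""MS2 annotation, spectrum comparison and isobaric-candidate discrimination.

A centroided MS2 spectrum is annotated against the theoretical fragment set
of a peptidoform by greedy nearest-peak assignment within a mass tolerance.
For a pair of isobaric candidates (same residue multiset, hence the same
precursor mass), fragments are partitioned into mass-shared ions — those the
other candidate also predicts within tolerance — and diagnostic ions unique
to one candidate; counting observed diagnostic ions discriminates which
candidate a spectrum supports.  A surrogate match score (binomial tail, on
the -10*log10 scale familiar from database search engines) ranks candidate
assignments; retention-time comparison against synthetic-standard references
provides the orthogonal evidence axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .fragments import FragmentConfig, FragmentIon, theoretical_fragments
from .peptidome import Peptidoform


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 peak list with precursor information.

    ``peaks`` is a list of ``(mz, intensity)`` pairs, sorted by m/z on
    construction; ``rt`` is the retention time in minutes.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    rt: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("peak intensities must be non-negative")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)


@dataclass(frozen=True)
class Tolerance:
    """A mass-match window, relative (ppm) or absolute (Da)."""

    mode: str  # "ppm" or "Da"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("ppm", "Da"):
            raise ValueError("tolerance mode must be 'ppm' or 'Da'")
        if self.value <= 0:
            raise ValueError("tolerance value must be positive")

    def window(self, theoretical_mz: float) -> float:
        """Half-width of the acceptance window at a theoretical m/z."""
        if self.mode == "ppm":
            return theoretical_mz * self.value * 1e-6
        return self.value

    def matches(self, observed_mz: float, theoretical_mz: float) -> bool:
        return abs(observed_mz - theoretical_mz) <= self.window(theoretical_mz)


#: Instrument presets mirroring common Orbitrap search settings:
#: "QE" (Q Exactive / Q Exactive HF) and "Exploris" (Exploris 480 / Lumos).
TOLERANCE_PRESETS: dict[str, dict[str, Tolerance]] = {
    "QE": {"ms1": Tolerance("ppm", 6.0), "ms2": Tolerance("ppm", 20.0)},
    "Exploris": {"ms1": Tolerance("ppm", 5.0), "ms2": Tolerance("Da", 0.02)},
}


@dataclass
class AnnotationResult:
    matched: list[tuple[tuple[float, float], FragmentIon]]
    unmatched_ions: list[FragmentIon]
    unmatched_peaks: list[tuple[float, float]]
    matched_intensity_fraction: float
    matched_ion_count: int

    @property
    def matched_labels(self) -> set[str]:
        return {ion.label for _, ion in self.matched}


def annotate_spectrum(
    spectrum: Spectrum,
    peptidoform: Peptidoform | str,
    tol: Tolerance,
    frag_cfg: FragmentConfig = FragmentConfig(),
) -> AnnotationResult:
    """Assign spectrum peaks to theoretical fragment ions.

    Ions are processed in ascending theoretical m/z; each takes the nearest
    unused peak inside the tolerance window.  The procedure is deterministic
    and, for peaks separated by more than two windows, independent of
    processing order.
    """
    ions = theoretical_fragments(peptidoform, frag_cfg)  # sorted by mz
    mz = spectrum.mz_array
    used = np.zeros(len(mz), dtype=bool)
    matched, unmatched_ions = [], []
    for ion in ions:
        if len(mz) == 0:
            unmatched_ions.append(ion)
            continue
        w = tol.window(ion.mz)
        dist = np.abs(mz - ion.mz)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= w:
            used[j] = True
            matched.append((spectrum.peaks[j], ion))
        else:
            unmatched_ions.append(ion)
    unmatched_peaks = [p for p, u in zip(spectrum.peaks, used) if not u]
    total = float(spectrum.intensity_array.sum())
    frac = sum(p[1] for p, _ in matched) / total if total > 0 else 0.0
    return AnnotationResult(matched, unmatched_ions, unmatched_peaks, frac, len(matched))


def spectra_agreement(
    spectrum1: Spectrum,
    spectrum2: Spectrum,
    peptidoform: Peptidoform | str,
    tol: Tolerance,
    frag_cfg: FragmentConfig = FragmentConfig(),
) -> dict[str, set[str]]:
    """Compare two spectra annotated against the same peptidoform.

    An ion label is *shared* if matched in both spectra (rendered red in the
    usual mirror-plot convention) and *unique* if matched in exactly one
    (blue).
    """
    l1 = annotate_spectrum(spectrum1, peptidoform, tol, frag_cfg).matched_labels
    l2 = annotate_spectrum(spectrum2, peptidoform, tol, frag_cfg).matched_labels
    return {
        "shared_ions": l1 & l2,
        "unique_to_1": l1 - l2,
        "unique_to_2": l2 - l1,
    }


@dataclass
class DiscriminationReport:
    """Mass-shared vs diagnostic fragment partition for two candidates."""

    candidate_a: Peptidoform
    candidate_b: Peptidoform
    shared_a: list[FragmentIon]
    shared_b: list[FragmentIon]
    diagnostic_a: list[FragmentIon]
    diagnostic_b: list[FragmentIon]
    support_a: int | None = None
    support_b: int | None = None
    verdict: str | None = None
    rt_resolved: bool | None = None


def diagnostic_ions(
    candidate_a: Peptidoform | str,
    candidate_b: Peptidoform | str,
    frag_cfg: FragmentConfig = FragmentConfig(),
    tol: Tolerance = Tolerance("Da", 0.02),
) -> DiscriminationReport:
    """Partition each candidate's fragments into mass-shared and diagnostic.

    An ion of candidate A is mass-shared if any theoretical ion of B lies
    within the tolerance window, else it is diagnostic for A; symmetric for
    B.  For isobaric sequence isomers with identical fragment configs the two
    diagnostic lists have equal size.
    """
    if isinstance(candidate_a, str):
        candidate_a = Peptidoform(candidate_a)
    if isinstance(candidate_b, str):
        candidate_b = Peptidoform(candidate_b)
    ions_a = theoretical_fragments(candidate_a, frag_cfg)
    ions_b = theoretical_fragments(candidate_b, frag_cfg)

    def split(ions, others):
        other_mz = np.array([o.mz for o in others])
        shared, diag = [], []
        for ion in ions:
            if np.any(np.abs(other_mz - ion.mz) <= tol.window(ion.mz)):
                shared.append(ion)
            else:
                diag.append(ion)
        return shared, diag

    shared_a, diag_a = split(ions_a, ions_b)
    shared_b, diag_b = split(ions_b, ions_a)
    return DiscriminationReport(
        candidate_a, candidate_b, shared_a, shared_b, diag_a, diag_b
    )


def support_in_spectrum(
    spectrum: Spectrum,
    report: DiscriminationReport,
    tol: Tolerance,
) -> DiscriminationReport:
    """Count observed diagnostic ions per candidate and call a verdict.

    The verdict names the candidate with strictly more matched diagnostic
    ions; equal support (including zero) is ``ambiguous``.
    """
    mz = spectrum.mz_array

    def count(ions):
        if len(mz) == 0:
            return 0
        return sum(
            1 for ion in ions if np.min(np.abs(mz - ion.mz)) <= tol.window(ion.mz)
        )

    sa, sb = count(report.diagnostic_a), count(report.diagnostic_b)
    if sa > sb:
        verdict = "A"
    elif sb > sa:
        verdict = "B"
    else:
        verdict = "ambiguous"
    return replace(report, support_a=sa, support_b=sb, verdict=verdict)


def match_score(
    spectrum: Spectrum,
    peptidoform: Peptidoform | str,
    tol: Tolerance,
    frag_cfg: FragmentConfig = FragmentConfig(),
) -> float:
    """Surrogate ion score: -10*log10 binomial tail of the matched-ion count.

    With m theoretical ions, k of them matched, and a per-ion random-match
    probability p estimated from the spectrum's peak density (number of peaks
    times the mean tolerance window, over the observed m/z span), the score
    is ``-10*log10 P(X >= k)`` for X ~ Binomial(m, p).  Empty spectra and
    zero-match annotations score 0.  This replaces the proprietary search
    engine score; downstream filtering treats scores as an opaque column.
    """
    if len(spectrum.peaks) == 0:
        return 0.0
    ann = annotate_spectrum(spectrum, peptidoform, tol, frag_cfg)
    ions = theoretical_fragments(peptidoform, frag_cfg)
    m = len(ions)
    k = ann.matched_ion_count
    if k == 0:
        return 0.0
    mz = spectrum.mz_array
    span = float(mz[-1] - mz[0]) if len(mz) > 1 else 0.0
    mean_window = float(np.mean([2.0 * tol.window(i.mz) for i in ions]))
    if span <= 0:
        p = 0.5
    else:
        p = len(mz) * mean_window / span
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    tail = float(stats.binom.sf(k - 1, m, p))
    tail = max(tail, 1e-300)
    return max(0.0, -10.0 * math.log10(tail))


def rt_resolved(rt_a: float, rt_b: float, rt_tol: float) -> bool:
    """Whether two retention times are chromatographically distinguishable.

    Strict inequality: a separation exactly equal to the tolerance is not
    resolved.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    return abs(rt_a - rt_b) > rt_tol
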