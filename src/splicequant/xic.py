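"""Extracted ion chromatograms, peak detection and kinetics quantification.

An XIC is the summed intensity within a fixed m/z window, per MS1 scan,
plotted against retention time.  Peak presence is called by matching the
trace apex to the retention time of a synthetic-standard reference within a
tolerance and requiring a minimum signal-to-noise ratio over the median
background; the peak area is the trapezoidal integral over the contiguous
region around the apex where intensity stays at or above 5% of the apex.
Peptide-generation kinetics are assembled by repeating extract → detect →
integrate per digestion time point, averaging technical replicates and
keeping biological replicates separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = np.finfo(float).eps


@dataclass(frozen=True)
class MzWindow:
    """Inclusive m/z extraction window (e.g. 421.275-421.875 for a doubly
    charged 9-mer and its isotope envelope)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")

    def contains(self, mz: float) -> bool:
        return self.lo <= mz <= self.hi


@dataclass(frozen=True)
class ChromatogramRun:
    """Time-ordered MS1 scans of one LC-MS run.

    ``time_point_h`` is the digestion time in hours, or the string
    ``"synthetic_standard"`` for reference runs; ``scans`` is a tuple of
    ``(rt_minutes, peaks)`` with strictly increasing retention times.
    """

    run_id: str
    time_point_h: float | str
    scans: tuple[tuple[float, tuple[tuple[float, float], ...]], ...]

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")


@dataclass(frozen=True)
class XicTrace:
    """Per-scan windowed intensity, aligned with the source run's scan grid."""

    rt: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt and intensity must have equal length")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be non-negative")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.rt), np.asarray(self.intensity)


@dataclass(frozen=True)
class PeakCall:
    present: bool
    apex_rt: float | None = None
    area: float = 0.0
    bounds: tuple[float, float] | None = None
    snr: float = 0.0


def extract_xic(run: ChromatogramRun, window: MzWindow) -> XicTrace:
    """Sum peak intensities inside the window, per scan (inclusive bounds)."""
    rts, vals = [], []
    for rt, peaks in run.scans:
        rts.append(rt)
        vals.append(sum(i for m, i in peaks if window.contains(m)))
    return XicTrace(tuple(rts), tuple(vals))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima, including the endpoints."""
    n = len(y)
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0], dtype=int)
    idx = []
    for i in range(n):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] >= left and y[i] >= right:
            idx.append(i)
    return np.array(idx, dtype=int)


def _integration_bounds(y: np.ndarray, apex: int, frac: float = 0.05) -> tuple[int, int]:
    """Contiguous index range around the apex with y >= frac * y[apex]."""
    thr = frac * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] >= thr:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] >= thr:
        hi += 1
    return lo, hi


def detect_peak(
    trace: XicTrace,
    ref_rt: float,
    rt_tol: float = 0.5,
    snr_min: float = 3.0,
) -> PeakCall:
    """Call peak presence by reference-RT match and signal-to-noise.

    The apex is the highest local maximum within ``rt_tol`` minutes of the
    reference retention time (measured on the cognate synthetic peptide).
    SNR is the apex intensity over the median of the trace outside the
    integration bounds, floored at machine epsilon.  Present requires an
    apex with positive intensity and SNR >= ``snr_min``.
    """
    if rt_tol <= 0 or snr_min <= 0:
        raise ValueError("rt_tol and snr_min must be positive")
    rt, y = trace.arrays()
    if len(y) == 0 or np.all(y <= 0):
        return PeakCall(present=False)
    cand = [i for i in _local_maxima(y) if abs(rt[i] - ref_rt) <= rt_tol and y[i] > 0]
    if not cand:
        return PeakCall(present=False)
    apex = max(cand, key=lambda i: y[i])
    lo, hi = _integration_bounds(y, apex)
    outside = np.concatenate([y[:lo], y[hi + 1 :]])
    background = float(np.median(outside)) if len(outside) else 0.0
    snr = float(y[apex]) / max(background, EPS)
    if snr < snr_min:
        return PeakCall(present=False, apex_rt=float(rt[apex]), snr=snr)
    return PeakCall(
        present=True,
        apex_rt=float(rt[apex]),
        area=0.0,
        bounds=(float(rt[lo]), float(rt[hi])),
        snr=snr,
    )


def integrate_area(trace: XicTrace, call: PeakCall) -> float:
    """Trapezoidal area (intensity * minutes) between the call's bounds.

    Absent calls integrate to zero by contract; the baseline is zero.
    """
    if not call.present or call.bounds is None:
        return 0.0
    rt, y = trace.arrays()
    lo, hi = call.bounds
    mask = (rt >= lo) & (rt <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[mask], rt[mask]))


def quantify_run(
    run: ChromatogramRun,
    window: MzWindow,
    ref_rt: float,
    rt_tol: float = 0.5,
    snr_min: float = 3.0,
) -> tuple[PeakCall, float]:
    """Extract → detect → integrate for one run; returns (call, area)."""
    trace = extract_xic(run, window)
    call = detect_peak(trace, ref_rt, rt_tol, snr_min)
    return call, integrate_area(trace, call)


@dataclass
class KineticsSeries:
    """Peak areas across the digestion time course, one value per time point
    (technical replicates averaged) and per biological replicate."""

    peptide_label: str
    #: (bio_replicate, time_point_h) -> mean area over technical replicates
    areas: dict[tuple[str, float], float]

    def time_course(self, bio: str) -> dict[float, float]:
        return {
            t: a for (b, t), a in sorted(self.areas.items()) if b == bio
        }


def kinetics(
    runs: list[tuple[str, int, ChromatogramRun]],
    window: MzWindow,
    ref_rt: float,
    rt_tol: float = 0.5,
    snr_min: float = 3.0,
    peptide_label: str = "",
) -> KineticsSeries:
    """Assemble a kinetics series from labelled runs.

    ``runs`` holds ``(bio_replicate, tech_replicate, run)`` triples; each
    run's ``time_point_h`` places it on the time axis.  Duplicate
    (bio, tech, time) labels are a design error.  Absent peaks contribute
    area 0.
    """
    seen = set()
    per_slot: dict[tuple[str, float], list[float]] = {}
    for bio, tech, run in runs:
        key = (bio, tech, run.time_point_h)
        if key in seen:
            raise ValueError(f"duplicate design slot {key}")
        seen.add(key)
        _, area = quantify_run(run, window, ref_rt, rt_tol, snr_min)
        per_slot.setdefault((bio, float(run.time_point_h)), []).append(area)
    areas = {slot: float(np.mean(vals)) for slot, vals in per_slot.items()}
    return KineticsSeries(peptide_label, areas)
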