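"""Seeded generators emulating in-vitro digestion LC-MS experiments.

Every generator is a pure function of (config, seed), so each pipeline stage
can be tested against planted ground truth without instrument data.  The
emulated design mirrors a proteasome digestion kinetics study: three
biological replicates, five time points (0-4 h), three technical replicates
each (45 kinetics runs), a 20 h endpoint digest, 0 h / no-proteasome
negative controls, and synthetic-peptide reference runs with known retention
times.

Substrate consumption follows a biphasic first-order decay
``S(t) = exp(-k1*min(t, tau) - k2*max(0, t - tau))`` — proteasomes change
their catalytic dynamics over time, so a single rate constant is not
assumed.  The default calibration sets k1 = ln(4)/4 per hour (a quarter of
the substrate remains at 4 h), breakpoint tau = 4 h and k2 = k1/2 (the 20 h
endpoint leaves ~1.6% of the substrate).  Product formation is tied to
substrate consumption by one amplitude per product:
``product_i(t) = alpha_i * (1 - S(t))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import HitRow
from .fragments import FragmentConfig, precursor_mz, theoretical_fragments
from .peptidome import KRAS_2_35_G12V, Peptidoform, Substrate
from .spectra import Spectrum
from .xic import ChromatogramRun

#: Default substrate-consumption calibration.
K1_DEFAULT = math.log(4.0) / 4.0  # 1/h; S(4 h) = 0.25
TAU_DEFAULT = 4.0  # h
K2_DEFAULT = K1_DEFAULT / 2.0  # 1/h; S(20 h) ~ 0.016

#: The two isobaric target peptides of the KRAS fixture and their reference
#: retention times (minutes).  The pair is RT-resolved by 2 min, exceeding
#: the default 0.5 min matching tolerance; use `coeluting_rts` to stress the
#: discrimination logic instead.
KRAS_SPLICED = "KLVVGAVGV"  # [KL][VVGAVGV], origin 5-6/8-14
KRAS_NONSPLICED = "KLVVVGAVG"  # contiguous, origin 5-13
DEFAULT_RTS = {KRAS_SPLICED: 10.0, KRAS_NONSPLICED: 12.0}
COELUTING_RTS = {KRAS_SPLICED: 10.0, KRAS_NONSPLICED: 10.2}


def derive_seed(seed: int, *labels) -> int:
    """Deterministic sub-seed for a labelled slot, kept below 2**31."""
    h = seed & 0x7FFFFFFF
    for lab in labels:
        for ch in str(lab):
            h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h % (2**31 - 1)


@dataclass(frozen=True)
class DigestionSimConfig:
    substrate: Substrate = KRAS_2_35_G12V
    #: (peptide sequence, amplitude alpha >= 0)
    products: tuple[tuple[str, float], ...] = (
        (KRAS_SPLICED, 1.0),
        (KRAS_NONSPLICED, 1.0),
    )
    k1: float = K1_DEFAULT
    k2: float = K2_DEFAULT
    tau: float = TAU_DEFAULT
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0 or self.tau < 0:
            raise ValueError("rates and breakpoint must be non-negative")
        if any(a < 0 for _, a in self.products):
            raise ValueError("amplitudes must be non-negative")


def substrate_fraction(t: float, cfg: DigestionSimConfig) -> float:
    """Biphasic first-order survival of the substrate at time t (hours)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return math.exp(-cfg.k1 * min(t, cfg.tau) - cfg.k2 * max(0.0, t - cfg.tau))


def simulate_digestion(cfg: DigestionSimConfig) -> dict[float, dict]:
    """Deterministic product amounts per time point.

    Returns ``{t: {"substrate_fraction": S(t), "products": {seq: amount}}}``
    with ``amount = alpha * (1 - S(t))``; everything is zero-product at t=0.
    """
    out = {}
    for t in cfg.time_points:
        s = substrate_fraction(t, cfg)
        out[t] = {
            "substrate_fraction": s,
            "products": {seq: alpha * (1.0 - s) for seq, alpha in cfg.products},
        }
    return out


@dataclass(frozen=True)
class SpectrumSimConfig:
    detection_probability: float = 0.8
    mz_jitter_ppm: float = 5.0
    noise_peaks: int = 20
    noise_intensity_mean: float = 50.0
    intensity_lognorm_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_probability <= 1.0):
            raise ValueError("detection probability must lie in [0, 1]")
        if self.mz_jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")


def simulate_ms2(
    peptidoform: Peptidoform | str,
    cfg: SpectrumSimConfig = SpectrumSimConfig(),
    frag_cfg: FragmentConfig = FragmentConfig(),
    spectrum_id: str = "sim",
    rt: float = 10.0,
    precursor_charge: int = 2,
) -> Spectrum:
    """Simulate a centroided MS2 spectrum of a peptidoform.

    Each theoretical ion is detected with probability p at
    ``mz * (1 + eps)``, eps ~ Normal(0, sigma ppm), with lognormal intensity;
    noise peaks are spread uniformly over the fragment m/z range.
    """
    rng = np.random.default_rng(cfg.seed)
    ions = theoretical_fragments(peptidoform, frag_cfg)
    peaks = []
    for ion in ions:
        if rng.random() <= cfg.detection_probability:
            eps = rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6
            inten = float(rng.lognormal(math.log(1000.0), cfg.intensity_lognorm_sigma))
            peaks.append((ion.mz * (1.0 + eps), inten))
    if cfg.noise_peaks > 0 and ions:
        lo = min(i.mz for i in ions)
        hi = max(i.mz for i in ions)
        for _ in range(cfg.noise_peaks):
            peaks.append(
                (
                    float(rng.uniform(lo, hi)),
                    float(rng.exponential(cfg.noise_intensity_mean)),
                )
            )
    return Spectrum(
        id=spectrum_id,
        precursor_mz=precursor_mz(peptidoform, precursor_charge),
        precursor_charge=precursor_charge,
        rt=rt,
        peaks=tuple(peaks),
    )


@dataclass(frozen=True)
class ChromSimConfig:
    """Elution model for MS1 run simulation.

    ``elution`` maps peptide sequence to (reference RT in minutes, Gaussian
    peak width sigma in minutes, area scale per unit amount).  The noise
    floor is uniform on [0, noise_level] per scan.
    """

    elution: tuple[tuple[str, tuple[float, float, float]], ...] = (
        (KRAS_SPLICED, (DEFAULT_RTS[KRAS_SPLICED], 0.1, 1000.0)),
        (KRAS_NONSPLICED, (DEFAULT_RTS[KRAS_NONSPLICED], 0.1, 1000.0)),
    )
    rt_start: float = 5.0
    rt_end: float = 15.0
    scan_spacing: float = 0.02
    noise_level: float = 0.5
    precursor_charge: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_spacing <= 0:
            raise ValueError("scan spacing must be positive")
        for _, (_, sigma, _) in self.elution:
            if sigma <= 0:
                raise ValueError("peak width must be positive")


def simulate_run(
    run_id: str,
    time_point_h: float | str,
    amounts: dict[str, float],
    cfg: ChromSimConfig = ChromSimConfig(),
) -> ChromatogramRun:
    """Simulate the MS1 scan series of one LC-MS run.

    Each peptide with non-zero amount contributes a Gaussian elution profile
    at its precursor m/z whose integral over retention time equals
    ``amount * area_scale``; a uniform noise floor is placed inside the
    standard extraction window so extracted traces carry a realistic
    non-zero baseline for signal-to-noise estimation.
    """
    rng = np.random.default_rng(cfg.seed)
    rts = np.arange(cfg.rt_start, cfg.rt_end + cfg.scan_spacing / 2, cfg.scan_spacing)
    scans = []
    for rt in rts:
        peaks = []
        for seq, (ref_rt, sigma, scale) in cfg.elution:
            amount = amounts.get(seq, 0.0)
            if amount <= 0:
                continue
            area = amount * scale
            inten = area / (sigma * math.sqrt(2 * math.pi)) * math.exp(
                -0.5 * ((rt - ref_rt) / sigma) ** 2
            )
            if inten > 0:
                mz = precursor_mz(seq, cfg.precursor_charge)
                peaks.append((mz + rng.normal(0.0, 1e-4), float(inten)))
        if cfg.noise_level > 0:
            noise_mz = 421.5 + rng.uniform(-0.2, 0.2)
            peaks.append((float(noise_mz), float(rng.uniform(0, cfg.noise_level))))
        scans.append((float(rt), tuple(peaks)))
    return ChromatogramRun(run_id=run_id, time_point_h=time_point_h, scans=tuple(scans))


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate structure of the emulated kinetics experiment."""

    n_biological: int = 3
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    n_technical: int = 3
    include_no_proteasome_control: bool = True
    include_synthetic_standards: bool = True
    endpoint_h: float | None = 20.0

    def __post_init__(self) -> None:
        if self.n_biological < 1 or self.n_technical < 1 or not self.time_points:
            raise ValueError("design counts must be >= 1")

    @property
    def n_kinetics_runs(self) -> int:
        return self.n_biological * len(self.time_points) * self.n_technical


@dataclass
class DesignBundle:
    manifest: pd.DataFrame
    runs: dict[str, ChromatogramRun]
    digestion: dict[float, dict]
    reference_rts: dict[str, float]


def generate_design_bundle(
    design: ExperimentDesign = ExperimentDesign(),
    digestion_cfg: DigestionSimConfig | None = None,
    chrom_cfg: ChromSimConfig = ChromSimConfig(),
    seed: int = 0,
) -> DesignBundle:
    """Simulate every run of the design with a manifest enumerating them.

    One kinetics run per (biological, time point, technical) slot, plus 0 h /
    no-proteasome controls, an optional 20 h endpoint digest per biological
    replicate, and one synthetic-standard reference run per target peptide
    (pure peptide, known retention time).  Sub-seeds derive deterministically
    from the global seed and the slot labels.
    """
    digestion_cfg = digestion_cfg or DigestionSimConfig(
        time_points=tuple(design.time_points)
        + ((design.endpoint_h,) if design.endpoint_h else ())
    )
    digestion = simulate_digestion(digestion_cfg)
    ref_rts = {seq: rt for seq, (rt, _, _) in chrom_cfg.elution}

    rows = []
    runs: dict[str, ChromatogramRun] = {}

    def add_run(run_id, kind, bio, tech, t, amounts):
        sub = derive_seed(seed, run_id)
        cfg = ChromSimConfig(
            elution=chrom_cfg.elution,
            rt_start=chrom_cfg.rt_start,
            rt_end=chrom_cfg.rt_end,
            scan_spacing=chrom_cfg.scan_spacing,
            noise_level=chrom_cfg.noise_level,
            precursor_charge=chrom_cfg.precursor_charge,
            seed=sub,
        )
        runs[run_id] = simulate_run(run_id, t, amounts, cfg)
        rows.append(
            {
                "run_id": run_id,
                "kind": kind,
                "biological": bio,
                "technical": tech,
                "time_point_h": t,
            }
        )

    for b in range(1, design.n_biological + 1):
        for t in design.time_points:
            amounts = digestion[t]["products"]
            for k in range(1, design.n_technical + 1):
                add_run(f"bio{b}_t{t:g}h_tech{k}", "kinetics", f"bio{b}", k, t, amounts)
        if design.endpoint_h is not None:
            add_run(
                f"bio{b}_endpoint_{design.endpoint_h:g}h",
                "endpoint",
                f"bio{b}",
                1,
                design.endpoint_h,
                digestion[design.endpoint_h]["products"],
            )
    if design.include_no_proteasome_control:
        add_run("control_no_proteasome", "control", "control", 1, 0.0, {})
    if design.include_synthetic_standards:
        for seq, (rt, _, _) in chrom_cfg.elution:
            add_run(
                f"standard_{seq}",
                "synthetic_standard",
                "standard",
                1,
                "synthetic_standard",
                {seq: 1.0},
            )
    manifest = pd.DataFrame(
        rows, columns=["run_id", "kind", "biological", "technical", "time_point_h"]
    )
    return DesignBundle(manifest, runs, digestion, ref_rts)


def simulate_hit_table(
    n_scans: int,
    true_sequence: str = KRAS_SPLICED,
    true_category: str = "spliced",
    seed: int = 0,
    score_range: tuple[float, float] = (5.0, 80.0),
    q_range: tuple[float, float] = (0.0, 0.2),
) -> tuple[list[HitRow], dict[str, bool]]:
    """Hit tables whose filter outcome is known in closed form.

    Per scan, the true peptide is placed at rank 1 with a random score and
    q-value, and spliced/non-spliced competitors follow at controlled score
    gaps.  Returns the rows plus ``{scan_id: ground-truth accept}`` computed
    from the closed-form rule (score >= 20, q <= 0.05, and for spliced tops
    delta >= 10% over spliced / >= 30% over non-spliced competitors).
    """
    rng = np.random.default_rng(seed)
    rows: list[HitRow] = []
    truth: dict[str, bool] = {}
    for s in range(n_scans):
        scan = f"scan{s:05d}"
        top = float(rng.uniform(*score_range))
        q = float(rng.uniform(*q_range))
        gap_ss = float(rng.uniform(0.0, 50.0))  # percent of top score
        gap_sn = float(rng.uniform(0.0, 60.0))
        rows.append(HitRow(scan, 1, true_sequence, true_category, top, q))
        comp_s = top * (1.0 - gap_ss / 100.0)
        comp_n = top * (1.0 - gap_sn / 100.0)
        rows.append(HitRow(scan, 2, "SPLICEDCMP", "spliced", comp_s, q))
        rows.append(HitRow(scan, 3, "LINEARCMP", "nonspliced", comp_n, q))
        ok = top >= 20.0 and q <= 0.05
        if true_category == "spliced":
            ok = ok and gap_ss >= 10.0 and gap_sn >= 30.0
        truth[scan] = ok
    return rows, truth
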