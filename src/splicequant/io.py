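"""Readers and writers for the interchange formats the pipeline touches.

MGF (Mascot generic format) is the MS2 peak-list interchange format; MS1
scan series travel as long-form CSV (run_id, rt_min, mz, intensity); the
substrate arrives as single-record FASTA.  Configuration is one YAML file
with a section per pipeline stage; unknown keys are rejected so typos fail
loudly instead of silently using defaults.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .peptidome import Substrate
from .spectra import Spectrum
from .xic import ChromatogramRun


class ParseError(ValueError):
    """A positioned file-format error."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def read_fasta_substrate(path: str | Path, numbering_offset: int = 1) -> Substrate:
    """Read a single-record FASTA as the substrate polypeptide.

    Multiple records are an explicit error: enumeration is defined for one
    substrate at a time.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    return Substrate(
        id=rec.id, sequence=str(rec.seq).upper(), numbering_offset=numbering_offset
    )


_CHARGE_RE = re.compile(r"^(\d+)\+?$|^\+?(\d+)$")


def _parse_charge(text: str) -> int:
    text = text.strip()
    m = _CHARGE_RE.match(text)
    if not m:
        raise ValueError(f"unparseable CHARGE value {text!r}")
    return int(m.group(1) or m.group(2))


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file (keys TITLE, PEPMASS, CHARGE, RTINSECONDS).

    Retention times are converted from seconds to minutes; "2+"-style charge
    strings are accepted.
    """
    spectra = []
    in_ions = False
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_ions:
                    raise ParseError(path, line_no, "nested BEGIN IONS")
                in_ions, meta, peaks = True, {}, []
            elif line == "END IONS":
                if not in_ions:
                    raise ParseError(path, line_no, "END IONS without BEGIN IONS")
                try:
                    spectra.append(
                        Spectrum(
                            id=meta.get("TITLE", f"spectrum{len(spectra) + 1}"),
                            precursor_mz=float(meta["PEPMASS"].split()[0]),
                            precursor_charge=_parse_charge(meta.get("CHARGE", "1")),
                            rt=float(meta.get("RTINSECONDS", "0")) / 60.0,
                            peaks=tuple(peaks),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(path, line_no, f"bad spectrum block: {exc}")
                in_ions = False
            elif in_ions:
                if "=" in line:
                    key, _, value = line.partition("=")
                    meta[key.strip().upper()] = value.strip()
                else:
                    parts = line.split()
                    if len(parts) < 2:
                        raise ParseError(path, line_no, f"bad peak row {line!r}")
                    try:
                        peaks.append((float(parts[0]), float(parts[1])))
                    except ValueError:
                        raise ParseError(path, line_no, f"bad peak row {line!r}")
    if in_ions:
        raise ParseError(path, line_no, "unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; m/z printed with 5 decimals."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            fh.write(f"RTINSECONDS={sp.rt * 60.0:.3f}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.6g}\n")
            fh.write("END IONS\n")


SCANS_COLUMNS = ["run_id", "rt_min", "mz", "intensity"]


def write_scans_csv(
    runs: dict[str, ChromatogramRun] | list[ChromatogramRun], path: str | Path
) -> None:
    """Write MS1 scan series as long-form CSV (run_id, rt_min, mz, intensity).

    Scans with no peaks are written as a single zero-intensity sentinel row
    so the scan grid survives the round trip.
    """
    if isinstance(runs, dict):
        runs = list(runs.values())
    rows = []
    for run in runs:
        for rt, peaks in run.scans:
            if peaks:
                for mz, inten in peaks:
                    rows.append((run.run_id, rt, mz, inten))
            else:
                rows.append((run.run_id, rt, 0.0, 0.0))
    pd.DataFrame(rows, columns=SCANS_COLUMNS).to_csv(path, index=False)


def read_scans_csv(
    path: str | Path, time_points: dict[str, float | str] | None = None
) -> dict[str, ChromatogramRun]:
    """Read MS1 scan series CSV back into per-run scan lists.

    ``time_points`` optionally maps run_id to its digestion time label;
    unknown runs default to 0.
    """
    df = pd.read_csv(path)
    missing = set(SCANS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: scans CSV missing column(s) {sorted(missing)}")
    runs = {}
    for run_id, g in df.groupby("run_id", sort=False):
        scans = []
        for rt, gg in g.groupby("rt_min", sort=True):
            peaks = tuple(
                (float(m), float(i))
                for m, i in zip(gg["mz"], gg["intensity"])
                if not (float(m) == 0.0 and float(i) == 0.0)
            )
            scans.append((float(rt), peaks))
        tp = (time_points or {}).get(str(run_id), 0.0)
        runs[str(run_id)] = ChromatogramRun(
            run_id=str(run_id), time_point_h=tp, scans=tuple(scans)
        )
    return runs


#: Recognised config sections and keys (YAML); see each module for semantics.
CONFIG_SCHEMA: dict[str, set[str]] = {
    "enumeration": {
        "min_len",
        "max_len",
        "min_reactant_len",
        "allow_reverse",
        "max_variable_mods",
    },
    "fragments": {"series", "losses", "max_charge"},
    "tolerance": {"preset", "ms1_mode", "ms1_value", "ms2_mode", "ms2_value"},
    "filter": {
        "score_min",
        "q_max",
        "delta_spliced_spliced_pct",
        "delta_spliced_nonspliced_pct",
        "delta_combination",
    },
    "xic": {"window_lo", "window_hi", "rt_tol", "snr_min"},
    "simulation": {"seed", "detection_probability", "mz_jitter_ppm", "noise_peaks"},
}


def read_config(path: str | Path) -> dict:
    """Read the pipeline YAML config, rejecting unknown sections and keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    for section, values in data.items():
        if section not in CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config section {section!r}")
        if values is None:
            continue
        unknown = set(values) - CONFIG_SCHEMA[section]
        if unknown:
            raise ValueError(
                f"{path}: unknown key(s) {sorted(unknown)} in section {section!r}"
            )
    return data
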