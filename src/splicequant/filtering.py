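"""Peptide-spectrum-match filtering: score, q-value, rank and delta-score rules.

Search engines emit ranked candidate lists per MS2 scan.  The acceptance
rule implemented here keeps, per scan, at most the unique top-scoring hit,
subject to an ion-score cutoff, a q-value cutoff and — for spliced peptides,
whose identification competes against contiguous sequences of the same
substrate — two relative delta-score conditions: the top spliced hit must
beat the next spliced hit by at least 10% of its own score and the best
non-spliced hit by at least 30%.  Spliced identifications therefore carry a
deliberately higher evidential burden than non-spliced ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .peptidome import EnumerationConfig, Substrate, classify_sequence

REJECTION_REASONS = (
    "below_score",
    "above_q",
    "not_rank1",
    "delta_ss_fail",
    "delta_sn_fail",
    "ambiguous_tie",
)

HIT_COLUMNS = ["scan_id", "rank", "sequence", "category", "ion_score", "q_value"]


@dataclass(frozen=True)
class HitRow:
    scan_id: str
    rank: int
    sequence: str
    category: str  # "spliced" or "nonspliced"
    ion_score: float
    q_value: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.category not in ("spliced", "nonspliced"):
            raise ValueError(f"unknown category {self.category!r}")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must lie in [0, 1]")


@dataclass(frozen=True)
class FilterConfig:
    """Cutoffs for hit acceptance; all thresholds inclusive.

    ``delta_combination`` chooses how the two spliced delta conditions
    combine: ``"and"`` (stricter, default) requires both, ``"or"`` either.
    """

    score_min: float = 20.0
    q_max: float = 0.05
    delta_spliced_spliced_pct: float = 10.0
    delta_spliced_nonspliced_pct: float = 30.0
    delta_combination: str = "and"

    def __post_init__(self) -> None:
        if self.score_min < 0 or self.q_max < 0:
            raise ValueError("cutoffs must be non-negative")
        for d in (self.delta_spliced_spliced_pct, self.delta_spliced_nonspliced_pct):
            if not (0.0 <= d <= 100.0):
                raise ValueError("delta thresholds must lie in [0, 100]")
        if self.delta_combination not in ("and", "or"):
            raise ValueError("delta_combination must be 'and' or 'or'")


@dataclass(frozen=True)
class ScanDecision:
    scan_id: str
    accepted: HitRow | None
    reason: str | None  # rejection reason when accepted is None


@dataclass
class FilterResult:
    decisions: list[ScanDecision]

    @property
    def accepted(self) -> list[HitRow]:
        return [d.accepted for d in self.decisions if d.accepted is not None]

    def decision_for(self, scan_id: str) -> ScanDecision:
        for d in self.decisions:
            if d.scan_id == scan_id:
                return d
        raise KeyError(scan_id)


def delta_pct(top_score: float, other_score: float) -> float:
    """Relative score gap, in percent of the top score."""
    if top_score <= 0:
        raise ValueError("delta undefined for non-positive top score")
    return 100.0 * (top_score - other_score) / top_score


def _decide_scan(scan_id: str, hits: list[HitRow], cfg: FilterConfig) -> ScanDecision:
    top_score = max(h.ion_score for h in hits)
    top_hits = [h for h in hits if h.ion_score == top_score]
    if len(top_hits) > 1:
        return ScanDecision(scan_id, None, "ambiguous_tie")
    top = top_hits[0]
    if top_score <= 0 and len(hits) > 1:
        # percentage deltas against competitors are undefined
        return ScanDecision(scan_id, None, "below_score")
    if top.ion_score < cfg.score_min:
        return ScanDecision(scan_id, None, "below_score")
    if top.q_value > cfg.q_max:
        return ScanDecision(scan_id, None, "above_q")
    if top.category == "spliced":
        others_s = [
            h.ion_score for h in hits if h is not top and h.category == "spliced"
        ]
        others_n = [h.ion_score for h in hits if h.category == "nonspliced"]
        # a missing competitor satisfies its condition vacuously
        ok_ss = (
            not others_s
            or delta_pct(top_score, max(others_s)) >= cfg.delta_spliced_spliced_pct
        )
        ok_sn = (
            not others_n
            or delta_pct(top_score, max(others_n)) >= cfg.delta_spliced_nonspliced_pct
        )
        if cfg.delta_combination == "and":
            passed = ok_ss and ok_sn
        else:
            passed = ok_ss or ok_sn
        if not passed:
            reason = "delta_ss_fail" if not ok_ss else "delta_sn_fail"
            return ScanDecision(scan_id, None, reason)
    return ScanDecision(scan_id, top, None)


def filter_hits(hits: list[HitRow], cfg: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply the acceptance rule per scan.

    Only the unique top-scoring (rank-1) hit of a scan can be accepted; scans
    whose top score is shared are rejected as ``ambiguous_tie``.  Non-spliced
    top hits pass on score and q-value alone; spliced top hits additionally
    need the delta-score margins over the best competing spliced and
    non-spliced hits.
    """
    by_scan: dict[str, list[HitRow]] = {}
    for h in hits:
        by_scan.setdefault(h.scan_id, []).append(h)
    decisions = [
        _decide_scan(scan_id, scan_hits, cfg)
        for scan_id, scan_hits in by_scan.items()
    ]
    return FilterResult(decisions)


def read_hit_table(
    path: str | Path,
    substrate: Substrate | None = None,
    enum_cfg: EnumerationConfig | None = None,
) -> list[HitRow]:
    """Read a hit-table CSV (columns scan_id, rank, sequence, category,
    ion_score, q_value).

    The ``category`` column may be omitted if a substrate is supplied, in
    which case categories are derived by sequence classification against the
    substrate (spliced-only products become ``spliced``).
    """
    df = pd.read_csv(path, dtype={"scan_id": str}, float_precision="round_trip")
    required = set(HIT_COLUMNS) - {"category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing column(s) {sorted(missing)}")
    if "category" not in df.columns:
        if substrate is None:
            raise ValueError("hit table has no category column and no substrate given")
        cfg = enum_cfg or EnumerationConfig()
        cats = []
        for seq in df["sequence"]:
            c = classify_sequence(seq, substrate, cfg)
            cats.append("nonspliced" if c == "nonspliced" else "spliced")
        df["category"] = cats
    return [
        HitRow(
            scan_id=str(r.scan_id),
            rank=int(r.rank),
            sequence=str(r.sequence),
            category=str(r.category),
            ion_score=float(r.ion_score),
            q_value=float(r.q_value),
        )
        for r in df.itertuples()
    ]


def write_hit_table(hits: list[HitRow], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS).to_csv(
        path, index=False
    )


def write_filter_report(result: FilterResult, path: str | Path) -> None:
    """Write per-scan decisions as CSV (scan_id, accepted_sequence, reason)."""
    rows = [
        {
            "scan_id": d.scan_id,
            "accepted_sequence": d.accepted.sequence if d.accepted else "",
            "reason": d.reason or "",
        }
        for d in result.decisions
    ]
    pd.DataFrame(rows, columns=["scan_id", "accepted_sequence", "reason"]).to_csv(
        path, index=False
    )


def target_decoy_qvalues(
    scores: list[float], is_decoy: list[bool]
) -> list[float]:
    """Plumbing helper: q-values by decoy counting for synthetic runs.

    At each score threshold the FDR estimate is (#decoys >= t) / (#targets
    >= t); the q-value of a PSM is the minimum FDR over thresholds at or
    below its score.  Real searches supply engine q-values instead.
    """
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    q = [0.0] * len(scores)
    decoys = targets = 0
    fdrs = []
    for i in order:
        if is_decoy[i]:
            decoys += 1
        else:
            targets += 1
        fdrs.append((i, decoys / max(targets, 1)))
    # enforce monotonicity from the bottom of the ranking
    running_min = 1.0
    for i, fdr in reversed(fdrs):
        running_min = min(running_min, fdr)
        q[i] = running_min
    return q
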