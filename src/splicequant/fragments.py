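"""Monoisotopic mass arithmetic and theoretical b-, a- and y-ion series.

Masses are monoisotopic throughout.  b ions are N-terminal backbone fragments
(prefix residue sum plus protons), a ions are b ions minus carbon monoxide,
y ions are C-terminal fragments (suffix residue sum plus water plus protons).
Ammonia (NH3) neutral loss variants and multiply charged ions are generated
on request; the label grammar appends ``*`` for NH3 loss and ``++`` for
charge 2 (``b5``, ``y4*``, ``b3++``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .peptidome import Peptidoform, _check_alphabet

# Monoisotopic residue masses (Da), standard values to 6 decimals.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.0072765
AMMONIA = 17.026549
CARBON_MONOXIDE = 27.994915


@dataclass(frozen=True)
class FragmentIon:
    series: str  # b, a or y
    index: int
    charge: int
    loss: str | None  # None or "NH3"
    mz: float

    @property
    def label(self) -> str:
        star = "*" if self.loss == "NH3" else ""
        plus = "+" * self.charge if self.charge >= 2 else ""
        return f"{self.series}{self.index}{star}{plus}"


@dataclass(frozen=True)
class FragmentConfig:
    """Which series, neutral losses and charge states to generate.

    Water loss is off by default (only the ammonia loss is annotated in the
    reference figures); enable with ``losses=("NH3", "H2O")``.
    """

    series: tuple[str, ...] = ("b", "a", "y")
    losses: tuple[str, ...] = ("NH3",)
    max_charge: int = 2

    def __post_init__(self) -> None:
        bad = set(self.series) - {"b", "a", "y"}
        if bad:
            raise ValueError(f"unsupported series {sorted(bad)}")
        bad = set(self.losses) - {"NH3", "H2O"}
        if bad:
            raise ValueError(f"unsupported losses {sorted(bad)}")
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")


_LOSS_MASS = {"NH3": AMMONIA, "H2O": WATER}


def _as_peptidoform(peptidoform: Peptidoform | str) -> Peptidoform:
    if isinstance(peptidoform, str):
        return Peptidoform(peptidoform)
    return peptidoform


def neutral_mass(peptidoform: Peptidoform | str) -> float:
    """Monoisotopic neutral mass: residue sum + water + modification deltas.

    The empty sequence gives the mass of water (the free chain termini).
    """
    pf = _as_peptidoform(peptidoform)
    _check_alphabet(pf.sequence)
    total = WATER + sum(RESIDUE_MASS[aa] for aa in pf.sequence)
    total += sum(pf.mass_delta_at(i) for i in range(1, len(pf.sequence) + 1))
    return total


def precursor_mz(peptidoform: Peptidoform | str, charge: int) -> float:
    """m/z of the intact peptide at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass(peptidoform) + charge * PROTON) / charge


def theoretical_fragments(
    peptidoform: Peptidoform | str,
    cfg: FragmentConfig = FragmentConfig(),
) -> list[FragmentIon]:
    """All theoretical fragment ions of a peptidoform under ``cfg``.

    For a peptide of n residues each series runs over indices 1..n-1.
    Modifications on residue k shift exactly the prefix fragments with
    index >= k and the suffix fragments covering position k.
    """
    pf = _as_peptidoform(peptidoform)
    n = len(pf.sequence)
    if n < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")

    residue = [
        RESIDUE_MASS[aa] + pf.mass_delta_at(i)
        for i, aa in enumerate(pf.sequence, start=1)
    ]
    prefix = [0.0]
    for m in residue:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    losses: list[str | None] = [None] + [l for l in cfg.losses]
    ions = []
    for i in range(1, n):
        # cut after prefix of length i: b_i/a_i on the left, y_(n-i) on the right
        neutral = {}
        if "b" in cfg.series:
            neutral[("b", i)] = prefix[i]
        if "a" in cfg.series:
            neutral[("a", i)] = prefix[i] - CARBON_MONOXIDE
        if "y" in cfg.series:
            neutral[("y", n - i)] = (total - prefix[i]) + WATER
        for (series, idx), base in neutral.items():
            for loss in losses:
                m = base - (_LOSS_MASS[loss] if loss else 0.0)
                for z in range(1, cfg.max_charge + 1):
                    ions.append(
                        FragmentIon(series, idx, z, loss, (m + z * PROTON) / z)
                    )
    ions.sort(key=lambda f: (f.mz, f.series, f.index, f.charge))
    return ions
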