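"""Enumeration of non-spliced and cis-spliced peptide products of a substrate.

The proteasome degrades a polypeptide substrate into contiguous fragments
(non-spliced peptides) but can also ligate two non-contiguous fragments of the
same molecule (cis-splicing).  Ligation in N-to-C order of the parent protein
is *normal* cis-splicing; ligation with the C-terminal fragment taken from a
position N-terminal to the other reactant is *reverse* cis-splicing.  This
module enumerates every product a substrate can theoretically yield under
those rules, keeping full coordinate bookkeeping in protein numbering.

Coordinates are 1-based inclusive in full-protein numbering throughout: the
substrate carries a ``numbering_offset`` giving the protein coordinate of its
first residue (2 for a KRAS fragment starting at residue 2).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass deltas of the supported variable modifications (Da).
OXIDATION_DA = 15.994915
DEAMIDATION_DA = 0.984016

#: Residues each variable modification applies to.
VARIABLE_MOD_SITES = {
    "Oxidation": "M",
    "Deamidation": "NQ",
}
VARIABLE_MOD_DELTAS = {
    "Oxidation": OXIDATION_DA,
    "Deamidation": DEAMIDATION_DA,
}


class AlphabetError(ValueError):
    """A sequence contains a letter outside the 20 canonical amino acids."""


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise AlphabetError(
            f"non-canonical amino-acid letter(s) {sorted(bad)} in {sequence!r}"
        )


@dataclass(frozen=True)
class Substrate:
    """A substrate polypeptide with full-protein residue numbering.

    Parameters
    ----------
    id : str
        Identifier (FASTA header).
    sequence : str
        Uppercase sequence over the 20 canonical amino-acid letters.
    numbering_offset : int
        Protein coordinate of the first substrate residue (>= 1).
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("substrate sequence must be non-empty")
        _check_alphabet(self.sequence)
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first(self) -> int:
        """Protein coordinate of the first residue."""
        return self.numbering_offset

    @property
    def last(self) -> int:
        """Protein coordinate of the last residue."""
        return self.numbering_offset + len(self.sequence) - 1

    def segment(self, start: int, end: int) -> str:
        """Substring between protein coordinates ``start``..``end`` inclusive."""
        if start < self.first or end > self.last or start > end:
            raise ValueError(
                f"interval {start}-{end} outside substrate bounds "
                f"{self.first}-{self.last}"
            )
        off = self.numbering_offset
        return self.sequence[start - off : end - off + 1]


#: KRAS residues 2-35 carrying the G12V driver mutation — the substrate used
#: throughout the worked examples and the synthetic fixtures.
KRAS_2_35_G12V = Substrate(
    id="KRAS_2-35_G12V",
    sequence="TEYKLVVVGAVGVGKSALTIQLIQNHFVDEYDPT",
    numbering_offset=2,
)


@dataclass(frozen=True)
class ProductOrigin:
    """One generating event for a peptide product.

    ``kind`` is ``nonspliced`` (a contiguous substring, interval
    ``r1_start``-``r1_end``), ``cis_normal`` (two reactants ligated in
    substrate N-to-C order with at least one skipped residue) or
    ``cis_reverse`` (reactant 2 lies N-terminal to reactant 1).  All
    coordinates are 1-based inclusive protein coordinates; reactant 1 is
    always the N-terminal part of the *product*.
    """

    kind: str
    r1_start: int
    r1_end: int
    r2_start: int | None = None
    r2_end: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nonspliced", "cis_normal", "cis_reverse"):
            raise ValueError(f"unknown origin kind {self.kind!r}")
        if self.r1_start > self.r1_end:
            raise ValueError("reactant-1 interval reversed")
        if self.kind == "nonspliced":
            if self.r2_start is not None or self.r2_end is not None:
                raise ValueError("nonspliced origin has a single interval")
            return
        if self.r2_start is None or self.r2_end is None:
            raise ValueError(f"{self.kind} origin needs two intervals")
        if self.r2_start > self.r2_end:
            raise ValueError("reactant-2 interval reversed")
        if self.kind == "cis_normal" and self.r2_start < self.r1_end + 2:
            raise ValueError(
                "cis_normal requires >= 1 skipped residue between reactants"
            )
        if self.kind == "cis_reverse" and self.r2_end > self.r1_start - 1:
            raise ValueError(
                "cis_reverse requires reactant 2 strictly N-terminal to reactant 1"
            )

    def intervals(self) -> list[tuple[int, int]]:
        """Intervals in product order (reactant 1 first)."""
        if self.kind == "nonspliced":
            return [(self.r1_start, self.r1_end)]
        return [(self.r1_start, self.r1_end), (self.r2_start, self.r2_end)]

    def realize(self, substrate: Substrate) -> str:
        """Concatenate the substrate segments of this origin."""
        return "".join(substrate.segment(a, b) for a, b in self.intervals())


@dataclass(frozen=True)
class PeptideProduct:
    """A candidate product sequence with every event that generates it."""

    sequence: str
    origins: tuple[ProductOrigin, ...]

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence)
        if not self.origins:
            raise ValueError("a product needs at least one origin")
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("origins must be deduplicated")

    @property
    def is_spliced(self) -> bool:
        return all(o.kind != "nonspliced" for o in self.origins)


@dataclass(frozen=True)
class EnumerationConfig:
    """Bounds and switches for product enumeration.

    Product length defaults to 5-25 residues (brackets HLA class I ligand
    lengths and keeps enumeration desk-scale); each splice reactant must have
    at least ``min_reactant_len`` residues; ``allow_reverse`` includes
    reverse-order cis products.
    """

    min_len: int = 5
    max_len: int = 25
    min_reactant_len: int = 1
    allow_reverse: bool = True
    max_variable_mods: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.min_reactant_len < 1:
            raise ValueError("min_reactant_len must be >= 1")
        if self.max_variable_mods < 0:
            raise ValueError("max_variable_mods must be >= 0")


def _merge(events: list[tuple[str, ProductOrigin]]) -> list[PeptideProduct]:
    by_seq: dict[str, list[ProductOrigin]] = {}
    for seq, origin in events:
        by_seq.setdefault(seq, [])
        if origin not in by_seq[seq]:
            by_seq[seq].append(origin)
    return [
        PeptideProduct(seq, tuple(origins)) for seq, origins in sorted(by_seq.items())
    ]


def enumerate_nonspliced(
    substrate: Substrate, cfg: EnumerationConfig = EnumerationConfig()
) -> list[PeptideProduct]:
    """All contiguous substrings with length in ``[min_len, max_len]``.

    Sequence-identical products from different positions are merged with
    multiple origins.  A substrate shorter than ``min_len`` yields an empty
    list.
    """
    events = []
    n = len(substrate)
    off = substrate.numbering_offset
    for length in range(cfg.min_len, min(cfg.max_len, n) + 1):
        for i in range(n - length + 1):
            start = off + i
            origin = ProductOrigin("nonspliced", start, start + length - 1)
            events.append((substrate.sequence[i : i + length], origin))
    return _merge(events)


def enumerate_cis_spliced(
    substrate: Substrate, cfg: EnumerationConfig = EnumerationConfig()
) -> list[PeptideProduct]:
    """All cis-spliced products ``reactant1 + reactant2``.

    Normal order requires at least one skipped residue between the reactants
    (a zero gap would reproduce the contiguous, non-spliced case); reverse
    order requires non-overlapping reactants with reactant 2 N-terminal to
    reactant 1 — one molecule cannot contribute the same residue twice.
    """
    events: list[tuple[str, ProductOrigin]] = []
    lo, hi = substrate.first, substrate.last
    mrl = cfg.min_reactant_len

    def reactant_intervals():
        for a in range(lo, hi + 1):
            for b in range(a + mrl - 1, hi + 1):
                yield a, b

    intervals = list(reactant_intervals())
    for (a1, b1), (a2, b2) in itertools.product(intervals, repeat=2):
        total = (b1 - a1 + 1) + (b2 - a2 + 1)
        if not (cfg.min_len <= total <= cfg.max_len):
            continue
        if a2 >= b1 + 2:
            kind = "cis_normal"
        elif cfg.allow_reverse and b2 <= a1 - 1:
            kind = "cis_reverse"
        else:
            continue
        origin = ProductOrigin(kind, a1, b1, a2, b2)
        events.append((origin.realize(substrate), origin))
    return _merge(events)


def classify_sequence(
    sequence: str,
    substrate: Substrate,
    cfg: EnumerationConfig = EnumerationConfig(),
) -> str:
    """Classify a peptide as ``nonspliced``, ``spliced_only`` or ``not_producible``.

    A substring of the substrate is non-spliced regardless of any splicing
    routes that also generate it; otherwise the sequence is spliced-only if at
    least one cis event under ``cfg`` produces it.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    _check_alphabet(sequence)
    if sequence in substrate.sequence:
        return "nonspliced"
    n = len(sequence)
    lo, hi = substrate.first, substrate.last
    mrl = cfg.min_reactant_len
    # split the query at every cut point and look for both halves as substrings
    for cut in range(mrl, n - mrl + 1):
        left, right = sequence[:cut], sequence[cut:]
        for m1 in re.finditer(f"(?={re.escape(left)})", substrate.sequence):
            a1 = lo + m1.start()
            b1 = a1 + cut - 1
            for m2 in re.finditer(f"(?={re.escape(right)})", substrate.sequence):
                a2 = lo + m2.start()
                b2 = a2 + (n - cut) - 1
                if a2 >= b1 + 2:
                    return "spliced_only"
                if cfg.allow_reverse and b2 <= a1 - 1:
                    return "spliced_only"
    return "not_producible"


_ORIGIN_RE = re.compile(r"^(\d+)-(\d+)(?:/(\d+)-(\d+))?$")


def parse_origin_notation(text: str) -> ProductOrigin:
    """Parse ``"a-b"`` (non-spliced) or ``"a-b/c-d"`` (cis) coordinate labels.

    Two-interval labels are classified normal or reverse from coordinate
    order, matching the ``5-6/8-14`` convention for splice reactants.
    """
    m = _ORIGIN_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed origin notation {text!r}")
    a, b, c, d = (int(g) if g is not None else None for g in m.groups())
    if c is None:
        return ProductOrigin("nonspliced", a, b)
    kind = "cis_normal" if c >= b + 2 else "cis_reverse"
    return ProductOrigin(kind, a, b, c, d)


def format_origin(origin: ProductOrigin) -> str:
    """Inverse of :func:`parse_origin_notation`."""
    if origin.kind == "nonspliced":
        return f"{origin.r1_start}-{origin.r1_end}"
    return f"{origin.r1_start}-{origin.r1_end}/{origin.r2_start}-{origin.r2_end}"


@dataclass(frozen=True)
class Peptidoform:
    """A sequence plus a set of (1-based position, modification-name) pairs."""

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence)
        for pos, name in self.modifications:
            if name not in VARIABLE_MOD_DELTAS:
                raise ValueError(f"unknown modification {name!r}")
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(f"modification position {pos} out of range")
            if self.sequence[pos - 1] not in VARIABLE_MOD_SITES[name]:
                raise ValueError(
                    f"{name} not applicable to {self.sequence[pos - 1]}{pos}"
                )

    def mass_delta_at(self, pos: int) -> float:
        return sum(
            VARIABLE_MOD_DELTAS[name] for p, name in self.modifications if p == pos
        )


def expand_modifications(
    product: PeptideProduct | str,
    cfg: EnumerationConfig = EnumerationConfig(),
) -> list[Peptidoform]:
    """All peptidoforms with up to ``max_variable_mods`` variable modifications.

    Variable modifications are methionine oxidation (+15.994915 Da) and
    asparagine/glutamine deamidation (+0.984016 Da); the unmodified form is
    always included.
    """
    sequence = product if isinstance(product, str) else product.sequence
    sites = []
    for i, aa in enumerate(sequence, start=1):
        for name, residues in VARIABLE_MOD_SITES.items():
            if aa in residues:
                sites.append((i, name))
    forms = []
    for k in range(0, min(cfg.max_variable_mods, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            forms.append(Peptidoform(sequence, combo))
    return forms
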