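"""Peptidome enumeration: worked examples, brute-force oracle, invariants."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from splicequant import (
    EnumerationConfig,
    Peptidoform,
    Substrate,
    classify_sequence,
    enumerate_cis_spliced,
    enumerate_nonspliced,
    expand_modifications,
    format_origin,
    parse_origin_notation,
)
from splicequant.peptidome import AlphabetError, ProductOrigin

# ---------------------------------------------------------------------------
# independent brute-force oracle: double loop over all interval pairs
# ---------------------------------------------------------------------------


def brute_force_cis(substrate: Substrate, cfg: EnumerationConfig):
    """Every (interval1, interval2) event, by exhaustive index loops."""
    seq, off = substrate.sequence, substrate.numbering_offset
    n = len(seq)
    events = set()
    for i1, j1 in itertools.combinations_with_replacement(range(n), 2):
        for i2, j2 in itertools.combinations_with_replacement(range(n), 2):
            len1, len2 = j1 - i1 + 1, j2 - i2 + 1
            if len1 < cfg.min_reactant_len or len2 < cfg.min_reactant_len:
                continue
            if not (cfg.min_len <= len1 + len2 <= cfg.max_len):
                continue
            normal = i2 > j1 + 1
            reverse = cfg.allow_reverse and j2 < i1
            if not (normal or reverse):
                continue
            product = seq[i1 : j1 + 1] + seq[i2 : j2 + 1]
            events.add((product, off + i1, off + j1, off + i2, off + j2))
    return events


def events_of(products):
    out = set()
    for p in products:
        for o in p.origins:
            if o.kind == "nonspliced":
                out.add((p.sequence, o.r1_start, o.r1_end))
            else:
                out.add((p.sequence, o.r1_start, o.r1_end, o.r2_start, o.r2_end))
    return out


# ---------------------------------------------------------------------------
# worked examples (4-letter amino-acid alphabet stands in for "ABCD")
# ---------------------------------------------------------------------------


def test_nonspliced_fixed_length_substrings():
    s = Substrate("t", "ACDE")
    cfg = EnumerationConfig(min_len=3, max_len=3)
    products = enumerate_nonspliced(s, cfg)
    assert events_of(products) == {("ACD", 1, 3), ("CDE", 2, 4)}


def test_nonspliced_too_short_substrate_is_empty():
    s = Substrate("t", "ACDE")
    assert enumerate_nonspliced(s, EnumerationConfig(min_len=5, max_len=9)) == []


def test_cis_normal_fixed_length():
    s = Substrate("t", "ACDE")
    cfg = EnumerationConfig(min_len=3, max_len=3, allow_reverse=False)
    products = enumerate_cis_spliced(s, cfg)
    assert events_of(products) == {("ADE", 1, 1, 3, 4), ("ACE", 1, 2, 4, 4)}


def test_cis_reverse_fixed_length():
    s = Substrate("t", "ACDE")
    cfg = EnumerationConfig(min_len=3, max_len=3)
    seqs = {p.sequence for p in enumerate_cis_spliced(s, cfg)}
    reverse_only = seqs - {"ADE", "ACE"}
    # positional pattern CAB,DAB,DBC,CDA,CDB,BCA on alphabet A->A,B->C,C->D,D->E
    assert reverse_only == {"DAC", "EAC", "ECD", "DEA", "DEC", "CDA"}


def test_kras_contains_both_targets(kras, enum9):
    non = {p.sequence: p for p in enumerate_nonspliced(kras, enum9)}
    assert "KLVVVGAVG" in non
    assert (ProductOrigin("nonspliced", 5, 13)) in non["KLVVVGAVG"].origins
    cis = {p.sequence: p for p in enumerate_cis_spliced(kras, enum9)}
    assert "KLVVGAVGV" in cis
    assert ProductOrigin("cis_normal", 5, 6, 8, 14) in cis["KLVVGAVGV"].origins


def test_count_identity(kras):
    # non-spliced events of length L from an N-residue substrate: N - L + 1
    n = len(kras)
    for L in (5, 9, 20):
        cfg = EnumerationConfig(min_len=L, max_len=L)
        events = events_of(enumerate_nonspliced(kras, cfg))
        assert len(events) == n - L + 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACDG", min_size=3, max_size=10),
    min_len=st.integers(2, 4),
    allow_reverse=st.booleans(),
)
def test_cis_enumeration_matches_brute_force(seq, min_len, allow_reverse):
    s = Substrate("t", seq)
    cfg = EnumerationConfig(
        min_len=min_len, max_len=min_len + 3, allow_reverse=allow_reverse
    )
    products = enumerate_cis_spliced(s, cfg)
    expected = brute_force_cis(s, cfg)
    assert events_of(products) == expected
    assert {p.sequence for p in products} == {e[0] for e in expected}
    # every origin reconstructs its product sequence
    for p in products:
        for o in p.origins:
            assert o.realize(s) == p.sequence


def test_classify_sequence(kras):
    assert classify_sequence("KLVVGAVGV", kras) == "spliced_only"
    assert classify_sequence("KLVVVGAVG", kras) == "nonspliced"
    assert classify_sequence("WWWW", kras) == "not_producible"
    with pytest.raises(AlphabetError):
        classify_sequence("KLXX", kras)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACDG", min_size=5, max_size=9))
def test_classified_nonspliced_appears_in_enumeration(seq):
    s = Substrate("t", "ACDGACDGAC")
    cfg = EnumerationConfig(min_len=len(seq), max_len=len(seq))
    if classify_sequence(seq, s, cfg) == "nonspliced":
        assert seq in {p.sequence for p in enumerate_nonspliced(s, cfg)}


@pytest.mark.parametrize(
    "text,kind,fields",
    [
        ("5-13", "nonspliced", (5, 13, None, None)),
        ("5-6/8-14", "cis_normal", (5, 6, 8, 14)),
        ("8-14/5-6", "cis_reverse", (8, 14, 5, 6)),
    ],
)
def test_parse_origin_notation(text, kind, fields):
    o = parse_origin_notation(text)
    assert o.kind == kind
    assert (o.r1_start, o.r1_end, o.r2_start, o.r2_end) == fields
    assert format_origin(o) == text


def test_parse_origin_rejects_malformed():
    for bad in ("5", "a-b", "5-6/8", "5-6/8-14/1-2"):
        with pytest.raises(ValueError):
            parse_origin_notation(bad)


@pytest.mark.parametrize(
    "seq,max_mods,n_forms",
    [
        ("KLVVGAVGV", 3, 1),  # no M/N/Q site
        ("NQM", 3, 8),  # all subsets of three sites
        ("NQM", 1, 4),  # unmodified + three singletons
        ("NQM", 0, 1),
    ],
)
def test_expand_modifications_counts(seq, max_mods, n_forms):
    forms = expand_modifications(seq, EnumerationConfig(max_variable_mods=max_mods))
    assert len(forms) == n_forms
    assert Peptidoform(seq) in forms  # unmodified always included


def test_origin_validation_rejects_bad_intervals():
    with pytest.raises(ValueError):
        ProductOrigin("cis_normal", 5, 6, 7, 9)  # zero gap is non-spliced
    with pytest.raises(ValueError):
        ProductOrigin("cis_reverse", 5, 6, 6, 8)  # overlapping reactants
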