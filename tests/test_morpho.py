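"""Unit and property tests for the core morphometry module."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from palmpattern import morpho
from palmpattern.morpho import (
    EmptyMeasureError,
    MorphometryError,
    OrganExtent,
    SpecimenMorphometry,
    SummaryStat,
    localize,
    percent_of_body,
    ratio_to_one,
    read_specimen_table,
    reconstruct_extents,
    region_fraction,
    round_half_up,
    summarize,
)


def _rec(**measures):
    return SpecimenMorphometry(specimen_id="t", measures=measures)


# ---------------------------------------------------------------------------
# types


def test_summary_stat_rejects_inverted_order():
    with pytest.raises(MorphometryError):
        SummaryStat(10, 5, 7)
    with pytest.raises(MorphometryError):
        SummaryStat(5, 10, 12)
    with pytest.raises(MorphometryError):
        SummaryStat(5, 10, 7, n=0)


def test_organ_extent_requires_positive_span():
    with pytest.raises(MorphometryError):
        OrganExtent("ovary", 100, 100)
    with pytest.raises(MorphometryError):
        OrganExtent("ovary", -1, 100)


# ---------------------------------------------------------------------------
# table reading


def test_read_specimen_table_counts_and_units(tmp_path):
    csv = tmp_path / "worms.csv"
    csv.write_text(
        "specimen_id,Length,Forebody,cirrus_sac_length (mm),color\n"
        "w1,2912,429,1.0,red\n"
        "w2,3500,700,0.9,blue\n"
        "w3,4563,1005,1.438,green\n"
    )
    records = read_specimen_table(csv)
    assert len(records) == 3
    assert records[0].measures["body_length"] == 2912.0
    assert records[0].measures["forebody_length"] == 429.0
    # (mm) suffix converts to µm
    assert records[0].measures["cirrus_sac_length"] == 1000.0
    assert records[2].measures["cirrus_sac_length"] == pytest.approx(1438.0)
    # unknown column preserved
    assert records[1].extras["color"] == "blue"


def test_read_specimen_table_rejects_bad_rows(tmp_path, caplog):
    csv = tmp_path / "worms.csv"
    csv.write_text(
        "specimen_id,length,ovary_length\n"
        "ok,3000,120\n"
        "nolength,,120\n"
        "badcell,3100,abc\n"
    )
    with caplog.at_level("WARNING"):
        records = read_specimen_table(csv)
    assert [r.specimen_id for r in records] == ["ok", "badcell"]
    assert "ovary_length" not in records[1].measures
    assert any("rejected" in m for m in caplog.messages)


def test_read_specimen_table_tsv_and_sidecar(tmp_path):
    tsv = tmp_path / "worms.tsv"
    tsv.write_text("specimen_id\tlength\nw1\t3000\n")
    sidecar = tmp_path / "worms.tsv.extents.json"
    sidecar.write_text('{"w1": {"ovary": [1500, 1650]}}')
    (rec,) = read_specimen_table(tsv)
    assert rec.extents == [OrganExtent("ovary", 1500, 1650)]


# ---------------------------------------------------------------------------
# summarize


@pytest.mark.parametrize(
    "values, expected",
    [
        ([10, 20, 30], (10, 30, 20, 3)),
        ([42], (42, 42, 42, 1)),
    ],
)
def test_summarize_examples(values, expected):
    records = [_rec(body_length=3000, ovary_length=v) for v in values]
    s = summarize(records, "ovary_length")
    assert (s.min, s.max, s.mean, s.n) == expected


def test_summarize_missing_measure_errors():
    with pytest.raises(EmptyMeasureError):
        summarize([_rec(body_length=3000)], "ovary_length")


@given(st.lists(st.floats(1, 1e5), min_size=1, max_size=30), st.randoms())
def test_summarize_permutation_invariant_and_ordered(values, rnd):
    records = [_rec(body_length=1e6, egg_length=v) for v in values]
    s1 = summarize(records, "egg_length")
    shuffled = list(records)
    rnd.shuffle(shuffled)
    s2 = summarize(shuffled, "egg_length")
    assert s1 == s2
    assert s1.min <= s1.mean <= s1.max


# ---------------------------------------------------------------------------
# percentages and ratios


@pytest.mark.parametrize(
    "part, body, decimals, expected",
    [
        (1045.8, 3669.4, 1, 28.5),  # mean cirrus-sac vs mean body length
        (130.4, 3669.4, 1, 3.6),    # mean oesophagus
        (387, 1249, 0, 31),         # pre-vitelline region
        (316, 1249, 0, 25),         # vitelline field
        (536, 1249, 0, 43),         # pre-ovarian region
        (0, 1000, 2, 0.0),
    ],
)
def test_percent_of_body_printed_values(part, body, decimals, expected):
    assert percent_of_body(part, body, decimals) == expected


@pytest.mark.parametrize(
    "num, den, decimals, expected",
    [
        (312.0, 312.0, 1, 1.0),
        (4563, 377.1, 1, 12.1),
        (250, 103, 1, 2.4),
    ],
)
def test_ratio_to_one_examples(num, den, decimals, expected):
    assert ratio_to_one(num, den, decimals) == expected


def test_domain_errors():
    with pytest.raises(MorphometryError):
        percent_of_body(10, 0)
    with pytest.raises(MorphometryError):
        ratio_to_one(10, -1)


@given(
    st.integers(0, 10_000_000),
    st.integers(1, 10_000_000),
    st.integers(0, 3),
)
def test_percent_matches_exact_rational_arithmetic(part, body, decimals):
    """Half-up rounding agrees with exact Fraction arithmetic."""
    got = percent_of_body(part / 100, body / 100, decimals)
    exact = Fraction(100 * part, body)
    quantum = Fraction(1, 10**decimals)
    floor = (exact / quantum).__floor__() * quantum
    expected = floor if exact - floor < quantum / 2 else floor + quantum
    assert Fraction(str(got)) == expected


def test_round_half_up_ties():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(99.418, 1) == 99.4


# ---------------------------------------------------------------------------
# extent reconstruction


def test_reconstruct_cirrus_sac_from_reach():
    rec = _rec(body_length=3669.4, cirrus_sac_reach=3046.3, cirrus_sac_length=1045.8)
    extents, warnings = reconstruct_extents(rec)
    (cs,) = [e for e in extents if e.organ == "cirrus_sac"]
    assert cs.anterior == pytest.approx(623.1, abs=1e-6)
    assert cs.posterior == pytest.approx(1668.9, abs=1e-6)


def test_reconstruct_ventral_sucker_anchored_at_forebody():
    rec = _rec(body_length=1000, forebody_length=200, ventral_sucker_length=100)
    extents, _ = reconstruct_extents(rec)
    (vs,) = [e for e in extents if e.organ == "ventral_sucker"]
    assert (vs.anterior, vs.posterior) == (200, 300)


def test_reconstruct_clamps_small_overrun_with_warning():
    # vitellarium posterior 3686.4 > L by ~0.46% of L: clamp + warn
    rec = _rec(body_length=3669.4, pre_vitelline_region=1565.3, vitelline_range=2121.1)
    extents, warnings = reconstruct_extents(rec)
    (v,) = [e for e in extents if e.organ == "vitellarium"]
    assert v.posterior == pytest.approx(3669.4)
    assert any("clamped" in w for w in warnings)


def test_reconstruct_rejects_large_overrun():
    rec = _rec(body_length=1000, pre_vitelline_region=500, vitelline_range=700)
    extents, warnings = reconstruct_extents(rec)
    assert not [e for e in extents if e.organ == "vitellarium"]
    assert any("invalid" in w for w in warnings)


def test_reconstruct_skips_missing_anchor_with_warning():
    rec = _rec(body_length=1000, cirrus_sac_length=300)
    extents, warnings = reconstruct_extents(rec)
    assert not [e for e in extents if e.organ == "cirrus_sac"]
    assert any("cirrus_sac" in w and "missing" in w for w in warnings)


def test_reconstruct_testes_chain():
    rec = _rec(
        body_length=3669.4,
        post_testicular_region=1209.8,
        posterior_testis_length=197.0,
        distance_between_testes=140.5,
        anterior_testis_length=179.3,
    )
    extents, _ = reconstruct_extents(rec)
    by = {e.organ: e for e in extents}
    assert by["posterior_testis"].posterior == pytest.approx(3669.4 - 1209.8)
    assert by["anterior_testis"].posterior == pytest.approx(
        by["posterior_testis"].anterior - 140.5
    )


# ---------------------------------------------------------------------------
# localization


@pytest.mark.parametrize(
    "extent, parts, expected",
    [
        ((0.0, 0.125), 8, {1}),
        ((0.40, 0.47), 8, {4}),   # completely restricted to the fourth eighth
        ((0.45, 0.55), 2, {1, 2}),
        ((0.0, 1.0), 3, {1, 2, 3}),
        ((0.25, 0.5), 8, {3, 4}),  # boundary touch does not claim bin 5
    ],
)
def test_localize_bins(extent, parts, expected):
    L = 3210.0
    e = OrganExtent("x", extent[0] * L, extent[1] * L)
    assert localize(e, L, parts) == expected


@given(
    st.floats(0, 0.999),
    st.floats(1e-6, 1.0),
    st.floats(100, 10000),
)
def test_localize_eighths_refine_halves(start, span, L):
    """Eighth-bins mapped through {1..4}->1, {5..8}->2 give the half-bins."""
    end = min(1.0, start + span)
    if end <= start:
        return
    e = OrganExtent("x", start * L, end * L)
    if abs((e.anterior + 0) - L / 2) < 1e-9 or abs(e.posterior - L / 2) < 1e-9:
        return  # extents ending exactly at the midline are boundary cases
    eighths = localize(e, L, 8)
    halves = localize(e, L, 2)
    assert {1 if b <= 4 else 2 for b in eighths} == halves


@pytest.mark.parametrize(
    "extent, index, expected",
    [
        ((0.6, 0.9), 2, 1.0),
        ((0.45, 0.55), 2, 0.5),
        ((0.48, 0.60), 2, pytest.approx(10 / 12)),  # 0.8333…
        ((0.0, 0.2), 2, 0.0),
    ],
)
def test_region_fraction_halves(extent, index, expected):
    L = 1000.0
    e = OrganExtent("x", extent[0] * L, extent[1] * L)
    assert region_fraction(e, L, index, 2) == expected


@given(st.floats(0, 0.99), st.floats(0.001, 1.0), st.floats(10, 5000))
def test_region_fraction_halves_sum_to_one(start, span, L):
    end = min(1.0, start + span)
    if end <= start:
        return
    e = OrganExtent("x", start * L, end * L)
    total = region_fraction(e, L, 1, 2) + region_fraction(e, L, 2, 2)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_localize_invalid_parts():
    with pytest.raises(MorphometryError):
        localize(OrganExtent("x", 0, 10), 100, 5)
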