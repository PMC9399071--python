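"""Tests for the dichotomous key engine and morphological-group classifier."""

import random

import pytest
import yaml

from palmpattern import fixtures, keys
from palmpattern.keys import (
    CharacterStates,
    KeyValidationError,
    classify_group,
    evaluate,
    load_key,
)
from palmpattern.morpho import OrganExtent

MINIMAL_KEY = {
    "schema_version": "1",
    "key_id": "toy",
    "start": "1",
    "taxa": ["Taxon one", "Taxon two", "Taxon three"],
    "couplets": {
        "1": {
            "A": {
                "primary": [
                    {"kind": "categorical_equals", "character": "testes_arrangement",
                     "value": "tandem"}
                ],
                "taxon": "Taxon one",
            },
            "B": {
                "primary": [
                    {"kind": "categorical_equals", "character": "testes_arrangement",
                     "value": "diagonal"}
                ],
                "next": "2",
            },
        },
        "2": {
            "A": {
                "primary": [
                    {"kind": "numeric_threshold", "measure": "body_length", "op": "lt",
                     "value": 2.0, "unit": "mm"}
                ],
                "taxon": "Taxon two",
            },
            "B": {
                "primary": [
                    {"kind": "numeric_threshold", "measure": "body_length", "op": "ge",
                     "value": 2.0, "unit": "mm"}
                ],
                "taxon": "Taxon three",
            },
        },
    },
}


def _write_key(tmp_path, data, name="key.yaml"):
    p = tmp_path / name
    p.write_text(yaml.safe_dump(data))
    return p


# ---------------------------------------------------------------------------
# loading / validation


def test_packaged_key_shape(grouper_key):
    assert len(grouper_key.couplets) == 6
    assert len(grouper_key.taxa) == 7
    assert grouper_key.start == "1"
    for cid, (a, b) in grouper_key.couplets.items():
        assert (a.label, b.label) == ("A", "B")
        assert a.primary and b.primary


def test_dangling_reference_error(tmp_path):
    bad = {**MINIMAL_KEY, "couplets": {**MINIMAL_KEY["couplets"]}}
    bad["couplets"]["2"] = {
        "A": {"primary": MINIMAL_KEY["couplets"]["2"]["A"]["primary"], "next": "9"},
        "B": MINIMAL_KEY["couplets"]["2"]["B"],
    }
    with pytest.raises(KeyValidationError, match="dangling"):
        load_key(_write_key(tmp_path, bad))


def test_cycle_error(tmp_path):
    bad = yaml.safe_load(yaml.safe_dump(MINIMAL_KEY))
    bad["couplets"]["2"]["A"] = {
        "primary": bad["couplets"]["2"]["A"]["primary"],
        "next": "1",
    }
    with pytest.raises(KeyValidationError, match="cycle"):
        load_key(_write_key(tmp_path, bad))


def test_unreachable_couplet_error(tmp_path):
    bad = yaml.safe_load(yaml.safe_dump(MINIMAL_KEY))
    bad["couplets"]["3"] = bad["couplets"]["2"]
    with pytest.raises(KeyValidationError, match="unreachable"):
        load_key(_write_key(tmp_path, bad))


def test_undeclared_taxon_error(tmp_path):
    bad = yaml.safe_load(yaml.safe_dump(MINIMAL_KEY))
    bad["taxa"] = ["Taxon one", "Taxon two"]
    with pytest.raises(KeyValidationError, match="not declared"):
        load_key(_write_key(tmp_path, bad))


def test_lead_needs_primary(tmp_path):
    bad = yaml.safe_load(yaml.safe_dump(MINIMAL_KEY))
    bad["couplets"]["1"]["A"]["primary"] = []
    with pytest.raises(KeyValidationError, match="primary"):
        load_key(_write_key(tmp_path, bad))


def test_json_key_files_also_load(tmp_path):
    import json

    p = tmp_path / "key.json"
    p.write_text(json.dumps(MINIMAL_KEY))
    assert len(load_key(p).couplets) == 2


# ---------------------------------------------------------------------------
# evaluation semantics


def test_insufficient_names_missing_character(grouper_key):
    result = evaluate(grouper_key, CharacterStates())
    assert result.outcome == "insufficient"
    assert "testes_arrangement" in result.missing
    assert result.path == ()


def test_mecopera_profile_resolves(grouper_key):
    states = CharacterStates(
        measures={"body_length": 2200.0, "body_width": 550.0, "cirrus_sac_length": 750.0},
        categoricals={"testes_arrangement": "tandem"},
    )
    result = evaluate(grouper_key, states)
    assert result.taxon == "Allopodocotyle mecopera"
    assert result.path == (("1", "A"), ("2", "B"))


def test_palmi_states_resolve_with_printed_path(grouper_key, palmi):
    result = evaluate(grouper_key, fixtures.profile_to_states(palmi))
    assert result.taxon == "Allopodocotyle palmi"
    assert result.path == (("1", "B"), ("3", "B"), ("4", "B"), ("5", "B"), ("6", "B"))
    assert result.conflicts == ()


def test_key_self_consistency_all_keyed_taxa(grouper_key, keyed_taxa):
    """Each keyed taxon at its published means resolves to itself (7/7)."""
    assert len(keyed_taxa) == 7
    for name, profile in keyed_taxa.items():
        result = evaluate(grouper_key, fixtures.profile_to_states(profile))
        assert result.outcome == "taxon", (name, result)
        assert result.taxon == name


def test_ambiguous_when_both_leads_fail(grouper_key, palmi):
    states = fixtures.profile_to_states(palmi)
    # a cirrus-sac in neither printed range (1.45 mm) leaves couplet 6 undecided
    states.measures["cirrus_sac_length"] = 1450.0
    result = evaluate(grouper_key, states)
    assert result.outcome == "ambiguous"
    assert set(result.candidates) == {"Allopodocotyle palmi", "Allopodocotyle serrani"}


def test_true_unknown_pair_is_insufficient(tmp_path):
    """With lead A satisfied but B undecidable the couplet stays open."""
    key = load_key(_write_key(tmp_path, MINIMAL_KEY))
    states = CharacterStates(categoricals={"testes_arrangement": "diagonal"})
    result = evaluate(key, states)
    assert result.outcome == "insufficient"
    assert "body_length" in result.missing


def test_auxiliary_failures_recorded_not_blocking(grouper_key, keyed_taxa):
    her = keyed_taxa["Allopodocotyle heronensis"]
    result = evaluate(grouper_key, fixtures.profile_to_states(her))
    assert result.taxon == "Allopodocotyle heronensis"
    assert any("cirrus" in c for c in result.conflicts)


# ---------------------------------------------------------------------------
# evaluation properties (seeded random partial-state draws)


def _drop_random_states(states: CharacterStates, rnd: random.Random) -> CharacterStates:
    keep = lambda: rnd.random() < 0.5  # noqa: E731
    return CharacterStates(
        measures={k: v for k, v in states.measures.items() if keep()},
        categoricals={k: v for k, v in states.categoricals.items() if keep()},
        extents={k: v for k, v in states.extents.items() if keep()},
        localizations=[f for f in states.localizations if keep()],
        relations={k: v for k, v in states.relations.items() if keep()},
    )


def test_monotone_information_and_ambiguity_soundness(grouper_key, keyed_taxa):
    """Over >=1000 random partial-state draws: adding the withheld characters
    never overturns a resolved taxon, and the true taxon always lies in an
    ambiguous result's candidate set."""
    rnd = random.Random(20260930)
    profiles = list(keyed_taxa.items())
    draws = 0
    while draws < 1050:
        name, profile = profiles[draws % len(profiles)]
        full = fixtures.profile_to_states(profile)
        partial = _drop_random_states(full, rnd)
        r_partial = evaluate(grouper_key, partial)
        r_full = evaluate(grouper_key, full)
        assert r_full.taxon == name
        if r_partial.outcome == "taxon":
            # monotone: the full-information outcome must agree
            assert r_partial.taxon == name, (name, r_partial)
        elif r_partial.outcome == "ambiguous":
            assert name in r_partial.candidates, (name, r_partial)
        draws += 1


# ---------------------------------------------------------------------------
# group classifier


def test_tandem_is_group_c():
    group, missing = classify_group(
        CharacterStates(categoricals={"testes_arrangement": "tandem"})
    )
    assert (group, missing) == ("C", ())


def test_palmi_reconstruction_is_group_a():
    states = CharacterStates(
        categoricals={"testes_arrangement": "diagonal"},
        extents={
            "cirrus_sac": OrganExtent("cirrus_sac", 623.1, 1668.9),
            "ventral_sucker": OrganExtent("ventral_sucker", 717.3, 1021.4),
        },
    )
    assert classify_group(states) == ("A", ())


def test_just_overlapping_anterior_margin_is_group_b():
    states = CharacterStates(
        categoricals={"testes_arrangement": "diagonal"},
        extents={
            "cirrus_sac": OrganExtent("cirrus_sac", 400.0, 750.0),
            "ventral_sucker": OrganExtent("ventral_sucker", 700.0, 1000.0),
        },
    )
    assert classify_group(states) == ("B", ())


def test_diagonal_without_relation_is_unknown():
    group, missing = classify_group(
        CharacterStates(categoricals={"testes_arrangement": "diagonal"})
    )
    assert group is None
    assert missing
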