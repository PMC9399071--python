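"""Quantitative dichotomous identification keys.

A key is a rooted binary decision structure of numbered couplets, each with
two leads (A/B).  A lead carries *primary* predicates — the measurable clauses
that actually decide the couplet (body length, cirrus-sac length, halves/
eighths localization, organ overlap relations, categorical characters) — and
*auxiliary* predicates for the qualitative wording of the printed couplet;
auxiliary failures are recorded as conflicts but never block traversal.

Evaluation is three-valued.  A predicate over character states that are not
known evaluates to "unknown"; at a couplet:

* exactly one lead true, the other false → follow the true lead;
* both true, or both false            → ambiguous (union of both subtrees);
* anything unknown otherwise          → insufficient, naming the missing
  characters.

The last rule keeps evaluation *monotone*: supplying more character states
can refine an ambiguous or insufficient result but can never overturn a
resolved taxon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import morpho
from .morpho import OrganExtent

__all__ = [
    "Predicate",
    "Lead",
    "KeyDefinition",
    "KeyResult",
    "CharacterStates",
    "KeyValidationError",
    "load_key",
    "packaged_key_path",
    "evaluate",
    "classify_group",
    "SQUAT_RATIO_THRESHOLD",
    "CONTIGUOUS_FRACTION",
]

#: Length:width ratio below which a body counts as "squat" rather than
#: "elongate".  Chosen so the one squat grouper-infecting congener
#: (ratio about 2.2–4.2) falls below and all printed elongate ratios
#: (>= 4.3) fall above; an encoding choice, documented, not key text.
SQUAT_RATIO_THRESHOLD = 4.25

#: Testes separated by less than this fraction of body length count as
#: "almost contiguous" for auxiliary predicates.
CONTIGUOUS_FRACTION = 0.05

_UM_PER_UNIT = {"um": 1.0, "µm": 1.0, "mm": 1000.0}

_TRUE, _FALSE, _UNKNOWN = True, False, None


class KeyValidationError(ValueError):
    """Itemized key-definition validation failure."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


# ---------------------------------------------------------------------------
# Character states


def _relation_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CharacterStates:
    """Partial character-state map for one specimen or taxon.

    ``measures`` are scalar values in µm (ratios dimensionless);
    ``categoricals`` hold states such as ``testes_arrangement`` ("tandem" /
    "diagonal") or ``body_shape`` ("squat" / "elongate"); ``extents`` are
    longitudinal organ intervals; ``localizations`` are qualitative placement
    facts ``(organ, parts, bins, completeness)`` used when no extent is
    available; ``relations`` are stated organ-pair interval relations, which
    take precedence over relations computed from (possibly mean-inconsistent)
    extents.
    """

    measures: dict[str, float] = field(default_factory=dict)
    categoricals: dict[str, str] = field(default_factory=dict)
    extents: dict[str, OrganExtent] = field(default_factory=dict)
    localizations: list[tuple[str, int, frozenset[int], str]] = field(default_factory=list)
    relations: dict[tuple[str, str], str] = field(default_factory=dict)

    # -- scalar and categorical lookups (None = unknown) --------------------

    def measure(self, name: str) -> float | None:
        if name in self.measures:
            return self.measures[name]
        if name == "length_to_width_ratio":
            L, W = self.measures.get("body_length"), self.measures.get("body_width")
            if L is not None and W is not None and W > 0:
                return L / W
        return None

    def categorical(self, name: str) -> str | None:
        if name in self.categoricals:
            return self.categoricals[name]
        if name == "body_shape":
            ratio = self.measure("length_to_width_ratio")
            if ratio is not None:
                return "squat" if ratio < SQUAT_RATIO_THRESHOLD else "elongate"
        return None

    # -- localization -------------------------------------------------------

    def region_fraction(self, organ: str, index: int, parts: int) -> float | None:
        e = self.extents.get(organ)
        L = self.measures.get("body_length")
        if e is None or L is None:
            return None
        return morpho.region_fraction(e, L, index, parts)

    def localization(
        self, organ: str, parts: int, bins: frozenset[int], completeness: str
    ) -> bool | None:
        """Does the organ lie (overlaps/mainly/completely) within ``bins``?"""
        e = self.extents.get(organ)
        L = self.measures.get("body_length")
        if e is not None and L is not None:
            frac = sum(morpho.region_fraction(e, L, k, parts) for k in sorted(bins))
            if completeness == "completely":
                return frac >= 1.0 - 1e-9
            if completeness == "mainly":
                return frac > 0.5
            return frac > 0.0
        verdict = _UNKNOWN
        for f_organ, f_parts, f_bins, f_comp in self.localizations:
            if f_organ != organ:
                continue
            v = _fact_implies(f_parts, f_bins, f_comp, parts, bins, completeness)
            if v is not _UNKNOWN:
                verdict = v
                if v is _FALSE:
                    return _FALSE
        return verdict

    # -- overlap relations ---------------------------------------------------

    def relation(self, organ_a: str, organ_b: str) -> str | None:
        direct = self.relations.get(_relation_key(organ_a, organ_b))
        if direct is not None:
            return direct
        ea, eb = self.extents.get(organ_a), self.extents.get(organ_b)
        if ea is None or eb is None:
            return None
        gap = max(ea.anterior, eb.anterior) - min(ea.posterior, eb.posterior)
        if gap > 1e-9:
            return "separated"
        if gap >= -1e-9:
            return "touching"
        return "overlapping"

    def merged_with(self, other: "CharacterStates") -> "CharacterStates":
        return CharacterStates(
            measures={**self.measures, **other.measures},
            categoricals={**self.categoricals, **other.categoricals},
            extents={**self.extents, **other.extents},
            localizations=[*self.localizations, *other.localizations],
            relations={**self.relations, **other.relations},
        )


def _map_bins(bins: frozenset[int], fine: int, coarse: int) -> frozenset[int]:
    step = fine // coarse
    return frozenset((b - 1) // step + 1 for b in bins)


def _fact_implies(
    f_parts: int,
    f_bins: frozenset[int],
    f_comp: str,
    parts: int,
    bins: frozenset[int],
    completeness: str,
) -> bool | None:
    """Three-valued implication from a stored placement fact to a predicate.

    A fact ``(parts, bins, comp)`` asserts the organ is completely / mainly /
    at least partly within the union of ``bins``.  Facts on a finer grid are
    coarsened when the predicate grid divides it (eighths → halves).
    """
    if f_parts != parts:
        if f_parts % parts == 0:
            f_bins = _map_bins(f_bins, f_parts, parts)
        else:
            return _UNKNOWN
    inter = f_bins & bins
    if f_comp == "completely":
        if f_bins <= bins:
            return _TRUE  # entirely inside the asserted region ⊆ queried region
        if not inter:
            return _FALSE
        if completeness == "overlaps" and len(f_bins) == 1:
            return _TRUE
        return _UNKNOWN
    if f_comp == "mainly":
        if f_bins <= bins:
            return _TRUE if completeness in ("mainly", "overlaps") else _UNKNOWN
        if not inter:
            # more than half elsewhere: cannot be mainly/completely here
            return _FALSE if completeness in ("mainly", "completely") else _UNKNOWN
        return _UNKNOWN
    # fact "overlaps": organ demonstrably touches every bin in f_bins
    if f_comp == "overlaps":
        if inter and completeness == "overlaps":
            return _TRUE
        if not f_bins <= bins and completeness == "completely":
            return _FALSE
        return _UNKNOWN
    raise morpho.MorphometryError(f"unknown completeness {f_comp!r}")


# ---------------------------------------------------------------------------
# Predicates

_PREDICATE_KINDS = (
    "numeric_threshold",
    "numeric_range",
    "categorical_equals",
    "localization",
    "overlap_relation",
)

_OPS = {"lt": "<", "le": "<=", "gt": ">", "ge": ">="}


@dataclass(frozen=True)
class Predicate:
    kind: str
    params: tuple[tuple[str, object], ...]
    note: str = ""

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "Predicate":
        d = dict(raw)
        kind = str(d.pop("kind"))
        note = str(d.pop("note", ""))
        if kind not in _PREDICATE_KINDS:
            raise KeyValidationError([f"unknown predicate kind {kind!r}"])
        if kind == "localization":
            d["bins"] = frozenset(int(b) for b in d["bins"])  # type: ignore[arg-type]
        return cls(kind=kind, params=tuple(sorted(d.items(), key=lambda kv: kv[0])), note=note)

    @property
    def p(self) -> dict[str, object]:
        return dict(self.params)

    def characters(self) -> set[str]:
        """Character names this predicate needs (for missing-state reports)."""
        p = self.p
        if self.kind in ("numeric_threshold", "numeric_range"):
            return {str(p["measure"])}
        if self.kind == "categorical_equals":
            return {str(p["character"])}
        if self.kind == "localization":
            return {f"{p['organ']} position ({p['parts']} parts)"}
        return {f"{p['organ_a']} vs {p['organ_b']} relation"}

    def _value_um(self, raw: float, unit: str) -> float:
        if unit in ("ratio", "dimensionless", ""):
            return raw
        try:
            return raw * _UM_PER_UNIT[unit]
        except KeyError:
            raise KeyValidationError([f"unknown unit {unit!r}"]) from None

    def evaluate(self, states: CharacterStates) -> bool | None:
        p = self.p
        if self.kind == "numeric_threshold":
            v = states.measure(str(p["measure"]))
            if v is None:
                return _UNKNOWN
            bound = self._value_um(float(p["value"]), str(p.get("unit", "um")))  # type: ignore[arg-type]
            op = str(p["op"])
            return {
                "lt": v < bound,
                "le": v <= bound,
                "gt": v > bound,
                "ge": v >= bound,
            }[op]
        if self.kind == "numeric_range":
            v = states.measure(str(p["measure"]))
            if v is None:
                return _UNKNOWN
            unit = str(p.get("unit", "um"))
            lo = self._value_um(float(p["low"]), unit)  # type: ignore[arg-type]
            hi = self._value_um(float(p["high"]), unit)  # type: ignore[arg-type]
            return lo <= v <= hi
        if self.kind == "categorical_equals":
            v = states.categorical(str(p["character"]))
            if v is None:
                return _UNKNOWN
            return v == str(p["value"])
        if self.kind == "localization":
            return states.localization(
                str(p["organ"]), int(p["parts"]), p["bins"], str(p["completeness"])  # type: ignore[arg-type]
            )
        if self.kind == "overlap_relation":
            v = states.relation(str(p["organ_a"]), str(p["organ_b"]))
            if v is None:
                return _UNKNOWN
            wanted = p["relation"]
            if isinstance(wanted, (list, tuple)):
                return v in wanted
            return v == wanted
        raise AssertionError(self.kind)

    def describe(self) -> str:
        p = self.p
        if self.note:
            return self.note
        if self.kind == "numeric_threshold":
            return f"{p['measure']} {_OPS[str(p['op'])]} {p['value']} {p.get('unit', 'um')}"
        if self.kind == "numeric_range":
            return f"{p['measure']} in [{p['low']}, {p['high']}] {p.get('unit', 'um')}"
        if self.kind == "categorical_equals":
            return f"{p['character']} = {p['value']}"
        if self.kind == "localization":
            bins = ",".join(str(b) for b in sorted(p["bins"]))  # type: ignore[arg-type]
            return f"{p['organ']} {p['completeness']} in bin(s) {bins} of {p['parts']}"
        return f"{p['organ_a']} {p['relation']} {p['organ_b']}"


# ---------------------------------------------------------------------------
# Key structure


@dataclass(frozen=True)
class Lead:
    label: str  # "A" | "B"
    primary: tuple[Predicate, ...]
    auxiliary: tuple[Predicate, ...]
    next_couplet: str | None
    taxon: str | None

    @property
    def outcome(self) -> str:
        return self.taxon if self.taxon is not None else f"couplet {self.next_couplet}"


@dataclass(frozen=True)
class KeyDefinition:
    key_id: str
    title: str
    start: str
    couplets: dict[str, tuple[Lead, Lead]]
    taxa: tuple[str, ...]
    schema_version: str = "1"

    def subtree_taxa(self, lead: Lead) -> set[str]:
        if lead.taxon is not None:
            return {lead.taxon}
        out: set[str] = set()
        stack = [lead.next_couplet]
        while stack:
            cid = stack.pop()
            for lr in self.couplets[cid]:  # type: ignore[index]
                if lr.taxon is not None:
                    out.add(lr.taxon)
                else:
                    stack.append(lr.next_couplet)
        return out


def _parse_lead(cid: str, label: str, raw: Mapping[str, object], errors: list[str]) -> Lead | None:
    primary_raw = raw.get("primary")
    if not primary_raw:
        errors.append(f"couplet {cid} lead {label}: at least one primary predicate required")
        return None
    try:
        primary = tuple(Predicate.from_dict(p) for p in primary_raw)  # type: ignore[union-attr]
        auxiliary = tuple(Predicate.from_dict(p) for p in raw.get("auxiliary", ()))  # type: ignore[union-attr]
    except KeyValidationError as exc:
        errors.extend(f"couplet {cid} lead {label}: {e}" for e in exc.errors)
        return None
    nxt = raw.get("next")
    taxon = raw.get("taxon")
    if (nxt is None) == (taxon is None):
        errors.append(f"couplet {cid} lead {label}: exactly one of next/taxon required")
        return None
    return Lead(
        label=label,
        primary=primary,
        auxiliary=auxiliary,
        next_couplet=None if nxt is None else str(nxt),
        taxon=None if taxon is None else str(taxon),
    )


def load_key(path: str | Path) -> KeyDefinition:
    """Load and validate a key definition from a YAML or JSON file.

    Validation reports all problems at once: schema shape, dangling couplet
    references, cycles, unreachable couplets and undeclared terminal taxa.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise KeyValidationError(["key file must contain a mapping"])
    errors: list[str] = []
    for required in ("key_id", "start", "couplets", "taxa"):
        if required not in raw:
            errors.append(f"missing required field {required!r}")
    if errors:
        raise KeyValidationError(errors)

    couplets: dict[str, tuple[Lead, Lead]] = {}
    for cid, leads_raw in raw["couplets"].items():
        cid = str(cid)
        if not isinstance(leads_raw, dict) or set(leads_raw) != {"A", "B"}:
            errors.append(f"couplet {cid}: must have exactly leads A and B")
            continue
        a = _parse_lead(cid, "A", leads_raw["A"], errors)
        b = _parse_lead(cid, "B", leads_raw["B"], errors)
        if a and b:
            couplets[cid] = (a, b)
    if errors:
        raise KeyValidationError(errors)

    start = str(raw["start"])
    taxa = tuple(str(t) for t in raw["taxa"])
    if start not in couplets:
        errors.append(f"start couplet {start!r} not defined")

    terminal: set[str] = set()
    for cid, (a, b) in couplets.items():
        for lead in (a, b):
            if lead.next_couplet is not None and lead.next_couplet not in couplets:
                errors.append(
                    f"couplet {cid} lead {lead.label}: dangling reference to "
                    f"couplet {lead.next_couplet}"
                )
            if lead.taxon is not None:
                terminal.add(lead.taxon)
    undeclared = terminal - set(taxa)
    if undeclared:
        errors.append(f"terminal taxa not declared: {sorted(undeclared)}")
    if errors:
        raise KeyValidationError(errors)

    # cycle check (iterative DFS with colours)
    WHITE, GRAY, BLACK = 0, 1, 2
    colour = {cid: WHITE for cid in couplets}

    def visit(root: str) -> None:
        stack: list[tuple[str, int]] = [(root, 0)]
        colour[root] = GRAY
        while stack:
            cid, child_idx = stack[-1]
            nexts = [l.next_couplet for l in couplets[cid] if l.next_couplet is not None]
            if child_idx < len(nexts):
                stack[-1] = (cid, child_idx + 1)
                nxt = nexts[child_idx]
                if colour[nxt] == GRAY:
                    errors.append(f"cycle detected through couplet {nxt}")
                    return
                if colour[nxt] == WHITE:
                    colour[nxt] = GRAY
                    stack.append((nxt, 0))
            else:
                colour[cid] = BLACK
                stack.pop()

    visit(start)
    if errors:
        raise KeyValidationError(errors)
    unreachable = [cid for cid, c in colour.items() if c == WHITE]
    if unreachable:
        raise KeyValidationError(
            [f"couplet {cid} unreachable from start" for cid in sorted(unreachable)]
        )
    return KeyDefinition(
        key_id=str(raw["key_id"]),
        title=str(raw.get("title", "")),
        start=start,
        couplets=couplets,
        taxa=taxa,
        schema_version=str(raw.get("schema_version", "1")),
    )


def packaged_key_path() -> Path:
    """Path of the shipped serranid-grouper *Allopodocotyle* key."""
    return Path(__file__).parent / "data" / "allopodocotyle_serranid_key.yaml"


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class KeyResult:
    outcome: str  # "taxon" | "ambiguous" | "insufficient"
    taxon: str | None
    candidates: tuple[str, ...]
    missing: tuple[str, ...]
    path: tuple[tuple[str, str], ...]  # (couplet id, lead label)
    conflicts: tuple[str, ...]

    @property
    def resolved(self) -> bool:
        return self.outcome == "taxon"

    def to_dict(self) -> dict[str, object]:
        return {
            "outcome": self.outcome,
            "taxon": self.taxon,
            "candidates": list(self.candidates),
            "missing": list(self.missing),
            "path": [list(step) for step in self.path],
            "conflicts": list(self.conflicts),
        }

    def trace(self) -> str:
        steps = " -> ".join(f"{cid}{label}" for cid, label in self.path)
        if self.outcome == "taxon":
            head = f"resolved: {self.taxon}"
        elif self.outcome == "ambiguous":
            head = f"ambiguous: {', '.join(self.candidates)}"
        else:
            head = f"insufficient: missing {', '.join(self.missing)}"
        lines = [head, f"path: {steps or '(start)'}"]
        lines += [f"conflict: {c}" for c in self.conflicts]
        return "\n".join(lines)


def _conjunction(predicates: Sequence[Predicate], states: CharacterStates) -> bool | None:
    verdict: bool | None = _TRUE
    for pred in predicates:
        v = pred.evaluate(states)
        if v is _FALSE:
            return _FALSE
        if v is _UNKNOWN:
            verdict = _UNKNOWN
    return verdict


def _unknown_characters(predicates: Sequence[Predicate], states: CharacterStates) -> set[str]:
    missing: set[str] = set()
    for pred in predicates:
        if pred.evaluate(states) is _UNKNOWN:
            missing |= pred.characters()
    return missing


def evaluate(key: KeyDefinition, states: CharacterStates) -> KeyResult:
    """Deterministically traverse the key under a (possibly partial) state map."""
    path: list[tuple[str, str]] = []
    conflicts: list[str] = []
    cid = key.start
    while True:
        lead_a, lead_b = key.couplets[cid]
        va = _conjunction(lead_a.primary, states)
        vb = _conjunction(lead_b.primary, states)
        if va is _TRUE and vb is _FALSE:
            chosen = lead_a
        elif vb is _TRUE and va is _FALSE:
            chosen = lead_b
        elif va is not _UNKNOWN and vb is not _UNKNOWN:
            # both true or both false under fully known primaries
            candidates = sorted(key.subtree_taxa(lead_a) | key.subtree_taxa(lead_b))
            return KeyResult(
                outcome="ambiguous",
                taxon=None,
                candidates=tuple(candidates),
                missing=(),
                path=tuple(path),
                conflicts=tuple(conflicts),
            )
        else:
            missing = _unknown_characters(lead_a.primary, states) | _unknown_characters(
                lead_b.primary, states
            )
            return KeyResult(
                outcome="insufficient",
                taxon=None,
                candidates=(),
                missing=tuple(sorted(missing)),
                path=tuple(path),
                conflicts=tuple(conflicts),
            )
        path.append((cid, chosen.label))
        for aux in chosen.auxiliary:
            if aux.evaluate(states) is _FALSE:
                conflicts.append(f"couplet {cid}{chosen.label}: {aux.describe()}")
        if chosen.taxon is not None:
            return KeyResult(
                outcome="taxon",
                taxon=chosen.taxon,
                candidates=(chosen.taxon,),
                missing=(),
                path=tuple(path),
                conflicts=tuple(conflicts),
            )
        cid = chosen.next_couplet  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Morphological groups A/B/C


def classify_group(states: CharacterStates) -> tuple[str | None, tuple[str, ...]]:
    """Classify into the genus-wide morphological groups A, B or C.

    Group C: testes tandem.  For diagonal testes the cirrus-sac's relation to
    the ventral sucker decides: extending well posterior to the sucker → A;
    just overlapping its anterior margin → B.  Returns ``(group, missing)``
    where ``group`` is None when the needed characters are unknown.
    """
    arrangement = states.categorical("testes_arrangement")
    if arrangement is None:
        return None, ("testes_arrangement",)
    if arrangement == "tandem":
        return "C", ()
    direct = states.categoricals.get("cirrus_sac_vs_ventral_sucker")
    if direct is not None:
        mapping = {"well_posterior": "A", "just_overlapping_anterior_margin": "B"}
        return mapping.get(direct), () if direct in mapping else ("cirrus_sac_vs_ventral_sucker",)
    cs = states.extents.get("cirrus_sac")
    vs = states.extents.get("ventral_sucker")
    if cs is None or vs is None:
        return None, ("cirrus_sac vs ventral_sucker relation",)
    if cs.posterior > vs.posterior:
        return "A", ()
    if cs.posterior >= vs.anterior:
        return "B", ()
    return None, ("cirrus_sac vs ventral_sucker relation",)
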