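"""Packaged species profiles and reproducible synthetic generators.

The package ships transcriptions of the published comparative morphometry of
the eight grouper-infecting *Allopodocotyle* records plus *Prosorhynchus
maternus* (``data/species_profiles.json``).  Per-specimen raw data are not
redistributed; instead :func:`synth_specimens` draws synthetic worms whose
every measure lies within the published min–max range of a profile and whose
derived quantities (ratios, percentages, reconstructed organ extents) are
jointly consistent, enforced by rejection sampling.  Identical seeds give
identical output.

:func:`synth_aligned_pair` builds a seeded aligned sequence pair that differs
at exactly the specified positions — by default the six positions at which
the Indonesian and Australian *P. maternus* 28S isolates differ over their
1031-bp overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import morpho
from .keys import CharacterStates
from .morpho import OrganExtent, SpecimenMorphometry, SpeciesProfile, SummaryStat
from .seqcompare import AlignedPair

__all__ = [
    "FixtureError",
    "SynthSpec",
    "MATERNUS_28S_OVERLAP",
    "MATERNUS_28S_DIFFS",
    "catalog_path",
    "load_catalog",
    "load_fixture",
    "catalog_to_dict",
    "profile_to_states",
    "specimen_states",
    "mean_record",
    "synth_specimens",
    "write_specimens_csv",
    "synth_aligned_pair",
]


class FixtureError(ValueError):
    """Catalog lookup or synthetic-generation failure."""


#: Overlap (bp) and difference catalogue of the published 28S comparison
#: between the Indonesian *P. maternus* isolate and Australian voucher
#: material: positions within the overlap, with the base in each isolate.
MATERNUS_28S_OVERLAP = 1031
MATERNUS_28S_DIFFS: tuple[tuple[int, str, str], ...] = (
    (189, "A", "G"),
    (308, "A", "G"),
    (317, "A", "G"),
    (508, "T", "C"),
    (622, "G", "T"),
    (837, "G", "A"),
)

#: Profile statistics that are derived from other measures; used both to
#: check joint consistency of synthetic specimens and to exclude these cells
#: from direct sampling.  name -> (numerator measure, denominator measure,
#: scale).
_DERIVED_STATS = {
    "length_to_width_ratio": ("body_length", "body_width", 1.0),
    "ventral_oral_width_ratio": ("ventral_sucker_width", "oral_sucker_width", 1.0),
    "ventral_oral_length_ratio": ("ventral_sucker_length", "oral_sucker_length", 1.0),
    "oral_pharynx_width_ratio": ("oral_sucker_width", "pharynx_width", 1.0),
    "forebody_pct": ("forebody_length", "body_length", 100.0),
    "oesophagus_pct": ("oesophagus_length", "body_length", 100.0),
    "post_testicular_pct": ("post_testicular_region", "body_length", 100.0),
    "pre_vitelline_pct": ("pre_vitelline_region", "body_length", 100.0),
    "cirrus_sac_reach_pct": ("cirrus_sac_reach", "body_length", 100.0),
    "body_width_pct": ("body_width", "body_length", 100.0),
    "pre_ovarian_pct": ("pre_ovarian_region", "body_length", 100.0),
    "vitelline_pct": ("vitelline_range", "body_length", 100.0),
    "post_uterine_pct": (None, None, 100.0),  # anchor not reconstructible
}

#: slack allowed when checking a drawn specimen against a printed derived
#: statistic (printed values are rounded to one decimal).
_DERIVED_SLACK = 0.05


def catalog_path() -> Path:
    return Path(__file__).parent / "data" / "species_profiles.json"


def _stat_from_cell(cell: dict, default_prov: str) -> tuple[SummaryStat, str]:
    lo, hi = float(cell["min"]), float(cell["max"])
    mean = float(cell.get("mean", (lo + hi) / 2.0))
    prov = str(cell.get("prov", default_prov))
    return SummaryStat(lo, hi, mean), prov


def _profile_from_dict(raw: dict) -> SpeciesProfile:
    default_prov = raw.get("default_provenance", "catalog")
    stats: dict[str, SummaryStat] = {}
    provenance: dict[str, str] = {}
    for name, cell in raw["stats"].items():
        stats[name], provenance[name] = _stat_from_cell(cell, default_prov)
    variants = {
        name: _stat_from_cell(cell, "variant")[0] for name, cell in raw.get("variants", {}).items()
    }
    localizations = [
        (str(f["organ"]), int(f["parts"]), frozenset(int(b) for b in f["bins"]), str(f["completeness"]))
        for f in raw.get("localizations", [])
    ]
    relations = {
        tuple(sorted((str(r["organ_a"]), str(r["organ_b"])))): str(r["relation"])
        for r in raw.get("relations", [])
    }
    return SpeciesProfile(
        taxon=str(raw["taxon"]),
        stats=stats,
        categoricals={k: str(v) for k, v in raw.get("categoricals", {}).items()},
        localizations=localizations,
        relations=relations,  # type: ignore[arg-type]
        host=str(raw.get("host", "")),
        locality=str(raw.get("locality", "")),
        source=str(raw.get("source", "")),
        n=raw.get("n"),
        notes=str(raw.get("notes", "")),
        caveats=[str(c) for c in raw.get("caveats", [])],
        provenance=provenance,
        variants=variants,
    )


def load_catalog(path: str | Path | None = None) -> dict[str, SpeciesProfile]:
    """Load the packaged species-profile catalog (taxon -> profile)."""
    with open(path if path is not None else catalog_path()) as fh:
        raw = json.load(fh)
    profiles = [_profile_from_dict(p) for p in raw["profiles"]]
    out: dict[str, SpeciesProfile] = {}
    for p in profiles:
        if p.taxon in out:
            raise FixtureError(f"duplicate taxon {p.taxon!r} in catalog")
        out[p.taxon] = p
    return out


def load_fixture(taxon: str, path: str | Path | None = None) -> SpeciesProfile:
    """Look up one profile by name.

    Accepts the full binomial, an abbreviated genus ("A. palmi") or a bare
    epithet ("palmi"); an ambiguous or unknown name raises
    :class:`FixtureError`.
    """
    catalog = load_catalog(path)
    query = taxon.strip().lower()
    for name, profile in catalog.items():
        if name.lower() == query:
            return profile
    tokens = [t for t in query.replace(".", ". ").split() if not t.endswith(".")]
    if tokens:
        matches = [
            p
            for name, p in catalog.items()
            if all(t in (w.lower() for w in name.split()) for t in tokens)
        ]
        if matches:
            fewest = min(len(p.taxon.split()) for p in matches)
            best = [p for p in matches if len(p.taxon.split()) == fewest]
            if len(best) == 1:
                return best[0]
            raise FixtureError(f"ambiguous taxon {taxon!r}: {[p.taxon for p in best]}")
    raise FixtureError(
        f"unknown taxon {taxon!r}; available: {sorted(catalog)}"
    )


def catalog_to_dict(catalog: dict[str, SpeciesProfile]) -> dict:
    """Serialize a catalog back to the JSON structure (round-trip support)."""
    profiles = []
    for p in catalog.values():
        stats = {}
        for name, s in p.stats.items():
            cell: dict[str, object] = {"min": s.min, "max": s.max, "mean": s.mean}
            cell["prov"] = p.provenance.get(name, "catalog")
            stats[name] = cell
        profiles.append(
            {
                "taxon": p.taxon,
                "host": p.host,
                "locality": p.locality,
                "source": p.source,
                "n": p.n,
                "default_provenance": "catalog",
                "stats": stats,
                "variants": {
                    name: {"min": s.min, "max": s.max, "mean": s.mean, "prov": "variant"}
                    for name, s in p.variants.items()
                },
                "categoricals": dict(p.categoricals),
                "localizations": [
                    {"organ": o, "parts": parts, "bins": sorted(bins), "completeness": comp}
                    for o, parts, bins, comp in p.localizations
                ],
                "relations": [
                    {"organ_a": a, "organ_b": b, "relation": rel}
                    for (a, b), rel in sorted(p.relations.items())
                ],
                "caveats": list(p.caveats),
                "notes": p.notes,
            }
        )
    return {"schema_version": "1.0", "profiles": profiles}


# ---------------------------------------------------------------------------
# Character states from profiles and specimens


def mean_record(profile: SpeciesProfile) -> SpecimenMorphometry:
    """A pseudo-specimen carrying the profile's mean of every µm measure."""
    measures = {
        name: s.mean
        for name, s in profile.stats.items()
        if name not in _DERIVED_STATS
    }
    return SpecimenMorphometry(
        specimen_id=f"{profile.taxon} (means)",
        measures=measures,
        categoricals=dict(profile.categoricals),
    )


def _states(
    measures: dict[str, float],
    profile: SpeciesProfile,
    extents: Sequence[OrganExtent],
) -> CharacterStates:
    return CharacterStates(
        measures=dict(measures),
        categoricals=dict(profile.categoricals),
        extents={e.organ: e for e in extents},
        localizations=list(profile.localizations),
        relations=dict(profile.relations),
    )


def profile_to_states(profile: SpeciesProfile) -> CharacterStates:
    """Character states of a taxon instantiated at its published means.

    Scalar states are the per-measure means; organ extents are reconstructed
    from those means where the anchoring measures exist; the profile's stated
    categorical characters, placement facts and organ-pair relations are
    carried over (stated relations outrank relations recomputed from
    mean-reconstructed extents, which are not exactly joint-consistent).
    """
    rec = mean_record(profile)
    extents: list[OrganExtent] = []
    if "body_length" in rec.measures:
        extents, _ = morpho.reconstruct_extents(rec)
    measures = {name: s.mean for name, s in profile.stats.items()}
    return _states(measures, profile, extents)


def specimen_states(rec: SpecimenMorphometry, profile: SpeciesProfile) -> CharacterStates:
    """Character states derived from one specimen of a known profile.

    Numeric states come from the specimen; species-level categoricals,
    placement facts and relations come from the profile.
    """
    extents, _ = morpho.reconstruct_extents(rec)
    return _states(rec.measures, profile, extents)


# ---------------------------------------------------------------------------
# Synthetic specimens


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic specimen series."""

    taxon: str
    n: int
    seed: int
    sampling: str = "uniform"  # "uniform" | "truncated-normal"
    max_attempts_per_record: int = 20000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise FixtureError("n must be >= 1")
        if self.sampling not in ("uniform", "truncated-normal"):
            raise FixtureError(f"unknown sampling {self.sampling!r}")


def _draw_measure(rng: np.random.Generator, s: SummaryStat, sampling: str) -> float:
    if s.is_point:
        return s.min
    if sampling == "uniform":
        return float(rng.uniform(s.min, s.max))
    sd = (s.max - s.min) / 4.0
    for _ in range(1000):
        v = float(rng.normal(s.mean, sd))
        if s.min <= v <= s.max:
            return v
    return s.mean


def _derived_ok(measures: dict[str, float], profile: SpeciesProfile) -> bool:
    for name, (num, den, scale) in _DERIVED_STATS.items():
        stat = profile.stats.get(name)
        if stat is None or num is None:
            continue
        if stat.is_point:
            # printed point values are statistics of the published means,
            # not per-specimen constraints
            continue
        if num not in measures or den not in measures or measures[den] <= 0:
            continue
        value = scale * measures[num] / measures[den]
        if not (stat.min - _DERIVED_SLACK <= value <= stat.max + _DERIVED_SLACK):
            return False
    return True


def _consistent(rec: SpecimenMorphometry, profile: SpeciesProfile) -> bool:
    if rec.validate():
        return False
    m = rec.measures
    if "cirrus_sac_reach" in m and "cirrus_sac_length" in m:
        if m["cirrus_sac_length"] > m["cirrus_sac_reach"]:
            return False
    if "egg_length" in m and "egg_width" in m and m["egg_width"] > m["egg_length"]:
        return False
    if not _derived_ok(m, profile):
        return False
    _, warnings = morpho.reconstruct_extents(rec, clamp_tolerance=0.0)
    return not any(
        ("overrun" in w) or ("invalid" in w) or ("degenerate" in w) for w in warnings
    )


def synth_specimens(spec: SynthSpec, profile: SpeciesProfile | None = None) -> list[SpecimenMorphometry]:
    """Draw ``spec.n`` synthetic specimens from a profile's published ranges.

    Every sampled measure lies within the printed min–max of the profile.
    The vitelline range is derived as ``body_length - pre_vitelline_region``
    (follicles extend to the posterior extremity) and must itself fall inside
    its printed range.  A candidate is rejected unless all printed derived
    statistics (ratios, percentages) hold, part measures fit the body, and
    all reconstructible organ extents are valid.  Raises
    :class:`FixtureError` when the rejection limit is exhausted.
    """
    if profile is None:
        profile = load_fixture(spec.taxon)
    rng = np.random.default_rng(spec.seed)
    drawable = {
        name: s
        for name, s in profile.stats.items()
        if name not in _DERIVED_STATS and name != "vitelline_range"
    }
    # The vitelline range is only derivable as L - pre-vitelline when the
    # follicles are stated to reach the posterior body extremity.
    derive_vitelline = (
        "vitelline_range" in profile.stats
        and "pre_vitelline_region" in profile.stats
        and profile.categoricals.get("vitelline_posterior_extent") == "body_end"
    )
    abbrev = "".join(w[0] for w in profile.taxon.split()[:2]).upper()
    records: list[SpecimenMorphometry] = []
    for i in range(spec.n):
        for _attempt in range(spec.max_attempts_per_record):
            measures = {
                name: _draw_measure(rng, s, spec.sampling) for name, s in drawable.items()
            }
            if derive_vitelline:
                rf = measures["body_length"] - measures["pre_vitelline_region"]
                s = profile.stats["vitelline_range"]
                if not (s.min <= rf <= s.max):
                    continue
                measures["vitelline_range"] = rf
            elif "vitelline_range" in profile.stats:
                measures["vitelline_range"] = _draw_measure(
                    rng, profile.stats["vitelline_range"], spec.sampling
                )
            rec = SpecimenMorphometry(
                specimen_id=f"SYN-{abbrev}-{i + 1:03d}",
                measures=measures,
                categoricals=dict(profile.categoricals),
            )
            if _consistent(rec, profile):
                records.append(rec)
                break
        else:
            raise FixtureError(
                f"rejection limit exhausted for {profile.taxon!r} record {i + 1}: "
                "published ranges plus joint-consistency constraints (derived "
                "ratios/percentages, extent validity) admit too few specimens"
            )
    return records


def write_specimens_csv(records: Sequence[SpecimenMorphometry], path: str | Path) -> None:
    """Write records in the CSV dialect :func:`palmpattern.morpho.read_specimen_table` reads."""
    measures: list[str] = []
    for r in records:
        for m in r.measures:
            if m not in measures:
                measures.append(m)
    lines = ["specimen_id," + ",".join(measures)]
    for r in records:
        cells = [r.specimen_id] + [
            (f"{r.measures[m]:.10g}" if m in r.measures else "") for m in measures
        ]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic aligned pairs


def synth_aligned_pair(
    length: int = MATERNUS_28S_OVERLAP,
    diffs: Sequence[tuple[int, str, str]] = MATERNUS_28S_DIFFS,
    seed: int = 0,
    id_a: str = "isolate_a",
    id_b: str = "isolate_b",
) -> AlignedPair:
    """A seeded aligned pair differing exactly at the given (1-based) positions.

    The shared background sequence is random (seeded); at each ``(position,
    base_a, base_b)`` the two sequences carry the specified, unequal bases.
    """
    if length < 1:
        raise FixtureError("length must be positive")
    positions = [p for p, _, _ in diffs]
    if len(set(positions)) != len(positions):
        raise FixtureError("difference positions must be distinct")
    for pos, a, b in diffs:
        if not 1 <= pos <= length:
            raise FixtureError(f"difference position {pos} outside 1..{length}")
        if a not in "ACGT" or b not in "ACGT":
            raise FixtureError(f"invalid bases {a!r}/{b!r} at position {pos}")
        if a == b:
            raise FixtureError(f"bases at position {pos} must differ")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    background = bases[rng.integers(0, 4, size=length)]
    seq_a = background.copy()
    seq_b = background.copy()
    for pos, a, b in diffs:
        seq_a[pos - 1] = a
        seq_b[pos - 1] = b
    return AlignedPair(id_a=id_a, id_b=id_b, seq_a="".join(seq_a), seq_b="".join(seq_b))
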