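"""Core data model and arithmetic for digenean morphometrics.

Everything works in a single longitudinal coordinate system: origin at the
anterior body extremity, axis increasing posteriorly, unit µm.  Intervals are
half-open ``[anterior, posterior)`` for binning purposes, with the terminal
bin closed at the body length, so every point of the body belongs to exactly
one bin.

The measures handled here are the ones conventional descriptions of opecoelid
and bucephalid digeneans report: sucker and gonad dimensions, the forebody,
the post-testicular region, the cirrus-sac and its "reach" (distance from the
posterior body extremity to the anterior-most extent of the sac), the
pre-vitelline region and the longitudinal range of the vitelline follicles.
From those scalar measures the longitudinal extent of several organs can be
reconstructed without any image input (:func:`reconstruct_extents`).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStat",
    "OrganExtent",
    "SpecimenMorphometry",
    "SpeciesProfile",
    "MorphometryError",
    "EmptyMeasureError",
    "CANONICAL_MEASURES",
    "HEADER_ALIASES",
    "round_half_up",
    "read_specimen_table",
    "read_extent_sidecar",
    "summarize",
    "summary_table",
    "format_summary",
    "percent_of_body",
    "ratio_to_one",
    "reconstruct_extents",
    "localize",
    "region_fraction",
]


class MorphometryError(ValueError):
    """Domain error in a morphometric computation."""


class EmptyMeasureError(MorphometryError):
    """No record carries the requested measure."""


#: Canonical scalar measure names (all µm unless the name says otherwise).
CANONICAL_MEASURES = (
    "body_length",
    "body_width",
    "forebody_length",
    "oral_sucker_length",
    "oral_sucker_width",
    "ventral_sucker_length",
    "ventral_sucker_width",
    "pharynx_length",
    "pharynx_width",
    "oesophagus_length",
    "distance_between_testes",
    "anterior_testis_length",
    "anterior_testis_width",
    "posterior_testis_length",
    "posterior_testis_width",
    "post_testicular_region",
    "cirrus_sac_length",
    "cirrus_sac_width",
    "cirrus_sac_reach",
    "ovary_length",
    "ovary_width",
    "pre_vitelline_region",
    "vitelline_range",
    "pre_ovarian_region",
    "egg_length",
    "egg_width",
)

#: Header spellings accepted by :func:`read_specimen_table` (after lowercasing
#: and squashing whitespace/hyphens to underscores).  Maps alias -> canonical.
HEADER_ALIASES = {
    "length": "body_length",
    "body": "body_length",
    "total_length": "body_length",
    "width": "body_width",
    "maximum_width": "body_width",
    "forebody": "forebody_length",
    "esophagus_length": "oesophagus_length",
    "oesophagus": "oesophagus_length",
    "post_testicular": "post_testicular_region",
    "posttesticular_region": "post_testicular_region",
    "cirrus_sac": "cirrus_sac_length",
    "pre_vitelline": "pre_vitelline_region",
    "previtelline_region": "pre_vitelline_region",
    "range_of_follicles": "vitelline_range",
    "vitelline_field_length": "vitelline_range",
    "pre_ovarian": "pre_ovarian_region",
    "eggs_length": "egg_length",
    "eggs_width": "egg_width",
    "id": "specimen_id",
    "specimen": "specimen_id",
    "worm": "specimen_id",
}

#: Measures that are longitudinal part lengths and therefore cannot exceed the
#: body length of the same specimen.
_PART_MEASURES = frozenset(
    m
    for m in CANONICAL_MEASURES
    if m not in ("body_length",)
)

_MM_SUFFIX = re.compile(r"\(\s*mm\s*\)\s*$")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero at ``decimals`` places.

    Python's builtin ``round`` uses banker's rounding; printed morphometric
    percentages follow the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStat:
    """Minimum, maximum and arithmetic mean of one measure (optionally n)."""

    min: float
    max: float
    mean: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.min, self.max, self.mean)):
            raise MorphometryError("summary values must be finite")
        if not (self.min <= self.mean <= self.max):
            raise MorphometryError(
                f"summary violates min <= mean <= max: {self.min}, {self.mean}, {self.max}"
            )
        if self.n is not None and self.n < 1:
            raise MorphometryError("n must be >= 1 when present")

    @property
    def is_point(self) -> bool:
        return self.min == self.max


@dataclass(frozen=True)
class OrganExtent:
    """Longitudinal interval occupied by one organ, µm from the anterior end."""

    organ: str
    anterior: float
    posterior: float

    def __post_init__(self) -> None:
        if not (0 <= self.anterior < self.posterior):
            raise MorphometryError(
                f"invalid extent for {self.organ}: [{self.anterior}, {self.posterior}]"
            )

    @property
    def length(self) -> float:
        return self.posterior - self.anterior


@dataclass
class SpecimenMorphometry:
    """One worm's named scalar measures plus optional direct organ extents."""

    specimen_id: str
    measures: dict[str, float] = field(default_factory=dict)
    extents: list[OrganExtent] = field(default_factory=list)
    categoricals: dict[str, str] = field(default_factory=dict)
    extras: dict[str, object] = field(default_factory=dict)

    @property
    def body_length(self) -> float:
        return self.measures["body_length"]

    @property
    def body_width(self) -> float | None:
        return self.measures.get("body_width")

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty = valid)."""
        problems: list[str] = []
        L = self.measures.get("body_length")
        if L is None or L <= 0:
            problems.append(f"{self.specimen_id}: missing or non-positive body_length")
            return problems
        for name, value in self.measures.items():
            if value < 0:
                problems.append(f"{self.specimen_id}: negative {name}")
            if name in _PART_MEASURES and value > L:
                problems.append(
                    f"{self.specimen_id}: {name}={value} exceeds body_length={L}"
                )
        return problems


@dataclass
class SpeciesProfile:
    """A taxon's published summary statistics plus categorical characters.

    ``localizations`` holds qualitative longitudinal placements stated in a
    description or key ("ovary mainly in posterior half") as tuples
    ``(organ, parts, bins, completeness)``; ``relations`` holds stated interval
    relations between organ pairs ("cirrus-sac separated from vitellarium").
    ``variants`` stores alternative published values (e.g. from an original
    description) that must not be merged into the primary cells.
    """

    taxon: str
    stats: dict[str, SummaryStat]
    categoricals: dict[str, str] = field(default_factory=dict)
    localizations: list[tuple[str, int, frozenset[int], str]] = field(default_factory=list)
    relations: dict[tuple[str, str], str] = field(default_factory=dict)
    host: str = ""
    locality: str = ""
    source: str = ""
    n: int | None = None
    notes: str = ""
    caveats: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    variants: dict[str, SummaryStat] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stats:
            raise MorphometryError(f"profile {self.taxon!r} has no statistics")

    def mean(self, measure: str) -> float | None:
        s = self.stats.get(measure)
        return None if s is None else s.mean


# ---------------------------------------------------------------------------
# I/O


def _canonical_header(raw: str) -> tuple[str, float]:
    """Normalize a column header; returns (canonical name, unit factor to µm)."""
    name = raw.strip()
    factor = 1.0
    if _MM_SUFFIX.search(name):
        factor = 1000.0
        name = _MM_SUFFIX.sub("", name).strip()
    name = re.sub(r"[\s\-]+", "_", name.lower())
    name = re.sub(r"_+", "_", name).strip("_")
    name = HEADER_ALIASES.get(name, name)
    return name, factor


def read_extent_sidecar(path: str | Path) -> dict[str, list[OrganExtent]]:
    """Read a JSON sidecar mapping specimen id -> {organ: [anterior, posterior]}."""
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, list[OrganExtent]] = {}
    for specimen_id, organs in raw.items():
        out[specimen_id] = [
            OrganExtent(organ, float(a), float(p)) for organ, (a, p) in organs.items()
        ]
    return out


def read_specimen_table(
    path: str | Path,
    sep: str | None = None,
    sidecar: str | Path | None = None,
) -> list[SpecimenMorphometry]:
    """Read a CSV/TSV specimen table into :class:`SpecimenMorphometry` records.

    Headers are matched case-insensitively against the canonical measure names
    and :data:`HEADER_ALIASES`; a ``(mm)`` suffix on a header converts that
    column to µm.  Rows without a usable body length are rejected with a logged
    message; non-numeric cells in measure columns are dropped with a warning.
    Unknown columns are preserved per record under ``extras``.

    If ``sidecar`` is not given, a file named ``<table>.extents.json`` next to
    the table is used automatically when present; it supplies direct organ
    extents (needed for organs such as the ovary and the uterine coils whose
    position cannot be reconstructed from scalar measures).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if df.empty:
        raise MorphometryError(f"{path}: no data rows")

    columns: list[tuple[str, str, float]] = []  # (raw, canonical, factor)
    for raw in df.columns:
        canonical, factor = _canonical_header(str(raw))
        columns.append((str(raw), canonical, factor))

    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".extents.json")
    extent_map: dict[str, list[OrganExtent]] = {}
    if sidecar_path.exists():
        extent_map = read_extent_sidecar(sidecar_path)

    records: list[SpecimenMorphometry] = []
    for i, row in df.iterrows():
        measures: dict[str, float] = {}
        categoricals: dict[str, str] = {}
        extras: dict[str, object] = {}
        specimen_id = f"row{i + 1}"
        for raw, canonical, factor in columns:
            cell = row[raw]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            cell = str(cell).strip()
            if canonical == "specimen_id":
                specimen_id = cell
            elif canonical in CANONICAL_MEASURES:
                try:
                    measures[canonical] = float(cell) * factor
                except ValueError:
                    logger.warning(
                        "%s row %s: non-numeric %s cell %r rejected", path.name, i + 1, canonical, cell
                    )
            elif canonical == "testes_arrangement":
                categoricals[canonical] = cell.lower()
            else:
                extras[canonical] = cell
        if "body_length" not in measures:
            logger.warning("%s row %s: record rejected, missing body_length", path.name, i + 1)
            continue
        rec = SpecimenMorphometry(
            specimen_id=specimen_id,
            measures=measures,
            extents=extent_map.get(specimen_id, []),
            categoricals=categoricals,
            extras=extras,
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Summaries and derived quantities


def summarize(records: Sequence[SpecimenMorphometry], measure: str) -> SummaryStat:
    """Min/max/arithmetic-mean of ``measure`` over the records that carry it."""
    values = [r.measures[measure] for r in records if measure in r.measures]
    if not values:
        raise EmptyMeasureError(f"no record carries measure {measure!r}")
    # fsum keeps the mean exactly permutation-invariant
    return SummaryStat(min(values), max(values), math.fsum(values) / len(values), n=len(values))


def summary_table(
    records: Sequence[SpecimenMorphometry],
    measures: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Description-table-style summary (columns: measure, min, max, mean, n)."""
    if measures is None:
        seen: dict[str, None] = {}
        for r in records:
            for m in r.measures:
                seen.setdefault(m, None)
        measures = [m for m in CANONICAL_MEASURES if m in seen]
        measures += [m for m in seen if m not in CANONICAL_MEASURES]
    rows = []
    for m in measures:
        try:
            s = summarize(records, m)
        except EmptyMeasureError:
            continue
        rows.append({"measure": m, "min": s.min, "max": s.max, "mean": s.mean, "n": s.n})
    return pd.DataFrame(rows, columns=["measure", "min", "max", "mean", "n"])


def format_summary(table: pd.DataFrame, decimals: int = 1) -> str:
    """Aligned plain-text rendering of a summary table."""
    lines = [f"{'measure':<28}{'min':>10}{'max':>10}{'mean':>10}{'n':>5}"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['measure']:<28}"
            f"{round_half_up(row['min'], decimals):>10}"
            f"{round_half_up(row['max'], decimals):>10}"
            f"{round_half_up(row['mean'], decimals):>10}"
            f"{int(row['n']):>5}"
        )
    return "\n".join(lines)


def percent_of_body(part: float, body_length: float, decimals: int = 1) -> float:
    """``100 * part / body_length`` rounded half-up to ``decimals`` places."""
    if body_length <= 0:
        raise MorphometryError(f"body_length must be positive, got {body_length}")
    if part < 0:
        raise MorphometryError(f"part must be non-negative, got {part}")
    return round_half_up(100.0 * part / body_length, decimals)


def ratio_to_one(numerator: float, denominator: float, decimals: int = 1) -> float:
    """``numerator / denominator`` (denominator normalized to 1), half-up rounded."""
    if denominator <= 0:
        raise MorphometryError(f"denominator must be positive, got {denominator}")
    return round_half_up(numerator / denominator, decimals)


# ---------------------------------------------------------------------------
# Extent reconstruction and longitudinal localization

#: default tolerated reconstruction overrun, as a fraction of body length.
#: Published summary values are means over specimens and are therefore not
#: exactly joint-consistent; small overruns are clamped with a warning.
DEFAULT_CLAMP_TOLERANCE = 0.02


def reconstruct_extents(
    rec: SpecimenMorphometry,
    clamp_tolerance: float = DEFAULT_CLAMP_TOLERANCE,
) -> tuple[list[OrganExtent], list[str]]:
    """Reconstruct organ extents from scalar measures.

    Anchors (all µm): body length L, forebody length F, cirrus-sac reach R,
    post-testicular region PT, distance between testes D, pre-vitelline region
    PV and vitelline range RF.  Reconstruction rules:

    * oral sucker       ``[0, OS_length]`` (sac opens terminally at the origin)
    * ventral sucker    ``[F, F + VS_length]``
    * cirrus-sac        ``[L - R, L - R + CS_length]``
    * posterior testis  ``[L - PT - PT_length, L - PT]``
    * anterior testis   ``[pt.anterior - D - AT_length, pt.anterior - D]``
    * vitellarium       ``[PV, PV + RF]``

    Organs whose direct extents are supplied on the record (ovary, uterine
    coils, seminal receptacle, ...) are passed through unchanged and are never
    re-derived.  An extent overrunning ``[0, L]`` by at most ``clamp_tolerance
    * L`` is clamped with a warning; a larger overrun marks the organ invalid
    and it is dropped (also with a warning).  Returns ``(extents, warnings)``.
    """
    m = rec.measures
    L = m.get("body_length")
    if L is None or L <= 0:
        raise MorphometryError(f"{rec.specimen_id}: body_length required for reconstruction")
    warnings: list[str] = []
    direct = {e.organ: e for e in rec.extents}
    out: list[OrganExtent] = []

    def emit(organ: str, anterior: float, posterior: float) -> None:
        if organ in direct:
            return
        if posterior <= anterior:
            warnings.append(f"{organ}: degenerate reconstructed extent, skipped")
            return
        overrun = max(0.0, -anterior) + max(0.0, posterior - L)
        if overrun > clamp_tolerance * L:
            warnings.append(
                f"{organ}: extent [{anterior:.1f}, {posterior:.1f}] overruns body "
                f"[0, {L:.1f}] by more than {clamp_tolerance:.0%} of body length; invalid"
            )
            return
        if overrun > 0:
            warnings.append(
                f"{organ}: extent [{anterior:.1f}, {posterior:.1f}] clamped to body "
                f"[0, {L:.1f}] (overrun {overrun / L:.2%})"
            )
            anterior, posterior = max(0.0, anterior), min(L, posterior)
        out.append(OrganExtent(organ, anterior, posterior))

    def need(organ: str, *names: str) -> list[float] | None:
        missing = [n for n in names if n not in m]
        if missing:
            if organ not in direct:
                warnings.append(f"{organ}: skipped, missing {', '.join(missing)}")
            return None
        return [m[n] for n in names]

    if (v := need("oral_sucker", "oral_sucker_length")) is not None:
        emit("oral_sucker", 0.0, v[0])
    if (v := need("ventral_sucker", "forebody_length", "ventral_sucker_length")) is not None:
        emit("ventral_sucker", v[0], v[0] + v[1])
    if (v := need("cirrus_sac", "cirrus_sac_reach", "cirrus_sac_length")) is not None:
        emit("cirrus_sac", L - v[0], L - v[0] + v[1])
    pt_extent = None
    if (v := need("posterior_testis", "post_testicular_region", "posterior_testis_length")) is not None:
        emit("posterior_testis", L - v[0] - v[1], L - v[0])
        pt_extent = (L - v[0] - v[1], L - v[0])
    if pt_extent is not None:
        if (v := need("anterior_testis", "distance_between_testes", "anterior_testis_length")) is not None:
            emit("anterior_testis", pt_extent[0] - v[0] - v[1], pt_extent[0] - v[0])
    elif "anterior_testis" not in direct:
        warnings.append("anterior_testis: skipped, posterior testis not reconstructible")
    if (v := need("vitellarium", "pre_vitelline_region", "vitelline_range")) is not None:
        emit("vitellarium", v[0], v[0] + v[1])

    for organ, e in direct.items():
        if e.posterior > L + 1e-9:
            warnings.append(f"{organ}: direct extent exceeds body length; invalid")
            continue
        out.append(e)
    return out, warnings


def localize(extent: OrganExtent, body_length: float, parts: int) -> set[int]:
    """1-based indices of the longitudinal bins the extent overlaps.

    The body is divided into ``parts`` equal bins (2 halves, 3 thirds or 8
    eighths), numbered from the anterior end.  A bin is reported when the
    intersection with the extent has strictly positive length, so an extent
    that merely touches a bin boundary does not claim the neighbouring bin.
    """
    if parts not in (2, 3, 8):
        raise MorphometryError(f"parts must be 2, 3 or 8, got {parts}")
    if body_length <= 0:
        raise MorphometryError("body_length must be positive")
    bins: set[int] = set()
    for k in range(1, parts + 1):
        lo = (k - 1) * body_length / parts
        hi = k * body_length / parts
        if min(extent.posterior, hi) - max(extent.anterior, lo) > 0:
            bins.add(k)
    return bins


def region_fraction(
    extent: OrganExtent, body_length: float, index: int, parts: int = 2
) -> float:
    """Fraction of the extent's length lying in body region ``index``/``parts``.

    Supports the key predicates "completely in" (fraction equal to 1) and
    "mainly in" (fraction greater than 0.5).
    """
    if body_length <= 0:
        raise MorphometryError("body_length must be positive")
    if not 1 <= index <= parts:
        raise MorphometryError(f"region index {index} out of range for parts={parts}")
    length = extent.posterior - extent.anterior
    if length <= 0:
        raise MorphometryError("zero-length extent has no region fraction")
    lo = (index - 1) * body_length / parts
    hi = index * body_length / parts
    inter = max(0.0, min(extent.posterior, hi) - max(extent.anterior, lo))
    return inter / length
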