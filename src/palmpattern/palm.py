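"""Palm-pattern construction and deterministic SVG rendering.

A Palm pattern reduces a digenean worm to a black bar for its total body
length with coloured bars marking the longitudinal position and range of each
organ.  Two plate modes are supported:

* ``absolute`` — every body is drawn at the same axis length, so organ
  *positions* are directly comparable; the bodies carry gridlines dividing
  them into eighths.
* ``relative`` — bodies are drawn to true scale, centre-aligned on a shared
  transverse axis, so interspecific *size* is directly comparable; a µm scale
  bar is drawn instead of gridlines.

Rendering is byte-deterministic: fixed element ordering, fixed numeric
formatting, no timestamps or generated ids.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence
from xml.sax.saxutils import escape

from .morpho import MorphometryError, OrganExtent

__all__ = [
    "PalmBar",
    "PalmPattern",
    "PatternPlate",
    "PlateConfig",
    "ORGAN_PALETTE",
    "build_pattern",
    "layout",
    "render_svg",
]

#: Default organ palette, in anterior-to-posterior legend order.
ORGAN_PALETTE = {
    "oral_sucker": "royalblue",
    "ventral_sucker": "steelblue",
    "cirrus_sac": "crimson",
    "uterine_coils": "orange",
    "ovary": "gold",
    "anterior_testis": "forestgreen",
    "posterior_testis": "darkgreen",
    "vitellarium": "saddlebrown",
}

_FALLBACK_COLORS = (
    "mediumpurple",
    "teal",
    "indianred",
    "olive",
    "slategray",
    "palevioletred",
)


def _fallback_color(organ: str) -> str:
    """Deterministic colour for organs absent from the palette."""
    digest = hashlib.sha256(organ.encode("utf-8")).digest()
    return _FALLBACK_COLORS[digest[0] % len(_FALLBACK_COLORS)]


@dataclass(frozen=True)
class PalmBar:
    organ: str
    start_fraction: float
    end_fraction: float
    color: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_fraction < self.end_fraction <= 1.0):
            raise MorphometryError(
                f"bar fractions out of range for {self.organ}: "
                f"[{self.start_fraction}, {self.end_fraction}]"
            )


@dataclass(frozen=True)
class PalmPattern:
    taxon: str
    body_length: float
    bars: tuple[PalmBar, ...]

    #: fixed internal gridline fractions (eighth boundaries)
    @property
    def gridlines(self) -> tuple[float, ...]:
        return tuple(k / 8 for k in range(1, 8))


@dataclass(frozen=True)
class PlateConfig:
    """Canvas geometry in abstract drawing units (rendered as SVG px)."""

    axis_length: float = 400.0  # drawn length of the longest/standard body
    column_width: float = 90.0
    column_gap: float = 30.0
    body_bar_width: float = 10.0
    organ_bar_width: float = 8.0
    lane_gap: float = 3.0
    margin: float = 40.0
    label_height: float = 28.0
    legend_row_height: float = 16.0
    scale_bar_um: float = 300.0
    font_size: float = 11.0
    orientation: str = "vertical"  # anterior at top

    def __post_init__(self) -> None:
        if self.axis_length <= 0 or self.column_width <= 0:
            raise MorphometryError("plate canvas must have positive size")


@dataclass(frozen=True)
class PatternPlate:
    patterns: tuple[PalmPattern, ...]
    mode: str  # "absolute" | "relative"
    config: PlateConfig = field(default_factory=PlateConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise MorphometryError(f"unknown plate mode {self.mode!r}")
        if not self.patterns:
            raise MorphometryError("plate needs at least one pattern")

    def drawn_length(self, pattern: PalmPattern) -> float:
        """Drawn axis length of one body, in drawing units."""
        if self.mode == "absolute":
            return self.config.axis_length
        longest = max(p.body_length for p in self.patterns)
        return self.config.axis_length * pattern.body_length / longest

    @property
    def units_per_um(self) -> float:
        """Drawing units per µm (relative mode scale)."""
        longest = max(p.body_length for p in self.patterns)
        return self.config.axis_length / longest


def build_pattern(
    extents: Sequence[OrganExtent],
    body_length: float,
    taxon: str,
    palette: dict[str, str] | None = None,
) -> PalmPattern:
    """Normalize organ extents by body length into a Palm pattern.

    Each extent becomes a bar with ``start_fraction = anterior / L`` and
    ``end_fraction = posterior / L``; extents must already be valid for this
    body length (validate/clamp upstream with
    :func:`palmpattern.morpho.reconstruct_extents`).
    """
    if body_length <= 0:
        raise MorphometryError("body_length must be positive")
    palette = dict(ORGAN_PALETTE if palette is None else palette)
    bars = []
    for e in extents:
        if e.anterior < 0 or e.posterior > body_length + 1e-9:
            raise MorphometryError(
                f"extent for {e.organ} exceeds body [0, {body_length}]; "
                "validate extents before building a pattern"
            )
        color = palette.get(e.organ, _fallback_color(e.organ))
        bars.append(
            PalmBar(
                organ=e.organ,
                start_fraction=e.anterior / body_length,
                end_fraction=min(1.0, e.posterior / body_length),
                color=color,
            )
        )
    bars.sort(key=lambda b: (b.start_fraction, b.end_fraction, b.organ))
    return PalmPattern(taxon=taxon, body_length=body_length, bars=tuple(bars))


def layout(
    patterns: Sequence[PalmPattern],
    mode: str,
    config: PlateConfig | None = None,
) -> PatternPlate:
    """Arrange patterns into a plate; column order is the input order."""
    return PatternPlate(
        patterns=tuple(patterns),
        mode=mode,
        config=config if config is not None else PlateConfig(),
    )


def _assign_lanes(bars: Sequence[PalmBar]) -> list[int]:
    """Greedy interval colouring: overlapping bars get parallel lanes."""
    lane_ends: list[float] = []
    assignment: list[int] = []
    for bar in bars:  # bars are sorted by start_fraction
        for lane, end in enumerate(lane_ends):
            if bar.start_fraction >= end - 1e-12:
                lane_ends[lane] = bar.end_fraction
                assignment.append(lane)
                break
        else:
            lane_ends.append(bar.end_fraction)
            assignment.append(len(lane_ends) - 1)
    return assignment


def _fmt(x: float) -> str:
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return "0" if s == "-0" else s


def render_svg(plate: PatternPlate, config: PlateConfig | None = None) -> str:
    """Render a plate as an SVG 1.1 document (text, byte-deterministic)."""
    cfg = config if config is not None else plate.config
    if config is not None and config is not plate.config:
        plate = replace(plate, config=config)
    n = len(plate.patterns)
    legend_organs = [o for o in ORGAN_PALETTE if any(
        b.organ == o for p in plate.patterns for b in p.bars
    )]
    extra = sorted({b.organ for p in plate.patterns for b in p.bars} - set(ORGAN_PALETTE))
    legend_organs += extra
    legend_height = cfg.legend_row_height * len(legend_organs) + 10
    width = 2 * cfg.margin + n * cfg.column_width + (n - 1) * cfg.column_gap
    height = (
        2 * cfg.margin + cfg.label_height + cfg.axis_length + 30 + legend_height
    )
    body_top = cfg.margin + cfg.label_height
    mid_y = body_top + cfg.axis_length / 2

    el: list[str] = []
    el.append('<?xml version="1.0" encoding="UTF-8"?>')
    el.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    el.append(f'<rect x="0" y="0" width="{_fmt(width)}" height="{_fmt(height)}" fill="white"/>')

    for i, pattern in enumerate(plate.patterns):
        col_x = cfg.margin + i * (cfg.column_width + cfg.column_gap)
        drawn = plate.drawn_length(pattern)
        top = body_top if plate.mode == "absolute" else mid_y - drawn / 2
        body_x = col_x

        label = escape(pattern.taxon)
        el.append(
            f'<text x="{_fmt(col_x)}" y="{_fmt(cfg.margin + cfg.font_size)}" '
            f'font-family="sans-serif" font-style="italic" '
            f'font-size="{_fmt(cfg.font_size)}">{label}</text>'
        )
        el.append(
            f'<rect x="{_fmt(body_x)}" y="{_fmt(top)}" '
            f'width="{_fmt(cfg.body_bar_width)}" height="{_fmt(drawn)}" fill="black"/>'
        )
        if plate.mode == "absolute":
            for frac in pattern.gridlines:
                y = top + frac * drawn
                el.append(
                    f'<line x1="{_fmt(body_x - 4)}" y1="{_fmt(y)}" '
                    f'x2="{_fmt(col_x + cfg.column_width)}" y2="{_fmt(y)}" '
                    f'stroke="lightgray" stroke-width="0.75"/>'
                )
        lanes = _assign_lanes(pattern.bars)
        for bar, lane in zip(pattern.bars, lanes):
            x = body_x + cfg.body_bar_width + cfg.lane_gap + lane * (
                cfg.organ_bar_width + cfg.lane_gap
            )
            y = top + bar.start_fraction * drawn
            h = (bar.end_fraction - bar.start_fraction) * drawn
            el.append(
                f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(cfg.organ_bar_width)}" '
                f'height="{_fmt(h)}" fill="{bar.color}"><title>{escape(bar.organ)}</title></rect>'
            )

    if plate.mode == "relative":
        el.append(
            f'<line x1="{_fmt(cfg.margin - 10)}" y1="{_fmt(mid_y)}" '
            f'x2="{_fmt(width - cfg.margin + 10)}" y2="{_fmt(mid_y)}" '
            f'stroke="gray" stroke-width="0.5" stroke-dasharray="4 3"/>'
        )
        bar_len = cfg.scale_bar_um * plate.units_per_um
        sb_y = body_top + cfg.axis_length + 15
        el.append(
            f'<line x1="{_fmt(cfg.margin)}" y1="{_fmt(sb_y)}" '
            f'x2="{_fmt(cfg.margin + bar_len)}" y2="{_fmt(sb_y)}" '
            f'stroke="black" stroke-width="2" id="scalebar"/>'
        )
        el.append(
            f'<text x="{_fmt(cfg.margin)}" y="{_fmt(sb_y + cfg.font_size + 2)}" '
            f'font-family="sans-serif" font-size="{_fmt(cfg.font_size)}">'
            f'{_fmt(cfg.scale_bar_um)} µm</text>'
        )

    legend_top = body_top + cfg.axis_length + 40
    for j, organ in enumerate(legend_organs):
        color = ORGAN_PALETTE.get(organ, _fallback_color(organ))
        y = legend_top + j * cfg.legend_row_height
        el.append(
            f'<rect x="{_fmt(cfg.margin)}" y="{_fmt(y)}" width="12" height="10" '
            f'fill="{color}"/>'
        )
        el.append(
            f'<text x="{_fmt(cfg.margin + 18)}" y="{_fmt(y + 9)}" '
            f'font-family="sans-serif" font-size="{_fmt(cfg.font_size)}">'
            f'{escape(organ.replace("_", " "))}</text>'
        )
    el.append("</svg>")
    return "\n".join(el) + "\n"
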