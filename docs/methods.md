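# Methods

## Scope and model

`palmpattern` operates on the morphometric vocabulary of digenean species
descriptions: a worm is reduced to a one-dimensional longitudinal axis with
origin at the anterior body extremity, increasing posteriorly, in µm.  Every
organ position is an interval `[anterior, posterior]` on that axis.  Three
conventions fix the geometry:

* Intervals are half-open `[anterior, posterior)` for binning, with the
  terminal bin closed at the body length `L`, so each point of the body
  belongs to exactly one bin when the body is divided into halves, thirds or
  eighths.
* The oral sucker is anchored at 0.  Many opecoelids open the mouth
  ventro-subterminally, but no sub-terminal offset is quantified in routine
  descriptions, so the offset defaults to 0 and can be overridden per record
  through a direct extent.
* "Forebody" is measured to the anterior margin of the ventral sucker (the
  alternative — to the sucker's centre — is not distinguishable from
  published tables; the anterior-margin convention makes the ventral sucker's
  reconstructed anterior edge equal the forebody length exactly).

### Extent reconstruction

Descriptions rarely publish organ extents directly, but several follow from
the scalar measures they do publish.  With `L` body length, `F` forebody,
`R` cirrus-sac reach (distance from the posterior body extremity to the
sac's anterior-most extent), `PT` post-testicular region, `D` distance
between testes, `PV` pre-vitelline region and `RF` vitelline range:

| organ            | extent                                         |
|------------------|------------------------------------------------|
| oral sucker      | `[0, OS_length]`                               |
| ventral sucker   | `[F, F + VS_length]`                           |
| cirrus-sac       | `[L − R, L − R + CS_length]`                   |
| posterior testis | `[L − PT − PT_length, L − PT]`                 |
| anterior testis  | `[pt.anterior − D − AT_length, pt.anterior − D]` |
| vitellarium      | `[PV, PV + RF]`                                |

Ovary, uterine coils and seminal receptacle have no anchoring measure in
standard tables; they are accepted only as direct extents (JSON sidecar) or
as qualitative placement facts (below).

Summary tables report per-measure means, and means of jointly constrained
measures are not jointly consistent: at the published means of the new
*Allopodocotyle* species, `PV + RF` overshoots `L` by ≈0.46% (the follicles
actually end at the posterior extremity in every worm, but means do not
compose).  Reconstruction therefore clamps overruns up to a tolerance
(default 2% of `L`) with a warning and marks larger overruns invalid.  The
same inconsistency means an organ-pair relation computed from
mean-reconstructed extents can contradict the described relation — the mean
cirrus-sac and mean vitellarium overlap by ≈104 µm although the description
states they are usually well separated.  Stated relations consequently
outrank computed ones wherever both exist.

### Rounding and ratio conventions

Printed percentages and ratios use half-up rounding at the printed number of
decimals (`round_half_up`); rounding happens only at presentation, never in
stored values.  Published tables mix two conventions: "% of mean body
length" is a ratio of means, while a printed mean percentage row is a mean
of per-specimen ratios.  Both are computable and are never silently
interchanged; e.g. the cirrus-sac reach is 83.0% as a ratio of means but
82.9% as the printed mean of ratios.

## Palm patterns

A Palm pattern is the bar-diagram reduction of a worm: a black bar for the
body, coloured bars for organ extents, each bar stored as body-length
fractions.  Two plate modes:

* **absolute** — all bodies drawn at one axis length; organ *positions*
  compare directly; eighth gridlines (7 internal boundaries) are drawn, as
  eighths are the standard comparison grid.
* **relative** — drawn lengths exactly proportional to body lengths, columns
  centre-aligned on a shared transverse midline; a µm scale bar (default
  300 µm) replaces the gridlines.

Rendering is byte-deterministic (fixed element order, fixed 3-decimal
coordinate formatting, no timestamps or generated ids), so plates diff
cleanly under version control.  Overlapping organs are laid out in parallel
lanes by greedy interval colouring rather than stacked transparency; the
organ palette (8 named colours, anterior-to-posterior legend order) is a
package choice, configurable, not a reproduction of any published figure;
organs outside the palette get a deterministic hash-derived fallback colour.
Bodies are drawn vertically, anterior up, matching habitus-drawing
convention.  Inputs are assumed to be measured along the body midline; no
image-domain straightening is performed.

## The key engine

Keys are declarative YAML/JSON files: couplets of two leads, each lead with
*primary* predicates (all must hold) and *auxiliary* predicates (checked,
reported as conflicts, never blocking).  Predicate kinds: numeric threshold,
numeric range (units explicit; mm in key files, matching printed keys,
converted internally to µm), categorical equality, localization (organ ×
{halves, thirds, eighths} × {overlaps, mainly, completely}) and organ-pair
overlap relation ({separated, touching, overlapping}).  Load-time validation
enforces exactly two leads per couplet, no dangling references, acyclicity,
reachability and declared terminal taxa, reporting all violations at once.

Evaluation is three-valued over partial character states.  At a couplet:
one lead true and the other false → follow it; both true or both false under
fully known primaries → ambiguous, returning the union of both subtree taxon
sets (keys are identification aids — a tie is a finding, not something to
break silently); any unknown otherwise → insufficient, naming the missing
characters.  The last rule is deliberate: resolving a couplet on
(true, unknown) could later flip to ambiguous when the unknown side turns
true, which would violate the monotone-information contract (more data may
refine an ambiguous/insufficient result but never overturn a resolved
taxon).

Localization predicates are answered from an extent when one is available
(exact interval arithmetic) and otherwise from stored qualitative facts
`(organ, parts, bins, completeness)` via a sound implication calculus —
e.g. "completely in eighth 4" implies "overlaps eighth 4" and coarsens to
"completely in the anterior half"; facts on a grid that the predicate grid
does not divide return unknown rather than a guess.

Encoding choices for the shipped serranid-grouper *Allopodocotyle* key
(6 couplets, 7 taxa):

* "Squat" vs "elongate" derives from the length:width ratio with threshold
  4.25 (the one squat congener spans ≈2.2–4.2; all printed elongate ratios
  are ≥4.3).  A stated `body_shape` character overrides the derivation.
* The tandem-testes couplet separates primarily on body width (printed in
  both leads: 0.2–0.4 vs 0.5–0.6 mm; threshold 0.45 mm), because the
  cirrus-sac clauses conflict with the drawing-based table value for
  *A. heronensis* (510 µm vs "< 0.5 mm"); the cirrus-sac clauses remain as
  auxiliary (lead A) and as the printed 0.75 mm ± 10% primary band (lead B,
  a point value needs a documented tolerance).
* "Body > 2.7 (2.4 for an outlier) mm" is encoded with the outlier value as
  the operative primary bound and an auxiliary note flagging bodies between
  2.4 and 2.7 mm.
* Qualitative wording ("testes very well separated", "almost contiguous") is
  auxiliary, with documented thresholds (e.g. separation < 5% of body length
  ⇔ almost contiguous); "mainly in" ⇔ region fraction > 0.5, "completely
  in" ⇔ fraction = 1 after clamping.
* Sucker-ratio states are ventral width / oral width (a printed "sucker
  ratio 1:1.9" means ventral is 1.9× the oral width).

The genus-wide morphological groups: tandem testes → C; diagonal testes with
the cirrus-sac ending posterior to the ventral sucker's posterior margin →
A; diagonal with the sac overlapping only the sucker's anterior margin → B.

## Sequence comparison

For a pre-aligned pair, the overlap is the set of columns where both bases
are unambiguous (A/C/G/T); gaps, N and IUPAC codes are excluded, matching
the simple difference counts descriptions report.  Differences are
catalogued with 1-based positions counted within the overlap and classed as
transitions (A↔G, C↔T) or transversions.  Percent identity is
`100·(overlap − differences)/overlap`, half-up to 1 decimal.  The K2P
distance uses the closed form `d = −½·ln((1 − 2P − Q)·√(1 − 2Q))` with
`P`, `Q` the transition and transversion proportions; proportions outside
the log domain raise an explicit saturation error.  The implementation was
cross-checked against `ape::dist.dna(model = "K80")`: for P = 5/1031,
Q = 1/1031 both give 0.0058487259 substitutions/site, and this value is
frozen in the test suite.  No alignment, database search or tree inference
is performed here.

## Packaged profiles and synthetic data

The catalog ships the published summary statistics of the eight
grouper-infecting *Allopodocotyle* records (the 7 keyed species plus a
regional record of uncertain identity, stored without a testes-arrangement
state and outside the key) and of *Prosorhynchus maternus*, with per-cell
provenance.  Alternative published values ("… in original reference") are
stored as variants, never merged.  The source table's extracted text lacks
column delimiters in places; cells that could not be assigned to a column
with certainty are stored as unknown rather than guessed — none of them
feeds the key or the headline numbers.  Known source conflicts (a
running-text maximum misprinted as 31,919 µm against the table's 3,919 µm;
body sizes of the squat congener smaller in text than its figure scale
implies) are kept with provenance notes or caveat flags.

`synth_specimens` emulates a measured series of gravid worms (default
conditions: n = 22, the size of the described type series; uniform sampling
within each published min–max).  Joint consistency is enforced by rejection:
parts must fit the body, the cirrus-sac must fit its reach, eggs must be
longer than wide, every printed *range-valued* derived statistic (length:
width ratio, forebody/oesophagus/post-testicular/pre-vitelline/reach
percentages, sucker ratios) must hold to within 0.05 (printed rounding), and
all reconstructible extents must be valid with zero clamping tolerance.
The vitelline range is derived as `L − PV` for taxa whose follicles reach
the posterior extremity, then checked against its printed range.
Point-valued derived statistics are statistics of the published means, not
per-specimen constraints, and are not enforced.  A truncated-normal mode
(mean at the printed mean, sd = range/4) is available for more realistic
recovery tests.  Generation is integer-seeded (`numpy.random.default_rng`)
and platform-deterministic; the rejection limit (20 000 attempts per record)
raises a named error listing the conflicting constraint families.

What the generator does **not** emulate: measurement error, allometric
correlation between organs beyond the enforced ratio constraints,
fixation/flattening artefacts, or any covariance structure of real series.
One visible consequence: independently drawn organ anchors decorrelate
positions, so roughly half of the synthetic worms have an anterior testis
straddling the body midline and key out as *ambiguous* at the posterior-half
couplet — with the true taxon always inside the candidate set.  Passing
recovery tests therefore demonstrate soundness of the key logic under range
variation, not field-realistic resolution rates.

`synth_aligned_pair` builds a seeded random background sequence shared by
both records and plants the specified differences — by default the six
positions (189, 308, 317 A↔G; 508 T↔C; 622 G↔T; 837 G↔A) distinguishing the
Indonesian and Australian *P. maternus* 28S isolates over their 1031-bp
overlap.  Positions are taken as coordinates within the gap-free overlap, so
string positions equal overlap positions by construction.  Background
composition is uniform; no substitution-model simulation is attempted.

## Problem sizes and determinism

Everything is desk-scale: the property suites use ~1000 seeded partial-state
key draws, 200 random pairs for the comparison oracle and 22-worm synthetic
series; the whole test suite runs in seconds on one CPU.
`scripts/acceptance.py --seed N` reseeds every stochastic component (the
aligned-pair background and the synthetic series) from the given seed; the
profile-derived quantities are deterministic.

## Known limitations

* The key engine is strictly boolean/three-valued; no probabilistic or
  fuzzy matching, and no automatic key construction from profiles.
* Transverse (width-axis) patterns are not implemented; neither is raster
  export — SVG only.
* The catalog transcription is only as good as the printed source; cells
  flagged unknown above stay unknown by design.
* Sequence comparison requires pre-aligned input and performs no BLAST
  search, multiple alignment or tree inference.
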