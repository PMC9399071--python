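# palmpattern

Morphometric comparison tools for digenean trematodes: standardized
organ-position diagrams ("Palm patterns"), quantitative dichotomous
identification keys, and pairwise comparison of aligned nucleotide
sequences.  Built for helminth taxonomists who work from the measurement
tables of species descriptions — the running example throughout is the
grouper-infecting *Allopodocotyle* species complex (Opecoelidae) and the
bucephalid *Prosorhynchus maternus*.

## What it does

**Palm patterns.**  A worm is reduced to a black bar for its total body
length with coloured bars marking each organ's longitudinal interval
`[anterior, posterior]` (µm from the anterior extremity).  Organ extents are
reconstructed from the scalar measures descriptions actually publish — e.g.
the cirrus-sac occupies `[L − R, L − R + ℓ]` where `R` is its *reach* (the
distance from the posterior body extremity to the sac's anterior-most
extent) and `ℓ` its length.  Plates come in two modes: *absolute* (all
bodies drawn at one axis length, divided into eighths, so organ positions
compare directly) and *relative* (bodies to true scale, centre-aligned on a
shared transverse axis, with a µm scale bar).  Output is byte-deterministic
SVG.

**Quantitative keys.**  Dichotomous keys are declarative YAML files whose
leads carry measurable *primary* predicates (thresholds and ranges with
explicit units, halves/thirds/eighths localization, organ-overlap relations,
categorical characters) plus non-blocking *auxiliary* predicates for the
qualitative wording.  Evaluation over a partial character-state map is
three-valued and monotone: it returns a taxon, an *ambiguous* candidate set,
or *insufficient* with the missing characters named — never a silently
broken tie.  The key to *Allopodocotyle* of serranid groupers (6 couplets,
7 species) ships with the package, as does the genus-wide A/B/C
morphological-group classifier.

**Sequence comparison.**  For a pre-aligned pair: overlap (columns with
unambiguous bases on both sides), a difference catalogue with
transition/transversion classes, percent identity over the overlap, and the
Kimura 2-parameter distance
`d = −½·ln((1 − 2P − Q)·√(1 − 2Q))`
with `P`/`Q` the transition/transversion proportions.

**Fixtures and synthesis.**  The published summary statistics (min–max–mean,
µm) of eight *Allopodocotyle* records and *P. maternus* are packaged with
per-cell provenance, and seeded generators produce synthetic specimen series
(every measure inside its published range, ratios/percentages and
reconstructed extents jointly consistent) and synthetic aligned pairs with a
prescribed difference catalogue.

## Worked example

```python
from palmpattern import fixtures, keys, morpho, seqcompare

# the two P. maternus 28S isolates over their 1031-bp overlap
pair = fixtures.synth_aligned_pair(seed=7)
print(seqcompare.format_report(pair, seqcompare.compare_aligned(pair)))

# mean cirrus-sac length as % of mean body length for A. palmi
palmi = fixtures.load_fixture("A. palmi")
print(morpho.percent_of_body(palmi.stats["cirrus_sac_length"].mean,
                             palmi.stats["body_length"].mean, 1))

# run the serranid-grouper key on the taxon's published means
key = keys.load_key(keys.packaged_key_path())
print(keys.evaluate(key, fixtures.profile_to_states(palmi)).trace())
```

prints

```
sequences: isolate_a vs isolate_b
overlap: 1031 bp
differences: 6 (5 transitions, 1 transversions)
identity: 99.4%
K2P distance: 0.005849 substitutions/site
   pos  isolate_a    isolate_b    class
   189  A            G            transition
   308  A            G            transition
   317  A            G            transition
   508  T            C            transition
   622  G            T            transversion
   837  G            A            transition
---
28.5
resolved: Allopodocotyle palmi
path: 1B -> 3B -> 4B -> 5B -> 6B
```

The six differences are the published positions distinguishing the
Indonesian from the Australian isolate, giving 99.4% similarity; the mean
cirrus-sac occupies 28.5% of mean body length; and the published means of
the new species traverse the key along 1B→3B→4B→5B→6B to its own couplet.

## Command line

```sh
palmpattern summarize worms.csv              # min/max/mean/n per measure
palmpattern palm --mode relative -o plate.svg
palmpattern key --states worm.json           # exit 0 resolved / 2 ambiguous / 3 insufficient
palmpattern seqcmp pair.fasta
palmpattern synth --taxon "A. palmi" -n 22 --seed 1 -o synth.csv
```

Specimen tables are CSV/TSV with µm values (a `(mm)` header suffix converts
that column); direct organ extents ride in a JSON sidecar.  See
`docs/methods.md` for conventions, encoding decisions and limitations.

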