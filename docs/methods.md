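# Methods

## The groove-bending-site map

Nucleosomal DNA contacts the histone octamer roughly every half helical
turn, alternating between minor-groove-inward and major-groove-inward
bends. The map fixes these sites inside the 0-based 147-bp NCP frame
(dyad at index 73): minor-GBS at superhelical locations (SHL) ±1.5 … ±6.5
and major-GBS at SHL ±1 … ±6. The two minor sites at SHL ±0.5 are defined
but excluded from counting, since their WW/SS preference is out of phase
with the remaining sites. Counted totals: 12 minor sites / 48 bp / 36
internal dinucleotide slots, 12 major sites / 44 bp / 32 slots, capacity
ratio exactly 1.125.

The per-site coordinates are not uniquely determined by those published
constraints, so the default layout is generated from them: positive-SHL
site centres at `dyad + round(10.3 · SHL)` (10.3 bp helical period), 4-bp
sites starting at centre−2 and 3-bp sites at centre−1, with the negative
side produced by mirror reflection through the dyad — which makes dyad
symmetry exact by construction. The four 3-bp major sites sit at SHL ±3 and
±6; this choice, and every coordinate, is overridable through a YAML layout
config (`src/nucpattern/data/gbs_default.yaml` is the canonical copy), and
construction validates every invariant (counts, lengths, coverage,
capacity, bounds, overlap, symmetry) and fails loudly naming the violated
one. With the 10.3-bp period no overlap-resolving nudges are needed.

## Classification and ΔNPS

A dinucleotide at start i occupies bases (i, i+1) and belongs to a site
only if both bases lie inside it (a k-bp site contributes k−1 slots).
Fragments are typed by the two threshold comparisons shown in the README;
ties sit on the ≥/≤ branches exactly as the classification table states
them. A consequence, accepted and tested, is that homopolymer-like
fragments (all counts tied at capacity on one side) fall into Type 1 —
including all-G, whose SS comparison ties at 36 = 32·1.125. `coef`
defaults to the active map's capacity ratio, so a custom layout with
different capacities stays internally consistent.

Two exact symmetries hold and are enforced by tests: reverse complement
preserves the type (WW and SS are closed under reverse complement and the
map is mirror-symmetric), and the W↔S base substitution (A↔G, T↔C)
exchanges the WW and SS counts, which on tie-free fragments maps Type 1↔4
and fixes Types 2 and 3 (both-classes-in-one-groove is invariant under the
exchange).

ΔNPS is reported in percentage points on [−100, 100]; summaries refuse
empty input rather than returning a silent zero.

The dyad-symmetrized frequency profile averages the per-position WW (or
SS) frequency at dinucleotide start i with position 145−i, then applies a
centred 3-bp running mean whose edges use the positions actually available
(so a symmetric input stays exactly symmetric). Symmetrization after
averaging across fragments is order-equivalent for the mean.

## Distance correlations

DAC counts ordered pairs of same-class dinucleotide occurrences at start
separation d = 1..150; DCC counts cross-class pairs, by default in both
orientations (|i−j|), switchable to forward-only. Pairs never span sequence
boundaries; non-ACGT positions split a sequence into independent segments.
Overlapping occurrences (d = 1) are counted — a deliberate choice with a
visible consequence: on iid sequence the normalized DAC at d = 1 is ~1/8
rather than 1/16, because overlapping WW dinucleotides share a base.
Flatness on random sequence therefore holds for d ≥ 2, and the flatness
test asserts exactly that. `normalized` divides each count by the total
number of valid position pairs at that distance; raw counts are always
retained, and `smoothed` is a 3-point running mean of the normalized curve.

TSS regions default to [−500, +1000] inclusive (1501 bp), strand-oriented
so downstream is positive, clipped (with a log message) at contig ends.

## Profiles

Genes are ranked into expression quartiles by a stable (expression,
gene_id) sort; group 1 is least expressed. Fragment dyads (start + 73) are
assigned to TSS-relative half-open zones; the defaults place −1 at
[−300, −80), +1 at [−80, 120) and +2..+5 as successive windows of one
nucleosome repeat length (165 bp in the yeast-like preset, 185 bp in the
mammal-like one). Published per-species zone tables vary, so zone ranges
are declarative and overridable, and every zones output embeds the ranges
in its header. Occupancy counts 147-bp fragment bodies per offset per gene,
averaged within quartile; the quartile profiles pool exactly to the
all-genes profile (weighted by group size), which is a tested identity.

Repeat elements shorter than 151 bp (about one nucleosome) are ignored; a
fragment resides in a family when its midpoint lies inside an element, with
nested elements resolved most-specific-first (Simple Repeat > SINE > LINE >
LTR > Other, configurable). Strain comparison computes per-chromosome ΔNPS,
takes the chromosome mean as the strain's genomic value, and tests each
strain against the reference with the classic equal-variance two-sample
t-test (Welch by flag).

## The synthetic-data generator

The generator emulates what the analysis assumes about real chromatin:

* **Geometry-planted fragments.** For each requested type, groove-site
  bases are set to the intended letter class (W or S) with probability
  `phasing_strength`, background elsewhere. At strength 1 classification
  equals the requested type by construction; at the default 0.9 recovery is
  ≥ 95 % (measured ~100 %); at strength 0 the output is statistically
  indistinguishable from background (chi-square-tested). Types 2/3 plant
  half the sites of the favoured groove with W and half with S, and fill
  the opposite groove with strictly alternating W/S so its internal
  dinucleotides belong to neither class.
* **Rejection-sampled fragments.** The mammal-like regime instead draws
  iid sequences and keeps those classifying as the target type. This
  controls type composition *without* planting positional periodicity —
  matching the mammalian observation that anti-WW/SS enrichment coincides
  with diminished ~10-bp DAC structure.
* **Gene arrays.** Each gene gets an NDR (default 200 bp) directly
  upstream of the TSS and six phased nucleosomes whose dyads sit mid-zone
  (−1 at TSS+60−147−NDR; +1..+5 at TSS+60+k·spacing), strand-aware.
* **Study conditions** (defaults, chosen once as realistic desk-scale
  analogues): 16 chromosomes totalling 4 Mb, 1000 genes with lognormal
  RPKM-like expression, 165/185 bp spacing (non-mammal/mammal), 8000
  background nucleosomes so the genomic reference is background-dominated
  (as in a real genome, where the TSS-proximal set is a small minority).
  Genomic type mixtures: (45, 21, 9, 25) % in the non-mammal regime
  (genomic ΔNPS ≈ 20 %) and (47, 21, 13, 19) % in the mammal regime
  (≈ 28 %). In the mammal regime a per-zone Type-1→Type-4 probability
  shift δ = {−1: .03, +1: .07, +2: .05, +3: .04, +4: .035, +5: .03},
  scaled by expression quartile q/2.5, produces the +1 minimum and the
  negative quartile slope; the remodeler-mutant regime moves ε = 0.0165
  of probability mass from Type 1 to Type 4 uniformly (ΔNPS drop ≈ 3.3
  points) without touching the spatial layout. Repeats cover 5 % (15 % in
  the mammal regime) of the background with a Type-1-enriched mixture
  (55/20/10/15) planted at strength 0.9, so repeat-borne nucleosomes carry
  periodicity and a ΔNPS above the genic value; a few sub-151-bp elements
  are emitted to exercise the length filter.
* **Determinism.** One `numpy` Generator seeded from the config drives
  everything; identical config + seed gives byte-identical FASTA/BED/TSV
  and truth JSON. Dyad jitter (default 0, 10 bp for realism runs) perturbs
  reported fragment coordinates, not the planted sequence.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: MNase sequence bias, sequencing error, linker
length variability, higher-order (Markov) base composition, overlapping or
alternative nucleosome configurations, and real repeat sequence content.
The background is iid at a configured GC (default 0.5, keeping the W↔S
symmetry exact); fragment counts are thousands rather than the millions of
a real chemical or MNase map, so per-zone ΔNPS values carry sampling errors
of a few percentage points, and the strain t-test reaches p ~ 10⁻² rather
than the extreme significance a genome-scale dataset would give.

## Numerical and design notes

* All internal coordinates are 0-based half-open; 1-based dyad tables
  (chemical-map convention) are converted at the input boundary under an
  explicit flag. A dyad at 0-based p expands to [p−73, p+74).
* Fragments with non-ACGT bases, wrong length, or out-of-bounds coordinates
  are excluded at ingest with per-reason counts; a missing contig is a hard
  error.
* Zone assignment is strictly half-open, so a dyad on a boundary belongs to
  the higher zone; the zone set is validated to be non-overlapping.
* Quartile ties break stably by (expression, gene_id); all-identical
  expression is refused rather than arbitrarily split.
* Problem sizes in the test suite and acceptance script (1000-fragment
  counting oracles, 100×1-kb correlation oracles, 8000-fragment recovery
  runs, 14000-fragment studies) are chosen so each measured quantity's
  sampling error is comfortably below the effect it checks.
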