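# nucpattern

Rotational nucleosome positioning from WW/SS dinucleotide sequence patterns.

Nucleosomal DNA bends sharply into the minor and the major groove at fixed
positions along its 147-bp wrap around the histone octamer. Sequence favours
this geometry when WW dinucleotides (AA, AT, TA, TT) sit where the minor
groove faces the histone core (minor groove-bending sites, minor-GBS) and SS
dinucleotides (CC, CG, GC, GG) sit where the major groove does (major-GBS).
`nucpattern` quantifies how strongly mapped nucleosomes follow — or invert —
this rotational code, genome-wide and around transcription start sites.

## The statistic

Within the 147-bp nucleosome core particle (NCP) frame, 12 minor-GBS
(covering 48 bp, holding up to 36 internal dinucleotides) and 12 major-GBS
(44 bp, up to 32 dinucleotides) are counted; the two minor sites flanking
the dyad (SHL ±0.5) are excluded because their WW/SS preference runs out of
phase. With `coef = 36/32 = 1.125` compensating the capacity difference,
each fragment is assigned one of four types:

| Type | WW predicate                 | SS predicate                 |
|------|------------------------------|------------------------------|
| 1    | minor WW ≥ major WW · coef   | minor SS ≤ major SS · coef   |
| 2    | minor WW ≥ major WW · coef   | minor SS > major SS · coef   |
| 3    | minor WW < major WW · coef   | minor SS ≤ major SS · coef   |
| 4    | minor WW < major WW · coef   | minor SS > major SS · coef   |

Type 1 is the canonical WW/SS pattern, Type 4 its inverse (anti-WW/SS).
For any fragment collection, **ΔNPS = Type 1 (%) − Type 4 (%)**.

On top of the classifier the package provides:

* **distance correlations** — DAC/DCC pair counts of WW/SS occurrences at
  separations d = 1..150 bp (periodic rotational sequence shows DAC peaks at
  ~10n bp and WW-vs-SS DCC peaks at ~10n+5 bp);
* **TSS-aligned profiles** — occupancy and per-zone ΔNPS for nucleosomes
  −1, +1 … +5, stratified by expression quartile;
* **repeat-family summaries** — fragment fractions and ΔNPS per
  SINE/LINE/LTR/Simple Repeat/Other family;
* **strain comparison** — per-chromosome ΔNPS with Student's t-tests
  against a reference strain;
* **a synthetic-data generator** — genomes with planted rotational
  structure (phased arrays, NDRs, expression-coupled anti-WW/SS enrichment,
  periodic repeats) providing ground truth for every stage.

## Worked example

```
$ python examples/classify_and_dnps.py
fragments analysed: 1576
  Type 1:  44.4 %
  Type 2:  21.7 %
  Type 3:   9.7 %
  Type 4:  24.2 %
  dNPS (Type1 - Type4): 20.1 %
agreement with the planted ground truth: 100.0 %
```

The generator planted a 45/21/9/25 type mixture at planting strength 0.9;
the classifier recovers the labels and the region-level ΔNPS of ~20 %,
meaning canonical WW/SS nucleosomes outnumber anti-WW/SS ones by 20
percentage points. The other scripts in `examples/` each demonstrate one
capability — `dinucleotide_periodicity.py` (DAC peaks at 10, 21, 31 bp and
DCC peaks at 5, 16, 26 bp in the periodic regime, flat otherwise),
`tss_zone_profiles.py` (zone +1 ΔNPS dipping below genomic with a negative
expression-quartile slope), `strain_comparison.py` (a remodeler-mutant's
genome-wide ΔNPS drop at unchanged spatial profile) and
`repeat_families.py` (repeat-borne nucleosomes above the genic ΔNPS).

A thin CLI wraps the same library calls for shell use:

```
nucpattern synth --seed 1 --out study/
nucpattern classify --fragments study/fragments.bed --genome study/genome.fa --out out/
nucpattern zones --fragments study/fragments.bed --genome study/genome.fa \
    --genes study/genes.tsv --out out/
nucpattern validate-gbs
```

Real inputs are plain text: genome FASTA, 147-bp fragment intervals (BED) or
chemical-map dyad positions (TSV), a gene table with TSS/strand/expression,
and a repeat table with family labels.

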