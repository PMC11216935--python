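# Methods

## Problem and model

`pulcensus` answers two questions about a conserved protein domain (the
default target is DUF1735) over a set of annotated bacterial genomes:

1. **What do the proteins carrying it look like?** Each protein's domain
   hits are reduced to a canonical *architecture*, and architectures,
   per-genome copy numbers and taxonomy are tabulated.
2. **Is the encoding gene part of a polysaccharide utilization locus
   (PUL)?** PULs are marked by an adjacent *susC*/*susD* gene pair, so a
   target gene is called PUL-encoded when SusD evidence lies within ±w genes
   of it (default w = 5).

Neither question requires sequences: domain hits and gene annotations are
inputs, never computed here. No HMM scanning, signal-peptide prediction or
structural comparison is performed.

## Domain architectures

Hits are filtered at an inclusive E-value cutoff ε = 1e-4. Inclusivity is a
deliberate reading of "cutoff": a hit scoring exactly ε survives, and the
comparison lives in one constant. Hits that share (domain, start, end) but
come from different sources are deduplicated keeping the lowest E-value.
Annotation-only hits without coordinates (e.g. from a KEGG MOTIF block) pass
the filter but are excluded from coordinate-based grouping; coordinate-bearing
hit tables supersede them.

Two hits overlap when their intersection covers at least
`min_overlap_frac` (default 0.5) of the *shorter* hit; overlap groups are
the connected components of this relation. The 0.5 default is a
parameterized choice: it separates genuinely co-called domains (nested or
near-coincident intervals) from merely adjacent ones, but no field-standard
constant exists, so it is exposed as a parameter. Within a group hits are
ordered by start then name; groups by minimum start. Labels join groups
with `" + "` and group members with `"|"` (a `paper_style` flag renders
`"I"` for byte-compatibility with typeset tables). A group whose domain set
equals a configured merge pair — default {DUF1735, DUF4973}, reflecting
that DUF4973 calls ride almost entirely on DUF1735 intervals — renders as
the primary domain plus `*`. Repeated domains are kept per occurrence, so
`DUF1735 + DUF1735` is two groups. A protein is *multimodular* iff it has
≥ 2 groups, and a domain is N-terminal iff it belongs to the first group
(so `DUF1735*` counts as an N-terminal DUF1735).

Per-protein domain copies are counted after filtering and deduplication but
*before* overlap merging: each named hit counts once, so a starred group
contributes one copy of each member.

## Gene distance on irregularly numbered genomes

KEGG-style locus tags end in a per-genome numeric index, extracted as the
longest trailing digit run (`BT_3987` → 3987). Genomes advance indices in a
constant step s — 1, 5 or 10 in practice — with occasional gaps.
"±5 genes" therefore means five *ranks* in the genome's sorted index list,
not five index units; the step model exists to make the two coincide on
regular genomes, and the package's neighbor search always uses ranks. The
step is inferred as the mode of consecutive sorted-index differences, ties
broken toward the smaller value (a genome with as many single gaps as
steps is better read as step s with gaps than as step 2s); `regular` is
true iff all differences equal the step.

## SusD evidence and position classes

Marker evidence is tiered, strongest first:

| tier    | criterion                                            |
|---------|------------------------------------------------------|
| SusD-ID | KO accession equals K21572 (exact match)             |
| SusD-D  | a domain annotation contains "RagB" or "SusD-like"   |
| SusD-N  | name/annotation contains "SusD" or "RagB"            |

Text matching is case-insensitive substring after whitespace collapsing; the
strings and the KO are configurable, so the scan generalizes to any marker.
Among several marker neighbors the best tier wins, ties broken by smaller
|offset|, then upstream. Window monotonicity holds by construction: growing
w can only add evidence.

Position classes name the target's slot downstream of the pair: one, two or
three genes downstream of *susD* (in the direction leading away from the
adjacent *susC*) are *susE*-, *susF*- and *susG*-like; anything else,
including targets on the *susC* side, is "other". The input schema carries
no strand, so orientation is taken from gene order: a susC-like gene
(KO K21573 or a SusC/TonB-dependent annotation) adjacent to *susD* fixes the
direction, and increasing index is the fallback. This is a documented
approximation, not a strand-aware reconstruction.

## Synthetic study conditions

The generator builds KEGG-like genomes whose defaults are the package's
study conditions: 20 genomes × 120 genes; steps drawn evenly from
{1, 5, 10}; gap rate 0.05; 49 planted susC/susD-anchored loci plus 1 decoy,
giving a 98% co-localization rate; evidence tiers 14% ID / 66% D / 20% N
(the KO-identifiable share matches the real census; the split of the two
indirect tiers is our choice, weighted toward domain evidence since domain
annotation is the commoner indirect signal); downstream offsets 47% / 35% /
18% over the susE/F/G-like slots; 30% of targets carry an overlapping
DUF4973; C-terminal partners mix LamG3, DUF4361, F5/8-typeC, DUF5627, GH18,
a repeated DUF1735, and none. All fractions are realized exactly by
largest-remainder counting, so manifest comparisons are equalities. Each
target also receives an above-cutoff noise hit and, half the time, a
boundary-E duplicate of its primary hit that deduplication must fold away.

Loci are laid out in blocks of 2w+6 gene slots so that scan windows of
distinct loci never intersect, and decoys are re-verified by brute force to
have no marker within w. What the generator does *not* emulate: real
taxonomic breadth (taxa are fictional and marked synthetic), real PUL gene
content beyond the susC/D/target skeleton, strand, pseudogenes, or
annotation noise inside marker strings. Passing tests therefore demonstrate
the correctness of the arithmetic and the scanning logic under the stated
conditions, not robustness to free-text annotation variability in real
databases.

Problem sizes in the test suite and acceptance script (500 random genomes
for the neighbor oracle, 300 genomes for step recovery, 50 seeds for
planted-truth recovery, 1000 overlap instances) were chosen so the full
suite runs in a few seconds while each check still covers every step/gap
regime and tier.

## Numerical and degenerate-input choices

* Printed statistics round half-away-from-zero at the final decimal
  (31.75 → 31.8); banker's rounding is explicitly not used. Implemented
  with decimal arithmetic, never binary-float rounding.
* Percentage and fold-change refuse zero denominators; frequency tables
  refuse empty censuses ("empty census") rather than emitting a 0-row table.
* An unknown target domain is an empty scan result with a logged notice,
  not an error — scanning for a domain absent from a dataset is a valid
  question with answer "none".
* Inconsistent declared lengths (AASEQ vs sequence, protein_length vs
  sequence) are rejected, never repaired.
* Gene-id separators `:` and `_` are both accepted on read; `:` is canonical
  on write. Absent optional fields are `None` in memory and empty TSV cells
  on disk.

## Known limitations

* Strand-blind position classification (above).
* The overlap fraction 0.5 and the D/N evidence-tier split are package
  choices where no authoritative constant exists; both are parameters.
* The copy-number "mean domains per genome" is reported as computed; no
  attempt is made to reproduce externally rounded variants of that figure.
* The live-backend contract is deliberately minimal (two calls) and
  untested against a real service; all shipped workflows are offline.
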