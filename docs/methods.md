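# Methods

This note documents the models, conventions and numerical choices behind
`motifarch`, and what the validation experiments do and do not demonstrate.

## Coordinates and strand conventions

All coordinates are 0-based, half-open, on the forward strand of the supplied
sequence.  Regions are assumed to be supplied 5′→3′ toward the gene (as
upstream regions normally are), so the "first" partner of a dimer is the 5′
one.  A `-` strand occurrence records the forward-strand window whose reverse
complement satisfies the pattern; its `matched` field is the forward
substring.  Both strands are scanned by default and the choice is recorded in
run manifests.  `N` in a sequence matches no pattern symbol (including
pattern `N`): upstream regions come from assembled genome sequence, where an
`N` is an unknown base, not a wildcard.

## Core-motif scanning

Core motifs are 3–12 bp IUPAC patterns.  The literature's `X/Y` shorthand
(e.g. the Pou core `TGCAA/T`) is compiled to the IUPAC code covering exactly
{X, Y} (`TGCAW`).  Scanning is exhaustive over windows — overlapping and
nested matches are all reported, because per-region motif counts (e.g. 17 Pou
hits in a single kilobase) only make sense under exhaustive window scanning.
A palindromic pattern matching one window on both strands yields two
occurrences, one per strand.  Internally each pattern becomes a regular
expression of character classes inside a lookahead (so overlapping starts are
all found); correctness is checked against a naive per-window, per-symbol
oracle in the tests.

The default motif set ships five patterns: Hox `AATTA` (Acj6), Pou `TGCAW`
(shared by Acj6, Pdm3 and Onecut), Pdm3 Hox `TAAT`, E-box `CANNTG`, and Cut
`ATCAA`.  The first three are published cores.  The E-box entry is the
canonical bHLH consensus and the Cut entry is the HNF6-family core; both are
**assumptions** — the authoritative motif list for the original OR analysis
is not reproduced in accessible form, so users with the real set should
supply their own motif table (TSV: name, tf, pattern), which overrides the
defaults and is echoed into the run manifest.

## Composite elements

**Dimers.**  A dimer pattern is an ordered motif pair with a gap window,
where gap = `start(second) − end(first)` in half-open coordinates — the
number of intervening bases.  "Spaced 2–6 bp apart" is therefore gap ∈
[2, 6] (edge-to-edge, chosen over start-to-start because the phrase counts
bases *between* the motifs).  Negative gaps encode required overlap.  Every
occurrence pair satisfying order, gap and orientation policy is reported, and
occurrences may participate in several dimers.  The orientation policy
defaults to `any` (no strand requirement is documented for these dimers);
`same_strand` is available.  The default Acj6 Hox/Pou gap window is [0, 12]:
the source material describes "variations in the spacing" without bounds, so
the window is configurable and recorded in output.

**Overlaps.**  All unordered pairs of different motifs with positive interval
overlap; half-open adjacency is not overlap.

**Clusters.**  A cluster is a maximal set of ≥ `min_members` dimers whose
span (max end − min start) is at most `max_span` (defaults 2 and 150 bp; the
notion of a "condensed cluster" has no quantitative published definition, so
both knobs are user-set and recorded).  The caller exploits that feasibility
is anchored: any dimer starting at or after a set's leftmost start and ending
within `leftmost start + max_span` can join without raising the span, so
every maximal feasible set equals the set of dimers contained in the window
anchored at its leftmost member.  The implementation enumerates those
anchored windows and removes duplicates and subsets — an exact algorithm,
simpler to reason about than incremental merging, and verified against
exhaustive subset search (≤ 15 dimers) in the tests.  No reported cluster is
a subset of another.

**Architecture strings.**  An arrangement serializes canonically as elements
left to right (`name` + strand) joined by `.gap.` tokens or `~` for flagged
overlaps: `Hox+.2.Pou+~Ebox+`.  Parsing round-trips exactly (element order,
strands, gaps, overlap markers).  Moving an element or toggling an overlap
changes the string whenever it changes a gap token or an overlap flag.  One
deliberate coarsening: a flagged overlap is rendered as `~` without its
length, treating an overlapped pair as a single composite unit, so two
arrangements differing only in the extent of the same overlap share a
string.  Negative gaps (overlap present but not flagged) are preserved
numerically.

## Enrichment statistics

Presence is ≥ 1 call in the region — the published comparisons count genes,
not sites — with `n_hits` retained for dose analyses (the 2× vs 6× dimer
constructs).  The enrichment result reports both group fractions, their fold
ratio (sentinels: +inf when only the regulated group has carriers, 1 when
neither does), the 2×2 table, and a two-sided Fisher exact p-value.  The
exact test is an addition to the published fractions-and-fold summary, so the
claim is testable; the two-sided convention sums all tables (margins fixed)
whose point hypergeometric probability does not exceed the observed table's
(scipy's convention, independently verified against full enumeration for
every table with n ≤ 20).  A Bonferroni helper is provided for scans of
several grammars; no correction is applied by default because the motivating
analyses test one pattern at a time.

## Comparative-Ct quantification

Fold change = 2^(−ΔΔCt), ΔΔCt = (Ct_target − Ct_ref)_experimental −
(Ct_target − Ct_ref)_control.  Replicate Cts are summarized by the
arithmetic mean (the standard choice for this method); the SEM of ΔΔCt is
the root sum of squared per-condition SEMs, reported on the ΔΔCt scale with
a ±1 SE fold interval.  Statistical testing across biological replicates is
left to the user — replicate designs vary and no single test is implied by
the method itself.

## Synthetic data

The generator emulates the study's input: ~1 kb regions upstream of each
gene, a "regulated" and a "non-regulated" cohort, and composite elements
present at different rates in the two.  Backgrounds are iid bases — uniform
by default, with a 60% AT preset (`at_rich_model`) available because fly
intergenic DNA is AT-rich; presets are never applied silently.  Planting
overwrites background bases in place (regions keep their length, as real
upstream regions would); only pattern-covered positions are overwritten, so
gap bases stay background.  Where planted patterns overlap, the IUPAC base
sets are intersected position by position; degenerate positions are sampled
uniformly from the allowed set, and an empty intersection rejects the
template with the conflicting positions.  One generator drives everything in
a fixed order — per sequence: background bases, planting flag, template
variant (e.g. which gap of a 2–6 bp window), position, degenerate bases left
to right — so all outputs are pure functions of (spec, seed).

What the simulations do **not** emulate: real base composition structure
(dinucleotide bias, repeats), motif degeneracy beyond the core patterns,
chromatin state, TF levels, or any environmental modulation.  Passing the
recovery experiments therefore shows the *detectors* are correct and
calibrated on known ground truth; it does not validate biological
conclusions about real upstream regions.

## Validation experiments and problem sizes

- *Oracle suites*: scanner vs naive window checking (200 random cases, plus
  reverse-complement coordinate symmetry), dimer finder vs brute-force pair
  enumeration, cluster caller vs exhaustive subset search (≤ 15 dimers),
  architecture round-trips, exact test vs hypergeometric enumeration (all
  2×2 tables, n ≤ 20).
- *Planted recovery*: 500 synthetic 1 kb regions with planted Pdm3
  Hox–gap–Pou dimers and Pou~E-box overlaps; sensitivity must be 100%
  (soundness by construction), and the chance-dimer rate on 500 unplanted
  backgrounds must sit within 3 SE of the closed-form product-of-window
  expectation (exact for non-negative gaps, where the windows are disjoint).
- *Cohort recovery*: 500 replicates of a 200 + 200 cohort, planting
  probabilities 0.7 / 0.1, run through the full scan → dimer → cluster →
  presence → enrichment pipeline.  The planted element is the tandem 2×
  Onecut Hox/Cut construct: requiring a 2-dimer cluster within 150 bp pushes
  the background false-positive rate to ~10⁻³–10⁻² per kilobase (chance
  clusters need two spurious dimers close together, which essentially
  requires twin strand-symmetric Hox hits), so detected fractions estimate
  the planting probability.  Recovery is scored as interval coverage per
  group: the detected fraction must fall inside the central 95% equal-tail
  binomial interval of the true planting probability in ≥ 93% of replicates
  for each group.  Per-group coverage is the standard notion for interval
  calibration; a joint both-groups-per-run score would be bounded near
  0.95² ≈ 0.90 even for a perfect estimator and would not measure anything
  about the detectors.

These sizes keep the whole suite at about a minute of compute while leaving
all empirical margins (coverage ≈ 95–97% against the 93% floor, |z| well
inside 3) comfortably wide.

## Known limitations

- Exact degenerate cores only: no position-weight matrices or affinity
  scores, by design — the analyses this supports are defined on exact core
  patterns.
- Architecture strings compare arrangements, not sequences; cross-gene
  comparison is structural (no multiple alignment of cluster sequences).
- The analytic dimer expectation assumes non-negative gaps and iid
  backgrounds; it ignores the (small) positive correlation between
  overlapping windows of self-similar patterns, which is visible only in
  higher moments, not the mean.
- Reproducing the published 71% / 8% Onecut fractions and the 17 Pou / 7 Hox
  counts requires the original 32-gene upstream sequences and
  regulated/non-regulated assignments, which are external downloads; the
  package computes the corresponding fold (8.875) from the published
  fractions and validates everything else on synthetic ground truth.
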