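# Methods

This note records the models, defaults and design choices behind
`pol3roadblock`, and what the synthetic validation does and does not show.
Coordinates are 0-based half-open throughout (BED convention); GFF3 output
converts to 1-based closed on write only.

## Tag weighting

A ChIP library is reduced to distinct tag sequences. Each carries

- *c* — the number of times the sequence was read (multiplicity), and
- *m* — the number of genomic positions it matches exactly (its match list).

Both schemes conserve weight per tag (the *m* assigned weights sum to *c*),
so library mass is never created or destroyed by re-weighting:

- **uniform** (reference semantics): each match receives *c/m*.
- **em**: weights start at *c/m* and are iterated; at each step a match's
  weight becomes *c* × (local coverage near that match) / (summed local
  coverage over the tag's matches), where local coverage is the current
  total assigned weight starting within ±500 bp of the match. Uniquely
  mapping tags are fixed anchors, so the iteration is seeded by unique
  coverage and refined by the evolving multi-mapper weights; it stops when
  the largest per-location change falls below 1e-6 or after 100 iterations.
  If a tag's windows hold no weight at all, it stays at the uniform split;
  if the library has no unique tags, the scheme falls back to uniform with
  a logged warning. For a (c=10, m=2) tag between neighborhoods with 9:1
  unique coverage the fixed point is weights 9 and 1, which the tests check
  by hand-iterated closed form.

Local coverage is anchored at placement start positions; placements are
tag-length (~36 bp), far below the 500 bp window, so start-anchoring is an
adequate approximation of overlap counting.

Coverage tracks are binned (default 10 bp): a bin stores the mean per-base
weighted coverage over the bin, so a placement of weight *w* and length *L*
contributes *w·L/bin_size* in total, prorated across partial overlaps. The
track records the (mean) placement length so per-base mass can be converted
back to tag counts; the bedGraph writer embeds it as a header comment
(`# read_length=`) to survive round trips.

From SAM/BAM input, *c* is reconstructed by collapsing identical
forward-strand sequences over distinct read names and the match list from
the distinct alignment positions of that sequence; an NH tag, when present,
is treated as a cross-check only.

## Occupancy scores

A locus score is S = log2((ip + p)/(inp + p)), where ip and inp are the
locus signal masses in parts per million of each track's total mass
(library-size normalization) and p is a pseudocount, default 1 ppm. S is
antisymmetric under IP/input exchange and strictly increasing in IP mass.
Percentages are 100·max(S, 0)/S_ref against a chosen reference locus (or
the maximum); depleted loci floor at 0% since a negative percentage of a
reference occupancy has no meaning here. "Pol III-occupied" defaults to
S ≥ 1 (2-fold); class means average S over occupied loci of one class.
Peak confirmation re-scores an externally supplied peak list on the
weighted tracks and keeps peaks with S at or above the threshold — this is
the step where multi-mapping-aware weighting separates real Pol III loci
from alignment artifacts.

## Nesting and roadblock detection

A peak is *nested* when fully contained in a gene's span minus a 250 bp
promoter-exclusion zone downstream of the TSS, so promoter-proximal pausing
signal can never masquerade as an intragenic Pol III unit. Orientation is
sense iff peak and host strands agree; unstranded peaks may take a strand
hint (e.g. from a promoter scan) and are otherwise rejected.
Cross-confirmation calls two peaks coincident when their summits (midpoints,
absent an explicit summit) lie within 200 bp.

The roadblock test asks whether Pol II accumulates *just before* the nested
unit from the traveling polymerase's point of view: the test window
(default 200 bp) abuts the unit boundary facing the host TSS — the left
boundary for a plus-strand host, the right for minus — regardless of the
Pol III unit's own orientation. Background is the median Pol II bin signal
over the gene body, excluding the TSS ± 500 bp, the window itself and the
unit. Fold is window mean over background. The p-value is a Poisson upper
tail on the window's tag count (per-base mass ÷ read length, ceiling), with
expectation = background density × window length ÷ read length;
Benjamini–Hochberg is applied across the events of a run. A zero background
leaves the call flagged and unclassified rather than producing an infinite
fold. Median-based backgrounds are slightly biased low for skewed count
distributions, making the test mildly anticonservative; the 200-event null
calibration keeps the empirical type-I error within 0.07 at nominal 0.05,
which is the tolerance the validation enforces.

Classification uses the elongation factors: NELF enrichment at the window
(same window/background construction on the NELF track) at or above 2-fold
marks a *putative internal TSS*; below it, the call is a *roadblock* (DSIF
may or may not be enriched — it travels with elongating Pol II and is
reported but not used as a gate); with no NELF track the call stays
*unclassified*. Gene-level "Pol II occupied" means gene-body mean at or
above 2× the intergenic median.

The funnel chains confirm → nest → cross-confirm → detect → classify and
reports per-stage counts, which are non-increasing by construction.

## Promoter scanning

Type-2 internal promoters are modeled as an A box and a B box with a spacer
measured from A-box end to B-box start (half-open). Defaults are the
community-standard consensi — A box `TRGCNNARYNNG`, B box `GTTCRANNC`, each
allowing 2 mismatches, `N` in the *sequence* never matching — with a
general spacer range of 20–40 bp and a `strict-mir` preset of 25–26 bp.
Boxes may alternatively be position weight matrices with a score floor.
Scanning enumerates all passing A/B pairs on both strands (B downstream of
A on the hit strand); an element is "potentially functional" when at least
one pair passes. The scanner is verified against an independent brute-force
pair enumeration on random sequences.

Two consensus boxes at a 2-mismatch budget are deliberately permissive and
will hit random sequence at a non-trivial base rate (roughly a few percent
per strand for a B box near a real A box); spacer-constraint checks in the
validation therefore use constructed elements on an inert homopolymer
background, where the planted boxes are provably the only promoter-like
content. Real-element scans should be interpreted with that base rate in
mind, or with tightened budgets/PWM floors.

## Distances and neighbor joining

Pairwise distance between aligned element copies is 100 − percent identity.
Under `pairwise_deletion` (default) only columns ungapped in both rows are
compared; under `count_as_mismatch` a gap opposite a base is a mismatch
(double gaps are never compared). A pair with no comparable columns is an
error naming the pair. Distances, and therefore branch lengths, are in
percent units.

Neighbor joining is the canonical algorithm: repeatedly join the pair
minimizing Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with branch
lengths from the standard split formula and new distances by the reduction
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, ending in a three-way join. Ties on Q go
to the lowest index pair in the current node ordering (deterministic);
negative branch lengths are clamped to zero with the original value logged.
On additive matrices the algorithm provably recovers the generating
topology and branch lengths; the tests verify this on random trees to
1e-9 and against exhaustive least-squares topology search for 5 taxa, and
cross-check topology against an independent library implementation.
Newick output round-trips through the bundled parser losslessly.

## Synthetic data

The generator emulates the data situation the pipeline targets:

- **Genome**: i.i.d. random background with repeat-family copies written in
  at recorded positions. Divergence is substitution-only (each hit base
  moves to one of the three other bases), so exact-string tag mapping is
  well defined and a copy's expected identity to the consensus is exactly
  1 − divergence. No indels, no sequencing errors, no paired ends.
- **Tags**: single-end fixed-length (default 36 bp) tags drawn from a
  per-start-position weight field, then mapped back to *every* genomic
  position whose sequence matches exactly (either strand) and collapsed
  into (sequence, c, match-list) records. The number of draws equals the
  requested depth exactly.
- **Tracks**: input is uniform; the Pol III IP multiplies planted-unit
  positions by their fold (default 8); Pol II runs at the gene body level
  (default 10× intergenic), adds a TSS pausing peak (default 5×, 200 bp)
  and a roadblock pileup (default 3× body, 200 bp wide) centred on the
  unit boundary first met by a polymerase traveling in the host's
  direction; NELF has TSS peaks only (plus a planted pileup when an event
  is configured as a decoy internal TSS); DSIF has TSS peaks plus
  roadblock pileups. Coverage is strand-collapsed, as in the browser
  tracks the analysis mirrors.

Because the pileup is centred on the boundary while the detection window
abuts it, a planted 3-fold pileup appears as roughly 2-fold in the window —
the detection conditions are intentionally not rigged to the generator's
geometry.

What passing on this synthetic data does **not** show: robustness to
mappability artifacts from indels or sequencing error, to fragment-length
effects, to copy-number variation between IP and input, or to annotation
errors in real gene models. The generator's defaults (8-fold IP enrichment,
10× gene bodies, 1e5 tags per track over ~0.1–1 Mb genomes) were chosen as
round, realistic magnitudes for well-powered ChIP experiments at this
genome scale and are fixed in `pol3roadblock.scenarios`; problem sizes in
the validation (10-gene funnel genome, 200-gene null genome, depth 1e5–2e5)
are the package's own choice of a compact but well-powered design.

## Numerical and degenerate-input choices

- Pseudocount 1 ppm; occupancy threshold S ≥ 1; NELF threshold 2-fold;
  summit distance 200 bp; promoter exclusion 250 bp; all configurable.
- EM tolerance 1e-6, max 100 iterations, ±500 bp windows.
- Empty peak lists, too-short sequences and absent optional tracks are
  valid inputs that produce empty/skipped results, not errors; empty match
  lists, out-of-bounds loci, asymmetric or negative distance matrices,
  overlapping same-strand planted features and roadblocks outside any gene
  are errors.
- Every stochastic stage takes an explicit seed and reproduces bit-exactly;
  the pipeline derives per-track seeds from the run seed and echoes them
  into the run report.
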