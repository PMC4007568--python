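# Methods

This note records the models, conventions and numerical choices behind
hetshear, and what the bundled simulator does and does not emulate.

## Coordinates and breakpoint convention

All positions are 1-based and inclusive (SAM convention).  A breakpoint is
the **last reference base before a junction**.  An SV's two breakpoints
(bp1 < bp2) delimit the affected segment bp1+1 … bp2: a deletion removes
it, a tandem duplication inserts a second copy immediately after bp2, an
inversion reverse-complements it in place.  Soft-clip boundaries are mapped
to junction coordinates the same way: a right clip whose last aligned base
is *p* sits at junction *p*; a left clip whose first aligned base is *p*
sits at junction *p* − 1.  With these conventions a matched cluster pair's
coordinates are directly the SV's breakpoints, and `genome_build.apply_edits`
and the simulator's `build_variant_genome` agree byte-for-byte (tested per
seed).

Worked diagram for a deletion with bp1 = 4, bp2 = 7 on `AAACCCGGGTTT`-like
coordinates: the segment 5…7 is removed; a variant read crossing the
junction aligns matching …4 and is right-clipped there, or aligns from 8
onward and is left-clipped at 8 (junction coordinate 7).

## Detection model

Split-read calling proceeds as cluster → match → type:

* **Clustering.** Clip boundaries with clip length ≥ `min_clip_len` (8 bp;
  shorter clips are uninformative for partner matching) merge within
  `merge_window` (2 bp) to the modal position; clusters need
  `min_cluster_support` (3) members.  The consensus clip is a per-column
  majority anchored at the junction (right clips at their start, left
  clips at their end); column ties break to the lexicographically smallest
  base — a rule chosen purely for reproducibility.
* **Matching.** Each cluster's consensus clip is locally aligned near every
  other cluster within `search_radius` (100 kb, generous for the 30 kb
  events the evaluation uses) on both strands, requiring identity ≥
  `min_identity` (0.9) over the clip **and** the implied junction to agree
  with the partner's coordinate within `clip_tolerance` (2 bp).  Matches
  must be reciprocal — each cluster explains the other — which is the
  precision guard that lets unmatched noise clusters sit harmlessly.
* **Typing** follows orientation: right-clip continuing forward *after* a
  downstream partner → deletion; right-clip jumping *back* to a forward
  match upstream → tandem duplication; same-side clusters matching through
  the reverse complement → inversion; reciprocal cross-chromosome forward
  match → translocation (reported only, never applied to a genome).
* **Derivative filter.** After refinement converges, a call sharing one
  breakpoint (within `clip_tolerance`) with a same-type call whose other
  breakpoint is within `main_window` (10 bp) is dropped when its total
  support is under `support_ratio` (0.1) of the stronger call's —
  low-support near-duplicates are sequencing-error artifacts.

## Local realignment

`local_align` is an affine-gap Smith–Waterman (numba-compiled) with
BWA-SW-like defaults match +1, mismatch −3, gap open −5, gap extend −2; a
length-*k* gap costs open + *k*·extend.  Unaligned read ends become
soft-clips.  Tie-breaking is deterministic: among equal-score optima,
lowest reference start, then longest aligned span, then lowest read start
(candidate end-cells are scanned in (ref_end, read_end) order and capped at
64 tracebacks, which only matters in degenerate low-complexity windows).
Scores are verified against an independently written brute-force DP in the
test suite.

The refinement loop (defaults): breakpoint `neighborhood` 650 bp = 2 × the
maximum fragment size, so mates and near-junction reads are always
captured; realignment windows are additionally padded by one read length so
an extracted read always fits entirely (otherwise window edges would
manufacture fake clips).  Unmapped reads are realigned against the whole
reference by exact 20 bp seeds (`seed_len`) in both orientations —
sufficient for error-free data; lower it for real reads.  Placements below
`min_score` 20 stay unmapped.  Extraction always re-reads the *original*
alignment, making each iteration's alignment a pure function of the
current SV set; the loop therefore cannot oscillate and converges when the
SV set repeats, or immediately when realignment moves nothing (an already
perfectly clipped alignment converges in one detection pass).
`max_iterations` is 5; the simulated grids converge in ≤ 3.

## Counting and estimation

`classify_read_at_breakpoint`: a read **spans** when one contiguous match
segment covers `anchor` (5 bp) on both sides of the junction and no clip
boundary lies within `clip_tolerance` (2 bp) of it; it is **soft-clipped**
when a clip boundary on the variant side lies within the tolerance.  The
small tolerance absorbs single-base junction ambiguity; the anchor demands
real evidence of spanning.  The clipped side per breakpoint follows the SV
type (deletion: right at bp1, left at bp2; duplication: the mirror image;
inversion: both sides at both breakpoints).  A read clipped at both
junction positions of one SV counts **once** in B; spanning classifications
sum into A per breakpoint.  A = B = 0 yields an explicitly undefined
estimate, never a silent 0 or 1.  A duplication whose B exceeds A/2 clamps
to H = 1 with a flag (the subtraction heuristic can go negative under
noise).  Translocations borrow the inversion formula and are flagged as
such — no copy-number-aware formula is derivable for them here.

Reported values: H as a fraction and as a percentage with two decimals.

## The simulator, and what passing tests mean

The generator reproduces the published evaluation protocol: 75 bp
paired-end reads; fragment lengths rejection-sampled from N(250, 20²)
truncated to the inclusive bounds [175, 325]; error-free bases, uniform
phred 40; fragment count = ⌊coverage × reference_length / (2 ×
read_length)⌋ with coverage defined over the reference haplotype's length;
fragment haplotype Bernoulli(variant_fraction); positions uniform with no
GC or positional bias.  Evaluation scenarios use a 70 kb reference with
three non-overlapping SVs of 150 bp, 1 kb and 30 kb, mixture fractions
20–100% and coverages 10–1000×; the default benchmark scales the coverage
grid down (≤ 500×, 10 seeds) to desk scale.

Reference sequences are uniform-random DNA — effectively non-repetitive,
matching the deliberately non-repetitive region the protocol evaluates in.
Scenario anchors are additionally resampled until every junction is
*clean*: no local-alignment extension across the junction can accumulate a
positive score under the default scoring.  This makes the true breakpoint
the unique optimum for every junction-crossing read, so exact-recall
assertions are well-posed.  Real genomes contain microhomology and repeats;
there, breakpoints may legitimately shift by a few bases and recall will be
lower — passing tests on this simulator demonstrate correctness of the
machinery, not performance on repetitive real data.

Two truth-alignment dialects: **oracle** (every read placed at its true
position, clipped exactly at true junctions; reverse-strand and
inverted-segment orientations composed correctly) and **naive**, which
reproduces global-aligner failures — junction-crossing reads with overhang
≤ `naive_margin` (5 bp) are forced end-to-end with mismatches, larger
overhangs are left unmapped.  Reads within one collinear segment place
identically in both dialects.

**Mixture truth at a breakpoint.**  Because fragments are Bernoulli-mixed
and spread uniformly over each haplotype's *own* length, a haplotype whose
genome is shorter (large deletions) carries proportionally higher per-locus
depth: the expected fraction of breakpoint reads from the variant is
κf/(κf + 1 − f) with κ = reference length / variant length, not f itself.
The heterogeneity benchmark measures error against this local fraction —
the quantity the estimator actually targets — at one mid-grid mixture
(60%), which preserves both asserted trends (error falls with coverage;
duplications err more than deletions) at a sixth of the cost of the full
fraction grid.  Residual error at high coverage (~2 pp for deletions)
reflects the asymmetric counting windows (spanning needs a 5 bp anchor,
clipping only a 2 bp tolerance), an inherent property of the counting
definitions rather than a bug.

## Known limitations

* Split-read evidence only: no read-pair, read-depth or assembly evidence;
  novel insertions and inter-chromosomal sequence construction are out of
  scope (translocations are reported, not applied).
* One personal sequence per run; no phasing into multiple haplotypes, no
  SNP/small-indel application, no confidence intervals on H.
* The realigner assumes a single reference contig per run (the pipeline is
  aimed at gene-scale regions).
* Targeted-capture bait bias against divergent fragments would make real
  H estimates underestimates; nothing here corrects for it.
* PCR duplicates are assumed removed upstream.
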