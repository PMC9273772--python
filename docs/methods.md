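# Methods

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention) everywhere
in the package; readers apply it verbatim and writers round-trip it
exactly. Chromosome names are compared by exact string equality — no
`chr` aliasing — so mismatched naming between inputs surfaces as a
validation warning rather than silently producing empty joins. The TSS
table carries one row per gene; resolving multi-isoform genes to a single
TSS is the annotation supplier's responsibility.

## Regulatory-potential model

Per gene, binding evidence is summed with exponential distance decay:

RP = Σ_{i=1..k} exp(−(c₀ + c₁·Δᵢ)), with defaults c₀ = 0.5, c₁ = 4,
Δᵢ = |anchor(siteᵢ) − TSS| / W and W = 100 kb (the half-window).

Choices that the formula itself does not fix:

- **Anchor point** of an interval is its midpoint, `floor((start+end)/2)`.
  Binding-site centers are the usual distance anchor and the midpoint is
  symmetric for summit-less BED input.
- **Window boundary is inclusive**: a site exactly 100 kb away has Δ = 1
  and contributes e^−4.5. "Within ±100 kb" is read literally.
- **Distance is unsigned**; upstream and downstream are weighted equally.
  Signed, strand-aware distance is kept in `PeakAnnotation` for reporting
  only (negative = upstream of the TSS on the gene's strand).
- **Deduplication**: motif hits reported on both strands at identical
  coordinates are collapsed to one contribution before scoring
  (`dedupe_hit_intervals` / `dedupe_intervals`); RP counts genomic
  elements, not strands.
- **Determinism of the float sum**: contributions are sorted by ascending
  Δ and summed left to right, so the indexed engine (`rp_score_all`,
  per-chromosome sorted anchors + binary search, O((n+m) log m)) is
  bit-identical to the all-pairs computation, not merely close.

Nearest-gene annotation uses the same anchor; ties in |anchor − TSS| break
to the lexicographically smaller gene id, and peaks on chromosomes without
genes receive a null assignment.

## Motif scanning

A consensus over IUPAC codes is matched by per-position set membership —
no position weight matrix and no score threshold, matching consensus-string
scanners. Both strands are scanned by default (the AP-1 site
`RATGASTCAT` is not its own reverse complement); minus-strand hits are
reported in forward coordinates. Every overlapping occurrence is reported
(no greedy masking), and a hit present on both strands at the same
coordinates appears once per strand — downstream RP scoring deduplicates.
`N` in the genome matches nothing, including against pattern position `N`:
assembly gaps should not generate hits.

## DE filtering and direct-target calls

The DE filter is strict on all three cutoffs (|log2FC| > 0.5, raw
p < 0.05, base mean > 100), so values exactly at a cutoff are excluded.
Raw p values drive the filter by default; `DEThresholds(use_padj=True)`
documents intent when the table's column carries adjusted values. Rows
with missing p are retained but unfilterable.

`is_direct` depends only on the operative criterion — DE-passing AND
RP > 0. The rank-product beta score (fractional RP rank over all genes by
RP descending × fractional DE rank over DE-passing genes by p ascending,
average ranks for ties, both in (0,1]) orders calls but never gates them;
it is undefined (null) for non-direct genes. The gene universe is the
union of the RP and DE tables: DE genes without annotation get RP = 0 and
can never be direct (conservative); annotated genes without DE rows are
"none". An empty intersection of the two universes is an error.

The pipeline computes RP three ways — reference-factor peaks, deduplicated
motif hits, and their union — but drives target calls from the *peak* RP:
knockout expression changes are attributable to where the factor actually
binds, while genome-wide consensus occurrences (most of which are unbound)
would give nearly every gene non-zero RP and dilute the call. Motif and
combined RP tables are persisted alongside for inspection.

## Colocalization

Two intervals overlap reciprocally at fraction f when the intersection
covers ≥ f of *both* (boundary inclusive, default 0.5); zero-length
(abutting) intersections never count. A reference-set peak is colocalized
when every other set has at least one passing witness; the recorded
witness is the first in coordinate order, so the group count counts
reference peaks rather than combinatorial matches. The first peak set
anchors the groups (the biological question is reference-factor-centric);
passing sets in a different order reverses the reference. Candidate
witnesses are located with an interval tree; the reciprocal-fraction test
itself is exact integer arithmetic.

The per-gene summary (`fraction_of_genes_with_colocalized_peak`) counts a
direct target when at least one group's reference-peak midpoint lies
within the RP window of its TSS; it takes the TSS table directly because
the check is against the gene's own TSS, not the peak's nearest gene.

## Conserved regions

Identity is alignment-column identity over a fixed-length window of
*reference* positions (default 200 bp): matching non-gap, non-N columns
divided by the window length. Gap columns and N count as mismatches
(conservative for indels and assembly gaps); query-insertion columns fall
between reference positions and can never match, so the per-reference-
position match profile loses nothing. The window slides by 1 bp;
qualifying windows (matches ≥ ⌈identity·window⌉, computed in integers so
150/200 = 0.75 passes and 148/200 does not) merge when overlapping or
abutting into maximal ECRs, numbered ECR1..n in coordinate order, each
reporting its best window identity. With a TSS given, the search is
restricted to ±flank (default 50 kb), clipped to the sequence.

Desk-scale alignment (`align_pair`) is global affine-gap (match +1,
mismatch −1, open −5, extend −1) via Biopython's `PairwiseAligner`, first
optimal alignment taken for deterministic tie-breaking, refused above
200 kb — genome-scale input should supply a precomputed alignment (the
synthetic generator's substitution-only pairs align gaplessly by
construction). ECR–peak pairing reports a colocalization group within
`proximity_bp` (default 1,000 bp — "proximal" has no canonical value; it
is a config knob, not an inference) of an ECR, overlap counting as
distance 0.

## Synthetic study design

The generator plants truth at the level the pipeline consumes (peaks and
DE summaries, not reads). One master seed derives an independent
`numpy` Generator per component as `default_rng([seed, stream_index])`
(genome 0, genes 1, peaks 2, DE 3, pair 4), so a single integer reproduces
the whole bundle byte-for-byte.

Default conditions and why:

- Genome: 4 × 25 Mb chromosomes of uniform A/C/G/T; 60 planted consensus
  instances (degenerate positions sampled from their IUPAC sets) at
  recorded non-overlapping coordinates. The expected chance-hit count for
  `RATGASTCAT` under a uniform background is 2·L·4/4¹⁰ (two degenerate
  two-fold positions, both strands) ≈ 7.6 hits per Mb — the Poisson target
  the scan tests check.
- Genes: 1,000, TSS uniform per chromosome. Peaks: 2,000 per factor,
  anchored on a 60% bound-gene subset so unbound neighborhoods genuinely
  carry RP = 0; distances from the anchor gene's TSS follow an 80/20
  mixture (80% within ±20 kb, 20% uniform within ±100 kb; widths
  200–800 bp) so Δ — and hence RP — spreads over its range instead of
  degenerating.
- Colocalization: a 60% fraction of reference peaks gets same-width
  witnesses in the other two sets jittered by at most width/4,
  guaranteeing ≥75% (hence ≥50%) reciprocal overlap; remaining partner
  peaks are placed independently.
- DE: planted targets (50) are drawn from genes with RP > 0; log2FC =
  ±(1.5 + N(0, sd)), p ~ U(0, 0.01), base mean ~ U(200, 2000). A
  `background_de_rate` fraction of the remaining genes is forced past the
  thresholds irrespective of binding (the false-positive layer); every
  other background gene is drawn from the null and redrawn if it would
  pass the filter by chance, so the false-DE rate is exactly the
  configured rate and a noise-free run has a clean negative class. The
  default noise regime is sd 0.3 with a 5% false-DE layer.
- Sequence pair: 20 kb, five non-overlapping blocks (200–400 bp) copied at
  identities drawn from {0.75, 0.80, …, 1.0}; background substitution rate
  0.6 (~40% identity, far below the ECR cutoff). Substitution-only, so
  the true alignment is the identity alignment.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level noise and peak-calling artifacts,
peak-width/intensity correlation with occupancy, non-uniform genomic
background (GC, repeats) inflating motif hits, correlated DE errors,
multi-TSS genes, and indel-containing orthologous alignment. Results on
synthetic data validate the *computation*, not the biology.

## Pipeline and problem sizes

Every stage persists its output in standard formats (BED/TSV) so any stage
can be re-run from its inputs; the report records package version, a hash
over the semantic configuration (paths and logging excluded), input
SHA-256 checksums and per-stage counts, plus planted-target recall and
precision when a truth file is supplied. All BED/TSV outputs are
byte-identical across reruns.

The test suite runs structural checks on laptop-scale configurations
(hundreds of genes, sub-Mb chromosomes) and reserves the full study —
1,000 genes, 50 planted targets, 3 × 2,000 peaks, 100 Mb genome — for the
end-to-end recovery checks and `scripts/acceptance.py`; these sizes are
the package's chosen reference conditions and complete in seconds to tens
of seconds. Oracle-equivalence tests (regex motif oracle, all-pairs RP,
O(n²) colocalization, per-position window scan) use fixed seeds and exact
equality where the implementation is designed to be bit-identical.

## Known limitations

- The BETA-style call implements the literal non-zero-score criterion;
  the published BETA tool's rank-product cutoff and its activating/
  repressive function test (one-tailed KS) are out of scope.
- No peak-intensity weighting in RP (the formula has none) and no
  multi-TSS aggregation.
- `align_pair` is quadratic-time/-memory; it is a desk-scale convenience,
  not a genome aligner.
- Consensus scanning has no mismatch tolerance; a PWM scanner is the right
  tool once a score threshold is wanted.
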