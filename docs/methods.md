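# Methods

## Normalized repair

The quantity computed everywhere is the ratio of real to simulated read
density over a feature, each RPKM-normalized with its own library total:

    NR(f) = [c_real(f) / (len_f/10^3 · N_real/10^6)] /
            [c_sim(f)  / (len_f/10^3 · N_sim/10^6)]

Library totals are the full mapped-read counts after deduplication, constant
across features within a run. No pseudocounts are used anywhere: a feature
with a zero among the counts entering a ratio is reported as undefined and
excluded from summaries, rather than shifted onto a distorted ratio scale.
This makes NR exactly 1 when the two libraries coincide and invariant under
duplicating both libraries.

Assumptions: reads are single-end, already aligned, and each read marks one
repair event at its mapped location; a read overlapping two features counts
in both (no ambiguity resolution); coordinates are 0-based half-open
throughout, with GFF3 converted at the parsing boundary.

## Damage-site geometry

In an excision product the lesion dinucleotide sits a fixed distance from
the 3' end: 1-based read positions (L−7, L−6), the 20th/21st positions of a
27-mer. The offset is a parameter (`DamageSiteSpec.offset3`, default 7) so
the same machinery serves both major UV photoproduct chemistries. Reads
shorter than 9 nt are excluded from damage-site statistics and counted in a
skip report; reads with N in a queried window leave that window's
denominator but stay in the library.

## Background simulation

The simulator draws, for each read of the real library, a target damage
dinucleotide from the empirical per-length-class distribution, then
rejection-samples genomic windows (chromosome weighted by length, position
uniform, strand equiprobable) until the window's damage-site dinucleotide
matches and the window is N-free. This preserves three things exactly or in
distribution: total count (exact), read-length histogram (exact), and
per-length damage-site composition (multinomial). Conditional on the
matched dinucleotide, accepted positions are uniform over all carriers —
verified by a chi-square test across genome tiles. Matching the damage-site
dinucleotide (rather than the full read sequence) is the design choice: it
is the content feature that governs where damage can occur and the one the
downstream analyses profile.

Implementation notes: candidate windows are drawn and screened in vectorized
batches, which is distributionally identical to a per-read rejection loop;
output is bit-identical under a fixed seed. After `max_tries_per_read × k`
tries for a class, remaining reads accept the last candidates regardless of
content, keeping the count contract exact; fallbacks are never silent (they
are counted per length class in the run report, alongside realized
total-variation distances). An optional `per_position_mono` mode adds a
second rejection step weighting windows by the real library's per-position
mononucleotide profile against genome background (envelope = product of
per-position maxima); it is off by default as slower with marginal gain.

## Strand convention and metagene binning

The excised oligonucleotide aligns to its strand of origin, so for a "+"
gene the template strand is "−": reads opposite the gene are TS, same-strand
reads NTS. Each gene is extended by half its length on both sides and the
2L region cut into 100 equal integer-edged bins (bins 26–75 cover the body);
minus-strand genes are flipped so bin 1 is always 5'-most. Counts are pooled
across genes per bin index (sums of counts and of bin lengths) and one
NR per bin is computed from the pooled RPKMs — robust to sparse per-gene
bins and scale-invariant, in contrast to averaging per-gene ratios.

Within the metagene a read belongs to the single bin containing its midpoint
(integer floor). This makes per-gene bin counts exactly conserved — the 100
bins partition the region — which is the invariant the binning tests check.
Whole-gene and segment-level counts instead use interval intersection
(≥ 1 bp overlap, configurable), matching standard intersection semantics;
the interval counter is a sorted-array/binary-search index validated
exactly against a nested-loop oracle. An alternative `appended` bin layout
(100 body bins plus 25 per flank) is available behind a flag; `inclusive`
(flanks inside the 100 bins) is the default reading.

Genes whose extended region leaves the chromosome are skipped and reported.
Modal-read-length ties break toward the smaller length.

## Statistics

* Per-gene TCR: log2(NR_TS / NR_NTS), defined only when all four counts are
  positive.
* State comparisons: Welch (unequal-variance) two-sided t-tests on
  segment-level NR vectors; "t-test" alone is ambiguous and Welch is the
  safe default when states contribute unequal segment counts. Raw p-values
  with the conventional star mapping (ns >0.05; * ≤0.05; ** ≤0.01;
  *** ≤0.001; **** ≤0.0001); no multiple-testing correction is applied, so
  the stars mirror the per-pair annotation convention.
* Expression: gene TPM is the TPM of the longest isoform (length ties break
  to the smallest transcript id); the correlation uses Pearson r between
  log2 TS/NTS and log10(TPM + 0.1). The pseudocount keeps zero-TPM genes on
  the axis; `transform="raw"` is available for sensitivity analysis.

## Synthetic data generator

The generator emulates the statistical structure of a (6-4)PP XR-seq study:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 500 kb, GC 0.36 | i.i.d. bases |
| genes | 200, log-normal lengths (median 2 kb, clipped 0.5–8 kb) | non-overlapping, random strands, 1–3 isoforms |
| reads | 200,000 | library size |
| length mixture | 0.8 × {25:.15, 26:.30, 27:.40, 28:.15} + 0.2 × U{16..21} | full-length vs 5'-degraded products |
| damage spectrum | TT .261, TC .242, CT .159, rest ∝ availability | lesion dinucleotide preferences |
| TCR | ρ(gene) = 1 + κ·rank(TPM)/n, κ = 1 | template-strand boost grows with expression |
| state multipliers | open 1.5, genic 1.0, hetAT 0.5, hetGC 0.6 | chromatin-dependent repair rates |
| bumps | amplitude 1.5, σ = 200 bp at promoter (−300), TSS, TES | positional repair enrichment |

Each read arises from a lesion site drawn with weight `spectrum preference ×
state multiplier × ρ (template strands inside genes) × bump factor`, where
the spectrum preference is q(d)/availability(d) so the realized spectrum
tracks q; a length from the mixture then places the read with the lesion at
(L−7, L−6). Chromatin states tile the intergenic space and are labeled by
empirical GC terciles (hetAT lowest, hetGC highest), so composition ordering
holds by construction. All recovery targets — per-gene expected TS/NTS, the
pooled gene-body expectation, per-state expected NR — are computed exactly
from the weight arrays and stored in the truth record.

What the generator does **not** emulate: sequencing errors and quality,
mappability and alignment artifacts, replicate structure, overlapping or
nested genes, isoform-level transcription units, chromatin states with
internal structure, and real Arabidopsis base composition beyond a global GC
fraction. Passing recovery tests therefore demonstrates correctness of the
computations under the stated generative model, not properties of any real
library.

Two residual effects are worth knowing. First, the realized damage spectrum
deviates from q by the (tiny, <0.5 point) correlation between a
dinucleotide's genomic locations and the position factors. Second, with
κ = 0 the exact per-gene expected TS/NTS is 1 only up to a small (~±2%)
interaction between per-strand dinucleotide availability and the
strand-symmetric position factors; the truth record carries the exact
values.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 200k-read study (100k for
the simulator-contract checks) on the 1 Mb synthetic genome; unit tests use
smaller instances of the same generator. Frequencies are exact rational
tallies; distribution sums are checked to 1e-9; bin edges are rounded
`linspace` values, so pooled bin lengths absorb the ±1 bp rounding. The
deduplication key is (chrom, start, end, strand) — coordinate-based, as
appropriate for aligned single-end reads — with the first occurrence kept
and sorted, deterministic output. Replicate merging, where used upstream,
is assumed to follow per-library deduplication.

## Known limitations

* BAM input is out of scope; the pipeline consumes aligned BED6 (upstream
  trimming/alignment/MAPQ filtering are external).
* bedGraph output is plain text (no BigWig).
* Metagene peak positions are descriptive; no peak calling is performed.
* The chromatin-state t-tests treat segments as independent units, as in
  the conventional analysis; spatial autocorrelation between neighboring
  segments is not modeled.
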