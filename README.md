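# xrprofile

Strand-aware analysis of excision-repair sequencing (XR-seq) maps of UV
photoproducts, built around normalization against a sequence-content-matched
simulated background.

## The problem

XR-seq sequences the short oligonucleotides (~16–28 nt) that nucleotide
excision repair cuts out around a UV lesion, so mapped read density reports
repair activity at near-nucleotide resolution. Raw density, however, confounds
*repair* with *damage opportunity*: dipyrimidine-rich sequence accumulates more
UV photoproducts — pyrimidine–pyrimidone (6-4) photoproducts and cyclobutane
pyrimidine dimers — and therefore yields more excision products regardless of
how efficiently it is repaired. `xrprofile` is for researchers who have aligned
XR-seq reads (BED6) plus a genome, gene annotation, chromatin-state
segmentation and expression table, and want the repair biology with the
sequence bias removed:

* how strong transcription-coupled repair (TCR) is relative to global repair,
* how repair distributes along genes, promoters, TSS and TES,
* which damage-site dinucleotides the lesions form at,
* how chromatin state modulates repair rates.

## The model

Everything reduces to **normalized repair** over a genomic feature *f*:

```
NR(f) = RPKM_real(f) / RPKM_sim(f),      RPKM = count / ((len/10^3) · (N/10^6))
```

where the simulated library is drawn uniformly from the genome while matching
the real library's total read count, exact read-length histogram and, per
length class *L*, the dinucleotide distribution at the damage site — read
positions (L−7, L−6), i.e. the 20th/21st position of a 27-mer, where the
lesion sits in an excision product. NR(f) = 1 means repair exactly at the
level the local sequence content predicts.

For a gene on strand *s*, reads on the opposite strand are template-strand
(TS) repair events and same-strand reads are non-transcribed-strand (NTS)
events; the per-gene statistic is

```
log2( NR_TS / NR_NTS )
```

which is 0 under pure global repair and positive under TCR. Metagene profiles
cut each gene plus half-length flanks into 100 equal bins and pool counts per
bin index across genes before normalization. Chromatin-state repair is NR per
segment, strandless, compared between states with Welch t-tests (stars:
`ns` p>0.05, `*` ≤0.05, `**` ≤0.01, `***` ≤0.001, `****` ≤0.0001). Expression
enters as the TPM of each gene's longest isoform, correlated with the log2
TS/NTS ratio (Pearson, on log10(TPM+0.1)).

A first-class synthetic-data generator produces genomes, annotations,
segmentations and read libraries with a controllable damage spectrum, TCR
strength, chromatin-state multipliers and promoter/TSS/TES enrichment — with
every expectation recorded exactly, so the entire pipeline is testable
without any downloads.

## Worked example

```python
from xrprofile import (SyntheticSpec, SimLibraryConfig, generate_dataset,
                       simulate_matched_library, metagene_profile,
                       gene_ts_nts, correlate_expression)

ds = generate_dataset(SyntheticSpec(seed=7, n_reads=200_000))
sim, _ = simulate_matched_library(ds.reads, ds.genome, SimLibraryConfig(seed=11))
prof = metagene_profile(ds.genes, ds.reads, sim, ds.genome)
rec = gene_ts_nts(ds.genes, ds.reads, sim)
res = correlate_expression(rec, ds.gene_tpm)
```

Running `python examples/04_metagene_tcr.py` (the same computation) prints:

```
genes in metagene: 198
mean gene-body TS/NTS normalized ratio: 1.512
generator's exact expectation:          1.503
median per-gene log2 TS/NTS: 0.580
Pearson r (log2 TS/NTS vs log10 TPM): 0.784  (p = 7.3e-43, n = 200)
```

The measured gene-body TS/NTS ratio (1.512) recovers the exact expectation
recorded by the generator (1.503): template strands of expressed genes are
repaired ~1.5× faster than coding strands, and the bias grows with expression
(positive Pearson r). `examples/02_read_qc.py` recovers the damage-site
spectrum (TT 26.0%, TC 24.3%, CT 16.1% at the generator's 26.1/24.2/15.9
settings), and `examples/05_chromatin_states.py` the chromatin ordering
(open 1.43 > genic 1.17 > hetGC 0.65 > hetAT 0.57, open vs hetAT `****`).
The other examples cover dataset generation, background simulation and the
end-to-end CLI pipeline.

A thin command line mirrors the library (`xrprofile synth / qc / simulate /
profile / tsnts / states / correlate / bedgraph / run-all`); `run-all`
executes the whole pipeline from a YAML config with checksum-based stage
caching.

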