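"""Generate a synthetic XR-seq study and write it to disk.

Builds a toy genome, gene annotation with isoform expression, a chromatin
state segmentation and an excision-repair read library with known,
recorded ground truth, then writes everything as plain-text files.
"""
from xrprofile import SyntheticSpec, generate_dataset, write_dataset

spec = SyntheticSpec(seed=7, n_reads=50_000, n_genes=100, chrom_length=250_000)
ds = generate_dataset(spec)
paths = write_dataset(ds, "scratch/example_dataset")

print(f"genome: {sum(ds.genome.chrom_sizes().values()):,} bp over {len(ds.genome)} chromosomes")
print(f"genes: {len(ds.genes)}, chromatin segments: {len(ds.states)}")
print(f"reads: {len(ds.reads):,}")
print(f"expected pooled gene-body TS/NTS: {ds.truth.expected_pooled_body_ts_nts:.3f}")
print("files:", ", ".join(p.name for p in paths.values()))
# The expected TS/NTS ratio above is what a perfect analysis should recover
# from this library; the recovery itself is demonstrated in example 04.
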