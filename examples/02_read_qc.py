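"""Read-level QC: length distribution and damage-site dinucleotide spectrum.

Excision products come in two length populations (full-length ~25-28 nt
peaking at 27, plus 5'-degraded 16-21 nt forms) and carry the UV lesion
dinucleotide at positions L-7/L-6, i.e. 20-21 of a 27-mer.
"""
from xrprofile import (
    SyntheticSpec,
    damage_site_composition,
    generate_dataset,
    length_distribution,
    positional_dinucleotide_frequencies,
)

ds = generate_dataset(SyntheticSpec(seed=7, n_reads=50_000))

hist = length_distribution(ds.reads)
print(f"modal read length: {hist.modal_length} nt")
print(f"fraction in primary window 25-28: {hist.primary_fraction:.3f}")

comp = damage_site_composition(ds.reads, ds.genome)
top = comp.fractions.sort_values(ascending=False).head(4)
print("damage-site dinucleotides (all read lengths):")
for dinuc, frac in top.items():
    print(f"  {dinuc}: {100 * frac:.1f}%")
print(f"pyrimidine-dinucleotide share: {100 * comp.pyrimidine_share:.1f}%")

# positions 20-21 of 27-mers are where the dipyrimidines concentrate
prof = positional_dinucleotide_frequencies(ds.reads, ds.genome, 27)
pyr = prof.pyrimidine_subset.sum(axis=0)
print(f"pyrimidine-dinucleotide fraction at position 20 of 27-mers: {pyr[20]:.3f}")
print(f"... at position 5 (background): {pyr[5]:.3f}")
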