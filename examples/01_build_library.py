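"""Build the transporter sgRNA library and its pseudogene null.

The manifest mirrors the screening composition: 413 SLC, 28 atypical SLC and
48 ABC transporter genes at 10 sgRNAs per transcription start site (37 genes
carry two TSSs), plus 730 non-targeting controls. Pseudogenes are random
groups of 10 NTC sgRNAs scored later exactly like real genes to calibrate
significance.
"""

from fluxscreen import build_manifest, make_pseudogenes

manifest = build_manifest(seed=1)
pseudogenes = make_pseudogenes(manifest, n_pseudogenes=len(manifest.genes), size=10, seed=2)

print(f"library entries:   {len(manifest)}")
print(f"target genes:      {len(manifest.genes)}")
print(f"two-TSS genes:     {len(manifest.two_tss_genes)}")
print(f"NTC sgRNAs:        {len(manifest.ntc_ids)}")
print(f"pseudogenes:       {len(pseudogenes)} x {len(pseudogenes[0].member_sgrna_ids)} members")
# 5,990 entries = (489 - 37) * 10 + 37 * 20 + 730: every number above is a
# fixed property of the library design, not of any particular seed.
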