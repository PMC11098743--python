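"""Quantify a growth phenotype from a qPCR competition assay.

A test knockdown line is mixed 50/50 with an NTC control and grown in a test
medium; two qPCR reactions (test-sgRNA primer vs NTC primer) read the
mixture composition. The per-doubling phenotype is -ddCt / dD: the change in
Ct difference between endpoint and T0, normalized by the doubling difference
between test and reference media, signed so depletion is negative.
"""

from fluxscreen import competition_phenotype, simulate_competition

# the test line loses 0.5 doublings per doubling in low amino acid:
records = simulate_competition(
    true_log2fc_per_doubling=-0.5, doublings_test=8, doublings_ref=4, ct_noise_sd=0.0
)
print(records[["condition", "timepoint", "ct_test", "ct_ntc"]].to_string(index=False))
phenotype = competition_phenotype(records)["test"]
print(f"estimated per-doubling phenotype: {phenotype:+.3f} (truth -0.500)")

# with qPCR noise the estimate scatters around the truth:
noisy = simulate_competition(-0.5, 8, 4, ct_noise_sd=0.2, seed=5)
print(f"with 0.2-cycle Ct noise:          {competition_phenotype(noisy)['test']:+.3f}")
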