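"""Quality control for tumour (in vivo) screen replicates.

Each tumour's technical noise is the number of NTC sgRNAs whose counts fall
outside one log2 of the NTC median. The two noisiest of six tumours are
excluded, survivors are averaged in rank-matched pairs, and gene scores from
tumour screens are reported after normalization to the most depleted gene
(so the strongest depletion is exactly -1).
"""

import pandas as pd

import fluxscreen as fs
from fluxscreen.scoring import ScreenExperiment, make_sample_sheet

manifest = fs.build_manifest({"SLC": 3}, two_tss_genes=0, n_ntc=200, seed=1)
ids = [e.sgrna_id for e in manifest.entries]

cols, rows = {}, []
for j, n_noisy in enumerate([0, 1, 2, 3, 50, 60]):
    col = pd.Series(100.0, index=ids)
    col.loc[manifest.ntc_ids[:n_noisy]] = 1000.0  # push NTCs out of band
    cols[f"tumour{j}"] = col
    rows.append({"sample_id": f"tumour{j}", "arm": "tumour", "replicate": j})
expt = ScreenExperiment(pd.DataFrame(cols), make_sample_sheet(rows), mode="in_vivo")

qc = fs.invivo_replicate_qc(expt, manifest, n_exclude=2)
print("noise metric per tumour:", qc.meta["invivo_noise_metrics"])
print("excluded:", qc.meta["invivo_excluded"])
print("paired samples kept:", list(qc.counts.columns))

table = pd.DataFrame(
    {
        "gene": ["g1", "g2", "g3"],
        "tss": ["primary"] * 3,
        "is_pseudogene": [False] * 3,
        "phenotype_score": [-0.8, -0.2, 0.1],
        "p_value": [1e-4, 1e-2, 0.5],
        "screen_score": [-1.7, -0.4, 0.2],
        "n_sgrnas": [10] * 3,
        "scored": [True] * 3,
        "class": ["none"] * 3,
    }
)
normalized = fs.normalize_to_most_depleted(table)
print("normalized growth scores:", normalized["screen_score"].round(3).tolist())
# The most depleted gene pins the scale at -1; other scores are fractions of
# the strongest in vivo depletion, making screens comparable across tumours.
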