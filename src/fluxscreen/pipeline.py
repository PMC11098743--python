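"""End-to-end reproducible runs: simulate -> score -> hits, with provenance.

Outputs are plain TSV/CSV plus a JSON sidecar recording the configuration
hash, seeds and package version, so a fixed-seed run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig, save_config
from .library import build_manifest, make_pseudogenes, pseudogenes_to_csv
from .scoring import (
    ScoringParams,
    ThresholdPolicy,
    average_replicates,
    call_hits,
    score_screen,
    write_gene_table,
)
from .synth import Arm, ScreenDesign, ScreenTruth, simulate_screen

log = logging.getLogger("fluxscreen")


def run_pipeline(config: RunConfig, outdir, effects: dict[str, float] | None = None) -> Path:
    """Simulate a screen under ``config`` and score it end to end.

    Writes the manifest, pseudogene assignments, simulated counts, the
    averaged gene table with hit classes, and a provenance sidecar.
    Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    manifest = build_manifest(seed=seed)
    pseudogenes = make_pseudogenes(manifest, len(manifest.genes), seed=seed + 1)
    manifest.to_csv(outdir / "manifest.csv")
    pseudogenes_to_csv(pseudogenes, outdir / "pseudogenes.csv")

    sim = config.simulation
    design = ScreenDesign(
        arms=[
            Arm("control", sim.doublings, effect_scale=0.0),
            Arm("treated", sim.doublings, effect_scale=1.0),
        ],
        n_replicates=sim.n_replicates,
        reads_per_sgrna=sim.reads_per_sgrna,
    )
    truth = ScreenTruth(effects=effects or {}, sigma_abundance=sim.sigma_abundance)
    expt = simulate_screen(manifest, truth, design, seed=seed + 2)
    expt.to_tsv(outdir / "counts.tsv")
    expt.samples.to_csv(outdir / "samples.csv")

    params = ScoringParams(
        min_count=config.scoring.min_count,
        pseudocount=config.scoring.pseudocount,
        top_k=config.scoring.top_k,
        min_sgrnas=config.scoring.min_sgrnas,
        p_floor=config.scoring.p_floor,
    )
    tables = []
    for rep in range(1, sim.n_replicates + 1):
        pair = (f"treated_rep{rep}", f"control_rep{rep}")
        tables.append(score_screen(expt, manifest, pseudogenes, pair, params))
        log.info("scored replicate %d (%s vs %s)", rep, *pair)
    averaged = average_replicates(tables)
    policy = ThresholdPolicy(
        source=config.scoring.threshold_source,
        untreated_threshold=config.scoring.untreated_threshold,
        resistant_cutoff=config.scoring.resistant_cutoff,
        hypersensitive_cutoff=config.scoring.hypersensitive_cutoff,
    )
    hits = call_hits(averaged, policy)
    write_gene_table(hits, outdir / "gene_scores.tsv")

    save_config(config, outdir / "config.yaml")
    provenance = {
        "config_hash": config.digest(),
        "seed": seed,
        "version": __version__,
        "n_genes": len(manifest.genes),
        "n_pseudogenes": len(pseudogenes),
        "thresholds": list(hits.attrs.get("thresholds", ())),
        "n_hits": int((hits["class"] != "none").sum()),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    log.info("pipeline complete: %d hits", provenance["n_hits"])
    return outdir
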