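"""Gene-level scoring of pooled CRISPRi/a screens.

The pipeline mirrors standard pooled-screen processing: exact-match
protospacer counting, technical-replicate averaging on a reads-per-million
scale, a minimum-count filter with pseudocount, per-sgRNA rho phenotypes
(log2 treated/control ratio, NTC-median-centred, divided by population
doublings), and gene-level summaries:

* phenotype score (PS): signed mean of the 7 largest-|rho| sgRNA phenotypes,
* p: two-sided Mann-Whitney of the gene's rhos against all NTC rhos,
* screen score (SS): PS * -log10(p).

Pseudogenes (random NTC groups) are scored identically and their extreme
screen scores define the significance cut-offs. In vivo (tumour) screens use
a lowered count filter, no doubling normalization, an NTC-dispersion QC that
drops the noisiest tumours, and normalization to the most depleted gene.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    CannotCenterError,
    CannotThresholdError,
    DegenerateSampleError,
    InsufficientReplicatesError,
    InvalidParameterError,
    ParseError,
    UndefinedCorrelationError,
)
from .library import LibraryManifest, PseudogeneAssignment

P_FLOOR = 1e-16  # p values are floored here before -log10

# ---------------------------------------------------------------------------
# containers


@dataclass
class ScreenExperiment:
    """An sgRNA x sample count table with per-sample metadata.

    ``samples`` is indexed by sample id with columns
    ``arm, replicate, tech_rep, doublings, mode``. ``mode`` is ``in_vitro``
    or ``in_vivo``; in vivo screens carry no doubling normalization.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    mode: str = "in_vitro"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (np.asarray(self.counts.to_numpy(), dtype=float) < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise InvalidParameterError(f"samples sheet missing metadata for {sorted(missing)}")

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all given column=value criteria."""
        sel = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            sel &= self.samples[col] == val
        return [s for s in self.samples.index[sel] if s in self.counts.columns]

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("sgrna_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, mode: str = "in_vitro"):
        counts = pd.read_csv(counts_path, sep="\t", index_col="sgrna_id")
        samples = pd.read_csv(samples_path, index_col="sample_id")
        return cls(counts, samples, mode=mode)


def make_sample_sheet(rows: list[dict]) -> pd.DataFrame:
    """Build a sample sheet from dicts with keys sample_id/arm/replicate/tech_rep/doublings/mode."""
    df = pd.DataFrame(rows)
    defaults = {"tech_rep": 1, "doublings": 0.0, "mode": "in_vitro"}
    for col, val in defaults.items():
        if col not in df:
            df[col] = val
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# read counting


def _iter_fastq(path):
    """Yield (index, sequence) from a FASTQ file (gzip allowed)."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    idx = -1
    with opener(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                idx += 1
                yield idx, str(rec.seq).upper()
        except ValueError as exc:  # Biopython raises ValueError on bad records
            raise ParseError(
                f"malformed FASTQ record at index {idx + 1}: {exc}", record_index=idx + 1
            ) from exc


def align_or_load_counts(
    path,
    manifest: LibraryManifest,
    sample_id: str = "sample",
    offset: int = 0,
    samples: pd.DataFrame | None = None,
) -> ScreenExperiment:
    """Count reads per sgRNA by exact protospacer match, or load a counts TSV.

    FASTQ reads are matched at ``offset`` against every protospacer length
    present in the manifest (longest first). The alignment rate (matched /
    total reads) is stored in ``meta['alignment_rate']``.
    """
    spath = str(path)
    if spath.endswith((".tsv", ".txt")):
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "sgrna_id"
        unknown = set(counts.index) - {e.sgrna_id for e in manifest.entries}
        if unknown:
            raise AlignmentError(f"counts contain sgRNAs absent from the manifest: {sorted(unknown)[:3]}")
        if samples is None:
            samples = make_sample_sheet(
                [{"sample_id": c, "arm": c, "replicate": 1} for c in counts.columns]
            )
        return ScreenExperiment(counts, samples)

    lut = {e.protospacer: e.sgrna_id for e in manifest.entries}
    lengths = sorted({len(p) for p in lut}, reverse=True)
    counts_map = {e.sgrna_id: 0 for e in manifest.entries}
    total = matched = 0
    for _, seq in _iter_fastq(path):
        total += 1
        for L in lengths:
            sg = lut.get(seq[offset : offset + L])
            if sg is not None:
                counts_map[sg] += 1
                matched += 1
                break
    counts = pd.DataFrame({sample_id: pd.Series(counts_map)})
    counts.index.name = "sgrna_id"
    if samples is None:
        samples = make_sample_sheet([{"sample_id": sample_id, "arm": sample_id, "replicate": 1}])
    meta = {
        "alignment_rate": matched / total if total else float("nan"),
        "reads_total": total,
        "reads_matched": matched,
    }
    return ScreenExperiment(counts, samples, meta=meta)


# ---------------------------------------------------------------------------
# normalization and phenotypes


def average_technical_replicates(expt: ScreenExperiment) -> ScreenExperiment:
    """Average technical replicates after normalizing each to reads per million.

    Samples with a single technical replicate pass through unchanged (raw
    scale); groups with several are emitted on the reads-per-million scale.
    """
    groups: dict[tuple, list[str]] = {}
    for sid in expt.counts.columns:
        row = expt.samples.loc[sid]
        groups.setdefault((row["arm"], row["replicate"]), []).append(sid)

    cols, rows = {}, []
    for (arm, rep), sids in groups.items():
        if len(sids) == 1:
            sid = sids[0]
            cols[sid] = expt.counts[sid]
            rows.append(expt.samples.loc[sid].to_dict() | {"sample_id": sid})
            continue
        normed = []
        for sid in sids:
            tot = expt.counts[sid].sum()
            if tot == 0:
                raise DegenerateSampleError(f"sample {sid} has zero total reads")
            normed.append(expt.counts[sid] / tot * 1e6)
        new_id = f"{arm}_rep{rep}"
        cols[new_id] = sum(normed) / len(normed)
        meta = expt.samples.loc[sids[0]].to_dict()
        meta.update({"sample_id": new_id, "tech_rep": 0})
        rows.append(meta)
    counts = pd.DataFrame(cols)
    counts.index.name = "sgrna_id"
    samples = pd.DataFrame(rows).set_index("sample_id")
    return ScreenExperiment(counts, samples, mode=expt.mode, meta=dict(expt.meta))


def filter_and_pseudocount(
    expt: ScreenExperiment,
    pair: tuple[str, str],
    min_count: float = 100,
    pseudocount: float = 10,
) -> pd.DataFrame:
    """Depth-match a (treated, control) sample pair, filter, add pseudocount.

    Both samples are rescaled to the geometric mean of their totals; sgRNAs
    whose depth-matched count reaches ``min_count`` in at least one of the
    two samples are retained and receive ``pseudocount``; the rest are
    flagged ``pass_filter=False`` and carry no phenotype.
    """
    if min_count < 0:
        raise InvalidParameterError("min_count must be non-negative")
    treated_id, control_id = pair
    for sid in pair:
        if sid not in expt.counts.columns:
            raise AlignmentError(f"sample {sid} not present in the experiment")
    t = expt.counts[treated_id].astype(float)
    c = expt.counts[control_id].astype(float)
    tot_t, tot_c = t.sum(), c.sum()
    if tot_t == 0 or tot_c == 0:
        raise DegenerateSampleError("cannot depth-match a zero-total sample")
    target = math.sqrt(tot_t * tot_c)
    t, c = t * target / tot_t, c * target / tot_c
    keep = (t >= min_count) | (c >= min_count)
    scaffold = pd.DataFrame({"treated": t, "control": c, "pass_filter": keep})
    scaffold.loc[keep, ["treated", "control"]] += pseudocount
    scaffold.attrs.update({"pair": pair, "min_count": min_count, "pseudocount": pseudocount})
    return scaffold


def sgrna_phenotype(
    scaffold: pd.DataFrame,
    ntc_ids,
    doublings: float,
    mode: str = "in_vitro",
) -> pd.DataFrame:
    """Per-sgRNA rho: NTC-median-centred log2 treated/control ratio per doubling.

    ``rho_i = [log2(t_i / c_i) - median_NTC log2(t/c)] / D`` with ``D := 1``
    for in vivo screens. The NTC median of the result is exactly 0.
    """
    if mode == "in_vitro":
        if doublings <= 0:
            raise InvalidParameterError("doublings must be positive for in vitro screens")
        D = float(doublings)
    else:
        D = 1.0
    ok = scaffold["pass_filter"]
    logr = np.log2(scaffold.loc[ok, "treated"] / scaffold.loc[ok, "control"])
    ntc_logr = logr[logr.index.intersection(pd.Index(ntc_ids))]
    if ntc_logr.empty:
        raise CannotCenterError("no NTC sgRNAs survive filtering")
    rho = (logr - ntc_logr.median()) / D
    out = pd.DataFrame({"rho": rho.reindex(scaffold.index), "pass_filter": ok})
    out.attrs.update(dict(scaffold.attrs), doublings=D, mode=mode)
    return out


# ---------------------------------------------------------------------------
# gene-level statistics


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by rank-sum DP over midranks (tie-safe).

    The permutation distribution of the rank sum of ``len(x)`` labels drawn
    without replacement from the combined midranks is computed exactly with
    a dynamic program over doubled (integer) midranks.
    """
    n, m = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(allv)).astype(int)  # doubled midranks
    obs = int(ranks2[:n].sum())
    N = n + m
    # ways[k][s] = number of k-subsets of the first i items with doubled rank sum s
    ways = [dict() for _ in range(n + 1)]
    ways[0][0] = 1
    for r in ranks2:
        for k in range(min(n, N) - 1, -1, -1):
            src = ways[k]
            dst = ways[k + 1]
            for s, w in src.items():
                dst[s + r] = dst.get(s + r, 0) + w
    dist = ways[n]
    total = math.comb(N, n)
    mu2 = n * (N + 1)  # doubled expected rank sum
    dev = abs(obs - mu2)
    favorable = sum(w for s, w in dist.items() if abs(s - mu2) >= dev)
    return favorable / total


def mannwhitney_p(x, y, exact_max: int = 12) -> float:
    """Two-sided Mann-Whitney p of ``x`` vs ``y``.

    Exact enumeration (tie-corrected) when both groups have at most
    ``exact_max`` observations, otherwise the normal approximation with tie
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if len(x) <= exact_max and len(y) <= exact_max:
        return _exact_mannwhitney_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def top_k_signed_mean(rhos, k: int = 7) -> float:
    """Signed mean of the ``min(k, n)`` phenotypes largest by absolute value."""
    arr = np.asarray(rhos, dtype=float)
    order = np.argsort(-np.abs(arr), kind="stable")
    return float(arr[order[: min(k, len(arr))]].mean())


def gene_score(
    rhos,
    ntc_rhos,
    top_k: int = 7,
    min_sgrnas: int = 5,
    p_floor: float = P_FLOOR,
) -> dict:
    """Score one gene unit: phenotype score, Mann-Whitney p and screen score.

    Returns ``{"phenotype_score", "p_value", "screen_score", "n_sgrnas",
    "scored"}``; a unit retaining fewer than ``min_sgrnas`` phenotypes is
    marked unscored (NaN scores) rather than raising.
    """
    arr = np.asarray(rhos, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < min_sgrnas:
        return {
            "phenotype_score": float("nan"),
            "p_value": float("nan"),
            "screen_score": float("nan"),
            "n_sgrnas": len(arr),
            "scored": False,
        }
    ps = top_k_signed_mean(arr, top_k)
    p = mannwhitney_p(arr, np.asarray(ntc_rhos, dtype=float))
    ss = ps * -math.log10(max(p, p_floor))
    return {
        "phenotype_score": ps,
        "p_value": p,
        "screen_score": ss,
        "n_sgrnas": len(arr),
        "scored": True,
    }


@dataclass
class ScoringParams:
    """Tunable scoring parameters (defaults follow the screening pipeline)."""

    min_count: float = 100.0
    pseudocount: float = 10.0
    top_k: int = 7
    min_sgrnas: int = 5
    p_floor: float = P_FLOOR


def score_screen(
    expt: ScreenExperiment,
    manifest: LibraryManifest,
    pseudogenes: list[PseudogeneAssignment],
    pair: tuple[str, str],
    params: ScoringParams | None = None,
    doublings: float | None = None,
) -> pd.DataFrame:
    """Score every gene unit and pseudogene for one treated/control pair.

    Genes with two TSSs are scored as independent 10-sgRNA units and the
    gene-level row keeps the unit with the larger |screen score|.
    Pseudogenes are scored identically to real genes and appear in the same
    table (``is_pseudogene=True``). The result carries provenance in
    ``attrs``.
    """
    params = params or ScoringParams()
    if doublings is None:
        doublings = float(expt.samples.loc[pair[0], "doublings"])
    scaffold = filter_and_pseudocount(expt, pair, params.min_count, params.pseudocount)
    ntc_ids = [i for i in manifest.ntc_ids if i in scaffold.index]
    pheno = sgrna_phenotype(scaffold, ntc_ids, doublings, expt.mode)
    rho = pheno["rho"]
    ntc_rhos = rho.loc[rho.index.intersection(pd.Index(ntc_ids))].dropna().to_numpy()

    by_unit: dict[tuple[str, str], list[str]] = {}
    for e in manifest.entries:
        if not e.is_ntc:
            by_unit.setdefault((e.gene, e.tss), []).append(e.sgrna_id)

    unit_rows = []
    for (gene, tss), sgrnas in by_unit.items():
        rhos = rho.reindex(sgrnas).dropna().to_numpy()
        row = gene_score(rhos, ntc_rhos, params.top_k, params.min_sgrnas, params.p_floor)
        unit_rows.append({"gene": gene, "tss": tss, "is_pseudogene": False, **row})
    units = pd.DataFrame(unit_rows)

    # gene-level: for two-TSS genes keep the TSS unit with larger |SS|
    def _pick(group: pd.DataFrame) -> pd.Series:
        scored = group[group["scored"]]
        if scored.empty:
            return group.iloc[0]
        return scored.loc[scored["screen_score"].abs().idxmax()]

    gene_rows = [_pick(g) for _, g in units.groupby("gene", sort=False)]

    pseudo_rows = []
    for pg in pseudogenes:
        rhos = rho.reindex(list(pg.member_sgrna_ids)).dropna().to_numpy()
        row = gene_score(rhos, ntc_rhos, params.top_k, params.min_sgrnas, params.p_floor)
        pseudo_rows.append(
            {"gene": pg.pseudogene_id, "tss": "primary", "is_pseudogene": True, **row}
        )

    table = pd.concat(
        [pd.DataFrame(gene_rows).reset_index(drop=True), pd.DataFrame(pseudo_rows)],
        ignore_index=True,
    )
    table["class"] = "none"
    table.attrs.update(
        {
            "pair": pair,
            "doublings": doublings,
            "mode": expt.mode,
            "params": vars(params),
            "n_ntc_rhos": len(ntc_rhos),
        }
    )
    return table


def average_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average screen and phenotype scores across replicate gene tables.

    Per-replicate screen scores are kept as ``screen_score_rep{i}`` columns
    so significance thresholds can be derived before averaging.
    """
    if not tables:
        raise InvalidParameterError("need at least one table")
    base = tables[0][["gene", "tss", "is_pseudogene"]].copy()
    key = tables[0]["gene"]
    for i, t in enumerate(tables):
        if not t["gene"].equals(key):
            raise AlignmentError(f"replicate {i} has a different gene universe")
    for col in ("phenotype_score", "p_value", "screen_score", "n_sgrnas"):
        base[col] = sum(t[col] for t in tables) / len(tables)
    for i, t in enumerate(tables, start=1):
        base[f"screen_score_rep{i}"] = t["screen_score"]
    base["scored"] = np.logical_and.reduce([t["scored"] for t in tables])
    base["class"] = "none"
    base.attrs["n_replicates"] = len(tables)
    return base


@dataclass
class ThresholdPolicy:
    """How significance cut-offs and the untreated-arm exclusion are applied.

    ``source='per_replicate'`` derives cut-offs from the extreme pseudogene
    screen score in any replicate column before averaging (the stringent
    variant); ``'averaged'`` uses the averaged pseudogene scores.
    ``require_reproducible`` additionally demands that every replicate score
    (not just the average) clears the cut-off, so hits are significantly
    *and reproducibly* enriched or depleted.
    """

    source: str = "per_replicate"
    require_reproducible: bool = True
    untreated_threshold: float = -0.12
    resistant_cutoff: float = 1.5
    hypersensitive_cutoff: float = -1.5


def pseudogene_thresholds(table: pd.DataFrame, source: str = "per_replicate") -> tuple[float, float]:
    """(theta_minus, theta_plus): extreme pseudogene screen scores."""
    pseudo = table[table["is_pseudogene"] & table["scored"]]
    if pseudo.empty:
        raise CannotThresholdError("no scored pseudogenes present")
    rep_cols = [c for c in table.columns if c.startswith("screen_score_rep")]
    if source == "per_replicate" and rep_cols:
        vals = pseudo[rep_cols].to_numpy().ravel()
    else:
        vals = pseudo["screen_score"].to_numpy()
    vals = vals[~np.isnan(vals)]
    return float(vals.min()), float(vals.max())


def call_hits(
    table: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
    thresholds: tuple[float, float] | None = None,
    untreated: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify genes as depleted/enriched/none at pseudogene-derived cut-offs.

    If an ``untreated`` control-arm table is supplied, significant genes
    whose untreated per-replicate screen score falls below
    ``policy.untreated_threshold`` are reset to ``none`` (pan-resistance
    guard) unless they are strongly resistant
    (> ``policy.resistant_cutoff``) or hypersensitive
    (< ``policy.hypersensitive_cutoff``) in the scored condition.
    """
    policy = policy or ThresholdPolicy()
    if thresholds is None:
        thresholds = pseudogene_thresholds(table, policy.source)
    theta_minus, theta_plus = thresholds
    out = table.copy()
    ss = out["screen_score"]
    depleted = out["scored"] & (ss < theta_minus)
    enriched = out["scored"] & (ss > theta_plus)
    rep_cols = [c for c in out.columns if c.startswith("screen_score_rep")]
    if policy.require_reproducible and rep_cols:
        depleted &= (out[rep_cols] < theta_minus).all(axis=1)
        enriched &= (out[rep_cols] > theta_plus).all(axis=1)
    out["class"] = np.select([depleted, enriched], ["depleted", "enriched"], default="none")
    out.loc[out["is_pseudogene"], "class"] = "none"

    if untreated is not None:
        rep_cols = [c for c in untreated.columns if c.startswith("screen_score_rep")]
        if not rep_cols:
            rep_cols = ["screen_score"]
        unt_min = untreated.set_index("gene")[rep_cols].min(axis=1)
        for idx in out.index[out["class"] != "none"]:
            gene = out.at[idx, "gene"]
            if gene in unt_min.index and unt_min[gene] < policy.untreated_threshold:
                score = out.at[idx, "screen_score"]
                if not (
                    score > policy.resistant_cutoff or score < policy.hypersensitive_cutoff
                ):
                    out.at[idx, "class"] = "none"
    out.attrs.update(dict(table.attrs), thresholds=thresholds)
    return out


# ---------------------------------------------------------------------------
# in vivo handling


def ntc_noise_metric(counts: pd.Series, ntc_ids) -> int:
    """Number of NTC sgRNAs more than 1 log2 away from the NTC median count."""
    ntc = counts.reindex(ntc_ids).astype(float)
    med = ntc.median()
    if med <= 0:
        raise DegenerateSampleError("NTC median count is zero")
    with np.errstate(divide="ignore"):
        dev = np.abs(np.log2(ntc.to_numpy() / med))
    return int(np.sum(dev > 1))


def invivo_replicate_qc(
    expt: ScreenExperiment,
    manifest: LibraryManifest,
    n_exclude: int = 2,
    arm: str = "tumour",
) -> ScreenExperiment:
    """Drop the noisiest tumours and average the survivors in rank-matched pairs.

    Noise per tumour is the number of NTC sgRNAs outside +/-1 log2 of the NTC
    median; the ``n_exclude`` worst tumours are removed, survivors are
    ordered by the metric and paired (1st with 2nd, 3rd with 4th, ...), and
    each pair is averaged after rescaling both members to their mean total.
    """
    tumour_ids = expt.sample_ids(arm=arm) or list(expt.counts.columns)
    if len(tumour_ids) < n_exclude + 2:
        raise InsufficientReplicatesError(
            f"need at least {n_exclude + 2} tumours, have {len(tumour_ids)}"
        )
    ntc_ids = manifest.ntc_ids
    metrics = {sid: ntc_noise_metric(expt.counts[sid], ntc_ids) for sid in tumour_ids}
    ranked = sorted(tumour_ids, key=lambda s: (metrics[s], s))
    survivors = ranked[: len(ranked) - n_exclude] if n_exclude else ranked

    cols, rows = {}, []
    other = [c for c in expt.counts.columns if c not in tumour_ids]
    for sid in other:
        cols[sid] = expt.counts[sid]
        rows.append(expt.samples.loc[sid].to_dict() | {"sample_id": sid})
    for i in range(0, len(survivors) - 1, 2):
        a, b = survivors[i], survivors[i + 1]
        ca, cb = expt.counts[a].astype(float), expt.counts[b].astype(float)
        target = (ca.sum() + cb.sum()) / 2
        avg = (ca * target / ca.sum() + cb * target / cb.sum()) / 2
        new_id = f"{arm}_pair{i // 2 + 1}"
        cols[new_id] = avg
        meta = expt.samples.loc[a].to_dict()
        meta.update({"sample_id": new_id, "replicate": i // 2 + 1, "tech_rep": 0})
        rows.append(meta)
    counts = pd.DataFrame(cols)
    counts.index.name = "sgrna_id"
    samples = pd.DataFrame(rows).set_index("sample_id")
    meta = dict(expt.meta)
    meta["invivo_noise_metrics"] = metrics
    meta["invivo_excluded"] = ranked[len(ranked) - n_exclude :] if n_exclude else []
    return ScreenExperiment(counts, samples, mode="in_vivo", meta=meta)


def normalize_to_most_depleted(table: pd.DataFrame) -> pd.DataFrame:
    """Divide screen scores by |most depleted score| so the minimum is -1."""
    out = table.copy()
    scored = out.loc[out["scored"], "screen_score"]
    if scored.empty or scored.min() >= 0:
        out.attrs.update(dict(table.attrs), normalized=False)
        return out
    scale = abs(scored.min())
    cols = ["screen_score"] + [c for c in out.columns if c.startswith("screen_score_rep")]
    out[cols] = out[cols] / scale
    out.attrs.update(dict(table.attrs), normalized=True, normalization_scale=scale)
    return out


# ---------------------------------------------------------------------------
# cross-condition comparison


def condition_correlation(
    tables: dict[str, pd.DataFrame],
    magnitude_filter: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of screen scores across conditions.

    The gene set is every real gene significant (class != 'none') in at
    least one condition; with ``magnitude_filter=(lo, hi)``, genes lacking a
    score < lo or > hi in any condition are additionally dropped (the
    display filter). Returns (r matrix, p matrix, gene list).
    """
    if len(tables) < 2:
        raise InvalidParameterError("need at least two conditions")
    conds = list(tables)
    frames = {
        c: t[~t["is_pseudogene"]].set_index("gene")[["screen_score", "class"]]
        for c, t in tables.items()
    }
    genes = frames[conds[0]].index
    for c in conds[1:]:
        genes = genes.intersection(frames[c].index)
    sig = pd.Series(False, index=genes)
    for c in conds:
        sig |= frames[c].loc[genes, "class"].ne("none")
    keep = sig
    if magnitude_filter is not None:
        lo, hi = magnitude_filter
        mag = pd.Series(False, index=genes)
        for c in conds:
            ss = frames[c].loc[genes, "screen_score"]
            mag |= (ss < lo) | (ss > hi)
        keep = keep & mag
    selected = list(genes[keep])
    if len(selected) < 3:
        raise UndefinedCorrelationError(
            f"only {len(selected)} genes after filtering; correlation undefined"
        )
    r = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    p = pd.DataFrame(np.zeros((len(conds), len(conds))), index=conds, columns=conds)
    for i, a in enumerate(conds):
        for j in range(i + 1, len(conds)):
            b = conds[j]
            res = stats.pearsonr(
                frames[a].loc[selected, "screen_score"],
                frames[b].loc[selected, "screen_score"],
            )
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return r, p, selected


def write_gene_table(table: pd.DataFrame, path) -> None:
    cols = [
        "gene",
        "tss",
        "phenotype_score",
        "p_value",
        "screen_score",
        "n_sgrnas",
        "class",
        "is_pseudogene",
    ]
    extra = [c for c in table.columns if c.startswith("screen_score_rep")]
    table[cols + extra].to_csv(path, sep="\t", index=False)
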