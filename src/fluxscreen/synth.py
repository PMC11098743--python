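"""Synthetic screens, tracer time courses and qPCR data with known truth.

Every downstream stage of the package is testable against these generators:
the screen simulator grows sgRNA abundances multiplicatively
(``2^(D (1 + efficacy * e_g))`` over D population doublings, the per-gene
fitness effect e_g acting only in selective arms) and samples reads
multinomially; the tracer simulator integrates first-order label exchange
(``H(t) = P (1 - exp(-J_in t / P))``), convolves with natural isotope
abundance and adds multiplicative noise; the competition simulator emits
qPCR Ct values from known mixture fractions assuming perfect doubling per
cycle, exactly invertible by the phenotype estimator when noiseless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, InvalidParameterError
from .kinetics import (
    DEFAULT_N_CELLS,
    DEFAULT_NATURAL_ABUNDANCES,
    IsotopologueSeries,
    correction_matrix,
)
from .library import LibraryManifest
from .scoring import ScreenExperiment, make_sample_sheet

# ---------------------------------------------------------------------------
# screens


@dataclass
class Arm:
    """One screen arm: name, population doublings, whether selection applies.

    ``effect_scale`` multiplies every gene's fitness effect in this arm; the
    treated arm of a comparison uses 1.0 and its control 0.0 so that the
    expected rho equals e_g after doubling normalization.
    """

    name: str
    doublings: float
    effect_scale: float = 1.0

    def __post_init__(self):
        if self.doublings < 0:
            raise InvalidDesignError(f"arm {self.name}: doublings must be non-negative")


@dataclass
class ScreenDesign:
    """T0 plus grown arms, replicate count and sequencing depth per sgRNA.

    ``overdispersion`` > 0 draws each sample's fractions from a Dirichlet
    around the expected fractions (concentration = library size /
    overdispersion) before the multinomial, adding extra-multinomial count
    noise; 0 keeps pure multinomial sampling.
    """

    arms: list[Arm]
    n_replicates: int = 2
    reads_per_sgrna: float = 500.0
    overdispersion: float = 0.0
    t0_name: str = "T0"

    def __post_init__(self):
        if not any(a.doublings > 0 for a in self.arms):
            raise InvalidDesignError("design needs at least one grown arm with doublings > 0")
        if self.overdispersion < 0:
            raise InvalidDesignError("overdispersion must be non-negative")


@dataclass
class ScreenTruth:
    """Ground truth for a simulated screen.

    ``effects`` maps gene -> fitness effect e_g (per-doubling log2 growth-
    rate difference; NTC sgRNAs always have effect 0), ``efficacy`` maps
    sgrna_id -> multiplier in [0, 1] (default 1), ``sigma_abundance`` is the
    lognormal sigma of the initial library representation.
    """

    effects: dict[str, float] = field(default_factory=dict)
    efficacy: dict[str, float] = field(default_factory=dict)
    sigma_abundance: float = 0.5

    def __post_init__(self):
        if self.sigma_abundance < 0:
            raise InvalidParameterError("sigma_abundance must be non-negative")
        if any(not (0 <= v <= 1) for v in self.efficacy.values()):
            raise InvalidParameterError("efficacy multipliers must lie in [0, 1]")


def expected_fractions(
    manifest: LibraryManifest, truth: ScreenTruth, arm: Arm, abundance: np.ndarray
) -> np.ndarray:
    """Expected sgRNA abundance fractions in one arm (infinite-depth limit)."""
    effects = np.array(
        [
            0.0
            if e.is_ntc
            else truth.effects.get(e.gene, 0.0) * truth.efficacy.get(e.sgrna_id, 1.0)
            for e in manifest.entries
        ]
    )
    grown = abundance * np.exp2(arm.doublings * (1.0 + arm.effect_scale * effects))
    return grown / grown.sum()


def simulate_screen(
    manifest: LibraryManifest,
    truth: ScreenTruth,
    design: ScreenDesign,
    seed: int = 0,
) -> ScreenExperiment:
    """Simulate a pooled screen: lognormal representation, growth, sampling.

    Each biological replicate draws its own initial abundance vector (an
    independent transduction); every sample's reads are drawn multinomially
    at ``reads_per_sgrna * library size`` total depth. Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(manifest)
    depth = int(round(design.reads_per_sgrna * n))
    sgrna_ids = [e.sgrna_id for e in manifest.entries]

    def draw(frac: np.ndarray) -> np.ndarray:
        if design.overdispersion > 0:
            frac = rng.dirichlet(frac * n / design.overdispersion)
        return rng.multinomial(depth, frac)

    cols: dict[str, np.ndarray] = {}
    rows = []
    for rep in range(1, design.n_replicates + 1):
        abundance = rng.lognormal(mean=0.0, sigma=truth.sigma_abundance, size=n)
        t0_frac = abundance / abundance.sum()
        t0_id = f"{design.t0_name}_rep{rep}"
        cols[t0_id] = draw(t0_frac)
        rows.append(
            {"sample_id": t0_id, "arm": design.t0_name, "replicate": rep, "doublings": 0.0}
        )
        for arm in design.arms:
            if arm.doublings == 0:
                continue
            frac = expected_fractions(manifest, truth, arm, abundance)
            sid = f"{arm.name}_rep{rep}"
            cols[sid] = draw(frac)
            rows.append(
                {"sample_id": sid, "arm": arm.name, "replicate": rep, "doublings": arm.doublings}
            )
    counts = pd.DataFrame(cols, index=pd.Index(sgrna_ids, name="sgrna_id"))
    samples = make_sample_sheet(rows)
    return ScreenExperiment(counts, samples, meta={"seed": seed, "depth": depth})


def truth_table(truth: ScreenTruth) -> pd.DataFrame:
    """Ground-truth effects as a tidy frame (for recovery tests on disk)."""
    return pd.DataFrame(
        {"gene": list(truth.effects), "effect": list(truth.effects.values())}
    )


def simulate_reads(
    manifest: LibraryManifest,
    path,
    reads_per_sgrna: int = 10,
    corruption_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write a FASTQ of protospacer reads, a fraction carrying one mismatch.

    Returns the number of reads written. Corrupted reads mutate one random
    protospacer base, so exact-match counting drops them (up to the
    negligible chance of colliding with another library member).
    """
    if not (0 <= corruption_rate <= 1):
        raise InvalidParameterError("corruption_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = "ACGT"
    n_written = 0
    with open(path, "w") as fh:
        for e in manifest.entries:
            for r in range(reads_per_sgrna):
                seq = e.protospacer
                if rng.random() < corruption_rate:
                    pos = int(rng.integers(len(seq)))
                    options = [b for b in alphabet if b != seq[pos]]
                    seq = seq[:pos] + options[int(rng.integers(3))] + seq[pos + 1 :]
                fh.write(f"@{e.sgrna_id}_{r}\n{seq}\n+\n{'I' * len(seq)}\n")
                n_written += 1
    return n_written


# ---------------------------------------------------------------------------
# tracers


@dataclass
class TracerTruth:
    """Ground truth for a tracer time course.

    Import flux ``j_in`` and export flux ``j_out`` are pmol min^-1 per 10^6
    cells, ``pool`` is the intracellular free pool (pmol per 10^6 cells,
    constant: the assay runs at steady state), ``response`` converts pmol to
    ion counts, ``noise_cv`` is the multiplicative (lognormal) noise
    coefficient of variation.
    """

    amino_acid: str = "Leu"
    j_in: float = 100.0
    j_out: float = 100.0
    pool: float = 1000.0
    fragment_formula: dict[str, int] = field(default_factory=lambda: {"C": 5, "H": 10, "N": 1, "O": 2})
    noise_cv: float = 0.05
    response: float = 50.0

    def __post_init__(self):
        if min(self.j_in, self.j_out, self.pool) <= 0:
            raise InvalidParameterError("j_in, j_out and pool must be positive")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be non-negative")

    @property
    def k_exchange(self) -> float:
        """Label-exchange rate constant J_in / P (min^-1)."""
        return self.j_in / self.pool


def heavy_fraction(truth: TracerTruth, t_seconds: np.ndarray) -> np.ndarray:
    """Closed-form heavy fraction ``1 - exp(-k t)`` of the intracellular pool."""
    t_min = np.asarray(t_seconds, dtype=float) / 60.0
    return 1.0 - np.exp(-truth.k_exchange * t_min)


def simulate_tracer(
    truth: TracerTruth,
    timepoints,
    natural_abundances: dict[str, dict[int, float]] | None = None,
    internal_standard_level: float = 1e5,
    seed: int = 0,
    n_cells: float = DEFAULT_N_CELLS,
) -> IsotopologueSeries:
    """Simulate an import-assay isotopologue series with known fluxes.

    The intracellular pool is split into unlabelled (M+0) and fully
    labelled (M+n) molecules per the exchange kinetics, convolved with
    natural abundance, scaled to ion counts via the per-pmol response and a
    per-10^6-cells basis, then perturbed: a shared per-timepoint handling
    factor (affecting norvaline too) and independent per-channel noise,
    both lognormal at ``noise_cv``.
    """
    abund = natural_abundances or DEFAULT_NATURAL_ABUNDANCES
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("timepoints must be non-negative")
    rng = np.random.default_rng(seed)
    n = truth.fragment_formula["C"]
    A = correction_matrix(truth.fragment_formula, abund)
    h = heavy_fraction(truth, t)
    cells_scale = n_cells / 1e6

    ions = np.empty((len(t), n + 1))
    for i, hf in enumerate(h):
        labelling = np.zeros(n + 1)
        labelling[0] = truth.pool * (1.0 - hf)
        labelling[n] = truth.pool * hf
        ions[i] = A @ labelling * truth.response * cells_scale

    norv = np.full(len(t), internal_standard_level)
    if truth.noise_cv > 0:
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        shared = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(t)))
        channel = np.exp(rng.normal(-sigma**2 / 2, sigma, size=ions.shape))
        ions = ions * shared[:, None] * channel
        norv = norv * shared * np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(t)))
    return IsotopologueSeries(
        amino_acid=truth.amino_acid,
        fragment_formula=dict(truth.fragment_formula),
        timepoints=t,
        ion_counts=ions,
        internal_standard=norv,
        assay_kind="import",
        time_unit="s",
        n_cells=n_cells,
        meta={"truth": truth},
    )


def tracer_standards(
    truths: list[TracerTruth],
    pmols=(10.0, 50.0, 100.0, 500.0),
    norvaline_level: float = 1e5,
) -> pd.DataFrame:
    """Noise-free standard-curve table matching the simulator's response."""
    rows = []
    for tr in truths:
        for p in pmols:
            rows.append(
                {
                    "amino_acid": tr.amino_acid,
                    "pmol": p,
                    "ion_counts": p * tr.response,
                    "norvaline": norvaline_level,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# competition assays


def simulate_competition(
    true_log2fc_per_doubling: float,
    doublings_test: float,
    doublings_ref: float,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "test",
    base_ct: float = 20.0,
) -> pd.DataFrame:
    """qPCR Ct records for a 50/50 test:NTC competition with known effect.

    The test line's abundance ratio changes by
    ``2^(e * (D_test - D_ref))`` between T0 and endpoint; Ct values assume
    perfect doubling per cycle (one cycle per log2 of template). With
    ``ct_noise_sd = 0`` the phenotype estimator inverts this exactly.
    """
    if doublings_test < 0 or doublings_ref < 0:
        raise InvalidParameterError("doublings must be non-negative")
    if ct_noise_sd < 0:
        raise InvalidParameterError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d_diff = doublings_test - doublings_ref
    log2_ratio_end = true_log2fc_per_doubling * d_diff  # T0 ratio is 1 (50/50)
    rows = [
        {
            "sample": f"{condition}_T0",
            "condition": condition,
            "timepoint": "T0",
            "ct_test": base_ct,
            "ct_ntc": base_ct,
            "doublings": doublings_test,
            "doublings_ref": doublings_ref,
        },
        {
            "sample": f"{condition}_end",
            "condition": condition,
            "timepoint": "endpoint",
            "ct_test": base_ct - log2_ratio_end,
            "ct_ntc": base_ct,
            "doublings": doublings_test,
            "doublings_ref": doublings_ref,
        },
    ]
    df = pd.DataFrame(rows)
    if ct_noise_sd > 0:
        df[["ct_test", "ct_ntc"]] += rng.normal(0, ct_noise_sd, size=(len(df), 2))
    return df
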