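"""Amino-acid transport rates from stable-isotope tracer time courses.

Cells at metabolic steady state are switched into medium whose amino acids
are fully heavy-labelled; the intracellular heavy pool rises as
``H(t) = P (1 - exp(-k t))`` with exchange constant ``k = J_in / P`` where
``J_in`` is the import flux (pmol min^-1 per 10^6 cells) and ``P`` the free
intracellular pool. The import rate is the initial slope of ``H(t)``,
estimated by ordinary least squares inside a short, amino-acid-specific
window. Consumption (medium depletion) and export (labelled release into
fresh medium) rates come from the slope of medium amounts over time.

Raw GC-MS isotopologue ion counts pass through, in order: natural-isotope
abundance correction (matrix deconvolution, the measured spectrum being the
labelling distribution convolved with natural abundances of the fragment's
atoms), internal-standard (norvaline) correction, a steady-state total-ion-
count correction (and a sampling-volume correction for consumption assays),
then absolute quantification against an external standard curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConditioningError,
    DegenerateSampleError,
    DegenerateStandardError,
    InsufficientPointsError,
    InvalidParameterError,
    InvalidScheduleError,
    LookupError_,
)

#: Terrestrial natural isotope abundances by mass shift, per element.
DEFAULT_NATURAL_ABUNDANCES: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "Si": {0: 0.92223, 1: 0.04685, 2: 0.03092},
}

#: Default regression windows (seconds) for import-rate estimation.
DEFAULT_IMPORT_WINDOWS: dict[str, float] = {
    **{aa: 100.0 for aa in ("Asn", "Asp", "Gln", "Glu", "Pro")},
    **{aa: 40.0 for aa in ("Arg", "Gly", "His", "Ile", "Lys", "Ser", "Thr", "Val")},
    **{aa: 20.0 for aa in ("Leu", "Tyr")},
    "Phe": 10.0,
}

#: Effective cells per assay dish: 0.8e6 in the monolayer minus ~20% wash loss.
DEFAULT_N_CELLS = 0.64e6


@dataclass
class IsotopologueSeries:
    """Isotopologue ion counts over time for one amino-acid fragment.

    ``ion_counts`` has shape (n_timepoints, capacity + 1) where capacity is
    the number of labelable atoms (``fragment_formula[label_element]``).
    ``internal_standard`` is the norvaline channel. Timepoints are seconds
    for import/export assays and minutes for consumption (``time_unit``).
    """

    amino_acid: str
    fragment_formula: dict[str, int]
    timepoints: np.ndarray
    ion_counts: np.ndarray
    internal_standard: np.ndarray
    assay_kind: str = "import"
    time_unit: str = "s"
    sampling_volumes: np.ndarray | None = None
    n_cells: float = DEFAULT_N_CELLS
    label_element: str = "C"
    units: str = "ions"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ion_counts = np.asarray(self.ion_counts, dtype=float)
        self.internal_standard = np.asarray(self.internal_standard, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise InvalidParameterError("timepoints must be strictly increasing")
        if (self.ion_counts < 0).any():
            raise InvalidParameterError("ion counts must be non-negative")
        cap = self.fragment_formula.get(self.label_element, 0)
        if self.ion_counts.shape != (len(self.timepoints), cap + 1):
            raise InvalidParameterError(
                f"ion_counts must be (n_timepoints, {cap + 1}) for this fragment"
            )

    @property
    def capacity(self) -> int:
        return self.fragment_formula[self.label_element]

    @property
    def total(self) -> np.ndarray:
        """Total signal per timepoint, summed over isotopologues."""
        return self.ion_counts.sum(axis=1)

    def heavy(self, mode: str = "full") -> np.ndarray:
        """Labelled signal per timepoint.

        Medium amino acids are uniformly fully labelled, so transported
        molecules sit in the fully-labelled M+n channel after natural-
        abundance correction (``mode='full'``, the default: the partially
        labelled channels carry only correction residuals, whose noise
        would otherwise swamp small early signals). ``mode='sum'`` sums
        M+1..M+n instead.
        """
        if mode == "full":
            return self.ion_counts[:, -1]
        if mode == "sum":
            return self.ion_counts[:, 1:].sum(axis=1)
        raise InvalidParameterError(f"unknown heavy mode {mode!r}")

    def to_frame(self) -> pd.DataFrame:
        cols = {f"M{k}": self.ion_counts[:, k] for k in range(self.capacity + 1)}
        return pd.DataFrame(
            {
                "amino_acid": self.amino_acid,
                "timepoint": self.timepoints,
                **cols,
                "norvaline": self.internal_standard,
            }
        )


def series_to_tsv(series_list: list[IsotopologueSeries], path) -> None:
    frames = []
    for s in series_list:
        df = s.to_frame()
        df.insert(1, "fragment_formula", _formula_str(s.fragment_formula))
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def _formula_str(formula: dict[str, int]) -> str:
    return "".join(f"{el}{n}" for el, n in sorted(formula.items()))


def parse_formula(text: str) -> dict[str, int]:
    """Parse an element-count formula string like ``C5H10N1O2Si1``."""
    import re

    out: dict[str, int] = {}
    for el, n in re.findall(r"([A-Z][a-z]?)(\d+)", text):
        out[el] = int(n)
    return out


def series_from_tsv(path, assay_kind: str = "import", **kwargs) -> list[IsotopologueSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    time_unit = "min" if assay_kind == "consumption" else "s"
    for aa, sub in df.groupby("amino_acid", sort=False):
        formula = parse_formula(sub["fragment_formula"].iloc[0])
        mcols = [c for c in sub.columns if c.startswith("M") and c[1:].isdigit()]
        mcols = sorted(mcols, key=lambda c: int(c[1:]))
        out.append(
            IsotopologueSeries(
                amino_acid=aa,
                fragment_formula=formula,
                timepoints=sub["timepoint"].to_numpy(),
                ion_counts=sub[mcols].to_numpy(),
                internal_standard=sub["norvaline"].to_numpy(),
                assay_kind=assay_kind,
                time_unit=time_unit,
                **kwargs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# natural-abundance correction


def _element_distribution(fractions: dict[int, float], n_atoms: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` atoms of one element."""
    shifts = sorted(fractions)
    base = np.zeros(max(shifts) + 1)
    for s in shifts:
        base[s] = fractions[s]
    dist = np.array([1.0])
    for _ in range(n_atoms):
        dist = np.convolve(dist, base)
    return dist


def correction_matrix(
    formula: dict[str, int],
    abundances: dict[str, dict[int, float]] | None = None,
    label_element: str = "C",
    normalize_columns: bool = True,
) -> np.ndarray:
    """Forward convolution matrix A with ``measured = A @ labelling``.

    Column j is the mass-shift distribution of a molecule carrying exactly j
    heavy labels: a delta at +j convolved with the natural-abundance
    distribution of the remaining (unlabelled) atoms, truncated to the
    observable M+0..M+n window. By default each column is renormalized to
    sum to 1, redistributing the (tiny) truncated tail so total signal is
    conserved.
    """
    abundances = abundances or DEFAULT_NATURAL_ABUNDANCES
    for el, fr in abundances.items():
        if not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-6):
            raise InvalidParameterError(f"abundance fractions for {el} must sum to 1")
    n = formula.get(label_element, 0)
    other = np.array([1.0])
    for el, count in formula.items():
        if el == label_element or count == 0:
            continue
        if el not in abundances:
            raise InvalidParameterError(f"no natural abundances supplied for element {el}")
        other = np.convolve(other, _element_distribution(abundances[el], count))
    A = np.zeros((n + 1, n + 1))
    label_fr = abundances[label_element]
    for j in range(n + 1):
        dist = np.convolve(other, _element_distribution(label_fr, n - j))
        for i in range(j, n + 1):
            if i - j < len(dist):
                A[i, j] = dist[i - j]
    if normalize_columns:
        A = A / A.sum(axis=0, keepdims=True)
    return A


def convolve_natural_abundance(
    labelling: np.ndarray,
    formula: dict[str, int],
    abundances: dict[str, dict[int, float]] | None = None,
    label_element: str = "C",
) -> np.ndarray:
    """Forward model: what the instrument sees for a labelling distribution."""
    A = correction_matrix(formula, abundances, label_element)
    return A @ np.asarray(labelling, dtype=float)


def natural_abundance_correct(
    series: IsotopologueSeries,
    abundances: dict[str, dict[int, float]] | None = None,
) -> IsotopologueSeries:
    """Deconvolve natural isotope abundance from measured isotopologues.

    Solves ``A x = y`` per timepoint by non-negative least squares, where A
    is the fragment's forward convolution matrix.
    """
    A = correction_matrix(series.fragment_formula, abundances, series.label_element)
    if np.linalg.cond(A) > 1e8:
        raise ConditioningError(
            f"correction matrix for {_formula_str(series.fragment_formula)} is ill-conditioned"
        )
    corrected = np.empty_like(series.ion_counts)
    for i, y in enumerate(series.ion_counts):
        corrected[i], _ = optimize.nnls(A, y)
    return replace(series, ion_counts=corrected)


# ---------------------------------------------------------------------------
# steady-state corrections


def internal_standard_correct(series: IsotopologueSeries) -> IsotopologueSeries:
    """Divide each timepoint by its norvaline signal relative to the mean.

    Removes per-sample extraction/injection variability; the corrected
    norvaline channel is constant by construction.
    """
    norv = series.internal_standard
    if np.any(norv <= 0):
        raise DegenerateStandardError("norvaline signal must be positive at every timepoint")
    factors = norv / norv.mean()
    return replace(
        series,
        ion_counts=series.ion_counts / factors[:, None],
        internal_standard=np.full_like(norv, norv.mean()),
        meta={**series.meta, "norvaline_raw_mean": float(norv.mean())},
    )


def steady_state_tic_correct(
    series: IsotopologueSeries,
    variant: str = "ratio_to_mean",
    tic: np.ndarray | None = None,
) -> IsotopologueSeries:
    """Correct each timepoint by its total ion count relative to steady state.

    At steady state the summed labelled + unlabelled signal is constant, so
    deviations are technical. ``ratio_to_mean`` divides by TIC_t / mean TIC
    (import assays); ``regression`` divides by TIC_t / fitted TIC(t) from a
    linear fit over the time course (consumption assays, where a genuine
    trend must be preserved). ``tic`` may supply an external total-ion-count
    vector (e.g. summed over all amino-acid fragments of the run).
    """
    tic = series.total if tic is None else np.asarray(tic, dtype=float)
    if np.any(tic <= 0):
        raise DegenerateSampleError("total ion count must be positive at every timepoint")
    if variant == "ratio_to_mean":
        expected = np.full_like(tic, tic.mean())
    elif variant == "regression":
        slope, intercept = np.polyfit(series.timepoints, tic, 1)
        expected = slope * series.timepoints + intercept
        if np.any(expected <= 0):
            raise DegenerateSampleError("fitted TIC crosses zero inside the time course")
    else:
        raise InvalidParameterError(f"unknown TIC correction variant {variant!r}")
    factors = tic / expected
    return replace(series, ion_counts=series.ion_counts / factors[:, None])


def volume_correct(
    series: IsotopologueSeries,
    initial_volume: float = 300.0,
    per_sample_volume: float = 15.0,
) -> IsotopologueSeries:
    """Rescale consumption signals to the whole-system amino-acid amount.

    Each draw removes ``per_sample_volume`` ul of medium; signals are
    proportional to concentration in the analysed aliquot. The corrected
    amount at draw i is ``conc_i * V_i`` plus the amounts carried away by
    earlier draws, so a constant-concentration (cell-free) medium gives a
    constant corrected total and consumption slopes are free of the
    sampling artefact. Volumes are in the same (arbitrary) units.
    """
    n = len(series.timepoints)
    withdrawn = per_sample_volume * (n - 1)
    if withdrawn >= initial_volume:
        raise InvalidScheduleError(
            f"schedule withdraws {withdrawn} from an initial volume of {initial_volume}"
        )
    remaining = initial_volume - per_sample_volume * np.arange(n)
    corrected = np.empty_like(series.ion_counts)
    for k in range(series.ion_counts.shape[1]):
        conc = series.ion_counts[:, k]
        removed = np.concatenate([[0.0], np.cumsum(conc[:-1]) * per_sample_volume])
        corrected[:, k] = (conc * remaining + removed) / initial_volume
    return replace(series, sampling_volumes=np.full(n, per_sample_volume), ion_counts=corrected)


# ---------------------------------------------------------------------------
# absolute quantification


@dataclass
class StandardCurve:
    """Per-amino-acid linear response: ion counts = slope * pmol + intercept."""

    slopes: dict[str, float]
    intercepts: dict[str, float]
    norvaline_mean: float

    def covers(self, amino_acid: str) -> bool:
        return amino_acid in self.slopes


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Unweighted OLS of ion counts vs pmol per amino acid (free intercept).

    ``standards`` columns: amino_acid, pmol, ion_counts, norvaline; at least
    three dilution points per amino acid.
    """
    slopes, intercepts = {}, {}
    for aa, sub in standards.groupby("amino_acid"):
        if len(sub) < 3:
            raise InvalidParameterError(f"standard curve for {aa} needs >= 3 dilution points")
        slope, intercept = np.polyfit(sub["pmol"], sub["ion_counts"], 1)
        if slope <= 0:
            raise InvalidParameterError(f"standard-curve slope for {aa} must be positive")
        slopes[aa], intercepts[aa] = float(slope), float(intercept)
    return StandardCurve(slopes, intercepts, float(standards["norvaline"].mean()))


def absolute_quantify(series: IsotopologueSeries, curve: StandardCurve) -> IsotopologueSeries:
    """Convert ion counts to pmol via the standard curve and norvaline ratio.

    ``pmol = (ions - intercept) / slope * (norvaline_standard / norvaline_sample)``
    applied channel-wise with the intercept apportioned by each channel's
    signal share; negative results clip to zero with a warning.
    """
    aa = series.amino_acid
    if not curve.covers(aa):
        raise LookupError_(f"standard curve does not cover {aa}")
    norv_sample = series.meta.get("norvaline_raw_mean", float(series.internal_standard.mean()))
    if norv_sample <= 0:
        raise DegenerateStandardError("sample norvaline mean must be positive")
    ratio = curve.norvaline_mean / norv_sample
    slope, intercept = curve.slopes[aa], curve.intercepts[aa]
    total = series.total
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total[:, None] > 0, series.ion_counts / total[:, None], 0.0)
    pmol = (series.ion_counts - intercept * share) / slope * ratio
    if (pmol < 0).any():
        warnings.warn(f"{aa}: negative pmol after intercept subtraction clipped to 0")
        pmol = np.clip(pmol, 0.0, None)
    return replace(series, ion_counts=pmol, units="pmol")


# ---------------------------------------------------------------------------
# rates, pools, turnover


@dataclass
class RateEstimate:
    """A transport rate: slope +/- SE in pmol min^-1 per 10^6 cells."""

    amino_acid: str
    rate: float
    se: float
    window: tuple[float, float]
    n_points: int
    r_squared: float
    kind: str = "import"


@dataclass
class PoolStats:
    """Intracellular pool size and (optionally) its turnover constant."""

    amino_acid: str
    level: float  # pmol per 10^6 cells
    k_turn: float | None = None  # min^-1


def _ols_rate(t_minutes, y, per_million_cells) -> tuple[float, float, float]:
    t = np.asarray(t_minutes, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise InsufficientPointsError("regression needs at least 3 timepoints")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    return res.slope / per_million_cells, res.stderr / per_million_cells, r2


def import_rate(
    series: IsotopologueSeries,
    window: float | dict[str, float] | None = None,
    n_cells: float | None = None,
    heavy_mode: str = "full",
) -> RateEstimate:
    """Initial slope of heavy amino-acid accumulation within the window.

    ``window`` is a per-amino-acid map or a single upper bound in seconds
    (default: the per-amino-acid schedule). The series should be fully
    corrected and in pmol.
    """
    if window is None:
        window = DEFAULT_IMPORT_WINDOWS
    w = window.get(series.amino_acid, 100.0) if isinstance(window, dict) else float(window)
    n_cells = n_cells or series.n_cells
    mask = series.timepoints <= w
    t_min = series.timepoints[mask] / 60.0
    heavy = series.heavy(heavy_mode)[mask]
    rate, se, r2 = _ols_rate(t_min, heavy, n_cells / 1e6)
    return RateEstimate(series.amino_acid, rate, se, (0.0, w), int(mask.sum()), r2, "import")


def consumption_rate(series: IsotopologueSeries, n_cells: float | None = None) -> RateEstimate:
    """Net consumption from the medium: minus the slope of medium amounts.

    Positive for amino acids the cells deplete; negative for secreted ones.
    Consumption timepoints are minutes.
    """
    n_cells = n_cells or series.n_cells
    t_min = series.timepoints if series.time_unit == "min" else series.timepoints / 60.0
    slope, se, r2 = _ols_rate(t_min, series.total, n_cells / 1e6)
    w = (float(series.timepoints[0]), float(series.timepoints[-1]))
    return RateEstimate(series.amino_acid, -slope, se, w, len(series.timepoints), r2, "consumption")


def export_rate(
    series: IsotopologueSeries, n_cells: float | None = None, heavy_mode: str = "full"
) -> RateEstimate:
    """Release of labelled amino acid into fresh medium: slope of heavy amounts."""
    n_cells = n_cells or series.n_cells
    t_min = series.timepoints if series.time_unit == "min" else series.timepoints / 60.0
    slope, se, r2 = _ols_rate(t_min, series.heavy(heavy_mode), n_cells / 1e6)
    w = (float(series.timepoints[0]), float(series.timepoints[-1]))
    return RateEstimate(series.amino_acid, slope, se, w, len(series.timepoints), r2, "export")


def intracellular_level(series: IsotopologueSeries, n_cells: float | None = None) -> PoolStats:
    """Mean total (labelled + unlabelled) amount per 10^6 cells over time."""
    n_cells = n_cells or series.n_cells
    if len(series.timepoints) < 1:
        raise InsufficientPointsError("need at least one timepoint")
    return PoolStats(series.amino_acid, float(series.total.mean() / (n_cells / 1e6)))


def pool_turnover(import_est: RateEstimate, pool: PoolStats) -> PoolStats:
    """Turnover constant k = import rate / intracellular level (min^-1)."""
    if pool.level <= 0:
        raise InvalidParameterError("intracellular level must be positive")
    return PoolStats(pool.amino_acid, pool.level, import_est.rate / pool.level)


def rates_to_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "amino_acid": [e.amino_acid for e in estimates],
            "rate_pmol_per_min_per_1e6": [e.rate for e in estimates],
            "se": [e.se for e in estimates],
            "window_s": [e.window[1] for e in estimates],
            "n_points": [e.n_points for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "kind": [e.kind for e in estimates],
        }
    )
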