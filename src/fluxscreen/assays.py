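"""Bespoke readouts: qPCR competition assays, viability titrations, peroxides.

Competition assays mix a test CRISPRi/a line 50/50 with its NTC control and
read the mixture composition by two qPCR reactions (test-sgRNA primer vs
NTC primer). The growth phenotype is ``-ddCt / D``: the change in Ct
difference between endpoint and T0, normalized per population doubling,
signed so that depletion of the test line is negative (higher Ct = less
template), matching screen-score signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    InvalidParameterError,
    UnpairedRecordError,
)


def competition_phenotype(
    records: pd.DataFrame,
    normalization: str = "condition_vs_reference",
    primer_efficiency: float = 2.0,
) -> pd.Series:
    """Per-doubling log2 growth phenotype of the test line per condition.

    ``records`` columns: sample, condition, timepoint (T0 | endpoint),
    ct_test, ct_ntc, doublings, doublings_ref. ``normalization``:

    * ``condition_vs_reference``: divide ddCt by the doubling difference
      between the test condition and its vehicle reference (low-nutrient
      assays);
    * ``per_doubling``: divide by the test condition's total doublings
      (complete-media assays).

    ``primer_efficiency`` converts Ct cycles to log2 template units
    (2.0 = perfect doubling per cycle).
    """
    if primer_efficiency <= 1:
        raise InvalidParameterError("primer_efficiency must exceed 1")
    cycle_to_log2 = np.log2(primer_efficiency)
    out = {}
    for cond, sub in records.groupby("condition", sort=False):
        t0 = sub[sub["timepoint"] == "T0"]
        end = sub[sub["timepoint"] == "endpoint"]
        if t0.empty or end.empty:
            raise UnpairedRecordError(f"condition {cond}: missing T0 or endpoint records")
        dct_t0 = (t0["ct_test"] - t0["ct_ntc"]).mean() * cycle_to_log2
        dct_end = (end["ct_test"] - end["ct_ntc"]).mean() * cycle_to_log2
        ddct = dct_end - dct_t0
        if normalization == "condition_vs_reference":
            d_norm = (end["doublings"] - end["doublings_ref"]).mean()
        elif normalization == "per_doubling":
            d_norm = end["doublings"].mean()
        else:
            raise InvalidParameterError(f"unknown normalization {normalization!r}")
        if d_norm == 0:
            raise InvalidParameterError(f"condition {cond}: doubling normalizer is zero")
        out[cond] = -ddct / d_norm
    return pd.Series(out, name="phenotype")


def viability_log2fc(
    plate: pd.DataFrame,
    normalizer_condition: str | None = None,
    layout: pd.DataFrame | None = None,
) -> pd.Series:
    """Population doublings per condition from a luminescent viability plate.

    Readings are averaged over replicates, divided by T0 luminescence,
    internally normalized to ``normalizer_condition`` (if given; e.g. the
    complete-medium control) and returned on a log2 scale. ``layout`` may
    remap a spatially randomized plate: a frame with row/col/condition that
    overrides the plate's condition labels.
    """
    df = plate.copy()
    if layout is not None:
        df = df.drop(columns=["condition"]).merge(layout, on=["row", "col"], how="left")
    t0 = df.loc[df["is_t0"], "reading"].mean()
    if not t0 > 0:
        raise DegenerateReferenceError("T0 luminescence must be positive")
    grown = df[~df["is_t0"]]
    ratios = grown.groupby("condition")["reading"].mean() / t0
    if normalizer_condition is not None:
        ratios = ratios / ratios[normalizer_condition]
    return np.log2(ratios).rename("log2_doublings")


def lipid_peroxidation_ratio(
    oxidized: float, reduced: float, control_ratio: float = 1.0
) -> float:
    """Peroxide level: oxidized/reduced fluorescence, relative to a control.

    The control (e.g. the cystine-replete condition) normalizes to 1.
    """
    if reduced <= 0 or control_ratio <= 0:
        raise InvalidParameterError("reduced signal and control ratio must be positive")
    return (oxidized / reduced) / control_ratio
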