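"""Population statistics and the expressing-fraction classifier.

A vesicle counts as "expressing" when its background-corrected mean reporter
intensity exceeds the negative-control threshold: the mean of a no-template
control population plus three sample standard deviations.  The comparison is
strict (``>``), so a population identical to its control yields fraction 0.

Fold activation is the ON/OFF ratio of reporter output; a variant's fold can
be decomposed as reference fold x OFF-state change x ON-state change (e.g. a
receiver whose OFF-state drops 7.2-fold and ON-state rises 3.6-fold over a
3.4-fold reference reaches ~88-fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from guvquant.vesicle_quantification import VesicleRecord, records_to_dataframe

#: Number of control standard deviations above the control mean.
THRESHOLD_SD_MULTIPLIER = 3.0


@dataclass(frozen=True)
class ControlThreshold:
    """Expression threshold derived from a no-template control population."""

    control_mean: float
    control_sd: float
    n_control: int

    def __post_init__(self) -> None:
        if self.n_control < 2:
            raise ValueError("control population must have >= 2 records")
        if self.control_sd < 0:
            raise ValueError("control sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.control_mean + THRESHOLD_SD_MULTIPLIER * self.control_sd


@dataclass(frozen=True)
class PopulationSummary:
    n: int
    diameter_mean_um: float
    diameter_sd_um: float
    diameter_median_um: float
    diameter_iqr_um: float
    txr_median: float
    txr_iqr: float
    gfp_median: float
    gfp_iqr: float
    expressing_fraction: float | None = None


def _as_frame(records: Sequence[VesicleRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_dataframe(records)
    if "flagged" in df.columns:
        df = df[~df["flagged"].astype(bool)]
    return df


def control_threshold(
    control_records: Sequence[VesicleRecord] | pd.DataFrame | np.ndarray,
) -> ControlThreshold:
    """Threshold = control mean + 3 s.d. of per-vesicle corrected GFP means.

    Accepts vesicle records (their ``mean_gfp_corr`` field is used) or a raw
    array of control intensities.  The s.d. uses the n-1 denominator.
    Negative corrected intensities (possible through noise) are legitimate
    inputs.
    """
    if isinstance(control_records, np.ndarray):
        values = np.asarray(control_records, dtype=float)
    else:
        values = _as_frame(control_records)["mean_gfp_corr"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 control records to estimate a threshold")
    return ControlThreshold(
        control_mean=float(values.mean()),
        control_sd=float(values.std(ddof=1)),
        n_control=int(values.size),
    )


def expressing_fraction(
    records: Sequence[VesicleRecord] | pd.DataFrame,
    thr: ControlThreshold,
) -> tuple[float, np.ndarray]:
    """Fraction of vesicles whose corrected GFP mean strictly exceeds the threshold.

    Returns ``(fraction, per_record_boolean)`` in record order.  Records
    flagged by quantification (pathologically small ROI) are excluded first;
    the boolean aligns with the remaining usable records.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no records to classify")
    flags = df["mean_gfp_corr"].to_numpy(dtype=float) > thr.threshold
    return float(flags.mean()), flags


def summarize(
    records: Sequence[VesicleRecord] | pd.DataFrame,
    thr: ControlThreshold | None = None,
) -> PopulationSummary:
    """Population summary: diameter and intensity order statistics.

    Quantiles use the linear-interpolation convention.  If a control
    threshold is given the expressing fraction is included.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    d = df["diameter_um"].to_numpy(dtype=float)
    txr = df["mean_txr_corr"].to_numpy(dtype=float)
    gfp = df["mean_gfp_corr"].to_numpy(dtype=float)

    def iqr(x: np.ndarray) -> float:
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)

    frac = None
    if thr is not None:
        frac, _ = expressing_fraction(df, thr)
    return PopulationSummary(
        n=len(df),
        diameter_mean_um=float(d.mean()),
        diameter_sd_um=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        diameter_median_um=float(np.median(d)),
        diameter_iqr_um=iqr(d),
        txr_median=float(np.median(txr)),
        txr_iqr=iqr(txr),
        gfp_median=float(np.median(gfp)),
        gfp_iqr=iqr(gfp),
        expressing_fraction=frac,
    )


def fold_activation(on_level: float, off_level: float) -> float:
    """ON/OFF dynamic range of a reporter."""
    if off_level <= 0:
        raise ValueError("fold activation undefined for OFF-state <= 0")
    return on_level / off_level


def decompose_fold(fold_ref: float, off_change: float, on_change: float) -> float:
    """Fold activation of a variant from a reference fold and state changes.

    ``fold_variant = fold_ref * off_change * on_change`` where ``off_change``
    is the factor by which the OFF-state *decreased* and ``on_change`` the
    factor by which the ON-state increased.
    """
    if fold_ref <= 0 or off_change <= 0 or on_change <= 0:
        raise ValueError("fold factors must be > 0")
    return fold_ref * off_change * on_change
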