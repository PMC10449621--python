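"""Photomask pattern-fidelity scoring.

When gene expression is photo-activated through a patterned mask, the
expressing vesicles should lie inside the transparent mask regions.  This
module scores that correspondence operationally:

* **fidelity** -- fraction of expressing vesicles whose centers lie inside
  the mask;
* **contrast** -- ratio of the mean background-corrected reporter intensity
  of vesicles inside vs. outside the mask;
* **feature resolution** -- the mask is decomposed into 4-connected features
  whose width is twice the maximum inscribed-disk radius; a feature counts
  as *resolved* when it contains at least ``k`` expressing vesicles and its
  local contrast reaches ``c_min``.  ``min_resolved_width_um`` is the width
  of the narrowest resolved feature.

Mask-to-image registration is assumed given: the mask shares the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from guvquant.vesicle_quantification import VesicleRecord, records_to_dataframe

#: Resolved-feature rule defaults: minimum expressing vesicles per feature
#: and minimum local contrast.
DEFAULT_MIN_VESICLES = 3
DEFAULT_MIN_CONTRAST = 2.0

#: 4-connectivity structuring element for feature labeling.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class MaskFeature:
    """One connected transparent region of a photomask."""

    label: int
    area_px: int
    width_um: float


@dataclass
class MaskPattern:
    """Binary photomask on the image grid with its decomposed features."""

    mask: np.ndarray
    pixel_size_um: float
    features: list[MaskFeature]
    labels: np.ndarray

    @classmethod
    def from_array(cls, mask: np.ndarray, pixel_size_um: float) -> "MaskPattern":
        mask = np.asarray(mask)
        if not np.all(np.isin(np.unique(mask), (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        if pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        boolean = mask.astype(bool)
        features, labels = _decompose(boolean, pixel_size_um)
        return cls(
            mask=boolean, pixel_size_um=pixel_size_um, features=features, labels=labels
        )


@dataclass
class PatternScore:
    fidelity: float
    contrast: float | None  # None when there is no outside population
    n_expressing: int
    n_inside: int
    n_outside: int
    feature_table: pd.DataFrame  # label, width_um, n_expressing, contrast, resolved
    min_resolved_width_um: float | None


def _decompose(
    mask: np.ndarray, pixel_size_um: float
) -> tuple[list[MaskFeature], np.ndarray]:
    labels, n = ndimage.label(mask, structure=_STRUCTURE_4)
    features: list[MaskFeature] = []
    if n:
        dt = ndimage.distance_transform_edt(mask)
        max_dt = ndimage.maximum(dt, labels=labels, index=np.arange(1, n + 1))
        areas = ndimage.sum_labels(mask, labels=labels, index=np.arange(1, n + 1))
        for i in range(n):
            features.append(
                MaskFeature(
                    label=i + 1,
                    area_px=int(areas[i]),
                    width_um=float(2.0 * max_dt[i] * pixel_size_um),
                )
            )
    return features, labels


def feature_decompose(mask: np.ndarray, pixel_size_um: float = 1.0) -> list[MaskFeature]:
    """Decompose a binary mask into 4-connected features with widths.

    A feature's width is ``2 x max(distance transform) x pixel size`` -- the
    diameter of its largest inscribed disk (so a 1-px-wide line has width
    2 px equivalent, the distance transform being 1 px from each side).
    """
    return MaskPattern.from_array(mask, pixel_size_um).features


def score_pattern(
    records: Sequence[VesicleRecord] | pd.DataFrame,
    mask: MaskPattern | np.ndarray,
    pixel_size_um: float | None = None,
    k: int = DEFAULT_MIN_VESICLES,
    c_min: float = DEFAULT_MIN_CONTRAST,
) -> PatternScore:
    """Score how well expressing vesicles match a photomask pattern.

    ``records`` must carry per-vesicle centers (``row``, ``col``),
    background-corrected reporter means (``mean_gfp_corr``) and boolean
    ``expressing`` flags.  Vesicle membership is by center pixel.
    """
    if isinstance(mask, np.ndarray):
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required when passing a raw mask array")
        mask = MaskPattern.from_array(mask, pixel_size_um)
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if "expressing" not in df.columns:
        raise ValueError("records need an 'expressing' column (classify first)")
    if df.empty:
        raise ValueError("no vesicle records to score")
    if not mask.mask.any():
        raise ValueError("mask has no transparent pixels")

    rows = np.clip(np.round(df["row"].to_numpy(float)).astype(int), 0, mask.mask.shape[0] - 1)
    cols = np.clip(np.round(df["col"].to_numpy(float)).astype(int), 0, mask.mask.shape[1] - 1)
    inside = mask.mask[rows, cols]
    expressing = df["expressing"].to_numpy(bool)
    gfp = df["mean_gfp_corr"].to_numpy(float)

    n_expr = int(expressing.sum())
    if n_expr == 0:
        raise ValueError("no expressing vesicles; pattern fidelity undefined")
    fidelity = float((expressing & inside).sum() / n_expr)

    outside_mean = float(gfp[~inside].mean()) if (~inside).any() else None
    if outside_mean is None or outside_mean <= 0:
        contrast = None  # no (usable) outside population: flagged, not a number
    else:
        contrast = float(gfp[inside].mean() / outside_mean)

    labels_at = mask.labels[rows, cols]
    feat_rows = []
    resolved_widths = []
    for feat in mask.features:
        in_feat = labels_at == feat.label
        n_expr_feat = int((expressing & in_feat).sum())
        if outside_mean is not None and outside_mean > 0 and in_feat.any():
            local_contrast = float(gfp[in_feat].mean() / outside_mean)
        else:
            local_contrast = np.nan
        # The contrast gate applies only when an outside population exists;
        # with no outside vesicles the count criterion alone decides.
        contrast_ok = local_contrast >= c_min if np.isfinite(local_contrast) else (
            outside_mean is None
        )
        resolved = bool(n_expr_feat >= k and contrast_ok)
        if resolved:
            resolved_widths.append(feat.width_um)
        feat_rows.append(
            {
                "label": feat.label,
                "width_um": feat.width_um,
                "area_px": feat.area_px,
                "n_expressing": n_expr_feat,
                "contrast": local_contrast,
                "resolved": resolved,
            }
        )
    feature_table = pd.DataFrame(
        feat_rows,
        columns=["label", "width_um", "area_px", "n_expressing", "contrast", "resolved"],
    )
    return PatternScore(
        fidelity=fidelity,
        contrast=contrast,
        n_expressing=n_expr,
        n_inside=int(inside.sum()),
        n_outside=int((~inside).sum()),
        feature_table=feature_table,
        min_resolved_width_um=min(resolved_widths) if resolved_widths else None,
    )
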