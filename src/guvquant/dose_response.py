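"""Four-parameter Hill dose-response fitting and inverse titer quantification.

The reporter output of AHSL receiver cells follows a four-parameter logistic
(Hill) curve in ligand concentration X:

    GFP(X) = b + (a - b) / (1 + (EC50 / X)^h)

with ``a`` the maximal fluorescence output, ``b`` the basal output, ``EC50``
the concentration at half-maximal output and ``h`` the Hill coefficient.
Equivalently the denominator is ``1 + 10^(h * (log10 EC50 - log10 X))``, the
standard 4PL in log-concentration.  ``GFP(0) = b`` by the X -> 0 limit, the
curve is monotone increasing for h > 0, and ``GFP(EC50) = (a + b) / 2``.

Curves are fitted per replicate by bounded least squares and summarized as
the mean +- sample s.d. of EC50 and h across replicates.  The fitted curve
is then invertible in closed form, which supports back-calculating unknown
AHSL titers from receiver fluorescence measured at known dilution factors,
and converting the resulting concentration into a biosynthetic yield per
microliter of vesicle inner solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Fraction of the dynamic range (a - b) treated as out of range near each
#: asymptote when inverting measured fluorescence.
DEFAULT_RANGE_MARGIN = 0.05


class FitError(RuntimeError):
    """Raised when a dose-response fit cannot be performed or did not converge."""


class TiterRangeError(RuntimeError):
    """Raised when no well lies inside the invertible dynamic range."""


@dataclass(frozen=True)
class HillParams:
    """Parameters of the four-parameter logistic: a > b >= 0, EC50 > 0, h > 0."""

    a: float
    b: float
    ec50: float
    h: float

    def __post_init__(self) -> None:
        if not (self.a > self.b):
            raise ValueError("require a > b (maximal above basal output)")
        if self.b < 0:
            raise ValueError("basal output b must be >= 0")
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")
        if self.h <= 0:
            raise ValueError("hill coefficient h must be > 0")


@dataclass
class ReplicateFit:
    replicate: object
    params: HillParams
    residual_norm: float
    converged: bool


@dataclass
class DoseResponseCurve:
    """Per-replicate Hill fits plus cross-replicate summaries."""

    per_replicate: list[ReplicateFit]
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = _summarize_replicates(self.per_replicate)

    @property
    def mean_params(self) -> HillParams:
        """Arithmetic mean of each parameter across replicate fits."""
        return HillParams(
            a=self.summary["a_mean"],
            b=self.summary["b_mean"],
            ec50=self.summary["ec50_mean"],
            h=self.summary["h_mean"],
        )

    def to_dict(self) -> dict:
        return {
            "per_replicate": [
                {
                    "replicate": str(f.replicate),
                    "a": f.params.a,
                    "b": f.params.b,
                    "ec50": f.params.ec50,
                    "h": f.params.h,
                    "residual_norm": f.residual_norm,
                    "converged": f.converged,
                }
                for f in self.per_replicate
            ],
            "summary": self.summary,
        }


def _summarize_replicates(fits: Sequence[ReplicateFit]) -> dict[str, float]:
    def stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    a_m, a_s = stats([f.params.a for f in fits])
    b_m, b_s = stats([f.params.b for f in fits])
    e_m, e_s = stats([f.params.ec50 for f in fits])
    h_m, h_s = stats([f.params.h for f in fits])
    return {
        "a_mean": a_m,
        "a_sd": a_s,
        "b_mean": b_m,
        "b_sd": b_s,
        "ec50_mean": e_m,
        "ec50_sd": e_s,
        "h_mean": h_m,
        "h_sd": h_s,
        "n_replicates": float(len(fits)),
    }


@dataclass
class TiterEstimate:
    """Stock-concentration estimate from receiver wells at known dilutions."""

    per_well: pd.DataFrame  # dilution_factor, fluorescence, assay_conc, stock_conc, flag
    stock_geomean: float
    stock_gsd: float  # geometric s.d. (>= 1)
    n_usable: int
    n_saturated: int
    n_below_range: int


# ---------------------------------------------------------------------------
# Forward / inverse model
# ---------------------------------------------------------------------------


def hill_forward(params: HillParams, X: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the Hill curve; X = 0 maps to the basal output b."""
    x = np.asarray(X, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    out = np.full(x.shape, params.b, dtype=float)
    pos = x > 0
    ratio = np.power(params.ec50 / x[pos], params.h)
    out[pos] = params.b + (params.a - params.b) / (1.0 + ratio)
    if np.isscalar(X) or np.ndim(X) == 0:
        return float(out)
    return out


def hill_inverse(
    params: HillParams | DoseResponseCurve, gfp: float
) -> float:
    """Closed-form inverse: the concentration producing fluorescence ``gfp``.

    Valid only strictly inside the dynamic range (b, a); outside it the
    concentration is unidentifiable and a ``ValueError`` is raised (flagging
    of saturated / below-range wells is handled by :func:`estimate_titer`).
    """
    p = params.mean_params if isinstance(params, DoseResponseCurve) else params
    if not (p.b < gfp < p.a):
        raise ValueError(
            f"fluorescence {gfp} outside the open dynamic range ({p.b}, {p.a})"
        )
    return float(p.ec50 * ((p.a - p.b) / (gfp - p.b) - 1.0) ** (-1.0 / p.h))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit_single(
    conc: np.ndarray, fluo: np.ndarray, replicate: object
) -> ReplicateFit:
    if np.ptp(fluo) <= 0:
        raise FitError(
            f"replicate {replicate}: flat fluorescence data; EC50 unidentifiable"
        )
    pos = conc[conc > 0]
    if np.unique(pos).size < 5:
        raise FitError(
            f"replicate {replicate}: need >= 5 distinct positive concentrations"
        )
    b0 = float(fluo.min())
    a0 = float(fluo.max())
    loge0 = float(np.mean(np.log10(pos)))
    lo_e = np.log10(pos.min()) - 2.0
    hi_e = np.log10(pos.max()) + 2.0
    span = a0 - b0

    def model(theta: np.ndarray) -> np.ndarray:
        a, b, loge, h = theta
        out = np.full(conc.shape, b)
        p = conc > 0
        out[p] = b + (a - b) / (1.0 + np.power(10.0, h * (loge - np.log10(conc[p]))))
        return out

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - fluo

    lower = [b0 - 0.5 * span, min(0.0, b0 - 0.5 * span), lo_e, 1e-3]
    upper = [a0 + 2.0 * span, a0, hi_e, 10.0]
    # The objective has shallow-h / runaway-EC50 local minima when the
    # transition is sparsely sampled; a small multi-start over EC50 decades
    # and slopes makes the global basin reliably reachable.
    logs = np.log10(np.unique(pos))
    starts = []
    for loge_start in (logs.min(), loge0, logs.max()):
        for h_start in (0.7, 1.0, 2.0):
            starts.append(np.clip([a0, b0, loge_start, h_start], lower, upper))
    sol = None
    for theta0 in starts:
        cand = least_squares(
            residuals, theta0, bounds=(lower, upper),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        if sol is None or cand.cost < sol.cost:
            sol = cand
    if sol is None or not sol.success:
        raise FitError(f"replicate {replicate}: fit did not converge")
    a, b, loge, h = sol.x
    if not a > b:
        raise FitError(f"replicate {replicate}: degenerate fit (a <= b)")
    return ReplicateFit(
        replicate=replicate,
        params=HillParams(a=float(a), b=max(float(b), 0.0), ec50=float(10.0**loge), h=float(h)),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
    )


def fit_curve(plate: pd.DataFrame) -> DoseResponseCurve:
    """Fit the Hill model per replicate and summarize across replicates.

    ``plate`` must carry ``concentration_molar``, ``fluorescence`` and
    (optionally) ``replicate`` columns; zero-concentration wells anchor the
    basal output through the X -> 0 limit.  Each replicate is fitted
    independently; the summary reports mean +- sample s.d. of every
    parameter across replicate fits.
    """
    if "concentration_molar" not in plate or "fluorescence" not in plate:
        raise FitError("plate table needs concentration_molar and fluorescence columns")
    df = plate.dropna(subset=["concentration_molar", "fluorescence"])
    if df.empty:
        raise FitError("plate table has no usable wells")
    replicates = df["replicate"].unique() if "replicate" in df else np.array([0])
    fits = []
    for rep in sorted(replicates, key=str):
        sub = df[df["replicate"] == rep] if "replicate" in df else df
        fits.append(
            _fit_single(
                sub["concentration_molar"].to_numpy(dtype=float),
                sub["fluorescence"].to_numpy(dtype=float),
                rep,
            )
        )
    return DoseResponseCurve(per_replicate=fits)


# ---------------------------------------------------------------------------
# Titer estimation and yields
# ---------------------------------------------------------------------------


def estimate_titer(
    plate: pd.DataFrame,
    curve: DoseResponseCurve | HillParams,
    margin: float = DEFAULT_RANGE_MARGIN,
) -> TiterEstimate:
    """Back-calculate a stock concentration from diluted receiver wells.

    Wells within ``margin`` of either asymptote (fluorescence outside
    ``[b + margin*(a-b), a - margin*(a-b)]``) are flagged saturated or
    below-range and excluded.  Each usable well's assay concentration is the
    closed-form inverse of the curve; its stock estimate is that
    concentration times the well's dilution factor; the pooled estimate is
    the geometric mean across usable wells (concentrations being log-scale
    quantities), with a geometric s.d. as dispersion.
    """
    params = curve.mean_params if isinstance(curve, DoseResponseCurve) else curve
    if "dilution_factor" not in plate or "fluorescence" not in plate:
        raise ValueError("plate table needs dilution_factor and fluorescence columns")
    df = plate.dropna(subset=["dilution_factor", "fluorescence"]).copy()
    if df.empty:
        raise ValueError("no wells with dilution factors to invert")
    if np.any(df["dilution_factor"].to_numpy(dtype=float) < 1):
        raise ValueError("dilution factors must be >= 1")
    span = params.a - params.b
    lo = params.b + margin * span
    hi = params.a - margin * span

    assay_conc = np.full(len(df), np.nan)
    stock = np.full(len(df), np.nan)
    flags = np.empty(len(df), dtype=object)
    fluo = df["fluorescence"].to_numpy(dtype=float)
    dil = df["dilution_factor"].to_numpy(dtype=float)
    for i in range(len(df)):
        if fluo[i] >= hi:
            flags[i] = "saturated"
        elif fluo[i] <= lo:
            flags[i] = "below_range"
        else:
            flags[i] = "ok"
            assay_conc[i] = hill_inverse(params, fluo[i])
            stock[i] = assay_conc[i] * dil[i]
    df["assay_conc_molar"] = assay_conc
    df["stock_conc_molar"] = stock
    df["flag"] = flags

    usable = flags == "ok"
    n_sat = int((flags == "saturated").sum())
    n_below = int((flags == "below_range").sum())
    if not usable.any():
        raise TiterRangeError(
            f"no wells inside the dynamic range: {n_sat} saturated, "
            f"{n_below} below range (sample fully activating or inactive "
            "at every dilution; extend the dilution series)"
        )
    logs = np.log(stock[usable])
    geomean = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if usable.sum() > 1 else 1.0
    return TiterEstimate(
        per_well=df,
        stock_geomean=geomean,
        stock_gsd=gsd,
        n_usable=int(usable.sum()),
        n_saturated=n_sat,
        n_below_range=n_below,
    )


def yield_per_inner_solution(
    conc_nM: float, sample_ul: float, inner_ul: float
) -> float:
    """Convert a sample concentration to pmol per ul of vesicle inner solution.

    A sample of ``sample_ul`` microliters at ``conc_nM`` nanomolar contains
    ``conc_nM * 1e-3 * sample_ul`` picomoles; dividing by the inner-solution
    volume that produced it gives the biosynthetic yield in pmol per ul of
    inner solution.  With equal sample and reference volumes, 1 uM
    corresponds to 1 pmol/ul.
    """
    if sample_ul <= 0 or inner_ul <= 0:
        raise ValueError("volumes must be > 0")
    if conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    return conc_nM * 1e-3 * sample_ul / inner_ul
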