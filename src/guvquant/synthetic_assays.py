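"""Synthetic 96-well receiver-cell assay tables with known ground truth.

Emulates the statistical structure of AHSL receiver-cell plate assays: a
serial-dilution dose-response series (default: ten-fold steps from 63.2 uM
down to 632 pM, a zero-ligand well, n = 3 replicates) and "unknown titer"
plates in which a stock of unknown concentration is assayed at known
dilution factors.  Fluorescence is the Hill curve evaluated at the well
concentration times a multiplicative log-normal error of unit mean and
configurable coefficient of variation; OD600 is carried as an inert column
(constant nominal density plus small Gaussian jitter), mirroring assays that
record optical density but fit raw fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng

from guvquant.dose_response import HillParams, hill_forward

#: Default serial dilution endpoints (molar) and step.
DEFAULT_TOP_MOLAR = 63.2e-6
DEFAULT_BOTTOM_MOLAR = 632e-12
DEFAULT_DILUTION_STEP = 10.0

DEFAULT_NOISE_CV = 0.10
OD600_NOMINAL = 0.05
OD600_CV = 0.05

PLATE_COLUMNS = [
    "well_id",
    "replicate",
    "concentration_molar",
    "dilution_factor",
    "fluorescence",
    "od600",
    "condition_label",
]


def dilution_series(
    top: float = DEFAULT_TOP_MOLAR,
    bottom: float = DEFAULT_BOTTOM_MOLAR,
    step: float = DEFAULT_DILUTION_STEP,
) -> list[float]:
    """Geometric concentration series from ``top`` down to ``bottom`` (molar).

    ``bottom`` must be reachable from ``top`` by an integral number of
    ``step``-fold dilutions (to within floating tolerance).  The default
    reproduces {63.2 uM, 6.32 uM, 632 nM, 63.2 nM, 6.32 nM, 632 pM}... i.e.
    six ten-fold steps spanning 63.2 uM to 632 pM.
    """
    if not (0 < bottom <= top):
        raise ValueError("require 0 < bottom <= top")
    if step <= 1:
        raise ValueError("dilution step must be > 1")
    n_steps = np.log(top / bottom) / np.log(step)
    n = int(round(n_steps))
    if abs(n_steps - n) > 1e-6:
        raise ValueError(
            f"bottom {bottom} not reachable from top {top} by {step}-fold steps"
        )
    return [top / step**k for k in range(n + 1)]


@dataclass
class AssayConfig:
    """Configuration of one simulated dose-response plate."""

    true_params: HillParams = field(
        default_factory=lambda: HillParams(a=3.6, b=1.0, ec50=1.0e-9, h=1.38)
    )
    concentrations: Sequence[float] | None = None
    n_replicates: int = 3
    noise_cv: float = DEFAULT_NOISE_CV
    include_zero_well: bool = True
    rng_seed: int = 0
    condition_label: str = "dose_response"

    def __post_init__(self) -> None:
        if self.concentrations is None:
            self.concentrations = dilution_series()
        conc = list(self.concentrations)
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be strictly positive")
        if any(c2 >= c1 for c1, c2 in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        self.concentrations = conc


def _multiplicative_noise(rng, cv: float, n: int) -> np.ndarray:
    """Log-normal factors with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.standard_normal(n) * sigma - 0.5 * sigma**2)


def simulate_dose_response(config: AssayConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a tidy dose-response plate table plus its generating truth.

    Each well's fluorescence is the Hill curve at the well concentration
    times independent multiplicative log-normal noise; zero-concentration
    wells evaluate to the basal output b before noise.
    """
    rng = default_rng(config.rng_seed)
    conc = list(config.concentrations)
    if config.include_zero_well:
        conc = conc + [0.0]
    rows = []
    for rep in range(1, config.n_replicates + 1):
        clean = np.asarray(
            [hill_forward(config.true_params, c) for c in conc], dtype=float
        )
        noisy = clean * _multiplicative_noise(rng, config.noise_cv, len(conc))
        od = OD600_NOMINAL * (1.0 + OD600_CV * rng.standard_normal(len(conc)))
        for i, c in enumerate(conc):
            rows.append(
                {
                    "well_id": f"r{rep}c{i}",
                    "replicate": rep,
                    "concentration_molar": c,
                    "dilution_factor": np.nan,
                    "fluorescence": noisy[i],
                    "od600": od[i],
                    "condition_label": config.condition_label,
                }
            )
    truth = {
        "a": config.true_params.a,
        "b": config.true_params.b,
        "ec50": config.true_params.ec50,
        "h": config.true_params.h,
        "noise_cv": config.noise_cv,
    }
    return pd.DataFrame(rows, columns=PLATE_COLUMNS), truth


def simulate_unknown_titer(
    stock_conc: float,
    dilution_factors: Sequence[float],
    curve: HillParams,
    noise_cv: float = DEFAULT_NOISE_CV,
    n_replicates: int = 3,
    rng_seed: int = 0,
    condition_label: str = "unknown_titer",
) -> tuple[pd.DataFrame, dict]:
    """Simulate receiver wells assaying an unknown stock at known dilutions.

    Each well's assay concentration is ``stock_conc / dilution_factor``; its
    fluorescence is the Hill response plus multiplicative noise.  The truth
    dict records the generating stock concentration.
    """
    if stock_conc <= 0:
        raise ValueError("stock_conc must be > 0")
    dil = np.asarray(list(dilution_factors), dtype=float)
    if np.any(dil < 1):
        raise ValueError("dilution factors must be >= 1")
    rng = default_rng(rng_seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        conc = stock_conc / dil
        clean = np.asarray([hill_forward(curve, c) for c in conc], dtype=float)
        noisy = clean * _multiplicative_noise(rng, noise_cv, len(conc))
        od = OD600_NOMINAL * (1.0 + OD600_CV * rng.standard_normal(len(conc)))
        for i in range(len(dil)):
            rows.append(
                {
                    "well_id": f"r{rep}d{i}",
                    "replicate": rep,
                    "concentration_molar": np.nan,
                    "dilution_factor": dil[i],
                    "fluorescence": noisy[i],
                    "od600": od[i],
                    "condition_label": condition_label,
                }
            )
    truth = {"stock_conc_molar": float(stock_conc), "noise_cv": noise_cv}
    return pd.DataFrame(rows, columns=PLATE_COLUMNS), truth
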