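"""End-to-end pipeline orchestration with flat-file handoffs.

Every stage reads and writes plain-text CSV/JSON or standard TIFF, so each
stage is independently runnable and auditable; a run manifest records the
configuration hash and a SHA-256 checksum of every artifact, making
bit-reproducibility checkable by manifest equality.  One global seed is
fanned out as ``seed + stage_index`` so stages are reproducible yet draw
independent streams.

Stages (each optional, executed in dependency order):

``simulate_images``
    Render a sample field and a no-template control field (+ truth tables).
``detect``
    Normalize the experiment, detect circles on each TXR image.
``quantify``
    Estimate background from a vesicle-free corner, measure every detection.
``population``
    Control threshold, expressing fraction, population summary (JSON).
``simulate_assay``
    Dose-response plate and unknown-titer plate tables.
``fit_dose_response``
    Per-replicate Hill fits + summary (JSON).
``quantify_ahsl``
    Invert the fitted curve on the unknown-titer plate (JSON).
``pattern_score``
    Photomask fidelity / resolution report (JSON; needs a mask).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from guvquant import (
    dose_response,
    patterning_analysis,
    population_analysis,
    synthetic_assays,
    synthetic_microscopy,
    vesicle_detection,
    vesicle_quantification,
)
from guvquant.dose_response import HillParams
from guvquant.synthetic_microscopy import GFP, TXR

logger = logging.getLogger("guvquant")

STAGE_ORDER = [
    "simulate_images",
    "detect",
    "quantify",
    "population",
    "simulate_assay",
    "fit_dose_response",
    "quantify_ahsl",
    "pattern_score",
]

DEFAULT_STAGES = STAGE_ORDER[:7]  # pattern_score needs an explicit mask


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-serializable)."""

    outdir: str = "guvquant_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash + per-artifact checksums."""

    version: str
    config_hash: str
    seed: int
    stages: list[str]
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    # hash only what changes results: output location and verbosity excluded
    semantic = {"seed": config.seed, "stages": config.stages, "params": config.params}
    return hashlib.sha256(
        json.dumps(semantic, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order; return the manifest.

    A stage whose recorded outputs already exist with matching checksums (per
    a manifest from a previous run in the same directory) is skipped.
    """
    from guvquant import __version__

    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    previous: RunManifest | None = None
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            candidate = RunManifest.read(manifest_path)
            if candidate.config_hash == _config_hash(config):
                previous = candidate
        except (json.JSONDecodeError, TypeError):  # stale/foreign manifest
            previous = None

    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        stages=list(config.stages),
    )
    handlers = {
        "simulate_images": _stage_simulate_images,
        "detect": _stage_detect,
        "quantify": _stage_quantify,
        "population": _stage_population,
        "simulate_assay": _stage_simulate_assay,
        "fit_dose_response": _stage_fit_dose_response,
        "quantify_ahsl": _stage_quantify_ahsl,
        "pattern_score": _stage_pattern_score,
    }
    for stage in config.stages:
        stage_seed = config.seed + STAGE_ORDER.index(stage)
        params = dict(config.params.get(stage, {}))
        if previous is not None and _stage_fresh(previous, stage, outdir):
            logger.info("stage %s: outputs up to date, skipping", stage)
            for name, digest in previous.checksums.items():
                if name.startswith(stage + "/"):
                    manifest.checksums[name] = digest
                    manifest.timestamps[name] = previous.timestamps.get(name, 0.0)
            continue
        logger.info("stage %s: running (seed %d)", stage, stage_seed)
        try:
            outputs = handlers[stage](outdir, params, stage_seed)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        now = time.time()
        for path in outputs:
            key = f"{stage}/{path.name}"
            manifest.checksums[key] = _sha256(path)
            manifest.timestamps[key] = now
    manifest.write(manifest_path)
    return manifest


def _stage_fresh(previous: RunManifest, stage: str, outdir: Path) -> bool:
    keys = [k for k in previous.checksums if k.startswith(stage + "/")]
    if not keys:
        return False
    for key in keys:
        path = outdir / key.split("/", 1)[1]
        if not path.exists() or _sha256(path) != previous.checksums[key]:
            return False
    return True


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise StageError(
            f"stage {stage}: required input {path} is missing "
            "(run the producing stage first or fix the path)"
        )
    return path


def _require_columns(df: pd.DataFrame, columns: list[str], stage: str, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StageError(f"stage {stage}: {name} lacks required column(s) {missing}")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate_images(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    sim_params = dict(params)
    mask_path = sim_params.pop("mask_png", None)
    base = synthetic_microscopy.config_from_dict(sim_params) if sim_params else (
        synthetic_microscopy.SimImageConfig()
    )
    outputs: list[Path] = []
    mask = None
    if mask_path is not None:
        import imageio.v3 as iio

        mask = (np.asarray(iio.imread(mask_path)) > 0).astype(np.uint8)
    for label, frac_override, offset in (("control", 0.0, 0), ("sample", None, 1)):
        cfg = dataclasses.replace(
            base,
            expressing_fraction=(
                base.expressing_fraction if frac_override is None else frac_override
            ),
            rng_seed=seed + offset,
            condition_label=label,
            mask=mask if label == "sample" else None,
        )
        images, truths = synthetic_microscopy.simulate_field(cfg)
        images.image_id = label
        logger.info(
            "simulate_images[%s]: %d vesicles, field %s, pixel %.3f um",
            label, cfg.n_vesicles, cfg.field_size_px, cfg.pixel_size_um,
        )
        paths = synthetic_microscopy.write_field(outdir, images, truths)
        outputs.extend(paths.values())
    return outputs


def _load_field(outdir: Path, label: str, stage: str, pixel_size_um: float):
    channels = {}
    for channel in (TXR, GFP):
        path = _require(outdir, f"{label}_{channel}.tif", stage)
        channels[channel] = synthetic_microscopy.read_channel_image(
            path, channel, pixel_size_um, experiment_id="pipeline", condition_label=label
        )
    return synthetic_microscopy.ImageSet(
        channels=channels, experiment_id="pipeline", condition_label=label, image_id=label
    )


def _stage_detect(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    px = float(params.get("pixel_size_um", synthetic_microscopy.PIXEL_SIZE_X10_UM))
    radius_range = (
        float(params.get("radius_min_um", vesicle_detection.DEFAULT_RADIUS_RANGE_UM[0])),
        float(params.get("radius_max_um", vesicle_detection.DEFAULT_RADIUS_RANGE_UM[1])),
    )
    sensitivity = float(params.get("sensitivity", vesicle_detection.DEFAULT_SENSITIVITY))
    logger.info(
        "detect: radius range %s um, sensitivity %.2f", radius_range, sensitivity
    )
    sets = [_load_field(outdir, label, "detect", px) for label in ("control", "sample")]
    normalized, model = vesicle_detection.normalize_experiment(sets)
    outputs = []
    for s in normalized:
        detections = vesicle_detection.detect_vesicles(
            s[TXR], radius_range_um=radius_range, sensitivity=sensitivity
        )
        path = outdir / f"{s.image_id}_detections.csv"
        vesicle_detection.detections_to_dataframe(detections).to_csv(path, index=False)
        outputs.append(path)
    anchors_path = outdir / "normalization.json"
    with open(anchors_path, "w") as fh:
        json.dump({"anchors": model.anchors, "experiment_id": model.experiment_id}, fh,
                  indent=2, sort_keys=True)
    outputs.append(anchors_path)
    return outputs


def _stage_quantify(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    px = float(params.get("pixel_size_um", synthetic_microscopy.PIXEL_SIZE_X10_UM))
    corner = int(params.get("background_corner_px", 40))
    sets = [_load_field(outdir, label, "quantify", px) for label in ("control", "sample")]
    normalized, _ = vesicle_detection.normalize_experiment(sets)
    outputs = []
    for s in normalized:
        det_path = _require(outdir, f"{s.image_id}_detections.csv", "quantify")
        det_df = pd.read_csv(det_path)
        _require_columns(det_df, ["id", "row", "col", "radius_px", "score"],
                         "quantify", det_path.name)
        detections = [
            vesicle_detection.Detection(
                row=r.row, col=r.col, radius_px=r.radius_px, score=r.score, id=int(r.id)
            )
            for r in det_df.itertuples()
        ]
        region = (slice(0, corner), slice(0, corner))
        bg = vesicle_detection.estimate_background(s, region)
        logger.info("quantify[%s]: background %s (corner %d px)",
                    s.image_id, {k: round(v, 4) for k, v in bg.background.items()}, corner)
        records = vesicle_quantification.quantify_image_set(s, detections, bg, px)
        path = outdir / f"{s.image_id}_records.csv"
        vesicle_quantification.records_to_dataframe(records).to_csv(path, index=False)
        outputs.append(path)
    return outputs


def _stage_population(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    control = pd.read_csv(_require(outdir, "control_records.csv", "population"))
    sample = pd.read_csv(_require(outdir, "sample_records.csv", "population"))
    _require_columns(sample, ["mean_gfp_corr", "diameter_um"], "population",
                     "sample_records.csv")
    thr = population_analysis.control_threshold(control)
    frac, flags = population_analysis.expressing_fraction(sample, thr)
    summary = population_analysis.summarize(sample, thr)
    logger.info("population: threshold %.4f (control mean %.4f + 3 x sd %.4f)",
                thr.threshold, thr.control_mean, thr.control_sd)
    report = {
        "control_mean": thr.control_mean,
        "control_sd": thr.control_sd,
        "threshold": thr.threshold,
        "n_control": thr.n_control,
        "expressing_fraction": frac,
        "summary": dataclasses.asdict(summary),
    }
    path = outdir / "population.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    flagged = sample.loc[~sample["flagged"].astype(bool)].copy()
    flagged["expressing"] = flags
    classified_path = outdir / "sample_classified.csv"
    flagged.to_csv(classified_path, index=False)
    return [path, classified_path]


def _stage_simulate_assay(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    curve = HillParams(
        a=float(params.get("a", 3.6)),
        b=float(params.get("b", 1.0)),
        ec50=float(params.get("ec50", 1.0e-9)),
        h=float(params.get("h", 1.38)),
    )
    noise_cv = float(params.get("noise_cv", synthetic_assays.DEFAULT_NOISE_CV))
    cfg = synthetic_assays.AssayConfig(
        true_params=curve, noise_cv=noise_cv, rng_seed=seed
    )
    plate, truth = synthetic_assays.simulate_dose_response(cfg)
    plate_path = outdir / "dose_response_plate.csv"
    plate.to_csv(plate_path, index=False)
    stock = float(params.get("stock_conc_molar", 458.5e-9))
    dilutions = [float(d) for d in params.get("dilution_factors", [200, 2000])]
    titer_plate, titer_truth = synthetic_assays.simulate_unknown_titer(
        stock, dilutions, curve, noise_cv=noise_cv, rng_seed=seed + 1000
    )
    titer_path = outdir / "unknown_titer_plate.csv"
    titer_plate.to_csv(titer_path, index=False)
    truth_path = outdir / "assay_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"dose_response": truth, "unknown_titer": titer_truth}, fh,
                  indent=2, sort_keys=True)
    return [plate_path, titer_path, truth_path]


def _stage_fit_dose_response(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    plate = pd.read_csv(_require(outdir, "dose_response_plate.csv", "fit_dose_response"))
    _require_columns(plate, ["concentration_molar", "fluorescence", "replicate"],
                     "fit_dose_response", "dose_response_plate.csv")
    curve = dose_response.fit_curve(plate)
    path = outdir / "dose_response_fit.json"
    with open(path, "w") as fh:
        json.dump(curve.to_dict(), fh, indent=2, sort_keys=True)
    logger.info("fit: EC50 %.3g +- %.2g M, h %.3f +- %.3f",
                curve.summary["ec50_mean"], curve.summary["ec50_sd"],
                curve.summary["h_mean"], curve.summary["h_sd"])
    return [path]


def _stage_quantify_ahsl(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    with open(_require(outdir, "dose_response_fit.json", "quantify_ahsl")) as fh:
        fit = json.load(fh)
    s = fit["summary"]
    curve = HillParams(a=s["a_mean"], b=s["b_mean"], ec50=s["ec50_mean"], h=s["h_mean"])
    plate = pd.read_csv(_require(outdir, "unknown_titer_plate.csv", "quantify_ahsl"))
    _require_columns(plate, ["dilution_factor", "fluorescence"], "quantify_ahsl",
                     "unknown_titer_plate.csv")
    estimate = dose_response.estimate_titer(plate, curve,
                                            margin=float(params.get("margin", 0.05)))
    sample_ul = float(params.get("sample_ul", 25.0))
    inner_ul = float(params.get("inner_ul", 5.0))
    conc_nM = estimate.stock_geomean * 1e9
    report = {
        "stock_conc_molar": estimate.stock_geomean,
        "stock_conc_nM": conc_nM,
        "stock_gsd": estimate.stock_gsd,
        "n_usable": estimate.n_usable,
        "n_saturated": estimate.n_saturated,
        "n_below_range": estimate.n_below_range,
        "yield_pmol_per_ul_inner": dose_response.yield_per_inner_solution(
            conc_nM, sample_ul, inner_ul
        ),
        "sample_ul": sample_ul,
        "inner_ul": inner_ul,
    }
    path = outdir / "titer_estimate.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return [path]


def _stage_pattern_score(outdir: Path, params: Mapping, seed: int) -> list[Path]:
    import imageio.v3 as iio

    px = float(params.get("pixel_size_um", synthetic_microscopy.PIXEL_SIZE_X10_UM))
    mask_path = _require(outdir, str(params.get("mask_png", "mask.png")), "pattern_score")
    mask = (np.asarray(iio.imread(mask_path)) > 0).astype(np.uint8)
    records = pd.read_csv(_require(outdir, "sample_classified.csv", "pattern_score"))
    _require_columns(records, ["row", "col", "mean_gfp_corr", "expressing"],
                     "pattern_score", "sample_classified.csv")
    score = patterning_analysis.score_pattern(
        records,
        mask,
        pixel_size_um=px,
        k=int(params.get("k", patterning_analysis.DEFAULT_MIN_VESICLES)),
        c_min=float(params.get("c_min", patterning_analysis.DEFAULT_MIN_CONTRAST)),
    )
    report = {
        "fidelity": score.fidelity,
        "contrast": score.contrast,
        "n_expressing": score.n_expressing,
        "min_resolved_width_um": score.min_resolved_width_um,
        "features": score.feature_table.to_dict(orient="records"),
    }
    path = outdir / "pattern_score.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return [path]
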