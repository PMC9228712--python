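"""Config-driven experiment runner.

Reproduces the comparison design of the study: NIR-only PLS, MIR-only PLS,
fused (MIR+NIR) PLS and fused PCR, each scored with RMSEC / RMSECV / RMSEP /
prediction R^2 plus a predicted-value LoB/LoD, optionally with the lowest
non-zero ("blind") concentration level excluded. One tidy report row per
variant and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, InvalidInputError
from .lod import LodResult, lod_from_model
from .preprocess import (
    DEFAULT_MASKS,
    FusedData,
    PreprocessPipeline,
    PreprocessSpec,
    fuse_blocks,
)
from .regress import (
    cross_validate,
    fit_pcr,
    fit_pls,
    predict,
    r_squared,
    rmse,
)
from .split import split_dataset
from .synthetic import SimulationConfig, SpectralBlock, simulate_dataset

__all__ = [
    "Variant",
    "ExperimentConfig",
    "DEFAULT_VARIANTS",
    "exclude_level",
    "run_experiment",
    "write_report",
    "load_config",
]


@dataclass(frozen=True)
class Variant:
    """One model variant: which blocks, which regression, how many components."""

    label: str
    method: str  # "PLS" | "PCR"
    blocks: tuple[str, ...]
    n_components: int
    include_blind: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("PLS", "PCR"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if not self.blocks:
            raise ConfigurationError("variant needs at least one block")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")


#: The four model variants of the study's comparison table.
DEFAULT_VARIANTS: tuple[Variant, ...] = (
    Variant("NIR PLS", "PLS", ("NIR",), 8),
    Variant("MIR PLS", "PLS", ("MIR",), 10),
    Variant("Fused PLS", "PLS", ("MIR", "NIR"), 10),
    Variant("Fused PCR", "PCR", ("MIR", "NIR"), 10),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one experiment deterministically."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    variants: tuple[Variant, ...] = DEFAULT_VARIANTS
    masks: Mapping[str, tuple[float, float] | None] = field(
        default_factory=lambda: dict(DEFAULT_MASKS)
    )
    n_calibration: int = 26
    blank_level: float = 0.0
    low_conc_level: float | None = None  # None: smallest non-zero level
    seeds: tuple[int, ...] = (0,)
    cv_splits: int = 10
    compute_cv: bool = True
    data_files: Mapping[str, str] | None = None  # real-data mode

    def __post_init__(self) -> None:
        if not self.variants:
            raise ConfigurationError("at least one variant is required")
        if not self.seeds:
            raise ConfigurationError("at least one seed is required")


def exclude_level(dataset, level: float, protected_levels: Sequence[float] = ()):
    """Remove every sample at one concentration level.

    Works on a :class:`FusedData`, a single :class:`SpectralBlock`, or a
    sequence of blocks (all filtered consistently). Excluding a protected
    level (e.g. the blanks while an LoD is requested) raises a
    :class:`ConfigurationError`; excluding an absent level raises
    :class:`InvalidInputError`.
    """
    for p in protected_levels:
        if np.isclose(level, p):
            raise ConfigurationError(
                f"level {level} is protected (needed downstream) and cannot "
                "be excluded"
            )
    if isinstance(dataset, (list, tuple)):
        return type(dataset)(
            exclude_level(b, level) for b in dataset
        )
    conc = np.asarray(dataset.concentration, dtype=float)
    drop = np.isclose(conc, level)
    if not drop.any():
        raise InvalidInputError(f"level {level} not present in dataset")
    return dataset.select_rows(~drop)


def _region_label(fused: FusedData) -> str:
    parts = []
    for mod, grp in fused.provenance.groupby("modality", sort=False):
        nm = grp["wavelength_nm"]
        parts.append(f"{mod} {nm.max():.0f}-{nm.min():.0f} nm")
    return "; ".join(parts)


def _load_blocks(config: ExperimentConfig) -> dict[str, SpectralBlock]:
    if config.data_files is not None:
        return {
            mod: SpectralBlock.read_csv(path, mod)
            for mod, path in config.data_files.items()
        }
    mir, nir = simulate_dataset(config.simulation)
    return {"MIR": mir, "NIR": nir}


def _fit_variant(
    variant: Variant,
    fused: FusedData,
    plan_cal_mask: np.ndarray,
    config: ExperimentConfig,
    low_level: float,
):
    """Fit one variant; returns (model, metrics dict)."""
    data = fused
    cal_mask = plan_cal_mask
    if not variant.include_blind:
        keep = ~np.isclose(data.concentration, low_level)
        if not (~keep).any():
            raise InvalidInputError(
                f"blind level {low_level} absent; cannot exclude it"
            )
        data = data.select_rows(keep)
        cal_mask = cal_mask[keep]
    pred_mask = ~cal_mask

    X_cal, y_cal = data.X[cal_mask], data.concentration[cal_mask]
    x_mean = X_cal.mean(axis=0)
    y_mean = float(y_cal.mean())
    fit = fit_pls if variant.method == "PLS" else fit_pcr
    model = fit(X_cal - x_mean, y_cal - y_mean, variant.n_components)
    model.x_mean = x_mean
    model.y_mean = y_mean
    model.preprocess = config.preprocess
    model.masks = {m: config.masks.get(m) for m in variant.blocks}
    model.provenance = fused.provenance

    out = {
        "rmsec": rmse(y_cal, predict(model, X_cal)),
        "rmsecv": float("nan"),
        "rmsep": float("nan"),
        "r2_pred": float("nan"),
        "n_cal_spectra": int(cal_mask.sum()),
        "n_pred_spectra": int(pred_mask.sum()),
    }
    if config.compute_cv:
        rmsecv = cross_validate(
            X_cal,
            y_cal,
            groups=data.sample_id[cal_mask],
            method=variant.method,
            n_components=variant.n_components,
            n_splits=config.cv_splits,
        )
        out["rmsecv"] = float(rmsecv[variant.n_components - 1])
    if pred_mask.any():
        y_pred_hat = predict(model, data.X[pred_mask])
        y_pred = data.concentration[pred_mask]
        out["rmsep"] = rmse(y_pred, y_pred_hat)
        out["r2_pred"] = r_squared(y_pred, y_pred_hat)
    return model, out


def run_experiment(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run every variant for every seed; returns (report, manifest).

    Per seed: simulate (or load) -> per-block derivative+SNV -> fuse all
    blocks -> Kennard-Stone sample split -> per variant: fuse its blocks,
    fit, score, LoB/LoD from predicted blank and low-level replicates.
    """
    rows = []
    for seed in config.seeds:
        cfg = config
        if config.data_files is None:
            cfg = replace(
                config, simulation=replace(config.simulation, seed=int(seed))
            )
        raw = _load_blocks(cfg)
        pipeline = PreprocessPipeline(cfg.preprocess)
        blocks = {m: pipeline.transform_block(b) for m, b in raw.items()}

        order = sorted(blocks)  # deterministic block order for the split
        fused_all = fuse_blocks([blocks[m] for m in order], cfg.masks)
        plan = split_dataset(fused_all, cfg.n_calibration)

        conc = fused_all.concentration
        if cfg.low_conc_level is None:
            nonzero = np.unique(conc[conc > cfg.blank_level])
            if nonzero.size == 0:
                raise ConfigurationError("no level above the blank level")
            low_level = float(nonzero[0])
        else:
            low_level = float(cfg.low_conc_level)

        for variant in cfg.variants:
            fused_v = fuse_blocks(
                [blocks[m] for m in sorted(variant.blocks)], cfg.masks
            )
            cal_mask = plan.calibration_mask(fused_v.sample_id)
            model, metrics = _fit_variant(
                variant, fused_v, cal_mask, cfg, low_level
            )
            lod_res = lod_from_model(
                model, fused_v, blank_conc=cfg.blank_level, low_conc=low_level
            )
            rows.append(
                {
                    "seed": int(seed),
                    "variant": variant.label,
                    "method": variant.method,
                    "blocks": "+".join(variant.blocks),
                    "regions": _region_label(fused_v),
                    "n_components": variant.n_components,
                    "include_blind": variant.include_blind,
                    **metrics,
                    "mean_blank": lod_res.mean_blank,
                    "sd_blank": lod_res.sd_blank,
                    "sd_low": lod_res.sd_low,
                    "lob": lod_res.lob,
                    "lod": lod_res.lod,
                    "n_cal_samples": len(plan.calibration_sample_ids),
                    "n_pred_samples": len(plan.prediction_sample_ids),
                }
            )
    report = pd.DataFrame(rows)
    manifest = {
        "specfuse_version": __version__,
        "config": _config_to_dict(config),
    }
    return report, manifest


def _config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["masks"] = {k: (list(v) if v is not None else None)
                  for k, v in config.masks.items()}
    return d


def write_report(report: pd.DataFrame, manifest: dict, out_dir) -> None:
    """Write the tidy report CSV and a YAML run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv", index=False)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


# -- YAML config loading ------------------------------------------------------


def load_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Top-level keys (all optional): ``simulation``, ``preprocess``,
    ``variants`` (list of mappings), ``masks``, ``n_calibration``,
    ``seeds``, ``cv_splits``, ``compute_cv``, ``blank_level``,
    ``low_conc_level``, ``data_files``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        if "concentration_series" in sim:
            sim["concentration_series"] = tuple(sim["concentration_series"])
        kwargs["simulation"] = SimulationConfig(**sim)
    if "preprocess" in raw:
        kwargs["preprocess"] = PreprocessSpec(**raw["preprocess"])
    if "variants" in raw:
        kwargs["variants"] = tuple(
            Variant(
                label=v["label"],
                method=v["method"],
                blocks=tuple(v["blocks"]),
                n_components=int(v["n_components"]),
                include_blind=bool(v.get("include_blind", True)),
            )
            for v in raw["variants"]
        )
    if "masks" in raw:
        kwargs["masks"] = {
            k: (tuple(v) if v is not None else None)
            for k, v in raw["masks"].items()
        }
    for key in ("n_calibration", "blank_level", "low_conc_level",
                "cv_splits", "compute_cv", "data_files"):
        if key in raw:
            kwargs[key] = raw[key]
    if "seeds" in raw:
        kwargs["seeds"] = tuple(int(s) for s in raw["seeds"])
    return ExperimentConfig(**kwargs)
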