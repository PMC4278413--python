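"""End-to-end orchestration: data → clocks → ensemble fit → selection → experiments.

A single :class:`RunConfig` drives every stage.  One master seed is split
into per-stage child seeds (``SeedSequence(master, spawn_key=(stage,))``
truncated to 31 bits), so partial re-runs of a stage are reproducible and a
full re-run with the same config is bit-identical; a manifest records the
config hash, the derived seeds and a checksum of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .cbf_model import ArchitectureSpec, enumerate_ensemble
from .clock_driver import GENOTYPES, REGIMES, WILD_TYPE, Waveform, simulate_clock
from .experiments import cold_gating_profile, predict_mutants
from .fitting import FitBounds, FitResult, fit_ensemble
from .model_selection import SelectionTable, rank_ensemble
from .synthetic_data import (
    ExpressionDataset,
    TemplateShape,
    generate_dataset,
    write_dataset_csvs,
)

__all__ = ["RunConfig", "PipelineStageError", "run_selection", "run_experiments"]

logger = logging.getLogger(__name__)

_STAGES = {"data": 0, "fit": 1, "experiments": 2}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Every tunable of a full analysis run, with documented defaults.

    ``data_csv_paths`` (regime label → CSV path) switches the data source
    from the synthetic generator to files on disk.  ``architectures``
    restricts the ensemble to the listed labels (default: all 13).
    ``clock_waveforms`` overrides surrogate waveform settings per species,
    e.g. ``{"EC": {"peak_zt": 23, "fwhm_h": 8, "amplitude": 1}}``.
    """

    master_seed: int = 1
    outdir: str = "results"
    regimes: tuple[str, ...] = ("8L/16D", "12L/12D", "16L/8D", "24L/0D")
    # data stage
    data_csv_paths: dict = field(default_factory=dict)
    sample_start_h: float = 0.0
    sample_stop_h: float = 48.0
    sample_step_h: float = 4.0
    noise_sd: float = 0.1
    template: dict = field(default_factory=dict)  # TemplateShape overrides
    # clock stage
    clock_mode: str = "surrogate"  # or "sbml"
    clock_step_h: float = 0.25
    clock_duration_h: float = 96.0
    clock_waveforms: dict = field(default_factory=dict)
    sbml_path: str | None = None
    sbml_species_map: dict = field(default_factory=dict)
    # fitting stage
    architectures: tuple[str, ...] | None = None
    n_restarts: int = 24
    restart_maxfev: int = 400
    polish_maxfev: int = 4000
    hill_n: float = 2.0
    log10_K_bounds: tuple[float, float] = (-3.0, 3.0)
    log10_d_bounds: tuple[float, float] = (float(np.log10(0.05)), float(np.log10(5.0)))
    # experiments stage
    genotypes: tuple[str, ...] = ("lhy cca1", "ni prr7 prr9", "toc1", "lux")
    gating_fold: float = 5.0
    gating_pulse_times: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    gating_pulse_duration_h: float = 4.0
    gating_observe_window_h: float = 4.0
    gating_statistic: str = "response"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.from_dict(payload or {})

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(payload)
        for key in ("regimes", "architectures", "genotypes", "gating_pulse_times"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("log10_K_bounds", "log10_d_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(entropy=self.master_seed, spawn_key=(_STAGES[stage],))
        return int(ss.generate_state(1)[0] % 2**31)

    def template_shape(self) -> TemplateShape:
        return TemplateShape(**self.template) if self.template else TemplateShape()

    def waveform_overrides(self) -> dict[str, Waveform]:
        return {sp: Waveform(**cfg) for sp, cfg in self.clock_waveforms.items()}

    def fit_bounds(self) -> FitBounds:
        return FitBounds(log10_K=self.log10_K_bounds, log10_d=self.log10_d_bounds)

    def ensemble(self) -> list[ArchitectureSpec]:
        archs = enumerate_ensemble()
        if self.architectures is None:
            return archs
        by_label = {a.label: a for a in archs}
        try:
            return [by_label[label] for label in self.architectures]
        except KeyError as err:
            raise ValueError(f"unknown architecture label {err.args[0]!r}") from None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, files: Sequence[Path], complete: bool) -> Path:
    manifest = {
        "version": __version__,
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "complete": complete,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files if p.exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def build_datasets(config: RunConfig) -> dict[str, ExpressionDataset]:
    """Synthetic (seeded) or CSV-loaded expression data per regime."""
    regimes = [REGIMES[label] for label in config.regimes]
    if config.data_csv_paths:
        return {
            r.label: ExpressionDataset.from_csv(config.data_csv_paths[r.label], r)
            for r in regimes
        }
    times = np.arange(
        config.sample_start_h, config.sample_stop_h + 1e-9, config.sample_step_h
    )
    return generate_dataset(
        regimes,
        times=times,
        noise_sd=config.noise_sd,
        seed=config.stage_seed("data"),
        shape=config.template_shape(),
    )


def build_clocks(config: RunConfig) -> dict[str, "object"]:
    """One wild-type clock trajectory per regime (surrogate or SBML mode)."""
    overrides = config.waveform_overrides()
    clocks = {}
    for label in config.regimes:
        if config.clock_mode == "surrogate":
            clocks[label] = simulate_clock(
                REGIMES[label],
                WILD_TYPE,
                duration=config.clock_duration_h,
                step=config.clock_step_h,
                waveforms=overrides or None,
            )
        elif config.clock_mode == "sbml":
            from .sbml_driver import simulate_sbml_clock

            clocks[label] = simulate_sbml_clock(
                config.sbml_path,
                config.sbml_species_map,
                regime=REGIMES[label],
                duration=config.clock_duration_h,
                step=config.clock_step_h,
            )
        else:
            raise ValueError(f"unknown clock mode {config.clock_mode!r}")
    return clocks


def run_selection(config: RunConfig) -> tuple[SelectionTable, list[FitResult]]:
    """Generate/load data, fit the ensemble, rank it, and write artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        logger.info("stage data: building expression datasets")
        datasets = build_datasets(config)
        written += write_dataset_csvs(datasets, outdir)
        clocks = build_clocks(config)
    except Exception as err:  # noqa: BLE001 - stage boundary
        _write_manifest(outdir, config, written, complete=False)
        raise PipelineStageError("data", err) from err
    try:
        archs = config.ensemble()
        logger.info("stage fit: fitting %d architectures", len(archs))
        fits = fit_ensemble(
            archs,
            datasets,
            clocks,
            seed=config.stage_seed("fit"),
            n_restarts=config.n_restarts,
            bounds=config.fit_bounds(),
            hill_n=config.hill_n,
            restart_maxfev=config.restart_maxfev,
            polish_maxfev=config.polish_maxfev,
        )
        fits_path = outdir / "fits.json"
        fits_path.write_text(json.dumps([f.to_dict() for f in fits], indent=2))
        written.append(fits_path)
        table = rank_ensemble(fits)
        csv_path = outdir / "selection.csv"
        table.to_frame().to_csv(csv_path, index=False)
        txt_path = outdir / "selection.txt"
        txt_path.write_text(table.to_text() + "\n")
        written += [csv_path, txt_path]
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001 - stage boundary
        _write_manifest(outdir, config, written, complete=False)
        raise PipelineStageError("fit", err) from err
    written.append(_write_manifest(outdir, config, written, complete=True))
    return table, fits


def run_experiments(config: RunConfig, fit: FitResult) -> dict[str, Path]:
    """Mutant predictions and gating profiles for one fitted model."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = config.waveform_overrides() or None
    paths: dict[str, Path] = {}
    try:
        import pandas as pd

        genotypes = [GENOTYPES[g] for g in config.genotypes]
        predictions = predict_mutants(
            fit.arch, fit.params, genotypes, waveforms=overrides
        )
        frame = pd.DataFrame(
            {
                "genotype": [p.genotype for p in predictions],
                "fold_change": [p.fold_change for p in predictions],
                "class": [p.qualitative_class for p in predictions],
                "mutant_arrhythmic": [p.mutant_arrhythmic for p in predictions],
            }
        )
        paths["mutants"] = outdir / "mutants.csv"
        frame.to_csv(paths["mutants"], index=False)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("mutants", err) from err
    try:
        for mode in ("via_LHY", "direct"):
            profile = cold_gating_profile(
                fit.arch,
                fit.params,
                mode,
                fold=config.gating_fold,
                pulse_times=config.gating_pulse_times,
                pulse_duration_h=config.gating_pulse_duration_h,
                observe_window_h=config.gating_observe_window_h,
                statistic=config.gating_statistic,
                waveforms=overrides,
            )
            paths[f"gating_{mode}"] = outdir / f"gating_{mode}.csv"
            profile.to_frame().to_csv(paths[f"gating_{mode}"], index=False)
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("gating", err) from err
    return paths
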