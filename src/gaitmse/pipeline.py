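"""End-to-end orchestration: simulate → fuse → events → entropy → report.

A :class:`RunConfig` names one or more walking conditions (each a generator
configuration or an input recording CSV), the entropy and detector
parameters, an output directory and a master seed.  The speed-comparison run
produces the per-condition stride series and MSE profiles, a SampEn /
MSE_S / MSE_L summary table, the per-region amplitude–pressure ratio table
and a manifest with seeds, parameters and output checksums.

Reproducibility: the master seed spawns an independent substream per
(condition index, replicate) via ``numpy.random.SeedSequence``, so adding a
condition or replicate never perturbs the data of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import REGIONS
from .entropy import EntropyParams, MSEReport, mse_report
from .errors import ConfigurationError, PipelineError
from .events import DetectorParams, amplitude_pressure_ratio, stride_intervals
from .fusion import fuse_regions, read_recording, write_recording
from .agreement import AgreementResult, validate_paired_traces
from .fusion import normalize_trace
from .events import split_contacts
from .synthetic import GaitGeneratorConfig, generate_paired_plate_signal, generate_recording

log = logging.getLogger("gaitmse")

__all__ = ["RunConfig", "SpeedComparisonResult", "run_speed_comparison", "run_validation"]

Condition = Union[GaitGeneratorConfig, str, Path]


@dataclass
class RunConfig:
    """Configuration of a full speed-comparison run."""

    conditions: list[tuple[str, Condition]]
    entropy: EntropyParams = field(default_factory=EntropyParams)
    detector: DetectorParams | None = None
    output_dir: str | Path = "gaitmse_out"
    seed: int = 0
    n_replicates: int = 1
    total_mode: str = "sum"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        labels = [label for label, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"condition labels must be unique: {labels}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for label, cond in self.conditions:
            if isinstance(cond, (str, Path)) and not Path(cond).exists():
                raise ConfigurationError(f"condition {label!r}: input file {cond} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Each entry of ``conditions`` is either ``{label, csv: path}`` or
        ``{label, speed_kmh, ...generator fields}``.
        """
        from .synthetic import speed_preset

        data = yaml.safe_load(Path(path).read_text())
        conditions: list[tuple[str, Condition]] = []
        for entry in data.get("conditions", []):
            label = str(entry.pop("label"))
            if "csv" in entry:
                conditions.append((label, entry["csv"]))
            elif entry.get("preset"):
                speed = entry.pop("preset")
                entry.pop("speed_kmh", None)
                conditions.append((label, speed_preset(speed, **entry)))
            else:
                conditions.append((label, GaitGeneratorConfig(**entry)))
        entropy = EntropyParams(**data.get("entropy", {}))
        detector = DetectorParams(**data["detector"]) if "detector" in data else None
        return cls(
            conditions=conditions,
            entropy=entropy,
            detector=detector,
            output_dir=data.get("output_dir", "gaitmse_out"),
            seed=int(data.get("seed", 0)),
            n_replicates=int(data.get("n_replicates", 1)),
            total_mode=data.get("total_mode", "sum"),
        )


@dataclass
class SpeedComparisonResult:
    """Outputs of one speed-comparison run."""

    report: MSEReport
    ratios: pd.DataFrame
    manifest: dict
    output_dir: Path


def _derived_seed(master: int, condition_idx: int, replicate: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(condition_idx, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_speed_comparison(cfg: RunConfig) -> SpeedComparisonResult:
    """Run the full simulate → fuse → events → entropy pipeline and write outputs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    series_by_condition: dict[str, list] = {}
    ratio_rows = []
    seeds_used: dict[str, list[int]] = {}
    for ci, (label, cond) in enumerate(cfg.conditions):
        series_by_condition[label] = []
        seeds_used[label] = []
        n_reps = cfg.n_replicates if isinstance(cond, GaitGeneratorConfig) else 1
        for rep in range(n_reps):
            with _stage(f"simulate[{label}]"):
                if isinstance(cond, GaitGeneratorConfig):
                    seed = _derived_seed(cfg.seed, ci, rep)
                    rec = generate_recording(dataclasses.replace(cond, seed=seed))
                    seeds_used[label].append(seed)
                else:
                    rec = read_recording(cond)
                    seeds_used[label].append(int(rec.meta.get("seed", -1)))
            with _stage(f"fuse[{label}]"):
                regional = fuse_regions(rec, total_mode=cfg.total_mode)
            with _stage(f"events[{label}]"):
                detector = cfg.detector
                if detector is None and isinstance(cond, GaitGeneratorConfig):
                    detector = DetectorParams(nominal_stride_s=cond.mean_stride_s)
                strides = stride_intervals(regional, detector)
                ratios = amplitude_pressure_ratio(regional, rec.weight_kg)
            series_by_condition[label].append(strides)
            ratio_rows.append({"condition": label, "replicate": rep, **ratios})
            stride_path = out / f"{label}_strides_rep{rep}.csv"
            strides.to_csv(stride_path)
            files.append(stride_path)
        log.info("condition %s: %d replicate(s) processed", label, n_reps)
    with _stage("entropy"):
        report = mse_report(series_by_condition, cfg.entropy)
    with _stage("report"):
        for label, profs in report.profiles.items():
            for rep, prof in enumerate(profs):
                p = out / f"{label}_mse_rep{rep}.csv"
                prof.to_csv(p)
                files.append(p)
        table_path = out / "entropy_table.csv"
        report.table.drop(columns=["series_lengths"]).to_csv(table_path, index=False)
        files.append(table_path)
        pairwise_path = out / "pairwise_mse_s.csv"
        report.pairwise_mse_s.to_csv(pairwise_path, index=False)
        files.append(pairwise_path)
        ratios_df = pd.DataFrame(ratio_rows)
        ratio_summary = ratios_df.groupby("condition", sort=False)[list(REGIONS)].mean()
        ratios_path = out / "amplitude_pressure_ratios.csv"
        ratio_summary.to_csv(ratios_path)
        files.append(ratios_path)
    manifest = {
        "gaitmse_version": __version__,
        "master_seed": cfg.seed,
        "seeds": seeds_used,
        "entropy": dataclasses.asdict(cfg.entropy),
        "detector": dataclasses.asdict(cfg.detector) if cfg.detector else None,
        "n_replicates": cfg.n_replicates,
        "total_mode": cfg.total_mode,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return SpeedComparisonResult(
        report=report, ratios=ratio_summary.reset_index(), manifest=manifest, output_dir=out
    )


def run_validation(
    gen_config: GaitGeneratorConfig,
    bias: float = 0.0,
    noise_sd: float = 0.02,
    second_peak_attenuation: float = 1.1,
    n_points: int = 101,
    output_dir: str | Path | None = None,
    total_mode: str = "sum",
) -> AgreementResult:
    """Insole-vs-plate agreement workflow on one synthetic trial.

    Generates a recording, fuses it, extracts one representative contact
    episode of the total trace, builds the paired plate surrogate (bias,
    noise in units of the normalized trace, push-off peak rescaling),
    normalizes both to a common ``n_points`` grid and runs the
    Bland–Altman / Pearson analysis.  Optionally writes the result and plot.
    """
    with _stage("simulate[validation]"):
        rec = generate_recording(gen_config)
    with _stage("fuse[validation]"):
        regional = fuse_regions(rec, total_mode=total_mode)
    with _stage("validate"):
        contacts = split_contacts(regional.total)
        if not contacts:
            raise PipelineError("stage 'validate' failed: no contact episodes")
        # representative contact: a middle episode, away from recording edges
        a, b = contacts[len(contacts) // 2]
        insole_cycle = regional.total[a:b]
        insole_norm = normalize_trace(insole_cycle, n_points)
        plate_cycle = generate_paired_plate_signal(
            insole_norm,
            bias=bias,
            noise_sd=noise_sd,
            second_peak_attenuation=second_peak_attenuation,
            seed=gen_config.seed + 1,
        )
        plate_norm = normalize_trace(np.clip(plate_cycle, 0, None), n_points)
        result = validate_paired_traces(insole_norm, plate_norm)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_json(out / "agreement.json")
        from .agreement import bland_altman_plot

        bland_altman_plot(insole_norm, plate_norm, out / "bland_altman.png")
    return result
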