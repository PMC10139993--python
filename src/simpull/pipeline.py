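"""End-to-end pipeline: simulate → detect → analyze (→ image quant) → report.

A run is described by a :class:`RunConfig` (loadable from a YAML file):
per-condition oligomer specs or trace files, photophysics, detector
parameters, the GFP-background correction, optional dissolution pairs
and optional synthetic image cohorts.  :func:`run_pipeline` executes the
stages deterministically given the seeds, writes TSV tables plus a
plain-text report, and records a manifest (config snapshot, per-file
SHA-256 checksums, per-stage counts, timestamps) so every reported
number is traceable to a stage output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_traces, write_steps, write_traces
from .oligomer import (
    CorrectionModel,
    OligomerModel,
    compare_conditions,
    dissolution_difference,
)
from .stepfit import StepFitParams, batch_detect
from .synthetic.traces import OligomerSpec, simulate_population
from .trace import GFPPhotophysics

__all__ = ["ConditionConfig", "RunConfig", "RunManifest", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental condition: either a simulation spec or a trace file."""

    name: str
    spec: dict[int, float] | None = None
    n_spots: int = 2000
    traces_path: str | None = None
    stress: bool = False
    dissolved_from: str | None = None  # name of the pre-dissolution condition

    def __post_init__(self) -> None:
        if (self.spec is None) == (self.traces_path is None):
            raise ValueError(
                f"condition {self.name!r}: exactly one of spec / traces_path required"
            )


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    conditions: tuple[ConditionConfig, ...]
    photophysics: GFPPhotophysics = field(default_factory=GFPPhotophysics)
    step_params: StepFitParams = field(default_factory=StepFitParams)
    correction: CorrectionModel = field(default_factory=CorrectionModel)
    n_frames: int = 800
    seed: int = 0
    n_boot: int = 1000
    images: tuple[str, ...] = ()  # two-channel TIFFs (nuclear, GFP)
    pixel_size: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        conds = tuple(
            ConditionConfig(
                name=c["name"],
                spec={int(k): float(v) for k, v in c["spec"].items()} if "spec" in c else None,
                n_spots=int(c.get("n_spots", 2000)),
                traces_path=c.get("traces_path"),
                stress=bool(c.get("stress", False)),
                dissolved_from=c.get("dissolved_from"),
            )
            for c in raw["conditions"]
        )
        return cls(
            out_dir=raw["out_dir"],
            conditions=conds,
            photophysics=GFPPhotophysics(**raw.get("photophysics", {})),
            step_params=StepFitParams(**raw.get("step_params", {})),
            correction=CorrectionModel(**raw.get("correction", {})),
            n_frames=int(raw.get("n_frames", 800)),
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 1000)),
            images=tuple(raw.get("images", ())),
            pixel_size=float(raw.get("pixel_size", 0.25)),
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict[str, int]
    counts: dict[str, dict]
    checksums: dict[str, str]
    started: str = ""
    finished: str = ""

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_snapshot(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline; outputs land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_snapshot(config),
        version=__version__,
        seeds={},
        counts={},
        checksums={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outputs: list[Path] = []
    results: dict[str, OligomerModel] = {}
    fitted = {}
    ss = np.random.SeedSequence(config.seed)
    cond_seeds = ss.generate_state(len(config.conditions)) % (2**31)

    # stage 1+2: per-condition traces and step detection
    step_tables: dict[str, pd.DataFrame] = {}
    for i, cond in enumerate(config.conditions):
        try:
            if cond.spec is not None:
                seed = int(cond_seeds[i])
                manifest.seeds[cond.name] = seed
                spec = OligomerSpec(probabilities=cond.spec, n_spots=cond.n_spots, seed=seed)
                traces = simulate_population(
                    spec, config.photophysics, n_frames=config.n_frames
                )
                tpath = out / "traces" / f"{cond.name}.tsv"
                write_traces(traces, tpath, truth_path=tpath.with_name(f"{cond.name}_truth.tsv"))
                outputs += [tpath, tpath.with_name(f"{cond.name}_truth.tsv")]
            else:
                traces = read_traces(cond.traces_path)
                if not traces:
                    raise PipelineError(f"simulate/load [{cond.name}]: no traces found")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - stage name + cause contract
            raise PipelineError(f"simulate/load [{cond.name}]: {e}") from e
        try:
            batch = batch_detect(traces, config.step_params)
            spath = out / "steps" / f"{cond.name}.tsv"
            write_steps(batch.table, spath)
            outputs.append(spath)
            step_tables[cond.name] = batch.table
            manifest.counts[cond.name] = {
                "n_traces": len(traces),
                "n_valid": batch.n_valid,
                "n_rejected": batch.n_rejected,
                "rejections": batch.rejection_counts,
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"detect [{cond.name}]: {e}") from e

    # stage 3: distributions, correction, summaries
    try:
        boot_seed = int(ss.generate_state(len(config.conditions) + 1)[-1] % (2**31))
        for cond in config.conditions:
            model = OligomerModel(
                step_tables[cond.name], condition=cond.name, correction=config.correction
            )
            fitted[cond.name] = model.fit(n_boot=config.n_boot, seed=boot_seed)
        results.update(fitted)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"analyze: {e}") from e

    # stage 4 (optional): image quantification
    if config.images:
        try:
            import tifffile

            from .imagequant import measure_image, summarize_cells

            measurements = []
            grouping: dict[int, str] = {}
            next_id = 0
            for path in config.images:
                stack = tifffile.imread(path).astype(float)
                if stack.ndim != 3 or stack.shape[0] < 2:
                    raise ValueError(f"{path}: expected a 2-channel stack")
                for m in measure_image(stack[0], stack[1], pixel_size=config.pixel_size):
                    next_id += 1
                    grouping[next_id] = Path(path).stem
                    measurements.append(dataclasses.replace(m, cell_id=next_id))
            manifest.counts["images"] = {
                "n_images": len(config.images), "n_cells": len(measurements)
            }
            if measurements:
                table = summarize_cells(measurements, grouping)
                p = out / "image_summary.tsv"
                table.to_csv(p, sep="\t", index=False, float_format="%.6f")
                outputs.append(p)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"image-quant: {e}") from e

    report_paths = write_report(fitted, out, conditions=config.conditions)
    outputs += report_paths
    for p in outputs:
        manifest.checksums[str(p.relative_to(out))] = _sha256(p)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "manifest.json")
    return manifest


def write_report(
    fitted: dict, out: Path, conditions: tuple[ConditionConfig, ...] = ()
) -> list[Path]:
    """Emit distribution/summary/difference/statistics tables + text summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    dist_rows, summary_rows = [], []
    for name, res in fitted.items():
        for k, f in sorted(res.raw.frequencies.items()):
            dist_rows.append(
                {"condition": name, "step": k, "frequency_raw": f,
                 "frequency_corrected": res.corrected.frequencies.get(k, 0.0)}
            )
        summary_rows.append(
            {
                "condition": name,
                "average_step_raw": res.summary_raw.average_step,
                "sem_raw": res.summary_raw.sem,
                "average_step_corrected": res.summary_corrected.average_step,
                "sem_corrected": res.summary_corrected.sem,
                "n_traces": res.raw.n_traces,
            }
        )
    ddf = pd.DataFrame(dist_rows)
    sdf = pd.DataFrame(summary_rows)
    p = out / "distributions.tsv"
    ddf.to_csv(p, sep="\t", index=False, float_format="%.6f")
    paths.append(p)
    p = out / "summary.tsv"
    sdf.to_csv(p, sep="\t", index=False, float_format="%.6f")
    paths.append(p)

    # dissolution differences for configured before/after pairs
    diff_rows = []
    for cond in conditions:
        if cond.dissolved_from and cond.dissolved_from in fitted and cond.name in fitted:
            d = dissolution_difference(
                fitted[cond.dissolved_from].raw, fitted[cond.name].raw
            )
            d.insert(0, "pair", f"{cond.dissolved_from}->{cond.name}")
            diff_rows.append(d)
    if diff_rows:
        p = out / "dissolution_differences.tsv"
        # full precision so the sum-to-zero invariant survives the round trip
        pd.concat(diff_rows, ignore_index=True).to_csv(p, sep="\t", index=False)
        paths.append(p)

    # cross-condition statistics on per-trace counts
    counted = {
        name: res.raw.counts for name, res in fitted.items() if res.raw.counts is not None
    }
    if len(counted) >= 2:
        test = "ttest" if len(counted) == 2 else "anova"
        stats_out = compare_conditions(counted, test=test)
        p = out / "statistics.json"
        with open(p, "w") as f:
            json.dump(
                {k: v for k, v in stats_out.items() if k != "anova_table"},
                f, indent=2, default=str,
            )
        paths.append(p)

    lines = ["SiMPull photobleaching analysis report", ""]
    for name, res in fitted.items():
        lines.append(res.summary())
        lines.append("")
    p = out / "report.txt"
    p.write_text("\n".join(lines))
    paths.append(p)
    return paths
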