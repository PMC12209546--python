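"""Study configuration and the end-to-end experiment driver.

A :class:`StudyConfig` describes the full sweep — outcome families x
selection families x interaction grid x selection fractions — plus the
shared parameter preset and master seed.  :func:`run_full_study` executes the
sweep, writes one CSV per bias curve and a JSON summary of slopes, and a run
manifest with derived seeds and truncation counts.  Re-running the same
config reproduces every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import OUTCOME_FAMILIES, SELECTION_FAMILIES
from .study import DEFAULT_DELTA3_GRID, DEFAULT_PRESET, run_bias_experiment

logger = logging.getLogger(__name__)

_STUDY_OUTCOMES = ("logistic", "linear", "poisson")


@dataclass(frozen=True)
class StudyConfig:
    master_seed: int = 0
    n_per_point: int = 500_000
    outcome_families: tuple = _STUDY_OUTCOMES
    selection_families: tuple = ("logistic", "probit", "double_threshold")
    delta3_grid: tuple = DEFAULT_DELTA3_GRID
    selection_fractions: tuple = (0.5,)
    parameter_preset: dict = field(default_factory=lambda: dict(DEFAULT_PRESET))
    calibration_n: int = 1_000_000
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        if not self.delta3_grid or not self.outcome_families or not self.selection_families:
            raise ValueError("grids must be nonempty")
        for fam in self.outcome_families:
            if fam not in OUTCOME_FAMILIES:
                raise ValueError(f"unknown outcome family {fam!r}")
        for fam in self.selection_families:
            if fam not in SELECTION_FAMILIES:
                raise ValueError(f"unknown selection family {fam!r}")
        for f in self.selection_fractions:
            if not 0 < f < 1:
                raise ValueError(f"selection fraction {f} outside (0, 1)")
        if self.n_per_point <= 0:
            raise ValueError("n_per_point must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("outcome_families", "selection_families", "delta3_grid", "selection_fractions"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("outcome_families", "selection_families", "delta3_grid", "selection_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_full_study(config: StudyConfig) -> dict:
    """Run the configured sweep and write outputs under ``config.output_dir``.

    Returns the manifest (also written as ``manifest.json``).  Raises
    ``RuntimeError`` after the sweep if any curve failed, so partial output
    is preserved alongside the failure record.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "curves": [],
        "failures": [],
    }
    summary = []
    for frac in config.selection_fractions:
        for sel_fam in config.selection_families:
            for out_fam in config.outcome_families:
                name = f"{out_fam}+{sel_fam}+f{frac:g}"
                logger.info("running curve %s", name)
                try:
                    curve = run_bias_experiment(
                        out_fam,
                        sel_fam,
                        config.delta3_grid,
                        frac,
                        config.n_per_point,
                        config.master_seed,
                        preset=config.parameter_preset,
                        calibration_n=config.calibration_n,
                    )
                except Exception as exc:
                    manifest["failures"].append({"curve": name, "error": str(exc)})
                    continue
                csv_path = outdir / f"curve_{name.replace('+', '_')}.csv"
                curve.grid.to_csv(csv_path, index=False)
                summary.append(curve.summary())
                manifest["curves"].append(
                    {
                        "curve": name,
                        "csv": csv_path.name,
                        "n_truncated_total": int(curve.grid["n_truncated"].sum()),
                    }
                )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if manifest["failures"]:
        raise RuntimeError(f"{len(manifest['failures'])} curve(s) failed; see manifest.json")
    return manifest
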