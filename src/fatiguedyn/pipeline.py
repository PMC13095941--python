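"""End-to-end analysis pipeline: trial table in, fits and comparison out.

Reads a long-format trial table, fits the requested model family to every
participant, runs the group-level comparison, and writes ``fits.csv``,
``comparison.json``, per-model predicted-trajectory CSVs and a run manifest
with a config hash, seeds and file checksums, so a run is fully auditable
and repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .comparison import compare_fits
from .data import read_trial_table
from .fitting import fit_cohort
from .models import EFFORT_MODEL_IDS, FATIGUE_MODEL_IDS

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    trial_table: str
    out_dir: str
    readout: str = "fatigue"
    models: Optional[list[str]] = None  # default: the family for the readout
    combination: str = "multiplicative"
    state_timing: str = "post"
    include_failed: bool = True
    n_starts_per_param: int = 6
    xatol: float = 1e-4
    fatol: float = 1e-4
    maxiter_factor: int = 200
    prior_alpha: float = 1.0
    bms_tol: float = 1e-6
    ep_samples: int = 1_000_000
    seed: int = 1

    def resolved_models(self) -> list[str]:
        if self.models:
            return list(self.models)
        if self.readout == "effort":
            suffix = "_add" if self.combination == "additive" else ""
            return [m + suffix for m in EFFORT_MODEL_IDS]
        return list(FATIGUE_MODEL_IDS)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.trial_table).exists():
            raise FileNotFoundError(f"trial table not found: {self.trial_table}")


@dataclass
class RunArtifacts:
    fits_csv: Path
    comparison_json: Path
    trajectory_csvs: list[Path]
    manifest_json: Path
    fits: pd.DataFrame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run fit + compare on a trial table and write all outputs."""
    config.validate()
    datasets = read_trial_table(config.trial_table)  # validate before any output
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_ids = config.resolved_models()
    logger.info("fitting %d models to %d participants", len(model_ids), len(datasets))

    fits_df, results = fit_cohort(
        datasets,
        model_ids,
        readout=config.readout,
        state_timing=config.state_timing,
        include_failed=config.include_failed,
        n_starts_per_param=config.n_starts_per_param,
        xatol=config.xatol,
        fatol=config.fatol,
        maxiter_factor=config.maxiter_factor,
    )
    fits_df = fits_df.sort_values(["participant", "model_id"]).reset_index(drop=True)
    fits_csv = out / "fits.csv"
    fits_df.to_csv(fits_csv, index=False)

    comparison = compare_fits(
        fits_df,
        prior_alpha=config.prior_alpha,
        tol=config.bms_tol,
        ep_samples=config.ep_samples,
        seed=config.seed,
    )
    comparison_json = out / "comparison.json"
    comparison_json.write_text(json.dumps(comparison.to_dict(), indent=2))

    traj_paths = []
    for mid in model_ids:
        rows = []
        for ds in datasets:
            fr = results[(ds.participant_id, mid)]
            frame = fr.trajectory.to_frame(observed=ds.ratings)
            frame.insert(0, "participant", ds.participant_id)
            rows.append(frame)
        path = out / f"trajectories_{mid}.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        traj_paths.append(path)

    manifest_json = out / "manifest.json"
    outputs = [fits_csv, comparison_json, *traj_paths]
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "models": model_ids,
        "n_participants": len(datasets),
        "n_fits": len(fits_df),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_json.write_text(json.dumps(manifest, indent=2))
    return RunArtifacts(
        fits_csv=fits_csv,
        comparison_json=comparison_json,
        trajectory_csvs=traj_paths,
        manifest_json=manifest_json,
        fits=fits_df,
    )
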