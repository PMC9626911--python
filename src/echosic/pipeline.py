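"""Pipeline orchestration: image scoring -> cohort -> cross-sectional ->
survival -> mediation, under a single reproducible configuration.

A run is controlled by a :class:`PipelineConfig` (YAML on disk).  One master
seed is fanned out to every stochastic stage through
``numpy.random.SeedSequence(master_seed).spawn(...)`` in a fixed stage
order, so a run is fully determined by its config.  Every output table is
written with a leading ``# config_hash: ...`` comment line and the
effective config is archived beside the outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_sectional import (
    CONTINUOUS_COLUMNS,
    association_table,
    cohort_summary,
    complete_cases,
    standardize_columns,
)
from .mediation import mediation_table
from .simulate import CohortSimConfig, ImageSimConfig, synth_cohort, synth_image_cohort_link
from .survival import (
    age_quartile_strata,
    cumulative_incidence_curves,
    model_ladder,
)
from .texture import score_manifest

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "save_config", "run_pipeline", "RunReport"]

_STAGES = ("simulate", "score", "cross_sectional", "survival", "mediation")


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "echosic_run"
    # inputs: either a cohort CSV (+ optional image manifest) or simulation
    cohort_csv: Optional[str] = None
    manifest_csv: Optional[str] = None
    simulate: bool = True
    simulate_images: bool = False
    n_subjects: int = 2511
    n_image_subjects: int = 100
    # stage toggles
    stages: tuple[str, ...] = _STAGES
    # model options
    strict: bool = False
    rcs_knots: int = 4
    bootstrap_reps: int = 0  # 0 => delta-method mediation SEs
    mediation_adjustment: str = "mutual"
    ph_time_transform: str = "identity"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so re-running the same analysis elsewhere yields identical files)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys
    (with a nearest-match suggestion)."""
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ValueError("config file must hold a mapping")
    payload.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in payload:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
    if "stages" in payload:
        payload["stages"] = tuple(payload["stages"])
        unknown = set(payload["stages"]) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
    return PipelineConfig(**payload)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


@dataclass
class RunReport:
    """Inventory of one pipeline run."""

    config: PipelineConfig
    outdir: Path
    outputs: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"echosic run in {self.outdir} (config {self.config.config_hash()})"]
        for stage, files in self.outputs.items():
            for f in files:
                lines.append(f"  [{stage}] {f}")
        return "\n".join(lines)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan the master seed out to the stochastic stages, in fixed order."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and write tidy result CSVs.

    Outputs (under ``config.outdir``): the cohort table, the clinical
    characteristics summary, risk-factor associations with HS-SIC, the Cox
    model ladder, cumulative-incidence curve data, the mediation table, a
    run log with seeds and versions, and the archived effective config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    report = RunReport(config=config, outdir=outdir, stage_seeds=seeds)

    def record(stage: str, name: str) -> Path:
        report.outputs.setdefault(stage, []).append(name)
        return outdir / name

    try:
        # ---- cohort acquisition ----------------------------------------
        if config.simulate and "simulate" in config.stages:
            sim_cfg = CohortSimConfig(n=config.n_subjects, seed=seeds["simulate"])
            cohort, truth = synth_cohort(sim_cfg)
            _write_table(cohort, record("simulate", "cohort.csv"), chash)
            (outdir / "sim_truth.json").write_text(truth.to_json())
            report.outputs["simulate"].append("sim_truth.json")
            if config.simulate_images:
                sub = cohort.head(config.n_image_subjects)
                manifest = synth_image_cohort_link(
                    sub, outdir / "images", template=ImageSimConfig(),
                    seed=seeds["simulate"],
                )
                manifest_path: Optional[Path] = outdir / "images" / "manifest.csv"
                report.outputs["simulate"].append("images/manifest.csv")
            else:
                manifest_path = None
        elif config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv, comment="#")
            manifest_path = Path(config.manifest_csv) if config.manifest_csv else None
        else:
            raise ValueError("config enables neither simulation nor a cohort_csv input")

        # ---- image scoring ---------------------------------------------
        if "score" in config.stages and manifest_path is not None:
            scores = score_manifest(manifest_path, strict=config.strict)
            _write_table(scores, record("score", "sic_scores.csv"), chash)

        # ---- cross-sectional -------------------------------------------
        analysis_cols = [c for c in CONTINUOUS_COLUMNS if c in cohort.columns]
        cohort_cc = complete_cases(cohort, analysis_cols + ["time", "event"])
        if "cross_sectional" in config.stages:
            summary = cohort_summary(cohort_cc)
            _write_table(summary, record("cross_sectional", "cohort_summary.csv"), chash)
            assoc = association_table(cohort_cc)
            _write_table(assoc, record("cross_sectional", "sic_associations.csv"), chash)

        # ---- survival ---------------------------------------------------
        std_cols = [c for c in ("hs_sic", "rwt", "bmi", "sbp", "tc_hdl_ratio")
                    if c in cohort_cc.columns]
        std, _params = standardize_columns(cohort_cc, std_cols)
        if "survival" in config.stages:
            std = age_quartile_strata(std)
            ladder = model_ladder(std)
            _write_table(ladder, record("survival", "cox_ladder.csv"), chash)
            curves = cumulative_incidence_curves(std)
            curve_rows = [
                frame.assign(group=label) for label, frame in curves.curves.items()
            ]
            _write_table(
                pd.concat(curve_rows, ignore_index=True),
                record("survival", "cumulative_incidence.csv"), chash,
            )

        # ---- mediation --------------------------------------------------
        if "mediation" in config.stages:
            med = mediation_table(
                cohort_cc,
                adjustment=config.mediation_adjustment,
                method="bootstrap" if config.bootstrap_reps else "delta",
                seed=seeds["mediation"],
            )
            _write_table(med, record("mediation", "mediation.csv"), chash)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    # ---- run log --------------------------------------------------------
    import lifelines
    import scipy
    import statsmodels

    log = {
        "config_hash": chash,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "versions": {
            "echosic": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    save_config(config, outdir / "config.yaml")
    report.outputs.setdefault("run", []).extend(["run_log.json", "config.yaml"])
    return report
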