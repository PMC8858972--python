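"""End-to-end orchestration: cohort -> ANOVA screen -> elimination -> evaluation.

Every run writes a self-contained run directory (cohort table, screening
TSV, selection trace JSON, per-comparison evaluation JSONs, summary TSV and
a run manifest embedding the configuration, seed, package version and a
config hash) so that a rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import CohortTable
from .evaluate import EvalConfig, evaluate_groupings
from .glycans import GlycanPanel
from .screen import filter_features, results_to_frame
from .select import EliminationConfig, RFConfig, iterative_elimination
from .simulate import SyntheticConfig, generate_cohort
from .spectra import DEFAULT_TOL_PPM, build_cohort_table, read_spot_json

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure carrying the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"              # synthetic | table | spectra
    cohort_table: str | None = None      # table mode: cohort TSV path
    spot_dir: str | None = None          # spectra mode: directory of spot JSONs
    panel_file: str | None = None        # spectra mode: panel TSV
    sample_meta: str | None = None       # spectra mode: sample_id/group/stage TSV
    tol_ppm: float = DEFAULT_TOL_PPM
    alpha: float = 0.05
    posthoc: str = "tukey"
    rf_trees: int = 500
    rf_importance: str = "impurity"
    delta: float = 2.0
    patience: int = 2
    min_features: int = 5
    stop_cv_reps: int = 5
    cv_reps: int = 200
    target_spec: float = 0.90
    include_stage_regrouping: bool = False
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "table", "spectra"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        paths = []
        if self.mode == "table":
            if not self.cohort_table:
                raise ValueError("table mode requires cohort_table")
            paths.append(self.cohort_table)
        if self.mode == "spectra":
            for name in ("spot_dir", "panel_file", "sample_meta"):
                if not getattr(self, name):
                    raise ValueError(f"spectra mode requires {name}")
            paths += [self.spot_dir, self.panel_file, self.sample_meta]
        for p in paths:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in doc:
            doc["synthetic"] = SyntheticConfig(**doc["synthetic"])
        return cls(**doc)


def _load_cohort(cfg: RunConfig) -> CohortTable:
    if cfg.mode == "synthetic":
        table, truth = generate_cohort(cfg.synthetic, seed=cfg.seed)
        return table
    if cfg.mode == "table":
        return CohortTable.from_tsv(cfg.cohort_table)
    # spectra mode: quantify one JSON spot file per (sample, channel)
    import pandas as pd

    panel = GlycanPanel.from_tsv(cfg.panel_file)
    meta = pd.read_csv(cfg.sample_meta, sep="\t", dtype={"stage": str}).set_index(
        "sample_id"
    )
    samples: dict[str, dict[str, list]] = {}
    for path in sorted(Path(cfg.spot_dir).glob("*.json")):
        pixels = read_spot_json(path)
        sample_id, _, _ = path.stem.partition("__")
        samples.setdefault(sample_id, {})[pixels[0].channel] = pixels
    return build_cohort_table(
        samples,
        panel,
        tol_ppm=cfg.tol_ppm,
        groups=meta["group"].to_dict(),
        stages=meta["stage"].to_dict(),
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns the run directory.  Stage failures raise `PipelineError` naming
    the stage, and a machine-readable error record is written.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
    }

    def fail(stage: str, exc: Exception) -> PipelineError:
        record = {"stage": stage, "error": str(exc)}
        (out / "error.json").write_text(json.dumps(record, indent=2, default=str))
        return PipelineError(stage, str(exc))

    try:
        cohort = _load_cohort(cfg)
        if cfg.mode == "synthetic":
            _, truth = generate_cohort(cfg.synthetic, seed=cfg.seed)
            truth.to_json(out / "truth.json")
        cohort.to_tsv(out / "cohort.tsv")
        logger.info(
            "cohort: %d samples, %d features", cohort.n_samples,
            len(cohort.feature_columns),
        )
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise fail("cohort", exc) from exc

    try:
        retained, results = filter_features(cohort, alpha=cfg.alpha, posthoc=cfg.posthoc)
        results_to_frame(results, alpha=cfg.alpha).to_csv(
            out / "anova_screen.tsv", sep="\t"
        )
        logger.info("ANOVA screen retained %d/%d features", len(retained),
                    len(cohort.feature_columns))
    except Exception as exc:
        raise fail("screen", exc) from exc

    rf = RFConfig(
        n_estimators=cfg.rf_trees, importance=cfg.rf_importance, seed=cfg.seed
    )
    try:
        elim_cfg = EliminationConfig(
            rf=rf,
            delta=cfg.delta,
            patience=cfg.patience,
            min_features=cfg.min_features,
            stop_cv_reps=cfg.stop_cv_reps,
            seed=cfg.seed,
        )
        trace = iterative_elimination(
            cohort.features[retained], cohort.groups.to_numpy(), elim_cfg
        )
        trace.to_json(out / "selection_trace.json")
        logger.info("retained panel (%d features): %s", len(trace.retained),
                    ", ".join(trace.retained))
    except Exception as exc:
        raise fail("selection", exc) from exc

    try:
        eval_cfg = EvalConfig(
            rf=rf,
            reps=cfg.cv_reps,
            target_spec=cfg.target_spec,
            include_stage_regrouping=cfg.include_stage_regrouping,
            seed=cfg.seed,
        )
        reports = evaluate_groupings(cohort, trace.retained, eval_cfg)
        summaries = []
        for rep in reports:
            rep.to_json(out / f"eval_{rep.comparison}.json")
            frame = rep.summary_frame()
            frame.insert(0, "comparison", rep.comparison)
            summaries.append(frame)
        import pandas as pd

        pd.concat(summaries).to_csv(out / "eval_summary.tsv", sep="\t")
    except Exception as exc:
        raise fail("evaluation", exc) from exc

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return out
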