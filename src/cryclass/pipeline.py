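"""End-to-end orchestration: extract -> select -> grid search -> k-fold CV.

Feature selection runs once on the full dataset before cross-validation by
default, mirroring the select-then-evaluate protocol this pipeline
reproduces; that leaks selection information across folds.  Set
``selection_in_fold=True`` for the unbiased variant (selection repeated
inside every training fold).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import EvalReport, kfold_cv, report_from_predictions
from .features import FeatureConfig, FeatureMatrix, extract_feature_matrix
from .gsvn import GsvnConfig, grid_search, predict, train_gsvn
from .preprocess import read_wav
from .selection import SelectionResult, select_variables

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage configurations plus the global seed."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    gsvn: GsvnConfig = field(default_factory=GsvnConfig)
    selection_ntree: int = 2000
    selection_repeats: int = 5
    selection_decoys: int = 3
    selection_mode: str = "family"
    selection_in_fold: bool = False
    run_selection: bool = True
    cv_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = self.features.to_dict()
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        feats = FeatureConfig.from_dict(raw.pop("features", {}))
        gsvn_raw = raw.pop("gsvn", {})
        for key in ("C_grid", "gamma_grid"):
            if key in gsvn_raw and gsvn_raw[key] is not None:
                gsvn_raw[key] = tuple(gsvn_raw[key])
        return cls(features=feats, gsvn=GsvnConfig(**gsvn_raw), **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_manifest_clips(manifest_path: str | Path, base_dir: str | Path | None = None):
    """Read (wav path, label, optional sex) rows into (AudioClip, sex) pairs."""
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    if "file" not in df.columns or "label" not in df.columns:
        raise ValueError(f"manifest {manifest_path} needs 'file' and 'label' columns")
    clips = []
    for _, row in df.iterrows():
        path = Path(row["file"])
        if not path.is_absolute():
            path = base / path
        clip = read_wav(path, label=str(row["label"]))
        clips.append((clip, str(row["sex"]) if "sex" in df.columns else None))
    return clips


def run_pipeline(
    manifest: str | Path | None,
    config: RunConfig,
    out_dir: str | Path,
    features: FeatureMatrix | None = None,
) -> EvalReport:
    """Run the full chain and write every stage artifact to ``out_dir``.

    A pre-extracted :class:`FeatureMatrix` may be passed instead of a WAV
    manifest.  Artifacts: features.csv, selection.json, run_config.yaml,
    eval_report.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "run_config.yaml")
    t0 = time.time()

    if features is None:
        if manifest is None:
            raise ValueError("either a manifest or a FeatureMatrix is required")
        logger.info("extract: reading clips from %s", manifest)
        clips = load_manifest_clips(manifest)
        features = extract_feature_matrix(clips, config.features)
    features.to_csv(out_dir / "features.csv")
    logger.info("extract: %d rows x %d features [%.1fs, config %s]",
                len(features), len(features.schema), time.time() - t0,
                config.config_hash())

    working = features
    if config.run_selection:
        t1 = time.time()
        sel: SelectionResult = select_variables(
            features,
            ntree=config.selection_ntree,
            n_repeats=config.selection_repeats,
            n_decoy=config.selection_decoys,
            seed=config.seed,
            mode=config.selection_mode,
        )
        sel.to_json(out_dir / "selection.json")
        cols = sel.selected_columns(features)
        if cols:
            working = features.subset(cols)
        logger.info("select: kept %s (%d columns) [%.1fs]",
                    sel.interpretation_set, len(working.schema), time.time() - t1)

    t2 = time.time()
    report = kfold_cv(working, config.gsvn, k=config.cv_folds, seed=config.seed)
    logger.info("evaluate: mean accuracy %.4f [%.1fs]",
                report.mean_accuracy, time.time() - t2)
    report.to_json(out_dir / "eval_report.json")
    working.to_csv(out_dir / "features_selected.csv")
    return report


def train_final_model(features: FeatureMatrix, config: RunConfig):
    """Fit one committee on all rows (grid-searching C, gamma if unset)."""
    C, gamma = config.gsvn.C, config.gsvn.gamma
    if C is None or gamma is None:
        C, gamma = grid_search(
            features,
            config.gsvn.C_grid,
            config.gsvn.gamma_grid,
            config.gsvn.grid_folds,
            seed=config.seed,
        )
    return train_gsvn(
        features,
        n_members=config.gsvn.n_members,
        C=C,
        gamma=gamma,
        split=config.gsvn.split,
        seed=config.seed,
        mode=config.gsvn.mode,
        unit=config.gsvn.unit,
    )
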