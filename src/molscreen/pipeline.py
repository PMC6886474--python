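"""End-to-end workflow: thresholds x selectors x classifiers.

For every activity threshold the pipeline binarizes labels, applies the
two-stage filter, splits train/test, runs each requested subset selector
on the training portion (plus a "none" control using all filtered
columns), tunes each requested classifier by cross-validated AUC, and
records test-set and cross-validation reports for every grid cell.  A
manifest written alongside the artifacts captures the full configuration
so the run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from . import __version__
from ._errors import ConfigurationError, StageError
from .cfs import (
    BFConfig,
    FeatureSubset,
    GPSOConfig,
    GSConfig,
    MeritScore,
    SSFSConfig,
    best_first_search,
    genetic_search,
    gpso_search,
    ssfs_search,
)
from .classify import (
    FAST_GRID,
    ModelSpec,
    SplitConfig,
    TrainedModel,
    ValidationReport,
    cross_validate,
    evaluate_test,
    optimize_hyperparameters,
    split_train_test,
    train,
)
from .io import read_feature_table, write_feature_table
from .preprocess import (
    ActivityThreshold,
    CorrelationFilterConfig,
    apply_filters,
    binarize_activity,
    canonical_thresholds,
)
from .screening import ConsensusConfig, screen_library
from .synthetic import SyntheticSpec, generate_training_dataset
from .table import ACTIVE, FeatureTable

SELECTORS = ("BF", "GS", "PSO", "SSFS", "none")


@dataclass
class PipelineConfig:
    output_dir: Union[str, Path] = "molscreen_out"
    input_table: Optional[Union[str, Path]] = None
    screening_library: Optional[Union[str, Path]] = None
    synthetic: Optional[SyntheticSpec] = None
    thresholds: List[ActivityThreshold] = field(default_factory=canonical_thresholds)
    selectors: List[str] = field(default_factory=lambda: list(SELECTORS))
    classifiers: List[str] = field(default_factory=lambda: ["DT", "RF", "NB"])
    filter: CorrelationFilterConfig = field(default_factory=CorrelationFilterConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    grid: Dict[str, tuple] = field(default_factory=lambda: dict(FAST_GRID))
    seed: int = 0

    def __post_init__(self):
        if not self.thresholds:
            raise ConfigurationError("at least one activity threshold is required")
        if not self.selectors:
            raise ConfigurationError("at least one selector (or 'none') is required")
        if not self.classifiers:
            raise ConfigurationError("at least one classifier is required")
        bad = set(self.selectors) - set(SELECTORS)
        if bad:
            raise ConfigurationError(f"unknown selector(s): {sorted(bad)}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "thresholds":
                out[f.name] = [dataclasses.asdict(t) for t in v]
            elif f.name == "grid":
                out[f.name] = {k: list(vv) for k, vv in v.items()}
            else:
                out[f.name] = enc(v)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            if isinstance(syn.get("ic50_range_um"), list):
                syn["ic50_range_um"] = tuple(syn["ic50_range_um"])
            d["synthetic"] = SyntheticSpec(**syn)
        if d.get("thresholds"):
            d["thresholds"] = [ActivityThreshold(**t) for t in d["thresholds"]]
        if d.get("filter"):
            d["filter"] = CorrelationFilterConfig(**d["filter"])
        if d.get("split"):
            d["split"] = SplitConfig(**d["split"])
        if d.get("consensus"):
            d["consensus"] = ConsensusConfig(**d["consensus"])
        if d.get("grid"):
            d["grid"] = {k: tuple(v) for k, v in d["grid"].items()}
        return cls(**d)


@dataclass
class GridEntry:
    threshold: ActivityThreshold
    selector: str
    classifier: str
    subset: Optional[FeatureSubset]
    spec: ModelSpec
    model: TrainedModel
    test_report: ValidationReport
    cv_report: ValidationReport


@dataclass
class RunManifest:
    config: dict
    version: str
    started: float
    finished: float
    stage_digests: Dict[str, str]
    artifacts: List[str]

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    manifest: RunManifest
    entries: List[GridEntry]
    grid_frame: pd.DataFrame
    screening_summary: Optional[object] = None


# ----------------------------------------------------------------------
def _run_selector(selector, table, seed, name):
    if selector == "BF":
        return best_first_search(table, BFConfig(), name)
    if selector == "GS":
        return genetic_search(table, GSConfig(seed=seed), name)
    if selector == "PSO":
        return gpso_search(table, GPSOConfig(seed=seed), name)
    if selector == "SSFS":
        return ssfs_search(table, SSFSConfig(seed=seed), name)
    return None  # "none" control: all filtered columns


def subset_to_frame(subset: FeatureSubset) -> pd.DataFrame:
    s = subset.score
    return pd.DataFrame(
        {
            "selector": [subset.selector],
            "dataset": [subset.dataset_name],
            "k": [s.k],
            "merit": [s.merit],
            "mean_class_corr": [s.mean_class_corr],
            "mean_inter_corr": [s.mean_inter_corr],
            "columns": [";".join(map(str, subset.columns))],
        }
    )


def run_pipeline(
    config: PipelineConfig, table: Optional[FeatureTable] = None
) -> PipelineResult:
    """Execute the full grid; returns entries, the grid frame, and manifest."""
    started = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []
    digests: Dict[str, str] = {}

    try:
        if table is None:
            if config.input_table is not None:
                table = read_feature_table(config.input_table, name="input")
            elif config.synthetic is not None:
                table = generate_training_dataset(config.synthetic).table
            else:
                raise ConfigurationError(
                    "provide an input table, a path, or a synthetic spec"
                )
    except ConfigurationError:
        raise
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    digests["input"] = table.digest()

    entries: List[GridEntry] = []
    rows = []
    subset_frames = []
    for threshold in config.thresholds:
        stage = f"threshold:{threshold.name}"
        try:
            labeled = binarize_activity(table, threshold)
            filtered, filter_report = apply_filters(labeled, config.filter)
            report_path = out_dir / f"filter_report_{threshold.name}.csv"
            filter_report.to_frame().to_csv(report_path, index=False)
            artifacts.append(str(report_path))
            train_tbl, test_tbl = split_train_test(filtered, config.split)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

        for selector in config.selectors:
            try:
                subset = _run_selector(
                    selector, train_tbl, config.seed, threshold.name
                )
            except Exception as exc:
                raise StageError(f"{stage}/select:{selector}", str(exc)) from exc
            if subset is not None:
                subset_frames.append(subset_to_frame(subset))
            feature_subset = subset if subset is not None else "all"
            for classifier in config.classifiers:
                cell = f"{stage}/{selector}/{classifier}"
                try:
                    spec = optimize_hyperparameters(
                        train_tbl,
                        classifier,
                        grid=config.grid,
                        config=config.split,
                        feature_subset=feature_subset,
                    )
                    model = train(train_tbl, spec, seed=config.seed)
                    model.name = f"{threshold.name}_{selector}_{classifier}"
                    test_report = evaluate_test(model, test_tbl)
                    cv_report = cross_validate(train_tbl, spec, config.split)
                except Exception as exc:
                    raise StageError(cell, str(exc)) from exc
                entries.append(
                    GridEntry(
                        threshold=threshold,
                        selector=selector,
                        classifier=classifier,
                        subset=subset,
                        spec=spec,
                        model=model,
                        test_report=test_report,
                        cv_report=cv_report,
                    )
                )
                rows.append(
                    {
                        "threshold": threshold.name,
                        "cutoff_um": threshold.cutoff_um,
                        "selector": selector,
                        "classifier": classifier,
                        "n_features": len(model.columns),
                        "max_depth": spec.max_depth,
                        "num_trees": spec.num_trees,
                        "cv_auc": cv_report.auc,
                        "cv_mcc": cv_report.mcc,
                        "test_auc": test_report.auc,
                        "test_mcc": test_report.mcc,
                    }
                )

    grid_frame = pd.DataFrame(rows)
    grid_path = out_dir / "validation_grid.csv"
    grid_frame.to_csv(grid_path, index=False)
    artifacts.append(str(grid_path))
    if subset_frames:
        subsets_path = out_dir / "feature_subsets.csv"
        pd.concat(subset_frames, ignore_index=True).to_csv(subsets_path, index=False)
        artifacts.append(str(subsets_path))

    screening_summary = None
    if config.screening_library is not None:
        try:
            top = select_top_models(entries)
            actives = _training_actives(table)
            from .io import iter_feature_table_chunks

            chunks = iter_feature_table_chunks(
                config.screening_library, config.consensus.chunk_size
            )
            results, screening_summary = screen_library(
                chunks, [e.model for e in top], actives, config.consensus
            )
            hits_path = out_dir / "screening_results.csv"
            results.to_csv(hits_path, index_label="__id")
            artifacts.append(str(hits_path))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("screen", str(exc)) from exc

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        started=started,
        finished=time.time(),
        stage_digests=digests,
        artifacts=artifacts,
    )
    manifest.write(out_dir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        entries=entries,
        grid_frame=grid_frame,
        screening_summary=screening_summary,
    )


def rerun_from_manifest(
    manifest_path: Union[str, Path], output_dir: Union[str, Path]
) -> PipelineResult:
    """Re-execute a previous run from its manifest into a new directory."""
    manifest = RunManifest.read(manifest_path)
    config = PipelineConfig.from_dict(manifest.config)
    config.output_dir = output_dir
    return run_pipeline(config)


def _training_actives(table: FeatureTable) -> FeatureTable:
    if table.labels is not None:
        mask = table.labels == ACTIVE
    elif table.ic50 is not None:
        mask = table.ic50.notna()
    else:
        raise ConfigurationError("cannot identify training actives: no labels/IC50")
    return table.select_rows(table.data.index[mask])


# ----------------------------------------------------------------------
def select_top_models(
    entries: List[GridEntry],
    rule: Optional[dict] = None,
) -> List[GridEntry]:
    """Pick the screening panel from a completed validation grid.

    Default rule (the study's recipe): keep the RF classifier with BF and
    SSFS selectors and drop the 1 uM threshold, yielding 4 thresholds x 2
    selectors = 8 models.  Alternative: ``{"top_n": N}`` ranks by test AUC,
    then MCC, then the cheaper spec.
    """
    if not entries:
        raise ConfigurationError("empty validation grid")
    if rule and "top_n" in rule:
        ranked = sorted(
            entries,
            key=lambda e: (
                -e.test_report.auc,
                -e.test_report.mcc,
                e.spec.num_trees or 0,
                e.spec.max_depth or 0,
            ),
        )
        picked = ranked[: rule["top_n"]]
    else:
        picked = [
            e
            for e in entries
            if e.classifier == "RF"
            and e.selector in ("BF", "SSFS")
            and e.threshold.cutoff_um != 1.0
        ]
    if not picked:
        raise ConfigurationError("selection rule matched zero models")
    return picked
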