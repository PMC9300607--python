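"""End-to-end study driver.

Reproduces the study design on simulated or supplied data:

1. obtain a cohort (node axis table + per-patient imaging reads);
2. score every node (2D ratio, sphericity);
3. select the training nodes — all nodes of *concordant* patients,
   i.e. patients whose nodes are all metastatic or all non-metastatic
   (only their node-level labels are unambiguous without node-by-node
   pathology mapping);
4. fit the four node-level methods on the training nodes;
5. predict every node, lift calls to patients (any-positive rule),
   build the combined methods with ultrasound/CT;
6. evaluate: node-level resubstitution metrics and ROC/AUC on the
   training nodes, patient-level correct classification rates on the
   whole cohort and on the post-NAC subgroup, and four-fold chi-square
   method comparisons;
7. write a reproducible report bundle (CSV/JSON) stamped with a run id
   derived from config and seed; identical config + seed gives an
   identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from nodesphere import io as nio
from nodesphere.classifiers import (
    ForestParams,
    Model,
    TreeParams,
    fit_forest,
    fit_threshold,
    fit_tree,
    predict_nodes,
)
from nodesphere.cohort_logic import CombinedRule, aggregate_patients, combine_frames
from nodesphere.evaluation import chi2_fourfold, evaluate_method, roc_auc
from nodesphere.morphometry import score_nodes
from nodesphere.simulate import (
    CohortConfig,
    cohort_to_imaging_frame,
    cohort_to_node_frame,
    generate_cohort,
)

logger = logging.getLogger(__name__)

MODEL_METHODS = ("ratio_2d", "sphericity", "tree", "forest")


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyDesign:
    """Which methods run and how they are combined and compared."""

    methods: tuple[str, ...] = MODEL_METHODS
    combined: tuple[tuple[str, str], ...] = (
        ("sphericity", "ultrasound"),
        ("sphericity", "CT"),
    )
    combine_mode: str = "OR"
    compare_pairs: tuple[tuple[str, str], ...] = (
        ("sphericity", "ratio_2d"),
        ("tree", "ratio_2d"),
        ("forest", "ratio_2d"),
    )


@dataclass
class PipelineConfig:
    """One study run: either a simulation block or input file paths."""

    simulate: Optional[CohortConfig] = field(default_factory=CohortConfig)
    nodes_path: Optional[str] = None
    imaging_path: Optional[str] = None
    design: StudyDesign = field(default_factory=StudyDesign)
    tree_params: TreeParams = field(default_factory=TreeParams)
    forest_params: ForestParams = field(default_factory=ForestParams)
    seed: Optional[int] = None  # overrides simulate.seed and forest seed

    def resolved_seed(self) -> int:
        if self.seed is not None:
            return int(self.seed)
        if self.simulate is not None:
            return int(self.simulate.seed)
        return 0


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run, plus where they were written."""

    run_id: str
    run_dir: Optional[Path]
    nodes: pd.DataFrame
    training_nodes: pd.DataFrame
    node_calls: pd.DataFrame
    patient_calls: pd.DataFrame
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    models: dict[str, Model]
    manifest: dict


def select_training_nodes(nodes: pd.DataFrame) -> pd.DataFrame:
    """Nodes of patients whose node labels are all 0 or all 1."""
    if "node_label" not in nodes.columns:
        raise PipelineError("training selection requires node_label")
    labelled = nodes.dropna(subset=["node_label"])
    per_patient = labelled.groupby("patient_id")["node_label"].agg(["min", "max"])
    concordant = per_patient.index[per_patient["min"] == per_patient["max"]]
    training = labelled[labelled["patient_id"].isin(concordant)].copy()
    logger.info(
        "training selector: %d/%d patients concordant, %d nodes "
        "(%d metastatic)",
        len(concordant), per_patient.shape[0], len(training),
        int(training["node_label"].sum()),
    )
    return training


def _patient_truth(nodes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient truth (any metastatic node) and NAC flag."""
    g = nodes.groupby("patient_id")
    if "patient_label" in nodes.columns and nodes["patient_label"].notna().all():
        truth = g["patient_label"].first()
    else:
        truth = g["node_label"].max()
    nac = g["nac"].first() if "nac" in nodes.columns else pd.Series(0, truth.index)
    return pd.DataFrame(
        {
            "patient_id": truth.index,
            "truth": truth.to_numpy(dtype=int),
            "nac": pd.Series(nac).fillna(0).to_numpy(dtype=int),
        }
    ).reset_index(drop=True)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _run_id(config: PipelineConfig) -> str:
    canon = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def fit_models(
    training: pd.DataFrame,
    methods: tuple[str, ...],
    tree_params: TreeParams,
    forest_params: ForestParams,
) -> dict[str, Model]:
    """Fit the requested node-level classifiers on scored training nodes."""
    y = training["node_label"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise PipelineError(
            "training selector yielded a single-class node set; "
            "cannot fit classifiers"
        )
    X = training[["a_mm", "b_mm", "c_mm"]].to_numpy(dtype=float)
    models: dict[str, Model] = {}
    for method in methods:
        if method in ("ratio_2d", "sphericity"):
            models[method] = fit_threshold(
                training[method].to_numpy(dtype=float), y, score_name=method
            )
        elif method == "tree":
            models[method] = fit_tree(X, y, tree_params)
        elif method == "forest":
            models[method] = fit_forest(X, y, forest_params)
        else:
            raise PipelineError(f"unknown method {method!r}")
    return models


def run_pipeline(
    config: PipelineConfig,
    outdir: Optional[Union[str, Path]] = None,
    overwrite: bool = False,
) -> ReportBundle:
    """Execute the full study; optionally write the report bundle."""
    run_id = _run_id(config)
    seed = config.resolved_seed()

    # -- inputs -------------------------------------------------------
    if config.nodes_path is not None:
        nodes = nio.read_nodes(config.nodes_path)
        imaging = (
            nio.read_imaging(config.imaging_path)
            if config.imaging_path is not None
            else pd.DataFrame(columns=list(nio.IMAGING_COLUMNS))
        )
    elif config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = CohortConfig(**{**asdict(sim), "seed": int(config.seed)})
            sim.class_params = config.simulate.class_params
            sim.imaging_specs = config.simulate.imaging_specs
        cohort = generate_cohort(sim)
        nodes = cohort_to_node_frame(cohort)
        imaging = cohort_to_imaging_frame(cohort)
    else:
        raise PipelineError("config must give either input paths or a simulate block")

    nodes = score_nodes(nodes)
    patients = _patient_truth(nodes)

    # -- training and models ------------------------------------------
    training = select_training_nodes(nodes)
    forest_params = config.forest_params
    if config.seed is not None:
        forest_params = ForestParams(**{**asdict(forest_params), "seed": seed})
    models = fit_models(
        training, config.design.methods, config.tree_params, forest_params
    )

    # -- node-level calls ---------------------------------------------
    X_all = nodes[["a_mm", "b_mm", "c_mm"]].to_numpy(dtype=float)
    call_frames = []
    for method, model in models.items():
        call_frames.append(
            pd.DataFrame(
                {
                    "patient_id": nodes["patient_id"],
                    "node_id": nodes["node_id"],
                    "method": method,
                    "call": predict_nodes(model, X_all),
                }
            )
        )
    node_calls = pd.concat(call_frames, ignore_index=True)

    # -- patient-level calls ------------------------------------------
    patient_calls = aggregate_patients(node_calls)
    if not imaging.empty:
        patient_calls = pd.concat(
            [patient_calls, imaging[["patient_id", "method", "call"]]],
            ignore_index=True,
        )
    for model_method, imaging_method in config.design.combined:
        have = set(patient_calls["method"])
        if model_method not in have or imaging_method not in have:
            logger.warning(
                "skipping combined method %s+%s: constituent calls missing",
                model_method, imaging_method,
            )
            continue
        rule = CombinedRule(
            mode=config.design.combine_mode,
            methods=(model_method, imaging_method),
        )
        combined = combine_frames(patient_calls, rule)
        patient_calls = pd.concat(
            [patient_calls, combined.drop(columns=["mode"])], ignore_index=True
        )
    patient_calls = patient_calls.merge(patients, on="patient_id", how="left")

    # -- metrics ------------------------------------------------------
    metric_rows = []
    y_train = training["node_label"].to_numpy(dtype=int)
    for method, model in models.items():
        X_train = training[["a_mm", "b_mm", "c_mm"]].to_numpy(dtype=float)
        calls_train = predict_nodes(model, X_train)
        m, counts = evaluate_method(
            pd.DataFrame({"call": calls_train, "truth": y_train}), unit="node"
        )
        row = {
            "method": method,
            "unit": "node",
            "cohort": "training",
            "n": counts.total,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "accuracy": m.accuracy,
            "youden_j": m.youden_j,
            "auc": None,
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        }
        if method in ("ratio_2d", "sphericity"):
            row["auc"] = roc_auc(
                training[method].to_numpy(dtype=float), y_train
            ).auc
        metric_rows.append(row)

    for method in sorted(patient_calls["method"].unique()):
        sub = patient_calls[patient_calls["method"] == method]
        for cohort, subgroup in (("validation", None), ("nac", "nac")):
            try:
                m, counts = evaluate_method(sub, unit="patient", subgroup=subgroup)
            except ValueError:
                continue
            metric_rows.append(
                {
                    "method": method,
                    "unit": "patient",
                    "cohort": cohort,
                    "n": counts.total,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                    "youden_j": m.youden_j,
                    "auc": None,
                    "tp": counts.tp, "fp": counts.fp,
                    "tn": counts.tn, "fn": counts.fn,
                }
            )
    metrics = pd.DataFrame(metric_rows)

    # -- comparisons (four-fold chi-square, validation patients) ------
    comparison_rows = []
    val = metrics[(metrics["unit"] == "patient") & (metrics["cohort"] == "validation")]
    by_method = {r["method"]: r for _, r in val.iterrows()}
    for method_a, method_b in config.design.compare_pairs:
        if method_a not in by_method or method_b not in by_method:
            logger.warning(
                "skipping comparison %s vs %s: metrics missing", method_a, method_b
            )
            continue
        ra, rb = by_method[method_a], by_method[method_b]
        correct_a = int(ra["tp"] + ra["tn"])
        wrong_a = int(ra["fp"] + ra["fn"])
        correct_b = int(rb["tp"] + rb["tn"])
        wrong_b = int(rb["fp"] + rb["fn"])
        try:
            stat, p = chi2_fourfold(correct_a, wrong_a, correct_b, wrong_b)
        except ValueError as exc:
            logger.warning("comparison %s vs %s undefined: %s",
                           method_a, method_b, exc)
            continue
        comparison_rows.append(
            {
                "method_a": method_a, "method_b": method_b,
                "correct_a": correct_a, "wrong_a": wrong_a,
                "correct_b": correct_b, "wrong_b": wrong_b,
                "chi2": stat, "p": round(p, 3),
            }
        )
    comparisons = pd.DataFrame(comparison_rows)

    # -- manifest and outputs -----------------------------------------
    manifest = {
        "run_id": run_id,
        "seed": seed,
        "config": _config_dict(config),
        "versions": _versions(),
        "counts": {
            "patients": int(patients.shape[0]),
            "nodes": int(nodes.shape[0]),
            "training_patients": int(training["patient_id"].nunique()),
            "training_nodes": int(training.shape[0]),
            "training_metastatic_nodes": int(training["node_label"].sum()),
        },
    }

    run_dir: Optional[Path] = None
    if outdir is not None:
        run_dir = Path(outdir) / f"run-{run_id}"
        if run_dir.exists() and not overwrite:
            raise PipelineError(
                f"{run_dir} already exists; refusing to overwrite "
                "(pass overwrite=True / --force)"
            )
        run_dir.mkdir(parents=True, exist_ok=True)
        nio.write_nodes(nodes, run_dir / "scored_nodes.csv", run_id)
        if not imaging.empty:
            nio.write_imaging(imaging, run_dir / "imaging.csv", run_id)
        nio.write_calls(node_calls, run_dir / "node_calls.csv", run_id)
        nio.write_calls(patient_calls, run_dir / "patient_calls.csv", run_id)
        nio.write_calls(metrics, run_dir / "metrics.csv", run_id)
        nio.write_calls(comparisons, run_dir / "comparisons.csv", run_id)
        for method, model in models.items():
            nio.save_model(model, run_dir / "models" / f"{method}.json")
        manifest["files"] = sorted(
            str(p.relative_to(run_dir)) for p in run_dir.rglob("*") if p.is_file()
        )
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        run_id=run_id,
        run_dir=run_dir,
        nodes=nodes,
        training_nodes=training,
        node_calls=node_calls,
        patient_calls=patient_calls,
        metrics=metrics,
        comparisons=comparisons,
        models=models,
        manifest=manifest,
    )


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn

    import nodesphere

    return {
        "nodesphere": nodesphere.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
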