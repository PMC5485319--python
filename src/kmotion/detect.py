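"""Artefact detection with decision forests under nested cross-validation.

The evaluation protocol mirrors careful practice for subject-level
image quality classification:

* exactly one image per subject enters the dataset (either the clean or
  the corrupted reconstruction, chosen at random under an exact 50/50
  class balance), so the forest cannot memorize a subject's anatomy;
* outer cross-validation folds are stratified by label and disjoint by
  subject and estimate generalization accuracy; inner folds on each
  outer-training split select forest hyperparameters by grid search,
  preventing selection bias;
* every random consumer (fold shuffling, forest, pairing) receives an
  independent child seed derived from one master seed.

``run_experiment`` sweeps a grid of motion conditions (exchange
fraction x offset for bulk motion, or breathing cycle counts for
respiratory motion) over a cohort of synthetic subjects, reusing each
subject's per-state k-spaces across grid cells, and reports one
accuracy per cell.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from . import kspace as ks
from . import motion as mo
from . import phantoms as ph

__all__ = [
    "ForestConfig",
    "EvalResult",
    "ExperimentConfig",
    "build_paired_dataset",
    "nested_cv_accuracy",
    "run_experiment",
]


@dataclass(frozen=True)
class ForestConfig:
    """Decision-forest size and hyperparameter search grid."""

    n_trees: int = 100
    max_depth_grid: tuple = (None, 8, 16)
    min_leaf_grid: tuple = (1, 5)

    def __post_init__(self) -> None:
        if self.n_trees < 1 or not self.max_depth_grid or not self.min_leaf_grid:
            raise ValueError("forest config needs n_trees >= 1 and non-empty grids")

    def grid(self) -> list[tuple]:
        return [(d, l) for d in self.max_depth_grid for l in self.min_leaf_grid]


@dataclass(frozen=True)
class EvalResult:
    """Outcome of one nested cross-validation run."""

    overall_accuracy: float
    per_fold_accuracies: tuple[float, ...]
    confusion: dict  # TP, TN, FP, FN over pooled outer-test predictions
    chosen_params: tuple[tuple, ...]  # per outer fold (max_depth, min_leaf)
    seed: int

    def __post_init__(self) -> None:
        c = self.confusion
        total = c["TP"] + c["TN"] + c["FP"] + c["FN"]
        acc = (c["TP"] + c["TN"]) / total
        if abs(acc - self.overall_accuracy) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion counts")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Documented splitting rule: children are the first word of each
    spawned SeedSequence, reduced below 2**31."""
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def build_paired_dataset(pairs, seed: int):
    """Pick one image per subject with exact class balance.

    ``pairs`` is a list of ``(clean, corrupted, subject_id)``.  A random
    permutation assigns floor(n/2) subjects the corrupted image
    (label 1) and the rest the clean image (label 0).
    """
    subject_ids = [p[2] for p in pairs]
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject ids must be unique")
    n = len(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.zeros(n, dtype=np.int64)
    labels[order[: n // 2]] = 1
    images = [pairs[i][1] if labels[i] else pairs[i][0] for i in range(n)]
    return images, labels, np.asarray(subject_ids)


def nested_cv_accuracy(
    matrix: feat.FeatureMatrix,
    outer_k: int = 5,
    inner_k: int = 3,
    config: ForestConfig = ForestConfig(),
    seed: int = 0,
) -> EvalResult:
    """Accuracy of a decision forest under nested cross-validation.

    Outer folds are stratified by label and, since each subject
    contributes exactly one row, automatically subject-disjoint.  Within
    each outer-training split an inner stratified k-fold grid search
    picks the hyperparameter pair with the highest mean accuracy (ties
    resolved in declared grid order); a forest with that pair is refit
    on the full outer-training split and scored on the held-out fold.
    The overall accuracy pools all outer-test predictions.
    """
    if outer_k < 2 or inner_k < 2:
        raise ValueError("outer_k and inner_k must be >= 2")
    X, y = matrix.values, matrix.labels
    if min(np.bincount(y, minlength=2)) < outer_k:
        raise ValueError("need at least outer_k subjects per class")
    s_outer, s_inner, s_forest = _child_seeds(seed, 3)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=s_outer)
    grid = config.grid()

    tp = tn = fp = fn = 0
    per_fold, chosen = [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        assert not set(matrix.subject_ids[tr]) & set(matrix.subject_ids[te])
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=s_inner + fold)
        inner_splits = list(inner.split(X[tr], y[tr]))
        means = []
        for depth, leaf in grid:
            accs = []
            for itr, ite in inner_splits:
                clf = RandomForestClassifier(
                    n_estimators=config.n_trees,
                    max_depth=depth,
                    min_samples_leaf=leaf,
                    random_state=s_forest,
                    n_jobs=1,
                )
                clf.fit(X[tr][itr], y[tr][itr])
                accs.append(clf.score(X[tr][ite], y[tr][ite]))
            means.append(np.mean(accs))
        best = grid[int(np.argmax(means))]  # argmax keeps the first maximum
        chosen.append(best)
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=best[0],
            min_samples_leaf=best[1],
            random_state=s_forest,
            n_jobs=1,
        )
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        per_fold.append(float(np.mean(pred == y[te])))
        tp += int(np.sum((pred == 1) & (y[te] == 1)))
        tn += int(np.sum((pred == 0) & (y[te] == 0)))
        fp += int(np.sum((pred == 1) & (y[te] == 0)))
        fn += int(np.sum((pred == 0) & (y[te] == 1)))

    total = tp + tn + fp + fn
    return EvalResult(
        overall_accuracy=(tp + tn) / total,
        per_fold_accuracies=tuple(per_fold),
        confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        chosen_params=tuple(chosen),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# experiment driver


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one detection experiment grid.

    ``motion_type`` is ``"bulk"`` (grid = fractions x offsets) or
    ``"respiratory"`` (grid = cycle counts).  ``feature_counts`` follows
    the features module (e.g. ``{"box": 200}`` to use box features
    only).
    """

    phantom: str = "brain"  # "brain" | "cardiac"
    n_subjects: int = 60
    shape: tuple[int, int, int] = (256, 256, 32)
    geometry: str = "cartesian"  # cartesian | radial | spiral
    trajectory_params: dict = field(default_factory=dict)
    motion_type: str = "bulk"
    fractions: tuple[float, ...] = (0.2,)
    offsets: tuple[float, ...] = (0.2,)
    cycles: tuple[float, ...] = (4.0,)
    max_displacement_mm: float = 7.0
    n_resp_states: int = 8
    max_translation_mm: float = mo.MAX_TRANSLATION_MM
    max_rotation_deg: float = mo.MAX_ROTATION_DEG
    feature_counts: dict | None = None
    outer_k: int = 5
    inner_k: int = 3
    forest: ForestConfig = ForestConfig()
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown experiment config fields: {sorted(unknown)}")
        if "forest" in d and isinstance(d["forest"], dict):
            fo = dict(d["forest"])
            for key in ("max_depth_grid", "min_leaf_grid"):
                if key in fo:
                    fo[key] = tuple(fo[key])
            d["forest"] = ForestConfig(**fo)
        for key in ("shape", "fractions", "offsets", "cycles"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if cfg.phantom not in ("brain", "cardiac"):
            raise ValueError(f"config field 'phantom': unknown value {cfg.phantom!r}")
        if cfg.geometry not in ("cartesian", "radial", "spiral"):
            raise ValueError(f"config field 'geometry': unknown value {cfg.geometry!r}")
        if cfg.motion_type not in ("bulk", "respiratory"):
            raise ValueError(f"config field 'motion_type': unknown value {cfg.motion_type!r}")
        return cfg


def _make_trajectory(cfg: ExperimentConfig) -> ks.Trajectory:
    N = cfg.shape[0]
    p = dict(cfg.trajectory_params)
    if cfg.geometry == "cartesian":
        return ks.make_cartesian_trajectory(p.get("n_lines", N), p.get("n_samples", N))
    if cfg.geometry == "radial":
        return ks.make_radial_trajectory(
            p.get("n_spokes", N), p.get("n_samples", 2 * N), grid_size=N
        )
    return ks.make_spiral_trajectory(
        p.get("n_interleaves", 16), p.get("n_samples", 2048), p.get("n_turns", 8.0), grid_size=N
    )


def _cell_grid(cfg: ExperimentConfig) -> list[dict]:
    if cfg.motion_type == "bulk":
        return [{"fraction": f, "offset": o} for f in cfg.fractions for o in cfg.offsets]
    return [{"cycles": c} for c in cfg.cycles]


def run_experiment(cfg: ExperimentConfig, out_dir=None, log=print) -> pd.DataFrame:
    """Run a full detection experiment grid.

    For each subject a phantom is generated and the k-space of every
    motion state is computed once; each grid cell then only re-merges
    readouts, reconstructs, extracts features with the experiment's one
    frozen spec set and runs nested CV.  Returns a table with one row
    per grid cell (grid axes, accuracy, per-fold details).  With
    ``out_dir`` set, results are written incrementally and finished
    cells of a partially complete grid are skipped on rerun.
    """
    t_start = time.time()
    seeds = _child_seeds(cfg.seed, 5)
    seed_phantom, seed_motion, seed_pairing, seed_specs, seed_cv = seeds
    traj = _make_trajectory(cfg)
    n = traj.n_readouts
    N = cfg.shape[0]
    if cfg.shape[1] != N:
        raise ValueError("experiment phantoms must have square axial slices")

    out_path = Path(out_dir) if out_dir is not None else None
    status: dict[str, dict] = {}
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        status_file = out_path / "cells.json"
        if status_file.exists():
            status = json.loads(status_file.read_text())

    # per-subject k-space states, computed once and reused by every cell
    k_states: list[list[ks.KSpaceData]] = []
    masks = []
    resp_levels = None
    for s in range(cfg.n_subjects):
        pseed = seed_phantom + s
        if cfg.phantom == "brain":
            vol = ph.make_brain_phantom(pseed, cfg.shape)
            mask = None
        else:
            vol, mask = ph.make_cardiac_phantom(pseed, cfg.shape)
            masks.append(mask)
        k_clean = ks.forward_transform(ph.central_slice(vol), traj)
        if cfg.motion_type == "bulk":
            tf = mo.sample_bulk_transform(
                seed_motion + s, cfg.max_translation_mm, cfg.max_rotation_deg
            )
            moved = mo.rigid_transform_volume(vol, tf)
            k_states.append([k_clean, ks.forward_transform(ph.central_slice(moved), traj)])
        else:
            model = mo.RespiratoryModel(1.0, cfg.max_displacement_mm, cfg.n_resp_states)
            _, resp_levels = mo.respiratory_schedule(n, model)
            states = [k_clean]
            for d in resp_levels[1:]:
                moved = mo.translate_heart(vol, mask, float(d))
                states.append(ks.forward_transform(ph.central_slice(moved), traj))
            k_states.append(states)

    weights = ks.density_weights(traj)
    clean_images = [
        np.abs(ks.adjoint_reconstruct(states[0], weights).data) for states in k_states
    ]
    roi = feat.compute_roi(masks if masks else None, (N, N))
    specs = feat.sample_feature_specs(seed_specs, roi, cfg.feature_counts)

    rows = []
    for cell in _cell_grid(cfg):
        key = json.dumps(cell, sort_keys=True)
        if key in status:
            rows.append(status[key])
            log(f"cell {cell}: cached")
            continue
        t0 = time.time()
        if cfg.motion_type == "bulk":
            schedule = mo.bulk_schedule(n, cell["offset"], cell["fraction"])
        else:
            model = mo.RespiratoryModel(cell["cycles"], cfg.max_displacement_mm, cfg.n_resp_states)
            schedule, _ = mo.respiratory_schedule(n, model)
        pairs = []
        for s in range(cfg.n_subjects):
            joint = mo.merge_kspace(k_states[s], schedule)
            corrupted = np.abs(ks.adjoint_reconstruct(joint, weights).data)
            pairs.append((clean_images[s], corrupted, f"subj{s:04d}"))
        images, labels, subject_ids = build_paired_dataset(pairs, seed_pairing)
        matrix = feat.extract_feature_matrix(images, labels, subject_ids, specs)
        result = nested_cv_accuracy(matrix, cfg.outer_k, cfg.inner_k, cfg.forest, seed_cv)
        row = {
            **cell,
            "accuracy": result.overall_accuracy,
            "per_fold": list(result.per_fold_accuracies),
            "chosen_params": [list(map(str, p)) for p in result.chosen_params],
            "n_subjects": cfg.n_subjects,
            "elapsed_s": round(time.time() - t0, 2),
        }
        rows.append(row)
        log(f"cell {cell}: accuracy {result.overall_accuracy:.3f} ({row['elapsed_s']}s)")
        if out_path is not None:
            status[key] = row
            (out_path / "cells.json").write_text(json.dumps(status, indent=1))

    table = pd.DataFrame(rows)
    if out_path is not None:
        table.drop(columns=["per_fold", "chosen_params"]).to_csv(
            out_path / "results.csv", index=False
        )
        report = {
            "config": _config_to_json(cfg),
            "child_seeds": dict(
                zip(["phantom", "motion", "pairing", "specs", "cv"], seeds)
            ),
            "cells": rows,
            "elapsed_s": round(time.time() - t_start, 2),
        }
        (out_path / "report.json").write_text(json.dumps(report, indent=1))
    return table


def _config_to_json(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["forest"]["max_depth_grid"] = [x if x is None else int(x) for x in cfg.forest.max_depth_grid]
    return d
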