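"""Repeated-split random-forest classification of hit surfaces.

Links a surface's design descriptors (or its cells' median shape features)
to its High/Low class.  The protocol: 100 repeats of a stratified 75/25
train/test split; on each training part a random forest is tuned by 10-fold
cross-validation; held-out accuracy and permutation feature importance are
recorded per repeat and aggregated as mean +/- sd.  The per-repeat split
seeds are retained so a report is exactly reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from topochip._seeds import stage_rng
from topochip.errors import ConfigurationError

DEFAULT_TUNING_GRID = {"max_features": ["sqrt", None]}

DESIGN_FEATURE_COLUMNS = [
    "pattern_area_um2", "space_area_um2", "foreground_fraction", "n_pillars",
    "wn0.1", "wn0.25", "wn0.5",
]
SHAPE_FEATURE_COLUMNS = [
    "area_um2", "perimeter_um", "form_factor", "solidity",
    "eccentricity", "median_radius_um",
]


@dataclass
class FeatureMatrix:
    """Standardized features + binary labels for the High/Low surfaces."""

    X: pd.DataFrame  # rows indexed by unit_id
    y: np.ndarray  # 1 = High, 0 = Low
    feature_names: list[str]
    label_map: dict[str, int] = field(default_factory=lambda: {"Low": 0, "High": 1})
    dropped_features: list[str] = field(default_factory=list)


def build_feature_matrix(
    hit_table: pd.DataFrame,
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> FeatureMatrix:
    """Join hit classes with per-surface features and standardize.

    NS surfaces are dropped; zero-variance feature columns are dropped with
    a warning; remaining columns are scaled to zero mean / unit variance
    over the included rows.
    """
    labeled = hit_table[hit_table["class"].isin(["High", "Low"])]
    if labeled.empty:
        raise ConfigurationError("no labeled surfaces: hit table is all NS")
    feats = features.set_index("unit_id")
    missing = [u for u in labeled["unit_id"] if u not in feats.index]
    if missing:
        raise ConfigurationError(f"hit surface(s) lacking features: {missing[:5]}")
    if feature_cols is None:
        feature_cols = [c for c in feats.columns
                        if c != "archetype" and np.issubdtype(feats[c].dtype, np.number)]
    X = feats.loc[labeled["unit_id"], feature_cols].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ConfigurationError(f"missing feature values in columns {bad}")
    dropped = [c for c in X.columns if X[c].std(ddof=0) == 0.0]
    if dropped:
        warnings.warn(f"dropping zero-variance feature(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    X = (X - X.mean()) / X.std(ddof=0)
    y = (labeled["class"] == "High").to_numpy().astype(int)
    return FeatureMatrix(X=X, y=y, feature_names=list(X.columns), dropped_features=dropped)


@dataclass
class ModelReport:
    accuracies: list[float]
    mean_accuracy: float
    importance_mean: dict[str, float]
    importance_sd: dict[str, float]
    split_seeds: list[int]
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "accuracies": self.accuracies,
            "mean_accuracy": self.mean_accuracy,
            "importance_mean": self.importance_mean,
            "importance_sd": self.importance_sd,
            "split_seeds": self.split_seeds,
            "config": self.config,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelReport":
        return cls(
            accuracies=[float(a) for a in d["accuracies"]],
            mean_accuracy=float(d["mean_accuracy"]),
            importance_mean={k: float(v) for k, v in d["importance_mean"].items()},
            importance_sd={k: float(v) for k, v in d["importance_sd"].items()},
            split_seeds=[int(s) for s in d["split_seeds"]],
            config=d["config"],
        )


def fit_one_split(
    fm: FeatureMatrix,
    seed: int,
    train_fraction: float = 0.75,
    cv_folds: int = 10,
    tuning_grid: dict | None = None,
    n_estimators: int = 100,
    importance_repeats: int = 5,
    indices: tuple[np.ndarray, np.ndarray] | None = None,
):
    """One stratified split: tune on the training part, score held out.

    Everything that is fit -- CV tuning included -- sees only the training
    rows, so held-out labels cannot influence the model.  Returns the fitted
    estimator, train/test indices, held-out accuracy, and permutation
    importances on the held-out split.  ``indices`` pins the split
    explicitly (used by the leakage checks).
    """
    grid = DEFAULT_TUNING_GRID if tuning_grid is None else tuning_grid
    if indices is not None:
        train_idx, test_idx = indices
    else:
        idx = np.arange(len(fm.y))
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, stratify=fm.y, random_state=seed
        )
    X, y = fm.X.to_numpy(), fm.y
    n_grid = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if n_grid > 1:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(rf, grid, cv=cv, n_jobs=1)
        search.fit(X[train_idx], y[train_idx])
        model = search.best_estimator_
    else:
        model = rf.fit(X[train_idx], y[train_idx])
    acc = float(model.score(X[test_idx], y[test_idx]))
    imp = permutation_importance(
        model, X[test_idx], y[test_idx], n_repeats=importance_repeats, random_state=seed
    )
    return model, train_idx, test_idx, acc, imp.importances_mean


def repeat_split_classify(
    fm: FeatureMatrix,
    n_repeats: int = 100,
    train_fraction: float = 0.75,
    cv_folds: int = 10,
    master_seed: int = 0,
    tuning_grid: dict | None = None,
    n_estimators: int = 100,
    split_seeds: list[int] | None = None,
) -> ModelReport:
    """The repeated-split protocol; fully reproducible from its seeds."""
    if len(fm.y) < 20:
        raise ConfigurationError(f"need >= 20 labeled surfaces, got {len(fm.y)}")
    if len(np.unique(fm.y)) < 2:
        raise ConfigurationError("both classes must be present")
    n_minority = int(min(np.bincount(fm.y)))
    if min(n_minority, int(round(len(fm.y) * train_fraction))) < cv_folds:
        raise ConfigurationError(
            f"{cv_folds}-fold CV impossible with minority class of {n_minority}"
        )
    if split_seeds is None:
        rng = stage_rng(master_seed, "ml-splits")
        split_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_repeats)]
    accs: list[float] = []
    importances = np.zeros((len(split_seeds), len(fm.feature_names)))
    for r, seed in enumerate(split_seeds):
        _, _, _, acc, imp = fit_one_split(
            fm, seed, train_fraction, cv_folds, tuning_grid, n_estimators
        )
        accs.append(acc)
        importances[r] = imp
    return ModelReport(
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        importance_mean=dict(zip(fm.feature_names, np.mean(importances, axis=0))),
        importance_sd=dict(zip(fm.feature_names, np.std(importances, axis=0, ddof=0))),
        split_seeds=list(split_seeds),
        config={
            "n_repeats": len(split_seeds),
            "train_fraction": train_fraction,
            "cv_folds": cv_folds,
            "n_estimators": n_estimators,
            "tuning_grid": tuning_grid if tuning_grid is not None else DEFAULT_TUNING_GRID,
            "master_seed": master_seed,
        },
    )


def report_model(report: ModelReport, path: str | Path, plot: bool = False) -> dict[str, Path]:
    """Write model_report.json, importance.csv and accuracies.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "report": path / "model_report.json",
        "importance": path / "importance.csv",
        "accuracies": path / "accuracies.csv",
    }
    out["report"].write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n")
    imp = pd.DataFrame(
        {
            "feature": list(report.importance_mean),
            "importance_mean": list(report.importance_mean.values()),
            "importance_sd": [report.importance_sd[k] for k in report.importance_mean],
        }
    ).sort_values("importance_mean", ascending=False, kind="mergesort")
    imp["rank"] = np.arange(1, len(imp) + 1)
    imp.to_csv(out["importance"], index=False)
    pd.DataFrame({"repeat": np.arange(len(report.accuracies)),
                  "accuracy": report.accuracies}).to_csv(out["accuracies"], index=False)
    if plot:  # pragma: no cover - optional dependency path
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.hist(report.accuracies, bins=20)
        ax.set_xlabel("held-out accuracy")
        ax.set_ylabel("repeats")
        fig.savefig(path / "accuracy_hist.png", dpi=120)
        plt.close(fig)
        out["figure"] = path / "accuracy_hist.png"
    return out
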