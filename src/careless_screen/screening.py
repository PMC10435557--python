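"""Scenario construction and the repeated-validation GBM benchmark.

A *scenario* names which variable blocks enter the predictor matrix:

====================  =====================================================
name                  blocks
====================  =====================================================
resp                  raw item responses (60 variables by default)
rt                    per-section response times (6 variables)
dem                   demographics (age + one-hot gender/occupation/education)
careless              the 13 careless-responding index columns
resp_dem, rt_dem,     pairwise combinations
resp_rt
all                   resp + rt + dem
all_extracted         all + careless indices + derived irvDiff/longDiff
====================  =====================================================

The validation protocol is repeated holdout: each repeat draws a
stratified train/test split (default 420/185) without replacement with
its own derived seed, tunes a gradient-boosting classifier by inner
k-fold cross-validated balanced accuracy over a hyperparameter grid,
refits on the full training set, and scores balanced accuracy on the
held-out test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline

from .indices import DERIVED_INDEX_COLUMNS
from .metrics import balanced_accuracy
from .synthetic import SurveyCohort

logger = logging.getLogger(__name__)

SCENARIO_BLOCKS: dict[str, tuple[str, ...]] = {
    "resp": ("resp",),
    "rt": ("rt",),
    "dem": ("dem",),
    "careless": ("careless",),
    "resp_dem": ("resp", "dem"),
    "rt_dem": ("rt", "dem"),
    "resp_rt": ("resp", "rt"),
    "all": ("resp", "rt", "dem"),
    "all_extracted": ("resp", "rt", "dem", "careless", "careless_derived"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    blocks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_BLOCKS:
            raise ValueError(f"unknown scenario {self.name!r}; known: "
                             f"{sorted(SCENARIO_BLOCKS)}")
        if not self.blocks:
            object.__setattr__(self, "blocks", SCENARIO_BLOCKS[self.name])


@dataclass
class ScenarioMatrix:
    """Predictor matrix with per-column block provenance."""

    spec: ScenarioSpec
    X: pd.DataFrame
    provenance: dict[str, str]   # column -> block name

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


@dataclass(frozen=True)
class ValidationPlan:
    """Repeated stratified holdout: 100 repeats of 420/185 by default."""

    n_repeats: int = 100
    train_size: int = 420
    test_size: int = 185
    inner_folds: int = 10
    base_seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if min(self.train_size, self.test_size) < 1:
            raise ValueError("split sizes must be positive")


@dataclass(frozen=True)
class GBMConfig:
    """Hyperparameter grid for the gradient-boosting classifier."""

    interaction_depth: tuple[int, ...] = (1, 2, 3)
    min_obs_leaf: tuple[int, ...] = (5, 10)
    n_trees: tuple[int, ...] = (50, 100, 200)
    shrinkage: tuple[float, ...] = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("interaction_depth", "min_obs_leaf", "n_trees"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} values must be positive")
        if any(not 0.0 < s <= 1.0 for s in self.shrinkage):
            raise ValueError("shrinkage must be in (0, 1]")

    @classmethod
    def compact(cls, seed: int = 0) -> "GBMConfig":
        """Reduced grid for fast runs (CI, scaled-down benchmarks)."""
        return cls(interaction_depth=(1, 3), min_obs_leaf=(10,),
                   n_trees=(50, 100), shrinkage=(0.1,), seed=seed)

    def param_grid(self) -> dict[str, list]:
        return {
            "gbm__max_depth": list(self.interaction_depth),
            "gbm__min_samples_leaf": list(self.min_obs_leaf),
            "gbm__n_estimators": list(self.n_trees),
            "gbm__learning_rate": list(self.shrinkage),
        }


# ---------------------------------------------------------------------------
# scenario matrices
# ---------------------------------------------------------------------------

def _one_hot_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    cats = [c for c in demo.columns if demo[c].dtype == object
            or isinstance(demo[c].dtype, pd.CategoricalDtype)]
    out = pd.get_dummies(demo, columns=cats, dtype=float)
    return out[sorted(out.columns)]


def build_scenario_matrix(cohort: SurveyCohort,
                          index_table: pd.DataFrame | None,
                          spec: ScenarioSpec | str) -> ScenarioMatrix:
    """Concatenate the scenario's variable blocks into one predictor matrix."""
    if isinstance(spec, str):
        spec = ScenarioSpec(spec)
    parts: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for block in spec.blocks:
        if block == "resp":
            df = cohort.responses.astype(float)
        elif block == "rt":
            df = cohort.times
        elif block == "dem":
            df = _one_hot_demographics(cohort.demographics)
        elif block in ("careless", "careless_derived"):
            if index_table is None:
                raise ValueError(f"scenario {spec.name!r} needs an index table")
            if block == "careless":
                wanted = [c for c in index_table.columns
                          if c not in DERIVED_INDEX_COLUMNS]
            else:
                missing = [c for c in DERIVED_INDEX_COLUMNS
                           if c not in index_table.columns]
                if missing:
                    raise ValueError(
                        f"index table lacks derived columns {missing}; "
                        "compute it with include_derived=True")
                wanted = list(DERIVED_INDEX_COLUMNS)
            df = index_table[wanted].astype(float)
        else:
            raise ValueError(f"unknown block {block!r}")
        df = df.reset_index(drop=True)
        parts.append(df)
        provenance.update({c: block for c in df.columns})
    X = pd.concat(parts, axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate predictor columns across blocks")
    return ScenarioMatrix(spec=spec, X=X, provenance=provenance)


# ---------------------------------------------------------------------------
# validation plan
# ---------------------------------------------------------------------------

def _split_counts(class_sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of `total` across classes."""
    quotas = class_sizes / class_sizes.sum() * total
    base = np.floor(quotas).astype(int)
    rest = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:rest]:
        base[i] += 1
    return base


def make_validation_plan(labels: np.ndarray, plan: ValidationPlan
                         ) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Deterministic per-repeat (train ids, test ids, seed) triples.

    Repeat r uses seed ``base_seed + r``; train and test are sampled
    without replacement and are disjoint. With ``stratify`` the class
    ratio of the cohort is preserved in both partitions
    (largest-remainder rounding).
    """
    labels = np.asarray(labels)
    n = labels.size
    if plan.train_size + plan.test_size > n:
        raise ValueError(f"train+test = {plan.train_size + plan.test_size} "
                         f"exceeds cohort size {n}")
    splits = []
    classes = np.unique(labels)
    for r in range(plan.n_repeats):
        seed = plan.base_seed + r
        rng = np.random.default_rng(seed)
        if plan.stratify and len(classes) > 1:
            sizes = np.array([(labels == c).sum() for c in classes])
            n_train = _split_counts(sizes, plan.train_size)
            n_test = _split_counts(sizes, plan.test_size)
            train_parts, test_parts = [], []
            for c, tr, te in zip(classes, n_train, n_test):
                ids = rng.permutation(np.flatnonzero(labels == c))
                train_parts.append(ids[:tr])
                test_parts.append(ids[tr:tr + te])
            train = np.sort(np.concatenate(train_parts))
            test = np.sort(np.concatenate(test_parts))
        else:
            ids = rng.permutation(n)
            train = np.sort(ids[:plan.train_size])
            test = np.sort(ids[plan.train_size:plan.train_size + plan.test_size])
        splits.append((train, test, seed))
    return splits


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedGBM:
    """A tuned gradient-boosting classifier with a stable feature order."""

    estimator: Pipeline
    feature_names: list[str]
    best_params: dict

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names]
        return pd.DataFrame(np.asarray(X), columns=self.feature_names)

    def predict_proba_careless(self, X) -> np.ndarray:
        """Probability of the positive (careless) class."""
        return self.estimator.predict_proba(self._frame(X))[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba_careless(X) >= threshold).astype(int)


def fit_gbm(X: pd.DataFrame, y: np.ndarray, config: GBMConfig | None = None,
            inner_folds: int = 10) -> FittedGBM:
    """Tune hyperparameters by inner stratified k-fold CV on balanced
    accuracy, then refit on the full training set.

    Index columns may contain NaN (undefined scores); these are median-
    imputed inside the CV pipeline.
    """
    config = config or GBMConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
        ("gbm", GradientBoostingClassifier(random_state=config.seed)),
    ])
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                         random_state=config.seed)
    search = GridSearchCV(pipe, config.param_grid(),
                          scoring="balanced_accuracy", cv=cv, refit=True)
    search.fit(X, y)
    return FittedGBM(estimator=search.best_estimator_,
                     feature_names=list(X.columns),
                     best_params=dict(search.best_params_))


# ---------------------------------------------------------------------------
# the benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    per_repeat: pd.DataFrame   # scenario, repeat, seed, balanced_accuracy, ...
    summary: pd.DataFrame      # scenario, mean, sd, n_repeats

    def mean_ba(self, scenario: str) -> float:
        row = self.summary.loc[self.summary["scenario"] == scenario]
        if row.empty:
            raise KeyError(f"scenario {scenario!r} not in benchmark")
        return float(row["mean"].iloc[0])


def run_benchmark(cohort: SurveyCohort, index_table: pd.DataFrame | None,
                  scenarios: Sequence[str], plan: ValidationPlan,
                  config: GBMConfig | None = None) -> BenchmarkResult:
    """Repeated-holdout balanced-accuracy benchmark over scenarios.

    Per-repeat failures are logged and tolerated up to 10% of repeats;
    beyond that the run fails.
    """
    config = config or GBMConfig()
    splits = make_validation_plan(cohort.labels, plan)
    rows = []
    n_failed = 0
    for name in scenarios:
        sm = build_scenario_matrix(cohort, index_table, name)
        for r, (train, test, seed) in enumerate(splits):
            try:
                model = fit_gbm(sm.X.iloc[train], cohort.labels[train],
                                replace(config, seed=seed),
                                inner_folds=plan.inner_folds)
                pred = model.predict(sm.X.iloc[test])
                ba = balanced_accuracy(pred, cohort.labels[test])
            except Exception:
                logger.exception("repeat %d of scenario %s failed", r, name)
                n_failed += 1
                continue
            rows.append({"scenario": name, "repeat": r, "seed": seed,
                         "balanced_accuracy": ba,
                         "best_params": str(model.best_params)})
    total = len(scenarios) * plan.n_repeats
    if n_failed > 0.10 * total:
        raise RuntimeError(f"{n_failed}/{total} benchmark repeats failed")
    per_repeat = pd.DataFrame(rows)
    summary = (per_repeat.groupby("scenario", sort=False)["balanced_accuracy"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_repeats="count")
               .reset_index())
    return BenchmarkResult(per_repeat=per_repeat, summary=summary)
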