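"""Multi-algorithm ensemble calibration and continuous suitability surfaces.

Nine learner families are registered by default, mirroring the classic
ensemble-SDM roster: boosted trees (GBM), a single classification tree
(CTA), random forest (RF), logistic regression (GLM), spline-basis logistic
regressions (GAM and MARS), a small multilayer perceptron (ANN), a
discriminant on spline features (FDA), and an L1-regularised logistic
regression on linear+quadratic+interaction features of the PCA scores as a
maximum-entropy-style model (MAXENT).  The registry is open: tests and
users can register further families, including fixed "oracle" surfaces.

Each (family, pseudo-absence set, run) triple yields one fitted model and
one continuous suitability surface per scenario; the ensemble is their
unweighted per-cell arithmetic mean.  For the heavily imbalanced 10 000-PA
designs, presences are up-weighted so total presence weight equals total
pseudo-absence weight (by ``sample_weight`` where supported, by
deterministic row replication otherwise).
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .env_layers import EnvStack
from .grids import GridSpec
from .pseudo_absence import FAMILY_PA_CLASS, PASample
from .utils import derive_seed, logger

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Presence/pseudo-absence design matrix for one model fit."""

    cell_ids: list[tuple[int, int]]
    X: np.ndarray  # (n_rows, n_predictors)
    y: np.ndarray  # 1 presence / 0 pseudo-absence
    predictor_names: list[str]
    family: str
    pa_set_index: int = 0
    run_index: int = 0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.cell_ids) != len(set(self.cell_ids)):
            raise ValueError("duplicated cell_id in training table")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite predictor values in training table")
        if self.X.shape != (len(self.y), len(self.predictor_names)):
            raise ValueError("X shape inconsistent with y / predictor_names")


@dataclass
class SuitabilityMap:
    """Continuous [0, 1] suitability surface on the predictor grid."""

    grid: GridSpec
    values: np.ndarray  # NaN outside the valid mask
    scenario_label: str = "current"
    provenance: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("suitability values outside [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def values_at(self, cells) -> np.ndarray:
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        return self.values[cells[:, 0], cells[:, 1]]


@dataclass
class FittedModel:
    """A fitted learner plus the predictor order it expects."""

    family: str
    predictor_names: list[str]
    estimator: object
    identifier: str = ""


@dataclass
class ReplicateResult:
    """Ensemble surfaces (one per scenario) from a full calibration replicate."""

    maps: dict[str, SuitabilityMap]
    n_models: int
    n_failed: int
    provenance: frozenset


# ---------------------------------------------------------------------------
# Learner registry
# ---------------------------------------------------------------------------

LearnerBuilder = Callable[[int, dict], object]

_REGISTRY: dict[str, LearnerBuilder] = {}

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "GBM": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "CTA": {},
    "RF": {"n_estimators": 100},
    "GLM": {"C": 1.0, "max_iter": 1000},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1.0, "max_iter": 1000},
    "ANN": {"hidden_layer_sizes": (8,), "max_iter": 500, "alpha": 1e-3},
    "FDA": {"n_knots": 5, "degree": 1},
    "MARS": {"n_knots": 5, "degree": 1, "C": 1.0, "max_iter": 1000},
    "MAXENT": {"C": 1.0, "max_iter": 100, "tol": 1e-2},
}


def register_family(name: str, builder: LearnerBuilder) -> None:
    """Register (or replace) a learner family.

    ``builder(seed, hyperparams)`` must return an object with
    ``fit(X, y[, sample_weight])`` and ``predict_proba(X)``.
    """
    _REGISTRY[name] = builder


def registered_families() -> list[str]:
    return sorted(_REGISTRY)


def _build_gbm(seed: int, hp: dict) -> object:
    return GradientBoostingClassifier(random_state=seed, **hp)


def _build_cta(seed: int, hp: dict) -> object:
    return DecisionTreeClassifier(random_state=seed, **hp)


def _build_rf(seed: int, hp: dict) -> object:
    return RandomForestClassifier(random_state=seed, **hp)


def _build_glm(seed: int, hp: dict) -> object:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(**hp)),
        ]
    )


def _spline(hp: dict, default_degree: int) -> SplineTransformer:
    # linear extrapolation: projected scenarios routinely leave the training
    # range, and freezing the basis there overstates transferred suitability
    return SplineTransformer(
        n_knots=hp.pop("n_knots", 5),
        degree=hp.pop("degree", default_degree),
        extrapolation=hp.pop("extrapolation", "linear"),
    )


def _build_gam(seed: int, hp: dict) -> object:
    hp = dict(hp)
    spline = _spline(hp, 3)
    return Pipeline(
        [
            ("spline", spline),
            ("clf", LogisticRegression(**hp)),
        ]
    )


def _build_ann(seed: int, hp: dict) -> object:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(random_state=seed, **hp)),
        ]
    )


def _build_fda(seed: int, hp: dict) -> object:
    hp = dict(hp)
    spline = _spline(hp, 1)
    return Pipeline(
        [
            ("spline", spline),
            ("clf", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto", **hp)),
        ]
    )


def _build_mars(seed: int, hp: dict) -> object:
    # piecewise-linear spline basis approximates hinge (MARS-style) terms
    hp = dict(hp)
    spline = _spline(hp, 1)
    return Pipeline(
        [
            ("spline", spline),
            ("clf", LogisticRegression(**hp)),
        ]
    )


def _build_maxent(seed: int, hp: dict) -> object:
    return Pipeline(
        [
            ("features", PolynomialFeatures(degree=2, include_bias=False)),
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(l1_ratio=1.0, solver="saga", random_state=seed, **hp),
            ),
        ]
    )


for _name, _builder in {
    "GBM": _build_gbm,
    "CTA": _build_cta,
    "RF": _build_rf,
    "GLM": _build_glm,
    "GAM": _build_gam,
    "ANN": _build_ann,
    "FDA": _build_fda,
    "MARS": _build_mars,
    "MAXENT": _build_maxent,
}.items():
    register_family(_name, _builder)


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def _supports_sample_weight(estimator: object) -> bool:
    target = estimator.steps[-1][1] if isinstance(estimator, Pipeline) else estimator
    try:
        return "sample_weight" in inspect.signature(target.fit).parameters
    except (TypeError, ValueError):
        return False


def _balanced_fit(estimator: object, X: np.ndarray, y: np.ndarray) -> None:
    """Fit with presence weight totalling the pseudo-absence weight.

    Uses ``sample_weight`` when the final estimator accepts it; otherwise
    presences are deterministically replicated to approximately the same
    balance (for learners, e.g. neural nets, without weight support).
    """
    n_pres = int((y == 1).sum())
    n_abs = int((y == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise ValueError("single class in training table")
    if n_pres == n_abs:
        estimator.fit(X, y)
        return
    if _supports_sample_weight(estimator):
        w = np.where(y == 1, n_abs / n_pres, 1.0)
        w = w * (w.size / w.sum())  # mean-1 weights keep solver tolerances scale-free
        if isinstance(estimator, Pipeline):
            estimator.fit(X, y, **{f"{estimator.steps[-1][0]}__sample_weight": w})
        else:
            estimator.fit(X, y, sample_weight=w)
        return
    reps = max(1, round(n_abs / n_pres))
    Xp, yp = X[y == 1], y[y == 1]
    X_aug = np.concatenate([X[y == 0], np.tile(Xp, (reps, 1))])
    y_aug = np.concatenate([y[y == 0], np.tile(yp, reps)])
    estimator.fit(X_aug, y_aug)


def fit_learner(table: TrainingTable, family: str, seed: int, hyperparams: dict | None = None) -> FittedModel:
    """Fit one learner family on a training table; deterministic given seed."""
    if family not in _REGISTRY:
        raise ValueError(f"unregistered learner family {family!r}")
    if len(np.unique(table.y)) < 2:
        raise ValueError("single class in training table")
    hp = dict(DEFAULT_HYPERPARAMS.get(family, {}))
    if hyperparams:
        hp.update(hyperparams)
    estimator = _REGISTRY[family](seed, hp)
    _balanced_fit(estimator, table.X, table.y)
    ident = f"{family}/pa{table.pa_set_index}/run{table.run_index}"
    return FittedModel(
        family=family,
        predictor_names=list(table.predictor_names),
        estimator=estimator,
        identifier=ident,
    )


def predict_surface(model: FittedModel, score_stack: EnvStack) -> SuitabilityMap:
    """Per-cell presence probability on a predictor stack.

    The stack must carry the model's predictors (order-insensitive);
    NoData cells propagate and outputs are clamped into [0, 1].
    """
    missing = [n for n in model.predictor_names if n not in score_stack.layer_names]
    if missing:
        raise ValueError(f"predictor mismatch: stack lacks {missing}")
    ordered = score_stack.subset(model.predictor_names)
    m = ordered.mask
    X = ordered.values[:, m].T
    proba = model.estimator.predict_proba(X)
    classes = getattr(model.estimator, "classes_", np.array([0, 1]))
    col = int(np.where(np.asarray(classes) == 1)[0][0])
    p = np.clip(proba[:, col], 0.0, 1.0)
    surface = np.full(ordered.grid.shape, np.nan)
    surface[m] = p
    return SuitabilityMap(
        grid=ordered.grid,
        values=surface,
        scenario_label=score_stack.scenario_label,
        provenance=frozenset([model.identifier or model.family]),
    )


def ensemble_mean(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Unweighted per-cell arithmetic mean of suitability surfaces."""
    if not maps:
        raise ValueError("no maps to average")
    base = maps[0]
    for m in maps[1:]:
        if not m.grid.matches(base.grid):
            raise ValueError("cannot average maps on different grids")
    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)
    prov = frozenset().union(*(m.provenance for m in maps))
    return SuitabilityMap(
        grid=base.grid,
        values=mean,
        scenario_label=base.scenario_label,
        provenance=prov,
    )


def build_training_table(
    presence_cells: Sequence[tuple[int, int]],
    pa: PASample,
    score_stack: EnvStack,
    family: str,
    pa_set_index: int = 0,
    run_index: int = 0,
    replicate_index: int = 0,
) -> TrainingTable:
    """Assemble the presence/pseudo-absence design matrix for one fit."""
    cells = list(presence_cells) + list(pa.cell_ids)
    X = score_stack.values_at(cells)
    y = np.concatenate(
        [np.ones(len(presence_cells), int), np.zeros(len(pa.cell_ids), int)]
    )
    return TrainingTable(
        cell_ids=cells,
        X=X,
        y=y,
        predictor_names=list(score_stack.layer_names),
        family=family,
        pa_set_index=pa_set_index,
        run_index=run_index,
        replicate_index=replicate_index,
    )


def calibrate_replicate(
    presence_cells: Sequence[tuple[int, int]],
    pa_sets: Sequence[Mapping[str, PASample]],
    score_stacks: Mapping[str, EnvStack],
    families: Sequence[str],
    n_runs: int,
    seed_base: int,
    hyperparams: Mapping[str, dict] | None = None,
    train_scenario: str = "current",
) -> ReplicateResult:
    """Fit families x pseudo-absence sets x runs and average the surfaces.

    Each model is trained on the ``train_scenario`` predictor stack and
    predicted onto every scenario stack, so one replicate yields a
    co-calibrated ensemble surface per scenario.  Runs differ only by the
    derived seed (they reseed stochastic learners).  Individual failed fits
    are skipped with a warning; the replicate errors only if every fit
    failed.
    """
    if train_scenario not in score_stacks:
        raise ValueError(f"train scenario {train_scenario!r} not among stacks")
    train = score_stacks[train_scenario]
    per_scenario: dict[str, list[SuitabilityMap]] = {k: [] for k in score_stacks}
    n_failed = 0
    prov: set[str] = set()
    for fi, family in enumerate(families):
        cls = FAMILY_PA_CLASS.get(family, "large")
        hp = dict(hyperparams.get(family, {})) if hyperparams else None
        for si, pa_set in enumerate(pa_sets):
            pa = pa_set[cls] if cls in pa_set else next(iter(pa_set.values()))
            table = build_training_table(
                presence_cells, pa, train, family, pa_set_index=si
            )
            for ri in range(n_runs):
                seed = derive_seed(seed_base, fi, si, ri)
                try:
                    model = fit_learner(table, family, seed, hp)
                    model.identifier = f"{family}/pa{si}/run{ri}"
                    for label, stack in score_stacks.items():
                        per_scenario[label].append(predict_surface(model, stack))
                except Exception as exc:  # noqa: BLE001 - skip-and-log contract
                    n_failed += 1
                    logger.warning(
                        "fit failed for %s (pa_set=%d run=%d): %s", family, si, ri, exc
                    )
                    continue
                prov.add(model.identifier)
    if not per_scenario[train_scenario]:
        raise RuntimeError("all model fits failed in this replicate")
    maps = {label: ensemble_mean(ms) for label, ms in per_scenario.items()}
    return ReplicateResult(
        maps=maps,
        n_models=len(prov),
        n_failed=n_failed,
        provenance=frozenset(prov),
    )
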