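"""First-pass screen: gradient-boosted relative-energy regression, initial
ranking, and the acceptance-capacity pruning heuristic.

The regressor predicts a per-model relative energy (RE, kcal/mol; RE = 0 is
the most stable model of a system) from the 10 descriptors.  The predicted
REs of one system's model ensemble, together with the regressor's held-out
RMSE, feed the acceptance capacity

    capacity = (1/3) * (RMSE + RE_min) / (sigma + S)

with sigma/S the population standard deviation/variance of the predicted
REs.  The capacity sets how many top-ranked models advance to geometry
refinement: a confident, well-separated ensemble forwards only its leader,
while a noisy or tightly-bunched one forwards more to safeguard against
losing the true charge state.
"""

from __future__ import annotations

import dataclasses
import math

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GroupShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, InputError, TrainingError
from .features import FEATURE_NAMES, featurize
from .sites import ChargeStateModel

_FORMAT_VERSION = 1
_LABEL_COL = "re_label"
_SYSTEM_COL = "system_id"
_RE_TOL = 1e-9


class TrainingTable:
    """Per-model feature rows with relative-energy labels.

    Thin wrapper over a DataFrame whose columns are the feature schema plus
    ``re_label`` (kcal/mol) and ``system_id``.  Labels are relative to the
    per-system minimum, so within every system min(re_label) == 0.
    """

    def __init__(self, frame: pd.DataFrame):
        if _LABEL_COL not in frame.columns or _SYSTEM_COL not in frame.columns:
            raise InputError(
                f"training table needs '{_LABEL_COL}' and '{_SYSTEM_COL}' columns"
            )
        self.frame = frame.reset_index(drop=True)
        labels = self.frame[_LABEL_COL].to_numpy(dtype=float)
        if labels.size == 0:
            raise InputError("training table is empty")
        if labels.min() < -_RE_TOL:
            raise InputError("re_label values must be >= 0 (relative energies)")
        per_system_min = self.frame.groupby(_SYSTEM_COL)[_LABEL_COL].min()
        if (per_system_min.abs() > 1e-6).any():
            bad = per_system_min[per_system_min.abs() > 1e-6].index[0]
            raise InputError(
                f"system {bad!r}: min(re_label) != 0 — labels must be "
                "relative to the per-system minimum"
            )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c not in (_LABEL_COL, _SYSTEM_COL))

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[_LABEL_COL].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame[_SYSTEM_COL].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def drop_feature(self, name: str) -> "TrainingTable":
        if name not in self.feature_names:
            raise InputError(f"no such feature column: {name!r}")
        return TrainingTable(self.frame.drop(columns=[name]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        return cls(pd.read_csv(path))


class EnergyRegressor(RegressorMixin, BaseEstimator):
    """Gradient-boosted-tree relative-energy regressor.

    scikit-learn estimator: composes with pipelines and model selection.
    Defaults (300 trees, depth 6, learning rate 0.1) are exposed so users
    with their own hyperparameter tables can match them exactly.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int = 6,
        learning_rate: float = 0.1,
        subsample: float = 1.0,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise InputError("X must be 2-D with one label per row")
        if len(X) and np.all(np.ptp(X, axis=0) == 0):
            raise TrainingError(
                "degenerate training table: every feature is constant"
            )
        self.regressor_ = GradientBoostingRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "regressor_")
        return self.regressor_.predict(np.asarray(X, dtype=float))


@dataclasses.dataclass
class RankerModel:
    """A trained energy regressor plus the metadata ranking needs: its
    held-out RMSE (the uncertainty term in the acceptance capacity), the
    ordered feature schema it was fit on, the ion mode, and the seed."""

    estimator: EnergyRegressor
    training_rmse: float
    feature_schema: tuple[str, ...]
    mode: str
    seed: int

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(X)


@dataclasses.dataclass
class SelectionStats:
    """The acceptance-capacity ingredients for one system's ensemble."""

    rmse: float  # kcal/mol, regressor held-out RMSE
    re_min: float  # kcal/mol, minimum predicted RE
    sigma: float  # kcal/mol, population std dev of predicted REs
    variance_s: float  # population variance of predicted REs
    capacity: float  # dimensionless


def train(
    table: TrainingTable,
    hyperparams: dict | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    mode: str = "[M+H]+",
) -> RankerModel:
    """Fit the GBT regressor with a grouped held-out split.

    The split is by ``system_id`` so no system straddles train/test; the
    held-out RMSE is stored on the returned model because the acceptance
    capacity of a frozen model needs it at prediction time.
    """
    systems = np.unique(table.groups)
    if len(table) < 20 or len(systems) < 2:
        raise TrainingError(
            f"need >= 20 rows spanning >= 2 systems, got {len(table)} rows / "
            f"{len(systems)} systems"
        )
    est = EnergyRegressor(random_state=seed, **(hyperparams or {}))
    splitter = GroupShuffleSplit(
        n_splits=1, test_size=holdout_fraction, random_state=seed
    )
    train_idx, test_idx = next(splitter.split(table.X, table.y, table.groups))
    est.fit(table.X[train_idx], table.y[train_idx])
    resid = est.predict(table.X[test_idx]) - table.y[test_idx]
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RankerModel(
        estimator=est,
        training_rmse=rmse,
        feature_schema=table.feature_names,
        mode=mode,
        seed=seed,
    )


def predict_and_rank(
    ranker: RankerModel, models: list[ChargeStateModel]
) -> list[ChargeStateModel]:
    """Predict REs and assign initial ranks r = 1..n by ascending predicted
    RE; exact ties go to the lower charge-bearing-atom index."""
    if tuple(ranker.feature_schema) != FEATURE_NAMES:
        raise ConfigurationError(
            "ranker feature schema does not match the descriptor schema: "
            f"{ranker.feature_schema} vs {FEATURE_NAMES}"
        )
    if not models:
        raise InputError("no charge-state models to rank")
    X = np.vstack([featurize(m).as_array() for m in models])
    predicted = ranker.predict(X)
    for m, re in zip(models, predicted):
        m.predicted_re = float(re)
    ranked = sorted(models, key=lambda m: (m.predicted_re, m.cba_index))
    for r, m in enumerate(ranked, start=1):
        m.initial_rank_r = r
    return ranked


def acceptance_capacity(rmse: float, predicted_res: list[float]) -> SelectionStats:
    """The pruning heuristic: (1/3)(RMSE + RE_min)/(sigma + S).

    sigma and S are the population standard deviation and variance of the
    predicted REs.  The formula is a heuristic in kcal/mol units throughout;
    it is not dimensionally homogeneous and is not meant to be.  A
    degenerate ensemble (single model, or all predictions equal, so
    sigma + S < 1e-9) gets capacity 1 so exactly the top model advances.
    """
    if len(predicted_res) == 0:
        raise InputError("acceptance capacity of an empty ensemble is undefined")
    if rmse < 0:
        raise InputError("rmse must be >= 0")
    res = np.asarray(predicted_res, dtype=float)
    re_min = float(res.min())
    sigma = float(res.std(ddof=0))
    variance = float(res.var(ddof=0))
    denom = sigma + variance
    if denom < 1e-9:
        capacity = 1.0
    else:
        capacity = (rmse + re_min) / (3.0 * denom)
    return SelectionStats(
        rmse=float(rmse),
        re_min=re_min,
        sigma=sigma,
        variance_s=variance,
        capacity=capacity,
    )


def select_models(
    ranked: list[ChargeStateModel], stats: SelectionStats
) -> list[ChargeStateModel]:
    """Forward the top k = clamp(ceil(capacity), 1, n) models.

    The ceiling preserves the capacity's safeguard semantics; the rank-1
    model is always forwarded.
    """
    n = len(ranked)
    k = min(max(math.ceil(stats.capacity), 1), n)
    return ranked[:k]


def mir_feature_importance(
    table: TrainingTable,
    hyperparams: dict | None = None,
    seed: int = 0,
    n_repeats: int = 3,
) -> dict[str, float]:
    """Mean increase in RMSE (MIR) upon eliminating each feature.

    For every feature the model is retrained without it over ``n_repeats``
    seeded grouped splits; MIR(f) = mean(RMSE_without_f - RMSE_full).
    Larger MIR = the model leans on that feature harder; a useless feature
    scores about zero (slightly negative values are ordinary resampling
    noise).
    """
    out = {name: 0.0 for name in table.feature_names}
    for rep in range(n_repeats):
        rep_seed = seed + rep
        full = train(table, hyperparams, seed=rep_seed)
        for name in table.feature_names:
            reduced = train(table.drop_feature(name), hyperparams, seed=rep_seed)
            out[name] += (reduced.training_rmse - full.training_rmse) / n_repeats
    return out


def save_ranker(ranker: RankerModel, path) -> None:
    """Single-file bundle: regressor + schema + held-out RMSE + mode + seed."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "estimator": ranker.estimator,
            "training_rmse": ranker.training_rmse,
            "feature_schema": tuple(ranker.feature_schema),
            "mode": ranker.mode,
            "seed": ranker.seed,
        },
        path,
    )


def load_ranker(path) -> RankerModel:
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != _FORMAT_VERSION:
        raise ConfigurationError(
            f"ranker bundle format version {version!r} is not supported"
        )
    return RankerModel(
        estimator=bundle["estimator"],
        training_rmse=bundle["training_rmse"],
        feature_schema=tuple(bundle["feature_schema"]),
        mode=bundle["mode"],
        seed=bundle["seed"],
    )
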