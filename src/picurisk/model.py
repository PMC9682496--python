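"""Balanced-bootstrap random forest for unplanned-intubation risk.

The model is a classification forest of 800 trees in which each tree is
grown on a bootstrap sample of the case records plus an equal number of
control records sampled with replacement — the balanced bootstrap that
corrects the severe class imbalance (events are rare).  floor(sqrt(p))
features are candidates at each split.  The model output for a record
is the fraction of trees voting "event"; dividing by the mean vote over
a reference population gives predicted *relative risk*, and multiplying
by the average probability of unplanned intubation in the next 12 h
gives a predicted probability.

Missing predictor values are imputed with age-decile medians: the
deciles of age and the median of each feature within each decile are
computed on training data and reused for test rows, so imputation never
leaks information across cross-validation folds.

The public surface is statsmodels-like: build an
:class:`UnplannedIntubationForest` from a feature matrix, call
``fit()``, and work with the returned :class:`ForestResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "AgeDecileImputer",
    "impute_age_decile",
    "mtry_default",
    "UnplannedIntubationForest",
    "ForestResults",
    "scale_risk",
    "marginal_profile",
    "random_feature_screen",
]

N_TREES_DEFAULT = 800
#: cohort-average probability of unplanned intubation in the next 12 h,
#: used in worked examples when no training prior is supplied
PRIOR_12H_DEFAULT = 0.0063


def mtry_default(p: int) -> int:
    """Candidate features per split: floor(sqrt(p)); 6 at p = 39 or 40."""
    return int(math.floor(math.sqrt(p)))


@dataclass
class AgeDecileImputer:
    """Median imputation within deciles of age, fitted on training data."""

    decile_edges: np.ndarray = field(default=None)
    medians: pd.DataFrame = field(default=None)  # 10 rows x features
    global_medians: pd.Series = field(default=None)

    def fit(self, X: pd.DataFrame, ages: np.ndarray) -> "AgeDecileImputer":
        ages = np.asarray(ages, dtype=float)
        if np.isnan(ages).any():
            raise ValueError("age must be present for every row")
        self.decile_edges = np.quantile(ages, np.linspace(0.1, 0.9, 9))
        dec = self._assign(ages)
        self.global_medians = X.median()
        fully_missing = self.global_medians.index[
            self.global_medians.isna()].tolist()
        if fully_missing:
            raise ValueError(
                "feature(s) entirely missing in training data: "
                + ", ".join(map(str, fully_missing)))
        med = X.groupby(dec).median().reindex(range(10))
        self.medians = med.fillna(self.global_medians)
        return self

    def _assign(self, ages: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.decile_edges, np.asarray(ages, float),
                               side="right")

    def transform(self, X: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
        dec = self._assign(ages)
        fill = self.medians.iloc[dec].reset_index(drop=True)
        fill.index = X.index
        return X.fillna(fill[X.columns])


def impute_age_decile(X: pd.DataFrame, ages: np.ndarray,
                      fitted: AgeDecileImputer | None = None
                      ) -> tuple[pd.DataFrame, AgeDecileImputer]:
    """Fill missing values with age-decile medians.

    When ``fitted`` is given (the training-fitted imputer), its decile
    edges and medians are reused; otherwise they are computed from the
    data at hand.  Observed values are never altered.
    """
    imp = fitted if fitted is not None else AgeDecileImputer().fit(X, ages)
    return imp.transform(X, ages), imp


def scale_risk(votes: np.ndarray, reference_mean_votes: float,
               prior12h: float = PRIOR_12H_DEFAULT) -> pd.DataFrame:
    """Vote fraction -> relative risk -> predicted probability.

    relative_risk = votes / reference mean votes; probability =
    relative_risk x the 12-h event prior, clipped to [0, 1].
    """
    if reference_mean_votes <= 0:
        raise ValueError("reference mean votes must be positive")
    v = np.asarray(votes, dtype=float)
    rr = v / reference_mean_votes
    return pd.DataFrame({
        "votes": v,
        "relative_risk": rr,
        "probability": np.clip(rr * prior12h, 0.0, 1.0),
    })


class UnplannedIntubationForest:
    """Balanced-bootstrap random forest model of unplanned intubation.

    Parameters
    ----------
    X : DataFrame
        Predictor matrix (may contain NaN; imputed at fit time).
    y : array-like of bool
        Case indicator per record.
    ages : array-like
        Age in years per record (drives imputation; usually also a
        column of ``X``).
    n_trees, mtry, seed
        Forest size (800), candidate features per split
        (floor(sqrt(p)) when None), and RNG seed.
    """

    def __init__(self, X: pd.DataFrame, y, ages, *,
                 n_trees: int = N_TREES_DEFAULT, mtry: int | None = None,
                 seed: int = 0):
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=bool)
        self.ages = np.asarray(ages, dtype=float)
        if len(self.X) != self.y.size or self.y.size != self.ages.size:
            raise ValueError("X, y and ages must have equal length")
        self.n_trees = int(n_trees)
        self.mtry = mtry_default(X.shape[1]) if mtry is None else int(mtry)
        self.seed = int(seed)

    @classmethod
    def from_records(cls, records: pd.DataFrame, feature_columns: list[str],
                     **kw) -> "UnplannedIntubationForest":
        """Build from a labeled record table (as produced by the pipeline)."""
        return cls(records[feature_columns],
                   records["label"].to_numpy() == "case",
                   records["age_years"].to_numpy(), **kw)

    def fit(self, *, prior12h: float | None = None) -> "ForestResults":
        if self.y.all() or not self.y.any():
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(self.seed)
        Xf, imputer = impute_age_decile(self.X, self.ages)
        Xv = Xf.to_numpy(dtype=float)
        case_idx = np.nonzero(self.y)[0]
        ctrl_idx = np.nonzero(~self.y)[0]
        n_bal = case_idx.size
        trees = []
        for _ in range(self.n_trees):
            ic = rng.choice(case_idx, size=n_bal, replace=True)
            in_ = rng.choice(ctrl_idx, size=n_bal, replace=True)
            idx = np.concatenate([ic, in_])
            tree = DecisionTreeClassifier(
                max_features=self.mtry,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(Xv[idx], self.y[idx])
            trees.append(tree)
        res = ForestResults(self, trees, imputer)
        votes = res.predict_votes(self.X, self.ages)
        res.reference_mean_votes_ = float(votes.mean())
        res.prior12h_ = float(prior12h) if prior12h is not None \
            else float(self.y.mean())
        return res


class ForestResults:
    """Fitted forest: votes, risk scaling, profiles and importances."""

    def __init__(self, model: UnplannedIntubationForest, trees: list,
                 imputer: AgeDecileImputer):
        self.model = model
        self.trees = trees
        self.imputer = imputer
        self.reference_mean_votes_: float = math.nan
        self.prior12h_: float = math.nan
        self.columns = list(model.X.columns)

    # --- prediction -----------------------------------------------------

    def predict_votes(self, X: pd.DataFrame, ages) -> np.ndarray:
        """Fraction of trees classifying each record as an event."""
        missing = [c for c in self.columns if c not in X.columns]
        extra = [c for c in X.columns if c not in self.columns]
        if missing or extra:
            raise ValueError(
                f"column schema mismatch: missing {missing}, unexpected {extra}")
        Xv = self.imputer.transform(X[self.columns],
                                    np.asarray(ages, float)).to_numpy(float)
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(Xv)
        return votes / len(self.trees)

    def predict_risk(self, X: pd.DataFrame, ages) -> pd.DataFrame:
        """Votes, relative risk and probability for new records."""
        return scale_risk(self.predict_votes(X, ages),
                          self.reference_mean_votes_, self.prior12h_)

    # --- interpretation -------------------------------------------------

    def marginal_profile(self, feature: str, grid=None,
                         n_points: int = 25) -> pd.DataFrame:
        """Risk profile: log odds of an event as one feature varies.

        All other features are held at their (training) median while
        ``feature`` sweeps its observed range; the predicted probability
        is converted to natural log odds ln(p / (1 - p)).
        """
        return marginal_profile(self, feature, grid=grid, n_points=n_points)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Unplanned intubation balanced-bootstrap random forest",
            "=" * 56,
            f"records:              {len(m.X)}",
            f"cases:                {int(m.y.sum())} "
            f"({100 * m.y.mean():.2f}%)",
            f"features (p):         {m.X.shape[1]}",
            f"trees:                {m.n_trees}",
            f"mtry (per split):     {m.mtry}",
            f"reference mean votes: {self.reference_mean_votes_:.4f}",
            f"12-h event prior:     {self.prior12h_:.4f}",
        ]
        return "\n".join(lines)


def marginal_profile(results: ForestResults, feature: str, grid=None,
                     n_points: int = 25) -> pd.DataFrame:
    """(feature value, log odds) pairs with other features at medians."""
    X = results.model.X
    if feature not in X.columns:
        raise KeyError(feature)
    med = results.imputer.global_medians
    if grid is None:
        col = X[feature].dropna()
        grid = np.linspace(col.min(), col.max(), n_points)
    grid = np.asarray(grid, dtype=float)
    probe = pd.DataFrame([med.to_dict()] * grid.size)
    probe[feature] = grid
    ages = probe["age_years"].to_numpy() if "age_years" in probe.columns \
        else np.full(grid.size, float(med.get("age_years", 1.0)))
    if feature == "age_years":
        ages = grid
    risk = results.predict_risk(probe[results.columns], ages)
    p = np.clip(risk["probability"].to_numpy(), 1e-12, 1 - 1e-12)
    return pd.DataFrame({feature: grid,
                         "log_odds": np.log(p / (1.0 - p)),
                         "probability": risk["probability"].to_numpy()})


def random_feature_screen(X: pd.DataFrame, y, ages, *, seed: int = 0,
                          n_repeats: int = 3,
                          n_trees: int = N_TREES_DEFAULT) -> pd.DataFrame:
    """Permutation-importance screen against an i.i.d. random feature.

    A uniform random column is appended, the forest refitted, and each
    feature's permutation importance (mean drop in training AUC over
    ``n_repeats`` shuffles) reported relative to the random feature's;
    features below the random feature are flagged as candidates for
    removal.
    """
    from .evaluate import auc as _auc

    rng = np.random.default_rng(seed)
    Xa = X.reset_index(drop=True).copy()
    Xa["_random_feature"] = rng.uniform(size=len(Xa))
    res = UnplannedIntubationForest(
        Xa, y, ages, n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1))
    ).fit()
    yb = np.asarray(y, dtype=bool)
    base = _auc(res.predict_votes(Xa, ages), yb)
    rows = []
    for col in Xa.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = Xa.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(base - _auc(res.predict_votes(Xp, ages), yb))
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    out = pd.DataFrame(rows).set_index("feature")
    random_imp = out.loc["_random_feature", "importance"]
    out["above_random"] = out["importance"] > random_imp
    out.loc["_random_feature", "above_random"] = False
    out["importance_vs_random"] = out["importance"] - random_imp
    return out.sort_values("importance", ascending=False)
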