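"""Site-state classification and responder/non-responder analysis.

A random forest is trained on baseline site measurements (clinical indices,
cytokines, MMPs and virulence factors) to classify gingival sites as
healthy, gingivitis or periodontitis.  Month-24 measurements are pushed
through the baseline-trained model, and each site's transition from its
recorded baseline category to its predicted month-24 state is mapped to a
responder / non-responder call: improvement (P->G, P->H, G->H) or staying
healthy (H->H) is a response; everything else is not.  Arms are compared on
the resulting 2x2 table with a continuity-corrected chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = [
    "SiteState",
    "StateModel",
    "ResponderTable",
    "train_state_model",
    "classify_transition",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "responder_analysis",
]


class SiteState(str, Enum):
    """Gingival site condition, ordered by severity."""

    HEALTHY = "healthy"
    GINGIVITIS = "gingivitis"
    PERIODONTITIS = "periodontitis"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]

    @classmethod
    def coerce(cls, value) -> "SiteState":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


_SEVERITY = {SiteState.HEALTHY: 0, SiteState.GINGIVITIS: 1, SiteState.PERIODONTITIS: 2}


@dataclass
class StateModel:
    """Baseline-trained site-state classifier with its importance filter."""

    classifier: RandomForestClassifier
    features: list[str]
    importance: pd.Series  # permutation mean decrease in accuracy, percent
    per_class_accuracy: dict[str, float]  # out-of-bag recall per true class
    seed: int

    def predict(self, features: pd.DataFrame) -> pd.Series:
        X = features[self.features].to_numpy(float)
        return pd.Series(self.classifier.predict(X), index=features.index)

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "n_trees": self.classifier.n_estimators,
            "features_kept": self.features,
            "importance_percent": {k: float(v) for k, v in self.importance.items()},
            "per_class_accuracy": self.per_class_accuracy,
        }


@dataclass
class ResponderTable:
    """Per-site transition calls plus the arm x call contingency table."""

    sites: pd.DataFrame  # arm, baseline_state, month24_state, call
    counts: pd.DataFrame  # 2x2: rows arms, cols responder/non_responder
    statistic: float
    p_value: float
    proportions: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.sites.to_csv(path, index=True)

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p_value,
            "proportions": self.proportions,
            "counts": {
                arm: {c: int(v) for c, v in row.items()}
                for arm, row in self.counts.iterrows()
            },
        }


def _oob_per_class_accuracy(
    clf: RandomForestClassifier, y: np.ndarray
) -> dict[str, float]:
    proba = clf.oob_decision_function_
    seen = ~np.isnan(proba).any(axis=1) & (proba.sum(axis=1) > 0)
    pred = clf.classes_[np.argmax(proba[seen], axis=1)]
    truth = y[seen]
    return {
        str(c): float(np.mean(pred[truth == c] == c)) for c in np.unique(truth)
    }


def train_state_model(
    features: pd.DataFrame,
    labels,
    n_trees: int = 400,
    seed: int = 12345,
    importance_min: float = 2.0,
    importance_repeats: int = 10,
) -> StateModel:
    """Random forest site-state model with permutation-importance filtering.

    The forest is fit once to measure permutation importance (mean decrease
    in accuracy, on a percent scale), then refit on the features whose
    importance is at least ``importance_min``.  Per-class accuracy is the
    out-of-bag recall of each true class.
    """
    y = np.asarray([SiteState.coerce(v).value for v in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("site-state model requires at least two classes")
    X = features.to_numpy(float)

    probe = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    ).fit(X, y)
    imp = permutation_importance(
        probe, X, y, n_repeats=importance_repeats, random_state=seed, n_jobs=1
    )
    importance = pd.Series(
        imp.importances_mean * 100.0, index=features.columns, name="importance"
    ).sort_values(ascending=False)
    kept = importance.index[importance >= importance_min].tolist()
    if not kept:
        raise ValueError("importance filter removed every feature")

    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    ).fit(features[kept].to_numpy(float), y)
    return StateModel(
        classifier=clf,
        features=kept,
        importance=importance,
        per_class_accuracy=_oob_per_class_accuracy(clf, y),
        seed=seed,
    )


_RESPONDER_TRANSITIONS = {
    (SiteState.PERIODONTITIS, SiteState.GINGIVITIS),
    (SiteState.PERIODONTITIS, SiteState.HEALTHY),
    (SiteState.GINGIVITIS, SiteState.HEALTHY),
    (SiteState.HEALTHY, SiteState.HEALTHY),
}


def classify_transition(baseline, month24) -> str:
    """Responder call from (baseline, month-24) states.

    Responder: improvement (P->G, P->H, G->H) or staying healthy (H->H).
    Non-responder: persistence of disease (P->P, G->G), worsening (G->P),
    or a healthy site deteriorating (H->G, H->P).
    """
    pair = (SiteState.coerce(baseline), SiteState.coerce(month24))
    return "responder" if pair in _RESPONDER_TRANSITIONS else "non_responder"


def chi_square_2x2(table) -> tuple[float, float]:
    """Yates continuity-corrected Pearson chi-square for a 2x2 table.

    The correction term |O - E| - 0.5 is floored at zero.  Returns
    (statistic, two-sided p) on 1 degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integers")
    rows, cols, N = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    expected = np.outer(rows, cols) / N
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def fisher_exact_2x2(table, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (within ``rel_tol``).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative integers")
    a = t[0, 0]
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    N = t.sum()
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = stats.hypergeom.pmf(a, N, r1, c1)
    return float(probs[probs <= p_obs * (1.0 + rel_tol)].sum())


def responder_analysis(
    model: StateModel,
    baseline_states,
    month24_features: pd.DataFrame,
    arms,
    arm_order: tuple[str, str] = ("regimen", "control"),
) -> ResponderTable:
    """End-to-end responder calling and arm comparison.

    ``baseline_states`` are the recorded baseline site categories (the model
    only re-states month 24); rows of ``month24_features`` align with them.
    """
    baseline = pd.Series(
        [SiteState.coerce(s).value for s in baseline_states],
        index=month24_features.index,
    )
    arms = pd.Series(list(arms), index=month24_features.index)
    predicted = model.predict(month24_features)
    calls = pd.Series(
        [classify_transition(b, m) for b, m in zip(baseline, predicted)],
        index=month24_features.index,
    )
    sites = pd.DataFrame(
        {
            "arm": arms,
            "baseline_state": baseline,
            "month24_state": predicted,
            "call": calls,
        }
    )
    counts = (
        sites.pivot_table(index="arm", columns="call", aggfunc="size", fill_value=0)
        .reindex(index=list(arm_order), columns=["responder", "non_responder"])
        .fillna(0)
        .astype(int)
    )
    statistic, p = chi_square_2x2(counts.to_numpy())
    proportions = {
        arm: float(counts.loc[arm, "responder"] / counts.loc[arm].sum())
        for arm in counts.index
    }
    return ResponderTable(sites, counts, statistic, p, proportions)
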