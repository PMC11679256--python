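"""Minimal Pawlak-style rough-set classifier.

Continuous attributes are discretised with boundary-midpoint cuts chosen
greedily to discern as many class-different object pairs as possible;
decision rules are then induced by sequential covering — a conjunction
of interval conditions is grown until the rule is class-pure on the
training data (or no condition improves it), the covered objects of the
target class are removed, and the process repeats.  Classification lets
all matching rules vote with weight ``support x accuracy``; an object
matched by no rule (or an exact vote tie) is an abstention, counted
against coverage.

The estimator validates the claim that interpretable threshold rules can
approach the accuracy of the parametric models on the same features; it
does not replicate any particular rule-induction software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

ABSTAIN = "ABSTAIN"


@dataclass(frozen=True)
class Cut:
    """A discretisation threshold on one attribute (strictly between two observed values)."""

    attribute: str
    threshold: float


@dataclass(frozen=True)
class Rule:
    """A conjunction of interval conditions implying a decision class.

    ``conditions`` maps attribute name to a half-open interval
    ``[lo, hi)`` (``-inf``/``+inf`` for unbounded sides).  ``support`` is
    the number of matching training objects and ``accuracy`` the
    fraction of them carrying the decision class.
    """

    conditions: Tuple[Tuple[str, float, float], ...]
    decision: str
    support: int
    accuracy: float

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("rule support must be >= 1")
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError("rule accuracy must lie in (0, 1]")

    def __str__(self) -> str:
        if not self.conditions:
            parts = ["TRUE"]
        else:
            parts = []
            for attr, lo, hi in self.conditions:
                if math.isinf(lo) and lo < 0:
                    parts.append(f"{attr} < {hi:g}")
                elif math.isinf(hi):
                    parts.append(f"{attr} >= {lo:g}")
                else:
                    parts.append(f"{lo:g} <= {attr} < {hi:g}")
        return f"IF {' AND '.join(parts)} THEN {self.decision} (support={self.support}, accuracy={self.accuracy:.2f})"


def candidate_cuts(values: np.ndarray, y: np.ndarray) -> List[float]:
    """Class-boundary midpoints: cuts between adjacent distinct values
    whose surrounding objects do not all share one class."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    labels = y[order]
    cuts: List[float] = []
    distinct = np.unique(v)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        left = set(labels[v == lo])
        right = set(labels[v == hi])
        if len(left | right) > 1:
            cuts.append(float((lo + hi) / 2.0))
    return cuts


def discretize(
    X: np.ndarray,
    y: np.ndarray,
    attributes: Sequence[str],
    max_cuts_per_attribute: Optional[int] = None,
) -> Tuple[List[Cut], int]:
    """Greedy discernibility-driven cut selection.

    Returns the selected cuts and the number of class-different object
    pairs that remain indiscernible (pairs identical on every attribute
    are inherently inconsistent and can never be discerned).
    """
    n, m = X.shape
    # All class-different pairs.
    ii, jj = np.triu_indices(n, k=1)
    diff = y[ii] != y[jj]
    pi, pj = ii[diff], jj[diff]
    undiscerned = np.ones(len(pi), dtype=bool)

    cand: List[Tuple[int, float]] = []
    for a in range(m):
        for t in candidate_cuts(X[:, a], y):
            cand.append((a, t))
    if not cand:
        return [], int(undiscerned.sum())

    # Pair-discernment matrix per candidate cut (cuts x pairs).
    disc = np.zeros((len(cand), len(pi)), dtype=bool)
    for k, (a, t) in enumerate(cand):
        left = X[:, a] < t
        disc[k] = left[pi] != left[pj]

    per_attr: Dict[int, int] = {a: 0 for a in range(m)}
    chosen: List[Cut] = []
    active = np.ones(len(cand), dtype=bool)
    while undiscerned.any() and active.any():
        gains = disc[:, undiscerned].sum(axis=1)
        gains[~active] = -1
        best = int(np.argmax(gains))  # ties: first candidate (attribute, then value order)
        if gains[best] <= 0:
            break
        a, t = cand[best]
        chosen.append(Cut(attributes[a], t))
        per_attr[a] += 1
        undiscerned &= ~disc[best]
        active[best] = False
        if max_cuts_per_attribute is not None and per_attr[a] >= max_cuts_per_attribute:
            for k, (aa, _) in enumerate(cand):
                if aa == a:
                    active[k] = False
    return chosen, int(undiscerned.sum())


def _bin_matrix(X: np.ndarray, attributes: Sequence[str], cuts: Sequence[Cut]) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Discretised bin index per object per attribute."""
    by_attr: Dict[str, np.ndarray] = {}
    for a in attributes:
        ts = np.sort([c.threshold for c in cuts if c.attribute == a])
        by_attr[a] = ts
    bins = np.zeros(X.shape, dtype=int)
    for j, a in enumerate(attributes):
        bins[:, j] = np.searchsorted(by_attr[a], X[:, j], side="right")
    return bins, by_attr


def induce_rules(
    bins: np.ndarray,
    y: np.ndarray,
    attributes: Sequence[str],
    thresholds: Dict[str, np.ndarray],
) -> List[Rule]:
    """Sequential covering over the discretised training table."""
    n, m = bins.shape
    rules: List[Rule] = []
    classes = list(dict.fromkeys(y))  # first-appearance order, deterministic
    for c in classes:
        uncovered = [i for i in range(n) if y[i] == c]
        while uncovered:
            seed = uncovered[0]
            matched = np.ones(n, dtype=bool)
            conds: Dict[int, int] = {}  # attr index -> bin
            avail = list(range(m))
            while True:
                pos = int((y[matched] == c).sum())
                tot = int(matched.sum())
                acc = pos / tot
                if acc == 1.0 and conds:
                    break
                best_key: Optional[Tuple[float, int]] = None
                best_a = -1
                best_mask = None
                for a in avail:
                    new_mask = matched & (bins[:, a] == bins[seed, a])
                    ntot = int(new_mask.sum())
                    npos = int((y[new_mask] == c).sum())
                    key = (npos / ntot, npos)
                    if best_key is None or key > best_key:
                        best_key, best_a, best_mask = key, a, new_mask
                if best_key is None or (conds and best_key[0] <= acc):
                    break
                conds[best_a] = int(bins[seed, best_a])
                matched = best_mask
                avail.remove(best_a)
                if not avail:
                    break
            tot = int(matched.sum())
            pos = int((y[matched] == c).sum())
            cond_tuple = []
            for a, b in sorted(conds.items()):
                ts = thresholds[attributes[a]]
                lo = float(ts[b - 1]) if b > 0 else -math.inf
                hi = float(ts[b]) if b < len(ts) else math.inf
                cond_tuple.append((attributes[a], lo, hi))
            rules.append(Rule(conditions=tuple(cond_tuple), decision=str(c), support=tot, accuracy=pos / tot))
            uncovered = [i for i in uncovered if not matched[i]]
    return rules


class RoughSetClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based rough-set classifier with abstention.

    Parameters
    ----------
    max_cuts_per_attribute :
        Discretisation budget per attribute (None = unlimited; cuts are
        added until every class-different pair is discerned).
    abstain_label :
        Label returned for objects matched by no rule or by an exact
        vote tie.

    Attributes
    ----------
    rules_ : list of Rule
    cuts_ : list of Cut
    inconsistent_pairs_ : int
        Class-different training pairs the selected cuts cannot discern.
    """

    def __init__(self, max_cuts_per_attribute: Optional[int] = None, abstain_label: str = ABSTAIN):
        self.max_cuts_per_attribute = max_cuts_per_attribute
        self.abstain_label = abstain_label

    def fit(self, X, y):
        X_arr, self.attributes_ = self._coerce(X)
        y_arr = np.asarray(y).astype(str)
        if len(X_arr) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y_arr)) < 2:
            raise ValueError("need at least two classes")
        self.classes_ = np.unique(y_arr)
        self.cuts_, self.inconsistent_pairs_ = discretize(
            X_arr, y_arr, self.attributes_, self.max_cuts_per_attribute
        )
        bins, self.thresholds_ = _bin_matrix(X_arr, self.attributes_, self.cuts_)
        self.rules_ = induce_rules(bins, y_arr, self.attributes_, self.thresholds_)
        return self

    def _coerce(self, X) -> Tuple[np.ndarray, List[str]]:
        if isinstance(X, pd.DataFrame):
            return np.asarray(X, dtype=float), [str(c) for c in X.columns]
        X_arr = np.asarray(X, dtype=float)
        names = getattr(self, "attributes_", None)
        return X_arr, names if names is not None else [f"x{j}" for j in range(X_arr.shape[1])]

    def _match_matrix(self, X_arr: np.ndarray) -> np.ndarray:
        """(n_samples, n_rules) boolean rule-match matrix."""
        bins, _ = _bin_matrix(X_arr, self.attributes_, self.cuts_)
        col = {a: j for j, a in enumerate(self.attributes_)}
        out = np.ones((len(X_arr), len(self.rules_)), dtype=bool)
        for r, rule in enumerate(self.rules_):
            for attr, lo, hi in rule.conditions:
                ts = self.thresholds_[attr]
                b = np.searchsorted(ts, [lo], side="right")[0] if not math.isinf(lo) else 0
                out[:, r] &= bins[:, col[attr]] == b
        return out

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rules_")
        X_arr, _ = self._coerce(X)
        match = self._match_matrix(X_arr)
        weights = np.array([r.support * r.accuracy for r in self.rules_])
        decisions = np.array([r.decision for r in self.rules_])
        out = np.empty(len(X_arr), dtype=object)
        for i in range(len(X_arr)):
            votes: Dict[str, float] = {}
            for r in np.flatnonzero(match[i]):
                votes[decisions[r]] = votes.get(decisions[r], 0.0) + weights[r]
            if not votes:
                out[i] = self.abstain_label
                continue
            ranked = sorted(votes.items(), key=lambda kv: -kv[1])
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                out[i] = self.abstain_label  # exact tie -> abstain
            else:
                out[i] = ranked[0][0]
        return out

    def coverage(self, X) -> float:
        """Fraction of objects matched by at least one rule."""
        check_is_fitted(self, "rules_")
        X_arr, _ = self._coerce(X)
        return float(self._match_matrix(X_arr).any(axis=1).mean())

    def report(self, X, y) -> Dict[str, object]:
        """Accuracy, per-class true-positive rates, coverage, rule count.

        Abstentions count as misclassifications in the overall accuracy.
        """
        y_arr = np.asarray(y).astype(str)
        pred = self.predict(X)
        acc = float((pred == y_arr).mean())
        tpr = {
            str(c): float((pred[y_arr == c] == c).mean()) if (y_arr == c).any() else float("nan")
            for c in self.classes_
        }
        return {
            "accuracy": acc,
            "tpr": tpr,
            "coverage": self.coverage(X),
            "n_rules": len(self.rules_),
            "n_abstained": int((pred == self.abstain_label).sum()),
        }

    def rules_text(self) -> str:
        check_is_fitted(self, "rules_")
        return "\n".join(str(r) for r in self.rules_)


def rough_classify(clf: RoughSetClassifier, X) -> np.ndarray:
    """Functional alias for :meth:`RoughSetClassifier.predict`."""
    return clf.predict(X)
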