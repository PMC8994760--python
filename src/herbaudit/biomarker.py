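"""Manufacturer-discriminating marker selection and the MEI score.

Candidate markers are screened by a Kruskal-Wallis test combined with a
one-dimensional linear-discriminant effect size (a deliberately simplified
single-factor variant of the LEfSe procedure), reduced by a greedy
mutual-information mRMR step, scored per sample as

    MEI = sum of group-A marker relative abundances
          / sum of group-B marker relative abundances

and pruned by per-marker ROC AUC (markers with AUC < 0.5 are dropped).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

__all__ = [
    "MarkerPanel",
    "MeiResult",
    "RocResult",
    "differential_screen",
    "mrmr_select",
    "mei_score",
    "mei_scores",
    "roc_auc",
    "prune_markers",
]

#: LEfSe-style abundance scale: relative abundances are mapped to [0, 1e6]
#: before the log10 effect size is taken.
_EFFECT_SCALE = 1e6
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class MarkerPanel:
    """Disjoint marker lists for the two groups, with provenance."""

    group_a_markers: tuple[str, ...]
    group_b_markers: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.group_a_markers) & set(self.group_b_markers)
        if overlap:
            raise ValueError(f"markers in both groups: {sorted(overlap)}")


@dataclass(frozen=True)
class MeiResult:
    """MEI score of one sample (always positive and finite)."""

    score: float
    epsilon: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.score > 0 and math.isfinite(self.score)):
            raise ValueError(f"MEI score must be positive and finite: {self.score}")


@dataclass(frozen=True)
class RocResult:
    """AUC plus accuracy/F1 at the Youden-optimal threshold."""

    auc: float
    thresholds: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    optimal_threshold: float
    accuracy: float
    f1: float


def differential_screen(
    table: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
) -> dict[str, list[str]]:
    """Screen species that differ between the two label groups.

    A species is a candidate when its Kruskal-Wallis p-value is below
    *alpha* AND its one-dimensional effect size
    ``log10(|mean difference| * 1e6)`` reaches *lda_cutoff*.  Candidates are
    tagged by the group with the higher mean.  Returns
    ``{group_label: [species, ...], ...}`` for both groups.
    """
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    mask_a = labels == groups[0]
    if mask_a.all() or (~mask_a).all():
        raise ValueError("one group is empty")
    selected: dict[str, list[str]] = {groups[0]: [], groups[1]: []}
    for species in table.columns:
        xa = table.loc[mask_a, species].to_numpy(dtype=float)
        xb = table.loc[~mask_a, species].to_numpy(dtype=float)
        diff = float(xa.mean() - xb.mean())
        effect = math.log10(max(abs(diff) * _EFFECT_SCALE, 1.0))
        if effect < lda_cutoff:
            continue
        try:
            _, pval = stats.kruskal(xa, xb)
        except ValueError:  # all values identical
            continue
        if pval >= alpha:
            continue
        selected[groups[0] if diff > 0 else groups[1]].append(species)
    return selected


def _discretize(values: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency binning (ties collapse bins; constant -> one bin)."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(values, edges, right=True)


def mrmr_select(
    candidates: Sequence[str],
    table: pd.DataFrame,
    labels: Sequence[str],
    k: int,
) -> list[str]:
    """Greedy mRMR (MID variant): relevance minus mean redundancy.

    Mutual information is computed on equal-frequency 3-bin discretized
    abundances.  Deterministic given input order (score ties fall back to
    candidate order).  Returns a ranked list of at most *k* features.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        raise ValueError("no candidate features")
    labels = np.asarray(labels)
    disc = {
        f: _discretize(table[f].to_numpy(dtype=float)) for f in candidates
    }
    relevance = {f: mutual_info_score(labels, disc[f]) for f in candidates}

    ranked: list[str] = []
    remaining = list(candidates)
    redundancy_cache: dict[tuple[str, str], float] = {}

    def redundancy(f: str, g: str) -> float:
        key = (f, g) if f <= g else (g, f)
        if key not in redundancy_cache:
            redundancy_cache[key] = mutual_info_score(disc[f], disc[g])
        return redundancy_cache[key]

    while remaining and len(ranked) < k:
        if not ranked:
            scores = {f: relevance[f] for f in remaining}
        else:
            scores = {
                f: relevance[f] - np.mean([redundancy(f, g) for g in ranked])
                for f in remaining
            }
        best = max(remaining, key=lambda f: (scores[f], -remaining.index(f)))
        ranked.append(best)
        remaining.remove(best)
    return ranked


def mei_score(
    rel_abundances: Union[Mapping[str, float], pd.Series],
    panel: MarkerPanel,
    epsilon: float = DEFAULT_EPSILON,
) -> MeiResult:
    """Ratio of summed group-A to summed group-B marker relative abundances.

    A zero denominator is replaced by *epsilon*; if both sums are zero the
    score is 1.0 and flagged degenerate.
    """
    if not panel.group_a_markers or not panel.group_b_markers:
        raise ValueError("both panel sides must be non-empty")
    get = rel_abundances.get if hasattr(rel_abundances, "get") else rel_abundances.__getitem__
    a_sum = float(sum(get(m, 0.0) for m in panel.group_a_markers))
    b_sum = float(sum(get(m, 0.0) for m in panel.group_b_markers))
    if a_sum == 0.0 and b_sum == 0.0:
        return MeiResult(score=1.0, epsilon=epsilon, degenerate=True)
    return MeiResult(
        score=max(a_sum, epsilon) / max(b_sum, epsilon), epsilon=epsilon
    )


def mei_scores(
    table: pd.DataFrame, panel: MarkerPanel, epsilon: float = DEFAULT_EPSILON
) -> pd.Series:
    """Per-sample MEI scores for a samples x species abundance table."""
    return pd.Series(
        {sid: mei_score(table.loc[sid], panel, epsilon).score for sid in table.index},
        name="mei_score",
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC analysis of scores against binary labels (True = positive).

    AUC uses the rank (Mann-Whitney) formulation with midranks for ties;
    accuracy and F1 are evaluated at the Youden-optimal threshold
    (predict positive when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(scores)[::-1]
    tpr, fpr = [], []
    for t in thresholds:
        pred = scores >= t
        tpr.append(float((pred & y).sum() / n_pos))
        fpr.append(float((pred & ~y).sum() / n_neg))
    youden = np.asarray(tpr) - np.asarray(fpr)
    best = int(np.argmax(youden))
    opt = float(thresholds[best])
    pred = scores >= opt
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    accuracy = float((pred == y).mean())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return RocResult(
        auc=float(auc),
        thresholds=tuple(float(t) for t in thresholds),
        tpr=tuple(tpr),
        fpr=tuple(fpr),
        optimal_threshold=opt,
        accuracy=accuracy,
        f1=float(f1),
    )


def prune_markers(
    panel: MarkerPanel,
    table: pd.DataFrame,
    labels: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
) -> MarkerPanel:
    """Drop markers whose single-marker MEI has ROC AUC < 0.5.

    Each marker is evaluated alone against the full opposing panel, with its
    own group as the positive class.  Strict inequality: AUC of exactly 0.5
    is retained.  Raises when pruning would empty a side.
    """
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")

    removed: list[str] = []

    def keep(marker: str, own_side_a: bool) -> bool:
        if own_side_a:
            single = MarkerPanel((marker,), panel.group_b_markers)
            positive = labels == groups[0]
        else:
            single = MarkerPanel((marker,), panel.group_a_markers)
            positive = labels == groups[1]
        scores = mei_scores(table, single, epsilon)
        auc = roc_auc(scores.to_numpy(), positive).auc
        if auc < 0.5:
            removed.append(marker)
            return False
        return True

    new_a = tuple(m for m in panel.group_a_markers if keep(m, True))
    new_b = tuple(m for m in panel.group_b_markers if keep(m, False))
    if not new_a or not new_b:
        raise ValueError(
            "pruning emptied one panel side; re-run the differential screen "
            f"(removed: {removed})"
        )
    provenance = dict(panel.provenance)
    provenance["pruned_markers"] = removed
    return MarkerPanel(new_a, new_b, provenance)
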