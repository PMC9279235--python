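"""AUC comparison statistics: bootstrap CIs and paired permutation tests.

``auc`` is the Mann-Whitney probability that a random positive outranks a
random negative, with midrank tie handling (identical to the trapezoidal
ROC area).  Two scorers evaluated on the same nodules are compared by

* a percentile bootstrap of the AUC difference — groups (participants by
  default, since nodules within a participant are correlated) are drawn
  with replacement, both AUCs recomputed per draw, and the 2.5/97.5
  percentiles of the difference distribution reported; and
* a two-sided paired permutation test — under the null that the two
  scorers are exchangeable, each nodule's (a, b) score pair is swapped
  independently with probability 1/2 per resampling, and the add-one
  estimator ``p = (1 + #{|null diff| >= |observed|}) / (n_perm + 1)``
  is reported, so p is never zero and never below ``1/(n_perm+1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ModelComparison",
    "auc",
    "bootstrap_auc_difference",
    "permutation_test_auc",
    "compare_scores",
    "subgroup_compare",
    "roc_points",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelComparison:
    """Paired AUCs, bootstrap CI of their difference, and permutation p."""

    auc_a: float
    auc_b: float
    diff: float
    ci95: tuple[float, float]
    p_value: float
    n_boot: int
    n_perm: int
    resampling_unit: str
    n: int
    n_redraws: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(d["ci95"])
        return d


def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; AUC is undefined")


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank ties (= trapezoidal ROC area)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in shape")
    _check_labels(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auc_rows(scores_2d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (m, n) score matrix against one label vector."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores_2d, axis=1)
    return (ranks[:, labels == 1].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_auc_difference(
    scores_a,
    scores_b,
    labels,
    group_ids=None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], int]:
    """Observed AUC difference and its 95% percentile-bootstrap CI.

    Draws resample whole groups (participants) with replacement; with
    ``group_ids=None`` each nodule is its own group.  Single-class
    resamples are redrawn and counted.  Returns
    ``(diff, (lo, hi), n_redraws)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired scores and labels must be aligned")
    _check_labels(y)
    gid = np.arange(len(y)) if group_ids is None else np.asarray(group_ids)
    uniq, inv = np.unique(gid, return_inverse=True)
    members = [np.flatnonzero(inv == g) for g in range(len(uniq))]

    observed = auc(a, y) - auc(b, y)
    if np.array_equal(a, b):
        return 0.0, (0.0, 0.0), 0

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n_redraws = 0
    for i in range(n_boot):
        while True:
            draw = rng.integers(0, len(uniq), size=len(uniq))
            idx = np.concatenate([members[g] for g in draw])
            if 0 < y[idx].sum() < len(idx):
                break
            n_redraws += 1
        diffs[i] = auc(a[idx], y[idx]) - auc(b[idx], y[idx])
    if n_redraws:
        logger.info("bootstrap redrew %d single-class resamples", n_redraws)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return float(observed), (float(lo), float(hi)), n_redraws


def permutation_test_auc(scores_a, scores_b, labels, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided paired permutation p-value for the AUC difference.

    Each resampling swaps every nodule's (a, b) pair independently with
    probability 1/2, which respects exchangeability of the two scorers on
    the same nodules under the null.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired scores and labels must be aligned")
    _check_labels(y)
    observed = abs(auc(a, y) - auc(b, y))

    rng = np.random.default_rng(seed)
    # chunked so rank matrices stay modest in memory
    chunk = max(1, int(5_000_000 // max(len(y), 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        swap = rng.random((m, len(y))) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        null = _auc_rows(pa, y) - _auc_rows(pb, y)
        exceed += int((np.abs(null) >= observed - 1e-12).sum())
        done += m
    return float((1 + exceed) / (n_perm + 1))


def compare_scores(
    scores_a,
    scores_b,
    labels,
    group_ids=None,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int = 0,
    resampling_unit: str = "participant",
) -> ModelComparison:
    """Full paired comparison of two scorers on the same labelled nodules."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if resampling_unit == "nodule":
        group_ids = None
    diff, ci, n_redraws = bootstrap_auc_difference(a, b, y, group_ids, n_boot, seed)
    if np.array_equal(a, b):
        p = 1.0
    else:
        p = permutation_test_auc(a, b, y, n_perm, seed + 1)
    return ModelComparison(
        auc_a=auc(a, y),
        auc_b=auc(b, y),
        diff=diff,
        ci95=ci,
        p_value=p,
        n_boot=n_boot,
        n_perm=n_perm,
        resampling_unit=resampling_unit if group_ids is not None or resampling_unit == "nodule" else "nodule",
        n=len(y),
        n_redraws=n_redraws,
    )


def subgroup_compare(
    score_table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    stratifier: str = "nodule_type",
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, ModelComparison]:
    """Run the comparison machinery independently per stratum.

    ``score_table`` is a long-format ScoreTable (one row per nodule per
    condition, columns ``participant_id, nodule_id, condition, score,
    label`` plus the stratifier).  Strata whose labels are single-class
    are skipped with a warning.
    """
    if stratifier not in score_table.columns:
        raise KeyError(f"stratifier column {stratifier!r} missing from the score table")
    out: dict[str, ModelComparison] = {}
    for stratum, sub in score_table.groupby(stratifier, sort=True):
        wide = sub.pivot_table(
            index=["participant_id", "nodule_id", "label"], columns="condition", values="score"
        ).reset_index()
        if condition_a not in wide or condition_b not in wide:
            logger.warning("stratum %r lacks both conditions; skipped", stratum)
            continue
        y = wide["label"].to_numpy()
        if len(np.unique(y)) < 2 or len(wide) == 0:
            logger.warning("stratum %r has single-class labels; skipped", stratum)
            continue
        out[str(stratum)] = compare_scores(
            wide[condition_a].to_numpy(),
            wide[condition_b].to_numpy(),
            y,
            group_ids=wide["participant_id"].to_numpy(),
            n_boot=n_boot,
            n_perm=n_perm,
            seed=seed,
        )
    return out


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (false/true positive rates) for CSV export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
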