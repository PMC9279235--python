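"""A lightweight trainable risk scorer for ablated and unablated patches.

This is a deliberately simple stand-in for a 3D CNN: a fixed, deterministic
featurization of each patch (intensity, gradient, thresholded-component
shape, and radial-profile descriptors — computed without any access to the
ground-truth mask or label) followed by an L2-regularized logistic
regression.  It is evaluated under a grouped k-fold protocol: participants
are stratified into k groups; fold i trains on k-2 groups, selects the
regularization strength on one validation group, and scores the held-out
test group, so every participant is scored out-of-fold exactly once.  For
k = 8 this gives the 6/8 : 1/8 : 1/8 train/validation/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .grids import CTVolume
from .stats import auc

__all__ = ["FoldPlan", "make_folds", "featurize", "FEATURE_NAMES", "fit_and_score"]

#: HU threshold separating nodule-like tissue (solid core, sub-solid
#: shell, implanted spheres) from aerated-lung background.
COMPONENT_THRESHOLD_HU = -650.0

#: HU threshold below which a voxel counts as emphysema-like low density.
LOW_DENSITY_HU = -920.0

C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class FoldPlan:
    """A partition of participants into k groups and the per-fold roles.

    ``groups`` maps participant id -> group index.  Fold i uses group i as
    test, group (i+1) mod k as validation, and the remaining k-2 groups as
    training, so each participant is in the test partition of exactly one
    fold.
    """

    k: int
    groups: dict

    def roles(self, fold: int) -> tuple[list[int], list[int], list[int]]:
        """(train, validation, test) group indices of one fold."""
        test = [fold]
        val = [(fold + 1) % self.k]
        train = [g for g in range(self.k) if g not in test + val]
        return train, val, test

    def participant_role(self, fold: int) -> dict:
        """participant id -> 'train' | 'validation' | 'test' for one fold."""
        train, val, test = self.roles(fold)
        out = {}
        for pid, g in self.groups.items():
            out[pid] = "test" if g in test else "validation" if g in val else "train"
        return out


def make_folds(participant_ids, participant_labels, k: int = 8, seed: int = 0) -> FoldPlan:
    """Stratified assignment of participants into k groups.

    Participants are shuffled within each label class and dealt
    round-robin across groups, giving each group an approximately equal
    share of malignant-nodule participants.
    """
    ids = np.asarray(list(participant_ids))
    labels = np.asarray(list(participant_labels)).astype(int)
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    if k < 3:
        raise ValueError(f"k must be at least 3 (train/validation/test need distinct groups), got {k}")
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(
                f"need at least k={k} participants with label {cls}, "
                f"got {(labels == cls).sum()}"
            )
    rng = np.random.default_rng(seed)
    groups: dict = {}
    offset = 0
    for cls in (1, 0):
        members = ids[labels == cls]
        members = members[rng.permutation(len(members))]
        for i, pid in enumerate(members):
            groups[pid] = (i + offset) % k
        # continue dealing where the previous class stopped, keeping sizes even
        offset = (offset + len(members)) % k
    return FoldPlan(k=k, groups=groups)


_RADIAL_CACHE: dict = {}


def _radial_bins(shape: tuple, spacing: tuple, n_bins: int = 5):
    """Cached shell-membership index arrays for a patch geometry."""
    key = (shape, spacing, n_bins)
    if key not in _RADIAL_CACHE:
        sh = np.asarray(shape)
        center = (sh - 1) / 2.0
        grids = np.meshgrid(*(np.arange(n) for n in sh), indexing="ij")
        dist = np.sqrt(sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing)))
        edges = np.linspace(0.0, float(dist.max()) + 1e-9, n_bins + 1)
        _RADIAL_CACHE[key] = [
            (dist >= edges[b]) & (dist < edges[b + 1]) for b in range(n_bins)
        ]
    return _RADIAL_CACHE[key]


def _radial_profile(values: np.ndarray, spacing: np.ndarray, n_bins: int = 5) -> np.ndarray:
    shells = _radial_bins(values.shape, tuple(spacing), n_bins)
    return np.array([values[sel].mean() if sel.any() else 0.0 for sel in shells])


FEATURE_NAMES = (
    ["hu_mean", "hu_std", "grad_mean", "grad_std", "grad_p95"]
    + [f"hu_q{q}" for q in (1, 5, 25, 50, 75, 95, 99)]
    + ["low_density_fraction", "low_density_mean_excess"]
    + [
        "comp_volume_mm3",
        "comp_esd_proxy_mm",
        "comp_max_slice_extent_mm",
        "comp_surface_to_volume",
        "comp_mean_hu",
        "comp_std_hu",
        "comp_spike_count",
        "comp_fill_fraction",
    ]
    + [f"radial_mean_{b}" for b in range(5)]
)


def featurize(patch: CTVolume) -> np.ndarray:
    """Deterministic feature vector of one cubic patch (no mask access).

    Blocks: intensity moments and quantiles; gradient-magnitude
    statistics; low-density (emphysema-like) occupancy; size/shape
    descriptors of the largest component above a tissue threshold,
    including a morphological spike count; and a 5-bin radial
    mean-intensity profile around the patch centre.
    """
    extent = np.asarray(patch.shape) * np.asarray(patch.spacing_mm)
    if np.ptp(extent) > max(patch.spacing_mm):
        raise ValueError(f"featurize expects a cubic patch, got extents {extent.tolist()} mm")
    v = patch.values.astype(float)
    spacing = np.asarray(patch.spacing_mm)
    vv = float(np.prod(spacing))

    feats = [v.mean(), v.std()]
    if v.std() > 0:
        gx, gy, gz = np.gradient(v, *spacing)
        gmag = np.sqrt(gx**2 + gy**2 + gz**2)
        feats += [gmag.mean(), gmag.std(), float(np.percentile(gmag, 95))]
    else:
        feats += [0.0, 0.0, 0.0]
    feats += list(np.percentile(v, [1, 5, 25, 50, 75, 95, 99]))

    low = v < LOW_DENSITY_HU
    feats.append(low.mean())
    feats.append(float((LOW_DENSITY_HU - v[low]).mean()) if low.any() else 0.0)

    tissue = v > COMPONENT_THRESHOLD_HU
    labels, n = ndimage.label(tissue, structure=np.ones((3, 3, 3), dtype=bool))
    if n:
        sizes = ndimage.sum_labels(tissue, labels, index=np.arange(1, n + 1))
        comp = labels == (1 + int(np.argmax(sizes)))
        n_vox = int(comp.sum())
        vol = n_vox * vv
        esd_proxy = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        # per-slice in-plane extent (bounding-box diagonal), max over slices
        max_extent = 0.0
        for kz in range(comp.shape[2]):
            sl = comp[:, :, kz]
            if sl.any():
                ii, jj = np.nonzero(sl)
                ex = np.hypot((ii.max() - ii.min() + 1) * spacing[0], (jj.max() - jj.min() + 1) * spacing[1])
                max_extent = max(max_extent, float(ex))
        eroded = ndimage.binary_erosion(comp)
        surface = int(comp.sum() - eroded.sum())
        s2v = surface / n_vox
        # spikes: what a small opening removes, counted as residue pieces
        opened = ndimage.binary_opening(comp, structure=ndimage.generate_binary_structure(3, 1), iterations=1)
        _, n_res = ndimage.label(comp & ~opened, structure=np.ones((3, 3, 3), dtype=bool))
        feats += [vol, esd_proxy, max_extent, s2v, v[comp].mean(), v[comp].std(),
                  float(n_res), n_vox / comp.size]
    else:
        feats += [0.0] * 8

    feats += list(_radial_profile(v, spacing))
    out = np.asarray(feats, dtype=float)
    assert out.shape == (len(FEATURE_NAMES),)
    return out


def _select_and_fit(X_tr, y_tr, X_val, y_val, seed: int) -> LogisticRegression:
    """Fit at each C on the training block; keep the best validation AUC."""
    best_model, best_auc = None, -np.inf
    for c in C_GRID:
        model = LogisticRegression(C=c, max_iter=2000, random_state=seed)
        model.fit(X_tr, y_tr)
        if len(np.unique(y_val)) < 2:
            val_auc = 0.0 if c != 1.0 else 1.0  # degenerate validation: default to C=1
        else:
            val_auc = auc(model.predict_proba(X_val)[:, 1], y_val)
        if val_auc > best_auc:
            best_model, best_auc = model, val_auc
    assert best_model is not None
    return best_model


def fit_and_score(
    cohort: pd.DataFrame,
    features_by_condition: dict[str, np.ndarray],
    plan: FoldPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold malignancy scores per nodule per condition (ScoreTable).

    ``cohort`` has one row per nodule with ``participant_id``,
    ``nodule_id``, ``malignant`` (and optionally ``nodule_type`` for
    subgroup analysis); ``features_by_condition[mode]`` is the aligned
    (n_nodules, n_features) matrix for one ablation condition.  One model
    per fold per condition is trained independently; the k test blocks
    are concatenated into a single cross-validation ScoreTable with
    exactly one out-of-fold score per nodule per condition.
    """
    y = cohort["malignant"].to_numpy().astype(int)
    pids = cohort["participant_id"].to_numpy()
    frames = []
    for condition, X in features_by_condition.items():
        if len(X) != len(cohort):
            raise ValueError(f"feature matrix for {condition!r} is misaligned with the cohort")
        scores = np.full(len(cohort), np.nan)
        for fold in range(plan.k):
            role = plan.participant_role(fold)
            tr = np.array([role[p] == "train" for p in pids])
            va = np.array([role[p] == "validation" for p in pids])
            te = np.array([role[p] == "test" for p in pids])
            if len(np.unique(y[tr])) < 2:
                raise ValueError(f"fold {fold}: training labels are single-class")
            scaler = StandardScaler().fit(X[tr])
            model = _select_and_fit(
                scaler.transform(X[tr]), y[tr], scaler.transform(X[va]), y[va], seed
            )
            scores[te] = model.predict_proba(scaler.transform(X[te]))[:, 1]
        assert not np.isnan(scores).any(), "every nodule must be scored out-of-fold once"
        frame = pd.DataFrame(
            {
                "participant_id": pids,
                "nodule_id": cohort["nodule_id"].to_numpy(),
                "condition": condition,
                "score": scores,
                "label": y,
            }
        )
        if "nodule_type" in cohort:
            frame["nodule_type"] = cohort["nodule_type"].to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
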