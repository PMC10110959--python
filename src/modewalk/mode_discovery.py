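"""Hybrid unsupervised/supervised discovery of migration modes.

The kernel works in two stages on the five per-segment features:

1. **K-means pseudo-labeling.**  Features are z-scored per column (they
   span different units and orders of magnitude and K-means is
   scale-sensitive), the cluster count is chosen by scanning the mean
   silhouette score over a range of k, and the winning K-means assignment
   becomes the pseudo-label of every segment.

2. **Boosted-tree classification.**  An XGBoost classifier is trained on
   a random subset of pseudo-labeled segments with a small cross-validated
   hyperparameter grid; held-out agreement with the pseudo-labels and
   per-feature importances are recorded.  The trained classifier then
   annotates arbitrary (unsegmented) trajectories window by window.

The silhouette here follows the within-cluster mean distance D_W(i)
averaged over *all* members of i's cluster including i itself (d(i,i)=0),
which differs from the |C|-1 normalization common in libraries; the
neighbor distance D_D(i) is the minimum over other clusters of the mean
distance to their members, and s(i) = (D_D - D_W) / max(D_W, D_D).

When k = 3 the clusters are named by their summary statistics: highest
mean energy -> FP; of the remaining two, higher mean asphericity -> SP,
lower -> SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import GridSearchCV

from .errors import (
    AmbiguousNamingError,
    ClusteringError,
    ModelIOError,
    SizeError,
    StratificationError,
    UndefinedScoreError,
)
from .features import FEATURE_NAMES, feature_matrix
from .preprocess import segment_trajectory
from .tracks_io import Trajectory

MODEL_FORMAT = "modewalk-mode-model/1"

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100, 300],
}


@dataclass
class SilhouetteDiagnostics:
    """Per-point silhouette decomposition: D_W, D_D, s(i) and their mean."""

    d_within: np.ndarray
    d_neighbor: np.ndarray
    scores: np.ndarray
    mean_score: float


@dataclass
class ModeSequence:
    """Ordered per-window mode labels of one trajectory."""

    track_id: str
    windows: list[tuple[float, float, str]]

    @property
    def modes(self) -> list[str]:
        return [m for _, _, m in self.windows]

    def __len__(self) -> int:
        return len(self.windows)


def silhouette(points: np.ndarray, labels: np.ndarray) -> SilhouetteDiagnostics:
    """Silhouette decomposition with the self-inclusive D_W normalization."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise UndefinedScoreError("silhouette undefined for a single cluster")
    dist = cdist(points, points)
    n = points.shape[0]
    d_within = np.empty(n)
    d_neighbor = np.empty(n)
    members = {c: labels == c for c in clusters}
    for i in range(n):
        own = labels[i]
        d_within[i] = dist[i, members[own]].mean()  # includes d(i, i) = 0
        d_neighbor[i] = min(dist[i, members[c]].mean() for c in clusters if c != own)
    denom = np.maximum(d_within, d_neighbor)
    scores = np.where(denom > 0, (d_neighbor - d_within) / np.where(denom > 0, denom, 1.0), 0.0)
    return SilhouetteDiagnostics(d_within=d_within, d_neighbor=d_neighbor,
                                 scores=scores, mean_score=float(scores.mean()))


def _standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = features.mean(axis=0)
    scale = features.std(axis=0)
    if np.any(scale == 0):
        raise ClusteringError("a feature column is constant; clustering is degenerate")
    return (features - center) / scale, center, scale


def scan_cluster_count(
    features: np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[dict[int, float], int]:
    """Mean silhouette per k over K-means fits; returns (scores, argmax k)."""
    features = np.asarray(features, dtype=float)
    ks = list(k_range)
    if features.shape[0] < max(ks) + 1:
        raise SizeError("need at least max(k_range)+1 points")
    z, _, _ = _standardize(features)
    scores: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(z)
        scores[k] = silhouette(z, labels).mean_score
    best = max(scores, key=scores.get)
    return scores, best


@dataclass
class ModeModel:
    """Fitted mode model: scaling + K-means centers + XGBoost classifier."""

    k: int
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    cluster_centers: np.ndarray  # in scaled space
    booster: xgb.Booster = field(repr=False)
    feature_importances: np.ndarray
    naming: dict[int, str] | None
    seed: int
    train_fraction: float
    train_count: int
    heldout_agreement: float
    train_agreement: float
    best_params: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------
    def _scale(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.center) / self.scale

    def predict_clusters(self, features: np.ndarray) -> np.ndarray:
        """Cluster indices predicted by the boosted classifier."""
        z = self._scale(np.atleast_2d(features))
        raw = self.booster.predict(xgb.DMatrix(z))
        if raw.ndim == 2:  # multi:softprob
            return raw.argmax(axis=1).astype(int)
        if self.k == 2:  # binary:logistic gives P(class 1)
            return (raw > 0.5).astype(int)
        return raw.astype(int)

    def predict_modes(self, features: np.ndarray) -> list[str]:
        if self.naming is None:
            raise AmbiguousNamingError("model has no cluster-to-mode naming map")
        return [self.naming[int(c)] for c in self.predict_clusters(features)]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "k": self.k,
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "cluster_centers": self.cluster_centers.tolist(),
            "feature_importances": self.feature_importances.tolist(),
            "naming": {str(c): m for c, m in self.naming.items()} if self.naming else None,
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "train_count": self.train_count,
            "heldout_agreement": self.heldout_agreement,
            "train_agreement": self.train_agreement,
            "best_params": self.best_params,
            "booster": json.loads(self.booster.save_raw(raw_format="json")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModeModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT:
            raise ModelIOError(
                f"unsupported model format {payload.get('format')!r}; "
                f"expected {MODEL_FORMAT!r}")
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        naming = payload["naming"]
        return cls(
            k=int(payload["k"]),
            feature_names=tuple(payload["feature_names"]),
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            cluster_centers=np.asarray(payload["cluster_centers"], dtype=float),
            booster=booster,
            feature_importances=np.asarray(payload["feature_importances"], dtype=float),
            naming={int(c): m for c, m in naming.items()} if naming else None,
            seed=int(payload["seed"]),
            train_fraction=float(payload["train_fraction"]),
            train_count=int(payload["train_count"]),
            heldout_agreement=float(payload["heldout_agreement"]),
            train_agreement=float(payload["train_agreement"]),
            best_params=payload.get("best_params", {}),
        )


def _gain_importances(booster: xgb.Booster, n_features: int) -> np.ndarray:
    imp = booster.get_score(importance_type="gain")
    out = np.zeros(n_features)
    for key, val in imp.items():
        out[int(key.lstrip("f"))] = val
    total = out.sum()
    return out / total if total > 0 else out


def fit_modes(
    features: np.ndarray,
    k: int,
    train_fraction: float = 0.366,
    train_count: int | None = None,
    seed: int = 0,
    grid: Mapping[str, list] | None = None,
    cv: int = 5,
    n_init: int = 10,
) -> ModeModel:
    """Fit the full hybrid kernel at a given cluster count.

    Standardizes features, K-means clusters them into pseudo-labels,
    randomly splits segments into a training subset (by ``train_count``
    when given, else by ``train_fraction``) and a held-out remainder,
    grid-searches the boosted classifier with ``cv``-fold cross-validation
    and records held-out/train agreement with the pseudo-labels plus
    normalized gain importances.

    The split is unstratified unless that would leave a pseudo-class
    empty, in which case a stratified split is drawn instead; if even that
    is impossible a :class:`StratificationError` is raised.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    z, center, scale = _standardize(features)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    pseudo = km.fit_predict(z)

    n_train = int(train_count) if train_count is not None else int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise SizeError("training split must be a non-empty strict subset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx, test_idx = order[:n_train], order[n_train:]
    if len(set(pseudo[train_idx])) < k:
        # redraw stratified: proportional take per pseudo-class
        train_parts = []
        for c in range(k):
            idx_c = rng.permutation(np.nonzero(pseudo == c)[0])
            take = max(1, int(round(n_train * idx_c.size / n)))
            if idx_c.size == 0:
                raise StratificationError(f"pseudo-class {c} is empty")
            train_parts.append(idx_c[:take])
        train_idx = np.concatenate(train_parts)
        test_idx = np.setdiff1d(order, train_idx)
        if len(set(pseudo[train_idx])) < k:
            raise StratificationError("a pseudo-class is absent from the training split")

    search = GridSearchCV(
        # "exact" places split thresholds midway between neighboring feature
        # values, which generalizes cleanly across wide inter-cluster gaps
        xgb.XGBClassifier(tree_method="exact", n_jobs=1, random_state=seed),
        param_grid=dict(grid if grid is not None else DEFAULT_GRID),
        cv=cv,
        n_jobs=1,
    )
    search.fit(z[train_idx], pseudo[train_idx])
    clf = search.best_estimator_
    booster = clf.get_booster()

    train_agree = float((clf.predict(z[train_idx]) == pseudo[train_idx]).mean())
    heldout_agree = float((clf.predict(z[test_idx]) == pseudo[test_idx]).mean())

    model = ModeModel(
        k=k,
        feature_names=FEATURE_NAMES,
        center=center,
        scale=scale,
        cluster_centers=km.cluster_centers_,
        booster=booster,
        feature_importances=_gain_importances(booster, features.shape[1]),
        naming=None,
        seed=seed,
        train_fraction=train_fraction,
        train_count=n_train,
        heldout_agreement=heldout_agree,
        train_agreement=train_agree,
        best_params=dict(search.best_params_),
    )
    if k == 3:
        model.naming = name_modes(model, features)
    return model


def name_modes(model: ModeModel, features: np.ndarray,
               rel_tol: float = 1e-9) -> dict[int, str]:
    """Map the three clusters to mode names by their feature means.

    The cluster with the highest mean energy is FP; of the remaining two,
    the one with higher mean asphericity is SP and the other SD.  Naming
    is invariant to cluster index permutation; ties beyond ``rel_tol``
    (relative) raise :class:`AmbiguousNamingError`.
    """
    if model.k != 3:
        raise AmbiguousNamingError("mode naming is defined for k = 3 only")
    features = np.asarray(features, dtype=float)
    labels = model.predict_clusters(features)
    i_energy = model.feature_names.index("energy")
    i_asph = model.feature_names.index("asphericity")
    means = {}
    for c in range(3):
        sel = labels == c
        if not sel.any():
            raise AmbiguousNamingError(f"cluster {c} received no points")
        means[c] = (features[sel, i_energy].mean(), features[sel, i_asph].mean())

    def _assert_distinct(a: float, b: float, what: str) -> None:
        if abs(a - b) <= rel_tol * max(abs(a), abs(b), 1.0):
            raise AmbiguousNamingError(f"tied mean {what} between clusters")

    by_energy = sorted(means, key=lambda c: means[c][0])
    _assert_distinct(means[by_energy[2]][0], means[by_energy[1]][0], "energy")
    fp = by_energy[2]
    rest = by_energy[:2]
    _assert_distinct(means[rest[0]][1], means[rest[1]][1], "asphericity")
    sp = max(rest, key=lambda c: means[c][1])
    sd = min(rest, key=lambda c: means[c][1])
    return {sd: "SD", sp: "SP", fp: "FP"}


def annotate_trajectory(
    model: ModeModel,
    traj: Trajectory,
    window: float = 60.0,
    min_points: int = 50,
) -> ModeSequence:
    """Classify each admissible one-hour window of a gap-free trajectory.

    Windows failing the segment invariants are omitted; a trajectory with
    no valid window yields an empty sequence.
    """
    segments = segment_trajectory(traj, window=window, min_points=min_points)
    if not segments:
        return ModeSequence(track_id=traj.track_id, windows=[])
    feats = feature_matrix(segments)
    if model.naming is not None:
        labels = model.predict_modes(feats)
    else:
        labels = [str(c) for c in model.predict_clusters(feats)]
    windows = [(s.start_min, s.end_min, lab) for s, lab in zip(segments, labels)]
    return ModeSequence(track_id=traj.track_id, windows=windows)
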