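"""Bioactivity-cluster subprofiles and cluster assignment.

A bioactivity cluster (tubulin, DNA synthesis, lysosomotropism/cholesterol
homeostasis, ...) is described by a set of *defining* Z-score profiles of
reference compounds.  Its *subprofile* keeps only the features whose sign
agrees across at least a consistency fraction (default 85%) of the defining
profiles, with the per-feature median Z-value over those profiles.  Test
compounds are assigned to every cluster whose subprofile they match with
biosimilarity >= 80% (subprofiles are shorter than full profiles, hence the
higher threshold than the 75% used for full-profile similarity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .profiles import ConstantProfileError, biosimilarity, profile_matrix

logger = logging.getLogger(__name__)

NO_CLUSTER = "no cluster"

DEFAULT_CONSISTENCY = 0.85
DEFAULT_CLUSTER_THRESHOLD = 80.0


@dataclass
class ClusterSubprofile:
    """Reduced median profile of a bioactivity cluster."""

    name: str
    feature_names: list[str]
    median_z: np.ndarray
    n_defining: int

    def __post_init__(self):
        self.median_z = np.asarray(self.median_z, dtype=float)
        if len(self.feature_names) != len(self.median_z):
            raise ValueError("feature_names and median_z lengths differ")

    def __len__(self) -> int:
        return len(self.feature_names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.median_z, index=self.feature_names,
                         name=self.name)

    def to_dict(self) -> dict:
        return {"name": self.name, "features": list(self.feature_names),
                "median_z": self.median_z.tolist(),
                "n_defining": self.n_defining}

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterSubprofile":
        return cls(d["name"], list(d["features"]),
                   np.asarray(d["median_z"], dtype=float),
                   int(d["n_defining"]))


def save_subprofiles(subs: list[ClusterSubprofile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in subs], indent=1))


def load_subprofiles(path: str | Path) -> list[ClusterSubprofile]:
    return [ClusterSubprofile.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def build_subprofile(
    name: str,
    defining: pd.DataFrame,
    consistency: float = DEFAULT_CONSISTENCY,
) -> ClusterSubprofile:
    """Construct a cluster subprofile from its defining profiles.

    ``defining`` holds one row per defining profile, one column per feature
    (an ``induction`` column, if present, is ignored).  For each feature the
    strictly positive and strictly negative values are counted across the
    defining profiles; the feature is retained iff
    ``max(n_pos, n_neg) / n_defining >= consistency`` (inclusive).  Zeros
    count toward neither sign but remain in the denominator.  The subprofile
    value of a retained feature is the median over all defining profiles.
    """
    defining = profile_matrix(defining)
    n = len(defining)
    if n < 1:
        raise ValueError(f"cluster {name!r} has no defining profiles")
    X = defining.to_numpy(dtype=float)
    n_pos = (X > 0).sum(axis=0)
    n_neg = (X < 0).sum(axis=0)
    dominant = np.maximum(n_pos, n_neg) / n
    keep = dominant >= consistency
    if not keep.any():
        raise ValueError(
            f"cluster {name!r}: no feature passes the {consistency:.0%} "
            "sign-consistency rule")
    features = [f for f, k in zip(defining.columns, keep) if k]
    median_z = np.median(X[:, keep], axis=0)
    return ClusterSubprofile(name, features, median_z, n)


def cluster_biosimilarity(profile: pd.Series | pd.DataFrame,
                          sub: ClusterSubprofile) -> float:
    """Biosimilarity of a profile to a cluster subprofile.

    The profile is restricted to the subprofile's feature subset before the
    correlation; it must cover all subprofile features.
    """
    if isinstance(profile, pd.DataFrame):
        profile = profile.iloc[0]
    missing = [f for f in sub.feature_names if f not in profile.index]
    if missing:
        raise ValueError(f"profile lacks subprofile features: {missing[:5]}")
    x = profile.loc[sub.feature_names].to_numpy(dtype=float)
    return biosimilarity(x, sub.median_z)


class ClusterAssigner(BaseEstimator):
    """Assign profiles to bioactivity clusters via subprofile biosimilarity.

    ``fit(X, y)`` takes the defining profiles as rows of X with their cluster
    labels y, builds one subprofile per cluster with the sign-consistency
    rule, and ``predict`` returns for each profile the best-matching cluster
    at biosimilarity >= ``threshold`` percent (or ``"no cluster"``).
    ``decision_function`` exposes the full biosimilarity matrix in percent
    (NaN where the restricted profile is constant).

    Parameters
    ----------
    threshold : float, default 80.0
        Cluster biosimilarity threshold in percent.
    consistency : float, default 0.85
        Sign-consistency fraction for subprofile construction.
    feature_names : list of str, optional
        Names for the columns of X; defaults to DataFrame columns or
        positional names.
    """

    def __init__(self, threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                 consistency: float = DEFAULT_CONSISTENCY,
                 feature_names: list[str] | None = None):
        self.threshold = threshold
        self.consistency = consistency
        self.feature_names = feature_names

    def _resolve_names(self, X) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        if isinstance(X, pd.DataFrame):
            return [c for c in X.columns if c != "induction"]
        return [f"x{i}" for i in range(np.asarray(X).shape[1])]

    def fit(self, X, y):
        names = self._resolve_names(X)
        if isinstance(X, pd.DataFrame):
            X = X[names]
        X = check_array(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        frame = pd.DataFrame(X, columns=names)
        self.classes_ = np.array(sorted(map(str, set(y))), dtype=object)
        self.subprofiles_ = {}
        for label in self.classes_:
            block = frame[np.asarray(y).astype(str) == label]
            self.subprofiles_[label] = build_subprofile(
                label, block, consistency=self.consistency)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "subprofiles_")
        names = list(self.feature_names_in_)
        if isinstance(X, pd.DataFrame):
            X = X[names]
        X = check_array(X)
        out = np.full((X.shape[0], len(self.classes_)), np.nan)
        col = {f: i for i, f in enumerate(names)}
        for j, label in enumerate(self.classes_):
            sub = self.subprofiles_[label]
            idx = [col[f] for f in sub.feature_names]
            for i in range(X.shape[0]):
                try:
                    out[i, j] = biosimilarity(X[i, idx], sub.median_z)
                except ConstantProfileError:
                    logger.warning("constant restricted profile (row %d) for "
                                   "cluster %r", i, label)
        return out

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        best = np.nanmax(np.where(np.isnan(scores), -np.inf, scores), axis=1)
        arg = np.nanargmax(np.where(np.isnan(scores), -np.inf, scores), axis=1)
        labels = self.classes_[arg].copy()
        labels[~(best >= self.threshold)] = NO_CLUSTER
        return labels


def assign_clusters(
    profiles: pd.DataFrame,
    clusters: list[ClusterSubprofile],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> pd.DataFrame:
    """Biosimilarity of every profile to every cluster, with assignments.

    Returns a table indexed like ``profiles`` with one biosimilarity column
    per cluster (NaN where undefined), an ``assigned`` column holding the
    sorted list of clusters at or above ``threshold`` (empty = no cluster),
    and a ``best_cluster`` column (``"no cluster"`` when none qualifies).
    """
    mat = profile_matrix(profiles)
    out = pd.DataFrame(index=profiles.index)
    for sub in clusters:
        vals = np.full(len(mat), np.nan)
        x = mat[sub.feature_names].to_numpy(dtype=float)
        for i in range(len(mat)):
            try:
                vals[i] = biosimilarity(x[i], sub.median_z)
            except ConstantProfileError:
                logger.warning("assign_clusters: constant restricted profile "
                               "%s for cluster %r", profiles.index[i], sub.name)
        out[sub.name] = vals
    names = [sub.name for sub in clusters]
    score = out[names].to_numpy()
    out["assigned"] = [
        [n for n, v in zip(names, row) if np.isfinite(v) and v >= threshold]
        for row in score
    ]
    filled = np.where(np.isnan(score), -np.inf, score)
    best = filled.max(axis=1)
    out["best_cluster"] = [
        names[i] if b >= threshold else NO_CLUSTER
        for i, b in zip(filled.argmax(axis=1), best)
    ]
    return out


def cluster_counts(assignment: pd.DataFrame) -> pd.Series:
    """Per-cluster compound counts from an assignment table (multi-assignment
    counts a compound in every cluster it reaches)."""
    names = [c for c in assignment.columns
             if c not in ("assigned", "best_cluster")]
    counts = {n: int(sum(n in a for a in assignment["assigned"]))
              for n in names}
    counts[NO_CLUSTER] = int(sum(len(a) == 0 for a in assignment["assigned"]))
    return pd.Series(counts, name="n_compounds")


def noncluster_clustering(
    profiles: pd.DataFrame,
    exclude: ClusterSubprofile | list[str],
    method: str = "average",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Hierarchical clustering of profiles on the non-cluster feature space.

    Restricts the profiles to the complement of the excluded cluster's
    features and clusters rows with correlation distance and (by default)
    average linkage.  Returns (linkage matrix, leaf order, features used);
    deterministic given the input row order.
    """
    mat = profile_matrix(profiles)
    excl = set(exclude.feature_names if isinstance(exclude, ClusterSubprofile)
               else exclude)
    used = [f for f in mat.columns if f not in excl]
    if not used:
        raise ValueError("excluded feature set leaves no features to cluster on")
    if len(mat) < 2:
        raise ValueError("need at least two profiles to cluster")
    X = mat[used].to_numpy(dtype=float)
    dist = pdist(X, metric="correlation")
    Z = linkage(dist, method=method)
    return Z, leaves_list(Z), used
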