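"""Morphological Z-score profiles, induction, and biosimilarity.

The profiling model: per plate (and per DMSO load), each feature of a test
well is converted to a robust Z-score against the plate's DMSO control wells,

    z = (value - median(controls)) / MAD(controls),

with MAD the raw median absolute deviation by default.  A compound's profile
is the vector of Z-scores over the robust feature set; its *induction* is the
percentage of features whose |z| passes a significance cutoff, and serves as
the activity measure (active at induction >= 5%).  Profile similarity
(*biosimilarity*) is derived from the correlation distance between two
profiles and clipped to [0, 100]%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .tables import CONTROL, TEST, feature_columns, order_wells, validate_feature_table

logger = logging.getLogger(__name__)

#: |z| cutoff used inside the induction statistic: three Gaussian standard
#: deviations expressed in raw-MAD units (3 / Phi^-1(0.75) = 4.4478).  Under
#: the raw-MAD convention the Z-scores of pure Gaussian noise have standard
#: deviation 1.4826, so a cutoff of 3 raw-MAD units would flag 4.3% of null
#: features; this default keeps the per-feature false-positive rate at the
#: conventional two-sided 0.27%.
DEFAULT_SIGNIFICANCE_CUTOFF = float(3.0 / norm.ppf(0.75))

DEFAULT_ACTIVITY_THRESHOLD = 5.0  # induction percent


class ConstantProfileError(ValueError):
    """Correlation is undefined for a constant (zero-variance) vector."""


def mad(a, axis=0, scale: str | float = "raw"):
    """Median absolute deviation.

    ``scale="raw"`` is the plain median(|x - median(x)|); ``scale="normal"``
    multiplies by 1.4826 so the statistic is consistent for the Gaussian
    standard deviation.  A float scales by that factor directly.
    """
    a = np.asarray(a, dtype=float)
    med = np.nanmedian(a, axis=axis, keepdims=True)
    raw = np.nanmedian(np.abs(a - med), axis=axis)
    if scale == "raw":
        factor = 1.0
    elif scale == "normal":
        factor = 1.0 / norm.ppf(0.75)
    else:
        factor = float(scale)
    return raw * factor


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_to_wells(
    sites: pd.DataFrame,
    by: tuple[str, ...] = ("plate_id", "well"),
) -> pd.DataFrame:
    """Aggregate a feature table by median within groups.

    With the default grouping this collapses microscope sites to one row per
    (plate, well); called again with ``by=("compound_id", "concentration_um")``
    it collapses replicate plates to one row per compound and concentration.
    Missing values are excluded from each median; a group whose values are all
    missing for a feature yields a missing output and is logged.
    """
    features = feature_columns(sites)
    meta = [c for c in sites.columns if c not in features and c not in by
            and c != "site"]

    grouped = sites.groupby(list(by), sort=False, dropna=False)
    agg = grouped[features].median()
    # metadata: a single representative value per group (first occurrence)
    meta_agg = grouped[meta].first() if meta else None

    all_nan = agg.isna() & grouped[features].count().eq(0)
    if all_nan.any().any():
        for (key, feat) in zip(*np.nonzero(all_nan.to_numpy())):
            logger.warning(
                "aggregate_to_wells: group %s has no values for feature %r",
                agg.index[key], features[feat],
            )

    out = agg if meta_agg is None else pd.concat([meta_agg, agg], axis=1)
    return out.reset_index()


# ---------------------------------------------------------------------------
# MAD Z-scoring
# ---------------------------------------------------------------------------

class ControlMadScaler(TransformerMixin, BaseEstimator):
    """Robust scaler fit on control observations: z = (x - median) / MAD.

    Parameters
    ----------
    mad_scale : {"raw", "normal"} or float, default "raw"
        MAD convention; "raw" applies no consistency factor.
    eps_abs, eps_rel : float
        A feature whose control MAD is zero gets its scale replaced by
        ``max(eps_abs, eps_rel * |median|)`` rather than emitting infinities;
        such features are flagged in ``degenerate_mask_``.

    Attributes
    ----------
    center_ : ndarray of shape (n_features,)
        Per-feature control median.
    scale_ : ndarray of shape (n_features,)
        Per-feature control MAD after the epsilon floor.
    degenerate_mask_ : boolean ndarray
        True where the control MAD was zero.
    """

    def __init__(self, mad_scale="raw", eps_abs: float = 1e-6,
                 eps_rel: float = 1e-6):
        self.mad_scale = mad_scale
        self.eps_abs = eps_abs
        self.eps_rel = eps_rel

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan", ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.center_ = np.nanmedian(X, axis=0)
        scale = mad(X, axis=0, scale=self.mad_scale)
        self.degenerate_mask_ = scale == 0
        floor = np.maximum(self.eps_abs, self.eps_rel * np.abs(self.center_))
        self.scale_ = np.where(self.degenerate_mask_, floor, scale)
        if self.degenerate_mask_.any():
            logger.warning(
                "ControlMadScaler: %d feature(s) with zero control MAD; "
                "epsilon floor applied", int(self.degenerate_mask_.sum()),
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = check_array(X, ensure_all_finite="allow-nan")
        return (X - self.center_) / self.scale_


# ---------------------------------------------------------------------------
# induction / biosimilarity
# ---------------------------------------------------------------------------

def induction(z, cutoff: float = DEFAULT_SIGNIFICANCE_CUTOFF) -> float:
    """Percentage of features with |z| >= cutoff (the activity measure)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("induction of an empty feature vector is undefined")
    return 100.0 * float(np.count_nonzero(np.abs(z) >= cutoff)) / z.size


def biosimilarity(x, y) -> float:
    """Profile similarity in percent, from the correlation distance.

    With centered vectors xc = x - mean(x), yc = y - mean(y), the correlation
    distance is CD = 1 - (xc . yc) / (||xc||_2 ||yc||_2); the biosimilarity is
    max(0, 1 - CD) * 100, i.e. the positive part of the Pearson correlation
    expressed in percent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("biosimilarity requires two 1-d vectors of equal length")
    if x.size < 2:
        raise ValueError("biosimilarity requires vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / (nx * ny))
    return max(0.0, 1.0 - (1.0 - r)) * 100.0


def activity_call(induction_percent,
                  threshold: float = DEFAULT_ACTIVITY_THRESHOLD):
    """Active iff induction >= threshold (boundary inclusive).

    Accepts a scalar or array; returns bool or boolean array.
    """
    arr = np.asarray(induction_percent, dtype=float)
    result = arr >= threshold
    return bool(result) if np.isscalar(induction_percent) else result


# ---------------------------------------------------------------------------
# robust feature selection
# ---------------------------------------------------------------------------

class ReplicateCorrelationSelector(SelectorMixin, BaseEstimator):
    """Select features reproducible across two repeats of a reference plate.

    ``fit(X, Y)`` takes the two repeats as (n_wells, n_features) matrices with
    wells paired row-by-row.  A feature is retained when the biosimilarity of
    its two well-vectors is >= ``min_similarity`` percent; features whose
    vector is constant in either repeat have undefined correlation and are
    dropped (similarity recorded as NaN).

    Attributes
    ----------
    similarities_ : ndarray of shape (n_features,)
        Cross-repeat biosimilarity in percent (NaN for constant features).
    """

    def __init__(self, min_similarity: float = 80.0):
        self.min_similarity = min_similarity

    def fit(self, X, y=None):
        if y is None:
            raise ValueError(
                "ReplicateCorrelationSelector.fit requires the second repeat "
                "as y: fit(repeat_a, repeat_b)")
        X = check_array(X)
        Y = check_array(y)
        if X.shape != Y.shape:
            raise ValueError(
                f"repeats have mismatched shapes {X.shape} vs {Y.shape}")
        self.n_features_in_ = X.shape[1]

        xc = X - X.mean(axis=0)
        yc = Y - Y.mean(axis=0)
        nx = np.linalg.norm(xc, axis=0)
        ny = np.linalg.norm(yc, axis=0)
        sims = np.full(X.shape[1], np.nan)
        ok = (nx > 0) & (ny > 0)
        r = np.einsum("ij,ij->j", xc[:, ok], yc[:, ok]) / (nx[ok] * ny[ok])
        sims[ok] = np.maximum(0.0, r) * 100.0
        if (~ok).any():
            logger.warning(
                "ReplicateCorrelationSelector: %d constant feature(s) dropped "
                "(undefined correlation)", int((~ok).sum()))
        self.similarities_ = sims
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "similarities_")
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.similarities_, nan=-1.0) >= self.min_similarity


@dataclass
class RobustFeatureSet:
    """Ordered feature subset passing the replicate-reproducibility rule."""

    feature_names: list[str]
    source_similarity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be duplicate-free")

    def __len__(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": list(self.source_similarity),
            "similarity": list(self.source_similarity.values()),
            "retained": [f in set(self.feature_names)
                         for f in self.source_similarity],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RobustFeatureSet":
        retained = df.loc[df["retained"], "feature"].tolist()
        sims = dict(zip(df["feature"], df["similarity"]))
        return cls(retained, sims)


def select_robust_features(
    repeat_a: pd.DataFrame,
    repeat_b: pd.DataFrame,
    min_similarity: float = 80.0,
) -> RobustFeatureSet:
    """Robust feature set from two repeats of one reference plate.

    Each feature's whole-plate profile is its value vector across wells in the
    fixed row-major well order (A01...P24); the feature is retained when the
    two repeats' vectors have biosimilarity >= ``min_similarity`` percent.
    """
    wells_a = set(repeat_a["well"])
    wells_b = set(repeat_b["well"])
    if wells_a != wells_b:
        raise ValueError(
            "repeats cover different wells; only in A: "
            f"{order_wells(wells_a - wells_b)}; only in B: "
            f"{order_wells(wells_b - wells_a)}")
    feats_a = feature_columns(repeat_a)
    feats_b = feature_columns(repeat_b)
    if feats_a != feats_b:
        raise ValueError("repeats have different feature sets")

    order = order_wells(wells_a)
    A = repeat_a.set_index("well").loc[order, feats_a].to_numpy(dtype=float)
    B = repeat_b.set_index("well").loc[order, feats_a].to_numpy(dtype=float)

    sel = ReplicateCorrelationSelector(min_similarity=min_similarity).fit(A, B)
    mask = sel.get_support()
    retained = [f for f, keep in zip(feats_a, mask) if keep]
    sims = {f: (float(s) if np.isfinite(s) else float("nan"))
            for f, s in zip(feats_a, sel.similarities_)}
    return RobustFeatureSet(retained, sims)


# ---------------------------------------------------------------------------
# Z-profiles
# ---------------------------------------------------------------------------

@dataclass
class ZProfile:
    """A compound's Z-score profile at one concentration, with its induction."""

    compound_id: str
    concentration_um: float
    z: pd.Series  # indexed by feature name
    induction: float

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class ZScoreDiagnostics:
    """Side-channel report from Z-scoring: degenerate and rejected items."""

    degenerate_features: dict[tuple, list[str]] = field(default_factory=dict)
    rejected_profiles: list[tuple] = field(default_factory=list)


def zscore_wells(
    wells: pd.DataFrame,
    robust: RobustFeatureSet | list[str] | None = None,
    significance_cutoff: float = DEFAULT_SIGNIFICANCE_CUTOFF,
    mad_scale="raw",
    min_controls: int = 3,
    max_missing_fraction: float = 0.05,
    return_diagnostics: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, ZScoreDiagnostics]:
    """Z-score all test wells of a well-level feature table.

    Controls are matched to each test well by plate **and** DMSO load
    (``dmso_percent``); a test group without at least ``min_controls`` matching
    control wells is an error, never silently pooled.  Wells of the same
    compound and concentration (replicate plates) are collapsed by median
    after scoring.  Returns a profile table indexed by
    (compound_id, concentration_um) with one column per robust feature plus an
    ``induction`` column; profiles missing more than ``max_missing_fraction``
    of the robust features are rejected with a diagnostic.
    """
    validate_feature_table(wells, site_level=False)
    if robust is None:
        features = feature_columns(wells)
    elif isinstance(robust, RobustFeatureSet):
        features = list(robust.feature_names)
    else:
        features = list(robust)
    missing_feats = set(features) - set(wells.columns)
    if missing_feats:
        raise ValueError(f"robust features absent from table: "
                         f"{sorted(missing_feats)[:5]}")

    diags = ZScoreDiagnostics()
    scored = []
    for (plate, dmso), grp in wells.groupby(["plate_id", "dmso_percent"],
                                            sort=False):
        tests = grp[grp["role"] == TEST]
        if tests.empty:
            continue
        ctrl = grp[grp["role"] == CONTROL]
        if len(ctrl) < min_controls:
            raise ValueError(
                f"plate {plate!r} at {dmso}% DMSO has {len(ctrl)} control "
                f"wells; >= {min_controls} required")
        scaler = ControlMadScaler(mad_scale=mad_scale).fit(
            ctrl[features].to_numpy(dtype=float))
        if scaler.degenerate_mask_.any():
            degen = [f for f, d in zip(features, scaler.degenerate_mask_) if d]
            diags.degenerate_features[(plate, dmso)] = degen
        z = scaler.transform(tests[features].to_numpy(dtype=float))
        block = pd.DataFrame(z, columns=features, index=tests.index)
        block.insert(0, "compound_id", tests["compound_id"].to_numpy())
        block.insert(1, "concentration_um", tests["concentration_um"].to_numpy())
        scored.append(block)

    if not scored:
        raise ValueError("no test wells to score")
    ztab = pd.concat(scored, axis=0)
    profiles = ztab.groupby(["compound_id", "concentration_um"],
                            sort=False)[features].median()

    frac_missing = profiles.isna().mean(axis=1)
    bad = frac_missing > max_missing_fraction
    if bad.any():
        for key in profiles.index[bad]:
            logger.warning("zscore_wells: profile %s rejected "
                           "(%.1f%% robust features missing)",
                           key, 100 * frac_missing.loc[key])
            diags.rejected_profiles.append(key)
        profiles = profiles[~bad]

    profiles["induction"] = [
        induction(row.dropna().to_numpy(), cutoff=significance_cutoff)
        for _, row in profiles[features].iterrows()
    ]
    if return_diagnostics:
        return profiles, diags
    return profiles


def compute_zprofile(
    wells: pd.DataFrame,
    robust: RobustFeatureSet | list[str] | None,
    compound_id: str,
    concentration_um: float,
    **kwargs,
) -> ZProfile:
    """Z-score profile of one compound at one concentration (see zscore_wells)."""
    sub = wells[(wells["compound_id"] == compound_id)
                & (wells["concentration_um"] == concentration_um)
                | (wells["role"] == CONTROL)]
    if not (sub["role"] == TEST).any():
        raise ValueError(
            f"no test wells for {compound_id!r} at {concentration_um} uM")
    profiles = zscore_wells(sub, robust, **kwargs)
    row = profiles.loc[(compound_id, concentration_um)]
    z = row.drop("induction")
    return ZProfile(compound_id, float(concentration_um), z,
                    float(row["induction"]))


def profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Feature part of a profile table (drops the induction column)."""
    return profiles.drop(columns=["induction"], errors="ignore")


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(
    run1: pd.DataFrame,
    run2: pd.DataFrame,
    biosim_threshold: float = 80.0,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Cross-run reproducibility of profiles and activity.

    Both runs are profile tables from :func:`zscore_wells` (or any table with
    feature columns plus ``induction``, indexed by compound).  The compound
    intersection is used; mismatches are logged.  Returns a per-compound table
    (cross-run biosimilarity, both inductions, confirmed flag) and a summary
    dict with the Pearson correlation and r^2 of the induction values, the
    median biosimilarity, the fraction of compounds with biosimilarity >=
    ``biosim_threshold``, and the fraction confirmed active in both runs.
    """
    r1 = _one_row_per_compound(run1)
    r2 = _one_row_per_compound(run2)
    shared = [c for c in r1.index if c in set(r2.index)]
    if not shared:
        raise ValueError("runs share no compounds")
    dropped = (set(r1.index) | set(r2.index)) - set(shared)
    if dropped:
        logger.warning("replicate_concordance: %d compound(s) present in only "
                       "one run are ignored", len(dropped))

    feats = [c for c in r1.columns if c != "induction" and c in r2.columns]
    P1 = r1.loc[shared, feats].to_numpy(dtype=float)
    P2 = r2.loc[shared, feats].to_numpy(dtype=float)
    bs = np.full(len(shared), np.nan)
    for i in range(len(shared)):
        try:
            bs[i] = biosimilarity(P1[i], P2[i])
        except ConstantProfileError:
            logger.warning("replicate_concordance: constant profile for %r; "
                           "biosimilarity undefined", shared[i])
    ind1 = r1.loc[shared, "induction"].to_numpy(dtype=float)
    ind2 = r2.loc[shared, "induction"].to_numpy(dtype=float)
    confirmed = (ind1 >= activity_threshold) & (ind2 >= activity_threshold)
    per_compound = pd.DataFrame(
        {"biosimilarity": bs, "induction_run1": ind1, "induction_run2": ind2,
         "confirmed": confirmed},
        index=pd.Index(shared, name="compound_id"))

    if len(shared) >= 2 and ind1.std() > 0 and ind2.std() > 0:
        pearson = float(np.corrcoef(ind1, ind2)[0, 1])
    else:
        pearson = float("nan")
    bsv = per_compound["biosimilarity"].dropna()
    active1 = ind1 >= activity_threshold
    summary = {
        "n_compounds": len(shared),
        "induction_pearson": pearson,
        "induction_r2": pearson ** 2 if np.isfinite(pearson) else float("nan"),
        "median_biosimilarity": float(bsv.median()) if len(bsv) else float("nan"),
        "fraction_biosim_ge_threshold":
            float((bsv >= biosim_threshold).mean()) if len(bsv) else float("nan"),
        "fraction_confirmed_active": float(confirmed.mean()),
        "fraction_run1_actives_confirmed":
            float(confirmed[active1].mean()) if active1.any() else float("nan"),
    }
    return per_compound, summary


def _one_row_per_compound(profiles: pd.DataFrame) -> pd.DataFrame:
    """Collapse a profile table to one row per compound id (first concentration)."""
    if isinstance(profiles.index, pd.MultiIndex):
        return profiles.groupby(level=0, sort=False).first()
    return profiles[~profiles.index.duplicated()]
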