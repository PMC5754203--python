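"""Classification and clustering of promoter expression profiles.

Promoters are classified as housekeeping (< 5-fold variation across the
time course) or developmentally regulated (>= 60% of total expression inside
one 8 hr window); developmental profiles are hierarchically clustered on
Pearson distance.  Cross-species statistics (profile conservation, Shannon
entropy, replicate concordance) live here as well.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = ["ExpressionClass", "classify_hk_dev", "cluster_profiles",
           "profile_conservation", "shannon_entropy",
           "replicate_concordance"]


@dataclass
class ExpressionClass:
    """Expression-based promoter annotation."""

    label: str  # 'housekeeping' | 'developmental' | 'unclassified'
    cluster: int | None = None  # developmental promoters only
    phase: str | None = None    # 'Early' | 'Intermediate' | 'Late'

    def __post_init__(self):
        if self.label not in ("housekeeping", "developmental", "unclassified"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.phase is not None and self.label == "unclassified":
            raise ValueError("phase only applies to classified promoters")


def classify_hk_dev(values: np.ndarray, mask: np.ndarray | None = None,
                    min_max_rpm: float = 10.0, hk_fold: float = 5.0,
                    dev_frac: float = 0.6, window_hr: int = 8,
                    step: float = 1.0) -> ExpressionClass:
    """Classify one hourly expression profile as housekeeping/developmental.

    Unclassified when the (unmasked) maximum falls below ``min_max_rpm``.
    Housekeeping: max/min < ``hk_fold`` (a zero minimum means unbounded fold
    variation, hence never housekeeping).  Developmental: the best window of
    ``window_hr`` consecutive points holds >= ``dev_frac`` of the summed
    profile.  A profile meeting both definitions is housekeeping (the two
    classes are disjoint, with housekeeping precedence).
    """
    values = np.asarray(values, dtype=float)
    if mask is None and isinstance(values, np.ma.MaskedArray):
        mask = np.ma.getmaskarray(values)
    mask = np.zeros(values.shape, bool) if mask is None else np.asarray(mask, bool)
    v = np.asarray(values)[~mask]
    if v.size == 0:
        raise ValueError("profile is entirely masked")
    vmax = v.max()
    if vmax < min_max_rpm:
        return ExpressionClass("unclassified")
    vmin = v.min()
    if vmin > 0 and vmax / vmin < hk_fold:
        return ExpressionClass("housekeeping")
    if vmin == 0:
        logger.debug("zero minimum: fold variation unbounded, not housekeeping")
    total = v.sum()
    w = max(1, int(round(window_hr / step)))
    filled = np.where(mask, 0.0, values)
    if filled.size >= w and total > 0:
        sums = np.convolve(filled, np.ones(w), mode="valid")
        if sums.max() >= dev_frac * total:
            return ExpressionClass("developmental")
    return ExpressionClass("unclassified")


def cluster_profiles(X: np.ndarray, k: int = 12, min_size: int = 200,
                     method: str = "complete",
                     hours: np.ndarray | None = None) -> np.ndarray:
    """Hierarchically cluster developmental profiles on Pearson distance.

    Distance is ``1 - r`` between profiles; the ``method``-linkage tree is
    cut into ``k`` groups; groups smaller than ``min_size`` are dropped
    (their members labelled -1); survivors are renumbered 0..m-1 by
    increasing mean peak time.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant profiles have undefined Pearson distance; "
                         "filter them out first")
    d = pdist(X, metric="correlation")
    Z = linkage(d, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    if hours is None:
        hours = np.arange(X.shape[1], dtype=float)
    labels = np.full(n, -1, dtype=int)
    surviving = []
    for c in np.unique(raw):
        members = np.flatnonzero(raw == c)
        if members.size < min_size:
            continue
        peak = hours[np.argmax(X[members], axis=1)].mean()
        surviving.append((peak, members))
    surviving.sort(key=lambda t: t[0])
    for newc, (_, members) in enumerate(surviving):
        labels[members] = newc
    return labels


def profile_conservation(profiles: np.ndarray, signed: bool = False) -> float:
    """Conservation of one promoter's profile across species.

    ``profiles`` is (n_species, T) of aligned expression values; the
    statistic is the mean squared Pearson correlation over all unordered
    species pairs.  ``signed=True`` keeps the correlation sign
    (``sign(r) * r**2``) instead of the literal R-squared.  Pairs involving
    a zero-variance profile are skipped (logged); with no valid pair the
    result is NaN.  Divergence is 1 minus this value.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need profiles for at least 2 species")
    vals = []
    for i, j in itertools.combinations(range(P.shape[0]), 2):
        si, sj = P[i].std(), P[j].std()
        if si == 0 or sj == 0:
            logger.debug("zero-variance profile in pair (%d, %d): skipped", i, j)
            continue
        r = np.corrcoef(P[i], P[j])[0, 1]
        vals.append(np.sign(r) * r ** 2 if signed else r ** 2)
    return float(np.mean(vals)) if vals else float("nan")


def shannon_entropy(values: np.ndarray, min_max_rpm: float = 2.0) -> float:
    """Shannon entropy (bits) of a temporal expression profile.

    The profile is normalized to a distribution over time points; the
    entropy ranges from 0 (a single active point) to log2(T) (uniform).
    Profiles whose maximum falls below ``min_max_rpm`` are rejected, as are
    all-zero profiles.
    """
    v = np.asarray(values, dtype=float)
    if isinstance(values, np.ma.MaskedArray):
        v = values.compressed()
    if v.sum() <= 0:
        raise ValueError("profile sums to zero: entropy undefined")
    if v.max() < min_max_rpm:
        raise ValueError(f"profile maximum below the {min_max_rpm} RPM filter")
    p = v / v.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def replicate_concordance(rpm1: np.ndarray, rpm2: np.ndarray,
                          thresholds: tuple = (10.0, 25.0)
                          ) -> dict[float, float | None]:
    """Reproducibility of expression quantification between replicates.

    For each maximum-RPM threshold, the squared Pearson correlation of the
    paired per-time-point values over all promoters whose profile maximum
    (in either replicate) reaches the threshold.  Strata with fewer
    than 3 promoters are skipped (``None``).
    """
    A = np.asarray(rpm1, dtype=float)
    B = np.asarray(rpm2, dtype=float)
    if A.shape != B.shape:
        raise ValueError("replicate matrices must have identical shapes")
    peak = np.maximum(A, B).max(axis=1)
    out: dict[float, float | None] = {}
    for thr in thresholds:
        sel = peak >= thr
        if sel.sum() < 3:
            out[thr] = None
            continue
        r, _ = stats.pearsonr(A[sel].ravel(), B[sel].ravel())
        out[thr] = float(r ** 2)
    return out
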