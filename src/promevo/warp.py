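"""Registration of developmental time series across species.

Species develop at different paces, so their hourly expression series are
registered to a reference by dynamic time warping: profiles are z-scored,
upsampled 5-fold and smoothed (2 hr window); a Pearson-distance matrix
between time points (computed across orthologous genes) is aligned globally
under a Sakoe-Chiba band (3 hr); the optimal path then transfers individual
promoter profiles onto the reference grid, with a final 1 hr smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Profile", "WarpPath", "preprocess", "distance_matrix",
           "dtw_align", "apply_warp"]


@dataclass
class Profile:
    """A temporal expression profile on a uniform hourly-style grid.

    ``values[k]`` is measured at hour ``start_hour + k * step``; masked
    points mark missing libraries and are excluded from statistics.
    """

    values: np.ndarray
    start_hour: float = 0.5
    step: float = 1.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have the same shape")

    @property
    def hours(self) -> np.ndarray:
        return self.start_hour + self.step * np.arange(self.values.size)


def _fill_masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked points (edge points take nearest value)."""
    if not mask.any():
        return values.copy()
    ok = ~mask
    if ok.sum() < 2:
        raise ValueError("profile needs at least 2 unmasked points")
    x = np.arange(values.size)
    return np.interp(x, x[ok], values[ok])


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with window shrinking at the edges."""
    if w <= 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _window_points(hours: float, step: float) -> int:
    w = int(round(hours / step))
    return w + 1 if w % 2 == 0 else w  # odd, centered


def preprocess(profiles: list[Profile], upsample: int = 5,
               smooth_hr: float = 2.0) -> list[Profile]:
    """Z-score, upsample and smooth profiles onto a refined grid.

    Each profile is z-scored over its unmasked points (a zero-variance
    profile maps to all zeros, logged), linearly interpolated onto a grid
    ``upsample`` times finer ((T-1)*u + 1 points) and smoothed with a
    centered moving average of width ``smooth_hr`` (shrinking at edges).
    Originally masked points are re-marked on the refined grid.
    """
    out = []
    for p in profiles:
        if (~p.mask).sum() == 0:
            raise ValueError("profile is entirely masked")
        v = _fill_masked(p.values, p.mask)
        ok = ~p.mask
        mu, sd = p.values[ok].mean(), p.values[ok].std()
        if sd == 0:
            logger.info("zero-variance profile: z-scores set to 0")
            z = np.zeros_like(v)
        else:
            z = (v - mu) / sd
        n = v.size
        fine = np.linspace(0, n - 1, (n - 1) * upsample + 1)
        zf = np.interp(fine, np.arange(n), z)
        new_step = p.step / upsample
        zf = _moving_average(zf, _window_points(smooth_hr, new_step))
        # re-mask refined points nearest to an originally masked point
        mf = np.zeros(zf.size, dtype=bool)
        for k in np.flatnonzero(p.mask):
            lo = max(0, int((k - 0.5) * upsample) + 1)
            hi = min(zf.size, int((k + 0.5) * upsample) + 1)
            mf[lo:hi] = True
        out.append(Profile(zf, start_hour=p.start_hour, step=new_step, mask=mf))
    return out


def _standardize_columns(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    return (X - mu) / sd_safe, degenerate


def distance_matrix(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Pearson-distance matrix between time points of two species.

    ``values_a``/``values_b`` are (n_genes, T) matrices of matched ortholog
    profiles.  ``D[i, j] = 1 - r`` where r correlates the cross-gene
    expression vectors at time i of A and time j of B; D lies in [0, 2].
    A zero-variance time point yields maximal distance (2), logged.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("species must share the same ortholog rows")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 shared ortholog pairs")
    Az, bad_a = _standardize_columns(A)
    Bz, bad_b = _standardize_columns(B)
    R = Az.T @ Bz / A.shape[0]
    D = 1.0 - R
    if bad_a.any() or bad_b.any():
        logger.info("zero-variance time points set to maximal distance")
        D[bad_a, :] = 2.0
        D[:, bad_b] = 2.0
    return np.clip(D, 0.0, 2.0)


@dataclass
class WarpPath:
    """Monotone correspondence between two time grids.

    ``pairs`` is an (L, 2) index array starting at (0, 0), ending at
    (T_A - 1, T_B - 1), with steps in {(1,0), (0,1), (1,1)}.
    """

    pairs: np.ndarray
    hours_a: np.ndarray
    hours_b: np.ndarray

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.hours_a = np.asarray(self.hours_a, dtype=float)
        self.hours_b = np.asarray(self.hours_b, dtype=float)
        p = self.pairs
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (self.hours_a.size - 1,
                                                     self.hours_b.size - 1):
            raise ValueError("path must run corner to corner")
        steps = np.diff(p, axis=0)
        if not np.all((steps >= 0) & (steps <= 1)) or np.any(steps.sum(axis=1) == 0):
            raise ValueError("path steps must be (1,0), (0,1) or (1,1)")

    def time_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Median matched B-hour for every A grid point."""
        ia = self.pairs[:, 0]
        hb = self.hours_b[self.pairs[:, 1]]
        mapped = np.array([np.median(hb[ia == i])
                           for i in range(self.hours_a.size)])
        return self.hours_a, mapped

    def is_identity(self) -> bool:
        return bool(np.all(self.pairs[:, 0] == self.pairs[:, 1]))


def dtw_align(D: np.ndarray, hours_a: np.ndarray | None = None,
              hours_b: np.ndarray | None = None,
              band_hr: float = 3.0) -> WarpPath:
    """Optimal global alignment path through a distance matrix.

    Classic dynamic programming over monotone steps, restricted to the
    Sakoe-Chiba band ``|hour_a - hour_b| <= band_hr``.  Ties prefer the
    diagonal step (then the vertical), making the path deterministic.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    na, nb = D.shape
    if hours_a is None:
        hours_a = np.arange(na, dtype=float)
    if hours_b is None:
        hours_b = np.arange(nb, dtype=float)
    hours_a = np.asarray(hours_a, dtype=float)
    hours_b = np.asarray(hours_b, dtype=float)
    allowed = np.abs(hours_a[:, None] - hours_b[None, :]) <= band_hr + 1e-9
    if not (allowed[0, 0] and allowed[-1, -1]):
        raise ValueError("band excludes the path endpoints")
    INF = np.inf
    cost = np.full((na, nb), INF)
    back = np.zeros((na, nb), dtype=np.int8)  # 0 diag, 1 up(i-1), 2 left(j-1)
    cost[0, 0] = D[0, 0]
    for i in range(na):
        for j in range(nb):
            if not allowed[i, j] or (i == 0 and j == 0):
                continue
            best, arg = INF, 0
            if i > 0 and j > 0 and cost[i - 1, j - 1] < best:
                best, arg = cost[i - 1, j - 1], 0
            if i > 0 and cost[i - 1, j] < best:
                best, arg = cost[i - 1, j], 1
            if j > 0 and cost[i, j - 1] < best:
                best, arg = cost[i, j - 1], 2
            if best < INF:
                cost[i, j] = best + D[i, j]
                back[i, j] = arg
    if not np.isfinite(cost[-1, -1]):
        raise ValueError("band excludes any complete path")
    pairs = [(na - 1, nb - 1)]
    i, j = na - 1, nb - 1
    while (i, j) != (0, 0):
        a = back[i, j]
        if a == 0 and i > 0 and j > 0:
            i, j = i - 1, j - 1
        elif a == 1 and i > 0:
            i -= 1
        else:
            j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(np.array(pairs), hours_a, hours_b)


def path_cost(D: np.ndarray, path: WarpPath) -> float:
    """Summed distance along a path (includes both endpoints)."""
    return float(D[path.pairs[:, 0], path.pairs[:, 1]].sum())


def apply_warp(values_b: np.ndarray, path: WarpPath,
               smooth_hr: float = 1.0, ref_step: float | None = None
               ) -> np.ndarray:
    """Transfer a target-species profile onto the reference grid.

    Every reference grid point receives the mean of the B values matched to
    it by the path, followed by a centered moving-average smoothing of
    ``smooth_hr`` (using the reference grid step from the path unless
    overridden).
    """
    values_b = np.asarray(values_b, dtype=float)
    if values_b.size != path.hours_b.size:
        raise ValueError("profile length does not match the path's B grid")
    na = path.hours_a.size
    out = np.zeros(na)
    cnt = np.zeros(na)
    np.add.at(out, path.pairs[:, 0], values_b[path.pairs[:, 1]])
    np.add.at(cnt, path.pairs[:, 0], 1.0)
    out /= cnt
    if ref_step is None:
        ref_step = float(path.hours_a[1] - path.hours_a[0]) if na > 1 else 1.0
    return _moving_average(out, _window_points(smooth_hr, ref_step))
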