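"""Correlation dimension (D2) of a binary 3D volume by probabilistic box counting.

The volume is covered with a regular grid of cubes of edge r voxels.  With
N_i(r) the number of occupied voxels in cube i and N_all the total, each
cube carries probability mass p_i = N_i(r) / N_all and the correlation sum
is

    C(r) = sum_i p_i^2 ,

the probability that two points of the set fall in the same cube.  D2 is
the slope of ln C(r) against ln r over the linear (scaling) portion of the
log-log plot.  Two practical refinements:

* Grid offsets.  The placement of the counting grid biases C(r); for each r
  the grid is re-counted at ``n_offsets`` integer offsets (the canonical
  (0,0,0) plus seeded uniform draws from [0, r-1]^3) and the median C(r) is
  kept.
* Breakpoint-optimized fit.  Finite resolution and saturation bend the
  log-log curve at its ends.  The final slope is the ordinary least-squares
  fit over the contiguous sub-range of box sizes (>= ``min_fit_points``
  points) that maximizes R^2; ties prefer more points, then the smaller
  lower bound.

Box sizes run from ``min_r`` (default 2 voxels) to 70% of the shortest grid
side in steps of ``r_step``.  All randomness is keyed by ``offset_seed``
and the box size, so results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import VoxelVolume

__all__ = [
    "FDParams",
    "BoxCountTable",
    "FDResult",
    "box_occupancy_counts",
    "correlation_sum",
    "boxcount_profile",
    "fit_fd",
    "estimate_fd",
]

#: R^2 difference below which two candidate fits are considered tied.
_R2_TIE_TOL = 1e-9

#: Spacing max/min ratio beyond which voxel-based counting is refused
#: (boxes are cubes in index space, so near-isotropy is assumed).
_MAX_ANISOTROPY = 1.05


@dataclass(frozen=True)
class FDParams:
    """Estimator configuration.

    Defaults follow the reference procedure: boxes from 2 voxels up to 70%
    of the shortest grid side in 1-voxel steps, 20 grid offsets per size
    aggregated by the median, and at least 10 points in the final fit.
    """

    min_r: int = 2
    max_r_fraction: float = 0.70
    r_step: int = 1
    n_offsets: int = 20
    offset_seed: int = 0
    min_fit_points: int = 10
    offset_aggregator: str = "median"
    allow_anisotropic: bool = False

    def __post_init__(self) -> None:
        if self.min_r < 2:
            raise ValueError("min_r must be >= 2")
        if not (0 < self.max_r_fraction <= 1):
            raise ValueError("max_r_fraction must be in (0, 1]")
        if self.r_step < 1:
            raise ValueError("r_step must be >= 1")
        if self.n_offsets < 1:
            raise ValueError("n_offsets must be >= 1")
        if self.min_fit_points < 3:
            raise ValueError("min_fit_points must be >= 3")
        if self.offset_aggregator != "median":
            raise ValueError("only the 'median' offset aggregator is supported")


@dataclass(frozen=True)
class BoxCountTable:
    """Per-box-size correlation sums.

    ``c_by_offset[i, j]`` is C(r_i) at offset j (offset 0 is the canonical
    (0,0,0) grid); ``c_median`` its median over offsets; ``nc`` the number
    of occupied boxes at the canonical offset; ``n_all`` the total occupied
    voxel count.
    """

    r: np.ndarray
    c_by_offset: np.ndarray
    c_median: np.ndarray
    nc: np.ndarray
    n_all: int

    def __len__(self) -> int:
        return len(self.r)

    def to_frame(self) -> pd.DataFrame:
        """Long-form per-r table (one row per box size)."""
        df = pd.DataFrame({"r": self.r, "ln_r": np.log(self.r)})
        for j in range(self.c_by_offset.shape[1]):
            df[f"c_offset_{j}"] = self.c_by_offset[:, j]
        df["c_median"] = self.c_median
        df["ln_c_median"] = np.log(self.c_median)
        df["nc_canonical"] = self.nc
        return df


@dataclass(frozen=True)
class FDResult:
    """Outcome of a D2 estimate: the dimension, the fitted box-size range,
    and fit quality (R^2 and log-space RMSE over the included points)."""

    fd: float
    r_min_used: int
    r_max_used: int
    breakpoint: int
    r_squared: float
    rmse: float
    n_points_used: int
    table: BoxCountTable
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "fd": self.fd,
            "r_min_used": int(self.r_min_used),
            "r_max_used": int(self.r_max_used),
            "breakpoint": int(self.breakpoint),
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_points_used": int(self.n_points_used),
        }


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _integral_table(occ: np.ndarray) -> np.ndarray:
    """3D summed-area table: S[i,j,k] = number of occupied voxels in occ[:i,:j,:k]."""
    shape = tuple(s + 1 for s in occ.shape)
    s = np.zeros(shape, dtype=np.int32)
    s[1:, 1:, 1:] = occ
    np.cumsum(s, axis=0, out=s)
    np.cumsum(s, axis=1, out=s)
    np.cumsum(s, axis=2, out=s)
    return s


def _box_edges(n: int, r: int, offset: int) -> np.ndarray:
    # box b covers indices [b*r - offset, (b+1)*r - offset), clipped to [0, n];
    # index 0 always lies in box 0 since 0 <= offset < r
    n_boxes = (n - 1 + offset) // r + 1
    edges = np.arange(n_boxes + 1, dtype=np.int64) * r - offset
    edges[0] = 0
    edges[-1] = min(edges[-1], n)
    return edges


def _counts_from_integral(
    table: np.ndarray, r: int, offset: tuple[int, int, int]
) -> np.ndarray:
    """All box sums (including empty boxes) via inclusion-exclusion on the
    summed-area table; one gather of the box-corner lattice plus three diffs."""
    shape = tuple(s - 1 for s in table.shape)
    ex, ey, ez = (_box_edges(shape[a], r, offset[a]) for a in range(3))
    corner = table[np.ix_(ex, ey, ez)]
    counts = np.diff(np.diff(np.diff(corner, axis=0), axis=1), axis=2)
    return counts.reshape(-1)


def box_occupancy_counts(
    vol: VoxelVolume, r: int, offset: tuple[int, int, int] = (0, 0, 0)
) -> np.ndarray:
    """Occupied-voxel counts {N_i} of all nonempty boxes of edge ``r``.

    Each occupied voxel is assigned to exactly one box by
    ``floor((index + offset) / r)`` per axis, so boxes straddling the grid
    edge are implicit (equivalent to zero-padding by r-1).  The counts sum
    to the total occupied count.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if any(not (0 <= o < r) for o in offset):
        raise ValueError(f"offset components must be in [0, {r - 1}], got {offset}")
    if vol.is_empty():
        raise ValueError("cannot box-count an empty volume")
    counts = _counts_from_integral(_integral_table(vol.occupancy), r, tuple(offset))
    return counts[counts > 0]


def correlation_sum(counts: np.ndarray, n_all: int) -> float:
    """C(r) = sum_i (N_i / N_all)^2 over nonempty boxes."""
    if n_all <= 0:
        raise ValueError("n_all must be > 0")
    counts = np.asarray(counts)
    if int(counts.sum()) != int(n_all):
        raise ValueError("box counts must sum to n_all (every voxel in exactly one box)")
    p = counts / float(n_all)
    return float(p @ p)


def _offsets_for_r(r: int, params: FDParams) -> np.ndarray:
    """Integer grid offsets for box size r: (0,0,0) first, then seeded draws.

    The RNG is keyed by (offset_seed, r) so each box size has its own
    reproducible stream independent of evaluation order.
    """
    offs = np.zeros((params.n_offsets, 3), dtype=np.int64)
    if params.n_offsets > 1 and r > 1:
        rng = np.random.default_rng(np.random.SeedSequence([int(params.offset_seed), int(r)]))
        offs[1:] = rng.integers(0, r, size=(params.n_offsets - 1, 3))
    return offs


def max_box_size(vol: VoxelVolume, params: FDParams) -> int:
    """Largest box size: floor(max_r_fraction x shortest grid side)."""
    return int(np.floor(params.max_r_fraction * min(vol.shape)))


def boxcount_profile(vol: VoxelVolume, params: FDParams | None = None) -> BoxCountTable:
    """Correlation sums C(r) for r = min_r ... 70% of the shortest side.

    For each r the grid is counted at ``n_offsets`` offsets and the median
    C(r) is stored alongside the per-offset values; ``nc`` records the
    occupied-box count at the canonical (0,0,0) offset as a diagnostic.
    """
    params = params or FDParams()
    if vol.is_empty():
        raise ValueError("cannot profile an empty volume")
    r_max = max_box_size(vol, params)
    r_values = np.arange(params.min_r, r_max + 1, params.r_step, dtype=np.int64)
    if len(r_values) < params.min_fit_points:
        raise ValueError(
            f"usable box-size range {params.min_r}..{r_max} step {params.r_step} has "
            f"{len(r_values)} sizes < min_fit_points={params.min_fit_points}; "
            "use a larger volume or reduce min_fit_points"
        )
    n_all = vol.n_occupied
    table_sat = _integral_table(vol.occupancy)

    c_by_offset = np.empty((len(r_values), params.n_offsets))
    nc = np.empty(len(r_values), dtype=np.int64)
    inv_n2 = 1.0 / (float(n_all) ** 2)
    for i, r in enumerate(r_values):
        for j, off in enumerate(_offsets_for_r(int(r), params)):
            counts = _counts_from_integral(table_sat, int(r), (int(off[0]), int(off[1]), int(off[2])))
            # C(r) without materializing the nonzero subset: sum of squares
            c = counts.astype(np.int64)
            c_by_offset[i, j] = float(c @ c) * inv_n2
            if j == 0:
                nc[i] = int(np.count_nonzero(counts))
    c_median = np.median(c_by_offset, axis=1)
    return BoxCountTable(r=r_values, c_by_offset=c_by_offset, c_median=c_median, nc=nc, n_all=n_all)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _window_stats(x: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) OLS statistics for any contiguous window."""
    z = np.zeros(1)
    return (
        np.concatenate([z, np.cumsum(x)]),
        np.concatenate([z, np.cumsum(y)]),
        np.concatenate([z, np.cumsum(x * x)]),
        np.concatenate([z, np.cumsum(y * y)]),
        np.concatenate([z, np.cumsum(x * y)]),
    )


def fit_fd(table: BoxCountTable, params: FDParams | None = None) -> FDResult:
    """Breakpoint-optimized log-log fit: D2 = slope of ln C(r) on ln r.

    Scans every contiguous sub-range of box sizes with at least
    ``min_fit_points`` points and keeps the one maximizing R^2 (ties: more
    points, then smaller lower bound).  Windows with zero variance in
    ln C(r) carry no scaling information (e.g. the saturated single-box
    tail) and are skipped.  The reported breakpoint is the lower edge of
    the fitted range — the boundary between discarded small-r points and
    the linear portion — and equals ``r_min_used`` when nothing is
    excluded.
    """
    params = params or FDParams()
    x = np.log(np.asarray(table.r, dtype=float))
    y = np.log(np.asarray(table.c_median, dtype=float))
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() < params.min_fit_points:
        raise ValueError("fewer finite (ln r, ln C) points than min_fit_points")
    # restrict to the finite block (C>0 always in practice, so typically all rows)
    idx = np.flatnonzero(finite)
    x, y, r_vals = x[idx], y[idx], np.asarray(table.r)[idx]
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: zero variance in ln r")

    sx, sy, sxx, syy, sxy = _window_stats(x, y)
    m = params.min_fit_points
    best = None  # (r2, npts, i, j)
    for i in range(0, n - m + 1):
        for j in range(i + m - 1, n):
            k = j - i + 1
            mx = (sx[j + 1] - sx[i]) / k
            my = (sy[j + 1] - sy[i]) / k
            cxx = (sxx[j + 1] - sxx[i]) - k * mx * mx
            cyy = (syy[j + 1] - syy[i]) - k * my * my
            cxy = (sxy[j + 1] - sxy[i]) - k * mx * my
            if cxx <= 0 or cyy <= 1e-30:
                continue  # no scaling information in this window
            r2 = (cxy * cxy) / (cxx * cyy)
            if best is None:
                best = (r2, k, i, j)
                continue
            if r2 > best[0] + _R2_TIE_TOL:
                best = (r2, k, i, j)
            elif r2 > best[0] - _R2_TIE_TOL:
                # tie: prefer more points, then smaller r_min_used
                if k > best[1] or (k == best[1] and i < best[2]):
                    best = (max(r2, best[0]), k, i, j)
    if best is None:
        raise ValueError("no window with variance in both ln r and ln C; cannot fit")

    _, k, i, j = best
    xw, yw = x[i : j + 1], y[i : j + 1]
    # final fit recomputed directly on the window for numerical hygiene
    mx, my = xw.mean(), yw.mean()
    dx, dy = xw - mx, yw - my
    slope = float(dx @ dy / (dx @ dx))
    resid = dy - slope * dx
    ss_res = float(resid @ resid)
    ss_tot = float(dy @ dy)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / k))
    return FDResult(
        fd=slope,
        r_min_used=int(r_vals[i]),
        r_max_used=int(r_vals[j]),
        breakpoint=int(r_vals[i]),
        r_squared=float(r2),
        rmse=rmse,
        n_points_used=int(k),
        table=table,
        residuals=resid,
    )


def estimate_fd(vol: VoxelVolume, params: FDParams | None = None) -> FDResult:
    """End-to-end D2 estimate: box-count profile then breakpoint-optimized fit."""
    params = params or FDParams()
    if not params.allow_anisotropic and vol.anisotropy_ratio() > _MAX_ANISOTROPY:
        raise ValueError(
            f"voxel spacing {vol.spacing} is anisotropic (max/min ratio "
            f"{vol.anisotropy_ratio():.3f} > {_MAX_ANISOTROPY}); box counting assumes "
            "near-isotropic voxels — set allow_anisotropic=True to override"
        )
    return fit_fd(boxcount_profile(vol, params), params)
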