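"""Ground-truth phantoms: the Menger sponge and parametric rough shells.

The Menger sponge is the package's exact validation phantom: a cube is
divided into 27 subcubes and the 7 face/body-center cubes are removed, a
process repeated recursively.  Its similarity dimension ln(20)/ln(3) ~
2.726833 is known in closed form, so an empirical estimate has an exact
reference.

Rough shells are the synthetic stand-in for thin, convoluted cortical
sheets (e.g. cerebellar gray matter): a spherical shell whose radius is
modulated by seeded band-limited angular noise.  The roughness amplitude
maps monotonically to the estimated fractal dimension over roughly the
2.0-2.9 range, which is the only property downstream code relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import VoxelVolume

__all__ = [
    "MengerSpec",
    "RoughShellSpec",
    "generate_menger",
    "menger_theoretical_fd",
    "generate_rough_shell",
]

#: Refuse to allocate phantom grids larger than this many voxels per axis cubed.
DEFAULT_MEMORY_GUARD_VOXELS = 1024**3

# Rough-shell noise field: number of random angular components, lowest
# angular frequency, and radial perturbation gain per unit amplitude as a
# fraction of the outer radius.  Chosen once so that amplitudes 0..~1.2 span
# estimated FD ~2.0..~2.6 on the default 96^3 grid (the cortical-sheet range).
_N_NOISE_COMPONENTS = 64
_MIN_FREQUENCY = 3.0
_ROUGHNESS_GAIN = 0.2


@dataclass(frozen=True)
class MengerSpec:
    """Menger sponge construction: ``iterations`` recursion levels, smallest
    hole edge ``cell_scale`` voxels.  Grid edge is ``cell_scale * 3**iterations``."""

    iterations: int
    cell_scale: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.cell_scale < 1:
            raise ValueError("cell_scale must be >= 1")

    @property
    def grid_edge(self) -> int:
        return self.cell_scale * 3**self.iterations


@dataclass(frozen=True)
class RoughShellSpec:
    """A thin closed shell around a sphere with seeded angular roughness.

    ``roughness_amplitude`` is dimensionless; 0 gives a smooth spherical
    shell.  ``roughness_scale`` bounds the angular frequency of the noise
    (higher = finer surface wrinkles).  The generated volume is a pure
    function of the spec (seed included).
    """

    outer_radius: float
    thickness: float = 2.0
    roughness_amplitude: float = 0.0
    roughness_scale: float = 96.0
    grid_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1 voxel")
        if self.outer_radius <= self.thickness:
            raise ValueError("degenerate spec: outer_radius must exceed thickness")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        if self.roughness_scale <= 0:
            raise ValueError("roughness_scale must be > 0")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")


def menger_theoretical_fd() -> float:
    """Similarity dimension of the Menger sponge, ln(20)/ln(3) ~ 2.726833.

    Each construction step keeps 20 of 27 subcubes at linear scale factor 3,
    so 3**D = 20 exactly.
    """
    return math.log(20.0) / math.log(3.0)


def generate_menger(
    spec: MengerSpec, *, memory_guard_voxels: int = DEFAULT_MEMORY_GUARD_VOXELS
) -> VoxelVolume:
    """Voxelized ``iterations``-level Menger sponge.

    A unit cell at the deepest level is retained iff at every recursion
    level the base-3 digit triple of its (x, y, z) cell coordinates has at
    most one digit equal to 1 — the digitwise form of the keep-20-of-27
    rule.  This is vectorizable and provably equivalent to recursive
    carving.  Occupied count is exactly ``20**k * s**3``.
    """
    n = spec.grid_edge
    if n**3 > memory_guard_voxels:
        raise ValueError(
            f"Menger grid {n}^3 = {n**3} voxels exceeds the memory guard "
            f"({memory_guard_voxels} voxels); reduce iterations or cell_scale"
        )
    cell = np.arange(n) // spec.cell_scale  # cell coordinate in [0, 3**k)
    occ = np.ones((n, n, n), dtype=bool)
    for level in range(spec.iterations):
        digit = (cell // 3**level) % 3
        is_one = (digit == 1).astype(np.uint8)
        ones_in_triple = (
            is_one[:, None, None] + is_one[None, :, None] + is_one[None, None, :]
        )
        occ &= ones_in_triple <= 1
    return VoxelVolume(occ)


def _angular_noise_params(spec: RoughShellSpec):
    """Seeded band-limited angular noise field parameters.

    The field is f(u) = sum_m a_m cos(k_m . u + phi_m) over unit directions
    u, with |k_m| log-uniform in [3, roughness_scale] and a flat spectrum,
    normalized to unit RMS over the sphere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5E11]))
    m = _N_NOISE_COMPONENTS
    # random directions for the wavevectors
    v = rng.normal(size=(m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    q_max = max(spec.roughness_scale, _MIN_FREQUENCY + 1e-6)
    freq = np.exp(rng.uniform(np.log(_MIN_FREQUENCY), np.log(q_max), size=m))
    k = v * freq[:, None]
    phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
    amp = rng.normal(size=m)
    # normalize to unit RMS on a fixed quasi-uniform direction sample
    u = rng.normal(size=(4096, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    sample = np.cos(u @ k.T + phase) @ amp
    rms = float(np.sqrt(np.mean(sample**2)))
    amp = amp / max(rms, 1e-12)
    return k, phase, amp


def _eval_noise(directions: np.ndarray, k, phase, amp) -> np.ndarray:
    return np.cos(directions @ k.T + phase) @ amp


def generate_rough_shell(spec: RoughShellSpec) -> VoxelVolume:
    """Closed shell of the given thickness around a noise-modulated sphere.

    The local outer radius along direction u is
    ``outer_radius + delta(u)`` where ``delta = h * tanh(g f(u) / h)``,
    f a unit-RMS seeded band-limited angular field,
    ``g = 0.2 * outer_radius * roughness_amplitude`` the roughness gain,
    and ``h`` the radial headroom between the sphere and the grid boundary.
    The tanh soft clip guarantees the perturbed shell always fits inside
    the grid while preserving monotonicity of surface irregularity in the
    amplitude.  A voxel is occupied iff its center distance from the grid
    center falls within ``(R_local - thickness, R_local]``.

    Raises
    ------
    ValueError
        If the grid leaves less than 2 voxels of radial headroom around the
        unperturbed shell.
    """
    k, phase, amp = _angular_noise_params(spec)
    gain = _ROUGHNESS_GAIN * spec.outer_radius * spec.roughness_amplitude
    headroom = spec.grid_size / 2.0 - 1.5 - spec.outer_radius
    if headroom < 2.0:
        raise ValueError(
            f"shell does not fit: outer_radius {spec.outer_radius} leaves "
            f"{headroom:.1f} < 2 voxels of headroom in a {spec.grid_size}^3 grid"
        )

    n = spec.grid_size
    c = (n - 1) / 2.0
    ax = np.arange(n) - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    d = np.sqrt(d2)

    # only voxels inside the widest possible radial band need the noise field
    lo = spec.outer_radius - spec.thickness - headroom
    hi = spec.outer_radius + headroom
    band = (d > max(lo, 0.0)) & (d <= hi) & (d > 0)
    occ = np.zeros((n, n, n), dtype=bool)
    if not band.any():
        raise ValueError("degenerate spec: shell band contains no voxels")

    pts = np.argwhere(band) - c
    dist = d[band]
    if gain > 0:
        dirs = pts / dist[:, None]
        delta = headroom * np.tanh(gain * _eval_noise(dirs, k, phase, amp) / headroom)
        r_local = spec.outer_radius + delta
    else:
        r_local = np.full(dist.shape, spec.outer_radius)
    inside = (dist > r_local - spec.thickness) & (dist <= r_local)
    occ[band] = inside
    if not occ.any():
        raise ValueError("degenerate spec: generated shell is empty")
    return VoxelVolume(occ)
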