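"""3D collagen fiber orientation from SHG-like volumes.

A second-harmonic-generation volume of fibrillar collagen is tiled into
overlapping subvolumes; within each, the local fiber axis is estimated in
the Fourier domain: the spectral energy of a straight fiber concentrates
in the plane normal to the fiber axis, so the axis is the eigenvector of
the *smallest* eigenvalue of the spectral second-moment tensor.  Each
axis is reported both as a unit 3-vector (with antipodal identification,
v and -v are the same fiber direction) and as the angle pair
``(theta, phi)``: theta the in-plane angle in [0, 180) deg from +x in the
x-y image plane, phi the out-of-plane angle in [-90, 90] deg between the
fiber and the image plane.

Dispersion is summarized by angle statistics and the spherical variance

    ``SV = 1 - |sum_i v_i| / n``,   0 <= SV <= 1,

computed after folding all axes into a common hemisphere (sign flipped to
a nonnegative dot product with the dominant eigenvector of the
orientation scatter matrix -- a rotation-invariant convention).  SV = 0
means perfectly aligned axes.  The reported normalized value divides by
``sv_max`` (default 0.4, the theoretical maximum for fully disordered
axial data under the folding convention of the upstream literature; the
constant is configuration, not re-derived here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberVolume",
    "OrientationField",
    "DispersionSummary",
    "estimate_orientations",
    "fold_axes",
    "spherical_variance",
    "dispersion_summary",
]


@dataclass
class FiberVolume:
    """Nonnegative intensity volume, indexed ``voxels[z, y, x]`` (TIFF
    page order), with per-axis voxel size in microns ``(dz, dy, dx)``."""

    voxels: np.ndarray
    voxel_size_um: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if np.nanmin(self.voxels) < 0:
            raise ValueError("intensities must be nonnegative")
        if max(self.voxels.shape) < 16:
            raise ValueError("at least one volume side must be >= 16 voxels")


@dataclass
class OrientationField:
    """Per-subvolume fiber axes: positions are subvolume-center indices
    (z, y, x); axes are unit vectors in (x, y, z) components with
    antipodal identification."""

    positions: np.ndarray   # (n, 3) voxel indices
    axes: np.ndarray        # (n, 3) unit vectors, (vx, vy, vz)
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    weight: np.ndarray      # spectral energy
    valid: np.ndarray

    def valid_axes(self) -> np.ndarray:
        return self.axes[self.valid]


@dataclass
class DispersionSummary:
    theta_mean_deg: float
    theta_std_deg: float
    phi_mean_deg: float
    phi_std_deg: float
    sv: float
    sv_normalized: float
    n_axes: int


def _axis_angles(v: np.ndarray):
    """(theta, phi) in degrees for unit axes (vx, vy, vz), after canonical
    antipodal choice theta in [0, 180)."""
    v = np.array(v, dtype=float, copy=True)
    # canonical representative: in-plane direction with vy >= 0 (theta < 180)
    flip = (v[..., 1] < 0) | ((v[..., 1] == 0) & (v[..., 0] < 0))
    v[flip] *= -1.0
    theta = np.rad2deg(np.arctan2(v[..., 1], v[..., 0])) % 180.0
    phi = np.rad2deg(np.arctan2(v[..., 2], np.hypot(v[..., 0], v[..., 1])))
    return theta, phi


def _hann3(shape):
    wins = [np.hanning(n) if n > 1 else np.ones(1) for n in shape]
    return wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]


def estimate_orientations(
    vol: FiberVolume,
    subvolume_size: int = 32,
    step: int | None = None,
    energy_min: float = 1e-6,
    aniso_min: float = 0.2,
    low_freq_shells: int = 2,
) -> OrientationField:
    """Estimate the local fiber axis in every windowed subvolume.

    Per subvolume: apply a Hann window, take the 3D power spectrum, remove
    the DC term and the lowest ``low_freq_shells`` frequency shells
    (suppresses illumination gradients), form the second-moment tensor of
    the spectral energy over physical frequency coordinates, and take the
    eigenvector of its smallest eigenvalue as the fiber axis.

    Subvolumes are flagged invalid when their windowed energy falls below
    ``energy_min`` times the global maximum subvolume energy, or when the
    spectral anisotropy ``1 - lambda_min/lambda_mid`` falls below
    ``aniso_min`` (an isotropic spectrum -- flat or pure noise -- carries
    no orientation).
    """
    data = vol.voxels
    n = int(subvolume_size)
    if any(s < n for s in data.shape):
        raise ValueError("subvolume does not fit in the volume")
    step = step or n // 2
    win = _hann3((n, n, n))
    dz, dy, dx = vol.voxel_size_um
    fz = np.fft.fftfreq(n, d=dz)
    fy = np.fft.fftfreq(n, d=dy)
    fx = np.fft.fftfreq(n, d=dx)
    FZ, FY, FX = np.meshgrid(fz, fy, fx, indexing="ij")
    # index-space radius for the DC/low-shell cut
    iz = np.minimum(np.arange(n), n - np.arange(n))
    IR = np.sqrt(
        iz[:, None, None] ** 2 + iz[None, :, None] ** 2 + iz[None, None, :] ** 2
    )
    keep = IR > low_freq_shells
    f = np.stack([FX, FY, FZ], axis=-1)

    positions, axes, weights = [], [], []
    aniso_vals = []
    for z0 in range(0, data.shape[0] - n + 1, step):
        for y0 in range(0, data.shape[1] - n + 1, step):
            for x0 in range(0, data.shape[2] - n + 1, step):
                sub = data[z0:z0 + n, y0:y0 + n, x0:x0 + n] * win
                spec = np.abs(np.fft.fftn(sub)) ** 2
                spec = np.where(keep, spec, 0.0)
                e = spec.sum()
                positions.append((z0 + n // 2, y0 + n // 2, x0 + n // 2))
                if e <= 0:
                    axes.append((np.nan, np.nan, np.nan))
                    weights.append(0.0)
                    aniso_vals.append(0.0)
                    continue
                # second-moment tensor in (fx, fy, fz) ordering
                T = np.einsum("zyx,zyxi,zyxj->ij", spec, f, f) / e
                lam, vec = np.linalg.eigh(T)  # ascending
                aniso = 1.0 - lam[0] / max(lam[1], 1e-300)
                v = vec[:, 0]
                axes.append(v / np.linalg.norm(v))
                weights.append(float(e))
                aniso_vals.append(float(aniso))

    positions = np.array(positions)
    axes = np.array(axes, dtype=float)
    weights = np.array(weights)
    aniso_vals = np.array(aniso_vals)
    wmax = weights.max() if weights.size else 0.0
    valid = (
        (weights > energy_min * max(wmax, 1e-300))
        & (aniso_vals >= aniso_min)
        & np.isfinite(axes).all(axis=1)
    )
    theta = np.full(len(axes), np.nan)
    phi = np.full(len(axes), np.nan)
    if np.any(valid):
        theta[valid], phi[valid] = _axis_angles(axes[valid])
    return OrientationField(
        positions=positions, axes=axes, theta_deg=theta, phi_deg=phi,
        weight=weights, valid=valid,
    )


def fold_axes(axes: np.ndarray) -> np.ndarray:
    """Fold antipodal axes into a common hemisphere.

    The hemisphere pole is the dominant eigenvector of the scatter matrix
    ``sum v v^T`` (rotation invariant); each axis is sign-flipped to a
    nonnegative dot product with it.
    """
    v = np.asarray(axes, dtype=float)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector is not a valid axis")
    v = v / norms
    S = v.T @ v
    _, vec = np.linalg.eigh(S)
    pole = vec[:, -1]
    sign = np.where(v @ pole < 0, -1.0, 1.0)
    return v * sign[:, None]


def spherical_variance(axes: np.ndarray, fold: bool = True) -> float:
    """``SV = 1 - |sum_i v_i| / n`` over unit axes.

    0 for identical (or antipodally identical) axes, approaching the
    axial-data maximum for fully disordered orientations.  ``fold``
    applies the hemisphere folding first (set False only if the input is
    already folded).
    """
    v = np.asarray(axes, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("need at least one axis")
    v = fold_axes(v) if fold else v / np.linalg.norm(v, axis=-1, keepdims=True)
    n = v.shape[0]
    return float(1.0 - np.linalg.norm(v.sum(axis=0)) / n)


def dispersion_summary(
    field_or_axes, sv_max: float = 0.4
) -> DispersionSummary:
    """Angle statistics and normalized spherical variance of a set of
    axes (or the valid axes of an :class:`OrientationField`)."""
    if isinstance(field_or_axes, OrientationField):
        axes = field_or_axes.valid_axes()
    else:
        axes = np.asarray(field_or_axes, dtype=float)
    if axes.shape[0] < 1:
        raise ValueError("need at least one valid axis")
    folded = fold_axes(axes)
    # theta is axial (period 180 deg): use double-angle circular statistics
    # so that axes straddling the 0/180 wrap do not bias the mean
    th = np.arctan2(folded[..., 1], folded[..., 0])
    z = np.exp(2j * th)
    zbar = z.mean()
    theta_mean = (0.5 * np.rad2deg(np.angle(zbar))) % 180.0
    R2 = min(max(np.abs(zbar), 1e-300), 1.0)
    theta_std = 0.5 * np.rad2deg(np.sqrt(-2.0 * np.log(R2)))
    phi = np.rad2deg(
        np.arctan2(folded[..., 2], np.hypot(folded[..., 0], folded[..., 1]))
    )
    sv = spherical_variance(folded, fold=False)
    return DispersionSummary(
        theta_mean_deg=float(theta_mean),
        theta_std_deg=float(theta_std),
        phi_mean_deg=float(np.mean(phi)),
        phi_std_deg=float(np.std(phi)),
        sv=sv,
        sv_normalized=sv / sv_max,
        n_axes=int(axes.shape[0]),
    )
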