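"""Synthetic data generators: ring-tissue Mueller phantoms, a time-course
cohort with a control and a growth-factor-treated arm, calibration
reference acquisitions, and 3D fiber volumes.

These generators stand in for microscope data.  The ring phantom mimics a
fibroblast-derived ring-shaped tissue construct imaged in transmission: an
annulus of birefringent tissue with a circumferential fast axis, a linear
retardance profile peaking nearer the inner ring edge, weak circular
depolarization, and near-zero circular retardance and linear
depolarization (the experimentally observed counterpart independence).
Outside the annulus is clean background (identity).  Optional defect
spots carry abnormally high depolarization so that the MAD tissue mask
has something to exclude.

Every generator returns machine-readable ground truth alongside the data,
and is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import mueller
from .calibration import ReferenceAcquisitionSet
from .instrument import (
    InstrumentModel,
    IntensityStack,
    NoiseSpec,
    forward_acquire,
)
from .mueller import ElementarySampleSpec
from .shg import FiberVolume

__all__ = [
    "RingPhantomSpec",
    "RingPhantom",
    "TimeCourseSpec",
    "make_ring_phantom",
    "make_cohort",
    "make_reference_acquisitions",
    "make_fiber_volume",
    "sample_watson_axes",
    "REFERENCE_ELEMENTS",
]

#: days at which constructs are measured
DAYS = (2, 4, 7, 14, 21)

#: per-(day, arm) mean linear retardance (deg) and circular depolarization
#: trajectories of the study the generator emulates, plus between-sample
#: standard deviations and per-cell sample sizes
DELTA_MEAN = {
    "control": (4.37, 2.31, 3.32, 7.66, 11.02),
    "treated": (3.73, 4.00, 12.55, 13.23, 11.96),
}
DELTA_SD = {
    "control": (0.77, 0.89, 1.03, 1.32, 2.99),
    "treated": (1.06, 0.65, 2.21, 2.15, 2.69),
}
DELTAC_MEAN = {
    "control": (12.83e-3, 22.93e-3, 14.24e-3, 28.47e-3, 35.44e-3),
    "treated": (13.25e-3, 14.70e-3, 50.65e-3, 44.39e-3, 43.93e-3),
}
DELTAC_SD = {
    "control": (3.04e-3, 28.28e-3, 3.23e-3, 12.55e-3, 12.42e-3),
    "treated": (1.934e-3, 3.25e-3, 24.33e-3, 17.42e-3, 15.70e-3),
}
N_SAMPLES = {"control": (8, 8, 12, 9, 13), "treated": (8, 8, 9, 10, 9)}


@dataclass(frozen=True)
class RingPhantomSpec:
    """Ground-truth description of one ring phantom.

    The delta and DeltaC radial profiles are ``baseline + amplitude *
    gauss((f - center)/width)`` with ``f`` the fractional distance across
    the ring width from the inner edge; the default peak sits at 30% of
    the width, nearer the inner ring.  Desk-scale geometry: the bench
    annulus (5 mm inner diameter, 0.75 mm trough) is shrunk to fit a
    256 px field while keeping the radial profile shape.
    """

    shape: tuple = (256, 256)
    pixel_pitch_um: float = 1.0
    center: tuple | None = None          # (row, col) px; default image center
    inner_radius_um: float = 60.0
    ring_width_um: float = 55.0
    axis_pattern: str = "circumferential"  # or "constant"
    axis_constant_deg: float = 0.0
    delta_baseline_deg: float = 3.0
    delta_bump_deg: float = 5.0
    delta_bump_center: float = 0.3
    delta_bump_width: float = 0.15
    deltac_baseline: float = 0.02
    deltac_bump: float = 0.01
    deltac_bump_center: float = 0.3
    deltac_bump_width: float = 0.15
    deltal: float = 0.005
    psi_deg: float = 0.0
    diattenuation: float = 0.01
    n_defects: int = 0
    defect_radius_um: float = 4.0
    defect_depol: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.delta_bump_center < 1.0:
            raise ValueError("bump center must be a fraction in (0, 1)")
        if not 0.0 <= self.diattenuation <= 1.0:
            raise ValueError("diattenuation must lie in [0, 1]")
        if not 0.0 <= self.deltal <= 1.0 or not 0.0 <= self.deltac_baseline <= 1.0:
            raise ValueError("depolarization levels must lie in [0, 1]")

    # radial profiles -------------------------------------------------------
    def delta_profile(self, f):
        f = np.asarray(f, dtype=float)
        return self.delta_baseline_deg + self.delta_bump_deg * np.exp(
            -0.5 * ((f - self.delta_bump_center) / self.delta_bump_width) ** 2
        )

    def deltac_profile(self, f):
        f = np.asarray(f, dtype=float)
        return self.deltac_baseline + self.deltac_bump * np.exp(
            -0.5 * ((f - self.deltac_bump_center) / self.deltac_bump_width) ** 2
        )

    def analytic_mean_delta(self, n: int = 4001) -> float:
        """Area-weighted mean of the delta profile over the annulus
        (closed-form radial integral evaluated on a fine grid)."""
        f = np.linspace(0.0, 1.0, n)
        r = self.inner_radius_um + f * self.ring_width_um
        w = r  # annular area element ~ r dr
        return float(np.trapezoid(self.delta_profile(f) * w, f)
                     / np.trapezoid(w, f))


@dataclass
class RingPhantom:
    """Composed phantom: per-pixel Mueller field plus the truth maps it
    was built from (delta_deg, axis_deg, DeltaC, DeltaL, psi_deg, D,
    in_ring, defect)."""

    spec: RingPhantomSpec
    mueller_field: np.ndarray  # (H, W, 4, 4)
    truth: dict


def make_ring_phantom(spec: RingPhantomSpec) -> RingPhantom:
    """Render a ring phantom as a per-pixel Mueller matrix field.

    Per pixel inside the annulus
    ``M = M_depol(1-DL, 1-DL, 1-DC) @ M_rot(psi) @ M_ret(delta, axis) @
    M_diat(D)``; background pixels are clean identity; defect spots are
    high-depolarization disks.
    """
    H, W = spec.shape
    cy, cx = spec.center if spec.center is not None else ((H - 1) / 2, (W - 1) / 2)
    rr, cc = np.mgrid[0:H, 0:W]
    dy = (rr - cy) * spec.pixel_pitch_um
    dx = (cc - cx) * spec.pixel_pitch_um
    r = np.hypot(dx, dy)
    f = (r - spec.inner_radius_um) / spec.ring_width_um
    in_ring = (f >= 0) & (f <= 1)

    delta = np.where(in_ring, spec.delta_profile(np.clip(f, 0, 1)), 0.0)
    deltac = np.where(in_ring, spec.deltac_profile(np.clip(f, 0, 1)), 0.0)
    deltal = np.where(in_ring, spec.deltal, 0.0)
    psi = np.where(in_ring, spec.psi_deg, 0.0)
    diat = np.where(in_ring, spec.diattenuation, 0.0)
    if spec.axis_pattern == "circumferential":
        # tangent to the ring; image rows grow downward, angles ccw from +x
        axis = (np.rad2deg(np.arctan2(-dy, dx)) + 90.0) % 180.0
    elif spec.axis_pattern == "constant":
        axis = np.full((H, W), spec.axis_constant_deg % 180.0)
    else:
        raise ValueError(f"unknown axis pattern {spec.axis_pattern!r}")

    defect = np.zeros((H, W), dtype=bool)
    if spec.n_defects:
        rng = np.random.default_rng(spec.seed)
        ring_px = np.argwhere(in_ring)
        picks = ring_px[rng.choice(len(ring_px), size=spec.n_defects, replace=False)]
        rad_px = spec.defect_radius_um / spec.pixel_pitch_um
        for py, px in picks:
            defect |= (rr - py) ** 2 + (cc - px) ** 2 <= rad_px**2
        defect &= in_ring

    a = 1.0 - deltal
    c = 1.0 - deltac
    a = np.where(defect, 1.0 - spec.defect_depol, a)
    c = np.where(defect, 1.0 - spec.defect_depol, c)

    Mdep = mueller.make_diagonal_depolarizer(a, a, c)
    Mret = mueller.make_linear_retarder(delta, axis)
    M = Mdep @ Mret
    if spec.psi_deg:
        M = M @ mueller.make_rotator(psi)
    if spec.diattenuation:
        q = np.ones_like(diat)
        rt = (1.0 - diat) / (1.0 + diat)
        M = M @ mueller.make_linear_diattenuator(q, rt, axis)
    M = np.where(in_ring[..., None, None], M, np.eye(4))

    truth = {
        "delta_deg": np.where(defect, np.nan, delta),
        "axis_deg": axis,
        "DeltaC": np.where(defect, spec.defect_depol, deltac),
        "DeltaL": np.where(defect, spec.defect_depol, deltal),
        "psi_deg": psi,
        "D": diat,
        "in_ring": in_ring,
        "defect": defect,
    }
    return RingPhantom(spec=spec, mueller_field=M, truth=truth)


# ---------------------------------------------------------------------------
# time-course cohort


@dataclass(frozen=True)
class TimeCourseSpec:
    """Cohort design: per-(day, arm) mean trajectories of linear
    retardance and circular depolarization with between-sample normal
    variation (truncated at zero) and the study's per-cell sample sizes.

    Defaults pin the trajectories, sds and n's to the measured study
    values, so the default cohort reproduces their qualitative structure:
    the treated arm reaches its delta plateau by day 7 while the control
    arm rises through day 21.
    """

    days: tuple = DAYS
    delta_mean: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DELTA_MEAN.items()})
    delta_sd: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DELTA_SD.items()})
    deltac_mean: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DELTAC_MEAN.items()})
    deltac_sd: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DELTAC_SD.items()})
    n_samples: dict = field(default_factory=lambda: {k: tuple(v) for k, v in N_SAMPLES.items()})
    phantom: RingPhantomSpec = field(
        default_factory=lambda: RingPhantomSpec(shape=(64, 64), inner_radius_um=14.0,
                                                ring_width_um=14.0, delta_bump_deg=0.0,
                                                deltac_bump=0.0)
    )
    seed: int = 0

    def subset(self, days=None, n_per_cell=None) -> "TimeCourseSpec":
        """Reduced design: restrict to a subset of days and/or override
        every cell's sample size (handy for quick runs)."""
        days = tuple(days) if days is not None else self.days
        idx = [self.days.index(d) for d in days]
        pick = lambda table: {k: tuple(v[i] for i in idx) for k, v in table.items()}
        n = (
            {k: (int(n_per_cell),) * len(idx) for k in self.n_samples}
            if n_per_cell is not None
            else pick(self.n_samples)
        )
        return dataclasses.replace(
            self, days=days, delta_mean=pick(self.delta_mean),
            delta_sd=pick(self.delta_sd), deltac_mean=pick(self.deltac_mean),
            deltac_sd=pick(self.deltac_sd), n_samples=n,
        )


def _trunc_normal(rng, mean, sd, size=None):
    if sd == 0:
        return np.full(size if size is not None else (), float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def make_cohort(spec: TimeCourseSpec):
    """Draw a cohort of ring-phantom specs with per-sample parameter means.

    Returns ``(samples, truth_table)``: a list of ``(RingPhantomSpec,
    meta)`` pairs and a DataFrame of the drawn ground-truth means (one row
    per sample; columns sample_id, batch_id, day, group, delta_deg,
    DeltaC).  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    samples, rows = [], []
    sid = 0
    for arm in ("control", "treated"):
        for k, day in enumerate(spec.days):
            n = spec.n_samples[arm][k]
            d_mu, d_sd = spec.delta_mean[arm][k], spec.delta_sd[arm][k]
            c_mu, c_sd = spec.deltac_mean[arm][k], spec.deltac_sd[arm][k]
            for _ in range(n):
                d = float(_trunc_normal(rng, d_mu, d_sd))
                c = float(np.clip(_trunc_normal(rng, c_mu, c_sd), 0.0, 0.95))
                ps = dataclasses.replace(
                    spec.phantom,
                    delta_baseline_deg=d,
                    deltac_baseline=c,
                    seed=int(rng.integers(2**31 - 1)),
                )
                meta = {"sample_id": sid, "batch_id": 0, "day": day, "group": arm}
                samples.append((ps, meta))
                rows.append({**meta, "delta_deg": d, "DeltaC": c})
                sid += 1
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration references

#: the bench's reference set: air, polarizer at 0/45/90 deg, QWP at 0/45 deg
REFERENCE_ELEMENTS = (
    ElementarySampleSpec("air"),
    ElementarySampleSpec("diattenuator", axis_deg=0.0),
    ElementarySampleSpec("diattenuator", axis_deg=45.0),
    ElementarySampleSpec("diattenuator", axis_deg=90.0),
    ElementarySampleSpec("retarder", retardance_deg=90.0, axis_deg=0.0),
    ElementarySampleSpec("retarder", retardance_deg=90.0, axis_deg=45.0),
)


def make_reference_acquisitions(
    instrument: InstrumentModel,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    elements=REFERENCE_ELEMENTS,
) -> ReferenceAcquisitionSet:
    """Forward-acquire the calibration reference set through a (possibly
    imperfect) instrument.  Returns the 8x6 intensity matrices paired with
    the nominal element specs."""
    b_air = None
    refs = []
    ss = np.random.SeedSequence(seed) if seed is not None else None
    for i, el in enumerate(elements):
        s = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)) if ss is not None else None
        stack = forward_acquire(el.to_mueller(), instrument, noise=noise, seed=s)
        B = stack.as_matrix()
        if el.kind == "air":
            b_air = B
        else:
            refs.append((el, B))
    if b_air is None:
        raise ValueError("reference element list must include air")
    return ReferenceAcquisitionSet(b_air=b_air, refs=tuple(refs))


# ---------------------------------------------------------------------------
# fiber volumes


def sample_watson_axes(mean_axis, kappa: float, n: int, rng) -> np.ndarray:
    """Sample ``n`` axes from a Watson distribution (axial, density
    proportional to ``exp(kappa (mu . x)^2)``) about ``mean_axis``.
    Rejection sampling on ``t = cos(angle)``; azimuth uniform."""
    if kappa <= 0:
        raise ValueError("concentration kappa must be > 0")
    mu = np.asarray(mean_axis, dtype=float)
    mu = mu / np.linalg.norm(mu)
    ts = []
    while len(ts) < n:
        cand = rng.uniform(-1.0, 1.0, size=4 * n)
        u = rng.uniform(0.0, 1.0, size=cand.size)
        acc = cand[u < np.exp(kappa * (cand**2 - 1.0))]
        ts.extend(acc.tolist())
    t = np.array(ts[:n])
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    s = np.sqrt(np.clip(1 - t**2, 0, None))
    local = np.stack([s * np.cos(phi), s * np.sin(phi), t], axis=1)
    # rotate local +z to mu
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, mu)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if mu[2] > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        c = float(z @ mu)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
    return local @ R.T


def make_fiber_volume(
    n_fibers: int = 40,
    mean_axis=(1.0, 0.0, 0.0),
    kappa: float = 20.0,
    fiber_radius_um: float = 1.0,
    shape: tuple = (48, 48, 48),
    voxel_size_um: tuple = (1.0, 1.0, 1.0),
    psf_sigma_um: float = 0.8,
    amplitude: float = 40.0,
    background: float = 2.0,
    poisson: bool = True,
    seed: int | None = None,
):
    """Render straight cylindrical fibers with Watson-distributed axes.

    Returns ``(FiberVolume, true_axes)`` where ``true_axes`` is the
    (n_fibers, 3) array of ground-truth axis vectors in (x, y, z)
    components.  Gaussian blur emulates the microscope PSF; Poisson noise
    the photon statistics.
    """
    rng = np.random.default_rng(seed)
    axes = sample_watson_axes(mean_axis, kappa, n_fibers, rng)
    nz, ny, nx = shape
    dz, dy, dx = voxel_size_um
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    P = np.stack([xx * dx, yy * dy, zz * dz], axis=-1).astype(float)  # (z,y,x,3)
    extent = np.array([nx * dx, ny * dy, nz * dz])
    vol = np.zeros(shape)
    for v in axes:
        c = rng.uniform(0.1, 0.9, size=3) * extent
        rel = P - c
        along = rel @ v
        d2 = np.einsum("...i,...i->...", rel, rel) - along**2
        vol += amplitude * np.exp(-0.5 * d2 / fiber_radius_um**2)
    vol += background
    sig = [psf_sigma_um / d for d in (dz, dy, dx)]
    vol = ndimage.gaussian_filter(vol, sigma=sig)
    if poisson:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
    return FiberVolume(voxels=vol, voxel_size_um=voxel_size_um), axes
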