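"""Digital twin of the transmission Mueller polarimeter.

The bench is a wide-field microscope with a polarization state generator
(PSG: rotatable linear polarizer + insertable quarter-wave plate) before
the sample and a polarization state analyzer (PSA: insertable quarter-wave
plate + rotatable polarizer) after it.  A full acquisition cycles the PSG
through 6 input states -- linear 0/45/90/-45 deg plus right- and
left-circular -- and, for each, the PSA through 8 analyzer configurations,
so 48 intensity frames are captured per measurement.

Writing the 6 input Stokes vectors as the columns of ``W`` (4x6) and the 8
analyzer projection vectors as the rows of ``A`` (8x4), the ideal camera
signal at one pixel is the 8x6 matrix ``B = A M W`` where ``M`` is the
sample Mueller matrix; reconstruction inverts this with pseudo-inverses.
The over-determined 6x8 schedule (48 frames instead of the minimal 16)
is what makes the measurement robust to noise.

``build_instrument`` composes the PSG/PSA optical trains from elementary
Mueller matrices, optionally with systematic imperfections (element
mounting offsets, wave-plate retardance error, polarizer leakage), which
is exactly what the eigenvalue calibration in :mod:`ringpol.calibration`
is later asked to recover.  ``forward_acquire`` adds shot noise, read
noise, frame averaging and quantization to emulate a camera.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .mueller import (
    make_linear_diattenuator,
    make_linear_retarder,
    rotation_mueller,
)

__all__ = [
    "PSGState",
    "PSAConfig",
    "MeasurementSchedule",
    "ArmErrors",
    "InstrumentModel",
    "NoiseSpec",
    "IntensityStack",
    "ideal_schedule",
    "build_instrument",
    "ideal_instrument",
    "forward_acquire",
]


@dataclass(frozen=True)
class PSGState:
    """One generator setting: polarizer angle, and whether/where the
    quarter-wave plate is inserted after it."""

    polarizer_deg: float
    qwp_in: bool = False
    qwp_deg: float = 0.0


@dataclass(frozen=True)
class PSAConfig:
    """One analyzer setting: light traverses the (optional) quarter-wave
    plate first, then the polarizer, then hits the camera."""

    polarizer_deg: float
    qwp_in: bool = False
    qwp_deg: float = 0.0


@dataclass(frozen=True)
class MeasurementSchedule:
    psg_states: tuple
    psa_configs: tuple

    @property
    def n_frames(self) -> int:
        return len(self.psg_states) * len(self.psa_configs)

    def frame_index(self, psg_j: int, psa_i: int) -> int:
        """Frames are ordered PSG-major: all 8 analyzer configurations for
        generator state 0, then state 1, ..."""
        return psg_j * len(self.psa_configs) + psa_i

    def fingerprint(self) -> str:
        blob = json.dumps(
            [
                [asdict(s) for s in self.psg_states],
                [asdict(c) for c in self.psa_configs],
            ],
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def ideal_schedule() -> MeasurementSchedule:
    """The 6x8 acquisition schedule.

    PSG states produce, in order, the Stokes vectors
    ``(1,1,0,0), (1,0,1,0), (1,-1,0,0), (1,0,-1,0), (1,0,0,1), (1,0,0,-1)``
    (linear 0/45/90/-45 deg, right circular, left circular).  The 8 PSA
    configurations analyze those same six states plus two redundant ones
    (0 deg and 45 deg re-analyzed with the quarter-wave plate inserted),
    keeping ``A`` rank 4 and well conditioned.
    """
    psg = (
        PSGState(0.0),
        PSGState(45.0),
        PSGState(90.0),
        PSGState(-45.0),
        PSGState(0.0, qwp_in=True, qwp_deg=45.0),   # right circular
        PSGState(0.0, qwp_in=True, qwp_deg=-45.0),  # left circular
    )
    psa = (
        PSAConfig(0.0),
        PSAConfig(45.0),
        PSAConfig(90.0),
        PSAConfig(-45.0),
        PSAConfig(0.0, qwp_in=True, qwp_deg=-45.0),  # analyzes right circular
        PSAConfig(0.0, qwp_in=True, qwp_deg=45.0),   # analyzes left circular
        PSAConfig(0.0, qwp_in=True, qwp_deg=0.0),    # redundant 0 deg
        PSAConfig(45.0, qwp_in=True, qwp_deg=45.0),  # redundant 45 deg
    )
    return MeasurementSchedule(psg, psa)


_MAX_ANGLE_OFFSET = 10.0
_MAX_RET_OFFSET = 20.0


@dataclass(frozen=True)
class ArmErrors:
    """Systematic imperfections of one arm (PSG or PSA).

    One physical polarizer and one physical wave plate serve all states of
    an arm, so a mounting offset shifts every nominal angle of that element
    by the same amount.
    """

    polarizer_offset_deg: float = 0.0
    qwp_offset_deg: float = 0.0
    qwp_retardance_offset_deg: float = 0.0
    polarizer_leakage: float = 0.0  # r-transmittance of the real polarizer

    def __post_init__(self):
        if (
            abs(self.polarizer_offset_deg) > _MAX_ANGLE_OFFSET
            or abs(self.qwp_offset_deg) > _MAX_ANGLE_OFFSET
        ):
            raise ValueError("element angle offsets are bounded by 10 deg")
        if abs(self.qwp_retardance_offset_deg) > _MAX_RET_OFFSET:
            raise ValueError("retardance offsets are bounded by 20 deg")
        if not 0.0 <= self.polarizer_leakage < 1.0:
            raise ValueError("polarizer leakage must lie in [0, 1)")


@dataclass
class InstrumentModel:
    """Characteristic matrices of the polarimeter: ``W`` (4x6, columns =
    generated Stokes vectors) and ``A`` (8x4, rows = analyzer projection
    vectors)."""

    W: np.ndarray
    A: np.ndarray
    schedule: MeasurementSchedule | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.W.shape != (4, 6) or self.A.shape != (8, 4):
            raise ValueError("W must be 4x6 and A 8x4")


def _psg_stokes(state: PSGState, errors: ArmErrors) -> np.ndarray:
    pol = make_linear_diattenuator(
        1.0, errors.polarizer_leakage, state.polarizer_deg + errors.polarizer_offset_deg
    )
    S = pol @ np.array([1.0, 0.0, 0.0, 0.0])
    if state.qwp_in:
        qwp = make_linear_retarder(
            90.0 + errors.qwp_retardance_offset_deg,
            state.qwp_deg + errors.qwp_offset_deg,
        )
        S = qwp @ S
    return 2.0 * S  # unit-intensity normalization of the ideal polarizer output


def _psa_row(config: PSAConfig, errors: ArmErrors) -> np.ndarray:
    M = make_linear_diattenuator(
        1.0, errors.polarizer_leakage, config.polarizer_deg + errors.polarizer_offset_deg
    )
    if config.qwp_in:
        qwp = make_linear_retarder(
            90.0 + errors.qwp_retardance_offset_deg,
            config.qwp_deg + errors.qwp_offset_deg,
        )
        M = M @ qwp
    return M[0]  # camera sees total intensity: first row of the train


def build_instrument(
    schedule: MeasurementSchedule,
    psg_errors: ArmErrors | None = None,
    psa_errors: ArmErrors | None = None,
) -> InstrumentModel:
    """Compose W and A from the schedule's optical trains.

    Raises ``ValueError`` if either matrix is rank deficient (an
    unmeasurable design).
    """
    psg_errors = psg_errors or ArmErrors()
    psa_errors = psa_errors or ArmErrors()
    W = np.column_stack([_psg_stokes(s, psg_errors) for s in schedule.psg_states])
    A = np.vstack([_psa_row(c, psa_errors) for c in schedule.psa_configs])
    if np.linalg.matrix_rank(W, tol=1e-8) < 4:
        raise ValueError("PSG matrix W is rank deficient: design unmeasurable")
    if np.linalg.matrix_rank(A, tol=1e-8) < 4:
        raise ValueError("PSA matrix A is rank deficient: design unmeasurable")
    return InstrumentModel(W=W, A=A, schedule=schedule)


def ideal_instrument() -> InstrumentModel:
    return build_instrument(ideal_schedule())


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise model: Poisson shot noise on ``gain * intensity``
    counts, additive Gaussian read noise, optional frame averaging
    (``n_averages`` independent exposures averaged, emulating the bench's
    rolling averaging), then clip and quantize to ``bit_depth``."""

    gain: float = 1.0
    shot_noise: bool = False
    read_sigma: float = 0.0
    bit_depth: int | None = None
    n_averages: int = 1

    def __post_init__(self):
        if self.bit_depth not in (None, 8, 16):
            raise ValueError("bit_depth must be None, 8 or 16")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")


#: camera emulation at the bench's 8-bit depth: near-full-well signal,
#: shot + read noise, and 4-frame rolling averaging
NOISE_8BIT = NoiseSpec(
    gain=230.0, shot_noise=True, read_sigma=1.5, bit_depth=8, n_averages=4
)


@dataclass
class IntensityStack:
    """The 48 raw intensity frames of one acquisition.

    ``frames`` has shape ``(..., 48)`` (trailing axis PSG-major: frame
    ``8*j + i`` is generator state j analyzed by configuration i).
    ``as_matrix()`` returns the per-pixel 8x6 measurement matrix B.
    """

    frames: np.ndarray
    bit_depth: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[-1] != 48:
            raise ValueError("an acquisition holds exactly 48 frames")
        if np.nanmin(self.frames) < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[-1]

    def as_matrix(self) -> np.ndarray:
        """Reshape frames to the (..., 8, 6) measurement matrix B
        (rows = PSA configurations, columns = PSG states)."""
        b = self.frames.reshape(self.frames.shape[:-1] + (6, 8))
        return np.swapaxes(b, -1, -2)

    @classmethod
    def from_matrix(cls, B: np.ndarray, **kw) -> "IntensityStack":
        frames = np.swapaxes(np.asarray(B, dtype=float), -1, -2)
        return cls(frames.reshape(frames.shape[:-2] + (48,)), **kw)


def forward_acquire(
    M_field: np.ndarray,
    instrument: InstrumentModel,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> IntensityStack:
    """Simulate one 48-frame acquisition of a Mueller-matrix field.

    Parameters
    ----------
    M_field : ndarray, shape (..., 4, 4)
        Per-pixel sample Mueller matrices (a single 4x4 matrix is treated
        as a one-pixel image).
    instrument : InstrumentModel
    noise : NoiseSpec, optional
        Defaults to the noise-free, unquantized path (ideal intensities).
    seed : int, optional
        Seeds the noise generator; identical seeds give identical stacks.

    Notes
    -----
    The noise-free, unquantized path is linear in ``M_field``.  Ideal
    intensities more negative than a small tolerance raise, since they
    signal a sign-convention bug in the sample matrices.
    """
    noise = noise or NoiseSpec()
    M = np.asarray(M_field, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("M_field must have trailing shape (4, 4)")
    B = np.einsum("ia,...ab,bj->...ij", instrument.A, M, instrument.W)
    peak = np.nanmax(np.abs(B)) or 1.0
    if np.nanmin(B) < -1e-9 * peak:
        raise ValueError(
            "negative ideal intensities: sample/instrument sign conventions disagree"
        )
    counts = np.clip(B, 0.0, None) * noise.gain
    if noise.shot_noise or noise.read_sigma > 0:
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(counts)
        for _ in range(noise.n_averages):
            x = rng.poisson(counts).astype(float) if noise.shot_noise else counts.copy()
            if noise.read_sigma > 0:
                x += rng.normal(0.0, noise.read_sigma, size=x.shape)
            acc += x
        counts = acc / noise.n_averages
    counts = np.clip(counts, 0.0, None)
    if noise.bit_depth is not None:
        full = 2**noise.bit_depth - 1
        counts = np.clip(np.round(counts), 0, full)
    meta = {
        "gain": noise.gain,
        "seed": seed,
        "bit_depth": noise.bit_depth,
        "n_averages": noise.n_averages,
        "frame_order": "psg_major",
        "schedule": (instrument.schedule.fingerprint() if instrument.schedule else None),
    }
    return IntensityStack(
        IntensityStack.from_matrix(counts).frames,
        bit_depth=noise.bit_depth,
        meta=meta,
    )
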