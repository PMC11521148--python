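"""Pixel-wise Mueller matrix estimation from intensity stacks.

With the 48 frames of one acquisition arranged per pixel as the 8x6
measurement matrix B, and the calibrated instrument matrices A (8x4) and
W (4x6), the sample Mueller matrix at that pixel is

    ``M = pinv(A) B pinv(W)``

which is exact in the noise-free case (A has full column rank, W full row
rank) and least-squares optimal otherwise.  The over-determined 6x8
schedule is what gives the pseudo-inverse its noise-averaging effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instrument import InstrumentModel, IntensityStack

__all__ = ["MuellerImage", "reconstruct_mueller"]


@dataclass
class MuellerImage:
    """Per-pixel Mueller matrices.

    ``field`` has shape ``(..., 4, 4)``; if ``normalized`` each finite
    pixel was divided by its m11.  ``valid`` flags pixels with finite,
    non-degenerate data; invalid pixels carry NaN and are excluded
    downstream rather than raising.
    """

    field: np.ndarray
    normalized: bool = False
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.shape[-2:] != (4, 4):
            raise ValueError("field must have trailing shape (4, 4)")
        if self.valid is None:
            self.valid = np.isfinite(self.field).all(axis=(-2, -1))


def reconstruct_mueller(
    stack: IntensityStack,
    instrument: InstrumentModel,
    normalize: bool = True,
) -> MuellerImage:
    """Estimate the Mueller matrix at every pixel of an intensity stack.

    Parameters
    ----------
    stack : IntensityStack
        Frame order must match the instrument schedule (PSG-major).
    instrument : InstrumentModel
    normalize : bool
        Divide each pixel by its m11 (standard for transmission maps);
        pixels with m11 <= 0 or non-finite data are flagged invalid and
        set to NaN, not raised.
    """
    if stack.n_frames != instrument.A.shape[0] * instrument.W.shape[1]:
        raise ValueError(
            f"frame count {stack.n_frames} does not match the "
            f"{instrument.A.shape[0]}x{instrument.W.shape[1]} schedule"
        )
    B = stack.as_matrix()
    Ainv = np.linalg.pinv(instrument.A)
    Winv = np.linalg.pinv(instrument.W)
    M = np.einsum("ai,...ij,jb->...ab", Ainv, B, Winv)
    valid = np.isfinite(B).all(axis=(-2, -1)) & np.any(B != 0, axis=(-2, -1))
    if normalize:
        m11 = M[..., 0, 0]
        valid = valid & np.isfinite(m11) & (m11 > 0)
        safe = np.where(valid, M[..., 0, 0], 1.0)
        M = M / safe[..., None, None]
    M = np.where(valid[..., None, None], M, np.nan)
    return MuellerImage(
        field=M,
        normalized=normalize,
        valid=valid,
        meta={"stack": dict(stack.meta)},
    )
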