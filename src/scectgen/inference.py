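"""Whole-volume synthesis by sliding 16-slice windows with overlap averaging.

The generator only sees 16 consecutive axial slices at a time; a volume with
N slices is covered by the N-15 windows starting at every slice, the
generator output is accumulated per global slice index and divided by the
number of covering windows, and channel 0 (lung/bone window) of the average
is mapped back to HU, so the synthetic volume spans [-1000, 1000] HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume
from .windowing import DEFAULT_WINDOWS, invert_window, make_three_channel

WINDOW_LENGTH = 16


@dataclass
class SlidingWindowPlan:
    """Window starts and per-slice contribution counts for an N-slice volume."""

    n_slices: int
    window_length: int
    starts: np.ndarray  # (N - L + 1,)
    counts: np.ndarray  # (N,) number of windows covering each slice

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def plan_windows(n_slices: int, window_length: int = WINDOW_LENGTH) -> SlidingWindowPlan:
    """Plan the N - L + 1 unit-stride windows and per-slice coverage counts."""
    if n_slices < window_length:
        raise ValueError(
            f"volume has {n_slices} slices but the generator needs "
            f"{window_length}; pad the volume explicitly if this is intended "
            f"(no silent padding is applied)")
    starts = np.arange(n_slices - window_length + 1)
    counts = np.zeros(n_slices, dtype=np.int64)
    for s in starts:
        counts[s: s + window_length] += 1
    return SlidingWindowPlan(n_slices, window_length, starts, counts)


def sliding_window_infer(
    generator,
    ncct: CTVolume,
    windows=DEFAULT_WINDOWS,
    window_length: int = WINDOW_LENGTH,
    return_channels: bool = False,
):
    """Synthesize a contrast-enhanced volume from a non-contrast volume.

    ``generator`` is any callable mapping a (3, X, Y, L) array in [-1, 1] to
    an array of the same shape.  Outputs of overlapping windows are averaged
    per slice in float64 (order-independent to ~1e-6 HU) before channel 0 is
    reconverted to HU.  Deterministic for fixed generator weights.
    """
    mcv = make_three_channel(ncct, windows)
    plan = plan_windows(mcv.n_slices, window_length)
    x = mcv.data
    acc = np.zeros(x.shape, dtype=np.float64)
    for s in plan.starts:
        out = generator(x[:, :, :, s: s + window_length])
        if out.shape != x[:, :, :, s: s + window_length].shape:
            raise ValueError(
                f"generator returned shape {out.shape}, expected "
                f"{x[:, :, :, s:s + window_length].shape}")
        acc[:, :, :, s: s + window_length] += out
    avg = acc / plan.counts[None, None, None, :]
    hu = invert_window(avg[0], windows[0])
    scect = CTVolume(hu=hu, spacing=ncct.spacing)
    if return_channels:
        return scect, avg.astype(np.float32)
    return scect
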