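"""Hounsfield-unit windowing and the 3-channel normalized representation.

A CT window is a (width W, level L) pair: HU are clamped to
[L - W/2, L + W/2] and mapped linearly onto [-1, 1].  The network consumes a
3-channel stack of three fixed windows (lung/bone, vascular, mediastinal) and
only channel 0 (lung/bone, W=2000/L=0) is mapped back to HU at inference,
which fixes the synthetic output range to [-1000, 1000] HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume


@dataclass(frozen=True)
class WindowSpec:
    """A display/normalization window: width and level in HU."""

    name: str
    width: float
    level: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @property
    def floor(self) -> float:
        return self.level - self.width / 2.0

    @property
    def ceiling(self) -> float:
        return self.level + self.width / 2.0


LUNG_BONE = WindowSpec("lung_bone", 2000.0, 0.0)
VASCULAR = WindowSpec("vascular", 1000.0, 200.0)
MEDIASTINAL = WindowSpec("mediastinal", 500.0, 50.0)

#: Channel order is fixed: (lung/bone, vascular, mediastinal).
DEFAULT_WINDOWS: tuple[WindowSpec, WindowSpec, WindowSpec] = (
    LUNG_BONE,
    VASCULAR,
    MEDIASTINAL,
)


@dataclass
class MultiChannelVolume:
    """Three window-normalized copies of one volume, stacked channel-first."""

    data: np.ndarray  # (3, X, Y, Z) float32 in [-1, 1]
    windows: tuple[WindowSpec, ...]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != len(self.windows):
            raise ValueError(
                f"channel-first data of shape {self.data.shape} does not match "
                f"{len(self.windows)} windows"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[3]


def _as_hu_array(volume) -> np.ndarray:
    if isinstance(volume, CTVolume):
        return volume.hu
    return np.asarray(volume, dtype=np.float32)


def apply_window(volume, w: WindowSpec) -> np.ndarray:
    """Clamp HU to the window and map linearly to [-1, 1] (float32).

    Clamp-then-scale: value = 2 * (clip(hu, L-W/2, L+W/2) - L) / W.
    """
    hu = _as_hu_array(volume)
    clamped = np.clip(hu, w.floor, w.ceiling)
    return (2.0 * (clamped - w.level) / w.width).astype(np.float32)


def invert_window(normalized, w: WindowSpec) -> np.ndarray:
    """Map normalized values in [-1, 1] back to HU: hu = L + (W/2) * value.

    Small numeric overshoot outside [-1, 1] is clamped first, so under the
    lung/bone default the output range is exactly [-1000, 1000] HU.
    """
    values = np.clip(np.asarray(normalized, dtype=np.float64), -1.0, 1.0)
    return (w.level + (w.width / 2.0) * values).astype(np.float32)


def make_three_channel(
    volume: CTVolume, windows: tuple[WindowSpec, ...] = DEFAULT_WINDOWS
) -> MultiChannelVolume:
    """Stack the three window-normalized copies of a volume, channel-first."""
    if len(windows) != 3:
        raise ValueError(f"exactly 3 windows required, got {len(windows)}")
    data = np.stack([apply_window(volume, w) for w in windows], axis=0)
    return MultiChannelVolume(data=data, windows=tuple(windows), spacing=volume.spacing)
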