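"""Temporal dynamism tensors.

A single contact matrix is a static snapshot; to expose whether contacts are
forming or breaking, each frame t is paired with the absolute difference
between its contacts and those at a lagged frame t−δ. For binary matrices
|c(t) − c(t−δ)| is the XOR: 1 marks a contact that appeared or disappeared
over the lag window (direction-independent), 0 a stable cell. The result is
a 2-channel binary tensor per frame — channel 0 the current contacts,
channel 1 the change — which is the autoencoder input. The default lag is
500 frames (10 ns at 20 ps/frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import ContactSeries
from .exceptions import ConsistencyError

__all__ = ["DynamismSeries", "build_dynamism", "flatten_whole_molecule", "split_flattened"]

DEFAULT_DELTA_FRAMES = 500


@dataclass
class DynamismSeries:
    """Binary (T, 2, R, M) tensor series; R = N whole-molecule, 1 per subtype."""

    values: np.ndarray
    delta: int
    frame_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[1] != 2:
            raise ConsistencyError("dynamism values must have shape (T, 2, R, M)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("dynamism values must be binary")
        self.values = self.values.astype(np.uint8)
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def build_dynamism(
    contacts: ContactSeries, delta: int = DEFAULT_DELTA_FRAMES
) -> DynamismSeries:
    """Pair contacts at t with |contacts(t) − contacts(t−δ)|.

    Frames with t < δ compare against frame 0 (clamped lag), keeping the
    output aligned frame-for-frame with the reference clustering series.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    c = contacts.values
    T = c.shape[0]
    lagged = c[np.maximum(np.arange(T) - delta, 0)]
    change = np.bitwise_xor(c, lagged)  # |a-b| on binary == XOR
    values = np.stack([c, change], axis=1)
    return DynamismSeries(
        values=values, delta=delta, frame_interval_ps=contacts.frame_interval_ps
    )


def flatten_whole_molecule(dyn: DynamismSeries) -> np.ndarray:
    """Concatenate the two channels row-wise into per-frame (2R, M) matrices.

    Used for the all-atom reference autoencoder, where the input is the
    contact rows stacked on the change rows.
    """
    T, _, R, M = dyn.values.shape
    return dyn.values.reshape(T, 2 * R, M)


def split_flattened(flat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_whole_molecule`: (T, 2R, M) → (T, 2, R, M)."""
    T, rows, M = flat.shape
    if rows % 2:
        raise ConsistencyError("row count must be even (two stacked channels)")
    return flat.reshape(T, 2, rows // 2, M)


def save_dynamism(dyn: DynamismSeries, path) -> None:
    path = Path(path)
    np.savez_compressed(path, values=dyn.values)
    path.with_suffix(".json").write_text(
        json.dumps({"delta": dyn.delta, "frame_interval_ps": dyn.frame_interval_ps})
    )


def load_dynamism(path) -> DynamismSeries:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        values = npz["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return DynamismSeries(values=values, delta=meta["delta"],
                          frame_interval_ps=meta["frame_interval_ps"])
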