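"""Foot-motion-pad analytics: magnitude series, Jaccard overlap, densities.

Each 100 Hz sample (pitch_y, yaw_z) is reduced to the scalar magnitude
``v_t = sqrt(pitch^2 + yaw^2)`` — 0 means the pad is neutral (no movement in
the virtual space), larger values mean greater lower-limb mobility.  The
similarity of movement between the encoding and recall phases is measured by a
Jaccard index of the two v_t distributions; the phases have different lengths,
so the series are histogrammed on shared bins and compared as distributions.

Three Jaccard variants are provided:

``weighted`` (default)
    Relative-frequency histograms p, q; J = sum(min(p,q)) / sum(max(p,q)).
    The standard continuous generalization; invariant to series length.
``counts``
    The same min/max ratio on raw bin counts (sensitive to phase length).
``binary``
    Set Jaccard of occupied bins, |A∩B| / |A∪B|.

All variants are 1 for identical series and 0 for disjoint magnitude supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .session_io import MotionTrace

#: default magnitude-histogram bin width for the Jaccard index
JACCARD_BIN_WIDTH = 0.05
#: default square-cell width for raw (pitch, yaw) density grids
DENSITY_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class MagnitudeSeries:
    """Scalar magnitude series v_t aligned with its timestamps."""

    t_ms: np.ndarray
    v: np.ndarray

    def __len__(self) -> int:
        return self.t_ms.size


@dataclass(frozen=True)
class DensityGrid:
    """Counts of (pitch, yaw) samples over square cells of side bin_width.

    Cell indices are floor(value / bin_width); ``to_frame`` lists occupied
    cells with their center coordinates and counts.
    """

    bin_width: float
    cells: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pitch_bin": iy,
                "yaw_bin": iz,
                "pitch_center": (iy + 0.5) * self.bin_width,
                "yaw_center": (iz + 0.5) * self.bin_width,
                "count": int(c),
            }
            for (iy, iz), c in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["pitch_bin", "yaw_bin", "pitch_center", "yaw_center", "count"]
        )


def magnitude_series(trace: MotionTrace) -> MagnitudeSeries:
    """Element-wise v_t = sqrt(pitch_y^2 + yaw_z^2), timestamps preserved."""
    v = np.hypot(trace.pitch_y, trace.yaw_z)
    return MagnitudeSeries(t_ms=trace.t_ms.copy(), v=v)


def _histogram(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(v, bins=edges)
    return counts.astype(float)


def jaccard_similarity(
    enc: MagnitudeSeries,
    rec: MagnitudeSeries,
    bin_width: float = JACCARD_BIN_WIDTH,
    variant: str = "weighted",
) -> float:
    """Jaccard overlap of the encoding and recall magnitude distributions.

    Both series are histogrammed over shared bins of width ``bin_width``
    covering [0, max(v)]; see the module docstring for the variants.  The
    result is in [0, 1] and symmetric in its arguments.
    """
    if len(enc) == 0 or len(rec) == 0:
        raise InputError("jaccard_similarity requires two non-empty series")
    if not bin_width > 0:
        raise InputError(f"bin_width must be positive, got {bin_width}")
    if variant not in ("weighted", "counts", "binary"):
        raise InputError(f"unknown Jaccard variant {variant!r}")
    vmax = float(max(enc.v.max(), rec.v.max()))
    n_bins = max(1, int(math.ceil(vmax / bin_width)) if vmax > 0 else 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    if edges[-1] < vmax:  # guard against ceil rounding at the float boundary
        edges = np.append(edges, edges[-1] + bin_width)
    # np.histogram's last bin is closed, so vmax itself is always counted
    he = _histogram(enc.v, edges)
    hr = _histogram(rec.v, edges)
    if variant == "binary":
        a, b = he > 0, hr > 0
        union = np.logical_or(a, b).sum()
        return float(np.logical_and(a, b).sum() / union) if union else 1.0
    if variant == "weighted":
        he = he / he.sum()
        hr = hr / hr.sum()
    num = np.minimum(he, hr).sum()
    den = np.maximum(he, hr).sum()
    return float(num / den) if den > 0 else 1.0


def phase_duration(trace: MotionTrace) -> float:
    """Span of a trace in minutes, (last t_ms - first t_ms) / 60000."""
    if len(trace) < 2:
        raise InputError("phase_duration requires at least 2 samples")
    return float(trace.t_ms[-1] - trace.t_ms[0]) / 60000.0


def density_grid(trace: MotionTrace, bin_width: float = DENSITY_BIN_WIDTH) -> DensityGrid:
    """Counts of raw (pitch, yaw) samples per square cell of side bin_width.

    Conserves the sample count: the counts sum to len(trace).
    """
    if not bin_width > 0:
        raise InputError(f"bin_width must be positive, got {bin_width}")
    if len(trace) == 0:
        return DensityGrid(bin_width=bin_width, cells={})
    iy = np.floor(trace.pitch_y / bin_width).astype(np.int64)
    iz = np.floor(trace.yaw_z / bin_width).astype(np.int64)
    cells: dict[tuple[int, int], int] = {}
    keys, counts = np.unique(np.stack([iy, iz], axis=1), axis=0, return_counts=True)
    for (a, b), c in zip(keys, counts):
        cells[(int(a), int(b))] = int(c)
    return DensityGrid(bin_width=bin_width, cells=cells)
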