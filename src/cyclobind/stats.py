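"""Time-series statistics over per-frame descriptors.

Distributions, bound-state occupancies, binding-mode occupancy and
transition counts, block-averaged uncertainties, and the grouping of ordered
mode profiles into contiguous intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import BOUND_CUTOFF

__all__ = [
    "BlockAverage",
    "ModeInterval",
    "ModeStats",
    "histogram",
    "bound_fraction",
    "mode_occupancy",
    "block_average",
    "group_contiguous_modes",
    "subsample_indices",
    "MMPBSA_CADENCE",
]

#: Frame-extraction preset used for end-state energy analyses: 1001 frames at
#: a 10 ps step (a 10 ns window).
MMPBSA_CADENCE = {"n_frames": 1001, "step_ps": 10.0}


@dataclass(frozen=True)
class BlockAverage:
    """Mean of contiguous-block means and their sample standard deviation."""

    mean: float
    sd_of_block_means: float
    n_blocks: int


@dataclass(frozen=True)
class ModeInterval:
    """A maximal run of one mode label over an ordered coordinate."""

    start: float
    end: float
    mode: str


@dataclass(frozen=True)
class ModeStats:
    occupancy: dict
    transitions: dict
    n_transitions: int


def histogram(values, bin_width: float, range_: tuple[float, float] | None = None):
    """Normalized histogram: (bin edges, densities integrating to 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    lo, hi = range_ if range_ is not None else (values.min(), values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    density, edges = np.histogram(values, bins=edges, density=True)
    return edges, density


def bound_fraction(d_signed, cutoff: float = BOUND_CUTOFF) -> float:
    """Fraction of frames with |signed COM distance| within the cutoff."""
    d = np.asarray(d_signed, dtype=float)
    if d.size == 0:
        raise ParameterError("empty distance series")
    return float(np.mean(np.abs(d) <= cutoff))


def mode_occupancy(modes) -> ModeStats:
    """Per-mode occupancy fractions and consecutive-frame transition counts."""
    modes = list(modes)
    if not modes:
        raise ParameterError("empty mode series")
    occupancy = {}
    for m in modes:
        occupancy[m] = occupancy.get(m, 0) + 1
    n = len(modes)
    occupancy = {m: c / n for m, c in occupancy.items()}
    transitions: dict[tuple[str, str], int] = {}
    n_trans = 0
    for a, b in zip(modes[:-1], modes[1:]):
        if a != b:
            transitions[(a, b)] = transitions.get((a, b), 0) + 1
            n_trans += 1
    return ModeStats(occupancy=occupancy, transitions=transitions,
                     n_transitions=n_trans)


def block_average(values, n_blocks: int = 5) -> BlockAverage:
    """Split a series into equal contiguous blocks and report the mean and
    sample SD of the block means (remainder frames dropped from the end)."""
    values = np.asarray(values, dtype=float)
    if n_blocks < 2:
        raise ParameterError("block averaging needs at least 2 blocks")
    if values.size < n_blocks:
        raise ParameterError(
            f"series of length {values.size} cannot form {n_blocks} blocks"
        )
    block_len = values.size // n_blocks
    trimmed = values[: block_len * n_blocks].reshape(n_blocks, block_len)
    means = trimmed.mean(axis=1)
    return BlockAverage(mean=float(means.mean()),
                        sd_of_block_means=float(means.std(ddof=1)),
                        n_blocks=n_blocks)


def group_contiguous_modes(coords, modes) -> list[ModeInterval]:
    """Merge maximal runs of identical mode labels along a strictly
    increasing coordinate into intervals; singleton runs are kept."""
    coords = np.asarray(coords, dtype=float)
    modes = list(modes)
    if coords.size != len(modes):
        raise ParameterError("coords and modes have different lengths")
    if coords.size == 0:
        return []
    if coords.size > 1 and not np.all(np.diff(coords) > 0):
        raise ParameterError("coordinates must be strictly increasing")
    intervals = []
    start = coords[0]
    current = modes[0]
    for i in range(1, coords.size):
        if modes[i] != current:
            intervals.append(ModeInterval(float(start), float(coords[i - 1]), current))
            start, current = coords[i], modes[i]
    intervals.append(ModeInterval(float(start), float(coords[-1]), current))
    return intervals


def subsample_indices(times, step_ps: float = MMPBSA_CADENCE["step_ps"],
                      max_frames: int | None = MMPBSA_CADENCE["n_frames"]):
    """Frame indices at (or just past) a fixed time cadence.

    Defaults mirror the end-state analysis preset of 1001 frames every 10 ps.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.array([], dtype=int)
    if step_ps <= 0:
        raise ParameterError("step_ps must be positive")
    idx = [0]
    next_t = times[0] + step_ps
    for i in range(1, times.size):
        if times[i] >= next_t - 1e-9:
            idx.append(i)
            next_t += step_ps
    idx = np.array(idx, dtype=int)
    if max_frames is not None:
        idx = idx[:max_frames]
    return idx
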