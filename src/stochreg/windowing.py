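"""Partition of the record into disjoint width-2h estimation windows.

The M increments are grouped into consecutive blocks of ``2k``; block ``j``
is centered on increment index ``k + 2k*j``, so with bandwidth ``h = dt*k``
each kernel's support coincides with (at most) its own block.  When ``2k``
does not divide M the record is padded with ``r`` fictitious increments,
``r`` being the least nonnegative integer with ``2k | (M + r)``; the padded
values are produced by linear extrapolation of the tail and are used only
for coefficient estimation, never for reconstruction or scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import Signal


@dataclass(frozen=True)
class WindowPartition:
    """Disjoint, exhaustive blocks of 2k increments (after padding)."""

    k: int
    window_centers: tuple
    l: int
    r: int
    member_map: np.ndarray  # window index owning each (padded) increment

    def members(self, j: int) -> range:
        """Increment indices owned by window ``j`` (padded indexing)."""
        return range(2 * self.k * j, 2 * self.k * (j + 1))


def make_partition(m: int, k: int) -> WindowPartition:
    """Partition ``m`` increments into blocks of ``2k``.

    ``r`` is the least nonnegative integer such that ``2k`` divides
    ``m + r`` (zero when ``m`` is already divisible — padding an already
    complete partition would serve no purpose).
    """
    if not 2 <= k <= m // 2:
        raise ValueError(f"k must satisfy 2 <= k <= floor(M/2) = {m // 2}, got {k}")
    width = 2 * k
    r = (-m) % width
    l = (m + r) // width
    centers = tuple(k + width * j for j in range(l))
    member_map = np.arange(m + r) // width
    return WindowPartition(k=k, window_centers=centers, l=l, r=r, member_map=member_map)


def extend_signal(s: Signal, r: int, tail_points: int | None = None) -> Signal:
    """Append ``r`` values on the continued grid by linear extrapolation.

    The appended values lie on the ordinary-least-squares line fitted to the
    final ``tail_points`` observed samples (the pipeline passes one full
    window, ``2k``).  Intended for signals whose tail is in a steady, nearly
    linear regime.  ``r = 0`` returns the input unchanged.
    """
    if r < 0:
        raise ValueError("r must be nonnegative")
    if r == 0:
        return s
    n = len(s)
    if tail_points is None:
        tail_points = min(n, max(2, 2 * r))
    tail_points = min(tail_points, n)
    if tail_points < 2:
        raise ValueError("need at least 2 tail points for extrapolation")
    t_tail = s.times[-tail_points:]
    x_tail = s.values[-tail_points:]
    slope, intercept = np.polyfit(t_tail, x_tail, 1)
    new_times = s.times[-1] + s.dt * np.arange(1, r + 1)
    new_values = intercept + slope * new_times
    return Signal(
        np.concatenate([s.times, new_times]),
        np.concatenate([s.values, new_values]),
        s.dt,
        char_time=s.char_time,
        char_value=s.char_value,
    )
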