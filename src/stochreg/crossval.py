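"""Leave-one-out consistency analysis of optimal bandwidths.

Given the optimal multipliers ``k*_1 .. k*_n`` found for an ensemble of
instruments, the leave-one-out mean for instrument i is

    kbar_i = (1/(n-1)) * sum_{j != i} k*_j,

and consistency is summarized by the absolute difference ``|k*_i - kbar_i|``
and the relative difference ``|k*_i - kbar_i| / k*_i``.  The absolute
difference is the headline statistic: the relative difference rewards
kernels merely for selecting larger multipliers.

The arithmetic stage is exposed standalone (:func:`loo_statistics`,
:func:`crossval_from_kstars`) and exact — integer inputs produce exact
rationals — so published bandwidth columns can be checked without
regenerating any ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Sequence

import pandas as pd

from .bandwidth import search_bandwidth
from .signal_model import Signal


class LooStats(NamedTuple):
    """Exact leave-one-out statistics for one ensemble position."""

    k_bar: Fraction
    abs_diff: Fraction
    rel_diff: Fraction


@dataclass(frozen=True)
class CrossValRecord:
    """One instrument's row of a cross-validation table."""

    epsilon: float
    k_star: int
    objective_value: float
    k_bar: float
    abs_diff: float
    rel_diff: float


def loo_mean(k_stars: Sequence[float], i: int) -> float:
    """Mean of all entries except position ``i`` (sum first, divide once)."""
    n = len(k_stars)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 entries")
    if not 0 <= i < n:
        raise ValueError(f"index {i} out of range for {n} entries")
    return (sum(k_stars) - k_stars[i]) / (n - 1)


def loo_statistics(k_stars: Sequence[int]) -> list[LooStats]:
    """Exact leave-one-out mean and differences for every position.

    Computed with rational arithmetic: integer inputs give exact fractions
    (e.g. repeating decimals like 47/9 are represented exactly).
    """
    if len(k_stars) < 2:
        raise ValueError("leave-one-out needs at least 2 entries")
    ks = [Fraction(k) for k in k_stars]
    total = sum(ks)
    n = len(ks)
    out = []
    for k in ks:
        k_bar = (total - k) / (n - 1)
        abs_diff = abs(k - k_bar)
        out.append(LooStats(k_bar=k_bar, abs_diff=abs_diff, rel_diff=abs_diff / k))
    return out


def crossval_from_kstars(
    epsilons: Sequence[float],
    k_stars: Sequence[int],
    objectives: Sequence[float] | None = None,
) -> list[CrossValRecord]:
    """Apply the leave-one-out arithmetic to a supplied k* column."""
    if len(epsilons) != len(k_stars):
        raise ValueError("epsilons and k_stars must have equal length")
    if objectives is None:
        objectives = [float("nan")] * len(k_stars)
    stats = loo_statistics(k_stars)
    return [
        CrossValRecord(
            epsilon=float(eps),
            k_star=int(k),
            objective_value=float(obj),
            k_bar=float(st.k_bar),
            abs_diff=float(st.abs_diff),
            rel_diff=float(st.rel_diff),
        )
        for eps, k, obj, st in zip(epsilons, k_stars, objectives, stats)
    ]


def crossval_table(
    ensemble: Sequence[tuple[float, Signal]],
    side: str,
    measure: str,
    seed: int = 0,
    k_range=None,
    compare_to: str = "reconstruction",
    scans: Sequence | None = None,
) -> list[CrossValRecord]:
    """Full cross-validation: bandwidth search per instrument, then
    leave-one-out statistics across the resulting k* vector.

    ``ensemble`` is a sequence of ``(epsilon, Signal)`` pairs; records are
    returned in input order.  Precomputed per-instrument scans (from
    :func:`stochreg.bandwidth.scan_bandwidths` with the same seed and range)
    may be supplied to share pipeline runs across measures.
    """
    if len(ensemble) < 2:
        raise ValueError("cross-validation needs at least 2 instruments")
    k_stars, objectives, epsilons = [], [], []
    for idx, (eps, signal) in enumerate(ensemble):
        scan = scans[idx] if scans is not None else None
        result = search_bandwidth(
            signal, side, measure, k_range=k_range, seed=seed,
            compare_to=compare_to, _scan=scan,
        )
        epsilons.append(eps)
        k_stars.append(result.k_star)
        objectives.append(result.objective_value)
    return crossval_from_kstars(epsilons, k_stars, objectives)


def records_to_frame(records: Sequence[CrossValRecord]) -> pd.DataFrame:
    """Tabulate records with the standard column layout."""
    return pd.DataFrame(
        {
            "epsilon": [r.epsilon for r in records],
            "k_star": [r.k_star for r in records],
            "objective": [r.objective_value for r in records],
            "k_bar": [r.k_bar for r in records],
            "abs_diff": [r.abs_diff for r in records],
            "rel_diff": [r.rel_diff for r in records],
        }
    )
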