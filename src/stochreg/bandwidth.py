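"""Error measures and exhaustive optimal-bandwidth search.

For deviations ``A_i = |X_i - Y_i(h)|`` over the M+1 samples the three
objectives are

    rmse = sqrt( sum A_i^2 / (M+1) )
    mae  = sum A_i / (M+1)
    std  = sqrt( sum (A_i - mae)^2 / M )

which satisfy the exact identity ``(M+1) rmse^2 = M std^2 + (M+1) mae^2``
and ``mae <= rmse``.  The optimal integer multiplier ``k*`` is found by
evaluating every candidate in the open interval ``1 < k < floor(M/2)``
(exhaustive search, no shortcuts); ties are broken toward the smallest k,
which best honors the piecewise-constant coefficient assumption.

One Brownian seed is shared by every k within a scan so the scan is a
deterministic function of (signal, kernel, seed).  ``compare_to``
selects whether deviations are taken against the full stochastic
reconstruction Y (the default) or against its deterministic component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .estimation import fit_coefficients
from .exceptions import DegenerateWindowError
from .reconstruction import Reconstruction, reconstruct
from .signal_model import Signal

logger = logging.getLogger(__name__)

MEASURES = ("rmse", "mae", "std")
COMPARE_MODES = ("reconstruction", "deterministic")


@dataclass(frozen=True)
class ErrorMeasures:
    """The three deviation summaries of one reconstruction."""

    rmse: float
    mae: float
    std: float
    deviations: np.ndarray

    def get(self, measure: str) -> float:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; use one of {MEASURES}")
        return getattr(self, measure)


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an exhaustive bandwidth scan for one (kernel, measure)."""

    side: str
    measure: str
    k_star: int
    objective_value: float
    scan: tuple  # ((k, objective), ...) for every scanned k
    seed: int
    compare_to: str


def error_measures(x, y) -> ErrorMeasures:
    """Deviation summaries between a signal and a reconstruction.

    ``x`` may be a :class:`Signal` or a plain array; ``y`` a
    :class:`Reconstruction` or a plain array of equal length.
    """
    x_vals = x.values if isinstance(x, Signal) else np.asarray(x, dtype=float)
    y_vals = y.y if isinstance(y, Reconstruction) else np.asarray(y, dtype=float)
    if x_vals.shape != y_vals.shape:
        raise ValueError(
            f"length mismatch: {x_vals.shape} vs {y_vals.shape}"
        )
    a = np.abs(x_vals - y_vals)
    n = a.size  # M + 1 samples
    mae = float(np.sum(a) / n)
    rmse = float(np.sqrt(np.sum(a * a) / n))
    std = float(np.sqrt(np.sum((a - mae) ** 2) / (n - 1)))
    return ErrorMeasures(rmse=rmse, mae=mae, std=std, deviations=a)


def _pipeline_measures(
    s: Signal, side: str, k: int, seed: int, compare_to: str
) -> ErrorMeasures:
    est = fit_coefficients(s, side, k)
    recon = reconstruct(s, est, seed)
    target = recon.y if compare_to == "reconstruction" else recon.y_det
    return error_measures(s.values, target)


def evaluate_k(
    s: Signal,
    side: str,
    k: int,
    measure: str,
    seed: int,
    compare_to: str = "reconstruction",
) -> float:
    """Objective value of the full pipeline at one bandwidth multiplier.

    Degenerate windows (empty kernel support) yield ``+inf`` and a log
    record rather than an exception, so a scan can simply skip them.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use one of {MEASURES}")
    if compare_to not in COMPARE_MODES:
        raise ValueError(f"unknown compare_to {compare_to!r}")
    try:
        return _pipeline_measures(s, side, k, seed, compare_to).get(measure)
    except DegenerateWindowError as exc:
        logger.info("k=%d skipped: %s", k, exc)
        return math.inf


def scan_bandwidths(
    s: Signal,
    side: str,
    seed: int,
    ks=None,
    compare_to: str = "reconstruction",
) -> list[tuple[int, ErrorMeasures]]:
    """Run the pipeline at every candidate k, returning all three measures.

    One pipeline run per k serves all objectives, so searches for different
    measures on the same kernel can share a single scan.
    """
    if compare_to not in COMPARE_MODES:
        raise ValueError(f"unknown compare_to {compare_to!r}")
    if ks is None:
        ks = range(2, s.n_increments // 2)
    out = []
    for k in ks:
        try:
            out.append((int(k), _pipeline_measures(s, side, int(k), seed, compare_to)))
        except DegenerateWindowError as exc:
            logger.info("k=%d skipped: %s", k, exc)
            inf = math.inf
            out.append((int(k), ErrorMeasures(inf, inf, inf, np.array([]))))
    return out


def search_bandwidth(
    s: Signal,
    side: str,
    measure: str,
    k_range=None,
    seed: int = 0,
    compare_to: str = "reconstruction",
    _scan: list | None = None,
) -> SearchResult:
    """Exhaustive search for the objective-minimizing multiplier k*.

    ``k_range`` defaults to every integer in the open interval
    ``(1, floor(M/2))``.  A precomputed scan (from :func:`scan_bandwidths`
    over the same range/seed) may be passed to avoid recomputation.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use one of {MEASURES}")
    if k_range is None:
        k_range = range(2, s.n_increments // 2)
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty bandwidth search range")
    scan = _scan if _scan is not None else scan_bandwidths(
        s, side, seed, ks, compare_to
    )
    pairs = tuple((k, em.get(measure)) for k, em in scan)
    k_star, objective = min(pairs, key=lambda kv: (kv[1], kv[0]))
    return SearchResult(
        side=side,
        measure=measure,
        k_star=k_star,
        objective_value=objective,
        scan=pairs,
        seed=seed,
        compare_to=compare_to,
    )
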