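"""Per-session firing rates, relative change scores, split-half baselines,
and spike-pairing-event counts.

The relative change score ``c = (r2 - r1) / (r2 + r1)`` is the bounded
[-1, 1] normalized difference used throughout for rates, transmission
probabilities, and pairing counts; -1 and +1 mean activity exclusive to one
of the two sessions. The split-half machinery cuts a session into
alternating 5 s blocks (odd- vs even-numbered) to give a within-session
stability ceiling against which cross-session correlations are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import Interval, SpikeTrain

PAIRING_WINDOWS_MS = (10, 20, 50, 100)


# ---------------------------------------------------------------------------
# Rates and change scores
# ---------------------------------------------------------------------------

def session_rate(
    train: SpikeTrain,
    interval: Interval | tuple[float, float] | Iterable[tuple[float, float]],
) -> float:
    """Mean firing rate (Hz) over an interval or a union of intervals."""
    if isinstance(interval, Interval):
        ivs = [(interval.start_s, interval.end_s)]
    else:
        seq = list(interval)
        ivs = [tuple(seq)] if seq and np.isscalar(seq[0]) else [tuple(p) for p in seq]
    total = sum(b - a for a, b in ivs)
    if total <= 0:
        raise ValueError("interval length must be positive")
    n = sum(train.restrict(a, b).size for a, b in ivs)
    return n / total


def relative_change(a: float, b: float) -> float:
    """Relative change score ``(b - a) / (b + a)``; nan when both are zero.

    Antisymmetric (``score(a, b) == -score(b, a)``) and bounded in [-1, 1]
    for non-negative inputs.
    """
    if a < 0 or b < 0:
        raise ValueError("relative_change expects non-negative magnitudes")
    s = a + b
    if s == 0:
        return float("nan")
    return (b - a) / s


# ---------------------------------------------------------------------------
# Alternating split-half
# ---------------------------------------------------------------------------

def alternating_split(
    interval: Interval | tuple[float, float], block_s: float = 5.0
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Cut an interval into consecutive blocks; return (odd, even) block sets.

    Blocks are numbered from 1 at the interval start; a trailing partial
    block is dropped. Requires at least two whole blocks.
    """
    a, b = (
        (interval.start_s, interval.end_s)
        if isinstance(interval, Interval)
        else interval
    )
    n_blocks = int(np.floor((b - a) / block_s))
    if n_blocks < 2:
        raise ValueError("interval shorter than two blocks")
    edges = a + block_s * np.arange(n_blocks + 1)
    blocks = list(zip(edges[:-1], edges[1:]))
    odd = blocks[0::2]  # blocks 1, 3, 5, ... (1-based numbering)
    even = blocks[1::2]
    return odd, even


def split_half_baseline(
    odd_metric: Sequence[float], even_metric: Sequence[float]
) -> tuple[float, int]:
    """Across-pairs correlation of a metric between odd and even half-blocks.

    Returns ``(r, n_used)``; pairs with a missing value in either half are
    dropped. ``(nan, n)`` when fewer than 3 usable pairs remain. This r is
    the within-session stability ceiling fed to the Fisher-Z comparison
    against cross-session correlations.
    """
    x = np.asarray(odd_metric, dtype=np.float64)
    y = np.asarray(even_metric, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), int(x.size)
    return float(np.corrcoef(x, y)[0, 1]), int(x.size)


# ---------------------------------------------------------------------------
# Spike pairing events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingCounts:
    """Pyramidal–interneuron spike pairs within ±window.

    ``plus`` counts pairs where the pyramidal spike precedes the interneuron
    spike by at most the window (causal direction); ``minus`` the reverse
    order. Exact zero-lag ties are directionless and counted in neither.
    """

    window_ms: int
    plus: int
    minus: int

    @property
    def all(self) -> int:
        return self.plus + self.minus


def pairing_counts(
    pyr: SpikeTrain,
    int_: SpikeTrain,
    interval: Interval | tuple[float, float],
    window_ms: int,
) -> PairingCounts:
    """Count all (pyramidal, interneuron) spike pairs with |lag| <= window.

    ``plus``: pairs with ``0 < t_int - t_pyr <= W``; ``minus``: pairs with
    ``0 < t_pyr - t_int <= W``. Every pair is counted — a spike may
    participate in several pairs.
    """
    a, b = (
        (interval.start_s, interval.end_s)
        if isinstance(interval, Interval)
        else interval
    )
    t_p = pyr.restrict(a, b)
    t_i = int_.restrict(a, b)
    w = window_ms / 1000.0
    plus = _count_lagged(t_p, t_i, w)  # int after pyr
    minus = _count_lagged(t_i, t_p, w)  # pyr after int
    return PairingCounts(window_ms=int(window_ms), plus=plus, minus=minus)


def _count_lagged(ref: np.ndarray, other: np.ndarray, w: float) -> int:
    """Number of (ref, other) pairs with 0 < t_other - t_ref <= w."""
    if ref.size == 0 or other.size == 0:
        return 0
    lo = np.searchsorted(other, ref, side="right")  # strictly after ref
    hi = np.searchsorted(other, ref + w, side="right")  # inclusive at +w
    return int((hi - lo).sum())
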