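"""Cross-correlogram construction, monosynaptic-peak detection, and
spike-transmission probability.

The connection statistic follows the classic extracellular approach to
putative pyramidal→interneuron coupling: the cross-correlogram (CCG) of the
two spike trains on a ±50 ms lattice of 1 ms bins is normalized by the number
of reference (presynaptic) spikes so each bin reads as the probability that
the interneuron fires in that 1 ms lag window per pyramidal spike. A
monosynaptic connection produces a sharp peak at 0.5–2.5 ms lag — the two
bins centered at +1 and +2 ms. Chance co-firing is estimated from the flank
bins at |lag| 10–50 ms, and the spike-transmission probability is the
peak-bin probability mass in excess of chance: extra interneuron spikes per
pyramidal spike. Significance uses a z-score of the larger peak bin against
the flank mean and SD of raw counts, at a 3 SD threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .types import Interval, SpikeTrain

HALF_WIDTH_MS = 50
BIN_MS = 1.0
#: lag-bin centers in ms: -50 ... +50 inclusive, 1 ms apart (101 bins)
LAG_CENTERS_MS = np.arange(-HALF_WIDTH_MS, HALF_WIDTH_MS + 1, dtype=np.float64)
#: bins centered at +1 and +2 ms cover lags in [0.5, 2.5) ms
PEAK_BIN_INDICES = (HALF_WIDTH_MS + 1, HALF_WIDTH_MS + 2)
#: flank bins: |center| in [10, 50] ms (41 per side, 82 total)
FLANK_MASK = np.abs(LAG_CENTERS_MS) >= 10.0

Z_THRESHOLD = 3.0
MIN_COINCIDENCE_COUNTS = 1000
DISPERSION_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class CrossCorrelogram:
    """Pair-count histogram of lags ``t_post - t_pre`` on the ±50 ms lattice.

    Attributes
    ----------
    raw_counts :
        Pair counts per bin; bin k spans ``[center_k - 0.5, center_k + 0.5)`` ms.
    n_ref :
        Number of reference (presynaptic) spikes in the analyzed interval.
    """

    raw_counts: np.ndarray
    n_ref: int
    lag_centers_ms: np.ndarray = field(default_factory=lambda: LAG_CENTERS_MS.copy())

    def __post_init__(self) -> None:
        rc = np.asarray(self.raw_counts, dtype=np.int64)
        object.__setattr__(self, "raw_counts", rc)
        if rc.shape != self.lag_centers_ms.shape:
            raise ValueError("raw_counts must have one entry per lag bin")
        if np.any(rc < 0):
            raise ValueError("raw counts must be non-negative")
        if self.n_ref < 1:
            raise ValueError("n_ref must be >= 1; an empty reference train has no CCG")

    @property
    def prob(self) -> np.ndarray:
        """Per-bin probability: raw counts per reference spike."""
        return self.raw_counts / self.n_ref

    @property
    def total_counts(self) -> int:
        return int(self.raw_counts.sum())


def _interval_list(
    interval: Interval | tuple[float, float] | Iterable[tuple[float, float]] | None,
) -> list[tuple[float, float]] | None:
    if interval is None:
        return None
    if isinstance(interval, Interval):
        return [(interval.start_s, interval.end_s)]
    seq = list(interval)  # type: ignore[arg-type]
    if seq and np.isscalar(seq[0]):
        return [tuple(seq)]  # a single (start, end) pair
    return [(float(a), float(b)) for a, b in seq]


def _restrict(train: SpikeTrain, ivs: list[tuple[float, float]] | None) -> np.ndarray:
    if ivs is None:
        return train.spikes
    return train.restrict_to_intervals(ivs)


def compute_ccg(
    pre: SpikeTrain,
    post: SpikeTrain,
    interval: Interval | tuple[float, float] | Iterable[tuple[float, float]] | None = None,
) -> CrossCorrelogram | None:
    """Cross-correlogram of ``post`` against reference ``pre`` within ``interval``.

    Every ordered spike pair contributes lag ``t_post - t_pre``; lags are
    histogrammed on the 101-bin ±50 ms lattice with half-open bins
    ``[center-0.5, center+0.5)`` ms. If the two trains share a cell id,
    zero-lag self-pairs are excluded.

    Returns ``None`` when the reference train has no spikes in the interval
    (the CCG is undefined there).
    """
    ivs = _interval_list(interval)
    t_pre = _restrict(pre, ivs)
    t_post = _restrict(post, ivs)
    if t_pre.size == 0:
        return None
    counts = _ccg_counts(t_pre, t_post)
    if pre.cell_id == post.cell_id:
        counts = counts.copy()
        counts[HALF_WIDTH_MS] -= t_pre.size  # drop self-pairs at lag 0
    return CrossCorrelogram(raw_counts=counts, n_ref=int(t_pre.size))


def _ccg_counts(t_pre: np.ndarray, t_post: np.ndarray) -> np.ndarray:
    """Vectorized pair-lag histogram restricted to |lag| <= 50.5 ms."""
    counts = np.zeros(LAG_CENTERS_MS.size, dtype=np.int64)
    if t_post.size == 0:
        return counts
    half_s = (HALF_WIDTH_MS + 0.5 * BIN_MS) / 1000.0
    lo = np.searchsorted(t_post, t_pre - half_s, side="left")
    hi = np.searchsorted(t_post, t_pre + half_s, side="left")
    n_pairs = hi - lo
    if n_pairs.sum() == 0:
        return counts
    ref_idx = np.repeat(np.arange(t_pre.size), n_pairs)
    post_idx = _ranges(lo, hi)
    lag_ms = (t_post[post_idx] - t_pre[ref_idx]) * 1000.0
    # bin k covers [k-0.5, k+0.5) ms -> index = floor(lag+0.5) + 50
    k = np.floor(lag_ms + 0.5).astype(np.int64) + HALF_WIDTH_MS
    valid = (k >= 0) & (k < counts.size)
    np.add.at(counts, k[valid], 1)
    return counts


def _ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(lo_i, hi_i)`` without a Python loop."""
    n = hi - lo
    keep = n > 0
    lo, n = lo[keep], n[keep]
    if lo.size == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(int(n.sum()), dtype=np.int64)
    starts = np.cumsum(n) - n
    out[starts] = lo
    out[starts[1:]] -= lo[:-1] + n[:-1] - 1
    return np.cumsum(out)


def chance_level(ccg: CrossCorrelogram) -> float:
    """Chance co-firing probability: mean of ``prob`` over the 10–50 ms flanks."""
    return float(ccg.prob[FLANK_MASK].mean())


def detect_monosynaptic(
    ccg: CrossCorrelogram | None, z_threshold: float = Z_THRESHOLD
) -> tuple[bool, float]:
    """Test for a monosynaptic peak in the 0.5–2.5 ms bins.

    The statistic is ``(max peak-bin raw count - flank mean) / flank SD``;
    the pair is significant when it reaches ``z_threshold`` (default 3 SD).
    A degenerate flank (SD = 0) yields ``(False, nan)``; a missing CCG yields
    ``(False, nan)``.
    """
    if ccg is None:
        return False, float("nan")
    flank = ccg.raw_counts[FLANK_MASK].astype(np.float64)
    mu, sd = float(flank.mean()), float(flank.std(ddof=0))
    if sd == 0.0:
        return False, float("nan")
    peak = float(ccg.raw_counts[list(PEAK_BIN_INDICES)].max())
    z = (peak - mu) / sd
    return bool(z >= z_threshold), z


def transmission_probability(ccg: CrossCorrelogram | None) -> float:
    """Spike-transmission probability: peak probability mass above chance.

    Sum over the two peak bins of ``prob - chance``; units are extra
    postsynaptic spikes per presynaptic spike. Negative values are retained —
    they are sampling noise around zero, not clamped. ``nan`` when the CCG
    is missing.
    """
    if ccg is None:
        return float("nan")
    chance = chance_level(ccg)
    idx = list(PEAK_BIN_INDICES)
    return float(ccg.prob[idx].sum() - len(idx) * chance)


def apply_quality_filters(
    ccg_fam1: CrossCorrelogram | None,
    ccg_fam2: CrossCorrelogram | None,
    min_counts: int = MIN_COINCIDENCE_COUNTS,
    dispersion_threshold: float = DISPERSION_THRESHOLD,
    dispersion_on_flanks: bool = True,
) -> tuple[bool, list[str]]:
    """Sparse-histogram quality filters on the FAM1/FAM2 CCGs.

    A pair passes when at least one of the two familiar-session CCGs has
    >= ``min_counts`` total coincidences in ±50 ms AND that qualifying
    session's bin values have SD below ``dispersion_threshold`` × mean.
    The dispersion is evaluated on the flank bins by default so a genuine
    peak cannot fail its own filter; set ``dispersion_on_flanks=False`` to
    use all 101 bins.

    Returns (passes, reasons) with reasons drawn from
    {"min_counts", "dispersion"}.
    """
    qualifying = []
    for ccg in (ccg_fam1, ccg_fam2):
        if ccg is not None and ccg.total_counts >= min_counts:
            qualifying.append(ccg)
    if not qualifying:
        return False, ["min_counts"]
    for ccg in qualifying:
        vals = ccg.raw_counts[FLANK_MASK] if dispersion_on_flanks else ccg.raw_counts
        vals = vals.astype(np.float64)
        mu = vals.mean()
        if mu > 0 and vals.std(ddof=0) < dispersion_threshold * mu:
            return True, []
    return False, ["dispersion"]


# ---------------------------------------------------------------------------
# Light-response PSTH
# ---------------------------------------------------------------------------

def light_response_psth(
    train: SpikeTrain,
    pulses: Sequence[Interval] | Sequence[tuple[float, float]],
    bin_ms: float = 20.0,
    window_s: tuple[float, float] = (-0.1, 0.6),
    theta: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Peri-stimulus time histogram around light-pulse onsets.

    Returns ``(bin_edges_s, prob, cls)`` where ``prob[k]`` is the spike count
    in bin k summed over pulses divided by the number of pulses, and ``cls``
    classifies the cell's light response by comparing the mean in-pulse bin
    value (0 to pulse width) against the pre-pulse baseline (window start
    to 0): ``suppressed`` if below ``(1-theta)`` × baseline, ``activated``
    if above ``(1+theta)`` ×, else ``unmodulated``.
    """
    if len(pulses) == 0:
        raise ValueError("light_response_psth requires at least one pulse")
    onsets, widths = [], []
    for p in pulses:
        a, b = (p.start_s, p.end_s) if isinstance(p, Interval) else (p[0], p[1])
        onsets.append(a)
        widths.append(b - a)
    onsets = np.asarray(onsets)
    pulse_width = float(np.median(widths))
    w0, w1 = window_s
    bw = bin_ms / 1000.0
    edges = np.arange(w0, w1 + 0.5 * bw, bw)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for onset in onsets:
        rel = train.restrict(onset + w0, onset + w1) - onset
        counts += np.histogram(rel, bins=edges)[0]
    prob = counts / onsets.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    pre = prob[centers < 0]
    inp = prob[(centers > 0) & (centers < pulse_width)]
    pre_mean = float(pre.mean()) if pre.size else 0.0
    in_mean = float(inp.mean()) if inp.size else 0.0
    if pre_mean == 0.0:
        cls = "activated" if in_mean > 0 else "unmodulated"
    elif in_mean < (1.0 - theta) * pre_mean:
        cls = "suppressed"
    elif in_mean > (1.0 + theta) * pre_mean:
        cls = "activated"
    else:
        cls = "unmodulated"
    return edges, prob, cls


# ---------------------------------------------------------------------------
# Detected-pair record
# ---------------------------------------------------------------------------

@dataclass
class MonosynapticPair:
    """A detected pyramidal→interneuron link with per-session transmission."""

    pre_id: str
    post_id: str
    animal_id: str
    detection_ccg: CrossCorrelogram
    peak_z: float
    significant: bool
    passes_filters: bool
    filter_reasons: list[str] = field(default_factory=list)
    transmission: dict[str, float] = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        return f"{self.pre_id}->{self.post_id}"
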