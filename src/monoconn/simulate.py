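"""Synthetic multi-session spike-train generator with planted connections.

The generator emulates the recording-day structure the analysis expects:
four 25 min exploration sessions (FAM1, NOV, FAML, FAM2) followed by an
18 min rest session with brief light pulses. Cells fire as homogeneous
Poisson processes within a session; log-normal base rates put pyramidal
cells around 0.3–3 Hz and interneurons around 5–30 Hz. During FAML,
alternating light epochs suppress a configurable subset of cells
(multiplying their rate by a suppression factor) and disinhibit a subset of
pyramidal cells (enhancement factor); the same cells respond to the 500 ms
rest pulses, which is what the light-response PSTH classifies.

Monosynaptic couplings are planted additively: for each presynaptic spike,
with session-specific probability ``p_trans`` an extra postsynaptic spike is
inserted at a truncated-normal latency inside the 0.5–2.5 ms detection
window. Ground truth (per-connection transmission by session, per-cell rates
and light classes) is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .types import CellType, Interval, SessionSet, SpikeTrain

EXPLORATION_SESSIONS = ("FAM1", "NOV", "FAML", "FAM2")
LATENCY_BOUNDS_MS = (0.5, 2.5)
MERGE_TOLERANCE_S = 1e-4  # near-coincident postsynaptic spikes (<0.1 ms) merge


@dataclass(frozen=True)
class Connection:
    """A planted pyramidal→interneuron coupling within one animal.

    ``pre`` indexes the animal's pyramidal cells, ``post`` its interneurons.
    ``p_trans`` maps session label -> transmission probability in [0, 1].
    """

    animal: int
    pre: int
    post: int
    p_trans: dict[str, float]
    latency_mean_ms: float = 1.4
    latency_sd_ms: float = 0.3

    def __post_init__(self) -> None:
        for s, p in self.p_trans.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_trans[{s}]={p} outside [0, 1]")


@dataclass
class LightConfig:
    """FAML-session light modulation and cell-population response structure."""

    fraction_suppressed_pyr: float = 0.3
    fraction_suppressed_int: float = 0.6
    fraction_disinhibited_pyr: float = 0.2
    suppression_factor: float = 0.3
    enhancement_factor: float = 2.0
    epoch_s: float = 10.0  # alternating light / no-light epoch length
    light_duty: float = 0.5


@dataclass
class SimConfig:
    """Full description of a simulated recording day.

    Defaults reproduce the study conditions the analysis was built for:
    4 × 1500 s exploration sessions plus a 1080 s rest session with 500 ms
    light pulses every 3 s; log-normal rates centered near 1 Hz (pyramidal)
    and 12 Hz (interneuron); truncated-normal transmission latencies within
    0.5–2.5 ms.
    """

    n_animals: int = 4
    n_pyr: int = 20
    n_int: int = 4
    pyr_rate_lognorm: tuple[float, float] = (0.0, 0.5)  # ln-Hz mean, sd -> ~0.3-3 Hz
    int_rate_lognorm: tuple[float, float] = (2.5, 0.4)  # -> ~5-30 Hz
    connections: list[Connection] = field(default_factory=list)
    session_lengths_s: dict[str, float] = field(
        default_factory=lambda: {
            "FAM1": 1500.0,
            "NOV": 1500.0,
            "FAML": 1500.0,
            "FAM2": 1500.0,
            "REST": 1080.0,
        }
    )
    session_rate_multipliers: dict[str, float] = field(default_factory=dict)
    faml_light: LightConfig = field(default_factory=LightConfig)
    rest_pulse_width_s: float = 0.5
    rest_pulse_period_s: float = 3.0
    animal_random_intercept_sd: float = 0.15  # log-rate offset per animal
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted values exported for recovery tests.

    ``connections`` rows: animal, pre_id, post_id, session, p_trans,
    latency_mean_ms, latency_sd_ms.
    ``cells`` rows: cell_id, animal_id, cell_type, session, rate_hz,
    light_class.
    """

    connections: "pd.DataFrame"  # noqa: F821 - imported lazily below
    cells: "pd.DataFrame"  # noqa: F821


def make_rest_pulses(
    rest_interval: Interval | tuple[float, float],
    width_s: float = 0.5,
    period_s: float = 3.0,
) -> list[Interval]:
    """Tile a rest interval with light pulses of ``width_s`` every ``period_s``.

    The last pulse that would extend past the interval end is dropped.
    """
    if width_s <= 0 or period_s <= 0:
        raise ValueError("pulse width and period must be positive")
    if width_s >= period_s:
        raise ValueError("pulse width must be smaller than the period")
    a, b = (
        (rest_interval.start_s, rest_interval.end_s)
        if isinstance(rest_interval, Interval)
        else rest_interval
    )
    onsets = np.arange(a, b, period_s)
    onsets = onsets[onsets + width_s <= b]
    return [Interval("LIGHT", float(t), float(t + width_s)) for t in onsets]


def _build_sessions(cfg: SimConfig) -> SessionSet:
    t = 0.0
    sessions = []
    for label in (*EXPLORATION_SESSIONS, "REST"):
        dur = cfg.session_lengths_s[label]
        sessions.append(Interval(label, t, t + dur))
        t += dur
    sset = SessionSet(sessions=sessions)
    lights: list[Interval] = []
    # FAML: alternating light / no-light epochs by duty cycle
    faml = sset["FAML"]
    lc = cfg.faml_light
    period = lc.epoch_s / lc.light_duty if lc.light_duty > 0 else np.inf
    t = faml.start_s
    while t + lc.epoch_s <= faml.end_s and np.isfinite(period):
        lights.append(Interval("LIGHT", t, t + lc.epoch_s))
        t += period
    # REST: brief pulses
    lights.extend(
        make_rest_pulses(sset["REST"], cfg.rest_pulse_width_s, cfg.rest_pulse_period_s)
    )
    return SessionSet(sessions=sessions, light_intervals=lights)


def _poisson_piecewise(
    rng: np.random.Generator,
    segments: list[tuple[float, float, float]],
) -> np.ndarray:
    """Homogeneous-Poisson spikes over (start, end, rate) segments."""
    parts = []
    for a, b, rate in segments:
        if rate <= 0 or b <= a:
            continue
        n = rng.poisson(rate * (b - a))
        if n:
            parts.append(rng.uniform(a, b, size=n))
    if not parts:
        return np.empty(0, dtype=np.float64)
    return np.sort(np.concatenate(parts))


def _segments_for_cell(
    sessions: SessionSet,
    base_rate: float,
    session_mult: dict[str, float],
    light_factor: float,
) -> list[tuple[float, float, float]]:
    """Split each session at its light intervals, scaling rate inside light."""
    segs: list[tuple[float, float, float]] = []
    for sess in sessions.sessions:
        rate = base_rate * session_mult.get(sess.label, 1.0)
        lights = sessions.lights_within(sess.label)
        t = sess.start_s
        for li in lights:
            if li.start_s > t:
                segs.append((t, li.start_s, rate))
            segs.append((li.start_s, li.end_s, rate * light_factor))
            t = li.end_s
        if t < sess.end_s:
            segs.append((t, sess.end_s, rate))
    return segs


def _merge_close(times: np.ndarray, tol: float = MERGE_TOLERANCE_S) -> np.ndarray:
    """Sort and drop spikes closer than ``tol`` to their predecessor."""
    if times.size < 2:
        return np.sort(times)
    t = np.sort(times)
    keep = np.empty(t.size, dtype=bool)
    keep[0] = True
    np.greater(np.diff(t), tol, out=keep[1:])
    return t[keep]


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[list[SpikeTrain], SessionSet, GroundTruth]:
    """Generate spike trains, the session layout, and planted ground truth.

    Deterministic for a fixed config (``cfg.seed`` drives all randomness).
    Background spikes are homogeneous Poisson per cell per session, scaled by
    the light factor inside light intervals for light-responsive cells.
    Transmission spikes are added on top of the interneuron background (no
    thinning); near-coincident postsynaptic spikes are merged.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    sessions = _build_sessions(cfg)
    lc = cfg.faml_light

    trains: list[SpikeTrain] = []
    cell_rows = []
    # per-animal multiplicative rate offset (log-normal intercept)
    animal_offset = np.exp(
        rng.normal(0.0, cfg.animal_random_intercept_sd, size=cfg.n_animals)
    )
    pyr_times: dict[tuple[int, int], np.ndarray] = {}
    int_bg: dict[tuple[int, int], np.ndarray] = {}
    int_meta: dict[tuple[int, int], tuple[str, str, float, dict[str, float], float]] = {}

    for a in range(cfg.n_animals):
        animal_id = f"rat{a}"
        mu_p, sd_p = cfg.pyr_rate_lognorm
        mu_i, sd_i = cfg.int_rate_lognorm
        pyr_rates = np.exp(rng.normal(mu_p, sd_p, cfg.n_pyr)) * animal_offset[a]
        int_rates = np.exp(rng.normal(mu_i, sd_i, cfg.n_int)) * animal_offset[a]

        n_sup_p = int(round(lc.fraction_suppressed_pyr * cfg.n_pyr))
        n_dis_p = int(round(lc.fraction_disinhibited_pyr * cfg.n_pyr))
        n_sup_i = int(round(lc.fraction_suppressed_int * cfg.n_int))
        pyr_classes = np.array(
            ["suppressed"] * n_sup_p
            + ["activated"] * n_dis_p
            + ["unmodulated"] * (cfg.n_pyr - n_sup_p - n_dis_p)
        )
        int_classes = np.array(
            ["suppressed"] * n_sup_i + ["unmodulated"] * (cfg.n_int - n_sup_i)
        )
        rng.shuffle(pyr_classes)
        rng.shuffle(int_classes)

        for j in range(cfg.n_pyr):
            factor = {
                "suppressed": lc.suppression_factor,
                "activated": lc.enhancement_factor,
            }.get(pyr_classes[j], 1.0)
            segs = _segments_for_cell(
                sessions, pyr_rates[j], cfg.session_rate_multipliers, factor
            )
            times = _poisson_piecewise(rng, segs)
            pyr_times[(a, j)] = times
            cid = f"{animal_id}_pyr{j}"
            trains.append(
                SpikeTrain(cid, animal_id, CellType.PYRAMIDAL, _merge_close(times))
            )
            for sess in sessions.sessions:
                cell_rows.append(
                    (cid, animal_id, "pyramidal", sess.label,
                     _true_rate(pyr_rates[j], cfg, sess, sessions, factor),
                     pyr_classes[j])
                )

        for j in range(cfg.n_int):
            factor = (
                lc.suppression_factor if int_classes[j] == "suppressed" else 1.0
            )
            segs = _segments_for_cell(
                sessions, int_rates[j], cfg.session_rate_multipliers, factor
            )
            int_bg[(a, j)] = _poisson_piecewise(rng, segs)
            int_meta[(a, j)] = (
                f"{animal_id}_int{j}", animal_id, int_rates[j],
                {}, factor,
            )
            cid = int_meta[(a, j)][0]
            for sess in sessions.sessions:
                cell_rows.append(
                    (cid, animal_id, "interneuron", sess.label,
                     _true_rate(int_rates[j], cfg, sess, sessions, factor),
                     int_classes[j])
                )

    # plant transmission spikes on top of interneuron background
    conn_rows = []
    extra: dict[tuple[int, int], list[np.ndarray]] = {}
    lat_lo, lat_hi = LATENCY_BOUNDS_MS
    for conn in cfg.connections:
        key = (conn.animal, conn.post)
        pre = pyr_times[(conn.animal, conn.pre)]
        added = []
        for sess in sessions.sessions:
            p = conn.p_trans.get(sess.label, 0.0)
            conn_rows.append(
                (f"rat{conn.animal}", f"rat{conn.animal}_pyr{conn.pre}",
                 f"rat{conn.animal}_int{conn.post}", sess.label, p,
                 conn.latency_mean_ms, conn.latency_sd_ms)
            )
            if p <= 0:
                continue
            t_pre = pre[(pre >= sess.start_s) & (pre < sess.end_s)]
            fired = t_pre[rng.random(t_pre.size) < p]
            if fired.size == 0:
                continue
            a_std = (lat_lo - conn.latency_mean_ms) / conn.latency_sd_ms
            b_std = (lat_hi - conn.latency_mean_ms) / conn.latency_sd_ms
            lat_ms = stats.truncnorm.rvs(
                a_std, b_std, loc=conn.latency_mean_ms,
                scale=conn.latency_sd_ms, size=fired.size, random_state=rng,
            )
            added.append(fired + lat_ms / 1000.0)
        if added:
            extra.setdefault(key, []).extend(added)

    for (a, j), meta in int_meta.items():
        cid, animal_id, _base, _, _ = meta
        times = int_bg[(a, j)]
        if (a, j) in extra:
            times = np.concatenate([times, *extra[(a, j)]])
        trains.append(
            SpikeTrain(cid, animal_id, CellType.INTERNEURON, _merge_close(times))
        )

    truth = GroundTruth(
        connections=pd.DataFrame(
            conn_rows,
            columns=["animal_id", "pre_id", "post_id", "session", "p_trans",
                     "latency_mean_ms", "latency_sd_ms"],
        ),
        cells=pd.DataFrame(
            cell_rows,
            columns=["cell_id", "animal_id", "cell_type", "session", "rate_hz",
                     "light_class"],
        ),
    )
    return trains, sessions, truth


def _true_rate(
    base: float,
    cfg: SimConfig,
    sess: Interval,
    sessions: SessionSet,
    light_factor: float,
) -> float:
    """Session-average configured rate, accounting for in-light time."""
    rate = base * cfg.session_rate_multipliers.get(sess.label, 1.0)
    lights = sessions.lights_within(sess.label)
    t_light = sum(li.duration_s for li in lights)
    frac = t_light / sess.duration_s
    return rate * ((1 - frac) + frac * light_factor)


def simulate_transmission_table(
    n_pairs: int = 78,
    n_animals: int = 4,
    seed: int = 0,
    b_fam1: float = 0.8,
    b_nov: float = 0.0,
    b_faml: float = 0.4,
    noise_sd: float = 0.3,
    animal_intercept_sd: float = 0.0,
    nov_fam1_corr: float = 0.7,
) -> "pd.DataFrame":
    """Synthetic pair-session table for the statistical layer.

    Standardized per-session transmission values: FAM1, FAML, and NOV are
    drawn with NOV correlated to FAM1 (so NOV predicts FAM2 marginally but
    carries no independent signal when ``b_nov = 0``); FAM2 is the stated
    linear combination plus Gaussian noise and an animal-level intercept.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    animal = rng.integers(0, n_animals, size=n_pairs)
    intercepts = rng.normal(0.0, animal_intercept_sd, size=n_animals)
    fam1 = rng.normal(size=n_pairs)
    nov = nov_fam1_corr * fam1 + np.sqrt(1 - nov_fam1_corr**2) * rng.normal(size=n_pairs)
    faml = rng.normal(size=n_pairs)
    fam2 = (
        b_fam1 * fam1
        + b_nov * nov
        + b_faml * faml
        + intercepts[animal]
        + rng.normal(0.0, noise_sd, size=n_pairs)
    )
    return pd.DataFrame(
        {
            "pair_id": [f"pair{i}" for i in range(n_pairs)],
            "animal_id": [f"rat{a}" for a in animal],
            "trans_FAM1": fam1,
            "trans_NOV": nov,
            "trans_FAML": faml,
            "trans_FAM2": fam2,
        }
    )


def random_connections(
    cfg: SimConfig,
    n_per_animal: int,
    p_trans: dict[str, float] | float,
    rng: np.random.Generator | None = None,
) -> list[Connection]:
    """Draw non-duplicate (pyr, int) couplings per animal with shared p_trans."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if not isinstance(p_trans, dict):
        p_trans = {s: float(p_trans) for s in EXPLORATION_SESSIONS}
    conns = []
    for a in range(cfg.n_animals):
        pairs = [(i, j) for i in range(cfg.n_pyr) for j in range(cfg.n_int)]
        idx = rng.choice(len(pairs), size=min(n_per_animal, len(pairs)), replace=False)
        for k in idx:
            i, j = pairs[k]
            conns.append(Connection(animal=a, pre=i, post=j, p_trans=dict(p_trans)))
    return conns
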