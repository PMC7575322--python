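import numpy as np
import pytest

from monoconn.simulate import Connection, SimConfig, simulate_dataset
from monoconn.types import CellType, SpikeTrain

EXPLORATION = ("FAM1", "NOV", "FAML", "FAM2")


def make_train(times, cell_id="c", animal_id="rat0", cell_type=CellType.UNKNOWN):
    return SpikeTrain(cell_id, animal_id, cell_type, np.asarray(times, dtype=float))


def simulate_pair(
    p_trans=0.0,
    seed=0,
    pyr_hz=1.0,
    int_hz=15.0,
    p_by_session=None,
    session_lengths=None,
):
    """One pyramidal + one interneuron over the standard session layout.

    Rates are fixed (not drawn) so tests control the regime exactly.
    Returns (pyr_train, int_train, sessions, truth).
    """
    p = p_by_session or {s: p_trans for s in (*EXPLORATION, "REST")}
    cfg = SimConfig(
        n_animals=1,
        n_pyr=1,
        n_int=1,
        seed=seed,
        pyr_rate_lognorm=(np.log(pyr_hz), 0.0),
        int_rate_lognorm=(np.log(int_hz), 0.0) if int_hz > 0 else (-100.0, 0.0),
        animal_random_intercept_sd=0.0,
        connections=[Connection(0, 0, 0, p)] if any(v > 0 for v in p.values()) else [],
    )
    if session_lengths:
        cfg.session_lengths_s = session_lengths
    trains, sessions, truth = simulate_dataset(cfg)
    pyr = next(t for t in trains if t.cell_type is CellType.PYRAMIDAL)
    intn = next(t for t in trains if t.cell_type is CellType.INTERNEURON)
    return pyr, intn, sessions, truth


def brute_force_ccg(t_pre, t_post, exclude_zero_lag=False):
    """Quadratic all-pairs lag histogram on the ±50 ms, 1 ms lattice."""
    counts = np.zeros(101, dtype=np.int64)
    for tp in t_pre:
        lags_ms = (np.asarray(t_post) - tp) * 1000.0
        k = np.floor(lags_ms + 0.5).astype(np.int64) + 50
        ok = (k >= 0) & (k < 101)
        if exclude_zero_lag:
            ok &= lags_ms != 0.0
        np.add.at(counts, k[ok], 1)
    return counts


@pytest.fixture(scope="session")
def planted_dataset():
    """A small multi-animal dataset with planted connections, reused across tests."""
    cfg = SimConfig(
        n_animals=2,
        n_pyr=6,
        n_int=2,
        seed=11,
        pyr_rate_lognorm=(0.0, 0.3),
        int_rate_lognorm=(np.log(12.0), 0.2),
        connections=[
            Connection(0, 0, 0, {s: 0.05 for s in EXPLORATION}),
            Connection(0, 1, 1, {"FAM1": 0.06, "NOV": 0.05, "FAML": 0.02, "FAM2": 0.03}),
            Connection(1, 2, 0, {s: 0.08 for s in EXPLORATION}),
        ],
    )
    return simulate_dataset(cfg)
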