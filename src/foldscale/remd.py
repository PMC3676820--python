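"""Temperature replica-exchange engine.

Runs one Metropolis walker per temperature slot of a ladder; every
``exchange_interval`` sweeps, neighbouring slots attempt to swap their
configurations with the standard replica-exchange acceptance

    p = min(1, exp[(1/kT_i - 1/kT_j)(E_i - E_j)]),

alternating even pairs (0-1, 2-3, ...) and odd pairs (1-2, 3-4, ...) on
successive attempts.  A swap exchanges configurations between the
fixed-temperature slots, so each slot records a constant-temperature
trajectory (the view behind melting curves and folded-replica counts), while
walker identities carry across slots (the view behind round-trip
diagnostics).

The engine is model-agnostic: anything satisfying the sampler contract
(``energy``, ``propose``/``run_sweeps``, ``k_B``) can be exchanged, from the
CA Gō model to the discrete two-level system.  Execution is sequential and
single-process; for a fixed seed the result is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cg_sampler import MCParams, _metropolis_sweeps
from .io_formats import Frame, Structure, Trajectory

__all__ = [
    "ExchangeRecord",
    "REMDResult",
    "exchange_probability",
    "remd_run",
    "acceptance_stats",
    "round_trips",
    "energy_histograms",
]


def exchange_probability(
    e_i: float, e_j: float, t_i: float, t_j: float, k_B: float = 1.0
) -> float:
    """Replica-exchange swap probability min(1, exp[(β_i − β_j)(E_i − E_j)]).

    ``e_i``/``t_i`` belong to the lower slot of the attempted pair; the
    formula is symmetric under swapping the pair, and equals 1 whenever the
    hotter replica holds the lower energy.
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be > 0")
    if not (math.isfinite(e_i) and math.isfinite(e_j)):
        raise ValueError("energies must be finite")
    delta = (1.0 / (k_B * t_i) - 1.0 / (k_B * t_j)) * (e_i - e_j)
    return min(1.0, math.exp(min(delta, 0.0))) if delta < 0 else 1.0


@dataclass(frozen=True)
class ExchangeRecord:
    """One swap attempt between adjacent ladder slots."""

    sweep: int
    pair: tuple  # (i, i+1) ladder indices
    delta: float  # log-acceptance exponent
    accepted: bool

    def __post_init__(self):
        if self.pair[1] != self.pair[0] + 1:
            raise ValueError("exchange pairs must be adjacent")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass
class REMDResult:
    """Everything a replica-exchange run produces.

    ``slot_states``/``slot_energies`` are the fixed-temperature views (one
    row per ladder slot, one column per record); ``walker_slots`` maps each
    walker to its slot index at every record; ``exchange_records`` hold the
    swap bookkeeping.  ``record_sweeps`` gives the sweep index of every
    record column.
    """

    temperatures: np.ndarray
    record_sweeps: np.ndarray
    slot_states: list  # [slot][record] -> state
    slot_energies: np.ndarray  # (n_slots, n_records)
    walker_slots: np.ndarray  # (n_records, n_walkers)
    exchange_records: list = field(default_factory=list)
    k_B: float = 1.0
    energy_units: str = "reduced (eps=1)"

    @property
    def n_slots(self) -> int:
        return len(self.temperatures)

    def validate(self) -> "REMDResult":
        n_rec = len(self.record_sweeps)
        if self.slot_energies.shape != (self.n_slots, n_rec):
            raise ValueError("slot_energies shape mismatch")
        if any(len(s) != n_rec for s in self.slot_states):
            raise ValueError("per-slot trajectories must have equal length")
        ident = np.arange(self.n_slots)
        for row in self.walker_slots:
            if not np.array_equal(np.sort(row), ident):
                raise ValueError("walker slots must be a permutation at every record")
        return self

    def slot_trajectory(self, slot: int, model) -> Trajectory:
        """Fixed-temperature Trajectory view of one slot (coordinate models)."""
        frames = [
            Frame(
                structure=model.state_to_structure(self.slot_states[slot][k]),
                energy=float(self.slot_energies[slot, k]),
                step=int(self.record_sweeps[k]),
                temperature=float(self.temperatures[slot]),
            )
            for k in range(len(self.record_sweeps))
        ]
        return Trajectory(frames, energy_units=self.energy_units).validate()


def remd_run(
    model,
    ladder,
    starts,
    n_sweeps: int,
    exchange_interval: int,
    seed: int = 0,
    mc_params: MCParams | None = None,
) -> REMDResult:
    """Replica exchange over a temperature ladder.

    ``ladder`` is a TemperatureLadder or a sequence of increasing
    temperatures; ``starts`` is one start state per slot (Structures are
    converted via the model, raw states are used as-is).  Between exchange
    attempts every slot advances ``exchange_interval`` sweeps of isothermal
    Metropolis MC at its own temperature; a record (state, energy, walker
    positions) is taken at every attempt.  Even/odd neighbour pairs
    alternate across attempts.  Deterministic for a fixed seed.
    """
    temperatures = np.asarray(getattr(ladder, "temperatures", ladder), dtype=float)
    n_slots = len(temperatures)
    if np.any(np.diff(temperatures) <= 0):
        raise ValueError("ladder temperatures must be strictly increasing")
    if len(starts) != n_slots:
        raise ValueError(f"need {n_slots} start states, got {len(starts)}")
    if exchange_interval < 1 or n_sweeps < 1:
        raise ValueError("n_sweeps and exchange_interval must be >= 1")
    p = mc_params or MCParams(n_sweeps=1, temperature=1.0)

    states = []
    for s in starts:
        if isinstance(s, Structure):
            states.append(model.start_state(s).copy())
        else:
            states.append(s.copy() if hasattr(s, "copy") else s)
    energies = [model.energy(s) for s in states]
    betas = 1.0 / (model.k_B * temperatures)
    rng = np.random.default_rng(seed)
    walkers = list(range(n_slots))  # walker id currently in each slot

    record_sweeps, walker_rows, exchange_records = [], [], []
    slot_states = [[] for _ in range(n_slots)]
    slot_energies = [[] for _ in range(n_slots)]

    def record(sweep):
        record_sweeps.append(sweep)
        for i in range(n_slots):
            slot_states[i].append(
                states[i].copy() if hasattr(states[i], "copy") else states[i]
            )
            slot_energies[i].append(energies[i])
        row = np.empty(n_slots, dtype=int)
        for slot, w in enumerate(walkers):
            row[w] = slot
        walker_rows.append(row)

    sweep = 0
    attempt = 0
    while sweep < n_sweeps:
        block = min(exchange_interval, n_sweeps - sweep)
        for i in range(n_slots):
            states[i], energies[i] = _metropolis_sweeps(
                model, states[i], energies[i], betas[i], block, rng, p
            )
        sweep += block
        if sweep >= n_sweeps and block < exchange_interval:
            record(sweep)
            break
        first = attempt % 2  # even pairs on even attempts, odd on odd
        for i in range(first, n_slots - 1, 2):
            delta = (betas[i] - betas[i + 1]) * (energies[i] - energies[i + 1])
            accepted = delta >= 0 or rng.random() < math.exp(delta)
            if accepted:
                states[i], states[i + 1] = states[i + 1], states[i]
                energies[i], energies[i + 1] = energies[i + 1], energies[i]
                walkers[i], walkers[i + 1] = walkers[i + 1], walkers[i]
            exchange_records.append(
                ExchangeRecord(sweep=sweep, pair=(i, i + 1), delta=float(delta), accepted=bool(accepted))
            )
        attempt += 1
        record(sweep)

    return REMDResult(
        temperatures=temperatures,
        record_sweeps=np.array(record_sweeps, dtype=int),
        slot_states=slot_states,
        slot_energies=np.array(slot_energies, dtype=float),
        walker_slots=np.array(walker_rows, dtype=int),
        exchange_records=exchange_records,
        k_B=model.k_B,
        energy_units=getattr(model, "energy_units", "model units"),
    ).validate()


def acceptance_stats(result: REMDResult):
    """Per-neighbour-pair exchange acceptance rates and the global mean.

    Returns a DataFrame with columns (pair_low, pair_high, attempted,
    accepted, rate); pairs with zero attempts are reported with a missing
    (NaN) rate, never 0.  The global mean is the mean over attempted pairs.
    """
    import pandas as pd

    rows = []
    for i in range(result.n_slots - 1):
        recs = [r for r in result.exchange_records if r.pair == (i, i + 1)]
        attempted = len(recs)
        accepted = sum(r.accepted for r in recs)
        rows.append(
            {
                "pair_low": i,
                "pair_high": i + 1,
                "attempted": attempted,
                "accepted": accepted,
                "rate": (accepted / attempted) if attempted else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def round_trips(result: REMDResult, walker_id: int) -> int:
    """Completed bottom-to-top-and-back excursions of one walker.

    A round trip arms when the walker sits in slot 0, fires when it returns
    to slot 0 after having visited the top slot n−1.
    """
    if not (0 <= walker_id < result.n_slots):
        raise ValueError(f"unknown walker {walker_id}")
    path = result.walker_slots[:, walker_id]
    top = result.n_slots - 1
    trips = 0
    armed = False
    seen_top = False
    for slot in path:
        if slot == 0:
            if armed and seen_top:
                trips += 1
                seen_top = False
            armed = True
        elif slot == top and armed:
            seen_top = True
    return trips


def energy_histograms(result: REMDResult, bins: int = 40):
    """Normalised per-slot energy histograms on a common grid, plus the
    neighbour overlap coefficient Σ min(h_i, h_{i+1})·Δ per adjacent pair.

    Returns (hist: (n_slots, bins), edges, overlaps: (n_slots-1,)).
    Broader histograms at higher slots and non-vanishing neighbour overlap
    are what make exchange acceptance non-zero.
    """
    e = result.slot_energies
    if e.size == 0:
        raise ValueError("empty result")
    edges = np.histogram_bin_edges(e.ravel(), bins=bins)
    width = np.diff(edges)
    hist = np.stack(
        [np.histogram(e[i], bins=edges, density=True)[0] for i in range(result.n_slots)]
    )
    overlaps = np.array(
        [float(np.sum(np.minimum(hist[i], hist[i + 1]) * width)) for i in range(result.n_slots - 1)]
    )
    return hist, edges, overlaps
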