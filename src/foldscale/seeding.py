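"""Replica seeding: energy-spanning snapshot selection, temperature ladder
construction, and energy-rank assignment of start structures to replicas.

The seeding idea: a coarse-grained trajectory that crossed the folding
transition already contains conformations from the whole energy range.
Picking snapshots that span that range and handing the low-energy ones to
the cold replicas (high-energy ones to the hot replicas) starts the
replica-exchange ensemble close to its stationary distribution, so
equilibration is fast compared to starting every replica from the extended
chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Frame, Trajectory

__all__ = [
    "TemperatureLadder",
    "SeedAssignment",
    "select_spanning_frames",
    "make_geometric_ladder",
    "assign_by_energy",
]


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing replica temperatures (K, or reduced units)."""

    temperatures: tuple

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperatures)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)

    def __len__(self) -> int:
        return len(self.temperatures)

    def __iter__(self):
        return iter(self.temperatures)


@dataclass(frozen=True)
class SeedAssignment:
    """Start-structure → ladder-slot mapping with the ranking energies.

    ``order`` holds, for each ladder slot (coldest first), the index of the
    chosen structure in the input list; ``energies`` the input energies.
    The mapping is a bijection with energy rank equal to temperature rank.
    """

    order: tuple  # slot -> input index
    energies: tuple
    ladder: TemperatureLadder

    def __post_init__(self):
        if sorted(self.order) != list(range(len(self.ladder))):
            raise ValueError("assignment must be a bijection onto ladder slots")

    def __iter__(self):
        """Yields (slot, temperature, input_index, energy), coldest first."""
        for slot, idx in enumerate(self.order):
            yield slot, self.ladder.temperatures[slot], idx, self.energies[idx]


def make_geometric_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """Geometric temperature ladder T_i = t_min (t_max/t_min)^(i/(n-1)).

    Geometric spacing gives approximately uniform neighbour exchange
    acceptance when the heat capacity varies slowly with temperature.
    Endpoints are exact; n = 1 requires t_min = t_max.
    """
    if t_min <= 0 or t_max < t_min or n < 1:
        raise ValueError("require 0 < t_min <= t_max and n >= 1")
    if n == 1:
        if t_min != t_max:
            raise ValueError("a single-slot ladder needs t_min == t_max")
        return TemperatureLadder((t_min,))
    ratio = (t_max / t_min) ** (1.0 / (n - 1))
    temps = [t_min * ratio**i for i in range(n)]
    temps[0], temps[-1] = t_min, t_max  # endpoints exact
    return TemperatureLadder(tuple(temps))


def select_spanning_frames(
    t: Trajectory, n: int, seed: int = 0, stratified: bool = True
) -> list[Frame]:
    """Randomly select ``n`` frames spanning the trajectory's energy range.

    Stratified mode (default): the energy range is split into ``n``
    equal-width bins; one frame is drawn uniformly from each non-empty bin,
    and the remainder are drawn uniformly from the most populated bin —
    mirroring a selection where most picks come from the dominant basin.
    With ``stratified=False`` all picks are plain uniform draws without
    replacement.  Deterministic per seed; output ordered by step.
    """
    frames = t.frames
    if n > len(frames):
        raise ValueError(f"cannot select {n} frames from {len(frames)}")
    energies = t.energies
    if np.any(np.isnan(energies)):
        raise ValueError("all frames need energies for spanning selection")
    rng = np.random.default_rng(seed)
    if n == len(frames):
        return sorted(frames, key=lambda f: f.step)
    if not stratified:
        picks = rng.choice(len(frames), size=n, replace=False)
    else:
        e_min, e_max = float(energies.min()), float(energies.max())
        if e_max == e_min:
            picks = rng.choice(len(frames), size=n, replace=False)
        else:
            edges = np.linspace(e_min, e_max, n + 1)
            bins = np.clip(np.digitize(energies, edges) - 1, 0, n - 1)
            picks = []
            for b in range(n):
                members = np.where(bins == b)[0]
                if len(members):
                    picks.append(int(rng.choice(members)))
            counts = np.bincount(bins, minlength=n)
            busiest = np.where(bins == int(np.argmax(counts)))[0]
            pool = [i for i in busiest if i not in picks]
            need = n - len(picks)
            if need > len(pool):  # busiest bin exhausted: fall back to all frames
                pool = [i for i in range(len(frames)) if i not in picks]
            extra = rng.choice(pool, size=need, replace=False) if need else []
            picks = np.array(list(picks) + list(extra))
    return sorted((frames[i] for i in picks), key=lambda f: f.step)


def assign_by_energy(structures_with_energy, ladder: TemperatureLadder) -> SeedAssignment:
    """Pair structures with ladder slots so energy rank equals temperature
    rank: the lowest-energy structure seeds the coldest replica.

    ``structures_with_energy`` is a sequence of (structure, energy) pairs or
    bare energies; ties keep input order (stable sort).
    """
    energies = []
    for item in structures_with_energy:
        energies.append(float(item[1]) if isinstance(item, (tuple, list)) else float(item))
    if len(energies) != len(ladder):
        raise ValueError(
            f"got {len(energies)} structures for a {len(ladder)}-slot ladder"
        )
    order = sorted(range(len(energies)), key=lambda i: energies[i])  # stable
    return SeedAssignment(order=tuple(order), energies=tuple(energies), ladder=ladder)
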