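"""Enumeration, canonicalization and measurement of synchronous attractors.

Under the deterministic synchronous update every trajectory ends in a
minimal cycle: a fixed point (period 1) or a cyclic attractor (period >= 2).
This module finds those cycles, deduplicates them by canonical rotation
(smallest integer state code first), and measures basins of attraction
either exactly (exhaustive sweep of all 2^n states) or by seeded sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import BooleanNetwork, decode_state, encode_state

__all__ = [
    "Attractor",
    "AttractorSet",
    "canonicalize_cycle",
    "trajectory_to_attractor",
    "enumerate_attractors",
    "EXHAUSTIVE_CEILING",
]

#: Largest node count for which the exhaustive sweep is allowed by default.
EXHAUSTIVE_CEILING = 22


@dataclass(frozen=True)
class Attractor:
    """A minimal cycle of states, stored in canonical rotation.

    ``states[i]`` maps to ``states[(i+1) % period]`` under the synchronous
    step; ``states[0]`` has the smallest integer code in the cycle.
    ``basin_size`` is the exact count of states draining into the cycle
    (exhaustive mode); ``basin_fraction`` the estimated fraction (sampled
    mode).  Either may be ``None`` when unknown.
    """

    states: tuple
    basin_size: Optional[int] = None
    basin_fraction: Optional[float] = None

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def codes(self) -> tuple:
        return tuple(encode_state(s) for s in self.states)

    def key(self) -> tuple:
        """Identity of the attractor: its canonical code sequence."""
        return self.codes()

    def bitstrings(self) -> tuple:
        return tuple("".join(str(b) for b in s) for s in self.states)


@dataclass(frozen=True)
class AttractorSet:
    """The attractor census of one network.

    ``coverage`` counts initial states explored (2^n in exhaustive mode,
    the sample count otherwise); ``seed`` is recorded for sampled runs.
    """

    network: BooleanNetwork
    attractors: tuple
    mode: str
    coverage: int
    seed: Optional[int] = None

    def __post_init__(self):
        keys = [a.key() for a in self.attractors]
        if len(set(keys)) != len(keys):
            raise ValueError("attractors are not pairwise distinct")

    def __len__(self):
        return len(self.attractors)

    def fixed_points(self) -> tuple:
        return tuple(a for a in self.attractors if a.is_fixed_point)

    def cycles(self) -> tuple:
        return tuple(a for a in self.attractors if not a.is_fixed_point)

    def period_counts(self) -> dict:
        counts: dict = {}
        for a in self.attractors:
            counts[a.period] = counts.get(a.period, 0) + 1
        return dict(sorted(counts.items()))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": list(self.network.nodes),
            "mode": self.mode,
            "coverage": self.coverage,
            "seed": self.seed,
            "attractors": [
                {
                    "period": a.period,
                    "states": list(a.bitstrings()),
                    "basin_size": a.basin_size,
                    "basin_fraction": a.basin_fraction,
                }
                for a in self.attractors
            ],
        }
        return json.dumps(doc, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str, network: BooleanNetwork) -> "AttractorSet":
        doc = json.loads(text)
        if list(network.nodes) != doc["nodes"]:
            raise ValueError("attractor file does not match the network's nodes")
        attractors = []
        for item in doc["attractors"]:
            states = tuple(tuple(int(c) for c in bits) for bits in item["states"])
            attractors.append(Attractor(
                states=states,
                basin_size=item.get("basin_size"),
                basin_fraction=item.get("basin_fraction"),
            ))
        return cls(network=network, attractors=tuple(attractors),
                   mode=doc["mode"], coverage=doc["coverage"],
                   seed=doc.get("seed"))

    def to_tsv(self) -> str:
        lines = ["attractor\tperiod\tbasin_size\tbasin_fraction\tstates"]
        for i, a in enumerate(self.attractors):
            basin = "" if a.basin_size is None else str(a.basin_size)
            frac = "" if a.basin_fraction is None else f"{a.basin_fraction:.6g}"
            lines.append(
                f"{i}\t{a.period}\t{basin}\t{frac}\t{'/'.join(a.bitstrings())}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cycle canonicalization
# ---------------------------------------------------------------------------

def canonicalize_cycle(states: Sequence, net: Optional[BooleanNetwork] = None):
    """Rotate a cycle so the state with the smallest integer code comes first.

    The input must be a minimal cycle (all states distinct).  When ``net``
    is given, the successor relation ``states[i] -> states[i+1]`` (wrapping)
    is verified and a violation raises ``ValueError``.
    """
    states = [tuple(int(b) for b in s) for s in states]
    if not states:
        raise ValueError("empty state sequence is not a cycle")
    codes = [encode_state(s) for s in states]
    if len(set(codes)) != len(codes):
        raise ValueError("cycle states are not distinct (not a minimal cycle)")
    if net is not None:
        for i, s in enumerate(states):
            expected = states[(i + 1) % len(states)]
            if net.step(s) != expected:
                raise ValueError(
                    f"not a cycle: step({s}) != {expected}")
    start = codes.index(min(codes))
    return tuple(states[start:] + states[:start])


# ---------------------------------------------------------------------------
# Single-trajectory resolution
# ---------------------------------------------------------------------------

def trajectory_to_attractor(net: BooleanNetwork, s0: Sequence,
                            max_steps: Optional[int] = None):
    """Follow the synchronous trajectory from ``s0`` until a state repeats.

    Returns ``(attractor, transient_length)`` where ``transient_length`` is
    the number of steps taken before entering the cycle.  ``max_steps``
    defaults to 2^n, which guarantees termination; smaller overrides raise
    if no repeat occurs in time.
    """
    s0 = net.validate_state(s0)
    if max_steps is None:
        max_steps = 1 << net.n_nodes
    seen = {s0: 0}
    path = [s0]
    s = s0
    for step in range(1, max_steps + 1):
        s = net.step(s)
        if s in seen:
            entry = seen[s]
            cycle = canonicalize_cycle(path[entry:])
            return Attractor(states=cycle), entry
        seen[s] = step
        path.append(s)
    raise RuntimeError(
        f"no repeated state within max_steps={max_steps}; the trajectory "
        "cannot have reached its attractor yet")


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def enumerate_attractors(net: BooleanNetwork, mode: str = "exhaustive",
                         n_samples: Optional[int] = None,
                         seed: Optional[int] = None,
                         ceiling: int = EXHAUSTIVE_CEILING) -> AttractorSet:
    """Find the network's attractors and measure their basins.

    ``exhaustive`` assigns every one of the 2^n states to its attractor via
    successor-table traversal with path memoization, so basin sizes are
    exact and sum to 2^n.  ``sampled`` follows trajectories from
    ``n_samples`` uniformly drawn initial states (seeded); the attractor
    list is then a subset of the exhaustive census and basin fractions are
    estimates.
    """
    if mode == "exhaustive":
        if net.n_nodes > ceiling:
            raise ValueError(
                f"exhaustive enumeration refused for n={net.n_nodes} > "
                f"ceiling {ceiling}; use mode='sampled' with a seed")
        return _enumerate_exhaustive(net)
    if mode == "sampled":
        if n_samples is None or n_samples < 1:
            raise ValueError("sampled mode requires n_samples >= 1")
        if seed is None:
            raise ValueError("sampled mode requires an explicit seed")
        return _enumerate_sampled(net, n_samples, seed)
    raise ValueError(f"unknown mode {mode!r}")


def _enumerate_exhaustive(net: BooleanNetwork) -> AttractorSet:
    n = net.n_nodes
    size = 1 << n
    succ = net.successor_table()
    # -1 = unvisited, -2 = on the current path, >=0 = attractor id
    assign = np.full(size, -1, dtype=np.int64)
    cycles = []  # list of code lists, canonical rotation
    for s0 in range(size):
        if assign[s0] >= 0:
            continue
        path = []
        cur = s0
        while assign[cur] == -1:
            assign[cur] = -2
            path.append(cur)
            cur = int(succ[cur])
        if assign[cur] == -2:  # closed a new cycle within this path
            idx = path.index(cur)
            cycle = path[idx:]
            rot = cycle.index(min(cycle))
            cycles.append(cycle[rot:] + cycle[:rot])
            aid = len(cycles) - 1
        else:
            aid = int(assign[cur])
        for code in path:
            assign[code] = aid
    basins = np.bincount(assign, minlength=len(cycles))
    order = sorted(range(len(cycles)), key=lambda i: tuple(cycles[i]))
    attractors = tuple(
        Attractor(
            states=tuple(decode_state(c, n) for c in cycles[i]),
            basin_size=int(basins[i]),
            basin_fraction=float(basins[i]) / size,
        )
        for i in order
    )
    return AttractorSet(network=net, attractors=attractors,
                        mode="exhaustive", coverage=size)


def _enumerate_sampled(net: BooleanNetwork, n_samples: int,
                       seed: int) -> AttractorSet:
    n = net.n_nodes
    size = 1 << n
    rng = np.random.default_rng(seed)
    if n <= 16:  # cheap table lookup; identical trajectories either way
        table = net.successor_table()
        step = lambda c: int(table[c])
    else:
        step = net.step_code
    assign: dict = {}   # code -> attractor index
    cycles: list = []   # canonical code tuples
    hits = []
    # one draw per sample keeps the stream prefix-stable: growing n_samples
    # with the same seed only appends samples, it never reorders them
    for _ in range(n_samples):
        s0 = int(rng.integers(0, size))
        path = []
        cur = s0
        while cur not in assign:
            assign[cur] = -1  # on path marker
            path.append(cur)
            cur = step(cur)
        if assign[cur] == -1:  # new cycle discovered on this walk
            idx = path.index(cur)
            cycle = path[idx:]
            rot = cycle.index(min(cycle))
            cycles.append(tuple(cycle[rot:] + cycle[:rot]))
            aid = len(cycles) - 1
        else:
            aid = assign[cur]
        for code in path:
            assign[code] = aid
        hits.append(aid)
    counts = np.bincount(hits, minlength=len(cycles))
    order = sorted(range(len(cycles)), key=lambda i: cycles[i])
    attractors = tuple(
        Attractor(
            states=tuple(decode_state(c, n) for c in cycles[i]),
            basin_fraction=float(counts[i]) / n_samples,
        )
        for i in order
    )
    return AttractorSet(network=net, attractors=attractors, mode="sampled",
                        coverage=n_samples, seed=seed)
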