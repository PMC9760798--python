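"""Test-bed network generators and the curated macrophage fixture.

Three sources of networks with known or controllable attractor structure:

* :func:`random_nk_network` -- random N-K networks with truth-table rules
  sampled at a given output bias, fully reproducible from the seed;
* :func:`analytic_fixture` -- tiny networks whose exact attractor census is
  known in closed form (or frozen once from brute force);
* :func:`macrophage_fixture` -- a 17-node macrophage polarization network
  encoding documented TF/cytokine interactions (cytokines and
  hypoxia/metabolic factors are held inputs), together with the default
  phenotype scheme.  Its census is a frozen regression surface, not an
  external-truth claim.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .attractors import AttractorSet, enumerate_attractors
from .fatemap import build_fate_map, fate_map_to_tsv
from .network import BooleanNetwork, TruthTable, parse_network
from .phenotype import PhenotypeScheme, default_scheme

__all__ = [
    "FixtureBundle",
    "random_nk_network",
    "analytic_fixture",
    "macrophage_fixture",
    "macrophage_snapshot",
    "compute_macrophage_snapshot",
    "ANALYTIC_FIXTURES",
]


@dataclass(frozen=True)
class FixtureBundle:
    """A network plus (optionally) a scheme and its expected attractor census."""

    network: BooleanNetwork
    scheme: Optional[PhenotypeScheme] = None
    expected: Optional[dict] = None


# ---------------------------------------------------------------------------
# Random N-K networks
# ---------------------------------------------------------------------------

def random_nk_network(n: int, k: int, bias: float = 0.5,
                      seed: int = 0) -> BooleanNetwork:
    """Random Boolean network: k distinct regulators and a biased table per node.

    Each node draws ``k`` distinct regulators uniformly and an independent
    truth table with ``P(output = 1) = bias``.  Byte-identical output for
    identical ``(n, k, bias, seed)``.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if not 0.0 < bias < 1.0:
        raise ValueError(f"bias must be in (0, 1), got {bias}")
    rng = np.random.default_rng(seed)
    names = tuple(f"X{i}" for i in range(n))
    rules = {}
    for name in names:
        regs = sorted(int(r) for r in rng.choice(n, size=k, replace=False))
        table = (rng.random(1 << k) < bias).astype(int)
        rules[name] = TruthTable([names[r] for r in regs], table.tolist())
    meta = f"random N-K network n={n} k={k} bias={bias} seed={seed}"
    return BooleanNetwork(names, rules, metadata=meta)


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

_TOGGLE_BNET = """\
targets, factors
X, !Y
Y, !X
"""

_NEGATION_RING_3_BNET = """\
targets, factors
X1, !X3
X2, !X1
X3, !X2
"""

# Xi = X(i-1) AND Xi with the chain closed (X0 = X4); census frozen from
# one-off brute force (see tests/oracle.py)
_AND_CHAIN_4_BNET = """\
targets, factors
X1, X4 & X1
X2, X1 & X2
X3, X2 & X3
X4, X3 & X4
"""

_AND_CHAIN_4_EXPECTED = {
    "n_attractors": 2,
    "period_counts": {1: 2},
    "states": [["0000"], ["1111"]],
    "basin_sizes": [15, 1],
}

ANALYTIC_FIXTURES = ("toggle", "negation_ring_3", "and_chain_4")


def analytic_fixture(name: str) -> FixtureBundle:
    """Fixture networks with exact expected censuses.

    ``identity_<n>`` (e.g. ``identity_3``) gives the n-node identity network
    with 2^n fixed points; the other names are listed in
    :data:`ANALYTIC_FIXTURES`.
    """
    if name.startswith("identity_"):
        try:
            n = int(name.split("_", 1)[1])
        except ValueError:
            raise ValueError(f"unknown fixture {name!r}") from None
        if not 1 <= n <= 20:
            raise ValueError("identity fixture size must be in [1, 20]")
        nodes = tuple(f"X{i + 1}" for i in range(n))
        net = BooleanNetwork(nodes, {m: m for m in nodes},
                             metadata=f"identity network n={n}")
        expected = {
            "n_attractors": 1 << n,
            "period_counts": {1: 1 << n},
            "basin_sizes": [1] * (1 << n),
        }
        return FixtureBundle(network=net, expected=expected)
    if name == "toggle":
        net = parse_network(_TOGGLE_BNET, "bnet")
        expected = {
            "n_attractors": 3,
            "period_counts": {1: 2, 2: 1},
            "states": [["00", "11"], ["10"], ["01"]],
            "basin_sizes": [2, 1, 1],
        }
        return FixtureBundle(network=net, expected=expected)
    if name == "negation_ring_3":
        net = parse_network(_NEGATION_RING_3_BNET, "bnet")
        expected = {
            "n_attractors": 2,
            "period_counts": {2: 1, 6: 1},
            "states": [["000", "111"],
                       ["100", "101", "001", "011", "010", "110"]],
            "basin_sizes": [2, 6],
        }
        return FixtureBundle(network=net, expected=expected)
    if name == "and_chain_4":
        net = parse_network(_AND_CHAIN_4_BNET, "bnet")
        return FixtureBundle(network=net, expected=dict(_AND_CHAIN_4_EXPECTED))
    raise ValueError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# Macrophage fixture
# ---------------------------------------------------------------------------

def _data_text(filename: str) -> str:
    return (resources.files("boolfate") / "data" / filename).read_text("utf-8")


def macrophage_fixture() -> FixtureBundle:
    """17-node macrophage polarization network plus the default scheme.

    Environmental cytokines (IFNG, GMCSF, IL4, IL6, IL10, IL1B, TNFA, TGFB)
    and the hypoxia/metabolic factors (HIF1A, PPARG, KLF4) are identity-rule
    inputs; the six transcription factors carry regulatory rules.  The
    ``expected`` census is the frozen regression snapshot shipped with the
    package.
    """
    net = parse_network(_data_text("macrophage.bnet"), "bnet")
    scheme = default_scheme()
    try:
        expected = macrophage_snapshot()
    except FileNotFoundError:
        expected = None
    return FixtureBundle(network=net, scheme=scheme, expected=expected)


def macrophage_snapshot() -> dict:
    """Load the frozen census/fate-map snapshot shipped with the package."""
    return json.loads(_data_text("macrophage_census.json"))


#: Fate-map digest covers the first SNAPSHOT_FATEMAP_ATTRACTORS attractors
#: (canonical order) perturbed at every node; the full map over thousands of
#: input-combination attractors is too large to freeze verbatim.
SNAPSHOT_FATEMAP_ATTRACTORS = 64


def compute_macrophage_snapshot() -> dict:
    """Recompute the snapshot from scratch (used by the regeneration flag)."""
    bundle = macrophage_fixture()
    net = bundle.network
    census = enumerate_attractors(net, mode="exhaustive")
    census_digest = hashlib.sha256(census.to_json().encode()).hexdigest()
    subset = AttractorSet(
        network=net,
        attractors=census.attractors[:SNAPSHOT_FATEMAP_ATTRACTORS],
        mode=census.mode, coverage=census.coverage)
    fmap = build_fate_map(net, subset, bundle.scheme)
    fmap_tsv = fate_map_to_tsv(fmap)
    return {
        "n_nodes": net.n_nodes,
        "n_states": 1 << net.n_nodes,
        "n_attractors": len(census),
        "n_fixed_points": len(census.fixed_points()),
        "period_counts": {str(k): v for k, v in census.period_counts().items()},
        "census_sha256": census_digest,
        "fatemap_attractors": SNAPSHOT_FATEMAP_ATTRACTORS,
        "fatemap_edges": len(fmap.edges),
        "fatemap_sha256": hashlib.sha256(fmap_tsv.encode()).hexdigest(),
    }


def regenerate_macrophage_snapshot(path, i_know_what_i_am_doing: bool = False):
    """Rewrite the frozen snapshot; guarded so drift cannot happen silently."""
    if not i_know_what_i_am_doing:
        raise RuntimeError(
            "snapshot regeneration is destructive to the regression surface; "
            "pass i_know_what_i_am_doing=True to proceed")
    snap = compute_macrophage_snapshot()
    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(snap, fh, indent=2)
        fh.write("\n")
    return snap
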