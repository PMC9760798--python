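"""Independent brute-force attractor oracle.

Deliberately avoids the package's enumeration path: rules are evaluated by
a separate recursive walker, the full successor table is built per state,
and cycles are extracted from the functional graph via
``networkx.attracting_components``.  Basins are counted by naive forward
walking with memoization.
"""

from __future__ import annotations

import networkx as nx

from boolfate.network import And, BooleanNetwork, Const, Not, Or, TruthTable, Var


def eval_expr(expr, env: dict) -> int:
    """Structural evaluator, independent of Expr.evaluate."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        return env[expr.name]
    if isinstance(expr, Not):
        return 0 if eval_expr(expr.operand, env) else 1
    if isinstance(expr, And):
        return 1 if (eval_expr(expr.left, env) and eval_expr(expr.right, env)) else 0
    if isinstance(expr, Or):
        return 1 if (eval_expr(expr.left, env) or eval_expr(expr.right, env)) else 0
    if isinstance(expr, TruthTable):
        idx = sum(env[reg] << j for j, reg in enumerate(expr.regulators))
        return expr.outputs[idx]
    raise TypeError(f"unknown expression node {type(expr).__name__}")


def successor_code(net: BooleanNetwork, code: int) -> int:
    n = net.n_nodes
    env = {name: (code >> i) & 1 for i, name in enumerate(net.nodes)}
    out = 0
    for i, name in enumerate(net.nodes):
        out |= eval_expr(net.rules[name], env) << i
    return out


def oracle_attractors(net: BooleanNetwork) -> dict:
    """Map canonical cycle (tuple of codes, min code first) -> exact basin size."""
    n = net.n_nodes
    size = 1 << n
    succ = [successor_code(net, c) for c in range(size)]
    graph = nx.DiGraph()
    graph.add_edges_from((c, succ[c]) for c in range(size))
    cycles = []
    for comp in nx.attracting_components(graph):
        start = min(comp)
        cyc = [start]
        cur = succ[start]
        while cur != start:
            cyc.append(cur)
            cur = succ[cur]
        cycles.append(tuple(cyc))
    owner = {}
    for i, cyc in enumerate(cycles):
        for code in cyc:
            owner[code] = i
    basins = [0] * len(cycles)
    for c in range(size):
        path = []
        cur = c
        while cur not in owner:
            path.append(cur)
            cur = succ[cur]
        idx = owner[cur]
        for p in path:
            owner[p] = idx
        basins[idx] += 1
    return {cyc: basins[i] for i, cyc in enumerate(cycles)}


def as_comparable(attr_set) -> dict:
    """Package AttractorSet -> {canonical code tuple: basin size}."""
    return {a.codes(): a.basin_size for a in attr_set.attractors}
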