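"""Boolean network representation, rule parsing, and synchronous updates.

A :class:`BooleanNetwork` is an ordered collection of named nodes, each
carrying one Boolean update rule.  Rules are expressions over node names
built from NOT/AND/OR (symbolic ``!``, ``&``, ``|`` or word forms),
parentheses and the constants ``0``/``1``; randomly generated networks may
instead carry explicit truth tables (see :class:`TruthTable`).

States are plain tuples of 0/1 ints in declaration order.  Node 0 occupies
the least-significant bit of the integer state code, so encodings are
reproducible across runs.

Two on-disk dialects are supported:

* ``bnet`` -- BoolNet-style text with a ``targets, factors`` header and one
  ``name, expression`` line per node;
* ``json`` -- an object with ``nodes``, ``rules`` (expression strings or
  truth-table objects), an optional ``inputs`` policy for rule-less nodes
  (``identity``, ``const0`` or ``const1``) and free-form ``metadata``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "BooleanNetwork",
    "NetworkParseError",
    "Expr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "TruthTable",
    "parse_expression",
    "parse_network",
    "serialize_network",
    "encode_state",
    "decode_state",
    "clamp_node",
    "synchronous_step",
]

State = tuple  # tuple of 0/1 ints, one per node, in declaration order

NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")
_KEYWORDS = {"NOT", "AND", "OR"}


class NetworkParseError(ValueError):
    """Raised on malformed rule files or expressions; carries position info."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean rule expressions."""

    def evaluate(self, env: Mapping[str, int]):
        """Evaluate against ``env`` mapping node name -> 0/1 (or numpy array)."""
        raise NotImplementedError

    def variables(self) -> set:
        raise NotImplementedError

    def unparse(self) -> str:
        return self._unparse(0)

    def _unparse(self, level: int) -> str:
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __hash__(self):
        return hash((type(self).__name__, self.unparse()))

    def __repr__(self):
        return f"{type(self).__name__}({self.unparse()!r})"


class Const(Expr):
    def __init__(self, value: int):
        if value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {value!r}")
        self.value = int(value)

    def evaluate(self, env):
        return self.value

    def variables(self):
        return set()

    def _unparse(self, level):
        return str(self.value)


class Var(Expr):
    def __init__(self, name: str):
        self.name = name

    def evaluate(self, env):
        return env[self.name]

    def variables(self):
        return {self.name}

    def _unparse(self, level):
        return self.name


class Not(Expr):
    def __init__(self, operand: Expr):
        self.operand = operand

    def evaluate(self, env):
        return 1 - self.operand.evaluate(env)

    def variables(self):
        return self.operand.variables()

    def _unparse(self, level):
        inner = self.operand._unparse(3)
        return f"!{inner}"


class _Binary(Expr):
    op = ""
    level = 0

    def __init__(self, left: Expr, right: Expr):
        self.left = left
        self.right = right

    def variables(self):
        return self.left.variables() | self.right.variables()

    def _unparse(self, level):
        s = f"{self.left._unparse(self.level)} {self.op} {self.right._unparse(self.level + 1)}"
        return f"({s})" if level > self.level else s


class And(_Binary):
    op = "&"
    level = 2

    def evaluate(self, env):
        return self.left.evaluate(env) & self.right.evaluate(env)


class Or(_Binary):
    op = "|"
    level = 1

    def evaluate(self, env):
        return self.left.evaluate(env) | self.right.evaluate(env)


class TruthTable(Expr):
    """Explicit truth table over an ordered regulator list.

    Row index is ``sum(value(reg_j) << j)``; ``outputs[row]`` is the result.
    Used for randomly sampled rules, where uniform sampling is defined over
    tables rather than expression strings.
    """

    def __init__(self, regulators: Sequence[str], outputs: Sequence[int]):
        regulators = tuple(regulators)
        outputs = tuple(int(o) for o in outputs)
        if len(outputs) != 1 << len(regulators):
            raise ValueError(
                f"truth table over {len(regulators)} regulators needs "
                f"{1 << len(regulators)} rows, got {len(outputs)}"
            )
        if any(o not in (0, 1) for o in outputs):
            raise ValueError("truth table outputs must be 0/1")
        self.regulators = regulators
        self.outputs = outputs

    def evaluate(self, env):
        idx = 0
        for j, reg in enumerate(self.regulators):
            idx = idx + (env[reg] << j)
        if isinstance(idx, (int, np.integer)):
            return self.outputs[int(idx)]
        return np.asarray(self.outputs, dtype=np.uint8)[idx]

    def variables(self):
        return set(self.regulators)

    def _unparse(self, level):
        bits = "".join(str(o) for o in self.outputs)
        return f"<table {','.join(self.regulators)}:{bits}>"


# ---------------------------------------------------------------------------
# Expression parser (recursive descent; OR < AND < NOT)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<sym>[()!&|])|(?P<word>[A-Za-z0-9_]+)|(?P<bad>\S))")


def _tokenize(text: str):
    tokens = []  # (kind, value, position)
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("bad"):
            raise NetworkParseError(
                f"unexpected character {m.group('bad')!r} at position {m.start('bad')}"
            )
        if m.group("sym"):
            sym = m.group("sym")
            kind = {"(": "lparen", ")": "rparen", "!": "not", "&": "and", "|": "or"}[sym]
            tokens.append((kind, sym, m.start("sym")))
        else:
            word = m.group("word")
            at = m.start("word")
            if word == "NOT":
                tokens.append(("not", word, at))
            elif word == "AND":
                tokens.append(("and", word, at))
            elif word == "OR":
                tokens.append(("or", word, at))
            elif word in ("0", "1"):
                tokens.append(("const", word, at))
            elif word.isdigit():
                raise NetworkParseError(
                    f"numeric literal {word!r} at position {at} is not a valid "
                    "node name (only 0 and 1 are Boolean constants)"
                )
            else:
                tokens.append(("name", word, at))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            raise NetworkParseError("empty expression")
        expr = self._or()
        kind, value, at = self._peek()
        if kind is not None:
            raise NetworkParseError(f"unexpected token {value!r} at position {at}")
        return expr

    def _or(self) -> Expr:
        expr = self._and()
        while self._peek()[0] == "or":
            self._next()
            expr = Or(expr, self._and())
        return expr

    def _and(self) -> Expr:
        expr = self._unary()
        while self._peek()[0] == "and":
            self._next()
            expr = And(expr, self._unary())
        return expr

    def _unary(self) -> Expr:
        kind, value, at = self._peek()
        if kind == "not":
            self._next()
            return Not(self._unary())
        return self._atom()

    def _atom(self) -> Expr:
        kind, value, at = self._next()
        if kind == "lparen":
            expr = self._or()
            kind2, value2, at2 = self._next()
            if kind2 != "rparen":
                raise NetworkParseError(f"expected ')' at position {at2}")
            return expr
        if kind == "const":
            return Const(int(value))
        if kind == "name":
            return Var(value)
        raise NetworkParseError(
            f"expected a node name, constant or '(' at position {at}"
            + (f", got {value!r}" if value else "")
        )


def parse_expression(text: str) -> Expr:
    """Parse a Boolean rule expression into its AST."""
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean dynamical system over named nodes.

    Parameters
    ----------
    nodes
        Ordered unique node names; declaration order defines bit positions
        (node 0 = least-significant bit of the integer state code).
    rules
        One expression per node.  Nodes missing from ``rules`` receive the
        identity rule (their value persists), the convention for
        environmental input nodes.
    metadata
        Free-form provenance text.
    """

    nodes: tuple
    rules: dict
    metadata: str = ""
    _index: dict = field(init=False, repr=False, compare=False)

    def __init__(self, nodes: Iterable[str], rules: Mapping[str, Union[Expr, str]],
                 metadata: str = ""):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
            raise ValueError(f"duplicate node names: {dupes}")
        for name in nodes:
            if not NAME_RE.match(name) or name.isdigit() or name in _KEYWORDS:
                raise ValueError(f"invalid node name {name!r}")
        compiled = {}
        for name, rule in rules.items():
            if name not in nodes:
                raise ValueError(f"rule given for undeclared node {name!r}")
            compiled[name] = parse_expression(rule) if isinstance(rule, str) else rule
        for name in nodes:
            compiled.setdefault(name, Var(name))  # inputs persist by default
        declared = set(nodes)
        for name, expr in compiled.items():
            missing = expr.variables() - declared
            if missing:
                raise ValueError(
                    f"rule for {name!r} references undeclared node(s): "
                    f"{sorted(missing)}"
                )
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "rules", compiled)
        object.__setattr__(self, "metadata", metadata)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(nodes)})

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def validate_state(self, state: Sequence[int]) -> State:
        state = tuple(int(b) for b in state)
        if len(state) != self.n_nodes:
            raise ValueError(
                f"state length {len(state)} != node count {self.n_nodes}")
        if any(b not in (0, 1) for b in state):
            raise ValueError("state bits must be 0 or 1")
        return state

    # -- state codec --------------------------------------------------------

    def encode(self, state: Sequence[int]) -> int:
        state = self.validate_state(state)
        return encode_state(state)

    def decode(self, code: int) -> State:
        return decode_state(code, self.n_nodes)

    # -- dynamics -----------------------------------------------------------

    def step(self, state: Sequence[int]) -> State:
        """Synchronous successor: every rule evaluated on the current state."""
        state = self.validate_state(state)
        env = dict(zip(self.nodes, state))
        return tuple(int(self.rules[name].evaluate(env)) for name in self.nodes)

    def step_code(self, code: int) -> int:
        return encode_state(self.step(decode_state(code, self.n_nodes)))

    def successor_table(self) -> np.ndarray:
        """Successor code for every state, vectorised over all 2^n codes.

        Memory and time are O(2^n); callers enforce any size ceiling.
        """
        n = self.n_nodes
        codes = np.arange(1 << n, dtype=np.int64)
        env = {name: ((codes >> i) & 1).astype(np.uint8)
               for i, name in enumerate(self.nodes)}
        out = np.zeros(1 << n, dtype=np.int64)
        for i, name in enumerate(self.nodes):
            vals = self.rules[name].evaluate(env)
            vals = np.asarray(vals, dtype=np.int64)
            if vals.ndim == 0:
                vals = np.full(1 << n, int(vals), dtype=np.int64)
            out += vals << i
        return out

    # -- editing ------------------------------------------------------------

    def clamp(self, node: str, value: int) -> "BooleanNetwork":
        """Return a copy with ``node`` held constant at ``value``."""
        if value not in (0, 1):
            raise ValueError("clamp value must be 0 or 1")
        self.node_index(node)  # raises KeyError for unknown nodes
        rules = dict(self.rules)
        rules[node] = Const(value)
        note = f"clamp {node}={value}"
        meta = f"{self.metadata}; {note}" if self.metadata else note
        return BooleanNetwork(self.nodes, rules, metadata=meta)

    def is_input(self, node: str) -> bool:
        """True when the node's rule is the identity (value persists)."""
        rule = self.rules[node]
        return isinstance(rule, Var) and rule.name == node

    # -- serialization ------------------------------------------------------

    def to_bnet(self) -> str:
        lines = ["targets, factors"]
        for name in self.nodes:
            rule = self.rules[name]
            if isinstance(rule, TruthTable):
                rule = _table_to_expr(rule)
            lines.append(f"{name}, {rule.unparse()}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        rules = {}
        inputs = {}
        for name in self.nodes:
            rule = self.rules[name]
            if self.is_input(name):
                inputs[name] = "identity"
                continue
            if isinstance(rule, TruthTable):
                rules[name] = {"regulators": list(rule.regulators),
                               "table": list(rule.outputs)}
            else:
                rules[name] = rule.unparse()
        doc = {"nodes": list(self.nodes), "rules": rules}
        if inputs:
            doc["inputs"] = inputs
        if self.metadata:
            doc["metadata"] = self.metadata
        return json.dumps(doc, indent=2) + "\n"


def _table_to_expr(table: TruthTable) -> Expr:
    """Disjunctive-normal-form expression equivalent to a truth table."""
    terms = []
    k = len(table.regulators)
    for row, out in enumerate(table.outputs):
        if not out:
            continue
        lits = []
        for j, reg in enumerate(table.regulators):
            lit = Var(reg)
            if not (row >> j) & 1:
                lit = Not(lit)
            lits.append(lit)
        term = lits[0] if lits else Const(1)
        for lit in lits[1:]:
            term = And(term, lit)
        terms.append(term)
    if not terms:
        return Const(0)
    expr = terms[0]
    for term in terms[1:]:
        expr = Or(expr, term)
    return expr


# ---------------------------------------------------------------------------
# Module-level operations (functional façade over the class methods)
# ---------------------------------------------------------------------------

def synchronous_step(net: BooleanNetwork, state: Sequence[int]) -> State:
    """Deterministic simultaneous update of every node."""
    return net.step(state)


def encode_state(state: Sequence[int]) -> int:
    """Integer code of a state; bit i is the node at position i (LSB first)."""
    code = 0
    for i, b in enumerate(state):
        b = int(b)
        if b not in (0, 1):
            raise ValueError("state bits must be 0 or 1")
        code |= b << i
    return code


def decode_state(code: int, n: int) -> State:
    if not 0 <= code < (1 << n):
        raise ValueError(f"code {code} out of range [0, 2^{n})")
    return tuple((code >> i) & 1 for i in range(n))


def clamp_node(net: BooleanNetwork, node: str, value: int) -> BooleanNetwork:
    """Replace ``node``'s rule with the constant ``value`` (persistent clamp)."""
    return net.clamp(node, value)


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def parse_network(text: str, dialect: str = "bnet") -> BooleanNetwork:
    """Parse rule-file content in the given dialect (``bnet`` or ``json``)."""
    if not text or not text.strip():
        raise NetworkParseError("empty network document")
    if dialect == "bnet":
        return _parse_bnet(text)
    if dialect == "json":
        return _parse_json(text)
    raise ValueError(f"unsupported dialect {dialect!r}")


def serialize_network(net: BooleanNetwork, dialect: str = "bnet") -> str:
    if dialect == "bnet":
        return net.to_bnet()
    if dialect == "json":
        return net.to_json()
    raise ValueError(f"unsupported dialect {dialect!r}")


def _parse_bnet(text: str) -> BooleanNetwork:
    nodes = []
    raw_rules = {}
    rule_lines = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if re.sub(r"\s+", "", line.lower()) != "targets,factors":
                raise NetworkParseError(
                    f"line {lineno}: expected 'targets, factors' header, "
                    f"got {line!r}")
            header_seen = True
            continue
        if "," not in line:
            raise NetworkParseError(
                f"line {lineno}: expected 'target, factors', got {line!r}")
        target, _, factors = line.partition(",")
        target = target.strip()
        if not NAME_RE.match(target):
            raise NetworkParseError(f"line {lineno}: invalid node name {target!r}")
        if target in raw_rules:
            raise NetworkParseError(
                f"line {lineno}: duplicate rule for node {target!r} "
                f"(first defined on line {rule_lines[target]})")
        try:
            expr = parse_expression(factors)
        except NetworkParseError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
        nodes.append(target)
        raw_rules[target] = expr
        rule_lines[target] = lineno
    if not header_seen:
        raise NetworkParseError("missing 'targets, factors' header")
    if not nodes:
        raise NetworkParseError("no rules found after header")
    declared = set(nodes)
    for target, expr in raw_rules.items():
        missing = sorted(expr.variables() - declared)
        if missing:
            raise NetworkParseError(
                f"line {rule_lines[target]}: rule for {target!r} references "
                f"undeclared node(s): {missing}")
    return BooleanNetwork(nodes, raw_rules)


_INPUT_POLICIES = {"identity", "const0", "const1"}


def _parse_json(text: str) -> BooleanNetwork:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise NetworkParseError("JSON dialect requires an object with 'nodes'")
    nodes = doc["nodes"]
    rules_doc = doc.get("rules", {})
    inputs = doc.get("inputs", {})
    rules = {}
    for name, rule in rules_doc.items():
        if isinstance(rule, str):
            try:
                rules[name] = parse_expression(rule)
            except NetworkParseError as exc:
                raise NetworkParseError(f"rule for {name!r}: {exc}") from None
        elif isinstance(rule, dict):
            try:
                rules[name] = TruthTable(rule["regulators"], rule["table"])
            except (KeyError, ValueError) as exc:
                raise NetworkParseError(
                    f"truth table for {name!r}: {exc}") from None
        else:
            raise NetworkParseError(
                f"rule for {name!r} must be a string or truth-table object")
    for name, policy in inputs.items():
        if policy not in _INPUT_POLICIES:
            raise NetworkParseError(
                f"input policy for {name!r} must be one of "
                f"{sorted(_INPUT_POLICIES)}, got {policy!r}")
        if name in rules:
            raise NetworkParseError(
                f"node {name!r} has both a rule and an input policy")
        if policy == "identity":
            rules[name] = Var(name)
        else:
            rules[name] = Const(int(policy[-1]))
    try:
        return BooleanNetwork(nodes, rules, metadata=doc.get("metadata", ""))
    except ValueError as exc:
        raise NetworkParseError(str(exc)) from None
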