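"""Phenotype labeling of attractor states and attractor classification.

A :class:`PhenotypeScheme` is data, not code: an ordered list of phenotype
labels, a Boolean marker condition per label (over network node names), a
fallback label assigned when no condition holds, and an outcome class per
label (tumor-eliminating / tumor-promoting / neutral).

The default scheme encodes the macrophage marker associations:
M1 when STAT1 or NFKB is active, M2a via STAT6, M2b via AP1, M2c via STAT3,
M2d via HIF1A, and M0 (monocyte) as the fallback when no driver is on.

Attractors are classified as a pure fixed point (period 1, one label), a
hybrid fixed point (period 1, two or more labels) or a cycle (period > 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .attractors import Attractor, AttractorSet
from .network import BooleanNetwork, parse_expression

__all__ = [
    "PhenotypeScheme",
    "AttractorAnnotation",
    "default_scheme",
    "label_state",
    "classify_attractor",
    "summarize",
    "PURE_FIXED_POINT",
    "HYBRID_FIXED_POINT",
    "CYCLE",
]

PURE_FIXED_POINT = "pure fixed point"
HYBRID_FIXED_POINT = "hybrid fixed point"
CYCLE = "cycle"

OUTCOME_CLASSES = ("tumor-eliminating", "tumor-promoting", "neutral")


@dataclass(frozen=True)
class PhenotypeScheme:
    """Ordered phenotype labels with marker conditions and outcome classes."""

    labels: tuple
    conditions: dict        # label -> Expr (absent for the fallback)
    fallback_label: str
    outcome_class: dict     # label -> one of OUTCOME_CLASSES

    def __post_init__(self):
        compiled = {label: parse_expression(cond) if isinstance(cond, str)
                    else cond
                    for label, cond in self.conditions.items()}
        object.__setattr__(self, "conditions", compiled)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate phenotype labels")
        if self.fallback_label not in self.labels:
            raise ValueError(
                f"fallback label {self.fallback_label!r} not among labels")
        if self.fallback_label in self.conditions:
            raise ValueError("the fallback label must not carry a condition")
        for label in self.labels:
            if label != self.fallback_label and label not in self.conditions:
                raise ValueError(f"label {label!r} has no marker condition")
            outcome = self.outcome_class.get(label)
            if outcome not in OUTCOME_CLASSES:
                raise ValueError(
                    f"label {label!r} has outcome {outcome!r}; expected one "
                    f"of {OUTCOME_CLASSES}")

    def validate_for(self, net: BooleanNetwork) -> None:
        """Raise if any marker condition references a node absent from net."""
        declared = set(net.nodes)
        for label, expr in self.conditions.items():
            missing = sorted(expr.variables() - declared)
            if missing:
                raise ValueError(
                    f"condition for {label!r} references node(s) not in the "
                    f"network: {missing}")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "labels": list(self.labels),
            "fallback": self.fallback_label,
            "conditions": {label: expr.unparse()
                           for label, expr in self.conditions.items()},
            "outcome_class": {label: self.outcome_class[label]
                              for label in self.labels},
        }
        return json.dumps(doc, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "PhenotypeScheme":
        doc = json.loads(text)
        conditions = {label: parse_expression(cond)
                      for label, cond in doc["conditions"].items()}
        return cls(labels=tuple(doc["labels"]),
                   conditions=conditions,
                   fallback_label=doc["fallback"],
                   outcome_class=dict(doc["outcome_class"]))


def default_scheme() -> PhenotypeScheme:
    """The macrophage M0/M1/M2a-d scheme used throughout the fixtures.

    M2b's marker (AP1) is counted as tumor-promoting; M0 is neutral.
    """
    return PhenotypeScheme(
        labels=("M0", "M1", "M2a", "M2b", "M2c", "M2d"),
        conditions={
            "M1": parse_expression("STAT1 | NFKB"),
            "M2a": parse_expression("STAT6"),
            "M2b": parse_expression("AP1"),
            "M2c": parse_expression("STAT3"),
            "M2d": parse_expression("HIF1A"),
        },
        fallback_label="M0",
        outcome_class={
            "M0": "neutral",
            "M1": "tumor-eliminating",
            "M2a": "tumor-promoting",
            "M2b": "tumor-promoting",
            "M2c": "tumor-promoting",
            "M2d": "tumor-promoting",
        },
    )


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_state(state: Sequence, scheme: PhenotypeScheme,
                net: BooleanNetwork):
    """Return ``(label_set, composite_name)`` for one network state.

    The label set contains every label whose marker condition holds; when
    none holds it is the fallback singleton.  The composite name joins the
    labels in scheme order with no separator (e.g. ``"M1M2c"``).
    """
    state = net.validate_state(state)
    env = dict(zip(net.nodes, state))
    labels = frozenset(
        label for label, expr in scheme.conditions.items()
        if expr.evaluate(env)
    )
    if not labels:
        labels = frozenset({scheme.fallback_label})
    name = "".join(label for label in scheme.labels if label in labels)
    return labels, name


@dataclass(frozen=True)
class AttractorAnnotation:
    """Phenotype reading of one attractor."""

    attractor: Attractor
    state_labels: tuple      # frozenset per state, canonical order
    state_names: tuple       # composite name per state
    name: str                # state names joined by "/"
    attractor_class: str     # PURE_FIXED_POINT / HYBRID_FIXED_POINT / CYCLE
    outcomes: frozenset      # outcome classes present across all states

    @property
    def period(self) -> int:
        return self.attractor.period

    def outcome_category(self) -> str:
        """Collapse the outcome set, ignoring the neutral class.

        Returns ``tumor-promoting``/``tumor-eliminating`` when only that
        class is present, ``mixed`` when both are, ``neutral`` otherwise.
        """
        active = self.outcomes - {"neutral"}
        if not active:
            return "neutral"
        if active == {"tumor-promoting"}:
            return "tumor-promoting"
        if active == {"tumor-eliminating"}:
            return "tumor-eliminating"
        return "mixed"


def classify_attractor(attractor: Attractor, scheme: PhenotypeScheme,
                       net: BooleanNetwork) -> AttractorAnnotation:
    """Name every state of the attractor and assign its class."""
    state_labels = []
    state_names = []
    for state in attractor.states:
        labels, name = label_state(state, scheme, net)
        state_labels.append(labels)
        state_names.append(name)
    all_labels = frozenset().union(*state_labels)
    if attractor.period > 1:
        cls = CYCLE
    elif len(state_labels[0]) == 1:
        cls = PURE_FIXED_POINT
    else:
        cls = HYBRID_FIXED_POINT
    outcomes = frozenset(scheme.outcome_class[label] for label in all_labels)
    return AttractorAnnotation(
        attractor=attractor,
        state_labels=tuple(state_labels),
        state_names=tuple(state_names),
        name="/".join(state_names),
        attractor_class=cls,
        outcomes=outcomes,
    )


def annotate_set(attr_set: AttractorSet, scheme: PhenotypeScheme):
    """Classify every attractor in the set, preserving order."""
    scheme.validate_for(attr_set.network)
    return tuple(classify_attractor(a, scheme, attr_set.network)
                 for a in attr_set.attractors)


def summarize(attr_set: AttractorSet, scheme: PhenotypeScheme) -> dict:
    """Counts by attractor class, period distribution and outcome categories.

    ``outcome_by_class[cls]`` counts, within each attractor class, the
    attractors whose outcome category is exclusively tumor-promoting,
    exclusively tumor-eliminating, mixed, or neutral.
    """
    annotations = annotate_set(attr_set, scheme) if len(attr_set) else ()
    by_class = {PURE_FIXED_POINT: 0, HYBRID_FIXED_POINT: 0, CYCLE: 0}
    period_counts: dict = {}
    outcome_by_class = {
        cls: {"tumor-promoting": 0, "tumor-eliminating": 0,
              "mixed": 0, "neutral": 0}
        for cls in (PURE_FIXED_POINT, HYBRID_FIXED_POINT, CYCLE)
    }
    for ann in annotations:
        by_class[ann.attractor_class] += 1
        period_counts[ann.period] = period_counts.get(ann.period, 0) + 1
        outcome_by_class[ann.attractor_class][ann.outcome_category()] += 1
    return {
        "n_attractors": len(attr_set),
        "by_class": by_class,
        "period_counts": dict(sorted(period_counts.items())),
        "outcome_by_class": outcome_by_class,
    }


def annotations_to_tsv(annotations, attr_set: Optional[AttractorSet] = None) -> str:
    """TSV: one row per attractor (id, class, period, name, outcomes, basin)."""
    lines = ["attractor\tclass\tperiod\tname\toutcome_category\tbasin"]
    for i, ann in enumerate(annotations):
        basin = ann.attractor.basin_size
        if basin is None:
            basin = ann.attractor.basin_fraction
        lines.append("\t".join([
            str(i), ann.attractor_class, str(ann.period), ann.name,
            ann.outcome_category(), "" if basin is None else str(basin),
        ]))
    return "\n".join(lines) + "\n"
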