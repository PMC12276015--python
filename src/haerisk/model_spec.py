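"""Network schema: nodes, category labels and the expert DAG.

A :class:`DagModel` is the single structural input to every other stage:
the synthetic-cohort generator samples along it, parameter fitting attaches
one conditional probability table per node, and exact inference factorizes
the joint distribution over it.  The default model describes hospitalized
hereditary-angioedema admissions: five demographic nodes (age group, race,
income quartile, primary payer, census region), three binary comorbidities
(hypertension, autoimmune disease, diabetes), APR-DRG admission severity,
and a binary mortality-risk outcome.  Demographics feed the comorbidities
and the outcome; comorbidities feed severity; severity feeds the outcome.
Edges encode statistical dependence, not causation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import yaml

ROLE_PREDICTOR = "predictor"
ROLE_OUTCOME = "outcome"


class ModelError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ModelError):
    """A node, edge, category label or record violates the declared schema."""


class AcyclicityError(ModelError):
    """The declared edge set contains a directed cycle."""


class CalibrationError(ModelError):
    """A ground-truth marginal missed its calibration target."""


class FormatError(ModelError):
    """A file on disk could not be parsed against the schema."""


class EstimationError(ModelError):
    """Parameter estimation is impossible for the requested configuration."""


class ImpossibleEvidenceError(ModelError):
    """The supplied evidence has zero probability under the model."""


def _canon_key(label: str) -> str:
    return label.strip().casefold()


@dataclass(frozen=True)
class NodeDef:
    """A discrete variable: name, ordered category labels, and role.

    Category labels are matched case-insensitively after trimming, but the
    declared spelling is canonical — unknown labels are errors, never
    silently coerced.
    """

    name: str
    categories: tuple[str, ...]
    role: str = ROLE_PREDICTOR

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise SchemaError("node name must be non-empty")
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        if len(self.categories) < 2:
            raise SchemaError(f"node {self.name!r} needs >= 2 categories")
        keys = [_canon_key(c) for c in self.categories]
        if len(set(keys)) != len(keys):
            raise SchemaError(f"node {self.name!r} has duplicate category labels")
        if self.role not in (ROLE_PREDICTOR, ROLE_OUTCOME):
            raise SchemaError(f"node {self.name!r}: unknown role {self.role!r}")

    @property
    def cardinality(self) -> int:
        return len(self.categories)

    def index_of(self, label: str) -> int:
        """Index of a category label, matched case-insensitively after trim."""
        key = _canon_key(str(label))
        for i, c in enumerate(self.categories):
            if _canon_key(c) == key:
                return i
        raise SchemaError(
            f"unknown category {label!r} for node {self.name!r}; "
            f"expected one of {list(self.categories)}"
        )

    def canonical(self, label: str) -> str:
        """Canonical (declared) spelling of a label."""
        return self.categories[self.index_of(label)]


@dataclass(frozen=True)
class DagModel:
    """Node schema plus directed acyclic edge set.

    Construction validates everything the rest of the pipeline relies on:
    edge endpoints exist, there are no duplicate edges or self-loops, the
    graph is acyclic, and exactly one node is the binary outcome.
    """

    nodes: tuple[NodeDef, ...]
    edges: tuple[tuple[str, str], ...]
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "edges", tuple((str(p), str(c)) for p, c in self.edges)
        )
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate node names")
        by_name = {n.name: n for n in self.nodes}
        object.__setattr__(self, "_by_name", by_name)
        seen: set[tuple[str, str]] = set()
        for parent, child in self.edges:
            if parent not in by_name:
                raise SchemaError(f"edge references unknown node {parent!r}")
            if child not in by_name:
                raise SchemaError(f"edge references unknown node {child!r}")
            if parent == child:
                raise SchemaError(f"self-loop on node {parent!r}")
            if (parent, child) in seen:
                raise SchemaError(f"duplicate edge {parent!r} -> {child!r}")
            seen.add((parent, child))
        outcomes = [n for n in self.nodes if n.role == ROLE_OUTCOME]
        if len(outcomes) != 1:
            raise SchemaError(
                f"exactly one outcome node required, found {len(outcomes)}"
            )
        if outcomes[0].cardinality != 2:
            raise SchemaError(
                f"outcome node {outcomes[0].name!r} must be binary (low/high)"
            )
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise AcyclicityError("edge set contains a directed cycle")

    # -- lookups -----------------------------------------------------------

    def node(self, name: str) -> NodeDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown node {name!r}") from None

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def outcome(self) -> NodeDef:
        return next(n for n in self.nodes if n.role == ROLE_OUTCOME)

    @property
    def predictors(self) -> tuple[NodeDef, ...]:
        return tuple(n for n in self.nodes if n.role == ROLE_PREDICTOR)

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of a node, in node-declaration order (deterministic)."""
        self.node(name)
        return tuple(
            n.name for n in self.nodes if (n.name, name) in set(self.edges)
        )

    def children(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return tuple(
            n.name for n in self.nodes if (name, n.name) in set(self.edges)
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from(self.edges)
        return g

    def joint_state_space_size(self) -> int:
        """Number of joint states (product of category counts)."""
        size = 1
        for n in self.nodes:
            size *= n.cardinality
        return size


def topological_order(dag: DagModel) -> list[str]:
    """Node names ordered so every parent precedes all of its children.

    Deterministic: ties are broken by node-declaration order.
    """
    rank = {name: i for i, name in enumerate(dag.node_names)}
    return list(
        nx.lexicographical_topological_sort(dag.to_networkx(), key=rank.get)
    )


# -- config parsing --------------------------------------------------------


def parse_model_config(config_text: str) -> DagModel:
    """Build a validated :class:`DagModel` from JSON or YAML config text.

    The config declares ``nodes`` (each with ``name``, ``categories`` and an
    optional ``role``, default predictor) and ``edges`` as ``[parent, child]``
    pairs.  JSON is a subset of YAML, so a single loader handles both.
    """
    try:
        data = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise FormatError(f"config is not valid JSON/YAML: {exc}") from exc
    if not isinstance(data, dict) or "nodes" not in data:
        raise FormatError("config must be a mapping with a 'nodes' key")
    nodes = []
    for spec in data["nodes"]:
        if not isinstance(spec, dict) or "name" not in spec or "categories" not in spec:
            raise FormatError("each node needs 'name' and 'categories'")
        nodes.append(
            NodeDef(
                name=str(spec["name"]),
                categories=tuple(spec["categories"]),
                role=str(spec.get("role", ROLE_PREDICTOR)),
            )
        )
    edges = []
    for edge in data.get("edges", []):
        if not isinstance(edge, (list, tuple)) or len(edge) != 2:
            raise FormatError(f"edge must be a [parent, child] pair, got {edge!r}")
        edges.append((str(edge[0]), str(edge[1])))
    return DagModel(nodes=tuple(nodes), edges=tuple(edges))


def serialize_model_config(dag: DagModel) -> str:
    """Serialize a DagModel to canonical JSON (round-trips exactly)."""
    data = {
        "nodes": [
            {"name": n.name, "categories": list(n.categories), "role": n.role}
            for n in dag.nodes
        ],
        "edges": [list(e) for e in dag.edges],
    }
    return json.dumps(data, indent=2, ensure_ascii=False)


def default_model() -> DagModel:
    """The shipped default model: 10 nodes, outcome ``MortalityRisk``.

    Age feeds the comorbidities and the outcome; race, income quartile,
    payer and region feed the outcome directly; the three comorbidities
    feed APR-DRG severity, which feeds the outcome.
    """
    text = (
        resources.files("haerisk.data").joinpath("default_model.json").read_text("utf-8")
    )
    return parse_model_config(text)
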