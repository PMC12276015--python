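"""Exact inference: enumeration oracle, variable elimination, virtual evidence.

Two independent engines compute every posterior:

* :func:`posterior_by_enumeration` — a deliberately plain Python loop over
  the full joint state space.  It is the correctness reference and is kept
  free of the factor machinery below.
* :func:`posterior_by_elimination` — factor-based variable elimination with
  a min-degree ordering.  This is the production path; it must agree with
  enumeration to 1e-9 on every query.

Evidence is hard (a node pinned to one state) or soft.  Soft evidence is
Pearl virtual evidence: a nonnegative likelihood vector over the node's
states enters the model as an extra unit-scope factor, so the conditioned
node's posterior is pulled toward — but not pinned at — the observed state,
and interacts with the rest of the network through the priors.  A flat
vector is vacuous; a one-hot vector reproduces hard evidence exactly.  This
is not Jeffrey conditioning, which would pin the node's posterior marginal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .bn_fit import DiscreteBN
from .model_spec import DagModel, ImpossibleEvidenceError, SchemaError


# -- evidence --------------------------------------------------------------


@dataclass(frozen=True)
class Hard:
    state: str


@dataclass(frozen=True)
class Soft:
    likelihood: tuple[float, ...]


@dataclass
class Evidence:
    """Per-node observations: at most one entry per node, hard or soft."""

    entries: dict[str, Union[Hard, Soft]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, dag: DagModel, spec: Mapping[str, object]) -> "Evidence":
        """Build evidence from ``{node: state}`` (hard) or
        ``{node: {state: weight, ...}}`` / ``{node: [w0, w1, ...]}`` (soft)."""
        entries: dict[str, Union[Hard, Soft]] = {}
        for name, value in spec.items():
            node = dag.node(name)
            if isinstance(value, str):
                entries[name] = Hard(node.canonical(value))
            elif isinstance(value, Mapping):
                vec = np.zeros(node.cardinality)
                for state, weight in value.items():
                    vec[node.index_of(str(state))] = float(weight)
                entries[name] = Soft(tuple(vec))
            elif isinstance(value, (list, tuple, np.ndarray)):
                vec = np.asarray(value, dtype=float)
                entries[name] = Soft(tuple(vec))
            else:
                raise SchemaError(
                    f"evidence for {name!r} must be a state label, a "
                    f"state->weight mapping, or a likelihood vector"
                )
        ev = cls(entries)
        ev.validate(dag)
        return ev

    def validate(self, dag: DagModel, query: str | None = None) -> None:
        for name, entry in self.entries.items():
            node = dag.node(name)
            if isinstance(entry, Hard):
                node.index_of(entry.state)
            elif isinstance(entry, Soft):
                vec = np.asarray(entry.likelihood, dtype=float)
                if vec.shape != (node.cardinality,):
                    raise SchemaError(
                        f"soft evidence on {name!r}: vector length {vec.size} "
                        f"!= {node.cardinality} categories"
                    )
                if (vec < 0).any() or not vec.any():
                    raise SchemaError(
                        f"soft evidence on {name!r} must be nonnegative and "
                        "not all zero"
                    )
            else:
                raise SchemaError(f"bad evidence entry for {name!r}")
        if query is not None and query in self.entries:
            raise SchemaError(f"query node {query!r} may not carry evidence")


@dataclass
class QueryResult:
    """Posterior over one node's categories, with the evidence echoed back."""

    node: str
    categories: tuple[str, ...]
    probabilities: np.ndarray
    evidence: Evidence
    method: str

    def __getitem__(self, state: str) -> float:
        key = state.strip().casefold()
        for cat, p in zip(self.categories, self.probabilities):
            if cat.strip().casefold() == key:
                return float(p)
        raise SchemaError(f"unknown category {state!r} for node {self.node!r}")


# -- joint probability -----------------------------------------------------


def joint_probability(bn: DiscreteBN, assignment: Mapping[str, str]) -> float:
    """Probability of one complete joint state: the product of CPT entries."""
    dag = bn.dag
    missing = set(dag.node_names) - set(assignment)
    if missing:
        raise SchemaError(f"assignment is missing nodes {sorted(missing)}")
    idx = {name: dag.node(name).index_of(assignment[name]) for name in dag.node_names}
    p = 1.0
    for name in dag.node_names:
        cpt = bn.cpt(name)
        p *= float(cpt.table[tuple(idx[q] for q in cpt.parents) + (idx[name],)])
    return p


# -- enumeration oracle ----------------------------------------------------


def posterior_by_enumeration(
    bn: DiscreteBN, query: str, evidence: Evidence | None = None
) -> QueryResult:
    """P(query | evidence) by brute-force summation over all joint states.

    Hard evidence restricts the loop; soft evidence multiplies each state's
    weight by the node's likelihood entry.  Slow by design — this is the
    oracle the elimination engine is checked against.
    """
    evidence = evidence or Evidence()
    dag = bn.dag
    evidence.validate(dag, query=query)
    names = dag.node_names
    pos = {name: i for i, name in enumerate(names)}
    ranges: list[Sequence[int]] = []
    softs: list[tuple[int, tuple[float, ...]]] = []
    for name in names:
        node = dag.node(name)
        entry = evidence.entries.get(name)
        if isinstance(entry, Hard):
            ranges.append((node.index_of(entry.state),))
        else:
            ranges.append(range(node.cardinality))
            if isinstance(entry, Soft):
                softs.append((pos[name], entry.likelihood))
    tables = []
    for name in names:
        cpt = bn.cpt(name)
        tables.append((tuple(pos[p] for p in cpt.parents), pos[name], cpt.table))
    qpos = pos[query]
    total = np.zeros(dag.node(query).cardinality)
    for state in itertools.product(*ranges):
        w = 1.0
        for ppos, spos, table in tables:
            w *= table[tuple(state[i] for i in ppos) + (state[spos],)]
        for spos, lik in softs:
            w *= lik[state[spos]]
        total[state[qpos]] += w
    z = total.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence has zero probability under the model (query {query!r})"
        )
    return QueryResult(
        node=query,
        categories=dag.node(query).categories,
        probabilities=total / z,
        evidence=evidence,
        method="enumeration",
    )


# -- factors and variable elimination --------------------------------------


@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray


def _align(f: _Factor, vs: tuple[str, ...]) -> np.ndarray:
    order = [f.vars.index(v) for v in vs if v in f.vars]
    arr = np.transpose(f.values, order) if order else f.values
    for i, v in enumerate(vs):
        if v not in f.vars:
            arr = np.expand_dims(arr, i)
    return arr


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vs = a.vars + tuple(v for v in b.vars if v not in a.vars)
    return _Factor(vs, _align(a, vs) * _align(b, vs))


def _sum_out(f: _Factor, var: str) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(
        tuple(v for v in f.vars if v != var), f.values.sum(axis=axis)
    )


def _cpt_factors(bn: DiscreteBN, evidence: Evidence) -> list[_Factor]:
    factors = []
    hard = {
        name: bn.dag.node(name).index_of(entry.state)
        for name, entry in evidence.entries.items()
        if isinstance(entry, Hard)
    }
    for name in bn.dag.node_names:
        cpt = bn.cpt(name)
        f = _Factor(cpt.parents + (name,), cpt.table)
        for var, idx in hard.items():
            if var in f.vars:
                axis = f.vars.index(var)
                f = _Factor(
                    tuple(v for v in f.vars if v != var),
                    np.take(f.values, idx, axis=axis),
                )
        factors.append(f)
    for name, entry in evidence.entries.items():
        if isinstance(entry, Soft):
            factors.append(_Factor((name,), np.asarray(entry.likelihood)))
    return factors


def posterior_by_elimination(
    bn: DiscreteBN, query: str, evidence: Evidence | None = None
) -> QueryResult:
    """P(query | evidence) by variable elimination (min-degree ordering).

    Hard evidence reduces factors before elimination; soft evidence enters
    as unit-scope likelihood factors.  Elimination order does not affect the
    result, only the intermediate factor sizes; ties break by declaration
    order for determinism.
    """
    evidence = evidence or Evidence()
    dag = bn.dag
    evidence.validate(dag, query=query)
    factors = _cpt_factors(bn, evidence)
    hard_vars = {
        name for name, e in evidence.entries.items() if isinstance(e, Hard)
    }
    hidden = [n for n in dag.node_names if n != query and n not in hard_vars]
    rank = {name: i for i, name in enumerate(dag.node_names)}
    while hidden:
        degree = {}
        for var in hidden:
            neigh: set[str] = set()
            for f in factors:
                if var in f.vars:
                    neigh.update(f.vars)
            neigh.discard(var)
            degree[var] = len(neigh)
        var = min(hidden, key=lambda v: (degree[v], rank[v]))
        hidden.remove(var)
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if related:
            prod = related[0]
            for f in related[1:]:
                prod = _multiply(prod, f)
            factors.append(_sum_out(prod, var))
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    if result.vars != (query,):
        result = _Factor((query,), _align(result, (query,)).reshape(-1))
    z = result.values.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence has zero probability under the model (query {query!r})"
        )
    return QueryResult(
        node=query,
        categories=dag.node(query).categories,
        probabilities=result.values / z,
        evidence=evidence,
        method="elimination",
    )


# -- exact marginals and prediction ----------------------------------------


def exact_marginals(bn: DiscreteBN) -> dict[str, np.ndarray]:
    """Exact single-node marginals of the full joint, by factor products.

    Equivalent to enumerating the joint state space; used by the generator's
    calibration check and by marginal audits.
    """
    joint = _Factor((), np.array(1.0))
    for name in bn.dag.node_names:
        cpt = bn.cpt(name)
        joint = _multiply(joint, _Factor(cpt.parents + (name,), cpt.table))
    out = {}
    for name in bn.dag.node_names:
        f = joint
        for var in joint.vars:
            if var != name:
                f = _sum_out(f, var)
        out[name] = _align(f, (name,)).reshape(-1)
    return out


def predict_outcome_proba(bn: DiscreteBN, record: Mapping[str, str]) -> float:
    """P(outcome = high | all predictors) for one complete predictor record."""
    outcome = bn.dag.outcome
    missing = [
        n.name for n in bn.dag.predictors if n.name not in record
    ]
    if missing:
        raise SchemaError(f"record is missing predictors {missing}")
    evidence = Evidence.from_dict(
        bn.dag, {n.name: record[n.name] for n in bn.dag.predictors}
    )
    result = posterior_by_elimination(bn, outcome.name, evidence)
    return result["high"]


def score_cohort(bn: DiscreteBN, frame) -> np.ndarray:
    """Vectorized P(outcome = high | predictors) for every cohort row.

    With every predictor observed, the posterior over the outcome is the
    normalized product of the factors that mention it — its own CPT row and
    the CPT rows of its children — so scoring reduces to table lookups.
    Agrees with :func:`posterior_by_elimination` per record.
    """
    from .bn_fit import encode_frame  # local import to avoid cycle at typing

    dag = bn.dag
    outcome = dag.outcome
    work = frame.copy()
    if outcome.name not in work.columns:
        work[outcome.name] = outcome.categories[0]  # dummy, never read
    codes = encode_frame(work, dag)
    col = {name: j for j, name in enumerate(dag.node_names)}
    k = outcome.cardinality
    lik = np.ones((len(work), k))
    touching = [outcome.name] + list(dag.children(outcome.name))
    for name in touching:
        cpt = bn.cpt(name)
        axes = []
        for p in cpt.parents + (name,):
            if p == outcome.name:
                axes.append(None)  # free axis over outcome states
            else:
                axes.append(codes[:, col[p]])
        for v in range(k):
            idx = tuple(a if a is not None else v for a in axes)
            lik[:, v] *= cpt.table[idx]
    z = lik.sum(axis=1)
    if (z <= 0).any():
        raise ImpossibleEvidenceError("a record has zero probability under the model")
    high = outcome.index_of("high")
    return lik[:, high] / z
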