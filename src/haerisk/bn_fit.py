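"""Bayesian parameter estimation: Dirichlet-smoothed conditional probability tables.

For each node X with parents Pa(X) the sufficient statistics are the
cross-tabulated counts N_ijk (parent configuration j, category k).  Under a
symmetric Dirichlet(α) prior on each CPT row the posterior mean is

    θ̂_ijk = (N_ijk + α) / (N_ij + k·α)

with N_ij = Σ_k N_ijk.  With α = 1 (the default, a uniform prior) every
unobserved parent configuration falls back to the uniform prior mean, which
is exactly the zero-count smoothing a 441-record cohort with sparse parent
cells needs.  The estimator is the posterior mean, not the MAP mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .model_spec import (
    DagModel,
    EstimationError,
    SchemaError,
    parse_model_config,
    serialize_model_config,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_synth import Cohort


# -- containers ------------------------------------------------------------


@dataclass
class CPT:
    """Conditional probability table for one node.

    ``table`` has one axis per parent (in ``parents`` order, sizes equal to
    the parents' cardinalities) plus a final axis over the node's own
    categories; every row along that final axis is a probability vector.
    Parent configurations enumerate lexicographically over the declared
    category orders, which makes serialization bit-stable.
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)

    def validate(self, dag: DagModel, atol: float = 1e-9) -> None:
        if self.parents != dag.parents(self.node):
            raise SchemaError(
                f"CPT for {self.node!r} has parents {self.parents}, "
                f"DAG declares {dag.parents(self.node)}"
            )
        expected = tuple(dag.node(p).cardinality for p in self.parents) + (
            dag.node(self.node).cardinality,
        )
        if self.table.shape != expected:
            raise SchemaError(
                f"CPT for {self.node!r}: shape {self.table.shape} != {expected}"
            )
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise SchemaError(f"CPT rows for {self.node!r} do not sum to 1")
        if (self.table < 0).any():
            raise SchemaError(f"CPT for {self.node!r} has negative entries")


@dataclass
class CountTable:
    """Cross-tabulated counts N_ijk for one node (same axis layout as CPT)."""

    node: str
    parents: tuple[str, ...]
    counts: np.ndarray  # integer, shape (*parent_cards, k)

    @property
    def config_totals(self) -> np.ndarray:
        """N_ij: per-parent-configuration totals."""
        return self.counts.sum(axis=-1)


@dataclass(frozen=True)
class FitConfig:
    """Dirichlet concentration per category (symmetric prior).

    ``alpha = 1`` is the uniform prior / add-one smoothing default;
    ``alpha = 0`` is the maximum-likelihood fallback and is only legal when
    every parent configuration was observed at least once.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise EstimationError(f"alpha must be >= 0, got {self.alpha}")


@dataclass
class DiscreteBN:
    """A DAG with one CPT per node: a fully specified joint distribution."""

    dag: DagModel
    cpts: dict[str, CPT]

    def __post_init__(self) -> None:
        missing = set(self.dag.node_names) - set(self.cpts)
        extra = set(self.cpts) - set(self.dag.node_names)
        if missing or extra:
            raise SchemaError(f"CPT set mismatch: missing {missing}, extra {extra}")
        for cpt in self.cpts.values():
            cpt.validate(self.dag)

    def cpt(self, node: str) -> CPT:
        return self.cpts[node]


@dataclass
class FittedBN(DiscreteBN):
    """A DiscreteBN estimated from data, with fit provenance attached."""

    fit_config: FitConfig = field(default_factory=FitConfig)
    provenance: dict = field(default_factory=dict)


# -- operations ------------------------------------------------------------


def encode_frame(frame: pd.DataFrame, dag: DagModel) -> np.ndarray:
    """Encode a cohort table to integer category codes, column per node.

    Labels are matched case-insensitively after trimming; anything else is a
    schema error naming the offending column.
    """
    missing = [n for n in dag.node_names if n not in frame.columns]
    if missing:
        raise SchemaError(f"cohort is missing columns {missing}")
    codes = np.empty((len(frame), len(dag.nodes)), dtype=np.int64)
    for j, node in enumerate(dag.nodes):
        lut = {label.strip().casefold(): i for i, label in enumerate(node.categories)}
        col = frame[node.name].astype(str).str.strip().str.casefold()
        mapped = col.map(lut)
        if mapped.isna().any():
            bad = frame[node.name][mapped.isna()].iloc[0]
            raise SchemaError(
                f"unknown category {bad!r} in column {node.name!r}"
            )
        codes[:, j] = mapped.to_numpy(dtype=np.int64)
    return codes


def count_configurations(cohort: "Cohort", dag: DagModel) -> dict[str, CountTable]:
    """Exact cross-tabulation of the cohort, one CountTable per node.

    Unobserved parent configurations appear as explicit zero rows; the grand
    total of every table equals the cohort size.
    """
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    codes = encode_frame(frame, dag)
    col = {name: j for j, name in enumerate(dag.node_names)}
    tables: dict[str, CountTable] = {}
    for node in dag.nodes:
        parents = dag.parents(node.name)
        shape = tuple(dag.node(p).cardinality for p in parents) + (node.cardinality,)
        counts = np.zeros(shape, dtype=np.int64)
        idx = tuple(codes[:, col[p]] for p in parents) + (codes[:, col[node.name]],)
        np.add.at(counts, idx, 1)
        tables[node.name] = CountTable(node.name, parents, counts)
    return tables


def posterior_cpt(counts: CountTable, config: FitConfig = FitConfig()) -> CPT:
    """Dirichlet posterior-mean CPT from a count table.

    θ̂_ijk = (N_ijk + α) / (N_ij + k·α).  With α = 0 this is the MLE, which
    is undefined on all-zero rows — those raise, instructing use of smoothing.
    """
    n = counts.counts.astype(float)
    k = n.shape[-1]
    totals = n.sum(axis=-1, keepdims=True)
    if config.alpha == 0:
        if (totals == 0).any():
            raise EstimationError(
                f"node {counts.node!r}: alpha=0 (MLE) with an unobserved parent "
                "configuration; use alpha > 0 for Dirichlet smoothing"
            )
        table = n / totals
    else:
        table = (n + config.alpha) / (totals + k * config.alpha)
    return CPT(counts.node, counts.parents, table)


def fit_network(
    cohort: "Cohort", dag: DagModel, config: FitConfig = FitConfig()
) -> FittedBN:
    """Fit posterior-mean CPTs for every node; deterministic given inputs."""
    tables = count_configurations(cohort, dag)
    cpts = {name: posterior_cpt(tab, config) for name, tab in tables.items()}
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    provenance = {"n_records": int(len(frame)), "alpha": config.alpha}
    if hasattr(cohort, "provenance"):
        provenance["cohort"] = dict(cohort.provenance)
    return FittedBN(dag=dag, cpts=cpts, fit_config=config, provenance=provenance)


# -- serialization ---------------------------------------------------------


def _row_key(dag: DagModel, parents: tuple[str, ...], index: tuple[int, ...]) -> str:
    return "|".join(dag.node(p).categories[i] for p, i in zip(parents, index))


def bn_to_json(bn: DiscreteBN) -> str:
    """Serialize a network to JSON.

    CPT rows are keyed by ``|``-joined parent category labels in lexicographic
    parent-configuration order; floats use Python's shortest round-trip
    representation, so parsing back is exact.
    """
    payload: dict = {"model": json.loads(serialize_model_config(bn.dag))}
    cpts = {}
    for name in bn.dag.node_names:
        cpt = bn.cpt(name)
        rows = {}
        flat = cpt.table.reshape(-1, cpt.table.shape[-1])
        shape = cpt.table.shape[:-1]
        for j in range(flat.shape[0]):
            index = np.unravel_index(j, shape) if shape else ()
            rows[_row_key(bn.dag, cpt.parents, tuple(int(i) for i in index))] = list(
                map(float, flat[j])
            )
        cpts[name] = {"parents": list(cpt.parents), "rows": rows}
    payload["cpts"] = cpts
    if isinstance(bn, FittedBN):
        payload["fit"] = {"alpha": bn.fit_config.alpha, "provenance": bn.provenance}
    return json.dumps(payload, indent=2, ensure_ascii=False)


def bn_from_json(text: str) -> DiscreteBN:
    """Parse a network serialized by :func:`bn_to_json` (exact round-trip)."""
    payload = json.loads(text)
    dag = parse_model_config(json.dumps(payload["model"]))
    cpts: dict[str, CPT] = {}
    for name, spec in payload["cpts"].items():
        parents = tuple(spec["parents"])
        shape = tuple(dag.node(p).cardinality for p in parents) + (
            dag.node(name).cardinality,
        )
        flat = np.empty((int(np.prod(shape[:-1], dtype=np.int64)), shape[-1]))
        for j in range(flat.shape[0]):
            index = np.unravel_index(j, shape[:-1]) if shape[:-1] else ()
            key = _row_key(dag, parents, tuple(int(i) for i in index))
            flat[j] = spec["rows"][key]
        cpts[name] = CPT(name, parents, flat.reshape(shape))
    if "fit" in payload:
        return FittedBN(
            dag=dag,
            cpts=cpts,
            fit_config=FitConfig(alpha=payload["fit"]["alpha"]),
            provenance=payload["fit"].get("provenance", {}),
        )
    return DiscreteBN(dag=dag, cpts=cpts)
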