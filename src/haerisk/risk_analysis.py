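"""Conditional mortality-risk reports: baseline, per-state deltas, scenarios.

The analysis surface mirrors the published workflow: the no-evidence model
marginal P(outcome = high) is the *baseline risk* (a posterior-smoothed
quantity, deliberately distinct from the raw sample prevalence); each
predictor state is then entered as hard evidence and the signed change in
risk, in percentage points, is tabulated; finally multi-factor scenarios
(e.g. Black × Midwest × ≥65) are evaluated with hard or soft (virtual)
evidence.  Deltas always satisfy the law of total probability against the
baseline: Σ_s P(S=s)·P(high | S=s) = P(high) for every predictor S.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_fit import DiscreteBN
from .bn_infer import Evidence, Hard, QueryResult, Soft, posterior_by_elimination
from .model_spec import SchemaError


@dataclass
class DeltaRow:
    """Risk conditioned on one predictor state, and its change vs baseline."""

    node: str
    state: str
    probability: float  # P(outcome = high | node = state)
    delta: float  # percentage points, signed; exactly (probability - baseline)*100


@dataclass
class Scenario:
    """A labelled multi-factor evidence query and its evaluated result."""

    label: str
    evidence: Evidence
    result: QueryResult
    probability: float
    delta: float  # percentage points vs baseline
    mode: str  # "hard" | "soft"


def baseline_risk(bn: DiscreteBN) -> float:
    """Model marginal P(outcome = high) with no evidence."""
    result = posterior_by_elimination(bn, bn.dag.outcome.name, Evidence())
    return result["high"]


def single_factor_deltas(bn: DiscreteBN) -> list[DeltaRow]:
    """One row per (predictor, state) with hard-evidence conditioning.

    Returned sorted by |delta| descending — the report ordering.
    """
    base = baseline_risk(bn)
    outcome = bn.dag.outcome.name
    rows: list[DeltaRow] = []
    for node in bn.dag.predictors:
        for state in node.categories:
            evidence = Evidence({node.name: Hard(state)})
            p = posterior_by_elimination(bn, outcome, evidence)["high"]
            rows.append(DeltaRow(node.name, state, p, (p - base) * 100.0))
    rows.sort(key=lambda r: (-abs(r.delta), r.node, r.state))
    return rows


def _soften(bn: DiscreteBN, node: str, state: str, strength: float) -> Soft:
    """Hard observation relaxed to a likelihood vector: ``strength`` on the
    observed state, the remainder spread uniformly over the rest."""
    nd = bn.dag.node(node)
    k = nd.cardinality
    vec = np.full(k, (1.0 - strength) / (k - 1))
    vec[nd.index_of(state)] = strength
    return Soft(tuple(vec))


def _scenario_evidence(
    bn: DiscreteBN, spec_evidence: Mapping[str, object], mode: str, strength: float
) -> Evidence:
    entries: dict[str, object] = {}
    for name, value in spec_evidence.items():
        node = bn.dag.node(name)
        if isinstance(value, str):
            if mode == "soft":
                entries[name] = _soften(bn, name, value, strength)
            else:
                entries[name] = Hard(node.canonical(value))
        elif isinstance(value, Mapping):
            # explicit weights (e.g. a Medicare/Medicaid disjunction) are a
            # likelihood vector in either mode
            vec = np.zeros(node.cardinality)
            for state, weight in value.items():
                vec[node.index_of(str(state))] = float(weight)
            entries[name] = Soft(tuple(vec))
        else:
            raise SchemaError(f"scenario evidence for {name!r}: bad value {value!r}")
    evidence = Evidence(entries)
    evidence.validate(bn.dag)
    return evidence


def default_scenarios() -> list[dict]:
    """The four shipped multi-factor scenario specs."""
    text = (
        resources.files("haerisk.data")
        .joinpath("default_scenarios.json")
        .read_text("utf-8")
    )
    return json.loads(text)


def run_scenarios(
    bn: DiscreteBN,
    scenarios: Sequence[Mapping] | None = None,
    mode: str = "hard",
    soft_strength: float = 0.9,
) -> list[Scenario]:
    """Evaluate scenario specs ({label, evidence}) in hard or soft mode.

    In soft mode each single-state observation becomes virtual evidence with
    likelihood ``soft_strength`` on the observed state; explicit weight
    mappings pass through unchanged.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    if scenarios is None:
        scenarios = default_scenarios()
    base = baseline_risk(bn)
    outcome = bn.dag.outcome.name
    out: list[Scenario] = []
    for spec in scenarios:
        if not spec.get("evidence"):
            raise SchemaError(f"scenario {spec.get('label')!r} has empty evidence")
        if outcome in spec["evidence"]:
            raise SchemaError(
                f"scenario {spec.get('label')!r} places evidence on the outcome"
            )
        try:
            evidence = _scenario_evidence(bn, spec["evidence"], mode, soft_strength)
        except SchemaError as exc:
            raise SchemaError(f"scenario {spec.get('label')!r}: {exc}") from exc
        result = posterior_by_elimination(bn, outcome, evidence)
        p = result["high"]
        out.append(
            Scenario(
                label=str(spec.get("label", "scenario")),
                evidence=evidence,
                result=result,
                probability=p,
                delta=(p - base) * 100.0,
                mode=mode,
            )
        )
    return out


# -- report emission -------------------------------------------------------


def write_report(
    rows: Sequence[DeltaRow],
    scenarios: Sequence[Scenario],
    baseline: float,
    out_dir,
    header_meta: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Emit the machine CSVs (full precision) and the human markdown report.

    CSV files carry provenance as leading ``# key=value`` comment lines
    (readable with ``pandas.read_csv(..., comment='#')``); the markdown
    rounds probabilities to one decimal place in percent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_lines = "".join(
        f"# {k}={v}\n" for k, v in (header_meta or {}).items()
    )

    deltas_path = out_dir / "deltas.csv"
    deltas = pd.DataFrame(
        [
            {
                "node": r.node,
                "state": r.state,
                "probability_high": repr(r.probability),
                "delta_pp": repr(r.delta),
            }
            for r in rows
        ]
    )
    with open(deltas_path, "w", encoding="utf-8") as fh:
        fh.write(meta_lines + f"# baseline={baseline!r}\n")
        deltas.to_csv(fh, index=False)

    paths = {"deltas": deltas_path}

    scen_path = out_dir / "scenarios.csv"
    scen = pd.DataFrame(
        [
            {
                "label": s.label,
                "mode": s.mode,
                "probability_high": repr(s.probability),
                "delta_pp": repr(s.delta),
            }
            for s in scenarios
        ]
    )
    if scenarios:
        with open(scen_path, "w", encoding="utf-8") as fh:
            fh.write(meta_lines + f"# baseline={baseline!r}\n")
            scen.to_csv(fh, index=False)
        paths["scenarios"] = scen_path

    md_path = out_dir / "report.md"
    lines = [
        "# Mortality-risk report",
        "",
        f"Baseline risk (no-evidence model marginal): **{baseline * 100:.1f}%**",
        "",
        "## Single-factor conditioning",
        "",
        "| node | state | P(high) | Δ (pp) |",
        "|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            f"| {r.node} | {r.state} | {r.probability * 100:.1f}% | {r.delta:+.1f} |"
        )
    if scenarios:
        lines += [
            "",
            "## Multi-factor scenarios",
            "",
            "| scenario | mode | P(high) | Δ (pp) |",
            "|---|---|---|---|",
        ]
        for s in scenarios:
            lines.append(
                f"| {s.label} | {s.mode} | {s.probability * 100:.1f}% | {s.delta:+.1f} |"
            )
    md_path.write_text("\n".join(lines) + "\n", "utf-8")
    paths["markdown"] = md_path
    return paths
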