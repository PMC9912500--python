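"""Parametric structural causal models, cohort simulation, and ground truth.

Each node of a :class:`~effectpath.dag.CausalDAG` gets a structural
assignment: the exposure is Bernoulli (two origin countries), the selection
indicator is Bernoulli with a logistic link on its parents (who ends up in
the analyzed dataset), and every other node is linear in its parents with
Gaussian noise, optionally with an exposure-by-mediator interaction on the
outcome.  Simulating the model produces a *full population* table together
with the selected ``S = 1`` view -- the dataset an analyst would actually
see.

Ground-truth effects come from do-interventions: the total effect is
``E[D | do(E=1)] - E[D | do(E=0)]`` and the controlled direct effect fixes
the measured mediator at a reference value ``m`` in both arms.  For fully
linear mediation pathways both are available in closed form by path-tracing
(:func:`analytic_effects`); when the binary selection node itself transmits
exposure effects to the outcome (an ``S -> R`` arrow, i.e. post-migration
change in the risk factor) the logistic link breaks linearity and Monte
Carlo (:func:`mc_effects`) is required.

Monte Carlo arms share exogenous noise per node (common random numbers), so
interventional contrasts are paired and their standard errors are far
smaller than independent-arm simulation at the same ``n``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .dag import CausalDAG, GraphError, NodeRoles, build_dag

__all__ = [
    "ModelError",
    "AnalyticError",
    "BernoulliNode",
    "LogisticNode",
    "LinearNode",
    "ConstantNode",
    "StructuralModel",
    "SimulatedCohort",
    "TruthValues",
    "DEFAULT_COEFFICIENTS",
    "TEMPLATES",
    "make_model",
    "simulate_cohort",
    "apply_do",
    "analytic_effects",
    "mc_effects",
    "derive_seed",
]


class ModelError(ValueError):
    """Invalid structural model specification."""


class AnalyticError(ValueError):
    """Closed-form effects are unavailable for this model; use Monte Carlo."""


def derive_seed(master: int, *parts) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed.

    Replicates, nodes, and experiment arms each get an independent stream
    keyed by human-readable labels, so runs are reproducible and streams do
    not overlap across uses of the same master seed.
    """
    key = "|".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class BernoulliNode:
    """Root binary node: P(node = 1) = p."""

    p: float


@dataclass(frozen=True)
class LogisticNode:
    """Binary node with logistic link on a linear predictor of its parents."""

    intercept: float
    coefficients: Mapping[str, float]


@dataclass(frozen=True)
class LinearNode:
    """Continuous node: intercept + linear parents + Gaussian noise.

    ``interaction`` is an optional ``(factor_a, factor_b, coefficient)``
    product term; the model validator restricts it to the outcome node and
    to an exposure-by-measured-mediator product.
    """

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    interaction: Optional[tuple] = None


@dataclass(frozen=True)
class ConstantNode:
    """Node fixed by a do-intervention."""

    value: float


Assignment = Union[BernoulliNode, LogisticNode, LinearNode, ConstantNode]


@dataclass(frozen=True)
class StructuralModel:
    """A DAG, node roles, and one structural assignment per node."""

    dag: CausalDAG
    roles: NodeRoles
    assignments: Mapping[str, Assignment]
    label: str = "custom"
    do_fixed: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        object.__setattr__(self, "do_fixed", frozenset(self.do_fixed))
        self.roles.validate(self.dag)
        missing = self.dag.nodes - set(self.assignments)
        if missing:
            raise ModelError(f"nodes lack assignments: {sorted(missing)}")
        extra = set(self.assignments) - self.dag.nodes
        if extra:
            raise ModelError(f"assignments for unknown nodes: {sorted(extra)}")
        for node, a in self.assignments.items():
            parents = self.dag.parents(node)
            if isinstance(a, (BernoulliNode, ConstantNode)):
                if parents:
                    raise ModelError(
                        f"node {node!r} has parents but a parent-free assignment"
                    )
            elif isinstance(a, (LogisticNode, LinearNode)):
                stated = frozenset(a.coefficients)
                if stated != parents:
                    raise ModelError(
                        f"assignment parents for {node!r} ({sorted(stated)}) do not "
                        f"match DAG parents ({sorted(parents)})"
                    )
            if isinstance(a, BernoulliNode) and not 0.0 < a.p < 1.0:
                raise ModelError(f"Bernoulli probability for {node!r} must lie in (0, 1)")
            if isinstance(a, LinearNode):
                if a.noise_sd < 0:
                    raise ModelError(f"negative noise SD on node {node!r}")
                if a.interaction is not None:
                    fa, fb, _ = a.interaction
                    if node != self.roles.outcome:
                        raise ModelError("interaction terms are only allowed on the outcome")
                    pair = {fa, fb}
                    if self.roles.exposure not in pair:
                        raise ModelError("the interaction must involve the exposure")
                    mediator = (pair - {self.roles.exposure}).pop()
                    if mediator not in self.roles.risk_factors_measured:
                        raise ModelError(
                            "the interaction partner must be a measured mediator"
                        )
                    if not pair <= parents:
                        raise ModelError("interaction factors must be parents of the outcome")
            if isinstance(a, LogisticNode) and self.roles.selection != node:
                raise ModelError("the logistic link is reserved for the selection node")

    def with_label(self, label: str) -> "StructuralModel":
        return replace(self, label=label)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated full population plus its selected (``S = 1``) view."""

    full_population: pd.DataFrame
    seed: int
    exposure: str
    outcome: str
    selection: Optional[str] = None
    do_nodes: frozenset = frozenset()

    @property
    def n(self) -> int:
        return len(self.full_population)

    @property
    def selected(self) -> pd.DataFrame:
        """Rows with ``S = 1`` -- the dataset the analyst observes."""
        if self.selection is None:
            return self.full_population
        if self.selection in self.do_nodes:
            raise ModelError(
                "the selection node was fixed by a do-intervention; selected-view "
                "statistics are contradictory"
            )
        df = self.full_population
        return df[df[self.selection] == 1.0]


@dataclass(frozen=True)
class TruthValues:
    """Interventional ground truth on the mean-difference scale.

    ``total_effect`` is the full-population contrast through every directed
    path, selection-mediated paths included; because its target population
    is debatable when selection itself mediates, the contrast excluding
    paths through the selection node is reported alongside.  ``cde`` is the
    controlled direct effect with the measured mediator fixed at
    ``m_reference``.
    """

    total_effect: float
    total_effect_excluding_S_paths: float
    cde: float
    m_reference: float
    method: str
    mc_se: Optional[float] = None


# Default generating coefficients.  Chosen once to emulate a realistic
# selection-sampled cohort: two origin countries equally represented in the
# full population; a logistic selection model under which the receiving
# country is a majority of the dataset and migrants a strongly selected
# minority; standardized continuous risk factors; effect sizes large enough
# that collider bias is decisively detectable at the default replicate
# budget (20 x 200,000).
DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "p_exposure": 0.5,          # P(E = 1): migrating-country share of the full population
    "E->D": 0.3,                # direct exposure effect on the outcome
    "E->R0": 0.5,               # pre-migration national difference in the risk factor
    "R0->R": 1.0,               # measured risk factor tracks its pre-migration value
    "R->D": 0.4,                # risk factor effect on the outcome
    "selection_intercept": 2.0, # logistic intercept: most of the receiving country selected
    "E->S": -2.5,               # migrants are a small subsample of their origin country
    "R0->S": -1.5,              # selection on the risk factor (e.g. SES)
    "C->R0": 0.5,               # mediator-outcome confounder into the risk factor
    "C->D": 0.5,                # mediator-outcome confounder into the outcome
    "S->R": 0.5,                # post-migration change in the risk factor
    "noise_sd": 1.0,            # standard-normal structural noise on continuous nodes
}


def _p(params: Mapping[str, float], key: str) -> float:
    return float(params[key])


def _template_fig1a(params):
    dag = build_dag([("E", "D"), ("E", "R0"), ("R0", "D")])
    roles = NodeRoles(
        exposure="E", outcome="D",
        risk_factors_measured=frozenset({"R0"}), measured=frozenset({"R0"}),
    )
    sd = _p(params, "noise_sd")
    assignments = {
        "E": BernoulliNode(_p(params, "p_exposure")),
        "R0": LinearNode(coefficients={"E": _p(params, "E->R0")}, noise_sd=sd),
        "D": LinearNode(
            coefficients={"E": _p(params, "E->D"), "R0": _p(params, "R->D")}, noise_sd=sd
        ),
    }
    return dag, roles, assignments


def _template_fig1b(params):
    dag = build_dag(
        [("E", "D"), ("E", "R0"), ("R0", "R"), ("R", "D"), ("E", "S"), ("R0", "S")]
    )
    roles = NodeRoles(
        exposure="E", outcome="D", selection="S",
        risk_factors_pre=frozenset({"R0"}),
        risk_factors_measured=frozenset({"R"}),
        measured=frozenset({"R"}),
    )
    sd = _p(params, "noise_sd")
    assignments = {
        "E": BernoulliNode(_p(params, "p_exposure")),
        "R0": LinearNode(coefficients={"E": _p(params, "E->R0")}, noise_sd=sd),
        "R": LinearNode(coefficients={"R0": _p(params, "R0->R")}, noise_sd=sd),
        "S": LogisticNode(
            intercept=_p(params, "selection_intercept"),
            coefficients={"E": _p(params, "E->S"), "R0": _p(params, "R0->S")},
        ),
        "D": LinearNode(
            coefficients={"E": _p(params, "E->D"), "R": _p(params, "R->D")}, noise_sd=sd
        ),
    }
    return dag, roles, assignments


def _template_fig1c(params):
    dag, roles, assignments = _template_fig1b(params)
    dag = build_dag(sorted(dag.edges | {("C", "R0"), ("C", "D")}))
    roles = replace(
        roles, confounders=frozenset({"C"}), measured=roles.measured | {"C"}
    )
    sd = _p(params, "noise_sd")
    assignments = dict(assignments)
    assignments["C"] = LinearNode(noise_sd=sd)
    assignments["R0"] = LinearNode(
        coefficients={"E": _p(params, "E->R0"), "C": _p(params, "C->R0")}, noise_sd=sd
    )
    assignments["D"] = LinearNode(
        coefficients={
            "E": _p(params, "E->D"), "R": _p(params, "R->D"), "C": _p(params, "C->D"),
        },
        noise_sd=sd,
    )
    return dag, roles, assignments


def _template_modelC(params):
    # risk factor is a mediator only: drop the R0 -> S selection arrow
    dag, roles, assignments = _template_fig1b(params)
    dag = build_dag(sorted(dag.edges - {("R0", "S")}))
    assignments = dict(assignments)
    assignments["S"] = LogisticNode(
        intercept=_p(params, "selection_intercept"),
        coefficients={"E": _p(params, "E->S")},
    )
    return dag, roles, assignments


def _template_modelD(params):
    # risk factor is neither a mediator nor a selection factor
    dag = build_dag([("E", "D"), ("R0", "R"), ("R", "D"), ("E", "S")])
    roles = NodeRoles(
        exposure="E", outcome="D", selection="S",
        risk_factors_pre=frozenset({"R0"}),
        risk_factors_measured=frozenset({"R"}),
        measured=frozenset({"R"}),
    )
    sd = _p(params, "noise_sd")
    assignments = {
        "E": BernoulliNode(_p(params, "p_exposure")),
        "R0": LinearNode(noise_sd=sd),
        "R": LinearNode(coefficients={"R0": _p(params, "R0->R")}, noise_sd=sd),
        "S": LogisticNode(
            intercept=_p(params, "selection_intercept"),
            coefficients={"E": _p(params, "E->S")},
        ),
        "D": LinearNode(
            coefficients={"E": _p(params, "E->D"), "R": _p(params, "R->D")}, noise_sd=sd
        ),
    }
    return dag, roles, assignments


def _template_fig1d(params):
    # risk factor is a selection factor only (no E -> R0), with the
    # mediator-outcome confounder C the figure carries
    dag = build_dag(
        [
            ("E", "D"), ("R0", "R"), ("R", "D"), ("E", "S"), ("R0", "S"),
            ("C", "R0"), ("C", "D"),
        ]
    )
    roles = NodeRoles(
        exposure="E", outcome="D", selection="S",
        risk_factors_pre=frozenset({"R0"}),
        risk_factors_measured=frozenset({"R"}),
        confounders=frozenset({"C"}),
        measured=frozenset({"R", "C"}),
    )
    sd = _p(params, "noise_sd")
    assignments = {
        "E": BernoulliNode(_p(params, "p_exposure")),
        "C": LinearNode(noise_sd=sd),
        "R0": LinearNode(coefficients={"C": _p(params, "C->R0")}, noise_sd=sd),
        "R": LinearNode(coefficients={"R0": _p(params, "R0->R")}, noise_sd=sd),
        "S": LogisticNode(
            intercept=_p(params, "selection_intercept"),
            coefficients={"E": _p(params, "E->S"), "R0": _p(params, "R0->S")},
        ),
        "D": LinearNode(
            coefficients={
                "E": _p(params, "E->D"), "R": _p(params, "R->D"), "C": _p(params, "C->D"),
            },
            noise_sd=sd,
        ),
    }
    return dag, roles, assignments


def _template_fig1d_timeconstant(params):
    # Time-constant risk factor (e.g. sex), or one measured at the point of
    # immigration: the pre-migration value and its measurement coincide, so
    # R0 and R contract to a single *measured* node R that is both a direct
    # cause of the outcome and a selection factor.
    dag = build_dag(
        [("E", "D"), ("R", "D"), ("R", "S"), ("E", "S"), ("C", "R"), ("C", "D")]
    )
    roles = NodeRoles(
        exposure="E", outcome="D", selection="S",
        risk_factors_measured=frozenset({"R"}),
        confounders=frozenset({"C"}),
        measured=frozenset({"R", "C"}),
    )
    sd = _p(params, "noise_sd")
    assignments = {
        "E": BernoulliNode(_p(params, "p_exposure")),
        "C": LinearNode(noise_sd=sd),
        "R": LinearNode(coefficients={"C": _p(params, "C->R0")}, noise_sd=sd),
        "S": LogisticNode(
            intercept=_p(params, "selection_intercept"),
            coefficients={"E": _p(params, "E->S"), "R": _p(params, "R0->S")},
        ),
        "D": LinearNode(
            coefficients={
                "E": _p(params, "E->D"), "R": _p(params, "R->D"), "C": _p(params, "C->D"),
            },
            noise_sd=sd,
        ),
    }
    return dag, roles, assignments


def _template_fig1d_postmigration(params):
    # selection-only model plus post-migration change: S -> R
    dag, roles, assignments = _template_fig1d(params)
    dag = build_dag(sorted(dag.edges | {("S", "R")}))
    assignments = dict(assignments)
    assignments["R"] = LinearNode(
        coefficients={"R0": _p(params, "R0->R"), "S": _p(params, "S->R")},
        noise_sd=_p(params, "noise_sd"),
    )
    return dag, roles, assignments


def _preeclampsia_edges(extended: bool):
    # E: refugee immigrant vs non-immigrant; D: preterm preeclampsia.
    # R01/R1: combined "other" risk factors (calendar year, marital status,
    # parity, chronic disease); R02/R2: socioeconomic status; R03/R3:
    # maternal age.  Pre-migration factors are unmeasured, differ by origin
    # country, and select into the dataset; their post-migration
    # measurements mediate to the outcome.
    edges = [("E", "D"), ("E", "S")]
    for k in ("1", "2", "3"):
        edges += [
            ("E", f"R0{k}"), (f"R0{k}", f"R{k}"), (f"R{k}", "D"), (f"R0{k}", "S"),
        ]
    if extended:
        edges += [("S", "R2"), ("R2", "R3")]
    return edges


def _template_fig2_preeclampsia(params, extended: bool = False):
    dag = build_dag(sorted(_preeclampsia_edges(extended)))
    roles = NodeRoles(
        exposure="E", outcome="D", selection="S",
        risk_factors_pre=frozenset({"R01", "R02", "R03"}),
        risk_factors_measured=frozenset({"R1", "R2", "R3"}),
        measured=frozenset({"R1", "R2", "R3"}),
    )
    sd = _p(params, "noise_sd")
    assignments: dict = {"E": BernoulliNode(_p(params, "p_exposure"))}
    sel_coeffs = {"E": _p(params, "E->S")}
    d_coeffs = {"E": _p(params, "E->D")}
    for k in ("1", "2", "3"):
        assignments[f"R0{k}"] = LinearNode(
            coefficients={"E": _p(params, "E->R0")}, noise_sd=sd
        )
        r_coeffs = {f"R0{k}": _p(params, "R0->R")}
        if extended and k == "2":
            r_coeffs["S"] = _p(params, "S->R")
        if extended and k == "3":
            r_coeffs["R2"] = 0.3
        assignments[f"R{k}"] = LinearNode(coefficients=r_coeffs, noise_sd=sd)
        sel_coeffs[f"R0{k}"] = -1.0
        d_coeffs[f"R{k}"] = 0.2
    assignments["S"] = LogisticNode(
        intercept=_p(params, "selection_intercept"), coefficients=sel_coeffs
    )
    assignments["D"] = LinearNode(coefficients=d_coeffs, noise_sd=sd)
    return dag, roles, assignments


TEMPLATES = {
    "fig1a": _template_fig1a,
    "fig1b": _template_fig1b,
    "fig1c": _template_fig1c,
    "modelC": _template_modelC,
    "modelD": _template_modelD,
    "fig1d": _template_fig1d,
    "fig1d_timeconstant": _template_fig1d_timeconstant,
    "fig1d_postmigration": _template_fig1d_postmigration,
    "fig2_preeclampsia": _template_fig2_preeclampsia,
    "fig2_preeclampsia_extended": lambda p: _template_fig2_preeclampsia(p, extended=True),
}


def make_model(
    template: str,
    *,
    coefficients: Optional[Mapping] = None,
    noise_sds: Optional[Mapping[str, float]] = None,
    interaction: Optional[float] = None,
    p_exposure: Optional[float] = None,
    selection_intercept: Optional[float] = None,
) -> StructuralModel:
    """Instantiate a named model template with optional overrides.

    ``coefficients`` overrides edge coefficients, keyed by ``(parent,
    child)`` pairs or ``"parent->child"`` strings; a key naming a pair that
    is not an edge of the template DAG is rejected.  ``noise_sds`` overrides
    structural noise per node.  ``interaction`` adds an
    exposure-by-measured-mediator product term with the given coefficient to
    the outcome assignment.
    """
    if template not in TEMPLATES:
        raise ModelError(
            f"unknown template {template!r}; available: {sorted(TEMPLATES)}"
        )
    params = dict(DEFAULT_COEFFICIENTS)
    if p_exposure is not None:
        params["p_exposure"] = float(p_exposure)
    if selection_intercept is not None:
        params["selection_intercept"] = float(selection_intercept)
    dag, roles, assignments = TEMPLATES[template](params)

    overrides = {}
    for key, value in (coefficients or {}).items():
        if isinstance(key, str):
            parent, _, child = key.partition("->")
            key = (parent.strip(), child.strip())
        overrides[tuple(key)] = float(value)
    for (parent, child) in overrides:
        if (parent, child) not in dag.edges:
            raise ModelError(
                f"coefficient given for absent edge {parent!r} -> {child!r}"
            )
    for (parent, child), value in overrides.items():
        a = assignments[child]
        coeffs = dict(a.coefficients)
        coeffs[parent] = value
        assignments[child] = replace(a, coefficients=coeffs)

    for node, sd in (noise_sds or {}).items():
        a = assignments.get(node)
        if not isinstance(a, LinearNode):
            raise ModelError(f"noise SD override on non-linear node {node!r}")
        assignments[node] = replace(a, noise_sd=float(sd))

    if interaction is not None:
        mediators = sorted(roles.risk_factors_measured & dag.parents(roles.outcome))
        if len(mediators) != 1:
            raise ModelError(
                "interaction override requires exactly one measured mediator parent "
                "of the outcome"
            )
        outcome = assignments[roles.outcome]
        assignments[roles.outcome] = replace(
            outcome, interaction=(roles.exposure, mediators[0], float(interaction))
        )

    return StructuralModel(
        dag=dag, roles=roles, assignments=assignments, label=template
    )


def _node_rng(seed: int, node: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(derive_seed(seed, "node", node)))


def simulate_cohort(model: StructuralModel, n: int, seed: int) -> SimulatedCohort:
    """Simulate ``n`` individuals from the model.

    Nodes are generated in topological order; every node draws from its own
    seed-derived stream, so the same ``(model structure, n, seed)`` gives
    bit-identical tables and do-modified variants of a model share exogenous
    noise node by node (common random numbers for paired contrasts).
    """
    if n < 1:
        raise ModelError("cohort size must be a positive integer")
    data: dict = {}
    for node in model.dag.topological_order():
        a = model.assignments[node]
        if isinstance(a, ConstantNode):
            data[node] = np.full(n, float(a.value))
            continue
        rng = _node_rng(seed, node)
        if isinstance(a, BernoulliNode):
            data[node] = (rng.random(n) < a.p).astype(float)
        elif isinstance(a, LogisticNode):
            eta = np.full(n, a.intercept)
            for parent, coef in a.coefficients.items():
                eta += coef * data[parent]
            data[node] = (rng.random(n) < expit(eta)).astype(float)
        else:
            col = np.full(n, a.intercept)
            for parent, coef in a.coefficients.items():
                col += coef * data[parent]
            if a.interaction is not None:
                fa, fb, coef = a.interaction
                col += coef * data[fa] * data[fb]
            if a.noise_sd > 0:
                col = col + a.noise_sd * rng.standard_normal(n)
            data[node] = col
    df = pd.DataFrame(data, columns=list(model.dag.topological_order()))
    return SimulatedCohort(
        full_population=df,
        seed=seed,
        exposure=model.roles.exposure,
        outcome=model.roles.outcome,
        selection=model.roles.selection,
        do_nodes=model.do_fixed,
    )


def apply_do(model: StructuralModel, assignments: Mapping[str, float]) -> StructuralModel:
    """Graph surgery: fix nodes at constants and sever their incoming edges."""
    unknown = set(assignments) - model.dag.nodes
    if unknown:
        raise ModelError(f"do-intervention on unknown nodes: {sorted(unknown)}")
    fixed = set(assignments)
    new_edges = frozenset(e for e in model.dag.edges if e[1] not in fixed)
    new_dag = CausalDAG(nodes=model.dag.nodes, edges=new_edges)
    new_assign = dict(model.assignments)
    for node, value in assignments.items():
        new_assign[node] = ConstantNode(float(value))
    return StructuralModel(
        dag=new_dag,
        roles=model.roles,
        assignments=new_assign,
        label=model.label,
        do_fixed=model.do_fixed | fixed,
    )


def _severed_selection(model: StructuralModel) -> StructuralModel:
    """Cut the selection node's outgoing edges (removes paths through S)."""
    s = model.roles.selection
    if s is None or not model.dag.children(s):
        return model
    new_edges = frozenset(e for e in model.dag.edges if e[0] != s)
    new_assign = dict(model.assignments)
    for child in model.dag.children(s):
        a = new_assign[child]
        coeffs = {k: v for k, v in a.coefficients.items() if k != s}
        new_assign[child] = replace(a, coefficients=coeffs)
    return StructuralModel(
        dag=CausalDAG(nodes=model.dag.nodes, edges=new_edges),
        roles=model.roles,
        assignments=new_assign,
        label=model.label,
        do_fixed=model.do_fixed,
    )


def _mean_under_do(model: StructuralModel, exposure_value: float) -> Mapping[str, float]:
    """Exact node means under do(exposure = value) for linear pathways.

    Valid because, with the exposure held constant, every ancestor of the
    outcome is linear-Gaussian and the only product term involves the (now
    constant) exposure, so expectations propagate through the assignments.
    """
    intervened = apply_do(model, {model.roles.exposure: exposure_value})
    relevant = intervened.dag.ancestors(model.roles.outcome) | {model.roles.outcome}
    means: dict = {}
    for node in intervened.dag.topological_order():
        if node not in relevant:
            continue
        a = intervened.assignments[node]
        if isinstance(a, ConstantNode):
            means[node] = float(a.value)
        elif isinstance(a, LinearNode):
            mu = a.intercept + sum(
                coef * means[parent] for parent, coef in a.coefficients.items()
            )
            if a.interaction is not None:
                fa, fb, coef = a.interaction
                mu += coef * means[fa] * means[fb]
            means[node] = mu
        else:
            raise AnalyticError(
                f"node {node!r} is binary with a nonlinear link on an exposure-"
                "outcome pathway; closed-form effects are unavailable, use mc_effects"
            )
    return means


def _direct_and_interaction(model: StructuralModel):
    outcome = model.assignments[model.roles.outcome]
    if not isinstance(outcome, LinearNode):
        raise AnalyticError("the outcome must be a linear node for closed-form effects")
    direct = outcome.coefficients.get(model.roles.exposure, 0.0)
    gamma = 0.0
    if outcome.interaction is not None:
        gamma = outcome.interaction[2]
    return direct, gamma


def analytic_effects(model: StructuralModel, m_reference: float = 0.0) -> TruthValues:
    """Closed-form total and controlled direct effect by mean propagation.

    Equivalent to summing coefficient products over every directed
    exposure-to-outcome path (plus the interaction contribution), but
    computed by propagating interventional means, which also handles the
    product term exactly.  Refused when the binary selection node transmits
    exposure effects to the outcome (``S -> R`` present): its logistic link
    breaks path-product linearity, and :func:`mc_effects` must be used.
    """
    s = model.roles.selection
    if s is not None and s in model.dag.ancestors(model.roles.outcome):
        raise AnalyticError(
            "the selection node lies on an exposure-outcome pathway (post-"
            "migration S -> R arrow); the analytic total is refused, use mc_effects"
        )
    outcome = model.roles.outcome
    total = (
        _mean_under_do(model, 1.0)[outcome] - _mean_under_do(model, 0.0)[outcome]
    )
    direct, gamma = _direct_and_interaction(model)
    cde = direct + gamma * m_reference
    return TruthValues(
        total_effect=total,
        total_effect_excluding_S_paths=total,
        cde=cde,
        m_reference=m_reference,
        method="analytic",
        mc_se=None,
    )


def mc_effects(
    model: StructuralModel, n: int, seed: int, m_reference: float = 0.0
) -> TruthValues:
    """Monte Carlo interventional effects with paired (common-noise) arms."""
    if n < 1:
        raise ModelError("Monte Carlo sample size must be a positive integer")
    e = model.roles.exposure
    outcome = model.roles.outcome

    def contrast(base: StructuralModel, extra: Mapping[str, float]):
        arm1 = simulate_cohort(apply_do(base, {e: 1.0, **extra}), n, seed)
        arm0 = simulate_cohort(apply_do(base, {e: 0.0, **extra}), n, seed)
        diff = arm1.full_population[outcome].to_numpy() - arm0.full_population[
            outcome
        ].to_numpy()
        se = float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(diff.mean()), se

    total, total_se = contrast(model, {})
    severed = _severed_selection(model)
    if severed is model:
        total_excl = total
    else:
        total_excl, _ = contrast(severed, {})
    fix_mediators = {r: m_reference for r in sorted(model.roles.risk_factors_measured)}
    cde, _ = contrast(model, fix_mediators)
    return TruthValues(
        total_effect=total,
        total_effect_excluding_S_paths=total_excl,
        cde=cde,
        m_reference=m_reference,
        method="monte_carlo",
        mc_se=total_se,
    )
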