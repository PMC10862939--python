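"""Non-equilibrium steady states of promoter state graphs.

Transcription initiation is described as a continuous-time Markov process on
a small graph of promoter states (e.g. empty E, RNAP-bound P, activator-bound
A, doubly bound AP).  The steady-state probability of each state follows
from the Matrix Tree Theorem: it is proportional to the sum over all
spanning trees rooted at (directed into) that state of the product of edge
rate constants.  Detailed balance holds when every cycle has unit ratio of
forward to backward rate products; investing an energy U on one edge
multiplies its rate by e^{beta U} and breaks that balance.

Sequence specificity enters through the off-rates: binding on-rates are
diffusion-limited and sequence-independent, while off-rates follow from the
dissociation constant K_d = c0 e^{beta dE} with dE computed from an energy
matrix, so k_off = k_on * K_d (times e^{beta U} on a driven edge).

The module provides exact spanning-tree enumeration for graphs up to six
states (with a linear-algebra fall-back beyond), the four-state square graph
of a simple-activation promoter, and a library simulator that feeds
per-variant steady-state active probabilities into the expression/footprint
pipeline.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .seqlib import MutantLibrary, library_site_energies
from .thermo import BindingSite, ConfigurationError, ThermoParams

#: Reference (standard-state) concentration for K_d = c0 e^{beta dE}, molar.
C0 = 1.0

#: Above this state count, exact spanning-tree enumeration falls back to the
#: Laplacian null-space solve.
MAX_TREE_STATES = 6


class GraphError(ValueError):
    """Ill-posed kinetic graph (disconnected, non-positive rates, ...)."""


@dataclass(frozen=True)
class DriveSpec:
    """An energy U (kBT) invested on one edge, multiplying its rate by e^{beta U}."""

    edge: tuple[str, str]
    energy: float


@dataclass
class KineticGraph:
    """Directed promoter state graph with per-edge rate constants.

    ``rates`` maps ordered state pairs (u, v) to the transition rate u -> v
    (1/time; binding edges carry concentration-scaled pseudo-first-order
    rates).  ``active_states`` is the set of transcribing states.  A unique
    steady state requires the graph to be strongly connected.
    """

    states: list[str]
    rates: dict[tuple[str, str], float]
    active_states: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.active_states = frozenset(self.active_states)
        known = set(self.states)
        if len(known) != len(self.states):
            raise GraphError("duplicate state labels")
        for (u, v), k in self.rates.items():
            if u not in known or v not in known or u == v:
                raise GraphError(f"edge ({u}, {v}) references unknown or identical states")
            if not k > 0:
                raise GraphError(f"rate for edge ({u}, {v}) must be positive, got {k}")
        extra = self.active_states - known
        if extra:
            raise GraphError(f"active states {sorted(extra)} not in the graph")
        g = nx.DiGraph(list(self.rates))
        g.add_nodes_from(self.states)
        if not nx.is_strongly_connected(g):
            raise GraphError("graph is not strongly connected: no unique steady state")

    def with_drive(self, drive: DriveSpec) -> "KineticGraph":
        """Return a copy with the driven edge's rate multiplied by e^{beta U}."""
        if drive.edge not in self.rates:
            raise GraphError(f"driven edge {drive.edge} not in the graph")
        rates = dict(self.rates)
        rates[drive.edge] = rates[drive.edge] * math.exp(drive.energy)
        return replace(self, rates=rates)


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------


def _in_trees(states: list[str], edges: list[tuple[str, str]], root: str):
    """Yield spanning trees directed into ``root`` as tuples of edges.

    Every non-root state contributes exactly one outgoing edge; a choice is
    a spanning in-tree iff following the chosen edges from any state reaches
    the root (no cycles among non-root states).
    """
    out_edges = {s: [(u, v) for (u, v) in edges if u == s] for s in states}
    choices = [out_edges[s] for s in states if s != root]
    if any(not c for c in choices):
        return
    for combo in itertools.product(*choices):
        succ = {u: v for (u, v) in combo}
        ok = True
        for start in succ:
            seen = set()
            node = start
            while node != root:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = succ[node]
            if not ok:
                break
        if ok:
            yield combo


def steady_state_tree(graph: KineticGraph) -> dict[str, float]:
    """Steady state by exact spanning-tree (Matrix Tree Theorem) enumeration.

    rho_i proportional to the sum over spanning trees rooted at state i of
    the product of edge rates; normalized to sum to 1.
    """
    edges = list(graph.rates)
    weights = {}
    for root in graph.states:
        total = 0.0
        for tree in _in_trees(graph.states, edges, root):
            prod = 1.0
            for e in tree:
                prod *= graph.rates[e]
            total += prod
        weights[root] = total
    Z = sum(weights.values())
    if Z <= 0:
        raise GraphError("no spanning trees found: graph is not strongly connected")
    return {s: w / Z for s, w in weights.items()}


def steady_state_nullspace(graph: KineticGraph) -> dict[str, float]:
    """Steady state as the null space of the rate (Laplacian) matrix.

    Independent linear-algebra route used as an oracle for the tree
    enumeration and as the solver for graphs with many states.
    """
    idx = {s: i for i, s in enumerate(graph.states)}
    n = len(graph.states)
    A = np.zeros((n, n))
    for (u, v), k in graph.rates.items():
        A[idx[v], idx[u]] += k
        A[idx[u], idx[u]] -= k
    ns = null_space(A)
    if ns.shape[1] != 1:
        raise GraphError("steady state is not unique (null space dimension != 1)")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-12):
        raise GraphError("negative steady-state probability: ill-posed graph")
    return {s: float(max(p[idx[s]], 0.0)) for s in graph.states}


def steady_state(graph: KineticGraph) -> dict[str, float]:
    """Per-state steady-state probabilities (sum to 1).

    Exact spanning-tree enumeration up to six states, Laplacian null space
    beyond.
    """
    if len(graph.states) <= MAX_TREE_STATES:
        return steady_state_tree(graph)
    return steady_state_nullspace(graph)


def pactive_graph(graph: KineticGraph) -> float:
    """Summed steady-state probability of the transcriptionally active states."""
    if not graph.active_states:
        raise ConfigurationError("kinetic graph has an empty active-state set")
    probs = steady_state(graph)
    return float(sum(probs[s] for s in graph.active_states))


# ---------------------------------------------------------------------------
# Sequence-dependent rates
# ---------------------------------------------------------------------------


def rates_from_energies(
    delta_e: float,
    k_on: float,
    concentration: float,
    drive: DriveSpec | None = None,
    beta: float = 1.0,
    c0: float = C0,
) -> tuple[float, float]:
    """Pseudo-first-order on-rate and sequence-dependent off-rate.

    K_d = c0 e^{beta dE}; the equilibrium off-rate is k_on * K_d, multiplied
    by e^{beta U} when the unbinding edge carries a drive.  Returns
    (k_on * concentration, k_off).
    """
    if k_on <= 0:
        raise ConfigurationError("k_on must be positive (diffusion-limited binding)")
    if concentration < 0:
        raise ConfigurationError("concentration must be >= 0")
    kd = c0 * math.exp(beta * delta_e)
    k_off = k_on * kd
    if drive is not None:
        k_off *= math.exp(beta * drive.energy)
    return k_on * concentration, k_off


# ---------------------------------------------------------------------------
# The four-state simple-activation square graph
# ---------------------------------------------------------------------------

SQUARE_STATES = ["E", "P", "A", "AP"]

#: Default active set: activator-bound states (A and AP).  The
#: polymerase-bound alternative {"P", "AP"} is selectable and is the set
#: under which a driven activator can present as a repressor.
SQUARE_ACTIVE: frozenset[str] = frozenset({"A", "AP"})


def square_activation_graph(
    e_pd: float,
    e_ad: float,
    p_conc: float,
    a_conc: float,
    k_on: float = 1.0,
    omega_ap: float = -4.0,
    drive: DriveSpec | None = None,
    beta: float = 1.0,
    active_states: frozenset[str] | set[str] = SQUARE_ACTIVE,
) -> KineticGraph:
    """The four-vertex, eight-edge square graph of a simple-activation promoter.

    States E (empty), P (RNAP bound), A (activator bound), AP (both).
    Binding edges have rate k_on * [X]; unbinding edges follow
    k_off = k_on c0 e^{beta dE}, where unbinding out of the doubly bound
    state includes the activator-RNAP interaction energy ``omega_ap``, so
    that with no drive every cycle satisfies detailed balance.  ``drive``
    multiplies one edge's rate by e^{beta U}.
    """
    rates = {
        ("E", "P"): k_on * p_conc,
        ("P", "E"): k_on * C0 * math.exp(beta * e_pd),
        ("E", "A"): k_on * a_conc,
        ("A", "E"): k_on * C0 * math.exp(beta * e_ad),
        ("P", "AP"): k_on * a_conc,
        ("AP", "P"): k_on * C0 * math.exp(beta * (e_ad + omega_ap)),
        ("A", "AP"): k_on * p_conc,
        ("AP", "A"): k_on * C0 * math.exp(beta * (e_pd + omega_ap)),
    }
    graph = KineticGraph(SQUARE_STATES, rates, frozenset(active_states))
    if drive is not None:
        graph = graph.with_drive(drive)
    return graph


def _square_pactive_vectorized(
    e_pd: np.ndarray,
    e_ad: np.ndarray,
    p_conc: float,
    a_conc: float,
    k_on: float,
    omega_ap: float,
    drive: DriveSpec | None,
    beta: float,
    active_states: frozenset[str],
) -> np.ndarray:
    """p_active for arrays of binding energies on the square graph.

    Enumerates the in-trees of the square graph once (on a template built
    from the first variant) and evaluates the tree-product sums with
    per-variant rate arrays.
    """
    template = square_activation_graph(
        float(e_pd[0]), float(e_ad[0]), p_conc, a_conc, k_on, omega_ap, None, beta,
        active_states,
    )
    edges = list(template.rates)
    rate_arrays = {
        ("E", "P"): np.full_like(e_pd, k_on * p_conc),
        ("P", "E"): k_on * C0 * np.exp(beta * e_pd),
        ("E", "A"): np.full_like(e_ad, k_on * a_conc),
        ("A", "E"): k_on * C0 * np.exp(beta * e_ad),
        ("P", "AP"): np.full_like(e_ad, k_on * a_conc),
        ("AP", "P"): k_on * C0 * np.exp(beta * (e_ad + omega_ap)),
        ("A", "AP"): np.full_like(e_pd, k_on * p_conc),
        ("AP", "A"): k_on * C0 * np.exp(beta * (e_pd + omega_ap)),
    }
    if drive is not None:
        if drive.edge not in rate_arrays:
            raise GraphError(f"driven edge {drive.edge} not in the square graph")
        rate_arrays[drive.edge] = rate_arrays[drive.edge] * math.exp(beta * drive.energy)
    weights = {}
    for root in SQUARE_STATES:
        total = np.zeros_like(e_pd)
        for tree in _in_trees(SQUARE_STATES, edges, root):
            prod = np.ones_like(e_pd)
            for e in tree:
                prod = prod * rate_arrays[e]
            total += prod
        weights[root] = total
    Z = sum(weights.values())
    return sum(weights[s] for s in active_states) / Z


def simulate_noneq_library(
    library: MutantLibrary,
    rnap_site: BindingSite,
    activator_site: BindingSite,
    params: ThermoParams,
    p_conc: float | None = None,
    a_conc: float | None = None,
    k_on: float = 1.0,
    drive: DriveSpec | None = None,
    active_states: frozenset[str] | set[str] = SQUARE_ACTIVE,
) -> pd.DataFrame:
    """Expression table from the graph-theoretic simple-activation model.

    Per-variant binding energies come from the site energy matrices; the
    off-rates follow via K_d = c0 e^{beta dE} and the steady state of the
    square graph gives p_active; counts are alpha * p_active.  The
    dimensionless concentrations default to copies/N_NS (times c0), which
    makes the undriven model agree state-for-state with the equilibrium
    states-and-weights engine.
    """
    e_pd = rnap_site.wt_energy + library_site_energies(library, rnap_site.matrix)
    e_ad = activator_site.wt_energy + library_site_energies(library, activator_site.matrix)
    p_conc = p_conc if p_conc is not None else C0 * params.P / params.N_NS
    a_conc = a_conc if a_conc is not None else C0 * params.A / params.N_NS
    p_active = _square_pactive_vectorized(
        e_pd, e_ad, p_conc, a_conc, k_on, params.omega_ap, drive,
        params.beta, frozenset(active_states),
    )
    return pd.DataFrame(
        {"variant": np.arange(library.n), "expected_count": params.alpha * p_active}
    )
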