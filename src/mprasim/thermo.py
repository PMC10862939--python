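"""Sequence-specific equilibrium models of transcription.

The central object is a states-and-weights model: every occupancy
configuration of the promoter's binding sites is enumerated, each state is
assigned a Boltzmann weight built from copy numbers, sequence-dependent
binding energies and factor-factor interaction energies, and the probability
of RNA polymerase (RNAP) being bound is the weight of the transcriptionally
active states over the partition function.

For a promoter with one repressor this reduces to the familiar

    p_bound = w_P / (1 + w_P + w_R),     w_X = (X/N_NS) exp(-beta * dE_X)

where ``N_NS`` is the number of genomic non-specific binding sites and
``dE_X`` the specific-over-non-specific binding energy of factor X.  The
generic engine here covers the six common regulatory architectures
(constitutive, simple repression, simple activation, repression-activation,
double repression, double activation) together with AND/OR/XOR logic for
dual repressors, and is complemented by:

* free-energy bookkeeping (:func:`free_energy`) and the repressor/RNAP
  weight ratio kappa used to reason about mutation rates
  (:func:`kappa`, :func:`optimal_mutation_rate`);
* MWC allosteric induction (:func:`pactive_mwc`, :func:`pbound_induction`);
* chemical-potential (fugacity) titration for binding-site copy number
  (:func:`solve_fugacity`, :func:`pbound_multicopy`);
* genome-wide non-specific RNAP binding with one bound state per promoter
  window (:func:`pbound_nonspecific`).

All energies are in kBT (beta = 1/kBT is a plain multiplier, default 1);
weights are accumulated in log space and normalized with logsumexp.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .seqlib import (
    DEFAULT_TSS_INDEX,
    EnergyMatrix,
    MutantLibrary,
    PromoterSequence,
    insert_motif,
    library_from_sequences,
    library_site_energies,
    random_promoter,
    synthetic_matrix,
    total_binding_energy,
)


class ConfigurationError(ValueError):
    """Inconsistent model configuration (unknown logic, empty active set, ...)."""


class InfeasibleError(ValueError):
    """A physical constraint cannot be satisfied (e.g. copies exceed sites)."""


# ---------------------------------------------------------------------------
# Parameters and architectures
# ---------------------------------------------------------------------------


@dataclass
class ThermoParams:
    """Copy numbers, reservoir size and interaction energies.

    Defaults reflect E. coli grown in minimal media: ~1000 RNAPs, ~10
    repressors, a genome of 4e6 bp acting as the non-specific reservoir, and
    a count scale alpha=100 mapping p_bound to a realistic mRNA count.
    ``omega_rr`` is the repressor-repressor cooperativity used under AND
    logic; ``omega_ap`` the activator-RNAP recruitment energy.
    """

    P: float = 1000.0
    R: float = 10.0
    R1: float = 10.0
    R2: float = 10.0
    A: float = 100.0
    A1: float = 100.0
    A2: float = 100.0
    N_NS: float = 4.0e6
    alpha: float = 100.0
    beta: float = 1.0
    omega_rr: float = -5.0
    omega_ap: float = -4.0

    def __post_init__(self) -> None:
        for key in ("P", "R", "R1", "R2", "A", "A1", "A2"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"copy number {key} must be >= 0")
        if self.N_NS <= 0 or self.alpha <= 0:
            raise ConfigurationError("N_NS and alpha must be positive")

    def copies(self, key: str) -> float:
        if not hasattr(self, key):
            raise ConfigurationError(f"unknown copy-number key {key!r}")
        return float(getattr(self, key))


@dataclass(frozen=True)
class BindingSite:
    """One binding site: an energy matrix plus its thermodynamic anchors.

    ``wt_energy`` is the wild-type specific binding energy (kBT, relative to
    non-specific background); the wild-type-normalized matrix adds the
    mutation-induced shift on top of it.  ``copies_key`` names the
    :class:`ThermoParams` attribute holding the factor's copy number.
    """

    matrix: EnergyMatrix
    copies_key: str
    wt_energy: float
    name: str = ""

    @property
    def role(self) -> str:
        return self.matrix.factor_role


LOGICS = ("AND", "OR", "XOR", "independent")

ActiveRule = Callable[[dict[str, bool]], bool]


@dataclass
class ArchitectureModel:
    """Binding sites, dual-repressor logic, and the transcribing-state rule.

    ``logic`` governs how two repressors combine: under ``AND`` both must be
    bound to exclude RNAP (with cooperativity ``omega_rr`` between them);
    under ``OR``/``independent`` either bound repressor excludes RNAP; under
    ``XOR`` exactly one bound repressor excludes RNAP.  ``active_rule`` maps
    a bound/unbound assignment (keyed by site name) to whether the state
    transcribes; the default declares any RNAP-bound state active with a
    uniform rate.
    """

    sites: list[BindingSite]
    logic: str = "independent"
    name: str = ""
    active_rule: ActiveRule | None = None

    def __post_init__(self) -> None:
        if self.logic not in LOGICS:
            raise ConfigurationError(f"unknown logic {self.logic!r}; expected one of {LOGICS}")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate site names in architecture: {names}")

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    def is_active(self, bound: dict[str, bool]) -> bool:
        if self.active_rule is not None:
            return bool(self.active_rule(bound))
        return any(
            bound[s.name] for s in self.sites if s.role == "polymerase"
        )

    # -- state enumeration ---------------------------------------------------

    def _represses(self, state: tuple[int, ...]) -> bool:
        bound_reps = [
            state[i] for i, s in enumerate(self.sites) if s.role == "repressor"
        ]
        k = sum(bound_reps)
        if not bound_reps:
            return False
        if len(bound_reps) == 1 or self.logic in ("OR", "independent"):
            return k >= 1
        if self.logic == "AND":
            return k == len(bound_reps)
        if self.logic == "XOR":
            return k == 1
        raise ConfigurationError(f"unknown logic {self.logic!r}")

    def allowed_states(self) -> list[tuple[int, ...]]:
        """All occupancy states compatible with steric exclusion and logic.

        A state is excluded when RNAP is bound together with a repressing
        repressor configuration; everything else coexists.
        """
        pol = [i for i, s in enumerate(self.sites) if s.role == "polymerase"]
        states = []
        for state in itertools.product((0, 1), repeat=len(self.sites)):
            if any(state[i] for i in pol) and self._represses(state):
                continue
            states.append(state)
        return states

    def interactions(self) -> list[tuple[int, int, str]]:
        """Pairs of sites carrying an interaction energy, with its params key.

        AND-logic repressor pairs interact via ``omega_rr``; every activator
        interacts with every polymerase site via ``omega_ap``.
        """
        pairs: list[tuple[int, int, str]] = []
        reps = [i for i, s in enumerate(self.sites) if s.role == "repressor"]
        if self.logic == "AND" and len(reps) == 2:
            pairs.append((reps[0], reps[1], "omega_rr"))
        pols = [i for i, s in enumerate(self.sites) if s.role == "polymerase"]
        acts = [i for i, s in enumerate(self.sites) if s.role == "activator"]
        pairs.extend((a, p, "omega_ap") for a in acts for p in pols)
        return pairs


# ---------------------------------------------------------------------------
# The generic states-and-weights engine
# ---------------------------------------------------------------------------


def _state_log_weights(
    architecture: ArchitectureModel,
    site_energies: Sequence[np.ndarray],
    params: ThermoParams,
    copies: dict[str, float | np.ndarray] | None = None,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Log weight of every allowed state, per variant.

    ``site_energies[j]`` is the per-variant total binding energy (kBT) of
    site j.  Returns (states, logW) with logW of shape (n_states, n_variants).
    """
    beta = params.beta
    states = architecture.allowed_states()
    pairs = architecture.interactions()
    log_conc = []
    for site in architecture.sites:
        c = None
        if copies is not None and site.copies_key in copies:
            c = np.asarray(copies[site.copies_key], dtype=float)
        else:
            c = np.asarray(params.copies(site.copies_key))
        with np.errstate(divide="ignore"):
            log_conc.append(np.log(c / params.N_NS))
    logW = []
    for state in states:
        lw = np.zeros(1)
        for j, occ in enumerate(state):
            if occ:
                lw = lw + log_conc[j] - beta * np.asarray(site_energies[j])
        for i, j, key in pairs:
            if state[i] and state[j]:
                lw = lw - beta * getattr(params, key)
        logW.append(np.broadcast_to(lw, np.broadcast_shapes(lw.shape, (1,))))
    shape = np.broadcast_shapes(*[w.shape for w in logW])
    return states, np.vstack([np.broadcast_to(w, shape) for w in logW])


def _site_energies_for_library(
    architecture: ArchitectureModel, library: MutantLibrary
) -> list[np.ndarray]:
    return [
        s.wt_energy + library_site_energies(library, s.matrix)
        for s in architecture.sites
    ]


def pbound_library(
    architecture: ArchitectureModel,
    library: MutantLibrary,
    params: ThermoParams,
    copies: dict[str, float | np.ndarray] | None = None,
) -> np.ndarray:
    """Per-variant probability of a transcriptionally active state.

    ``copies`` optionally overrides per-factor copy numbers, either with a
    scalar or a per-variant array (used for extrinsic noise).
    """
    energies = _site_energies_for_library(architecture, library)
    states, logW = _state_log_weights(architecture, energies, params, copies)
    names = architecture.site_names
    active = np.array(
        [architecture.is_active(dict(zip(names, map(bool, s)))) for s in states]
    )
    if not active.any():
        return np.zeros(logW.shape[1])
    log_num = logsumexp(logW[active], axis=0)
    log_den = logsumexp(logW, axis=0)
    return np.exp(log_num - log_den)


def pbound(
    architecture: ArchitectureModel,
    variant: PromoterSequence,
    params: ThermoParams,
) -> float:
    """Scalar :func:`pbound_library` for a single promoter variant."""
    lib = library_from_sequences(variant, [variant])
    return float(pbound_library(architecture, lib, params)[0])


# ---------------------------------------------------------------------------
# Default promoter, sites and the six-architecture preset registry
# ---------------------------------------------------------------------------

#: Default site placements (display coordinates, half-open) for the preset
#: architectures.  The RNAP site spans -36..-7, containing the -35 and -10
#: consensus elements; the primary repressor operator sits just downstream
#: of the TSS; additional regulator sites sit upstream, non-overlapping.
SITE_PLACEMENTS: dict[str, tuple[int, int]] = {
    "rnap": (-36, 30),
    "repressor": (1, 20),
    "repressor2": (-60, 20),
    "activator": (-60, 20),
    "activator2": (-85, 20),
}

#: Default wild-type binding energies (kBT relative to non-specific
#: background): RNAP -5 and repressor -15 are the standard lac-system
#: values; -13 for activators is a package convention giving strong but not
#: saturating activation.
WT_ENERGIES = {"polymerase": -5.0, "repressor": -15.0, "activator": -13.0}

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


def consensus_promoter(
    seed: int | None = None,
    length: int = 160,
    tss_index: int = DEFAULT_TSS_INDEX,
) -> PromoterSequence:
    """Random promoter carrying the sigma70 consensus -35/-10 elements.

    The background is uniform random (seeded); TTGACA is written at -35 and
    TATAAT at -12 so the wild type has a canonical core promoter.
    """
    p = random_promoter(length, tss_index, seed=seed)
    p = insert_motif(p, MINUS35, -35)
    p = insert_motif(p, MINUS10, -12)
    return p


def sigma70_site(
    promoter: PromoterSequence,
    strong_minus10: float = 2.0,
    strong_minus35: float = 0.1,
    weak: float = 0.02,
) -> BindingSite:
    """RNAP binding site with hexamer-concentrated specificity.

    A sigma70-like energy matrix over the default RNAP placement: mutations
    in the -10 hexamer cost ``strong_minus10`` kBT, in the -35 hexamer
    ``strong_minus35`` kBT, and elsewhere ``weak`` kBT.  The defaults mimic
    measured RNAP matrices, where specificity concentrates in the -10
    element and promoters can fire from an extended -10 with little -35
    dependence.  Because most of the information sits in the short -10
    element, windows elsewhere on the promoter that happen to carry a
    TATA-like motif can bind appreciably — the ingredient behind
    non-canonical binding-site signals in footprints.
    """
    offset, length = SITE_PLACEMENTS["rnap"]
    window = promoter.window(offset, length)
    e = np.full((length, 4), float(weak))
    rows = np.arange(offset, offset + length)
    e[(rows >= -12) & (rows <= -7)] = strong_minus10
    e[(rows >= -35) & (rows <= -30)] = strong_minus35
    codes = np.array([("ACGT").index(b) for b in window])
    e[np.arange(length), codes] = 0.0
    matrix = EnergyMatrix(e, offset, "rnap", "polymerase")
    return BindingSite(matrix, "P", WT_ENERGIES["polymerase"], "rnap")


def _site(
    promoter: PromoterSequence,
    placement: str,
    role: str,
    copies_key: str,
    mutant_energy: float = 1.0,
) -> BindingSite:
    offset, length = SITE_PLACEMENTS[placement]
    m = synthetic_matrix(
        promoter.window(offset, length), offset, role, placement, mutant_energy
    )
    return BindingSite(m, copies_key, WT_ENERGIES[role], placement)


def build_architecture(
    name: str,
    promoter: PromoterSequence,
    logic: str = "AND",
    mutant_energy: float = 1.0,
    wt_energies: dict[str, float] | None = None,
) -> ArchitectureModel:
    """Build one of the six named regulatory architectures on a promoter.

    Architectures are labelled (A, R) by the number of activator and
    repressor sites: constitutive (0,0), simple_repression (0,1),
    simple_activation (1,0), repression_activation (1,1), double_repression
    (0,2) and double_activation (2,0).  Binding sites use synthetic
    wild-type-normalized matrices (0 kBT at the wild-type base,
    ``mutant_energy`` kBT at mutant bases) at the default placements.
    ``wt_energies`` overrides wild-type binding energies per site name
    (e.g. ``{"repressor": -20.0}``).
    """
    if name not in ARCHITECTURES:
        raise ConfigurationError(
            f"unknown architecture {name!r}; expected one of {sorted(ARCHITECTURES)}"
        )
    rnap = _site(promoter, "rnap", "polymerase", "P", mutant_energy)
    sites = [rnap]
    if name == "simple_repression":
        sites.append(_site(promoter, "repressor", "repressor", "R", mutant_energy))
    elif name == "simple_activation":
        sites.append(_site(promoter, "activator", "activator", "A", mutant_energy))
    elif name == "repression_activation":
        sites.append(_site(promoter, "repressor", "repressor", "R", mutant_energy))
        sites.append(_site(promoter, "activator", "activator", "A", mutant_energy))
    elif name == "double_repression":
        sites.append(_site(promoter, "repressor", "repressor", "R1", mutant_energy))
        sites.append(_site(promoter, "repressor2", "repressor", "R2", mutant_energy))
    elif name == "double_activation":
        sites.append(_site(promoter, "activator", "activator", "A1", mutant_energy))
        sites.append(_site(promoter, "activator2", "activator", "A2", mutant_energy))
    if wt_energies:
        unknown = set(wt_energies) - {s.name for s in sites}
        if unknown:
            raise ConfigurationError(f"wt_energies for unknown sites: {sorted(unknown)}")
        sites = [
            replace(s, wt_energy=wt_energies.get(s.name, s.wt_energy)) for s in sites
        ]
    arch_logic = logic if name == "double_repression" else "independent"
    return ArchitectureModel(sites=sites, logic=arch_logic, name=name)


ARCHITECTURES: dict[str, tuple[int, int]] = {
    "constitutive": (0, 0),
    "simple_repression": (0, 1),
    "simple_activation": (1, 0),
    "repression_activation": (1, 1),
    "double_repression": (0, 2),
    "double_activation": (2, 0),
}


def binding_site_positions(architecture: ArchitectureModel) -> dict[str, np.ndarray]:
    """Display coordinates covered by each site, keyed by site name."""
    return {s.name: s.matrix.site_positions() for s in architecture.sites}


# ---------------------------------------------------------------------------
# Free energies and the kappa analysis
# ---------------------------------------------------------------------------


def free_energy(copies: float, delta_e: float, N_NS: float = 4.0e6, beta: float = 1.0) -> float:
    """Binding free energy F = dE - (1/beta) ln(copies / N_NS), in kBT.

    The first term is enthalpic (specific binding energy), the second
    entropic (availability of the factor against the non-specific
    reservoir).  ``copies == 0`` is rejected explicitly: the entropy of an
    absent species diverges.
    """
    if copies <= 0:
        raise ConfigurationError("free energy diverges at zero copies (ln 0)")
    if N_NS <= 0:
        raise ConfigurationError("N_NS must be positive")
    return float(delta_e - math.log(copies / N_NS) / beta)


@dataclass
class KappaInputs:
    """Inputs to the repressor/RNAP Boltzmann-weight ratio kappa.

    ``m_r``/``m_p`` are mutation counts in the repressor and RNAP sites; the
    theta-form replaces them with ``theta * l``.  ``dde_rd``/``dde_pd`` are
    the mean per-mutation energy shifts (kBT) and ``delta_e_rd`` /
    ``delta_e_pd`` the wild-type binding energies.
    """

    delta_e_rd: float = -15.0
    delta_e_pd: float = -5.0
    dde_rd: float = 2.24
    dde_pd: float = 0.36
    m_r: float | None = None
    m_p: float | None = None
    l_r: int = 20
    l_p: int = 20
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.l_r <= 0 or self.l_p <= 0:
            raise ConfigurationError("binding-site lengths must be positive")
        if self.theta is not None and not 0 <= self.theta <= 1:
            raise ConfigurationError("mutation rate theta must lie in [0, 1]")

    def mutation_counts(self) -> tuple[float, float]:
        if self.m_r is not None and self.m_p is not None:
            return float(self.m_r), float(self.m_p)
        if self.theta is None:
            raise ConfigurationError("provide either (m_r, m_p) or theta")
        return self.theta * self.l_r, self.theta * self.l_p

    def exponent(self) -> float:
        """Effective exponent E = dE_rd - dE_pd + m_r*dde_rd - m_p*dde_pd (kBT)."""
        m_r, m_p = self.mutation_counts()
        return (
            self.delta_e_rd - self.delta_e_pd + m_r * self.dde_rd - m_p * self.dde_pd
        )


def kappa(params: ThermoParams, inputs: KappaInputs) -> float:
    """Ratio of repressor to RNAP Boltzmann weights in a mutated library.

    kappa = (R/P) exp(-beta E) with E the effective exponent; kappa >> 1
    means the repressor dominates (RNAP-site signal lost), kappa << 1 means
    repression is invisible.
    """
    if params.P <= 0:
        raise ConfigurationError("kappa is undefined at zero RNAP copies")
    return float(params.R / params.P * math.exp(-params.beta * inputs.exponent()))


def optimal_mutation_rate(params: ThermoParams, inputs: KappaInputs) -> tuple[float, bool]:
    """Mutation rate solving kappa(theta) = 1, with a clipped-to-[0,1] flag.

    Setting the effective exponent so repressor and RNAP weights balance
    gives, in closed form,

        theta* = [ln(R/P)/beta - (dE_rd - dE_pd)] / (l_r dde_rd - l_p dde_pd).

    Returns (theta, clipped); when the unclipped solution falls outside
    [0, 1] it is clipped and flagged.
    """
    denom = inputs.l_r * inputs.dde_rd - inputs.l_p * inputs.dde_pd
    if denom == 0:
        raise ConfigurationError(
            "no unique optimal mutation rate: l_r*dde_rd == l_p*dde_pd"
        )
    if params.P <= 0 or params.R <= 0:
        raise ConfigurationError("optimal mutation rate requires positive copy numbers")
    theta = (
        math.log(params.R / params.P) / params.beta
        - (inputs.delta_e_rd - inputs.delta_e_pd)
    ) / denom
    clipped = not 0.0 <= theta <= 1.0
    return float(min(max(theta, 0.0), 1.0)), clipped


def kappa_threshold_energy(
    params: ThermoParams, inputs: KappaInputs, kappa_value: float = 0.1
) -> float:
    """Repressor binding energy at which kappa reaches ``kappa_value``.

    Solves kappa(dE_rd) = kappa_value in closed form, holding everything
    else in ``inputs`` fixed.
    """
    if kappa_value <= 0:
        raise ConfigurationError("kappa threshold must be positive")
    m_r, m_p = inputs.mutation_counts()
    rest = -inputs.delta_e_pd + m_r * inputs.dde_rd - m_p * inputs.dde_pd
    return float(
        -math.log(kappa_value * params.P / params.R) / params.beta - rest
    )


# ---------------------------------------------------------------------------
# MWC induction
# ---------------------------------------------------------------------------


@dataclass
class MWCParams:
    """Monod-Wyman-Changeux parameters for an inducible repressor.

    Defaults are the lac system's IPTG induction constants: K_A (inducer vs
    active repressor) 139 uM, K_I (vs inactive) 0.53 uM, active/inactive
    structural gap 4.5 kBT, two inducer binding sites.  ``delta_e_rdA`` and
    ``delta_e_rdI`` are the wild-type promoter binding energies of the
    active and inactive conformations; the inactive state binds only
    non-specifically by default.
    """

    K_A: float = 139e-6
    K_I: float = 0.53e-6
    delta_e_AI: float = 4.5
    c: float = 0.0
    delta_e_rdA: float = -15.0
    delta_e_rdI: float = 0.0
    n_sites: int = 2

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.K_I <= 0:
            raise ConfigurationError("dissociation constants must be positive")
        if self.c < 0:
            raise ConfigurationError("inducer concentration must be >= 0")


def pactive_mwc(c: float, mwc: MWCParams, beta: float = 1.0) -> float:
    """Probability that the repressor is in its active conformation.

    p_active = (1 + c/K_A)^n / [(1 + c/K_A)^n + e^{-beta dE_AI} (1 + c/K_I)^n]
    with n inducer binding sites (default 2).
    """
    if c < 0:
        raise ConfigurationError("inducer concentration must be >= 0")
    n = mwc.n_sites
    act = (1.0 + c / mwc.K_A) ** n
    ina = math.exp(-beta * mwc.delta_e_AI) * (1.0 + c / mwc.K_I) ** n
    return float(act / (act + ina))


def pbound_induction_library(
    architecture: ArchitectureModel,
    library: MutantLibrary,
    params: ThermoParams,
    mwc: MWCParams,
    c: float | None = None,
) -> np.ndarray:
    """p_bound for simple repression with an inducible repressor.

    The repressor pool R is split into R_A = p_active R (active, strong
    binding) and R_I = (1-p_active) R (inactive, weak binding); both
    conformations compete with RNAP through the four-state partition
    function.  The repressor site's sequence-dependent energy shift applies
    to both conformations on top of their wild-type anchors.
    """
    conc = mwc.c if c is None else c
    p_act = pactive_mwc(conc, mwc, params.beta)
    pol = [s for s in architecture.sites if s.role == "polymerase"]
    rep = [s for s in architecture.sites if s.role == "repressor"]
    if len(pol) != 1 or len(rep) != 1:
        raise ConfigurationError("induction model requires one RNAP and one repressor site")
    beta = params.beta
    e_p = pol[0].wt_energy + library_site_energies(library, pol[0].matrix)
    shift = library_site_energies(library, rep[0].matrix)
    w_p = np.log(params.P / params.N_NS) - beta * e_p
    terms = [np.zeros_like(w_p), w_p]
    with np.errstate(divide="ignore"):
        if p_act > 0:
            terms.append(
                np.log(p_act * params.R / params.N_NS)
                - beta * (mwc.delta_e_rdA + shift)
            )
        if p_act < 1:
            terms.append(
                np.log((1.0 - p_act) * params.R / params.N_NS)
                - beta * (mwc.delta_e_rdI + shift)
            )
    logZ = logsumexp(np.vstack(terms), axis=0)
    return np.exp(w_p - logZ)


def pbound_induction(
    architecture: ArchitectureModel,
    variant: PromoterSequence,
    params: ThermoParams,
    mwc: MWCParams,
    c: float | None = None,
) -> float:
    lib = library_from_sequences(variant, [variant])
    return float(pbound_induction_library(architecture, lib, params, mwc, c)[0])


# ---------------------------------------------------------------------------
# Chemical potential / binding-site copy number
# ---------------------------------------------------------------------------


def solve_fugacity(
    copies: float,
    site_energies: Sequence[float] | np.ndarray,
    N_NS: float = 4.0e6,
    beta: float = 1.0,
    rtol: float = 1e-12,
) -> float:
    """Fugacity lambda fixing the mean number of bound molecules.

    Solves  sum_j occ_j(lambda) + N_NS * lambda/(1+lambda) = copies  where
    occ_j = lambda e^{-beta e_j} / (1 + lambda e^{-beta e_j}); the specific
    sites and a zero-energy non-specific reservoir of N_NS sites share one
    chemical potential, so the partition function factorizes site by site.
    Monotone bracketed root finding in ln(lambda).
    """
    e = np.asarray(site_energies, dtype=float)
    if copies < 0:
        raise ConfigurationError("copies must be >= 0")
    if not np.all(np.isfinite(e)):
        raise ConfigurationError("site energies must be finite")
    if copies == 0:
        return 0.0
    capacity = e.size + N_NS
    if copies >= capacity:
        raise InfeasibleError(
            f"cannot bind a mean of {copies} molecules on {capacity} sites"
        )

    def occupancy_total(x: float) -> float:
        return float(expit(x - beta * e).sum() + N_NS * expit(x))

    # Initial guess from the dilute reservoir limit, then expand the bracket.
    x0 = math.log(copies / (N_NS + np.exp(-beta * e).sum()))
    lo, hi = x0 - 1.0, x0 + 1.0
    while occupancy_total(lo) > copies:
        lo -= 16.0
    while occupancy_total(hi) < copies:
        hi += 16.0
    x = brentq(lambda x: occupancy_total(x) - copies, lo, hi, xtol=1e-14, rtol=rtol)
    return float(math.exp(x))


def site_occupancies(
    lam: float, site_energies: Sequence[float] | np.ndarray, beta: float = 1.0
) -> np.ndarray:
    """Per-site occupancy lambda e^{-beta e} / (1 + lambda e^{-beta e})."""
    e = np.asarray(site_energies, dtype=float)
    if lam < 0:
        raise ConfigurationError("fugacity must be >= 0")
    if lam == 0:
        return np.zeros_like(e)
    return expit(math.log(lam) - beta * e)


def pbound_multicopy_library(
    architecture: ArchitectureModel,
    library: MutantLibrary,
    params: ThermoParams,
    n_sites: int,
) -> np.ndarray:
    """p_bound when the repressor's binding site exists in ``n_sites`` copies.

    All copies carry the variant's site sequence (a plasmid system delivers
    identical promoter copies).  The repressor is placed grand-canonically:
    the fugacity is solved so the mean bound number over the n_sites
    specific copies plus the non-specific reservoir equals R, and the
    reporter's repressor weight becomes lambda e^{-beta e_r} in place of the
    single-site (R/N_NS) e^{-beta e_r}.
    """
    if n_sites < 1:
        raise ConfigurationError("binding-site copy number must be >= 1")
    pol = [s for s in architecture.sites if s.role == "polymerase"]
    rep = [s for s in architecture.sites if s.role == "repressor"]
    if len(pol) != 1 or len(rep) != 1:
        raise ConfigurationError("multicopy model requires one RNAP and one repressor site")
    beta = params.beta
    e_p = pol[0].wt_energy + library_site_energies(library, pol[0].matrix)
    e_r = rep[0].wt_energy + library_site_energies(library, rep[0].matrix)
    R = params.copies(rep[0].copies_key)
    w_p = params.P / params.N_NS * np.exp(-beta * e_p)
    w_r = np.empty_like(e_r)
    for i, er in enumerate(e_r):
        lam = solve_fugacity(R, np.full(n_sites, er), params.N_NS, beta)
        w_r[i] = lam * math.exp(-beta * er)
    return w_p / (1.0 + w_p + w_r)


def pbound_multicopy(
    architecture: ArchitectureModel,
    variant: PromoterSequence,
    params: ThermoParams,
    n_sites: int,
) -> float:
    lib = library_from_sequences(variant, [variant])
    return float(pbound_multicopy_library(architecture, lib, params, n_sites)[0])


# ---------------------------------------------------------------------------
# Genome-wide non-specific RNAP binding
# ---------------------------------------------------------------------------


def window_energies(
    library: MutantLibrary, rnap_site: BindingSite
) -> np.ndarray:
    """(n, n_windows) binding energy of RNAP at every promoter window.

    Window i starts at string index i (i = 0 .. L - l_p); its energy is the
    site's wild-type anchor plus the matrix mapped onto the window sequence,
    so the canonical window of the wild type scores exactly ``wt_energy``.
    """
    M = rnap_site.matrix.energies
    l = rnap_site.matrix.site_length
    L = library.length
    if L < l:
        raise ConfigurationError("promoter shorter than the RNAP matrix")
    n_windows = L - l + 1
    E = np.zeros((library.n, n_windows))
    for j in range(l):
        E += M[j, library.codes[:, j : j + n_windows]]
    return rnap_site.wt_energy + E


def pbound_nonspecific_library(
    architecture: ArchitectureModel,
    library: MutantLibrary,
    params: ThermoParams,
    active_windows: np.ndarray | Sequence[int] | None = None,
    allowed_windows: np.ndarray | Sequence[int] | None = None,
) -> np.ndarray:
    """p_bound with one RNAP-bound state per promoter window.

    Every window start i in [0, L - l_p] is a mutually exclusive RNAP-bound
    state with weight (P/N_NS) e^{-beta dE_pd,i}.  If the architecture has a
    repressor site, repressor-bound states coexist with RNAP bound at
    windows that do not overlap the operator, while overlapping windows are
    sterically excluded; the canonical window is always repressible (bound
    RNAP's physical footprint extends downstream of its energy-matrix site
    across the TSS, which is what makes a downstream operator repress at
    all).  By default every RNAP-bound state transcribes;
    ``active_windows`` restricts transcription to a declared start-site set
    (windows still contribute to the partition function).  ``allowed_windows``
    restricts which windows exist at all (used for degenerate limits).
    """
    pol = [s for s in architecture.sites if s.role == "polymerase"]
    rep = [s for s in architecture.sites if s.role == "repressor"]
    if len(pol) != 1 or len(rep) > 1:
        raise ConfigurationError(
            "non-specific binding model requires one RNAP site and at most one repressor"
        )
    beta = params.beta
    E = window_energies(library, pol[0])
    n_windows = E.shape[1]
    window_idx = np.arange(n_windows)
    if allowed_windows is not None:
        keep = np.isin(window_idx, np.asarray(allowed_windows))
        if not keep.any():
            raise ConfigurationError("allowed_windows excludes every window")
        E = E[:, keep]
        window_idx = window_idx[keep]
    logw = math.log(params.P / params.N_NS) - beta * E  # (n, W)

    active = np.ones(window_idx.size, dtype=bool)
    if active_windows is not None:
        active = np.isin(window_idx, np.asarray(active_windows))

    if rep:
        site = rep[0]
        e_r = site.wt_energy + library_site_energies(library, site.matrix)
        logw_r = np.log(params.copies(site.copies_key) / params.N_NS) - beta * e_r
        start = library.wild_type.to_index(site.matrix.offset)
        stop = start + site.matrix.site_length
        l_p = pol[0].matrix.site_length
        overlaps = (window_idx + l_p > start) & (window_idx < stop)
        canonical = library.wild_type.to_index(pol[0].matrix.offset)
        overlaps |= window_idx == canonical
        # States: empty; R; P at window i; (R and P at non-overlapping i).
        co = logw[:, ~overlaps] + logw_r[:, None]
        num_parts = [logw[:, active]]
        den_parts = [np.zeros((library.n, 1)), logw_r[:, None], logw]
        if co.shape[1]:
            den_parts.append(co)
            co_active = logw[:, ~overlaps & active] + logw_r[:, None]
            if co_active.shape[1]:
                num_parts.append(co_active)
        log_num = logsumexp(np.concatenate(num_parts, axis=1), axis=1)
        log_den = logsumexp(np.concatenate(den_parts, axis=1), axis=1)
    else:
        log_num = logsumexp(logw[:, active], axis=1)
        log_den = logsumexp(
            np.concatenate([np.zeros((library.n, 1)), logw], axis=1), axis=1
        )
    return np.exp(log_num - log_den)


def pbound_nonspecific(
    architecture: ArchitectureModel,
    variant: PromoterSequence,
    params: ThermoParams,
    **kwargs,
) -> float:
    lib = library_from_sequences(variant, [variant])
    return float(pbound_nonspecific_library(architecture, lib, params, **kwargs)[0])


def window_state_probabilities(
    architecture: ArchitectureModel,
    variant: PromoterSequence,
    params: ThermoParams,
) -> np.ndarray:
    """Probability of RNAP occupying each window (diagnostic; sums to < 1)."""
    lib = library_from_sequences(variant, [variant])
    pol = [s for s in architecture.sites if s.role == "polymerase"][0]
    beta = params.beta
    logw = math.log(params.P / params.N_NS) - beta * window_energies(lib, pol)[0]
    logZ = logsumexp(np.concatenate([[0.0], logw]))
    return np.exp(logw - logZ)
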