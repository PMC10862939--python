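"""Equilibrium occupancy models: engine vs closed forms, free energies,
kappa, MWC induction, chemical-potential titration, non-specific binding."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mprasim.seqlib import library_from_sequences, mutagenize, synthetic_matrix
from mprasim.thermo import (
    ArchitectureModel,
    ConfigurationError,
    InfeasibleError,
    KappaInputs,
    MWCParams,
    ThermoParams,
    _site,
    build_architecture,
    consensus_promoter,
    free_energy,
    kappa,
    kappa_threshold_energy,
    optimal_mutation_rate,
    pactive_mwc,
    pbound,
    pbound_induction,
    pbound_induction_library,
    pbound_library,
    pbound_multicopy,
    pbound_multicopy_library,
    pbound_nonspecific,
    pbound_nonspecific_library,
    sigma70_site,
    site_occupancies,
    solve_fugacity,
    window_state_probabilities,
)
from mprasim.seqlib import library_site_energies


def closed_form_pbound(name, logic, w_p, w_r1, w_r2, w_a1, w_a2, g_ap, g_rr):
    """Hand-written states-and-weights expressions for the six architectures."""
    if name == "constitutive":
        return w_p / (1 + w_p)
    if name == "simple_repression":
        return w_p / (1 + w_p + w_r1)
    if name == "simple_activation":
        num = w_p + w_a1 * w_p * g_ap
        return num / (1 + w_p + w_a1 + num - w_p)
    if name == "repression_activation":
        num = w_p + w_a1 * w_p * g_ap
        den = 1 + w_p + w_a1 + w_a1 * w_p * g_ap + w_r1 + w_r1 * w_a1
        return num / den
    if name == "double_repression":
        if logic == "AND":
            num = w_p * (1 + w_r1 + w_r2)
            den = 1 + w_p + w_r1 + w_r2 + w_r1 * w_r2 * g_rr + w_p * (w_r1 + w_r2)
        elif logic == "OR":
            num = w_p
            den = 1 + w_p + w_r1 + w_r2 + w_r1 * w_r2
        else:  # XOR: only a lone repressor represses
            num = w_p * (1 + w_r1 * w_r2)
            den = 1 + w_p + w_r1 + w_r2 + w_r1 * w_r2 + w_p * w_r1 * w_r2
        return num / den
    if name == "double_activation":
        act = 1 + w_a1 * g_ap + w_a2 * g_ap + w_a1 * w_a2 * g_ap**2
        num = w_p * act
        den = 1 + w_a1 + w_a2 + w_a1 * w_a2 + num
        return num / den
    raise AssertionError(name)


@pytest.mark.parametrize(
    "name,logic",
    [
        ("constitutive", "independent"),
        ("simple_repression", "independent"),
        ("simple_activation", "independent"),
        ("repression_activation", "independent"),
        ("double_repression", "AND"),
        ("double_repression", "OR"),
        ("double_repression", "XOR"),
        ("double_activation", "independent"),
    ],
)
def test_engine_matches_closed_form_on_random_variants(promoter, params, name, logic):
    """The generic state engine reproduces hand-enumerated partition functions."""
    arch = build_architecture(name, promoter, logic=logic)
    lib = mutagenize(promoter, 100, 0.15, seed=21)
    got = pbound_library(arch, lib, params)
    energies = {s.name: s.wt_energy + library_site_energies(lib, s.matrix) for s in arch.sites}
    copies = {s.name: params.copies(s.copies_key) for s in arch.sites}

    def w(site):
        if site not in energies:
            return np.zeros(lib.n)
        return copies[site] / params.N_NS * np.exp(-params.beta * energies[site])

    expect = closed_form_pbound(
        name,
        logic,
        w("rnap"),
        w("repressor"),
        w("repressor2"),
        w("activator"),
        w("activator2"),
        math.exp(-params.beta * params.omega_ap),
        math.exp(-params.beta * params.omega_rr),
    )
    assert np.allclose(got, expect, rtol=1e-12, atol=0)
    assert np.all((got > 0) & (got < 1))


def test_simple_repression_reduces_to_constitutive_at_zero_r(promoter):
    arch = build_architecture("simple_repression", promoter)
    params = ThermoParams(R=0.0)
    w_p = params.P / params.N_NS * math.exp(5.0)
    assert pbound(arch, promoter, params) == pytest.approx(w_p / (1 + w_p), rel=1e-12)


def test_printed_boltzmann_weights(params):
    """RNAP weight ~0.04 and repressor weight ~8 at the standard lac parameters."""
    w_p = params.P / params.N_NS * math.exp(-params.beta * -5.0)
    w_r = params.R / params.N_NS * math.exp(-params.beta * -15.0)
    assert w_p == pytest.approx(0.04, abs=0.005)
    assert round(w_r) == 8


def test_weak_polymerase_simplification_within_bound(promoter, params):
    """Dropping w_P from the denominator changes p_bound by < 4%."""
    arch = build_architecture("simple_repression", promoter)
    full = pbound(arch, promoter, params)
    w_p = params.P / params.N_NS * math.exp(5.0)
    w_r = params.R / params.N_NS * math.exp(15.0)
    simplified = w_p / (1 + w_r)
    assert abs(simplified - full) / full < 0.04


def test_double_repression_and_logic_hand_enumeration(promoter, params):
    """AND logic: 7 states including the two single-repressor-plus-RNAP states."""
    arch = build_architecture("double_repression", promoter, logic="AND")
    lib = library_from_sequences(promoter, [promoter])
    e1 = arch.sites[1].wt_energy
    e2 = arch.sites[2].wt_energy
    w_p = params.P / params.N_NS * math.exp(5.0)
    w1 = params.R1 / params.N_NS * math.exp(-e1)
    w2 = params.R2 / params.N_NS * math.exp(-e2)
    coop = math.exp(-params.omega_rr)
    Z = 1 + w_p + w1 + w2 + w1 * w2 * coop + w_p * w1 + w_p * w2
    expect = w_p * (1 + w1 + w2) / Z
    assert pbound_library(arch, lib, params)[0] == pytest.approx(expect, rel=1e-12)


def test_monotone_in_repressor_and_activator_copy_number(promoter):
    rep = build_architecture("simple_repression", promoter)
    act = build_architecture("simple_activation", promoter)
    p_rep = [pbound(rep, promoter, ThermoParams(R=r)) for r in (0, 1, 10, 100, 1000)]
    assert np.all(np.diff(p_rep) < 0)
    p_act = [pbound(act, promoter, ThermoParams(A=a)) for a in (0, 1, 10, 100, 1000)]
    assert np.all(np.diff(p_act) > 0)


def test_unknown_logic_rejected(promoter):
    with pytest.raises(ConfigurationError):
        ArchitectureModel(sites=[], logic="NAND")


class TestFreeEnergy:
    def test_weak_operator_value(self):
        assert free_energy(10, -10.0, 4e6) == pytest.approx(3.0, abs=0.15)

    def test_strong_operator_value(self):
        assert free_energy(10, -20.0, 4e6) == pytest.approx(-7.0, abs=0.15)

    def test_reference_state_is_zero(self):
        assert free_energy(4e6, 0.0, 4e6) == 0.0

    def test_zero_copies_raises(self):
        with pytest.raises(ConfigurationError):
            free_energy(0, -10.0)

    def test_weak_polymerase_identity(self, promoter, params):
        """p_bound ~ e^{-beta F_P} / (1 + e^{-beta F_R}) in the weak-RNAP limit."""
        arch = build_architecture("simple_repression", promoter)
        f_p = free_energy(params.P, -5.0, params.N_NS)
        f_r = free_energy(params.R, -15.0, params.N_NS)
        approx = math.exp(-f_p) / (1 + math.exp(-f_r))
        assert pbound(arch, promoter, params) == pytest.approx(approx, rel=0.04)


class TestKappa:
    def test_unity_at_symmetry(self):
        params = ThermoParams(R=1000.0, P=1000.0)
        inputs = KappaInputs(delta_e_rd=-5.0, delta_e_pd=-5.0, m_r=0, m_p=0)
        assert kappa(params, inputs) == pytest.approx(1.0)

    def test_prefactor_at_two_mutations(self, params):
        """kappa = prefactor * e^{-beta dE_rd} with prefactor ~1.5e-6."""
        inputs = KappaInputs(delta_e_rd=0.0, m_r=2, m_p=2)
        prefactor = kappa(params, inputs)
        assert prefactor == pytest.approx(1.5e-6, rel=0.05)

    def test_length_weighted_energy_combination(self):
        inputs = KappaInputs()
        assert inputs.l_r * inputs.dde_rd - inputs.l_p * inputs.dde_pd == pytest.approx(37.6)

    def test_threshold_energy_near_minus_eleven(self, params):
        e = kappa_threshold_energy(params, KappaInputs(m_r=2, m_p=2), kappa_value=0.1)
        assert round(e) == -11
        # consistency: kappa at the threshold energy equals 0.1
        inputs = KappaInputs(delta_e_rd=e, m_r=2, m_p=2)
        assert kappa(params, inputs) == pytest.approx(0.1, rel=1e-10)

    def test_zero_polymerase_rejected(self):
        with pytest.raises(ConfigurationError):
            kappa(ThermoParams(P=0.0), KappaInputs(m_r=0, m_p=0))


class TestOptimalMutationRate:
    def test_zero_at_full_symmetry(self):
        params = ThermoParams(R=1000.0, P=1000.0)
        inputs = KappaInputs(delta_e_rd=-5.0, delta_e_pd=-5.0)
        theta, clipped = optimal_mutation_rate(params, inputs)
        assert theta == pytest.approx(0.0, abs=1e-12)
        assert not clipped

    def test_agrees_with_bisection_oracle(self, params):
        inputs = KappaInputs()
        theta, clipped = optimal_mutation_rate(params, inputs)
        assert not clipped

        def kappa_minus_one(t):
            return kappa(params, KappaInputs(theta=t)) - 1.0

        root = brentq(kappa_minus_one, 0.0, 1.0, xtol=1e-14)
        assert theta == pytest.approx(root, abs=1e-10)

    def test_degenerate_denominator_raises(self, params):
        with pytest.raises(ConfigurationError):
            optimal_mutation_rate(params, KappaInputs(dde_rd=0.36, dde_pd=0.36))


class TestMWC:
    def test_zero_inducer_closed_form(self):
        mwc = MWCParams()
        expect = 1.0 / (1.0 + math.exp(-mwc.delta_e_AI))
        assert pactive_mwc(0.0, mwc) == pytest.approx(expect, rel=1e-12)

    def test_large_structural_gap_forces_active(self):
        mwc = MWCParams(delta_e_AI=100.0)
        assert pactive_mwc(1e-3, mwc) == pytest.approx(1.0, abs=1e-12)

    def test_three_term_ratio_at_c_equals_ka(self):
        mwc = MWCParams()
        c = mwc.K_A
        act = (1 + c / mwc.K_A) ** 2
        ina = math.exp(-mwc.delta_e_AI) * (1 + c / mwc.K_I) ** 2
        assert pactive_mwc(c, mwc) == pytest.approx(act / (act + ina), rel=1e-12)

    def test_fully_active_reduces_to_simple_repression(self, promoter, params):
        arch = build_architecture("simple_repression", promoter)
        mwc = MWCParams(delta_e_AI=200.0, delta_e_rdA=-15.0)  # p_active = 1
        assert pbound_induction(arch, promoter, params, mwc, 0.0) == pytest.approx(
            pbound(arch, promoter, params), rel=1e-9
        )

    def test_saturating_inducer_approaches_constitutive(self, promoter, params):
        arch = build_architecture("simple_repression", promoter)
        mwc = MWCParams(delta_e_rdI=5.0)
        con = build_architecture("constitutive", promoter)
        high = pbound_induction(arch, promoter, params, mwc, 1.0)
        # at 1 M inducer a small active fraction survives, so agreement is
        # close but not exact
        assert high == pytest.approx(pbound(con, promoter, params), rel=0.05)

    def test_pbound_monotone_in_inducer(self, promoter, params):
        arch = build_architecture("simple_repression", promoter)
        mwc = MWCParams()
        cs = np.geomspace(1e-9, 1e-2, 12)
        vals = [pbound_induction(arch, promoter, params, mwc, c) for c in cs]
        assert np.all(np.diff(vals) > 0)


def canonical_occupancies(energies, n_particles, beta=1.0, first=None):
    """Exact fixed-N occupancies via elementary symmetric polynomials.

    Sites with Boltzmann factors x_j = e^{-beta e_j}; the canonical
    partition function with N indistinguishable particles on distinct
    sites is the elementary symmetric polynomial e_N(x), and the occupancy
    of site j is x_j e_{N-1}(x without j) / e_N(x).  ``first`` limits the
    output to the first k sites (the rest still shape the ensemble).
    """
    x = np.exp(-beta * np.asarray(energies, dtype=float))
    M, N = x.size, n_particles
    k = M if first is None else first

    def esp(values, upto):
        e = np.zeros(upto + 1)
        e[0] = 1.0
        for v in values:
            e[1 : upto + 1] = e[1 : upto + 1] + v * e[0:upto]
        return e

    eN = esp(x, N)[N]
    occ = np.empty(k)
    for j in range(k):
        others = np.delete(x, j)
        occ[j] = x[j] * esp(others, N - 1)[N - 1] / eN
    return occ


class TestFugacity:
    def test_zero_copies_zero_everything(self):
        assert solve_fugacity(0, [0.0, -1.0], N_NS=10) == 0.0
        assert np.all(site_occupancies(0.0, [0.0, -1.0]) == 0.0)

    def test_degenerate_sites_match_canonical_enumeration_exactly(self):
        """Equal-energy sites: grand-canonical equals fixed-N occupancy."""
        energies = [0.0, 0.0]
        lam = solve_fugacity(1, energies, N_NS=2)
        occ = site_occupancies(lam, energies)
        expect = canonical_occupancies([0.0, 0.0, 0.0, 0.0], 1)[:2]
        assert np.allclose(occ, expect, atol=1e-10)

    def test_large_reservoir_converges_to_canonical_enumeration(self):
        """Ensemble equivalence: mean-constrained occupancies approach the
        exact fixed-N result as the reservoir grows."""
        specific = [-10.0, -11.5]
        N_NS, copies = 10_000, 10
        lam = solve_fugacity(copies, specific, N_NS=N_NS)
        occ = site_occupancies(lam, specific)
        exact = canonical_occupancies(specific + [0.0] * N_NS, copies, first=2)
        assert np.allclose(occ, exact, atol=1e-2)

    def test_particle_number_conserved(self):
        rng = np.random.default_rng(8)
        energies = rng.uniform(-12, 0, 20)
        lam = solve_fugacity(7.5, energies, N_NS=1000)
        total = site_occupancies(lam, energies).sum() + 1000 * lam / (1 + lam)
        assert total == pytest.approx(7.5, rel=1e-9)

    def test_fifty_identical_sites_share_ten_repressors(self):
        energies = np.full(50, -15.0)
        lam = solve_fugacity(10, energies, N_NS=4e6)
        occ = site_occupancies(lam, energies)
        assert np.all(occ < 10 / 50)

    def test_infeasible_constraint_raises(self):
        with pytest.raises(InfeasibleError):
            solve_fugacity(5, [0.0, 0.0], N_NS=2)


class TestMulticopy:
    def test_single_copy_agrees_with_standard_model_within_depletion_bound(
        self, promoter, params, simple_repression
    ):
        """With one binding-site copy the grand-canonical model matches the
        standard p_bound up to the reporter site's self-depletion of the
        repressor pool (occupancy / R)."""
        single = pbound_multicopy(simple_repression, promoter, params, 1)
        standard = pbound(simple_repression, promoter, params)
        rep = simple_repression.sites[1]
        lam = solve_fugacity(params.R, [rep.wt_energy], params.N_NS)
        occ = float(site_occupancies(lam, [rep.wt_energy])[0])
        bound = occ / params.R
        assert abs(single - standard) / standard < 2 * bound + 1e-3

    def test_monotone_in_site_copies_and_titration_limit(
        self, promoter, params, simple_repression
    ):
        cons = build_architecture("constitutive", promoter)
        constitutive = pbound(cons, promoter, params)
        vals = [
            pbound_multicopy(simple_repression, promoter, params, n)
            for n in (1, 2, 5, 10, 50, 200, 5000)
        ]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(constitutive, rel=0.05)

    def test_invalid_copy_number(self, promoter, params, simple_repression):
        with pytest.raises(ConfigurationError):
            pbound_multicopy(simple_repression, promoter, params, 0)


class TestNonspecific:
    def test_canonical_only_window_reduces_to_single_site(self, promoter, params):
        rep = _site(promoter, "repressor", "repressor", "R")
        arch = ArchitectureModel([sigma70_site(promoter), rep], name="simple_repression")
        canonical = promoter.to_index(-36)
        restricted = pbound_nonspecific(
            arch, promoter, params, allowed_windows=[canonical]
        )
        w_p = params.P / params.N_NS * math.exp(5.0)
        w_r = params.R / params.N_NS * math.exp(15.0)
        assert restricted == pytest.approx(w_p / (1 + w_p + w_r), rel=1e-12)

    def test_window_probabilities_sum_below_one_and_match_partition_function(
        self, promoter, params
    ):
        arch = ArchitectureModel([sigma70_site(promoter)], name="constitutive")
        probs = window_state_probabilities(arch, promoter, params)
        assert probs.sum() < 1.0
        # brute-force partition function over all windows
        site = arch.sites[0]
        lib = library_from_sequences(promoter, [promoter])
        from mprasim.thermo import window_energies

        E = window_energies(lib, site)[0]
        w = params.P / params.N_NS * np.exp(-E)
        assert np.allclose(probs, w / (1 + w.sum()), rtol=1e-10)
        assert pbound_nonspecific(arch, promoter, params) == pytest.approx(
            w.sum() / (1 + w.sum()), rel=1e-10
        )

    def test_tagaat_insertion_strengthens_upstream_windows(self, params):
        """Inserting a near-consensus -10 motif at -80 raises the summed
        weight of windows overlapping the insertion."""
        from mprasim.seqlib import insert_motif
        from mprasim.thermo import window_energies

        p = consensus_promoter(seed=1)
        p2 = insert_motif(p, "TAGAAT", -80)
        total = {}
        for tag, prom in (("before", p), ("after", p2)):
            site = sigma70_site(prom)
            lib = library_from_sequences(prom, [prom])
            E = window_energies(lib, site)[0]
            w = params.P / params.N_NS * np.exp(-E)
            sel = slice(p.to_index(-80) - site.matrix.site_length + 1, p.to_index(-80) + 6)
            total[tag] = w[sel].sum()
        assert total["after"] > 3 * total["before"]
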