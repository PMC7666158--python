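"""Reaction expansion, mass-action RHS and conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoswitch import ModelParameters, ReactionNetwork, build_reactions
from phosphoswitch.network import InternalConsistencyError, Reaction
from phosphoswitch.species import (
    ATF2_FREE,
    ATF2_JNK,
    JNK_FREE,
    ComplexSpecies,
    RuleSet,
    enumerate_species,
)


def test_jnk_binding_rule_alone_counts():
    """2 JNK activity states x 8 ATF2 states: 16 kon1 + 16 koff1 reactions."""
    rules = RuleSet(jnk_binding=True, p38_bipartite=False, p38_drs=False,
                    jnk_catalysis=False, p38_catalysis=False,
                    mapk_activation=False, mapk_dephosphorylation=False,
                    atf2_dephosphorylation=False)
    rxns = build_reactions(enumerate_species(rules), rules)
    assert sum(r.rate_name == "kon1" for r in rxns) == 16
    assert sum(r.rate_name == "koff1" for r in rxns) == 16
    assert len(rxns) == 32


def test_dp3_reaction_count_on_full_network():
    """Independent count: species carrying pT69 / pT71 on the 44-species net."""
    species = enumerate_species()
    n_pt69 = sum(1 for s in species if s.t69 == "P")
    n_pt71 = sum(1 for s in species if s.t71 == "P")
    assert (n_pt69, n_pt71) == (20, 20)
    rxns = build_reactions(species)
    assert sum(r.rate_name == "dp3" for r in rxns) == n_pt69 + n_pt71 == 40


def test_empty_rule_set_gives_no_reactions():
    rules = RuleSet.none()
    assert build_reactions(enumerate_species(rules), rules) == []


def test_every_binding_reaction_has_matching_reverse():
    rxns = build_reactions(enumerate_species())
    pairs = {"kon1": "koff1", "kon2": "koff2", "kon3": "koff3"}
    by_name = {}
    for r in rxns:
        by_name.setdefault(r.rate_name, []).append(r)
    for fwd, rev in pairs.items():
        assert len(by_name[fwd]) == len(by_name[rev])
        reverse_index = {
            (frozenset(r.reactants), frozenset(r.products)) for r in by_name[rev]
        }
        for r in by_name[fwd]:
            assert (frozenset(r.products), frozenset(r.reactants)) in reverse_index


def test_reactions_balance_molecule_counts():
    with pytest.raises(InternalConsistencyError):
        Reaction(
            (ComplexSpecies(ATF2_FREE, "U", "U", "U"),),
            (ComplexSpecies(ATF2_JNK, "U", "U", "U", "np"),),
            "kon1",
        )


def test_rhs_zero_rates_gives_zero_vector(wt_network):
    params = ModelParameters().updated(
        **{n: 0.0 for n in ("kon1", "koff1", "kon2", "koff2", "kon3", "koff3",
                            "k1", "k2", "k3", "k4", "k_eq6", "k_eq7",
                            "dp1", "dp2", "dp3", "dp4")}
    )
    k = wt_network.rate_vector(params)
    state = wt_network.initial_state(params)
    assert np.all(wt_network.rhs(state, k) == 0.0)


def test_rhs_single_binding_hand_calculation():
    """np-JNK + ATF2 at 1 µM each, kon1 = 0.1: complex forms at 0.1 µM/s."""
    net = ReactionNetwork.build("WT")
    params = ModelParameters().updated(
        **{n: 0.0 for n in ("koff1", "kon2", "koff2", "kon3", "koff3",
                            "k1", "k2", "k3", "k4", "k_eq6", "k_eq7",
                            "dp1", "dp2", "dp3", "dp4")},
        kon1=0.1,
    )
    state = net.initial_state(params)
    dcdt = net.rhs(state, net.rate_vector(params))
    complex_idx = net.index[ComplexSpecies(ATF2_JNK, "U", "U", "U", "np")]
    assert dcdt[complex_idx] == pytest.approx(0.1)
    assert dcdt[net.index[ComplexSpecies(ATF2_FREE, "U", "U", "U")]] == pytest.approx(-0.1)
    assert dcdt[net.index[ComplexSpecies(JNK_FREE, act="np")]] == pytest.approx(-0.1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_rhs_conserves_molecule_weighted_sums(seed):
    """ATF2-, JNK- and p38-weighted derivative sums vanish for any state."""
    net = ReactionNetwork.build("WT")
    params = ModelParameters()
    rng = np.random.default_rng(seed)
    state = rng.uniform(0.0, 1.0, net.n_species)
    dcdt = net.rhs(state, net.rate_vector(params, stimulated=True))
    for w in (net.w_atf2, net.w_jnk, net.w_p38):
        assert abs(w @ dcdt) < 1e-12


def test_jacobian_matches_finite_differences(wt_network, rng):
    params = ModelParameters()
    k = wt_network.rate_vector(params, stimulated=True)
    x = rng.uniform(0.05, 0.5, wt_network.n_species)
    jac = wt_network.jacobian(x, k)
    # the RHS is quadratic, so central differences are exact up to the
    # cancellation noise of the largest flux terms (koff3 ~ 100 µM/s)
    eps = 1e-6
    for j in rng.choice(wt_network.n_species, size=8, replace=False):
        dx = np.zeros_like(x)
        dx[j] = eps
        col = (wt_network.rhs(x + dx, k) - wt_network.rhs(x - dx, k)) / (2 * eps)
        assert np.allclose(jac[:, j], col, rtol=1e-6, atol=1e-7)


def test_rhs_dimension_mismatch_raises(wt_network):
    params = ModelParameters()
    with pytest.raises(ValueError, match="species count"):
        wt_network.rhs(np.zeros(3), wt_network.rate_vector(params))


def test_variant_overrides_applied_exactly_once():
    base = ModelParameters()
    s90n = base.with_variant("S90N")
    assert s90n.k2 == 0.0
    assert s90n.kon2 == pytest.approx(4.5 * base.kon2)
    jnkin8 = base.with_variant("JNK_IN_8")
    assert jnkin8.k1 == jnkin8.k2 == 0.0
    with pytest.raises(Exception):
        s90n.with_variant("S90N")
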