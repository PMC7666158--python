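"""Reaction-network expansion and mass-action ODE right-hand side.

The rule set is expanded into an explicit list of mass-action reactions:

* reversible binding (kon1/koff1 for JNK, kon2/koff2 for the bipartite
  pp-p38 complex, kon3/koff3 for weak D-motif-only p38 binding);
* first-order catalysis from the bound complex (k1/k2 for pp-JNK,
  k3/k4 for pp-p38, with the slower k4 used for T71 once T69 is
  phosphorylated);
* first-order MAPK activation (k6/k7, resolved per protocol phase to
  the basal or stimulated value) and deactivation (dp1/dp2), restricted
  to free MAPKs because upstream kinases and phosphatases compete with
  substrate for the same docking surface;
* site dephosphorylation (dp3 for pT69/pT71, dp4 for pS90) acting on
  ATF2 regardless of its binding state, except where the product would
  violate a binding-eligibility constraint (dp4 on the pp-p38 DRS-only
  complex, whose existence requires pS90).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace, field

import numpy as np

from .params import ModelParameters
from .species import (
    ATF2_FREE,
    ATF2_JNK,
    ATF2_P38,
    JNK_FREE,
    P38_FREE,
    ComplexSpecies,
    ConfigurationError,
    RuleSet,
    bipartite_eligible,
    drs_only_eligible,
    enumerate_species,
)


class InternalConsistencyError(RuntimeError):
    """A generated reaction references a species outside the network."""


@dataclass(frozen=True, slots=True)
class Reaction:
    """A mass-action reaction with a symbolic rate-constant name."""

    reactants: tuple[ComplexSpecies, ...]
    products: tuple[ComplexSpecies, ...]
    rate_name: str

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ConfigurationError("reactions must be uni- or bimolecular")
        for counter in ("n_atf2", "n_jnk", "n_p38"):
            lhs = sum(getattr(s, counter) for s in self.reactants)
            rhs = sum(getattr(s, counter) for s in self.products)
            if lhs != rhs:
                raise InternalConsistencyError(
                    f"{counter} not balanced in {self.rate_name} reaction"
                )


def _bind(atf2: ComplexSpecies, kind: str, act: str, mode: str | None) -> ComplexSpecies:
    return ComplexSpecies(kind, atf2.t69, atf2.t71, atf2.s90, act, mode)


def build_reactions(
    species: list[ComplexSpecies],
    rules: RuleSet | None = None,
    variant: str = "WT",
) -> list[Reaction]:
    """Expand the rule set over ``species`` into explicit reactions.

    ``species`` must come from :func:`enumerate_species` with the same
    rule set and variant.
    """
    rules = (rules or RuleSet()).for_variant(variant)
    have = set(species)
    rxns: list[Reaction] = []

    def emit(reactants, products, rate_name):
        for s in (*reactants, *products):
            if s not in have:
                raise InternalConsistencyError(
                    f"reaction {rate_name} references species {s.name()} "
                    "absent from the network"
                )
        rxns.append(Reaction(tuple(reactants), tuple(products), rate_name))

    free_atf2 = [s for s in species if s.kind == ATF2_FREE]
    jnk_complexes = [s for s in species if s.kind == ATF2_JNK]
    p38_complexes = [s for s in species if s.kind == ATF2_P38]

    # --- binding ------------------------------------------------------
    if rules.jnk_binding:
        for a in free_atf2:
            for act in ("np", "pp"):
                c = _bind(a, ATF2_JNK, act, None)
                j = ComplexSpecies(JNK_FREE, act=act)
                emit([a, j], [c], "kon1")
                emit([c], [a, j], "koff1")
    if rules.p38_bipartite:
        for a in free_atf2:
            if bipartite_eligible("pp", a.s90):
                c = _bind(a, ATF2_P38, "pp", "bipartite")
                p = ComplexSpecies(P38_FREE, act="pp")
                emit([a, p], [c], "kon2")
                emit([c], [a, p], "koff2")
    if rules.p38_drs:
        for a in free_atf2:
            for act in ("np", "pp"):
                if drs_only_eligible(act, a.s90):
                    c = _bind(a, ATF2_P38, act, "drs")
                    p = ComplexSpecies(P38_FREE, act=act)
                    emit([a, p], [c], "kon3")
                    emit([c], [a, p], "koff3")

    # --- catalysis from the bound, active complex ---------------------
    if rules.jnk_catalysis:
        for c in jnk_complexes:
            if c.act != "pp":
                continue
            if c.t69 == "U":
                emit([c], [dc_replace(c, t69="P")], "k1")
            if c.t71 == "U":
                emit([c], [dc_replace(c, t71="P")], "k1")
            if c.s90 == "U":
                emit([c], [dc_replace(c, s90="P")], "k2")
    if rules.p38_catalysis:
        for c in p38_complexes:
            if c.act != "pp":
                continue
            if c.t69 == "U":
                emit([c], [dc_replace(c, t69="P")], "k3")
            if c.t71 == "U":
                emit([c], [dc_replace(c, t71="P")], "k3" if c.t69 == "U" else "k4")

    # --- MAPK activation cycle (free MAPKs only) ----------------------
    if rules.mapk_activation:
        emit([ComplexSpecies(P38_FREE, act="np")], [ComplexSpecies(P38_FREE, act="pp")], "k6")
        emit([ComplexSpecies(JNK_FREE, act="np")], [ComplexSpecies(JNK_FREE, act="pp")], "k7")
    if rules.mapk_dephosphorylation:
        emit([ComplexSpecies(JNK_FREE, act="pp")], [ComplexSpecies(JNK_FREE, act="np")], "dp1")
        emit([ComplexSpecies(P38_FREE, act="pp")], [ComplexSpecies(P38_FREE, act="np")], "dp2")

    # --- ATF2 dephosphorylation (binding-state independent) -----------
    if rules.atf2_dephosphorylation:
        for c in species:
            if c.n_atf2 == 0:
                continue
            if c.t69 == "P":
                emit([c], [dc_replace(c, t69="U")], "dp3")
            if c.t71 == "P":
                emit([c], [dc_replace(c, t71="U")], "dp3")
            if c.s90 == "P":
                # pp-p38 DRS-only complexes require pS90; the product of
                # dephosphorylation would be ineligible, so dp4 skips them.
                if c.kind == ATF2_P38 and c.act == "pp" and c.mode == "drs":
                    continue
                emit([c], [dc_replace(c, s90="U")], "dp4")
    return rxns


@dataclass
class ReactionNetwork:
    """Enumerated species plus reactions, with precomputed index arrays."""

    species: list[ComplexSpecies]
    reactions: list[Reaction]
    rules: RuleSet = field(default_factory=RuleSet)
    variant: str = "WT"

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise InternalConsistencyError("duplicate species in network")
        self.index: dict[ComplexSpecies, int] = {
            s: i for i, s in enumerate(self.species)
        }
        n, m = len(self.species), len(self.reactions)
        self.stoich = np.zeros((n, m), dtype=float)
        self._r1 = np.empty(m, dtype=np.intp)   # first reactant index
        self._r2 = np.full(m, -1, dtype=np.intp)  # second reactant or -1
        self.rate_names: list[str] = []
        for j, r in enumerate(self.reactions):
            for s in r.reactants:
                if s not in self.index:
                    raise InternalConsistencyError(
                        f"reaction references unknown species {s.name()}"
                    )
                self.stoich[self.index[s], j] -= 1.0
            for s in r.products:
                if s not in self.index:
                    raise InternalConsistencyError(
                        f"reaction references unknown species {s.name()}"
                    )
                self.stoich[self.index[s], j] += 1.0
            self._r1[j] = self.index[r.reactants[0]]
            self._r2[j] = self.index[r.reactants[1]] if r.order == 2 else -1
            self.rate_names.append(r.rate_name)
        self._bimol = self._r2 >= 0
        # conservation weight vectors
        self.w_atf2 = np.array([s.n_atf2 for s in self.species], dtype=float)
        self.w_jnk = np.array([s.n_jnk for s in self.species], dtype=float)
        self.w_p38 = np.array([s.n_p38 for s in self.species], dtype=float)

    # ------------------------------------------------------------------
    @classmethod
    def build(cls, params_or_variant: ModelParameters | str = "WT",
              rules: RuleSet | None = None) -> "ReactionNetwork":
        variant = (
            params_or_variant.variant
            if isinstance(params_or_variant, ModelParameters)
            else params_or_variant
        )
        rules = (rules or RuleSet()).for_variant(variant)
        sp = enumerate_species(rules, variant)
        rx = build_reactions(sp, rules, variant)
        return cls(sp, rx, rules, variant)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rate_vector(self, params: ModelParameters, stimulated: bool = False,
                    overrides: dict[str, float] | None = None) -> np.ndarray:
        """Numeric rate constants, one per reaction, for a protocol phase."""
        return np.array(
            [params.rate_value(nm, stimulated, overrides) for nm in self.rate_names]
        )

    def fluxes(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        v = k * state[self._r1]
        v[self._bimol] *= state[self._r2[self._bimol]]
        return v

    def rhs(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Mass-action derivative vector dC/dt (µM/s)."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state length {state.shape} does not match species count "
                f"{self.n_species}"
            )
        return self.stoich @ self.fluxes(state, k)

    def jacobian(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(rhs)/d(state) for implicit solvers."""
        m = len(self.reactions)
        dv = np.zeros((m, self.n_species))
        rows = np.arange(m)
        uni = ~self._bimol
        dv[rows[uni], self._r1[uni]] = k[uni]
        b = self._bimol
        dv[rows[b], self._r1[b]] += k[b] * state[self._r2[b]]
        # += handles A + A style terms, though none occur in this model
        np.add.at(dv, (rows[b], self._r2[b]), k[b] * state[self._r1[b]])
        return self.stoich @ dv

    def initial_state(self, params: ModelParameters,
                      extra_p38: float = 0.0) -> np.ndarray:
        """All molecules free, unphosphorylated and inactive, at totals."""
        x = np.zeros(self.n_species)
        x[self.index[ComplexSpecies(ATF2_FREE, "U", "U", "U")]] = params.atf2_total
        x[self.index[ComplexSpecies(JNK_FREE, act="np")]] = params.jnk_total
        x[self.index[ComplexSpecies(P38_FREE, act="np")]] = params.p38_total + extra_p38
        return x

    def totals(self, state: np.ndarray) -> dict[str, float]:
        return {
            "atf2": float(self.w_atf2 @ state),
            "jnk": float(self.w_jnk @ state),
            "p38": float(self.w_p38 @ state),
        }
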