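"""Molecular species of the JNK/p38/ATF2 phosphoswitch network.

The model tracks three molecules: the ATF2 transactivation domain (TAD)
with three phosphosites (T69, T71 of the phosphoswitch, and the
vertebrate-specific S90), and two MAPKs — JNK and p38 — each reduced to a
two-state activity cycle (np = non-phosphorylated/inactive, pp = doubly
phosphorylated/active).  ATF2 carries a single MAPK-binding slot (the
Zn-finger + D-motif module), so JNK and p38 binding are mutually
exclusive.  p38 can engage ATF2 in two distinct modes:

* ``bipartite`` — simultaneous D-motif/DRS and SPFENEF/FRS engagement,
  possible only for active (pp) p38 and only when S90 is unphosphorylated
  (pS90 sterically blocks the FRS interface);
* ``drs`` — weak D-motif-only binding (K_D ~ 1 mM), available to inactive
  p38 in any ATF2 state and to active p38 when S90 is phosphorylated.

A :class:`ComplexSpecies` is one fully specified molecular state; the
enumeration below is the exhaustive, canonically ordered list of states
reachable by structure under a given rule set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

# molecule classes, in canonical order
ATF2_FREE = "atf2_free"
ATF2_JNK = "atf2_jnk"
ATF2_P38 = "atf2_p38"
JNK_FREE = "jnk_free"
P38_FREE = "p38_free"

_KIND_ORDER = {ATF2_FREE: 0, ATF2_JNK: 1, ATF2_P38: 2, JNK_FREE: 3, P38_FREE: 4}
_MODE_ORDER = {None: 0, "bipartite": 0, "drs": 1}
_SITE_ORDER = {"U": 0, "P": 1, None: -1}
_ACT_ORDER = {None: -1, "np": 0, "pp": 1}

PHOSPHOSTATES = ("U", "P")
ACTIVITIES = ("np", "pp")

VARIANTS = ("WT", "S90N", "MUT4", "JNK_IN_8")


class ConfigurationError(ValueError):
    """Raised for invalid rule, variant or parameter configuration."""


@dataclass(frozen=True, slots=True)
class ComplexSpecies:
    """One fully specified molecular state.

    ``t69``/``t71``/``s90`` are ``"U"``/``"P"`` for ATF2-containing
    species and ``None`` for free MAPKs.  ``act`` is the activity of the
    MAPK contained in the species (``None`` for free ATF2).  ``mode``
    distinguishes the two p38 binding modes and is ``None`` otherwise.
    """

    kind: str
    t69: Optional[str] = None
    t71: Optional[str] = None
    s90: Optional[str] = None
    act: Optional[str] = None
    mode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ConfigurationError(f"unknown molecule class {self.kind!r}")
        if self.kind in (JNK_FREE, P38_FREE):
            if self.t69 is not None or self.t71 is not None or self.s90 is not None:
                raise ConfigurationError("free MAPK species carry no ATF2 site fields")
            if self.act not in ACTIVITIES:
                raise ConfigurationError("free MAPK requires act in {np, pp}")
        else:
            for site in (self.t69, self.t71, self.s90):
                if site not in PHOSPHOSTATES:
                    raise ConfigurationError("ATF2 sites must be U or P")
            if self.kind == ATF2_FREE and self.act is not None:
                raise ConfigurationError("free ATF2 has no partner activity")
            if self.kind in (ATF2_JNK, ATF2_P38) and self.act not in ACTIVITIES:
                raise ConfigurationError("bound MAPK requires act in {np, pp}")
        if self.kind == ATF2_P38:
            if self.mode not in ("bipartite", "drs"):
                raise ConfigurationError("ATF2:p38 complex requires a binding mode")
            if self.mode == "bipartite" and not (self.act == "pp" and self.s90 == "U"):
                raise ConfigurationError("bipartite binding requires pp-p38 and S90=U")
            if self.mode == "drs" and not (
                self.act == "np" or (self.act == "pp" and self.s90 == "P")
            ):
                raise ConfigurationError(
                    "DRS-only binding requires np-p38, or pp-p38 with S90=P"
                )
        elif self.mode is not None:
            raise ConfigurationError("binding mode only applies to ATF2:p38 complexes")

    # --- composition ------------------------------------------------
    @property
    def n_atf2(self) -> int:
        return 1 if self.kind in (ATF2_FREE, ATF2_JNK, ATF2_P38) else 0

    @property
    def n_jnk(self) -> int:
        return 1 if self.kind in (ATF2_JNK, JNK_FREE) else 0

    @property
    def n_p38(self) -> int:
        return 1 if self.kind in (ATF2_P38, P38_FREE) else 0

    def sort_key(self) -> tuple:
        return (
            _KIND_ORDER[self.kind],
            _MODE_ORDER[self.mode],
            _SITE_ORDER[self.t69],
            _SITE_ORDER[self.t71],
            _SITE_ORDER[self.s90],
            _ACT_ORDER[self.act],
        )

    def name(self) -> str:
        """Canonical species string, e.g. ``ATF2(T69~P,T71~U,S90~U)!p38(act~pp,mode~bipartite)``."""
        if self.kind == JNK_FREE:
            return f"JNK(act~{self.act})"
        if self.kind == P38_FREE:
            return f"p38(act~{self.act})"
        atf2 = f"ATF2(T69~{self.t69},T71~{self.t71},S90~{self.s90})"
        if self.kind == ATF2_FREE:
            return atf2
        if self.kind == ATF2_JNK:
            return f"{atf2}!JNK(act~{self.act})"
        return f"{atf2}!p38(act~{self.act},mode~{self.mode})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name()


@dataclass(frozen=True, slots=True)
class RuleSet:
    """Which binding / modification rules are active.

    The default is the full wild-type rule set.  Binding flags shape the
    reachable species list; the remaining flags only shape the reaction
    list.  ``MUT4`` (the FENEF → AENEA mutant) removes the bipartite rule.
    """

    jnk_binding: bool = True
    p38_bipartite: bool = True
    p38_drs: bool = True
    jnk_catalysis: bool = True
    p38_catalysis: bool = True
    mapk_activation: bool = True
    mapk_dephosphorylation: bool = True
    atf2_dephosphorylation: bool = True

    @classmethod
    def none(cls) -> "RuleSet":
        """Empty rule set: no binding, no catalysis — 12 seed species."""
        return cls(False, False, False, False, False, False, False, False)

    def for_variant(self, variant: str) -> "RuleSet":
        if variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {variant!r}; expected one of {VARIANTS}"
            )
        if variant == "MUT4":
            return RuleSet(
                self.jnk_binding,
                False,
                self.p38_drs,
                self.jnk_catalysis,
                self.p38_catalysis,
                self.mapk_activation,
                self.mapk_dephosphorylation,
                self.atf2_dephosphorylation,
            )
        return self


def _atf2_states():
    for t69 in PHOSPHOSTATES:
        for t71 in PHOSPHOSTATES:
            for s90 in PHOSPHOSTATES:
                yield t69, t71, s90


def drs_only_eligible(act: str, s90: str) -> bool:
    """D-motif-only p38 binding eligibility (independent of variant)."""
    return act == "np" or (act == "pp" and s90 == "P")


def bipartite_eligible(act: str, s90: str) -> bool:
    return act == "pp" and s90 == "U"


def enumerate_species(rules: RuleSet | None = None, variant: str = "WT") -> list[ComplexSpecies]:
    """Enumerate every structurally reachable species under ``rules``.

    Returns the canonical, deterministically ordered species list:
    free ATF2 states, ATF2:JNK complexes, ATF2:p38 complexes (bipartite
    then DRS-only), free JNK, free p38.  Wild-type full rule set gives 44
    species; MUT4 gives 40; an empty binding rule set gives the 12 seed
    species.
    """
    rules = (rules or RuleSet()).for_variant(variant)
    out: list[ComplexSpecies] = []
    for t69, t71, s90 in _atf2_states():
        out.append(ComplexSpecies(ATF2_FREE, t69, t71, s90))
    if rules.jnk_binding:
        for t69, t71, s90 in _atf2_states():
            for act in ACTIVITIES:
                out.append(ComplexSpecies(ATF2_JNK, t69, t71, s90, act))
    if rules.p38_bipartite:
        for t69, t71, s90 in _atf2_states():
            if bipartite_eligible("pp", s90):
                out.append(ComplexSpecies(ATF2_P38, t69, t71, s90, "pp", "bipartite"))
    if rules.p38_drs:
        for t69, t71, s90 in _atf2_states():
            for act in ACTIVITIES:
                if drs_only_eligible(act, s90):
                    out.append(ComplexSpecies(ATF2_P38, t69, t71, s90, act, "drs"))
    for act in ACTIVITIES:
        out.append(ComplexSpecies(JNK_FREE, act=act))
    for act in ACTIVITIES:
        out.append(ComplexSpecies(P38_FREE, act=act))
    out.sort(key=ComplexSpecies.sort_key)
    return out
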