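"""Model parameters: rate constants, totals and variant overrides.

Units: concentrations in µM, time in s, bimolecular on-rates in µM⁻¹s⁻¹,
all other rates in s⁻¹.  The defaults are a calibrated plausible set
consistent with the measured binding constants (JNK–ATF2 K_D ≈ 5 µM,
p38 DRS-only K_D ≈ 1 mM) and with the anchoring assumptions used to fix
the unmeasured in-cell rates: ~10% of JNK and ~5% of p38 active and ~80%
of ATF2 doubly phosphorylated 40 min after stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .species import ConfigurationError, VARIANTS

#: Rate-constant field names (excludes totals).
RATE_NAMES = (
    "kon1", "koff1", "kon2", "koff2", "kon3", "koff3",
    "k1", "k2", "k3", "k4",
    "k_eq6", "k_stim6", "k_eq7", "k_stim7",
    "dp1", "dp2", "dp3", "dp4",
)

TOTAL_NAMES = ("atf2_total", "jnk_total", "p38_total", "p38_exogenous")


@dataclass(frozen=True, slots=True)
class ModelParameters:
    """The 18 rate constants plus total concentrations.

    ``k_eq6``/``k_eq7`` are the basal (pre-stimulation) upstream-kinase
    activities on p38/JNK; ``k_stim6``/``k_stim7`` their stimulated
    values.  ``dp1``/``dp2`` deactivate free pp-JNK/pp-p38; ``dp3``
    dephosphorylates pT69/pT71 and ``dp4`` pS90.
    """

    # binding (µM⁻¹s⁻¹ / s⁻¹)
    kon1: float = 1.0        # JNK ↔ ATF2 (Zn-finger + D-motif), K_D ≈ 5 µM
    koff1: float = 5.0
    kon2: float = 1.0        # pp-p38 ↔ ATF2 bipartite (DRS + FRS)
    koff2: float = 2.0
    kon3: float = 0.1        # p38 ↔ ATF2 D-motif only, K_D ≈ 1 mM
    koff3: float = 100.0
    # catalysis from the bound complex (s⁻¹)
    k1: float = 0.1          # pp-JNK → T69 and → T71
    k2: float = 0.2          # pp-JNK → S90
    k3: float = 0.1          # pp-p38 → T69; → T71 while T69=U
    k4: float = 0.01         # pp-p38 → T71 when T69=P (slower)
    # MAPK activation by upstream kinases (s⁻¹); eq = basal, stim = anisomycin.
    # k_stim6, k_stim7 and dp3 are calibrated so that the wild-type
    # anisomycin run gives 10% pp-JNK, 5% pp-p38 and 80% pp-ATF2 at 40 min.
    k_eq6: float = 1e-6
    k_stim6: float = 2.2488e-4
    k_eq7: float = 1e-6
    k_stim7: float = 5.0002e-4
    # phosphatases (s⁻¹)
    dp1: float = 4.5e-3      # pp-JNK → np-JNK
    dp2: float = 4.75e-3     # pp-p38 → np-p38
    dp3: float = 1.6894e-4   # pT69 → T69 and pT71 → T71
    dp4: float = 1e-3        # pS90 → S90
    # totals (µM)
    atf2_total: float = 1.0
    jnk_total: float = 1.0
    p38_total: float = 1.0
    p38_exogenous: float = 1.65

    variant: str = field(default="WT")
    _variant_applied: bool = field(default=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("variant", "_variant_applied"):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} must be a finite number")
            if f.name in TOTAL_NAMES:
                if f.name != "p38_exogenous" and v <= 0:
                    raise ConfigurationError(f"total {f.name} must be > 0")
                if f.name == "p38_exogenous" and v < 0:
                    raise ConfigurationError("p38_exogenous must be ≥ 0")
            elif v < 0:
                raise ConfigurationError(f"rate {f.name} must be ≥ 0")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    # ------------------------------------------------------------------
    def with_variant(self, variant: str) -> "ModelParameters":
        """Return parameters with the variant override applied exactly once.

        S90N: S90 cannot be phosphorylated (k2 = 0) and the asparagine
        strengthens FRS binding (kon2 ← 4.5 × wild-type kon2).  MUT4:
        bipartite binding is disabled at the rule level (rates unchanged
        here).  JNK-IN-8: the JNK inhibitor zeroes JNK catalysis
        (k1 = k2 = 0) while leaving binding intact.
        """
        if self._variant_applied:
            raise ConfigurationError("variant override already applied")
        if variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {variant!r}; expected one of {VARIANTS}"
            )
        if variant == "S90N":
            return replace(self, k2=0.0, kon2=4.5 * self.kon2,
                           variant=variant, _variant_applied=True)
        if variant == "JNK_IN_8":
            return replace(self, k1=0.0, k2=0.0, variant=variant, _variant_applied=True)
        return replace(self, variant=variant, _variant_applied=True)

    def updated(self, **overrides: float) -> "ModelParameters":
        bad = set(overrides) - {f.name for f in fields(self)}
        if bad:
            raise ConfigurationError(f"unknown parameter(s): {sorted(bad)}")
        return replace(self, **overrides)

    def rate_value(self, name: str, stimulated: bool = False,
                   overrides: dict[str, float] | None = None) -> float:
        """Resolve a reaction rate name to its numeric value.

        The network's activation reactions are named ``k6``/``k7``; they
        resolve to the basal (``k_eq``) or stimulated (``k_stim``) value
        depending on the protocol phase, unless explicitly overridden.
        """
        if overrides and name in overrides:
            return overrides[name]
        if name == "k6":
            return self.k_stim6 if stimulated else self.k_eq6
        if name == "k7":
            return self.k_stim7 if stimulated else self.k_eq7
        if name not in RATE_NAMES:
            raise ConfigurationError(f"unknown rate name {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in RATE_NAMES + TOTAL_NAMES}
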