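"""Pre-equilibration → stimulation protocol simulation and observables.

A run starts from all molecules free, inactive and unphosphorylated,
relaxes to steady state under basal upstream-kinase activity
(k_eq6/k_eq7), and is then stimulated by stepping the activation rates to
k_stim6/k_stim7 (the anisomycin mimic).  Observables are the fractions
monitored in the cell experiments: active (pp) MAPK fractions, the
doubly phosphorylated T69/T71 phosphoswitch fraction, the pS90 fraction,
and total p38:ATF2 complex (the NanoBit-like signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .network import ReactionNetwork
from .params import ModelParameters
from .species import ATF2_P38

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12

#: anisomycin protocol: 40 min of stimulation, western-blot sampling grid
STIM_DURATION_S = 2400.0
DEFAULT_SAMPLING_S = (0.0, 300.0, 600.0, 1200.0, 2400.0)

OBSERVABLE_NAMES = (
    "pp_jnk_fraction",
    "pp_p38_fraction",
    "pp_atf2_fraction",
    "ps90_fraction",
    "p38_atf2_complex_total",
)


class ConvergenceError(RuntimeError):
    """Pre-equilibration failed to reach steady state within the time cap."""


class IntegrationError(RuntimeError):
    """The stiff solver failed during a protocol phase."""


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: a step change of k6/k7 at t = 0.

    ``overrides`` replaces the stimulated activation rates (used by the
    flux scan); by default the parameter set's k_stim values apply.
    """

    duration_s: float = STIM_DURATION_S
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_S
    overrides: dict | None = None

    def __post_init__(self) -> None:
        if any(t < 0 or t > self.duration_s for t in self.sampling_times):
            raise ValueError("sampling times must lie within the protocol duration")


@dataclass
class Trajectory:
    """Simulation output: concentration matrix plus derived observables."""

    times: np.ndarray                  # (T,) s
    concentrations: np.ndarray         # (T, n_species) µM
    network: ReactionNetwork
    params: ModelParameters
    solver_rtol: float = DEFAULT_RTOL
    solver_atol: float = DEFAULT_ATOL
    observables: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observables:
            self.observables = compute_observables(self)

    def to_frame(self):
        """Tidy (time_s, observable, value) table."""
        import pandas as pd

        rows = [
            {"time_s": t, "observable": name, "value": v}
            for name, series in self.observables.items()
            for t, v in zip(self.times, series)
        ]
        return pd.DataFrame(rows)

    def species_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.concentrations,
            index=pd.Index(self.times, name="time_s"),
            columns=[s.name() for s in self.network.species],
        )


def _integrate(network, state, k, times, rtol, atol):
    """LSODA (stiff, analytic Jacobian) integration to each time in ``times``.

    ``times`` must be increasing; a leading 0 is added internally when
    missing.  Returns the state matrix aligned with ``times``.
    """
    times = np.asarray(times, dtype=float)
    prepend = times[0] > 0.0
    ts = np.concatenate(([0.0], times)) if prepend else times
    if len(ts) == 1:
        return state[None, :].copy()
    out, info = odeint(
        lambda y, t: network.rhs(y, k),
        state,
        ts,
        Dfun=lambda y, t: network.jacobian(y, k),
        rtol=rtol,
        atol=atol,
        mxstep=200_000,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"stiff solver failed over t={ts[0]}..{ts[-1]}: {info['message']}; "
            f"state max={np.max(state):.3g}"
        )
    return out[1:] if prepend else out


def _newton_steady_state(network, state, k, totals, tol=1e-14, maxiter=50):
    """Newton refinement of a near-steady state.

    The mass-action Jacobian is singular along the three conservation
    directions, so three rows of the residual are replaced by the
    conservation constraints (ATF2, JNK, p38 totals).
    """
    rows = [
        network.index[s]
        for s in (
            _seed_species(network, "atf2"),
            _seed_species(network, "jnk"),
            _seed_species(network, "p38"),
        )
    ]
    weights = [network.w_atf2, network.w_jnk, network.w_p38]
    x = state.copy()
    for _ in range(maxiter):
        f = network.rhs(x, k)
        for r, w, tot in zip(rows, weights, totals):
            f[r] = w @ x - tot
        if np.max(np.abs(f)) < tol:
            break
        jac = network.jacobian(x, k)
        for r, w in zip(rows, weights):
            jac[r, :] = w
        try:
            step = np.linalg.solve(jac, f)
        except np.linalg.LinAlgError:
            return None
        x_new = x - step
        # damp steps that would push concentrations negative
        lam = 1.0
        while lam > 1e-4 and np.min(x - lam * step) < -1e-12:
            lam *= 0.5
        x_new = np.clip(x - lam * step, 0.0, None)
        if np.max(np.abs(x_new - x)) < 1e-16:
            x = x_new
            break
        x = x_new
    return x


def _seed_species(network, molecule):
    from .species import ATF2_FREE, JNK_FREE, P38_FREE, ComplexSpecies

    if molecule == "atf2":
        return ComplexSpecies(ATF2_FREE, "U", "U", "U")
    if molecule == "jnk":
        return ComplexSpecies(JNK_FREE, act="np")
    return ComplexSpecies(P38_FREE, act="np")


def pre_equilibrate(
    network: ReactionNetwork,
    params: ModelParameters,
    extra_p38: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    residual_tol: float = 1e-12,
    max_time_s: float = 1e9,
) -> np.ndarray:
    """Relax to the basal steady state (max |dC/dt| < ``residual_tol``).

    Integrates under basal k_eq activities, then refines with a
    conservation-constrained Newton solve; if the refinement does not
    meet the residual criterion the integration horizon is doubled until
    it does or ``max_time_s`` is exhausted.
    """
    k = network.rate_vector(params, stimulated=False)
    state = network.initial_state(params, extra_p38=extra_p38)
    totals = (
        float(network.w_atf2 @ state),
        float(network.w_jnk @ state),
        float(network.w_p38 @ state),
    )
    t = 1e5
    resid = np.inf
    while t <= max_time_s:
        out = _integrate(network, state, k, np.array([0.0, t]), rtol, atol)
        prev, state = state, out[-1]
        refined = _newton_steady_state(network, state, k, totals)
        if refined is not None:
            r = float(np.max(np.abs(network.rhs(refined, k))))
            if r < residual_tol:
                return refined
        resid = float(np.max(np.abs(network.rhs(state, k))))
        if resid < residual_tol:
            return state
        rel_change = float(
            np.max(np.abs(state - prev)) / max(np.max(np.abs(state)), 1e-30)
        )
        if rel_change < 1e-10:
            return state
        t *= 2.0
    raise ConvergenceError(
        f"pre-equilibration residual {resid:.3g} µM/s above {residual_tol:.3g} "
        f"after {max_time_s:.3g} s"
    )


def run_protocol(
    network: ReactionNetwork,
    params: ModelParameters,
    protocol: Protocol | None = None,
    initial_state: np.ndarray | None = None,
    extra_p38: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Simulate the stimulation phase from a pre-equilibrated state."""
    protocol = protocol or Protocol()
    if initial_state is None:
        initial_state = pre_equilibrate(
            network, params, extra_p38=extra_p38, rtol=rtol, atol=atol
        )
    k = network.rate_vector(params, stimulated=True, overrides=protocol.overrides)
    t_eval = np.asarray(sorted(set(protocol.sampling_times)), dtype=float)
    conc = _integrate(network, initial_state, k, t_eval, rtol, atol)
    return Trajectory(
        times=t_eval,
        concentrations=conc,
        network=network,
        params=params,
        solver_rtol=rtol,
        solver_atol=atol,
    )


def compute_observables(trajectory: Trajectory) -> dict[str, np.ndarray]:
    """Derive the monitored fractions from a concentration trajectory.

    ``pp_atf2_fraction`` counts species with BOTH T69 and T71
    phosphorylated (the anti-pT69/pT71 readout); MAPK fractions count
    every species containing that MAPK in the active state, bound or
    free; ``p38_atf2_complex_total`` sums all ATF2:p38 complexes in µM.
    """
    net = trajectory.network
    conc = trajectory.concentrations
    p = trajectory.params

    def mask(pred):
        return np.array([1.0 if pred(s) else 0.0 for s in net.species])

    pp_jnk = mask(lambda s: s.n_jnk == 1 and s.act == "pp")
    pp_p38 = mask(lambda s: s.n_p38 == 1 and s.act == "pp")
    pp_atf2 = mask(lambda s: s.n_atf2 == 1 and s.t69 == "P" and s.t71 == "P")
    ps90 = mask(lambda s: s.n_atf2 == 1 and s.s90 == "P")
    p38_cplx = mask(lambda s: s.kind == ATF2_P38)

    jnk_tot = float(net.w_jnk @ conc[0]) or p.jnk_total
    p38_tot = float(net.w_p38 @ conc[0]) or p.p38_total
    return {
        "pp_jnk_fraction": conc @ pp_jnk / jnk_tot,
        "pp_p38_fraction": conc @ pp_p38 / p38_tot,
        "pp_atf2_fraction": conc @ pp_atf2 / p.atf2_total,
        "ps90_fraction": conc @ ps90 / p.atf2_total,
        "p38_atf2_complex_total": conc @ p38_cplx,
    }


def simulate_condition(
    params: ModelParameters,
    variant: str = "WT",
    protocol: Protocol | None = None,
    nanobit: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Convenience wrapper: build network, apply variant, pre-equilibrate, run.

    With ``nanobit=True`` the simplified NanoBit system is used: a merged
    p38 pool of p38_total + p38_exogenous µM, and the complex signal is
    later normalized to its pre-stimulation value (see
    :func:`nanobit_signal`).
    """
    p = params.with_variant(variant) if not params._variant_applied else params
    net = ReactionNetwork.build(p)
    extra = p.p38_exogenous if nanobit else 0.0
    return run_protocol(net, p, protocol, extra_p38=extra, rtol=rtol, atol=atol)


def nanobit_signal(trajectory: Trajectory) -> np.ndarray:
    """NanoBit-like signal: total p38:ATF2 complex normalized to t = 0."""
    c = trajectory.observables["p38_atf2_complex_total"]
    baseline = c[0]
    if baseline <= 0:
        raise ZeroDivisionError("pre-stimulation complex level is zero")
    return c / baseline
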