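"""Stimulation-rate grid scans and response-surface metrics.

The model is pre-equilibrated once at basal activity and then stimulated
for 40 min at every (k_stim6, k_stim7) grid point, recording terminal
pp-JNK / pp-p38 levels (the surface axes, in µM) and the pp-ATF2
fraction.  Metrics reproduce the response-surface analyses: inflection
points along the diagonal or single-MAPK axes, the equal-sensitivity
contour separating JNK- from p38-dominated regions, interior local
minima along the JNK axis, and the binding-affinity perturbation
scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork
from .params import ModelParameters
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    STIM_DURATION_S,
    Protocol,
    pre_equilibrate,
    run_protocol,
)
from .species import ConfigurationError

PATHS = ("diagonal", "jnk_axis", "p38_axis")

#: Affinity-perturbation scenarios: multiplicative on-rate factors.
SCENARIOS: dict[str, dict[str, float]] = {
    "identity": {},
    "kon1_x100": {"kon1": 100.0},
    "kon2_x100": {"kon2": 100.0},
    "jnk_weak10_p38_strong10": {"kon1": 0.1, "kon2": 10.0, "kon3": 10.0},
}


class FlatResponseError(ValueError):
    """The response along the requested path is too flat to locate an inflection."""


@dataclass(frozen=True)
class FluxGrid:
    """Log-spaced stimulation-rate grid, default 25 × 25 over [1e-6, 1e-2] s⁻¹."""

    k_stim6_values: np.ndarray = field(
        default_factory=lambda: np.logspace(-6, -2, 25)
    )
    k_stim7_values: np.ndarray = field(
        default_factory=lambda: np.logspace(-6, -2, 25)
    )

    def __post_init__(self) -> None:
        for v in (self.k_stim6_values, self.k_stim7_values):
            if np.any(np.diff(v) <= 0):
                raise ConfigurationError("grid axes must be strictly increasing")

    @classmethod
    def default(cls, n: int = 25, lo: float = 1e-6, hi: float = 1e-2) -> "FluxGrid":
        axis = np.logspace(np.log10(lo), np.log10(hi), n)
        return cls(axis, axis.copy())


@dataclass
class ResponseSurface:
    """Terminal (40 min) responses over the flux grid.

    Rows index k_stim6 (p38 flux), columns k_stim7 (JNK flux).  ``pp_jnk``
    and ``pp_p38`` are in µM; ``pp_atf2`` is the phosphoswitch fraction.
    """

    grid: FluxGrid
    pp_jnk: np.ndarray
    pp_p38: np.ndarray
    pp_atf2: np.ndarray
    variant: str = "WT"
    params: ModelParameters | None = None

    def to_frame(self):
        import pandas as pd

        k6, k7 = np.meshgrid(
            self.grid.k_stim6_values, self.grid.k_stim7_values, indexing="ij"
        )
        return pd.DataFrame(
            {
                "k_stim6": k6.ravel(),
                "k_stim7": k7.ravel(),
                "pp_jnk_uM": self.pp_jnk.ravel(),
                "pp_p38_uM": self.pp_p38.ravel(),
                "pp_atf2_fraction": self.pp_atf2.ravel(),
            }
        )

    def path_arrays(self, path: str, totals: tuple[float, float] = (1.0, 1.0)):
        """(activated-MAPK fraction, pp-ATF2) along a scan path.

        The path coordinate is the activated fraction of the varied MAPK;
        on the diagonal it is the mean of the two fractions.
        """
        jnk_total, p38_total = totals
        if path == "diagonal":
            d = np.arange(min(self.pp_atf2.shape))
            x = 0.5 * (
                self.pp_jnk[d, d] / jnk_total + self.pp_p38[d, d] / p38_total
            )
            f = self.pp_atf2[d, d]
        elif path == "jnk_axis":
            x = self.pp_jnk[0, :] / jnk_total
            f = self.pp_atf2[0, :]
        elif path == "p38_axis":
            x = self.pp_p38[:, 0] / p38_total
            f = self.pp_atf2[:, 0]
        else:
            raise ConfigurationError(f"unknown path {path!r}; expected one of {PATHS}")
        return np.asarray(x, dtype=float), np.asarray(f, dtype=float)


def run_flux_scan(
    network: ReactionNetwork,
    params: ModelParameters,
    grid: FluxGrid | None = None,
    duration_s: float = STIM_DURATION_S,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ResponseSurface:
    """One pre-equilibration plus one stimulation run per grid point.

    Pre-equilibration depends only on the basal rates, so the relaxed
    state is shared across the grid.
    """
    grid = grid or FluxGrid.default()
    steady = pre_equilibrate(network, params, rtol=rtol, atol=atol)
    n6, n7 = len(grid.k_stim6_values), len(grid.k_stim7_values)
    pp_jnk = np.empty((n6, n7))
    pp_p38 = np.empty((n6, n7))
    pp_atf2 = np.empty((n6, n7))
    for i, k6 in enumerate(grid.k_stim6_values):
        for j, k7 in enumerate(grid.k_stim7_values):
            try:
                traj = run_protocol(
                    network,
                    params,
                    Protocol(
                        duration_s=duration_s,
                        sampling_times=(duration_s,),
                        overrides={"k6": float(k6), "k7": float(k7)},
                    ),
                    initial_state=steady,
                    rtol=rtol,
                    atol=atol,
                )
            except Exception as exc:  # annotate the failing grid point
                raise RuntimeError(
                    f"integration failed at grid point k_stim6={k6:g}, "
                    f"k_stim7={k7:g}: {exc}"
                ) from exc
            obs = traj.observables
            pp_jnk[i, j] = obs["pp_jnk_fraction"][-1] * params.jnk_total
            pp_p38[i, j] = obs["pp_p38_fraction"][-1] * params.p38_total
            pp_atf2[i, j] = obs["pp_atf2_fraction"][-1]
    return ResponseSurface(grid, pp_jnk, pp_p38, pp_atf2, params.variant, params)


def _interp_argmax(lx: np.ndarray, der: np.ndarray) -> float:
    """Parabolic interpolation of the derivative maximum on the log axis."""
    i = int(np.argmax(der))
    if 0 < i < len(der) - 1:
        y0, y1, y2 = der[i - 1], der[i], der[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            # local quadratic on an (approximately) uniform log grid
            h = 0.5 * (lx[i + 1] - lx[i - 1])
            return float(lx[i] + frac * h)
    return float(lx[i])


def find_inflection(
    surface: ResponseSurface,
    path: str = "diagonal",
    normalize: str = "axis_max",
) -> float:
    """Inflection location along a path, as a percentage.

    The inflection is the maximum of d(pp_atf2)/d(log activated-MAPK
    fraction), parabolic-interpolated on the log axis.  With
    ``normalize="axis_max"`` (default) the location is expressed as a
    percentage of the maximal activated-MAPK fraction reached on the
    path; with ``normalize="total"`` as a percentage of total MAPK.
    """
    x, f = surface.path_arrays(path)
    if len(x) < 15:
        raise ConfigurationError("inflection detection requires ≥ 15 path samples")
    if np.ptp(f) < 0.01 * max(np.max(np.abs(f)), 1.0):
        raise FlatResponseError(
            f"response range {np.ptp(f):.3g} along {path} is < 1% of span; "
            "no inflection"
        )
    lx = np.log(x)
    der = np.gradient(f, lx)
    x_star = float(np.exp(_interp_argmax(lx, der)))
    if normalize == "axis_max":
        return 100.0 * x_star / float(np.max(x))
    if normalize == "total":
        return 100.0 * x_star
    raise ConfigurationError(f"unknown normalization {normalize!r}")


def half_activation_crossing(surface: ResponseSurface, path: str = "p38_axis",
                             level: float = 0.5) -> float:
    """Activated-MAPK fraction at which pp-ATF2 first crosses ``level``.

    Log-interpolated between grid points; returns ``inf`` when the level
    is never reached and the first coordinate when it starts above.
    """
    x, f = surface.path_arrays(path)
    above = f >= level
    if above[0]:
        return float(x[0])
    if not above.any():
        return float("inf")
    i = int(np.argmax(above))
    lx = np.interp(level, [f[i - 1], f[i]], [np.log(x[i - 1]), np.log(x[i])])
    return float(np.exp(lx))


def equal_sensitivity_line(surface: ResponseSurface) -> np.ndarray:
    """Zero contour of ∂pp_atf2/∂log(pp-JNK) − ∂pp_atf2/∂log(pp-p38).

    Returns an (N, 2) polyline in (pp-JNK µM, pp-p38 µM) space; points
    above the line are more JNK-sensitive.  An empty array (with a
    warning) is returned when the difference field is one-signed.
    """
    f = surface.pp_atf2
    lj = np.log(surface.pp_jnk)
    lp = np.log(surface.pp_p38)
    # sensitivities wrt log pp-MAPK via chain rule on the index grid
    df_dj = np.gradient(f, axis=1) / np.gradient(lj, axis=1)
    df_dp = np.gradient(f, axis=0) / np.gradient(lp, axis=0)
    diff = df_dj - df_dp
    if np.all(diff > 0) or np.all(diff < 0):
        warnings.warn("sensitivity difference is one-signed; empty contour")
        return np.empty((0, 2))
    from skimage import measure

    contours = measure.find_contours(diff, 0.0)
    if not contours:
        warnings.warn("no zero contour found")
        return np.empty((0, 2))
    contour = max(contours, key=len)  # (row=k6 index, col=k7 index) floats
    rows, cols = contour[:, 0], contour[:, 1]
    ppj = np.exp(_bilinear(lj, rows, cols))
    ppp = np.exp(_bilinear(lp, rows, cols))
    return np.column_stack([ppj, ppp])


def _bilinear(field2d: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    r0 = np.clip(np.floor(rows).astype(int), 0, field2d.shape[0] - 2)
    c0 = np.clip(np.floor(cols).astype(int), 0, field2d.shape[1] - 2)
    fr, fc = rows - r0, cols - c0
    return (
        field2d[r0, c0] * (1 - fr) * (1 - fc)
        + field2d[r0 + 1, c0] * fr * (1 - fc)
        + field2d[r0, c0 + 1] * (1 - fr) * fc
        + field2d[r0 + 1, c0 + 1] * fr * fc
    )


def detect_local_minimum(
    surface: ResponseSurface | np.ndarray,
    row: int | None = None,
    noise_floor: float = 1e-3,
) -> list[int]:
    """Interior strict local minima of pp-ATF2 along the JNK axis.

    ``row`` selects a fixed-pp-p38 slice of a surface; a 1-D array may be
    passed directly.  A minimum counts when it sits at least
    ``noise_floor`` below the lower of the two flanking maxima.
    """
    if isinstance(surface, ResponseSurface):
        if row is None:
            raise ConfigurationError("row index required for a surface input")
        values = surface.pp_atf2[row, :]
    else:
        values = np.asarray(surface, dtype=float)
    minima: list[int] = []
    for i in range(1, len(values) - 1):
        if values[i] < values[i - 1] and values[i] < values[i + 1]:
            left_peak = np.max(values[: i + 1])
            right_peak = np.max(values[i:])
            depth = min(left_peak, right_peak) - values[i]
            if depth >= noise_floor:
                minima.append(i)
    return minima


@dataclass
class SurfaceMetrics:
    """Summary metrics of one response surface."""

    diagonal_inflection_pct: float
    diagonal_inflection_pct_of_total: float
    equal_sensitivity_curve: np.ndarray
    local_minima: dict[int, list[int]]

    @classmethod
    def from_surface(cls, surface: ResponseSurface,
                     noise_floor: float = 1e-3) -> "SurfaceMetrics":
        minima = {
            i: m
            for i in range(surface.pp_atf2.shape[0])
            if (m := detect_local_minimum(surface, i, noise_floor))
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            contour = equal_sensitivity_line(surface)
        return cls(
            diagonal_inflection_pct=find_inflection(surface, "diagonal"),
            diagonal_inflection_pct_of_total=find_inflection(
                surface, "diagonal", normalize="total"
            ),
            equal_sensitivity_curve=contour,
            local_minima=minima,
        )


def run_affinity_scenarios(
    params: ModelParameters,
    scenarios: tuple[str, ...] = ("kon1_x100", "kon2_x100", "jnk_weak10_p38_strong10"),
    grid: FluxGrid | None = None,
    include_baseline: bool = True,
) -> dict[str, ResponseSurface]:
    """Flux scans under multiplicative on-rate perturbations.

    Each scenario scales the stated kon values only, on the grid shared
    with the baseline; the ``identity`` scenario reproduces the baseline.
    """
    grid = grid or FluxGrid.default()
    out: dict[str, ResponseSurface] = {}
    names = (("baseline",) if include_baseline else ()) + tuple(scenarios)
    for name in names:
        key = "identity" if name == "baseline" else name
        if key not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
            )
        factors = SCENARIOS[key]
        p = params.updated(
            **{k: getattr(params, k) * v for k, v in factors.items()}
        )
        out[name] = run_flux_scan(ReactionNetwork.build(p), p, grid)
    return out
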