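"""Synthetic measurement generation from known ground-truth parameters.

Every input the calibration and assay-analysis code consumes can be
generated here: anisomycin-stimulation time courses of the western-blot
observables, NanoBit-like normalized p38:ATF2 complex signals, and the
in vitro saturation / inhibition assay tables.  Noise is multiplicative
lognormal with a stated coefficient of variation (CV), mean-preserving,
and fully determined by the seed — blot densitometry and luminescence
errors scale with signal, which an additive model would not capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import FITTABLE_OBSERVABLES
from .kinetics import (
    ASSAY_SUBSTRATE_UM,
    DEFAULT_DOSE_SERIES_UM,
    DEFAULT_SUBSTRATE_SERIES_UM,
    KM_REF_UM,
    ic50_from_ki,
)
from .params import ModelParameters
from .simulate import Protocol, nanobit_signal, simulate_condition
from .species import ConfigurationError

DEFAULT_SAMPLING_MIN = (0.0, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise with mean 1 and the given CV."""

    kind: str = "lognormal_multiplicative"
    cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal_multiplicative"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ConfigurationError("cv must be ≥ 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.cv == 0:
            return np.asarray(values, dtype=float)
        sigma = np.sqrt(np.log1p(self.cv ** 2))
        factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                size=np.shape(values))
        return np.asarray(values, dtype=float) * factors


@dataclass
class SyntheticDataset:
    """Observed table plus full provenance (truth, design, noise, seed)."""

    table: pd.DataFrame
    generating_parameters: dict
    design: dict
    noise: NoiseModel
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "noise": {"kind": self.noise.kind, "cv": self.noise.cv,
                      "seed": self.noise.seed},
            "generating_parameters": self.generating_parameters,
            "design": self.design,
        }

    def write(self, csv_path, manifest_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest(), fh, indent=2, default=float)


def generate_timecourse_dataset(
    truth_params: ModelParameters,
    variant: str = "WT",
    condition: str = "CTR",
    observables: tuple[str, ...] = (
        "pp_jnk_fraction", "pp_p38_fraction", "pp_atf2_fraction",
    ),
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_MIN,
    noise: NoiseModel | None = None,
    seed: int = 0,
    nanobit: bool = False,
) -> SyntheticDataset:
    """Simulated anisomycin observables at the sampling grid, noised.

    With ``nanobit=True`` the merged exogenous-p38 system is simulated
    and the ``p38_atf2_complex_norm`` observable (signal normalized to
    the untreated baseline) is emitted.
    """
    noise = noise or NoiseModel(kind="none", cv=0.0, seed=seed)
    for obs in observables:
        if obs not in FITTABLE_OBSERVABLES:
            raise ConfigurationError(f"unknown observable {obs!r}")
    times_s = tuple(60.0 * t for t in sampling_times_min)
    protocol = Protocol(duration_s=max(2400.0, max(times_s)),
                        sampling_times=times_s)
    traj = simulate_condition(truth_params, variant=variant,
                              protocol=protocol, nanobit=nanobit)
    rng = np.random.default_rng(noise.seed if noise.kind != "none" else seed)
    rows = []
    for obs in observables:
        series = (nanobit_signal(traj) if obs == "p38_atf2_complex_norm"
                  else traj.observables[obs])
        noised = noise.apply(series, rng)
        for t, v in zip(traj.times, noised):
            rows.append(
                {"condition": condition, "variant": variant, "observable": obs,
                 "time_s": t, "value": v, "weight": 1.0}
            )
    table = pd.DataFrame(rows)
    return SyntheticDataset(
        table=table,
        generating_parameters=truth_params.as_dict() | {"variant": variant},
        design={"condition": condition, "observables": list(observables),
                "sampling_times_min": list(sampling_times_min),
                "nanobit": nanobit},
        noise=noise,
        seed=seed,
    )


def generate_nanobit_pair(
    truth_params: ModelParameters,
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_MIN,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """CTR + JNK-IN-8 NanoBit signal pair, the p38-stage fitting input."""
    noise = noise or NoiseModel(kind="none", cv=0.0, seed=seed)
    rng_seeds = np.random.SeedSequence(noise.seed).spawn(2)
    parts = []
    for (cond, variant), sub in zip(
        (("CTR", "WT"), ("JNK_IN_8", "JNK_IN_8")), rng_seeds
    ):
        sub_noise = NoiseModel(noise.kind, noise.cv,
                               int(sub.generate_state(1)[0] % (2 ** 31)))
        ds = generate_timecourse_dataset(
            truth_params, variant=variant, condition=cond,
            observables=("p38_atf2_complex_norm",),
            sampling_times_min=sampling_times_min,
            noise=sub_noise, seed=seed, nanobit=True,
        )
        parts.append(ds.table)
    table = pd.concat(parts, ignore_index=True)
    return SyntheticDataset(
        table=table,
        generating_parameters=truth_params.as_dict(),
        design={"conditions": ["CTR", "JNK_IN_8"],
                "sampling_times_min": list(sampling_times_min),
                "nanobit": True},
        noise=noise,
        seed=seed,
    )


def generate_p38_stage_bundle(
    truth_params: ModelParameters,
    sampling_times_min: tuple[float, ...] = DEFAULT_SAMPLING_MIN,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Complete p38-stage fitting input: NanoBit pair + pp-p38 blot series.

    The control pp-p38 western-blot-like time course accompanies the two
    NanoBit complex signals; without it the normalized complex signal
    leaves (k_stim6, dp2) degenerate along a compensation valley.
    """
    noise = noise or NoiseModel(kind="none", cv=0.0, seed=seed)
    nb = generate_nanobit_pair(truth_params, sampling_times_min, noise, seed)
    blot_noise = NoiseModel(noise.kind, noise.cv, noise.seed + 50000)
    blot = generate_timecourse_dataset(
        truth_params, variant="WT", condition="CTR",
        observables=("pp_p38_fraction",),
        sampling_times_min=sampling_times_min,
        noise=blot_noise, seed=seed,
    )
    table = pd.concat([nb.table, blot.table], ignore_index=True)
    return SyntheticDataset(
        table=table,
        generating_parameters=truth_params.as_dict(),
        design={"conditions": ["CTR", "JNK_IN_8"],
                "observables": ["p38_atf2_complex_norm", "pp_p38_fraction"],
                "sampling_times_min": list(sampling_times_min)},
        noise=noise,
        seed=seed,
    )


def generate_invitro_dataset(
    kind: str,
    vmax: float = 1.0,
    km_um: float = KM_REF_UM,
    ki_um: float = 33.6,
    hill: float = 1.0,
    substrate_um: float = ASSAY_SUBSTRATE_UM,
    design: tuple[float, ...] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Saturation (``michaelis_menten``) or peptide ``inhibition`` tables.

    Inhibition activities follow a logistic curve with midpoint
    IC50 = Ki·(1 + S/KM) — the forward form of the competitive Ki
    conversion.
    """
    noise = noise or NoiseModel(kind="none", cv=0.0, seed=seed)
    rng = np.random.default_rng(noise.seed)
    if kind == "michaelis_menten":
        series = np.asarray(design or DEFAULT_SUBSTRATE_SERIES_UM, dtype=float)
        clean = vmax * series / (km_um + series)
        values = noise.apply(clean, rng)
        table = pd.DataFrame(
            {"substrate_uM": series, "replicate": 1, "value": values}
        )
        truth = {"vmax": vmax, "km_um": km_um}
    elif kind == "inhibition":
        series = np.asarray(design or DEFAULT_DOSE_SERIES_UM, dtype=float)
        ic50 = ic50_from_ki(ki_um, substrate_um, km_um)
        clean = 1.0 / (1.0 + (series / ic50) ** hill)
        values = noise.apply(clean, rng)
        table = pd.DataFrame({"dose_uM": series, "replicate": 1, "value": values})
        truth = {"ki_um": ki_um, "ic50_um": ic50, "km_um": km_um,
                 "substrate_um": substrate_um, "hill": hill}
    else:
        raise ConfigurationError(
            f"unknown assay kind {kind!r}; expected michaelis_menten or inhibition"
        )
    return SyntheticDataset(
        table=table,
        generating_parameters=truth,
        design={"kind": kind, "series_uM": series.tolist()},
        noise=noise,
        seed=seed,
    )
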