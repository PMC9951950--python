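"""Synthetic paired observed/simulated dataset generator.

Emulates the study design this package targets: a handful of forage diets,
a few steers per diet, observed intake anchored to the stub predictor,
observed methane proportional to intake, and simulated values related to
observed ones through group-specific multiplicative ratios. All noise is
multiplicative lognormal — every quantity is a positive rate or ratio, and
no error model is prescribed by the source data.

The generator exists to test the evaluation statistics, not to model animal
science: with the ratio ``rho`` and log-noise SD ``sigma``, the expected
mean S/O ratio is exactly ``rho * exp(sigma^2 / 2)``, which
:func:`recovery_check` exposes for parameter-recovery assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import AnimalRecord, DietComposition, default_diets, to_paired
from .errors import ConfigurationError, ValidationError
from .stub_model import StubParams, stub_predict

BW_FLOOR_KG = 120.0
_MAX_RESAMPLE = 1000


@dataclass
class GeneratorConfig:
    diets: list[DietComposition] = field(default_factory=default_diets)
    steers_per_diet: int = 4
    bw_mean: float = 206.0
    bw_sd: float = 36.0
    sigma_animal: float = 0.12  # SD of log animal intake effect
    ch4_yield: float = 34.5  # L CH4 per kg DMI observed
    leucaena_reduction: float = 0.10
    rho_dmi: float = 1.07
    rho_ch4_no_leuc: float = 0.637
    rho_ch4_leuc: float = 0.769
    sigma_sim: float = 0.05  # SD of log simulation error
    sigma_ch4_obs: float = 0.08  # SD of log day-level methane noise
    seed: int = 0
    stub_params: StubParams = field(default_factory=StubParams)

    def __post_init__(self) -> None:
        for name in ("sigma_animal", "sigma_sim", "sigma_ch4_obs", "bw_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("rho_dmi", "rho_ch4_no_leuc", "rho_ch4_leuc", "ch4_yield"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.leucaena_reduction < 1:
            raise ConfigurationError("leucaena_reduction must be in [0, 1)")
        if self.steers_per_diet < 1:
            raise ConfigurationError("steers_per_diet must be >= 1")
        if self.bw_mean <= BW_FLOOR_KG:
            raise ConfigurationError(f"bw_mean must exceed the {BW_FLOOR_KG} kg floor")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)


def _draw_bw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal body weight truncated below at the floor (resampling)."""
    for _ in range(_MAX_RESAMPLE):
        bw = rng.normal(mean, sd)
        if bw > BW_FLOOR_KG:
            return float(bw)
    raise ValidationError(
        f"could not draw bw > {BW_FLOOR_KG} kg in {_MAX_RESAMPLE} tries "
        f"(mean={mean}, sd={sd})"
    )


def generate(config: GeneratorConfig) -> list[AnimalRecord]:
    """Generate one paired dataset; deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    records: list[AnimalRecord] = []
    for period, diet in enumerate(config.diets, start=1):
        rho_ch4 = config.rho_ch4_leuc if diet.leucaena else config.rho_ch4_no_leuc
        for steer in range(1, config.steers_per_diet + 1):
            bw = _draw_bw(rng, config.bw_mean, config.bw_sd)
            dmi_base, _ = stub_predict(diet, bw, config.stub_params)
            dmi_obs = dmi_base * math.exp(rng.normal(0.0, config.sigma_animal))
            ch4_obs = (
                config.ch4_yield
                * dmi_obs
                * (1.0 - config.leucaena_reduction * diet.leucaena)
                * math.exp(rng.normal(0.0, config.sigma_ch4_obs))
            )
            dmi_sim = config.rho_dmi * dmi_obs * math.exp(
                rng.normal(0.0, config.sigma_sim)
            )
            ch4_sim = rho_ch4 * ch4_obs * math.exp(rng.normal(0.0, config.sigma_sim))
            records.append(
                AnimalRecord(
                    animal_id=f"s{steer:03d}",
                    diet_id=diet.diet_id,
                    period=period,
                    bw_kg=bw,
                    dmi_obs=dmi_obs,
                    dmi_sim=dmi_sim,
                    ch4_obs=ch4_obs,
                    ch4_sim=ch4_sim,
                )
            )
    return records


def expected_msor(rho: float, sigma_sim: float) -> float:
    """Expected mean S/O ratio under the lognormal error model: rho * exp(sigma^2/2)."""
    return rho * math.exp(sigma_sim**2 / 2.0)


def recovery_check(
    config: GeneratorConfig, n_steers_large: int
) -> dict[str, tuple[float, float]]:
    """Estimated vs expected mean S/O ratio at large n, per variable/group.

    Scales the design so every diet group holds at least ``n_steers_large``
    animals, generates one dataset, and returns
    ``{"dmi": (est, expected), "ch4_no_leuc": ..., "ch4_leuc": ...}``
    for assertion by the caller.
    """
    if n_steers_large < 100:
        raise ConfigurationError("n_steers_large must be >= 100 for a stable estimate")
    n_leuc = sum(d.leucaena for d in config.diets)
    n_no = len(config.diets) - n_leuc
    if n_leuc == 0 or n_no == 0:
        raise ConfigurationError("recovery check needs diets in both groups")
    per_diet = math.ceil(n_steers_large / min(n_leuc, n_no))
    big = replace(config, steers_per_diet=per_diet)
    records = generate(big)

    out: dict[str, tuple[float, float]] = {}
    dmi = to_paired(records, "dmi", config.diets)
    out["dmi"] = (
        float((dmi.s / dmi.o).mean()),
        expected_msor(config.rho_dmi, config.sigma_sim),
    )
    ch4 = to_paired(records, "ch4", config.diets)
    ratios = ch4.s / ch4.o
    out["ch4_no_leuc"] = (
        float(ratios[~ch4.group].mean()),
        expected_msor(config.rho_ch4_no_leuc, config.sigma_sim),
    )
    out["ch4_leuc"] = (
        float(ratios[ch4.group].mean()),
        expected_msor(config.rho_ch4_leuc, config.sigma_sim),
    )
    return out
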