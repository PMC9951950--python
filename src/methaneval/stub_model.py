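"""Pluggable intake + methane predictor interface and a stoichiometric stub implementation.

The stub is deliberately simple. Intake is a metabolic-weight scaling damped
by a fiber-fill term; fermentable substrate is partitioned into digested
fiber and non-structural carbohydrate, throttled by protein availability and
penalized by fat and ash; methane is derived from fermented hexose through a
Wolin-type yield that falls as the non-structural share of carbohydrate
rises. The normative contract is the direction of the methane response to
each composition variable, not the constants — any predictor honouring the
:class:`PredictorModel` protocol can be registered and substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Callable, Mapping, Protocol, runtime_checkable

from .dataset import DietComposition
from .errors import ConfigurationError, ValidationError

HEXOSE_MOLAR_MASS_G = 162.0  # g/mol anhydrous hexose
MOLAR_VOLUME_L = 22.4  # L/mol at STP


@dataclass(frozen=True)
class StubParams:
    """Constants of the stub predictor. All must be positive; the methane
    yield ``y0 - y1*phi`` must stay positive over the plausible range of the
    non-structural carbohydrate share phi (0 to 0.35)."""

    c_intake: float = 0.095  # intake scale, kg DM per kg^0.75
    theta: float = 1.25  # fiber-fill exponent
    ndf_ref: float = 65.0  # reference NDF, % DM
    gamma: float = 0.8  # non-structural inhibition of fiber digestion
    d_nsc: float = 0.9  # NSC digestibility
    k_cp: float = 4.0  # protein half-saturation, % DM
    kappa_ee: float = 2.0  # fat penalty per unit fraction
    lambda_ash: float = 0.5  # ash penalty per unit fraction
    y0: float = 0.44  # methane yield intercept, mol CH4 / mol hexose
    y1: float = 0.60  # methane yield slope vs phi
    c_methane: float = 1.6  # calibration scale

    # penalty/inhibition terms may be zeroed to switch a pathway off
    _NONNEGATIVE = ("gamma", "kappa_ee", "lambda_ash", "y1")

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in self._NONNEGATIVE:
                if value < 0:
                    raise ConfigurationError(
                        f"stub parameter {name} must be >= 0, got {value}"
                    )
            elif not value > 0:
                raise ConfigurationError(f"stub parameter {name} must be > 0, got {value}")
        if self.y0 - self.y1 * 0.35 <= 0:
            raise ConfigurationError(
                "methane yield y0 - y1*phi must remain positive for phi <= 0.35"
            )


@runtime_checkable
class PredictorModel(Protocol):
    """Contract for any intake + methane predictor."""

    name: str

    def predict(self, diet: DietComposition, bw_kg: float) -> tuple[float, float]:
        """Return (dmi_pred kg DM/d, ch4_pred L/d); strictly positive, deterministic."""
        ...


def stub_predict(
    diet: DietComposition, bw_kg: float, params: StubParams | None = None
) -> tuple[float, float]:
    """Predict (dmi kg DM/d, ch4 L/d) for one diet composition and body weight."""
    if not bw_kg > 0:
        raise ValidationError(f"bw_kg must be > 0, got {bw_kg}")
    p = params or StubParams()
    dmi = p.c_intake * bw_kg**0.75 * (p.ndf_ref / diet.ndf) ** p.theta

    phi = diet.nsc / (diet.nsc + diet.ndf)
    if not 0 <= phi < 1:
        raise ConfigurationError(f"carbohydrate share phi={phi} outside [0, 1)")
    yield_per_hexose = p.y0 - p.y1 * phi
    if yield_per_hexose <= 0:
        raise ConfigurationError(
            f"negative methane yield at phi={phi:.3f}; adjust y0/y1"
        )
    fermentable_g = (
        dmi
        * 1000.0
        * (
            (diet.ndf / 100.0) * (diet.ivdmd / 100.0) * (1.0 - p.gamma * phi)
            + (diet.nsc / 100.0) * p.d_nsc
        )
        * (diet.cp / (diet.cp + p.k_cp))
        * (1.0 - p.kappa_ee * diet.ee / 100.0)
        * (1.0 - p.lambda_ash * diet.ash / 100.0)
    )
    ch4 = (
        p.c_methane
        * (fermentable_g / HEXOSE_MOLAR_MASS_G)
        * yield_per_hexose
        * MOLAR_VOLUME_L
    )
    if not (math.isfinite(dmi) and math.isfinite(ch4) and dmi > 0 and ch4 > 0):
        raise ValidationError(
            f"non-positive or non-finite prediction for diet {diet.diet_id}"
        )
    return dmi, ch4


class StubPredictor:
    """:class:`PredictorModel` wrapper around :func:`stub_predict`."""

    name = "stub"

    def __init__(self, params: StubParams | None = None):
        self.params = params or StubParams()

    def predict(self, diet: DietComposition, bw_kg: float) -> tuple[float, float]:
        return stub_predict(diet, bw_kg, self.params)

    def with_params(self, **overrides) -> "StubPredictor":
        return StubPredictor(replace(self.params, **overrides))


_REGISTRY: dict[str, Callable[..., PredictorModel]] = {}


def register_predictor(name: str, factory: Callable[..., PredictorModel]) -> None:
    """Register a predictor factory under ``name`` for CLI/plug-in discovery."""
    _REGISTRY[name] = factory


def get_predictor(name: str, **kwargs) -> PredictorModel:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown predictor {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


register_predictor("stub", lambda params=None: StubPredictor(params))

SENSITIVITY_VARIABLES = ("cp", "ndf", "nsc", "ee", "ash", "ivdmd")


def finite_difference_signs(
    model: PredictorModel,
    diet: DietComposition,
    bw_kg: float,
    var_ranges: Mapping[str, tuple[float, float]],
) -> dict[str, int]:
    """Sign of the methane response to moving each variable from its range
    minimum to its maximum, the others held at the diet's values.

    Returns {variable: -1 | 0 | +1}.
    """
    signs: dict[str, int] = {}
    for var, (lo, hi) in var_ranges.items():
        if var not in SENSITIVITY_VARIABLES:
            raise ConfigurationError(f"unknown sensitivity variable {var!r}")
        try:
            ch4_lo = model.predict(replace(diet, **{var: lo}), bw_kg)[1]
            ch4_hi = model.predict(replace(diet, **{var: hi}), bw_kg)[1]
        except Exception as exc:
            raise ValidationError(f"prediction failed varying {var!r}: {exc}") from exc
        if not (math.isfinite(ch4_lo) and math.isfinite(ch4_hi)):
            raise ValidationError(f"non-finite methane prediction varying {var!r}")
        diff = ch4_hi - ch4_lo
        signs[var] = 0 if diff == 0 else (1 if diff > 0 else -1)
    return signs
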