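"""One-at-a-time (OAT) sensitivity analysis of a predictor to diet composition.

Each composition variable is substituted in turn — per base diet — with
levels spanning the dataset minimum to maximum while all other variables keep
their base values. The methane response direction is summarized per variable
(unanimity across bases required; disagreement is reported as ``"mixed"``),
and the run matrix of substituted inputs plus predicted methane undergoes a
standardized principal component analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataset import DietComposition
from .errors import ConfigurationError, InsufficientDataError
from .stub_model import PredictorModel, SENSITIVITY_VARIABLES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OATDesign:
    """The substitution plan: base diets x variables x per-variable levels."""

    bases: tuple[DietComposition, ...]
    variables: tuple[str, ...]
    levels: dict[str, tuple[float, ...]]
    include_baseline: bool = True

    @property
    def size(self) -> int:
        n = sum(len(self.bases) * len(self.levels[v]) for v in self.variables)
        if self.include_baseline:
            n += len(self.bases)
        return n


@dataclass
class SensitivityResult:
    """OAT run matrix, per-variable consensus methane-response signs, PCA summary."""

    runs: pd.DataFrame
    signs: dict[str, int | str]
    pca_loadings: np.ndarray | None
    pca_explained: np.ndarray | None
    pca_columns: list[str] = field(default_factory=list)
    pca_degenerate: bool = False
    failed_runs: list[dict] = field(default_factory=list)

    @property
    def partial_failure(self) -> bool:
        return bool(self.failed_runs)


def build_oat_design(
    diets: Sequence[DietComposition],
    levels_per_variable: int = 2,
    variables: Sequence[str] = SENSITIVITY_VARIABLES,
    include_baseline: bool = True,
) -> OATDesign:
    """Build the min-to-max substitution design over the diet table.

    Levels are ``levels_per_variable`` equally spaced values from the dataset
    minimum to the dataset maximum of each variable. A variable constant
    across all diets has no range and is skipped with a warning.
    """
    if len(diets) < 2:
        raise InsufficientDataError(
            f"need at least 2 diets to define min/max ranges, got {len(diets)}"
        )
    if levels_per_variable < 2:
        raise ConfigurationError(
            f"levels_per_variable must be >= 2, got {levels_per_variable}"
        )
    kept: list[str] = []
    levels: dict[str, tuple[float, ...]] = {}
    for var in variables:
        if var not in SENSITIVITY_VARIABLES:
            raise ConfigurationError(f"unknown sensitivity variable {var!r}")
        values = [getattr(d, var) for d in diets]
        lo, hi = min(values), max(values)
        if lo == hi:
            logger.warning("variable %r constant across diets; skipped", var)
            continue
        kept.append(var)
        levels[var] = tuple(np.linspace(lo, hi, levels_per_variable))
    if not kept:
        raise ConfigurationError("no variable varies across the diet table")
    return OATDesign(
        bases=tuple(diets),
        variables=tuple(kept),
        levels=levels,
        include_baseline=include_baseline,
    )


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def run_sensitivity(
    design: OATDesign,
    model: PredictorModel,
    bw_kg: float,
    seed: int | None = None,
) -> SensitivityResult:
    """Execute the design and summarize methane-response directions and PCA.

    ``seed`` is accepted for stochastic predictors; the stub is deterministic
    and ignores it. A run where the model raises is recorded in
    ``failed_runs`` and excluded from the summaries.
    """
    del seed  # deterministic models ignore it; kept for interface stability
    rows: list[dict] = []
    failed: list[dict] = []

    def _run(diet: DietComposition, varied: str | None, value: float | None, base_id: str):
        try:
            dmi, ch4 = model.predict(diet, bw_kg)
        except Exception as exc:
            failed.append({"base_diet": base_id, "variable": varied, "value": value,
                           "error": str(exc)})
            logger.warning("run failed (base=%s, var=%s=%s): %s", base_id, varied, value, exc)
            return
        rows.append({
            "base_diet": base_id,
            "variable": varied if varied is not None else "baseline",
            "value": value,
            "cp": diet.cp, "ndf": diet.ndf, "nsc": diet.nsc,
            "ee": diet.ee, "ash": diet.ash, "ivdmd": diet.ivdmd,
            "dmi_pred": dmi, "ch4_pred": ch4,
        })

    if design.include_baseline:
        for base in design.bases:
            _run(base, None, None, base.diet_id)
    for base in design.bases:
        for var in design.variables:
            for level in design.levels[var]:
                _run(replace(base, **{var: float(level)}), var, float(level), base.diet_id)

    runs = pd.DataFrame(rows)

    signs: dict[str, int | str] = {}
    for var in design.variables:
        lo, hi = design.levels[var][0], design.levels[var][-1]
        per_base: list[int] = []
        for base in design.bases:
            sub = runs[(runs.base_diet == base.diet_id) & (runs.variable == var)]
            at_lo = sub[sub.value == lo]["ch4_pred"]
            at_hi = sub[sub.value == hi]["ch4_pred"]
            if at_lo.empty or at_hi.empty:
                continue  # failed run; base excluded from consensus
            per_base.append(_sign(float(at_hi.iloc[0]) - float(at_lo.iloc[0])))
        if not per_base:
            signs[var] = "mixed"
        elif len(set(per_base)) == 1:
            signs[var] = per_base[0]
        else:
            signs[var] = "mixed"

    loadings = explained = None
    pca_cols = [*design.variables, "ch4_pred"]
    degenerate = False
    sub = runs[runs.variable != "baseline"] if design.include_baseline else runs
    matrix = sub[pca_cols].to_numpy(dtype=float) if len(sub) else np.empty((0, 0))
    if matrix.shape[0] >= 2:
        sd = matrix.std(axis=0, ddof=0)
        if np.any(sd == 0):
            degenerate = True
            keep = sd > 0
            matrix = matrix[:, keep]
            pca_cols = [c for c, k in zip(pca_cols, keep) if k]
            sd = sd[keep]
        if matrix.shape[1] >= 1:
            z = (matrix - matrix.mean(axis=0)) / sd
            pca = PCA(n_components=min(z.shape[0] - 1, z.shape[1]))
            pca.fit(z)
            loadings = pca.components_
            explained = pca.explained_variance_ratio_
    else:
        degenerate = True

    return SensitivityResult(
        runs=runs,
        signs=signs,
        pca_loadings=loadings,
        pca_explained=explained,
        pca_columns=pca_cols,
        pca_degenerate=degenerate,
        failed_runs=failed,
    )
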