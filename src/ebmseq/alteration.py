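"""Normative modelling and alteration weights.

Controls define a normative reference: each regional measure is regressed on
age and sex over controls only, and a patient's deviation below the predicted
normative value — in units of the control residual SD — is mapped onto a
fuzzy alteration weight in [0, 1]. A weight of 0 means the patient sits at
the normative mean; a weight of 1 means the measure is at or below
``cutoff_sd`` residual SD under it (default 2.5). Between the endpoints the
mapping is a linear ramp; deviations in the healthy direction (above the
normative prediction) map to 0. Alteration is a *decrease* for both cortical
thickness and fractional anisotropy, so the deviation sign convention is
shared across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .synthetic import CLINICAL_COLUMNS


class FittingError(ValueError):
    """Normative fit is not identifiable (too few controls or zero variance)."""


def linear_ramp(d_over_cutoff: np.ndarray) -> np.ndarray:
    """Default weighting function: clamp(d / cutoff, 0, 1)."""
    return np.clip(d_over_cutoff, 0.0, 1.0)


@dataclass
class WeightConfig:
    """How deviations become weights.

    cutoff_sd
        Residual-SD deviation at which the weight saturates at 1. Default
        2.5; 2.0 and 3.0 are the conventional sensitivity settings.
    ramp
        Maps deviation / cutoff_sd to a weight; pluggable, default linear.
    """

    cutoff_sd: float = 2.5
    ramp: Callable[[np.ndarray], np.ndarray] = field(default=linear_ramp)

    def __post_init__(self) -> None:
        if self.cutoff_sd <= 0:
            raise ValueError("cutoff_sd must be > 0")


@dataclass
class NormativeModel:
    """Per-region linear fit on controls: measure ~ intercept + age + sex."""

    #: rows indexed by region_id; columns intercept, age_coef, sex_coef, residual_sd
    params: pd.DataFrame
    n_controls: int
    #: the two sex levels, in the order mapped to (0, 1)
    sex_levels: tuple[str, str]

    def predict(self, age: np.ndarray, sex_numeric: np.ndarray) -> np.ndarray:
        """Predicted normative measures, subjects x regions."""
        p = self.params
        return (
            p["intercept"].to_numpy()[None, :]
            + np.outer(age, p["age_coef"].to_numpy())
            + np.outer(sex_numeric, p["sex_coef"].to_numpy())
        )


def _region_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in CLINICAL_COLUMNS]


def _encode_sex(sex: pd.Series, levels: tuple[str, str] | None = None) -> tuple[np.ndarray, tuple[str, str]]:
    """Fixed contrast: the lexicographically first level is 0, the other 1."""
    observed = sorted(map(str, sex.unique()))
    if levels is None:
        if len(observed) > 2:
            raise ValueError(f"sex must have at most two levels, got {observed}")
        levels = tuple(observed) if len(observed) == 2 else (observed[0], "__other__")
    unknown = set(map(str, sex.unique())) - set(levels)
    if unknown:
        raise ValueError(f"unknown sex levels {sorted(unknown)}; model fitted with {levels}")
    return (sex.astype(str) == levels[1]).to_numpy(dtype=float), levels


def fit_normative(controls: pd.DataFrame) -> NormativeModel:
    """Fit the per-region normative model on a table of control subjects.

    Requires strictly more controls than the three regression parameters so
    the residual SD has at least one degree of freedom.
    """
    n = len(controls)
    if n < 3:
        raise FittingError(f"need at least 3 controls, got {n}")
    if n <= 3:
        raise FittingError("3 controls exactly interpolate the 3-parameter model (zero residual df)")
    for col in ("age", "sex"):
        if col not in controls.columns:
            raise FittingError(f"controls table lacks required column {col!r}")
    regions = _region_columns(controls)
    sex_num, levels = _encode_sex(controls["sex"])
    X = np.column_stack([np.ones(n), controls["age"].to_numpy(dtype=float), sex_num])
    Y = controls[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    residual_sd = np.sqrt((resid**2).sum(axis=0) / dof)
    # relative floor: exact fits leave only float residue proportional to |Y|
    zero = residual_sd <= 1e-10 * (1.0 + np.abs(Y).mean(axis=0))
    if zero.any():
        bad = regions[int(np.argmax(zero))]
        raise FittingError(f"zero residual variance for region {bad!r}")
    params = pd.DataFrame(
        {
            "intercept": beta[0],
            "age_coef": beta[1],
            "sex_coef": beta[2],
            "residual_sd": residual_sd,
        },
        index=pd.Index(regions, name="region_id"),
    )
    return NormativeModel(params=params, n_controls=n, sex_levels=levels)


def compute_weights(
    patients: pd.DataFrame, model: NormativeModel, cfg: WeightConfig | None = None
) -> pd.DataFrame:
    """Alteration weights in [0, 1], patients x regions.

    The deviation is (predicted normative - observed) / residual SD, so
    positive means a reduced measure; the ramp maps deviation / cutoff_sd
    into [0, 1].
    """
    cfg = cfg or WeightConfig()
    regions = _region_columns(patients)
    missing = [r for r in regions if r not in model.params.index]
    if missing:
        raise KeyError(f"region {missing[0]!r} missing from normative model")
    sex_num, _ = _encode_sex(patients["sex"], model.sex_levels)
    pred = model.predict(patients["age"].to_numpy(dtype=float), sex_num)
    pred = pred[:, [model.params.index.get_loc(r) for r in regions]]
    observed = patients[regions].to_numpy(dtype=float)
    sd = model.params.loc[regions, "residual_sd"].to_numpy()
    deviation = (pred - observed) / sd[None, :]
    w = cfg.ramp(deviation / cfg.cutoff_sd)
    index = (
        patients["subject_id"].to_numpy()
        if "subject_id" in patients.columns
        else patients.index
    )
    return pd.DataFrame(w, index=index, columns=regions)


# ---------------------------------------------------------------------------
# serialization

def write_weights(w: pd.DataFrame, path: str | Path) -> None:
    w.to_csv(path, index_label="subject_id")


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_model(model: NormativeModel, path: str | Path) -> None:
    df = model.params.copy()
    df.insert(0, "n_controls", model.n_controls)
    df.insert(1, "sex_levels", "/".join(model.sex_levels))
    df.to_csv(path)


def read_model(path: str | Path) -> NormativeModel:
    df = pd.read_csv(path, index_col="region_id")
    levels = tuple(str(df["sex_levels"].iloc[0]).split("/"))
    return NormativeModel(
        params=df[["intercept", "age_coef", "sex_coef", "residual_sd"]],
        n_controls=int(df["n_controls"].iloc[0]),
        sex_levels=levels,  # type: ignore[arg-type]
    )
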