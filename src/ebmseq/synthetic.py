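"""Synthetic cohorts with a planted event ordering.

The generator emulates the statistical structure the downstream analysis
assumes: regional measures (cortical thickness for GM, fractional anisotropy
for WM) that are linear in age and sex with Gaussian noise in controls, and in
patients are additionally reduced along a planted monotone ordering of
"structural alteration" events. Each patient carries a latent disease time;
the reduction of region ``r`` ramps in sigmoidally as the latent time passes
the region's onset position. Clinical milestones (Hoehn-Yahr stage, cognitive
status) and symptom severity (UPDRS total) are coupled monotonically to the
same latent time, which is what lets staging and state-severity association
be tested against ground truth.

Within-patient regional noise is independent; real cohorts show correlated
residuals across regions, which this generator deliberately does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import atlas as atlas_mod

#: fixed two-level sex contrast used throughout: F -> 0, M -> 1
SEX_LEVELS = ("F", "M")

CLINICAL_COLUMNS = ["subject_id", "group", "age", "sex", "hys", "cognitive_status", "updrs"]


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration; message names the field."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a cohort of the scale and effect structure of a
    single-site Parkinson's disease study: 130 patients and 75 normative
    controls over 62 cortical GM and 48 WM regions, with WM events planted
    before GM events. Measures are in generic "measure units" (think mm of
    cortical thickness); the planted drop spans 6 residual SD so that fully
    altered regions sit well past a 2.5-SD cutoff.
    """

    n_patients: int = 130
    n_controls: int = 75
    n_gm_regions: int = 62
    n_wm_regions: int = 48
    #: event ids in planted onset order; None -> WM regions first, then GM
    planted_order: list[str] | None = None
    #: per-event onset on the latent-time axis, increasing along planted_order;
    #: None -> evenly spaced on [1, 9]
    onset_positions: np.ndarray | None = None
    effect_size: float = 0.3
    transition_width: float = 0.3
    noise_sd: float = 0.05
    age_slope: float = -0.005
    sex_offset: float = 0.02
    gm_baseline: float = 2.5
    wm_baseline: float = 0.45
    #: latent-time cutpoints for HYS>=2, HYS>=3, MCI, dementia
    clinical_thresholds: dict = field(
        default_factory=lambda: {"hys2": 4.0, "hys3": 8.0, "mci": 3.5, "dementia": 8.5}
    )
    updrs_slope: float = 4.0
    updrs_noise_sd: float = 8.0
    #: latent times are uniform on [min(onset) - margin, max(onset) + margin]
    latent_margin: float = 1.0
    #: explicit per-patient latent times (overrides the uniform draw)
    latent_times: np.ndarray | None = None
    seed: int = 0

    def resolve_atlas(self) -> pd.DataFrame:
        if self.n_gm_regions == 62 and self.n_wm_regions == 48:
            return atlas_mod.default_atlas()
        return atlas_mod.synthetic_atlas(self.n_gm_regions, self.n_wm_regions)

    def resolve_order(self, atlas: pd.DataFrame) -> list[str]:
        if self.planted_order is not None:
            return list(self.planted_order)
        wm = atlas.loc[atlas["tissue"] == atlas_mod.WM, "region_id"].tolist()
        gm = atlas.loc[atlas["tissue"] == atlas_mod.GM, "region_id"].tolist()
        return wm + gm

    def resolve_onsets(self, n_events: int) -> np.ndarray:
        if self.onset_positions is not None:
            return np.asarray(self.onset_positions, dtype=float)
        return np.linspace(1.0, 9.0, n_events)

    def validate(self) -> None:
        for name in ("n_patients", "n_controls", "n_gm_regions", "n_wm_regions"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_gm_regions + self.n_wm_regions < 1:
            raise ConfigurationError("n_gm_regions + n_wm_regions must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.transition_width < 0:
            raise ConfigurationError("transition_width must be >= 0")
        atlas = self.resolve_atlas()
        order = self.resolve_order(atlas)
        if sorted(order) != sorted(atlas["region_id"]):
            raise ConfigurationError("planted_order must be a permutation of the atlas region ids")
        onsets = self.resolve_onsets(len(order))
        if len(onsets) != len(order):
            raise ConfigurationError("onset_positions must have one entry per event")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ConfigurationError("onset_positions must be strictly increasing along planted_order")
        th = self.clinical_thresholds
        for key in ("hys2", "hys3", "mci", "dementia"):
            if key not in th:
                raise ConfigurationError(f"clinical_thresholds missing {key!r}")
        if not (th["hys2"] < th["hys3"] and th["mci"] < th["dementia"]):
            raise ConfigurationError("clinical_thresholds must be ordered (hys2 < hys3, mci < dementia)")


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic cohort."""

    planted_order: list[str]
    onset_positions: np.ndarray
    #: latent disease time per patient, indexed by subject_id
    latent_time: pd.Series
    #: number of events with onset at or before each patient's latent time
    true_state: pd.Series


def _onset_fraction(latent: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Degree of alteration in [0, 1]; a step function when width == 0."""
    latent = np.asarray(latent, dtype=float)
    if width == 0:
        return np.where(latent > onset, 1.0, np.where(latent < onset, 0.0, 0.5))
    return expit((latent - onset) / width)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort table plus its ground truth.

    The cohort table has the clinical columns followed by one column per
    region id (atlas order). Controls carry HYS 0, cognitive status NC and no
    UPDRS score.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    atlas = config.resolve_atlas()
    order = config.resolve_order(atlas)
    onsets = config.resolve_onsets(len(order))
    region_ids = atlas["region_id"].tolist()
    onset_by_region = dict(zip(order, onsets))

    n_p, n_c = config.n_patients, config.n_controls
    n = n_p + n_c
    # ages roughly matching a PD cohort (patients) and PPMI-like controls
    age = np.concatenate(
        [
            np.clip(rng.normal(69.0, 10.0, n_p), 40.0, 95.0),
            np.clip(rng.normal(60.0, 11.0, n_c), 30.0, 90.0),
        ]
    )
    sex = rng.random(n) < 0.55  # True = male
    if config.latent_times is not None:
        latent = np.asarray(config.latent_times, dtype=float)
        if latent.shape[0] != n_p:
            raise ConfigurationError("latent_times must have one entry per patient")
    else:
        lo = float(onsets.min()) - config.latent_margin if len(onsets) else 0.0
        hi = float(onsets.max()) + config.latent_margin if len(onsets) else 1.0
        latent = rng.uniform(lo, hi, n_p)

    baselines = np.where(
        atlas["tissue"].to_numpy() == atlas_mod.GM, config.gm_baseline, config.wm_baseline
    )
    normative = (
        baselines[None, :]
        + config.age_slope * age[:, None]
        + config.sex_offset * sex[:, None].astype(float)
    )
    measures = normative + rng.normal(0.0, config.noise_sd, size=(n, len(region_ids)))
    # patients: subtract the planted, latent-time-dependent reduction
    onset_vec = np.array([onset_by_region[r] for r in region_ids])
    frac = np.column_stack(
        [_onset_fraction(latent, o, config.transition_width) for o in onset_vec]
    ) if n_p else np.zeros((0, len(region_ids)))
    measures[:n_p] -= config.effect_size * frac

    th = config.clinical_thresholds
    hys = np.where(latent >= th["hys3"], 3.0, np.where(latent >= th["hys2"], 2.0, 1.0))
    cog = np.where(
        latent >= th["dementia"], "D", np.where(latent >= th["mci"], "MCI", "NC")
    )
    updrs = np.maximum(
        config.updrs_slope * latent + rng.normal(0.0, config.updrs_noise_sd, n_p), 0.0
    )

    subject_ids = [f"pd_{i:04d}" for i in range(n_p)] + [f"hc_{i:04d}" for i in range(n_c)]
    clin = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": ["patient"] * n_p + ["control"] * n_c,
            "age": age,
            "sex": np.where(sex, "M", "F"),
            "hys": np.concatenate([hys, np.zeros(n_c)]),
            "cognitive_status": np.concatenate([cog, np.array(["NC"] * n_c)]),
            "updrs": np.concatenate([updrs, np.full(n_c, np.nan)]),
        }
    )
    cohort = pd.concat(
        [clin, pd.DataFrame(measures, columns=region_ids)], axis=1
    )

    latent_s = pd.Series(latent, index=subject_ids[:n_p], name="latent_time")
    true_state = pd.Series(
        (latent[:, None] >= onsets[None, :]).sum(axis=1) if n_p else np.array([], dtype=int),
        index=subject_ids[:n_p],
        name="true_state",
        dtype=int,
    )
    gt = GroundTruth(
        planted_order=order,
        onset_positions=onsets,
        latent_time=latent_s,
        true_state=true_state,
    )
    return cohort, gt


def binary_alteration_matrix(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Ground-truth binarization of patients' measures for noise-free cohorts.

    Uses the known generative law: a region counts as altered when the
    observed measure sits more than half the planted effect below its
    noiseless normative prediction. On a zero-noise, zero-width cohort this
    returns the exact nested (Guttman) pattern of the planted order.
    """
    atlas = config.resolve_atlas()
    patients = cohort[cohort["group"] == "patient"]
    region_ids = atlas["region_id"].tolist()
    baselines = np.where(
        atlas["tissue"].to_numpy() == atlas_mod.GM, config.gm_baseline, config.wm_baseline
    )
    sex_num = patients["sex"].map({"F": 0.0, "M": 1.0}).to_numpy()
    normative = (
        baselines[None, :]
        + config.age_slope * patients["age"].to_numpy()[:, None]
        + config.sex_offset * sex_num[:, None]
    )
    deficit = normative - patients[region_ids].to_numpy()
    w = (deficit >= 0.5 * config.effect_size).astype(float)
    return pd.DataFrame(w, index=patients["subject_id"].to_numpy(), columns=region_ids)


def guttman_config(
    n_events: int = 20, n_patients: int = 100, n_controls: int = 75, seed: int = 0
) -> GeneratorConfig:
    """Config for a noise-free nested-pattern cohort (half GM, half WM events).

    Zero noise and zero transition width make every patient's altered regions
    an exact prefix of the planted order, and latent times are stratified
    round-robin across every inter-onset gap so patients straddle all onsets
    (every prefix length occurs; no event pair is left unseparated).
    """
    n_wm = n_events // 2
    onsets = np.linspace(1.0, 9.0, n_events)
    boundaries = np.concatenate([[onsets[0] - 1.0], onsets, [onsets[-1] + 1.0]])
    widths = np.diff(boundaries)
    # quarter points of every inter-onset gap: two patients per gap stratum,
    # straddling the gap-centred clinical thresholds
    quarters = np.concatenate(
        [boundaries[:-1] + 0.25 * widths, boundaries[:-1] + 0.75 * widths]
    )
    quarters.sort()
    latent_times = quarters[np.arange(n_patients) % len(quarters)]

    def gap_center(fraction: float) -> float:
        # midpoint of the inter-onset gap nearest the given progression fraction
        if n_events < 2:
            return float(onsets[0]) + fraction
        gaps = (onsets[:-1] + onsets[1:]) / 2.0
        target = onsets[0] + fraction * (onsets[-1] - onsets[0])
        return float(gaps[np.argmin(np.abs(gaps - target))])

    # thresholds centred between onsets so every milestone separates clean
    # blocks of events (no empty latent window hugging an onset)
    thresholds = {
        "hys2": gap_center(0.4),
        "hys3": gap_center(0.85),
        "mci": gap_center(0.3),
        "dementia": gap_center(0.95),
    }
    return GeneratorConfig(
        n_patients=n_patients,
        n_controls=n_controls,
        n_gm_regions=n_events - n_wm,
        n_wm_regions=n_wm,
        noise_sd=0.0,
        transition_width=0.0,
        clinical_thresholds=thresholds,
        latent_times=latent_times,
        seed=seed,
    )


def recovery_config(
    n_events: int = 20, n_patients: int = 200, n_controls: int = 200, seed: int = 0
) -> GeneratorConfig:
    """The standard noisy recovery cohort: steep onsets, moderate noise.

    The planted drop spans 6 residual SD and the transition width is a tenth
    of the onset spacing, a regime in which the event ordering is recoverable
    but weights are genuinely noisy.
    """
    n_wm = n_events // 2
    onsets = np.linspace(1.0, 9.0, n_events)
    spacing = float(onsets[1] - onsets[0]) if n_events > 1 else 1.0
    return GeneratorConfig(
        n_patients=n_patients,
        n_controls=n_controls,
        n_gm_regions=n_events - n_wm,
        n_wm_regions=n_wm,
        noise_sd=0.05,
        effect_size=0.3,
        transition_width=0.1 * spacing,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": gt.latent_time.index,
            "latent_time": gt.latent_time.to_numpy(),
            "true_state": gt.true_state.to_numpy(),
        }
    )
    df.to_csv(path, index=False)


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    data = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in vars(config).items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
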