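"""Clinical staging of the alteration sequence.

Clinical milestones — reaching Hoehn-Yahr stage 2 and 3, or progressing to
MCI and dementia — are encoded as binary per-patient events and simulated
*together with* the structural alteration events. In the resulting modal
sequence the clinical events act as boundary markers: structural events
falling between two adjacent clinical events share a stage. Because a
patient at HYS 3 is necessarily at HYS >= 2 (and a demented patient has
passed MCI), the later milestone's indicator is patient-wise a subset of the
earlier one, which alone forces the milestones into their natural order in
every trajectory: the joint probability of the later milestone occurring
while the earlier is still absent is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .progression import EventSequence, SimulationConfig, modal_sequence, simulate

#: scheme id -> (milestone event ids in natural order)
SCHEMES = {
    "HYS": ("HYS2", "HYS3"),
    "COGNITION": ("MCI", "DEMENTIA"),
}


@dataclass
class ClinicalEventScheme:
    scheme_id: str
    milestones: tuple[str, str]
    #: patients x milestones, values 0/1, later milestone implies earlier
    indicators: pd.DataFrame


@dataclass
class StagedSequence:
    #: modal ordering over structural + clinical events
    sequence: EventSequence
    #: stage label per structural event id
    stages: pd.Series
    #: events per stage, in stage order
    stage_counts: pd.Series
    scheme: ClinicalEventScheme


def build_clinical_events(cohort: pd.DataFrame, scheme_id: str) -> ClinicalEventScheme:
    """Derive milestone indicator columns from the cohort's clinical fields.

    HYS thresholds use >= comparisons, so fractional modified-scale values
    (e.g. 1.5) fall below the stage-2 milestone.
    """
    if scheme_id not in SCHEMES:
        raise ValueError(f"unknown clinical scheme {scheme_id!r}; expected one of {sorted(SCHEMES)}")
    patients = cohort[cohort["group"] == "patient"] if "group" in cohort.columns else cohort
    if scheme_id == "HYS":
        if "hys" not in patients.columns:
            raise ValueError("cohort lacks required clinical field 'hys'")
        hys = patients["hys"].astype(float)
        ind = pd.DataFrame(
            {
                "HYS2": (hys >= 2).astype(int).to_numpy(),
                "HYS3": (hys >= 3).astype(int).to_numpy(),
            },
            index=patients["subject_id"].to_numpy(),
        )
    else:
        if "cognitive_status" not in patients.columns:
            raise ValueError("cohort lacks required clinical field 'cognitive_status'")
        status = patients["cognitive_status"].astype(str)
        ind = pd.DataFrame(
            {
                "MCI": status.isin(["MCI", "D"]).astype(int).to_numpy(),
                "DEMENTIA": (status == "D").astype(int).to_numpy(),
            },
            index=patients["subject_id"].to_numpy(),
        )
    first, second = SCHEMES[scheme_id]
    if (ind[second] > ind[first]).any():
        raise ValueError(
            f"subset property violated: {second} present without {first} for some patient"
        )
    return ClinicalEventScheme(scheme_id=scheme_id, milestones=SCHEMES[scheme_id], indicators=ind)


def stage_events(
    w: pd.DataFrame, scheme: ClinicalEventScheme, cfg: SimulationConfig | None = None
) -> StagedSequence:
    """Simulate the augmented event set and label structural events by stage."""
    cfg = cfg or SimulationConfig()
    ind = scheme.indicators.reindex(w.index)
    if ind.isna().any().any():
        raise ValueError("clinical indicators do not cover every patient in the weight matrix")
    clash = set(ind.columns) & set(w.columns)
    if clash:
        raise ValueError(f"clinical event ids collide with structural events: {sorted(clash)}")
    augmented = pd.concat([w, ind.astype(float)], axis=1)
    seq = modal_sequence(simulate(augmented, cfg))

    first, second = scheme.milestones
    rank = {e: i for i, e in enumerate(seq.order)}
    labels = [f"pre-{first}", f"{first}-{second}", f"post-{second}"]
    stages = {}
    for e in w.columns:
        if rank[e] < rank[first]:
            stages[e] = labels[0]
        elif rank[e] < rank[second]:
            stages[e] = labels[1]
        else:
            stages[e] = labels[2]
    stages_s = pd.Series(stages, name="stage")
    counts = stages_s.value_counts().reindex(labels, fill_value=0)
    return StagedSequence(sequence=seq, stages=stages_s, stage_counts=counts, scheme=scheme)


def write_staged(staged: StagedSequence, path: str | Path) -> None:
    seq = staged.sequence
    rows = []
    for i, e in enumerate(seq.order):
        rows.append(
            {
                "rank": i + 1,
                "event": e,
                "kind": "clinical" if e in staged.scheme.milestones else "structural",
                "stage": staged.stages.get(e, ""),
                "modal_freq": seq.modal_freq[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
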