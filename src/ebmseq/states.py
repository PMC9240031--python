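"""Per-patient disease states and their association with symptom severity.

A disease state k means the first k events of the inferred sequence have
occurred; its template vector has ones through position k and zeros after.
A patient's state is the k maximizing the scalar product between the
template and the patient's observed alteration weights reordered by the
sequence — i.e. the running sum of the first k reordered weights. Ties
resolve to the earliest (most conservative) state, which also absorbs the
all-zero patient into state 1. The weights enter continuously, not
binarized, so the maximizer is well defined except under exact ties.

The ordinal association between predicted states and UPDRS totals is
Kendall's tau-b (tie-corrected — states are heavily tied in cohorts of this
size) with the asymptotic normal two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .progression import EventSequence


@dataclass
class DiseaseStateAssignment:
    #: per patient: 1-based state index and the maximizing scalar product
    table: pd.DataFrame  # columns: state, score


@dataclass
class AssociationResult:
    tau: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def predict_state(w_row: np.ndarray | pd.Series, seq: EventSequence) -> tuple[int, float]:
    """State index (1..R) and score for one patient.

    ``w_row`` may be a Series indexed by event id (reordered internally) or
    a bare array already in sequence order.
    """
    if isinstance(w_row, pd.Series):
        missing = [e for e in seq.order if e not in w_row.index]
        if missing:
            raise ValueError(f"weights missing event {missing[0]!r}")
        v = w_row.reindex(seq.order).to_numpy(dtype=float)
    else:
        v = np.asarray(w_row, dtype=float)
        if v.shape[0] != len(seq.order):
            raise ValueError(
                f"weight vector length {v.shape[0]} != sequence length {len(seq.order)}"
            )
    scores = np.cumsum(v)
    state = int(np.argmax(scores)) + 1  # argmax takes the first maximizer
    return state, float(scores[state - 1])


def predict_states(w: pd.DataFrame, seq: EventSequence) -> DiseaseStateAssignment:
    """Vectorized state prediction for every patient in the weight matrix."""
    v = w[seq.order].to_numpy(dtype=float)
    scores = np.cumsum(v, axis=1)
    state = scores.argmax(axis=1) + 1
    best = scores[np.arange(len(state)), state - 1]
    return DiseaseStateAssignment(
        table=pd.DataFrame({"state": state, "score": best}, index=w.index)
    )


def associate_with_updrs(
    states: DiseaseStateAssignment, updrs: pd.Series
) -> AssociationResult:
    """Kendall tau-b between predicted states and UPDRS totals."""
    joined = states.table.join(updrs.rename("updrs"), how="inner").dropna(subset=["updrs"])
    if len(joined) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(joined)}")
    x = joined["state"].to_numpy(dtype=float)
    y = joined["updrs"].to_numpy(dtype=float)
    if np.all(x == x[0]) and np.all(y == y[0]):
        raise ValueError("Kendall tau undefined: all states and all scores identical")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    if np.isnan(res.statistic):
        raise ValueError("Kendall tau undefined (a variable is constant)")
    return AssociationResult(tau=float(res.statistic), p_value=float(res.pvalue), n=len(joined))


def write_states(states: DiseaseStateAssignment, path: str | Path) -> None:
    states.table.to_csv(path, index_label="subject_id")


def write_association(result: AssociationResult, path: str | Path) -> None:
    pd.DataFrame(
        [{"kendall_tau": result.tau, "p_value": result.p_value, "n": result.n}]
    ).to_csv(path, index=False)
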