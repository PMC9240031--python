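"""Stochastic simulation of monotone event progressions.

The event-progression model assumes alterations accumulate monotonically:
each simulated trajectory starts with no events and adds one event per step
until all have occurred. At every step, the chance that event X comes next is
its conditional probability of being present given that all still-remaining
events are absent, estimated from the patient weight matrix under the
within-patient independence convention:

    score(X) = sum_i w_iX * prod_{Y rem, Y != X} (1 - w_iY)
               -----------------------------------------------
               sum_i       prod_{Y rem, Y != X} (1 - w_iY)

The next event is drawn from the scores normalized over remaining events.
Repeating this many times yields per-step occurrence counts, and the modal
sequence — the event most frequent at each step, assigned greedily without
repetition — is the inferred population-level ordering.

Two implementations share these semantics: a direct per-state evaluator
(`step_probabilities` / `sample_trajectory`) that computes every
leave-one-out product explicitly, and a batched sampler (`simulate`) that
advances all trajectories in lock-step using running products and BLAS
mat-mults. Weights within ``epsilon`` of 1 are snapped to exactly 1 and
handled by zero-factor counting, so the running products never divide by a
vanishing (1 - w) factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SimulationConfig:
    """Trajectory-simulation settings.

    n_trajectories defaults to the standard one-million production run;
    analyses at ten thousand are already stable for tens of events and are
    what the bundled drivers use.
    """

    n_trajectories: int = 1_000_000
    seed: int = 0
    #: weights above 1 - epsilon are treated as exactly 1 (certain events)
    epsilon: float = 1e-9
    #: trajectories advanced per batch; caps memory at n_patients x batch
    batch_size: int = 20_000

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if not (0 <= self.epsilon <= 0.01):
            raise ValueError("epsilon must lie in [0, 0.01]")


@dataclass
class TrajectoryCounts:
    """Occurrence counts: entry [step, event] = trajectories placing event at step."""

    counts: pd.DataFrame
    n_trajectories: int


@dataclass
class EventSequence:
    """An event ordering plus each step's modal frequency."""

    order: list[str]
    modal_freq: np.ndarray

    def ranks(self) -> pd.Series:
        """1-based rank per event id."""
        return pd.Series(range(1, len(self.order) + 1), index=self.order)


def step_probabilities(w: pd.DataFrame, altered: set[str] | frozenset[str]) -> pd.Series:
    """Distribution over remaining events for the next alteration.

    Exact leave-one-out evaluation; falls back to uniform over the remaining
    events when every score is zero (no patient information left).
    """
    remaining = [e for e in w.columns if e not in altered]
    if not remaining:
        raise ValueError("no remaining events: all events already altered")
    W = w[remaining].to_numpy(dtype=float)
    n_rem = len(remaining)
    scores = np.zeros(n_rem)
    one_minus = 1.0 - W
    for j in range(n_rem):
        others = np.delete(one_minus, j, axis=1)
        prod = others.prod(axis=1)
        den = prod.sum()
        scores[j] = (W[:, j] * prod).sum() / den if den > 0 else 0.0
    total = scores.sum()
    if total <= 0:
        probs = np.full(n_rem, 1.0 / n_rem)
    else:
        probs = scores / total
    return pd.Series(probs, index=remaining)


def sample_trajectory(
    w: pd.DataFrame, cfg: SimulationConfig | None = None, rng: np.random.Generator | None = None
) -> EventSequence:
    """Sample a single full trajectory with the direct evaluator."""
    cfg = cfg or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    altered: list[str] = []
    freqs = []
    while len(altered) < w.shape[1]:
        probs = step_probabilities(w, set(altered))
        choice = rng.choice(len(probs), p=probs.to_numpy())
        freqs.append(float(probs.iloc[choice]))
        altered.append(str(probs.index[choice]))
    return EventSequence(order=altered, modal_freq=np.asarray(freqs))


def simulate(w: pd.DataFrame, cfg: SimulationConfig | None = None) -> TrajectoryCounts:
    """Accumulate per-step occurrence counts over many trajectories."""
    cfg = cfg or SimulationConfig()
    events = list(w.columns)
    r = len(events)
    if r == 0:
        raise ValueError("weight matrix has no events")
    counts = np.zeros((r, r), dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    done = 0
    while done < cfg.n_trajectories:
        t = min(cfg.batch_size, cfg.n_trajectories - done)
        counts += _simulate_batch(w.to_numpy(dtype=float), t, cfg.epsilon, rng)
        done += t
    df = pd.DataFrame(counts, index=pd.RangeIndex(r, name="step"), columns=events)
    return TrajectoryCounts(counts=df, n_trajectories=cfg.n_trajectories)


def _simulate_batch(
    W: np.ndarray, n_traj: int, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Advance ``n_traj`` trajectories in lock-step; return per-step counts."""
    n, r = W.shape
    if n == 0:
        # no patients: every step is uniform over remaining events
        W = np.zeros((1, r))
        n = 1
    certain = W >= 1.0 - epsilon  # events snapped to w == 1
    Wf = np.where(certain, 0.0, W)  # finite part, strictly below 1
    one_minus = 1.0 - Wf
    A = Wf / one_minus  # w / (1 - w) for finite weights
    Binv = 1.0 / one_minus
    M = certain.astype(float)

    # per (patient, trajectory) state over the remaining-event set
    pnz = np.repeat(one_minus.prod(axis=1)[:, None], n_traj, axis=1)
    z = np.repeat(certain.sum(axis=1).astype(np.int32)[:, None], n_traj, axis=1)

    assigned = np.zeros((r, n_traj), dtype=bool)
    counts = np.zeros((r, r), dtype=np.int64)
    traj_idx = np.arange(n_traj)
    for step in range(r):
        p0 = np.where(z == 0, pnz, 0.0)
        p1 = np.where(z == 1, pnz, 0.0)
        num1 = M.T @ p1  # certain-event contributions (w == 1 exactly)
        num = A.T @ p0 + num1
        den = Binv.T @ p0 + num1
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(den > 0, num / den, 0.0)
        scores[assigned] = 0.0
        col_tot = scores.sum(axis=0)
        degenerate = col_tot <= 0
        if degenerate.any():
            uniform = (~assigned[:, degenerate]).astype(float)
            scores[:, degenerate] = uniform
            col_tot = scores.sum(axis=0)
        cs = np.cumsum(scores, axis=0)
        rdraw = (1.0 - rng.random(n_traj)) * col_tot  # in (0, total]
        chosen = (cs < rdraw[None, :]).sum(axis=0)
        chosen = np.minimum(chosen, r - 1)
        counts[step] += np.bincount(chosen, minlength=r)
        assigned[chosen, traj_idx] = True
        # remove the chosen event from each trajectory's remaining set
        z -= certain[:, chosen].astype(np.int32)
        pnz *= Binv[:, chosen]
        # rescale per trajectory to keep products in floating range
        peak = pnz.max(axis=0)
        np.divide(pnz, np.where(peak > 0, peak, 1.0)[None, :], out=pnz)
    return counts


def modal_sequence(tc: TrajectoryCounts) -> EventSequence:
    """Greedy per-step modal ordering.

    Step by step, assign the not-yet-assigned event with the largest count at
    that step. Ties break toward the event with more mass over the steps so
    far, then toward atlas (column) order.
    """
    counts = tc.counts.to_numpy(dtype=np.int64)
    events = list(tc.counts.columns)
    r = len(events)
    assigned = np.zeros(r, dtype=bool)
    cumulative = np.zeros(r, dtype=np.int64)
    order: list[str] = []
    freqs = []
    for step in range(r):
        row = counts[step]
        cumulative += row
        best, best_key = -1, None
        for j in range(r):
            if assigned[j]:
                continue
            key = (row[j], cumulative[j], -j)
            if best_key is None or key > best_key:
                best, best_key = j, key
        assigned[best] = True
        order.append(events[best])
        freqs.append(row[best] / tc.n_trajectories)
    return EventSequence(order=order, modal_freq=np.asarray(freqs))


def order_tau(order_a: list[str], order_b: list[str]) -> float:
    """Kendall tau between two orderings of the same event set."""
    if sorted(order_a) != sorted(order_b):
        raise ValueError("orderings must cover the same event set")
    rank_b = {e: i for i, e in enumerate(order_b)}
    tau = stats.kendalltau(range(len(order_a)), [rank_b[e] for e in order_a]).statistic
    return float(tau)


# ---------------------------------------------------------------------------
# serialization

def write_counts(tc: TrajectoryCounts, path: str | Path) -> None:
    df = tc.counts.copy()
    df.insert(0, "n_trajectories", tc.n_trajectories)
    df.to_csv(path, index_label="step")


def write_sequence(
    seq: EventSequence, path: str | Path, atlas: pd.DataFrame | None = None
) -> None:
    df = pd.DataFrame(
        {
            "rank": range(1, len(seq.order) + 1),
            "event": seq.order,
            "modal_freq": seq.modal_freq,
        }
    )
    if atlas is not None:
        tissue = atlas.set_index("region_id")["tissue"]
        df["tissue"] = df["event"].map(tissue)
    df.to_csv(path, index=False)


def read_weights_file(path: str | Path) -> pd.DataFrame:
    """Load a precomputed weights table so the simulator runs standalone."""
    return pd.read_csv(path, index_col=0)
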