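"""Pairwise conditional probabilities and precedence testing.

For two alteration events X and Y, P(X+|Y-) — the probability that X has
occurred given that Y has not — is informative about ordering: if X tends to
precede Y, patients with Y still intact will often already show X, so
P(X+|Y-) > P(Y+|X-). Weights in [0, 1] are treated as per-patient event
probabilities with within-patient independence, so joint probabilities are
products of weights; on binary weights the formulas reduce exactly to
counting patients.

Precedence within a pair is tested by McNemar's test of marginal homogeneity
on the binarized events (discordant counts b = #(X+, Y-), c = #(X-, Y+)),
with Benjamini-Hochberg FDR correction across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import atlas as atlas_mod

#: default binarization threshold: the midpoint of the weight ramp
DEFAULT_BINARIZE_AT = 0.5
#: discordant-count total below which the exact binomial McNemar p is used
EXACT_SWITCH = 25


def conditional_probability(w: pd.DataFrame, X: str, Y: str) -> float:
    """P(X+|Y-) = P(X+ and Y-) / P(Y-) under the fuzzy-indicator semantics.

    P(X+ and Y-) is the patient mean of w_X * (1 - w_Y) and P(Y-) the mean of
    (1 - w_Y). Returns 0 when P(Y-) = 0 (Y altered in every patient — the
    conditioning event never happens).
    """
    if X == Y:
        raise ValueError("conditional probability requires two distinct events")
    wx = w[X].to_numpy(dtype=float)
    wy = w[Y].to_numpy(dtype=float)
    p_y_minus = float(np.mean(1.0 - wy))
    if p_y_minus == 0.0:
        return 0.0
    return float(np.mean(wx * (1.0 - wy)) / p_y_minus)


def conditional_probability_matrix(w: pd.DataFrame) -> pd.DataFrame:
    """All ordered pairs at once: entry [X, Y] is P(X+|Y-); diagonal is NaN."""
    W = w.to_numpy(dtype=float)
    n = W.shape[0]
    joint = W.T @ (1.0 - W) / n  # [X, Y] = P(X+ and Y-)
    p_minus = (1.0 - W).mean(axis=0)  # P(Y-)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(p_minus[None, :] > 0, joint / p_minus[None, :], 0.0)
    np.fill_diagonal(cond, np.nan)
    return pd.DataFrame(cond, index=w.columns, columns=w.columns)


def mcnemar_pair(
    w: pd.DataFrame, X: str, Y: str, binarize_at: float = DEFAULT_BINARIZE_AT
) -> tuple[float, float, int]:
    """McNemar's test of marginal homogeneity for one event pair.

    Returns (statistic, two-sided p, direction) with direction = sign(b - c):
    +1 when X+ without Y+ is the more common discordance (X tends to precede
    Y). Exact binomial p when b + c < 25, else chi-square with continuity
    correction; b = c = 0 gives p = 1.
    """
    if X == Y:
        raise ValueError("McNemar's test requires two distinct events")
    bx = w[X].to_numpy(dtype=float) >= binarize_at
    by = w[Y].to_numpy(dtype=float) >= binarize_at
    b = int(np.sum(bx & ~by))
    c = int(np.sum(~bx & by))
    stat, p = _mcnemar_from_counts(np.array([b]), np.array([c]))
    return float(stat[0]), float(p[0]), int(np.sign(b - c))


def _mcnemar_from_counts(b: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized McNemar statistic and two-sided p over discordant counts."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    n = b + c
    exact = n < EXACT_SWITCH
    k = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_exact = np.minimum(2.0 * stats.binom.cdf(k, np.maximum(n, 1), 0.5), 1.0)
        chi2 = np.where(n > 0, (np.abs(b - c) - 1.0) ** 2 / np.where(n > 0, n, 1.0), 0.0)
        p_chi2 = stats.chi2.sf(chi2, df=1)
    stat = np.where(exact, k, chi2)
    p = np.where(exact, p_exact, p_chi2)
    p = np.where(n == 0, 1.0, p)
    stat = np.where(n == 0, 0.0, stat)
    return stat, p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConditionalProbabilityTable:
    """Ordered-pair conditional probabilities plus per-pair McNemar results."""

    #: events x events, [X, Y] = P(X+|Y-), NaN diagonal
    cond: pd.DataFrame
    #: P(X+) per event (patient mean weight)
    marginals: pd.Series
    #: one row per unordered tested pair: X, Y, b, c, statistic, p, p_adj,
    #: direction (+1: X precedes Y), significant
    tests: pd.DataFrame
    fdr_level: float

    @property
    def events(self) -> list[str]:
        return list(self.cond.index)


def build_cpt(
    w: pd.DataFrame,
    atlas: pd.DataFrame | None = None,
    pairs: str = "all",
    binarize_at: float = DEFAULT_BINARIZE_AT,
    fdr_level: float = 0.05,
) -> ConditionalProbabilityTable:
    """Compute the full conditional-probability table and pair tests.

    ``pairs`` selects the tested family: ``"all"`` tests every unordered
    event pair, ``"cross_tissue"`` only GM-WM pairs (requires an atlas).
    FDR correction is applied within the selected family.
    """
    cond = conditional_probability_matrix(w)
    marginals = w.mean(axis=0)
    events = list(w.columns)
    B = (w.to_numpy(dtype=float) >= binarize_at)
    bmat = (B.T.astype(int) @ (~B).astype(int)).astype(float)  # [X, Y] = #(X+, Y-)

    if pairs == "cross_tissue":
        if atlas is None:
            raise ValueError("cross_tissue pair selection requires an atlas")
        tissue = atlas_mod.tissue_of(atlas)
        gm = [e for e in events if tissue.get(e) == atlas_mod.GM]
        wm = [e for e in events if tissue.get(e) == atlas_mod.WM]
        if not gm or not wm:
            raise ValueError("cross_tissue pairs require both GM and WM events")
        pair_list = [(x, y) for x in gm for y in wm]
    elif pairs == "all":
        pair_list = [(events[i], events[j]) for i in range(len(events)) for j in range(i + 1, len(events))]
    else:
        raise ValueError(f"unknown pair family {pairs!r}")

    idx = {e: i for i, e in enumerate(events)}
    b = np.array([bmat[idx[x], idx[y]] for x, y in pair_list])
    c = np.array([bmat[idx[y], idx[x]] for x, y in pair_list])
    stat, p = _mcnemar_from_counts(b, c)
    p_adj = fdr_adjust(p) if len(p) else p
    tests = pd.DataFrame(
        {
            "X": [x for x, _ in pair_list],
            "Y": [y for _, y in pair_list],
            "b": b.astype(int),
            "c": c.astype(int),
            "statistic": stat,
            "p": p,
            "p_adj": p_adj,
            "direction": np.sign(b - c).astype(int),
            "significant": p_adj <= fdr_level,
        }
    )
    return ConditionalProbabilityTable(
        cond=cond, marginals=marginals, tests=tests, fdr_level=fdr_level
    )


@dataclass
class CrossTissuePrecedence:
    """Per-region cross-tissue precedence summaries.

    For a GM region g, ``precedence`` is mean over WM regions y of P(g+|y-)
    (the paper-style P(GM+|WM-)); for a WM region it is the mirrored mean.
    ``difference`` is the region's precedence minus the opposing tissue's
    average precedence over it, so positive means the region's alteration
    tends to come first.
    """

    summary: pd.DataFrame  # region_id, tissue, precedence, difference


def cross_tissue_summary(
    cpt: ConditionalProbabilityTable, atlas: pd.DataFrame
) -> CrossTissuePrecedence:
    tissue = atlas_mod.tissue_of(atlas)
    events = cpt.events
    gm = [e for e in events if tissue.get(e) == atlas_mod.GM]
    wm = [e for e in events if tissue.get(e) == atlas_mod.WM]
    if not gm or not wm:
        raise ValueError("cross-tissue summary requires both GM and WM events")
    cond = cpt.cond
    rows = []
    for g in gm:
        prec = float(cond.loc[g, wm].mean())  # P(g+ | WM-)
        opposing = float(cond.loc[wm, g].mean())  # mean_y P(y+ | g-)
        rows.append({"region_id": g, "tissue": atlas_mod.GM, "precedence": prec,
                     "difference": prec - opposing})
    for y in wm:
        prec = float(cond.loc[y, gm].mean())  # P(y+ | GM-)
        opposing = float(cond.loc[gm, y].mean())
        rows.append({"region_id": y, "tissue": atlas_mod.WM, "precedence": prec,
                     "difference": prec - opposing})
    return CrossTissuePrecedence(summary=pd.DataFrame(rows))


@dataclass
class SignificanceCensus:
    wm_precedes_gm: int
    gm_precedes_wm: int
    total_pairs: int


def pairwise_significance_census(
    cpt: ConditionalProbabilityTable, atlas: pd.DataFrame
) -> SignificanceCensus:
    """Census of FDR-significant cross-tissue pairs split by direction.

    Counts unordered GM-WM pairs; the total is n_GM x n_WM.
    """
    tissue = atlas_mod.tissue_of(atlas)
    t = cpt.tests
    tx = t["X"].map(tissue)
    ty = t["Y"].map(tissue)
    cross = (tx != ty) & tx.notna() & ty.notna()
    ct = t[cross]
    # orient direction as GM-vs-WM regardless of which event was X
    gm_first = (tx[cross] == atlas_mod.GM).to_numpy()
    oriented = np.where(gm_first, ct["direction"].to_numpy(), -ct["direction"].to_numpy())
    sig = ct["significant"].to_numpy()
    n_gm = int((tissue == atlas_mod.GM).sum())
    n_wm = int((tissue == atlas_mod.WM).sum())
    return SignificanceCensus(
        wm_precedes_gm=int(np.sum(sig & (oriented < 0))),
        gm_precedes_wm=int(np.sum(sig & (oriented > 0))),
        total_pairs=n_gm * n_wm,
    )


def all_regions_census(cpt: ConditionalProbabilityTable) -> tuple[int, int]:
    """(significant ordered pairs, total ordered pairs) over all events.

    Each significant unordered pair contributes both of its orderings, so the
    denominator is R x (R - 1).
    """
    r = len(cpt.events)
    sig_unordered = int(cpt.tests["significant"].sum())
    return 2 * sig_unordered, r * (r - 1)
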