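"""Per-transition differential classification and whole-protocol segregation.

Every protein is evaluated over each consecutive condition pair
(H0->H3, H3->H6, ...).  A transition is called "up" when the mean log10
normalized change exceeds log10(fold_threshold) AND an exact two-sided
Mann-Whitney U test on the replicate values reaches alpha; "down"
symmetrically; otherwise "unchanged".  Detection-pattern overrides: a
protein undetected in all earlier replicates but detected in at least
two later ones is de novo expression (reported as "up"); the converse is
"lost" (reported as "down").  Whole-protocol classes (the heatmap
grouping) are upregulated / downregulated / unchanged.

With three replicates per side the smallest achievable exact two-sided
p is 2/C(6,3) = 0.1, so the default alpha of 0.1 admits exactly the
fully separated arrangements — the only ones that can be "significant"
at this sample size.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .design import ExperimentDesign

__all__ = [
    "exact_mann_whitney",
    "classify_transition",
    "segregate",
    "CLASS_UP",
    "CLASS_DOWN",
    "CLASS_UNCHANGED",
]

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"


def exact_mann_whitney(a, b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration.

    All C(n+m, n) assignments of the pooled midranks to the first group
    are enumerated and the two-sided p is the fraction of arrangements
    whose U statistic deviates from its null mean n*m/2 at least as much
    as the observed one.  Ties are handled through midranks; no normal
    approximation is involved, which matters at n = m = 3.

    Returns NaN when either side has fewer than two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n < 2 or m < 2:
        return float("nan")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    null_mean = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev_obs = abs(u_obs - null_mean)
    total = comb(n + m, n)
    hits = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if abs(u - null_mean) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def classify_transition(
    delta: float,
    p: float,
    fold_threshold: float,
    alpha: float,
    detection_pattern: tuple[int, int] | None = None,
) -> tuple[str, bool, bool]:
    """Classify one (protein, transition) cell.

    Parameters
    ----------
    delta
        Mean log10 normalized change (later minus earlier); may be NaN
        when one side is entirely undetected.
    p
        Exact Mann-Whitney p, or NaN when a side has <2 detected
        replicates (the call then falls back to the fold criterion only).
    detection_pattern
        (detected earlier, detected later) replicate counts, used for
        the de novo / lost overrides.

    Returns
    -------
    (class, de_novo, lost)
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if detection_pattern is not None:
        n_early, n_late = detection_pattern
        if n_early == 0 and n_late >= 2:
            return CLASS_UP, True, False
        if n_late == 0 and n_early >= 2:
            return CLASS_DOWN, False, True
    if not np.isfinite(delta):
        return CLASS_UNCHANGED, False, False
    log_thr = np.log10(fold_threshold)
    significant = p <= alpha if np.isfinite(p) else True  # fold-only fallback
    if delta > log_thr and significant:
        return CLASS_UP, False, False
    if delta < -log_thr and significant:
        return CLASS_DOWN, False, False
    return CLASS_UNCHANGED, False, False


def _overall_class(sub: pd.DataFrame) -> str:
    """Whole-protocol label from one protein's transition calls.

    One color per protein: if both directions occur, the direction with
    the larger cumulative |delta| over its classified transitions wins
    (ties go to upregulated, deterministically).
    """
    up = sub["class"] == CLASS_UP
    down = sub["class"] == CLASS_DOWN
    if not up.any() and not down.any():
        return "unchanged"
    if up.any() and not down.any():
        return "upregulated"
    if down.any() and not up.any():
        return "downregulated"
    up_mag = sub.loc[up, "delta"].abs().sum(skipna=True)
    down_mag = sub.loc[down, "delta"].abs().sum(skipna=True)
    return "upregulated" if up_mag >= down_mag else "downregulated"


def segregate(
    normalized: pd.DataFrame,
    design: ExperimentDesign,
    fold_threshold: float = 2.0,
    alpha: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Evaluate every consecutive transition for every protein.

    Returns
    -------
    transition_table
        Long DataFrame keyed by (protein_id, transition) with the mean
        log10 change ``delta``, exact ``p_value``, a Benjamini-Hochberg
        ``q_value`` column (informational only; it never gates the
        class), the class and the de novo / lost flags.
    protocol_class
        Series protein_id -> upregulated / downregulated / unchanged.
    heatmap
        Proteins x conditions matrix of per-condition mean normalized
        values, rows grouped by protocol class.
    """
    cols = {t: design.sample_keys(t) for t in design.timepoints}
    rows = []
    for pid in normalized.index:
        vals = normalized.loc[pid]
        for a, b in design.transitions():
            earlier = vals[cols[a]].dropna().to_numpy()
            later = vals[cols[b]].dropna().to_numpy()
            delta = (
                later.mean() - earlier.mean()
                if len(earlier) and len(later)
                else float("nan")
            )
            p = exact_mann_whitney(earlier, later)
            cls, de_novo, lost = classify_transition(
                delta, p, fold_threshold, alpha,
                detection_pattern=(len(earlier), len(later)),
            )
            rows.append(
                {
                    "protein_id": pid,
                    "transition": f"{a}->{b}",
                    "delta": delta,
                    "p_value": p,
                    "class": cls,
                    "de_novo": de_novo,
                    "lost": lost,
                }
            )
    tt = pd.DataFrame(rows)
    finite = tt["p_value"].notna()
    tt["q_value"] = np.nan
    if finite.any():
        tt.loc[finite, "q_value"] = multipletests(
            tt.loc[finite, "p_value"], method="fdr_bh"
        )[1]
    protocol_class = tt.groupby("protein_id", sort=False).apply(
        _overall_class, include_groups=False
    )
    protocol_class.name = "protocol_class"

    cond_means = pd.DataFrame(
        {t: normalized[cols[t]].mean(axis=1, skipna=True)
         for t in design.timepoints}
    )
    order = pd.Categorical(
        protocol_class.loc[cond_means.index],
        categories=["upregulated", "downregulated", "unchanged"],
        ordered=True,
    )
    heatmap = cond_means.iloc[np.argsort(order, kind="stable")]
    return tt, protocol_class, heatmap
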