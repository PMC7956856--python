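"""Reference-protein selection by pairwise-stability (M value) exclusion,
and reference normalization of baseline ratios.

This adapts the geNorm reference-gene strategy to label-free LC-MS
signals.  Candidates are proteins detected in every sample with the
smallest coefficient of variation of their baseline ratios.  For a
candidate j within a set C, the stability measure is

    M(j) = mean_{k in C, k != j}  SD_s( log ratio_j(s) - log ratio_k(s) )

(sample SD, n-1 denominator, over samples s).  The least stable
candidate (highest M) is removed and the procedure repeats until a
terminal reference set remains (default two proteins).  All signals are
then divided by the per-sample geometric mean of the reference ratios
and log10-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CandidateShortlist",
    "StabilityReport",
    "shortlist_candidates",
    "m_value",
    "iterate_exclusion",
    "normalize",
]


@dataclass(frozen=True)
class CandidateShortlist:
    """Fully-detected proteins ranked by ascending CV of their ratios."""

    protein_ids: tuple[str, ...]
    cv_values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.protein_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": self.protein_ids, "cv": self.cv_values}
        )


@dataclass
class StabilityReport:
    """Per-iteration M values and the exclusion path of the candidate set."""

    iterations: list[pd.Series] = field(default_factory=list)
    exclusion_order: list[str] = field(default_factory=list)
    reference_set: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {"candidates": list(it.index), "m_values": it.to_dict()}
                for it in self.iterations
            ],
            "exclusion_order": list(self.exclusion_order),
            "reference_set": list(self.reference_set),
        }


def shortlist_candidates(
    ratios: pd.DataFrame, k: int = 10, *, log_scale: bool = False
) -> CandidateShortlist:
    """Select the k fully-detected proteins with the smallest CV of ratios.

    CV is the sample SD divided by the mean of the protein's ratios
    across all samples (the SD "as % of average" reading); with
    ``log_scale`` the SD of log10 ratios is ranked instead.  Ties break
    by protein id.
    """
    if k < 3:
        raise ValueError("shortlist size must be >= 3")
    full = ratios.dropna(axis=0, how="any")
    if len(full) < k:
        raise ValueError(
            f"only {len(full)} protein(s) are detected in all samples; "
            f"cannot shortlist {k}"
        )
    if log_scale:
        cv = np.log10(full).std(axis=1, ddof=1)
    else:
        cv = full.std(axis=1, ddof=1) / full.mean(axis=1)
    order = sorted(cv.index, key=lambda p: (cv[p], p))[:k]
    return CandidateShortlist(
        protein_ids=tuple(order),
        cv_values=tuple(float(cv[p]) for p in order),
    )


def m_value(candidate: str, others: set[str] | list[str],
            logratios: pd.DataFrame) -> float:
    """Average over partners of the SD across samples of the pairwise
    log-ratio difference; low M = stable (geNorm stability measure).

    ``logratios`` holds log-scale ratios (any base; the ranking is
    base-invariant) with proteins as rows.
    """
    others = [o for o in others if o != candidate]
    if not others:
        raise ValueError("m_value needs at least one partner protein")
    block = logratios.loc[[candidate, *others]]
    if block.isna().any().any():
        raise ValueError("masked cells among M-value candidates")
    diffs = block.loc[others].values - block.loc[candidate].values
    return float(np.mean(np.std(diffs, axis=1, ddof=1)))


def iterate_exclusion(
    shortlist: CandidateShortlist,
    ratios: pd.DataFrame,
    stop_size: int = 2,
) -> StabilityReport:
    """Repeatedly drop the highest-M candidate until ``stop_size`` remain.

    Ties at the top break by removing the lexicographically last id, so
    runs are reproducible.  Each iteration (candidate set plus its M
    values) is recorded.
    """
    if stop_size < 2:
        raise ValueError("stop_size must be >= 2")
    if len(shortlist) <= stop_size:
        raise ValueError("shortlist must be larger than stop_size")
    logratios = np.log2(ratios.loc[list(shortlist.protein_ids)])
    current = list(shortlist.protein_ids)
    report = StabilityReport()
    while len(current) > stop_size:
        m = pd.Series(
            {c: m_value(c, current, logratios) for c in current},
            name="M",
        )
        report.iterations.append(m)
        worst = max(current, key=lambda p: (m[p], p))
        report.exclusion_order.append(worst)
        current = [p for p in current if p != worst]
    report.reference_set = tuple(current)
    return report


def normalize(
    ratios: pd.DataFrame,
    refs: list[str] | tuple[str, ...],
    *,
    ref_mean: str = "geometric",
) -> pd.DataFrame:
    """log10 of each ratio divided by the per-sample mean of the
    reference proteins' ratios.

    The per-sample normalization factor is the geometric mean of the
    reference ratios (geNorm convention); ``ref_mean="arithmetic"`` is
    available for sensitivity analysis.  Detected zero ratios cannot be
    log-transformed and are masked with a warning.
    """
    if not len(refs):
        raise ValueError("reference set is empty")
    ref_block = ratios.loc[list(refs)]
    if ref_block.isna().any().any():
        raise ValueError("reference proteins must be detected in all samples")
    if (ref_block <= 0).any().any():
        raise ValueError("reference ratios must be positive")
    if ref_mean == "geometric":
        factor = np.exp(np.log(ref_block).mean(axis=0))
    elif ref_mean == "arithmetic":
        factor = ref_block.mean(axis=0)
    else:
        raise ValueError(f"unknown ref_mean {ref_mean!r}")
    scaled = ratios.div(factor, axis=1)
    zero_detected = scaled.eq(0)
    if zero_detected.any().any():
        import logging

        logging.getLogger("proteokinetics").warning(
            "masking %d detected zero ratio(s) before log transform",
            int(zero_detected.sum().sum()),
        )
        scaled = scaled.mask(zero_detected)
    return np.log10(scaled)
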