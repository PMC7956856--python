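"""Ontology-level kinetic profiles of expression change.

Per-transition changes are averaged over the proteins annotated to each
ontology family (every protein weighted equally; a multi-family protein
contributes to each of its families), giving one independent series per
family and its running sum anchored at 0 at baseline.  The onset of
sustained decline during ischemia ("collapse") and the qualitative shape
of the full profile are extracted from these series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = [
    "KineticProfile",
    "aggregate_family",
    "aggregate_all",
    "detect_collapse",
    "pattern_summary",
]

PATTERN_BURST = "burst_maintain_collapse"
PATTERN_REBOUND = "collapse_rebound"
PATTERN_OTHER = "other"


@dataclass
class KineticProfile:
    """One ontology family's mean change per transition and its cumulative
    series (log10 ratio units)."""

    family: str
    transitions: tuple[str, ...]
    mean_change: tuple[float, ...]       # per-transition, independent
    cumulative: tuple[float, ...]        # prefix sums, anchored at 0 at H0
    member_count: tuple[int, ...]        # proteins with finite delta
    collapse_index: int | None = None    # index into `transitions`, or None
    collapse_detected: bool = False      # whether detect_collapse has run

    @property
    def collapse_transition(self) -> str | None:
        return (
            self.transitions[self.collapse_index]
            if self.collapse_index is not None
            else None
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "transition": self.transitions,
                "mean_change": self.mean_change,
                "cumulative": self.cumulative,
                "n_proteins": self.member_count,
            }
        )


def aggregate_family(
    transition_table: pd.DataFrame,
    annotation: pd.DataFrame,
    family: str,
    *,
    altered_only: bool = False,
) -> KineticProfile:
    """Average the per-transition log10 changes of one family's proteins.

    Proteins with a masked (non-finite) change at a transition are
    dropped from that transition's mean rather than imputed.  With
    ``altered_only`` only transitions classified up or down contribute.
    """
    members = annotation.loc[annotation["family"] == family, "protein_id"]
    sub = transition_table[transition_table["protein_id"].isin(set(members))]
    sub = sub[np.isfinite(sub["delta"])]
    if altered_only:
        sub = sub[sub["class"].isin(["up", "down"])]
    if sub.empty:
        raise ValueError(f"ontology family {family!r} has no usable protein")
    transitions = list(
        dict.fromkeys(transition_table["transition"])  # keep design order
    )
    g = sub.groupby("transition")["delta"]
    means = g.mean().reindex(transitions)
    counts = g.size().reindex(transitions).fillna(0).astype(int)
    mean_change = tuple(float(x) if np.isfinite(x) else 0.0 for x in means)
    return KineticProfile(
        family=family,
        transitions=tuple(transitions),
        mean_change=mean_change,
        cumulative=tuple(np.cumsum(mean_change)),
        member_count=tuple(counts),
    )


def detect_collapse(
    profile: KineticProfile,
    design: ExperimentDesign,
    tau: float = 0.05,
) -> int | None:
    """Earliest ischemia transition opening a sustained decline.

    Returns the index (into ``profile.transitions``) of the first
    ischemia transition whose mean change is below ``-tau`` with every
    subsequent ischemia transition non-positive; None if there is none.
    The result is also stored on the profile.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    isch = [f"{a}->{b}" for a, b in design.ischemia_transitions()]
    idx = [profile.transitions.index(t) for t in isch]
    found = None
    for pos, i in enumerate(idx):
        if profile.mean_change[i] < -tau and all(
            profile.mean_change[j] <= 0 for j in idx[pos + 1:]
        ):
            found = i
            break
    profile.collapse_index = found
    profile.collapse_detected = True
    return found


def pattern_summary(
    profiles: list[KineticProfile], design: ExperimentDesign
) -> pd.Series:
    """Label each family profile with its qualitative shape.

    ``burst_maintain_collapse``: positive first ischemia step, a collapse
    onset exists, and a further drop at reperfusion.
    ``collapse_rebound``: negative first ischemia step, recovery on the
    second, and a rise at reperfusion.  Everything else is ``other``.
    """
    isch = [f"{a}->{b}" for a, b in design.ischemia_transitions()]
    a, b = design.reperfusion_transition()
    reper = f"{a}->{b}"
    labels = {}
    for kp in profiles:
        first = kp.mean_change[kp.transitions.index(isch[0])]
        second = kp.mean_change[kp.transitions.index(isch[1])]
        rep = kp.mean_change[kp.transitions.index(reper)]
        if not kp.collapse_detected:
            detect_collapse(kp, design)
        if first > 0 and kp.collapse_index is not None and rep < 0:
            labels[kp.family] = PATTERN_BURST
        elif first < 0 and second > 0 and rep > 0:
            labels[kp.family] = PATTERN_REBOUND
        else:
            labels[kp.family] = PATTERN_OTHER
    return pd.Series(labels, name="pattern")


def aggregate_all(
    transition_table: pd.DataFrame,
    annotation: pd.DataFrame,
    design: ExperimentDesign,
    *,
    tau: float = 0.05,
    altered_only: bool = False,
) -> list[KineticProfile]:
    """Profiles for every family present in the annotation, with collapse
    detection applied, in first-appearance order."""
    profiles = []
    for family in dict.fromkeys(annotation["family"]):
        try:
            kp = aggregate_family(
                transition_table, annotation, family, altered_only=altered_only
            )
        except ValueError:
            continue  # family with no usable protein in this dataset
        detect_collapse(kp, design, tau)
        profiles.append(kp)
    return profiles
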