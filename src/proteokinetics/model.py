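"""Model/Results facade over the full time-course analysis.

`TimecourseModel` binds an intensity matrix to an experiment design (and
optionally an ontology annotation); `fit()` runs baseline ratios ->
reference-stability selection -> reference normalization -> transition
classification -> ontology kinetics and returns a `TimecourseResults`
holding every intermediate product, with a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .design import ExperimentDesign, default_design
from .kinetics import KineticProfile, aggregate_all, pattern_summary
from .segregation import segregate
from .stability import (
    CandidateShortlist,
    StabilityReport,
    iterate_exclusion,
    normalize,
    shortlist_candidates,
)

__all__ = ["TimecourseModel", "TimecourseResults"]


class TimecourseModel:
    """Reference-normalized differential time-course analysis of a
    protein intensity matrix.

    Parameters
    ----------
    intensities
        Proteins x samples DataFrame, NaN marking not-detected cells;
        columns keyed ``<timepoint>_r<k>``.
    design
        The condition/replicate layout; defaults to the H0..H24 + R6,
        three-replicate protocol.
    annotation
        Optional long protein -> ontology family table enabling the
        kinetics stage.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        design: ExperimentDesign | None = None,
        annotation: pd.DataFrame | None = None,
    ) -> None:
        self.design = design or default_design()
        for col in intensities.columns:
            self.design.parse_sample_key(str(col))
        if intensities.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        self.intensities = intensities[self.design.sample_keys()].astype(float)
        self.annotation = annotation

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        design: ExperimentDesign | None = None,
        annotation_path: str | Path | None = None,
        **read_kwargs,
    ) -> "TimecourseModel":
        design = design or default_design()
        intensities = pio.read_intensity_table(path, design, **read_kwargs)
        ann = pio.read_annotation(annotation_path) if annotation_path else None
        return cls(intensities, design, ann)

    def fit(
        self,
        *,
        shortlist_size: int = 10,
        stop_size: int = 2,
        ref_mean: str = "geometric",
        fold_threshold: float = 2.0,
        alpha: float = 0.1,
        tau: float = 0.05,
        altered_only: bool = False,
        detection_floor: float | None = None,
    ) -> "TimecourseResults":
        ratios, baseline_absent = pio.ratio_to_baseline(
            self.intensities, self.design, detection_floor=detection_floor
        )
        shortlist = shortlist_candidates(ratios, shortlist_size)
        stability = iterate_exclusion(shortlist, ratios, stop_size)
        normalized = normalize(ratios, stability.reference_set, ref_mean=ref_mean)
        transitions, protocol_class, heatmap = segregate(
            normalized, self.design, fold_threshold, alpha
        )
        profiles: list[KineticProfile] = []
        patterns = pd.Series(dtype=object, name="pattern")
        if self.annotation is not None and len(self.annotation):
            profiles = aggregate_all(
                transitions, self.annotation, self.design,
                tau=tau, altered_only=altered_only,
            )
            patterns = pattern_summary(profiles, self.design)
        return TimecourseResults(
            model=self,
            params={
                "shortlist_size": shortlist_size,
                "stop_size": stop_size,
                "ref_mean": ref_mean,
                "fold_threshold": fold_threshold,
                "alpha": alpha,
                "tau": tau,
                "altered_only": altered_only,
            },
            ratios=ratios,
            baseline_absent=baseline_absent,
            shortlist=shortlist,
            stability=stability,
            normalized=normalized,
            transitions=transitions,
            protocol_class=protocol_class,
            heatmap=heatmap,
            kinetic_profiles=profiles,
            family_patterns=patterns,
        )


@dataclass
class TimecourseResults:
    """Everything the fitted pipeline produced."""

    model: TimecourseModel
    params: dict
    ratios: pd.DataFrame
    baseline_absent: pd.Series
    shortlist: CandidateShortlist
    stability: StabilityReport
    normalized: pd.DataFrame
    transitions: pd.DataFrame
    protocol_class: pd.Series
    heatmap: pd.DataFrame
    kinetic_profiles: list[KineticProfile] = field(default_factory=list)
    family_patterns: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def reference_set(self) -> tuple[str, ...]:
        return self.stability.reference_set

    def kinetics_frame(self) -> pd.DataFrame:
        if not self.kinetic_profiles:
            return pd.DataFrame(
                columns=["family", "transition", "mean_change",
                         "cumulative", "n_proteins"]
            )
        return pd.concat(
            [kp.to_frame() for kp in self.kinetic_profiles], ignore_index=True
        )

    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        d = self.model.design
        lines = [
            "Proteomic time-course analysis",
            "=" * 46,
            f"Conditions:        {', '.join(d.timepoints)} "
            f"(baseline {d.baseline})",
            f"Proteins analyzed: {len(self.normalized)}",
            f"Shortlist (k={len(self.shortlist)}): "
            + ", ".join(self.shortlist.protein_ids),
            f"Reference set:     {', '.join(self.reference_set)} "
            f"(after {len(self.stability.iterations)} exclusion rounds)",
            "",
            "Whole-protocol segregation:",
        ]
        counts = self.protocol_class.value_counts()
        for label in ("upregulated", "downregulated", "unchanged"):
            lines.append(f"  {label:<13} {counts.get(label, 0):>4}")
        de_novo = int(self.transitions["de_novo"].sum())
        lines.append(f"  de novo calls {de_novo:>4}")
        if self.kinetic_profiles:
            lines += ["", "Ontology kinetics:"]
            for kp in self.kinetic_profiles:
                pat = self.family_patterns.get(kp.family, "other")
                onset = kp.collapse_transition or "-"
                lines.append(
                    f"  {kp.family:<38} pattern={pat:<22} collapse={onset}"
                )
        return "\n".join(lines)

    def plot_kinetics(self, path: str | Path | None = None):
        from .plotting import plot_kinetics

        return plot_kinetics(self.kinetic_profiles, path=path)
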