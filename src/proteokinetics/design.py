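"""Experimental design of a preservation/reperfusion time course.

The modeled protocol samples cells at a baseline (H0), during cold
ischemia (H3 .. H24, hours in preservation solution) and after
reoxygenation (R6, six hours after return to culture conditions), with a
small number of independent replicates per condition.  Sample columns in
intensity tables are keyed ``<timepoint>_r<k>`` (e.g. ``H12_r2``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = ["ExperimentDesign", "default_design", "SAMPLE_KEY_RE"]

SAMPLE_KEY_RE = re.compile(r"^(?P<timepoint>.+)_r(?P<replicate>\d+)$")


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered conditions, replicate layout and ischemia/reperfusion split.

    Parameters
    ----------
    timepoints
        Ordered condition labels; the first is the baseline.
    n_replicates
        Replicates per condition, either one integer for all conditions
        or a mapping label -> count.  Every condition needs at least two
        replicates so that a rank test is defined.
    ischemia_labels
        Ordered subset of ``timepoints`` covering baseline and cold
        ischemia; the remaining labels are reperfusion conditions.
    """

    timepoints: tuple[str, ...]
    n_replicates: dict[str, int] = field(default_factory=dict)
    ischemia_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need at least two conditions")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("condition labels must be unique")
        reps = self.n_replicates or {t: 3 for t in self.timepoints}
        if isinstance(reps, int):
            reps = {t: reps for t in self.timepoints}
        missing = [t for t in self.timepoints if t not in reps]
        if missing:
            raise ValueError(f"no replicate count for conditions {missing}")
        for t, n in reps.items():
            if n < 2:
                raise ValueError(
                    f"condition {t!r} has {n} replicate(s); at least 2 required"
                )
        object.__setattr__(self, "n_replicates", dict(reps))
        isch = self.ischemia_labels or self.timepoints[:-1]
        if tuple(isch) != tuple(self.timepoints[: len(isch)]):
            raise ValueError("ischemia_labels must be a prefix of timepoints")
        object.__setattr__(self, "ischemia_labels", tuple(isch))

    # -- derived views -------------------------------------------------

    @property
    def baseline(self) -> str:
        return self.timepoints[0]

    @property
    def reperfusion_labels(self) -> tuple[str, ...]:
        return self.timepoints[len(self.ischemia_labels):]

    def sample_keys(self, timepoint: str | None = None) -> list[str]:
        """All sample column keys in design order, or those of one condition."""
        tps = [timepoint] if timepoint is not None else list(self.timepoints)
        for t in tps:
            if t not in self.timepoints:
                raise KeyError(f"unknown condition {t!r}")
        return [
            f"{t}_r{k}" for t in tps for k in range(1, self.n_replicates[t] + 1)
        ]

    def transitions(self) -> list[tuple[str, str]]:
        """Consecutive condition pairs, e.g. (H0, H3), (H3, H6), ..."""
        return list(zip(self.timepoints[:-1], self.timepoints[1:]))

    def ischemia_transitions(self) -> list[tuple[str, str]]:
        isch = set(self.ischemia_labels)
        return [(a, b) for a, b in self.transitions() if a in isch and b in isch]

    def reperfusion_transition(self) -> tuple[str, str]:
        """The transition crossing from ischemia into reperfusion."""
        for a, b in self.transitions():
            if a in self.ischemia_labels and b not in self.ischemia_labels:
                return (a, b)
        raise ValueError("design has no reperfusion condition")

    def parse_sample_key(self, key: str) -> tuple[str, int]:
        m = SAMPLE_KEY_RE.match(key)
        if m:
            t, r = m.group("timepoint"), int(m.group("replicate"))
            if t in self.timepoints and 1 <= r <= self.n_replicates[t]:
                return t, r
        raise KeyError(
            f"sample column {key!r} does not match any (condition, replicate) "
            f"of the design {list(self.timepoints)}"
        )

    # -- (de)serialization --------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "timepoints": list(self.timepoints),
                "n_replicates": self.n_replicates,
                "ischemia_labels": list(self.ischemia_labels),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        d = json.loads(text)
        return cls(
            timepoints=tuple(d["timepoints"]),
            n_replicates={k: int(v) for k, v in d["n_replicates"].items()},
            ischemia_labels=tuple(d.get("ischemia_labels", ())),
        )


def default_design() -> ExperimentDesign:
    """The study layout: H0 baseline, 3-24 h cold ischemia, R6 reoxygenation,
    three replicates each."""
    tps = ("H0", "H3", "H6", "H12", "H19", "H24", "R6")
    return ExperimentDesign(
        timepoints=tps,
        n_replicates={t: 3 for t in tps},
        ischemia_labels=tps[:-1],
    )
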