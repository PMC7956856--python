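"""Synthetic intensity matrices with planted ground truth.

The generator emulates the study design — 7 conditions (H0..H24 cold
ischemia, R6 reoxygenation) x 3 replicates, ~174 proteins — so that
every downstream stage can be exercised and scored against a known
truth.  Planted kinetic archetypes:

``stable``
    constant expression; the reference pool, two of which are
    "ultra-stable" (much lower noise) and should terminate the
    stability-exclusion procedure.
``burst_collapse(T)``
    rise at the first ischemia step, plateau until the collapse time T,
    then a multiplicative decline at every later ischemia step and a
    further drop at reoxygenation.
``energy_rebound``
    drop at the first ischemia step, recovery at the second, plateau to
    mid-protocol, decline, then a strong rise at reoxygenation.
``de_novo(T)``
    undetected before its onset T, constant afterwards.
``unregulated``
    constant, ordinary noise; the background proteome.

Intensities are planted mean x multiplicative log-normal noise with
sigma chosen so the natural-scale coefficient of variation equals the
configured CV.  Cells whose planted mean falls in the lowest
``dropout_quantile`` fraction of all planted means are masked as not
detected (missing-at-low-abundance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign, default_design

__all__ = [
    "Pattern",
    "SimulationConfig",
    "GroundTruth",
    "default_pattern_assignment",
    "planted_trajectory",
    "simulate",
    "truth_transition_classes",
]

#: gene symbols used for the planted reference pool (classic stable,
#: abundant proteins); the first and last are the ultra-stable pair
REF_SYMBOLS = (
    "VIM", "CLTC", "LGALS1", "PDIA6", "PPIA",
    "PFN1", "MIF", "CD99", "P4HA2", "SCARB2",
)
ULTRA_STABLE = ("VIM", "SCARB2")

FAMILY_TRANSCRIPTION = "Transcription/Translation Regulation"
FAMILY_IONIC = "Ionic balance regulation"
FAMILY_CYTOSKELETON = "Cytoskeleton"
FAMILY_ENERGY = "Energy metabolism"
FAMILY_ENVIRONMENT = "Interaction with the environment"
MISC_FAMILIES = (
    "Intracellular Transport", "RedOx regulation",
    "Proteasome", "Nucleotide biosynthesis",
)


@dataclass(frozen=True)
class Pattern:
    """A planted kinetic archetype; ``at`` is the collapse time
    (burst_collapse), last plateau label (energy_rebound) or detection
    onset (de_novo)."""

    kind: str
    at: str | None = None

    def __str__(self) -> str:
        return self.kind if self.at is None else f"{self.kind}({self.at})"


@dataclass
class SimulationConfig:
    n_proteins: int = 174
    design: ExperimentDesign = field(default_factory=default_design)
    n_stable_refs: int = 10
    n_ultra_stable: int = 2
    noise_cv: float = 0.15
    ref_noise_cv: float = 0.02
    dropout_quantile: float = 0.05
    fold_amplitude: float = 4.0
    pattern_assignment: dict[str, Pattern] | None = None
    annotation: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.ref_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 2 <= self.n_ultra_stable <= self.n_stable_refs:
            raise ValueError("need 2 <= n_ultra_stable <= n_stable_refs")
        if self.n_stable_refs > self.n_proteins:
            raise ValueError("n_stable_refs cannot exceed n_proteins")


@dataclass
class GroundTruth:
    """Planted truth: per-protein pattern, mean ratio trajectory over the
    conditions, and the ultra-stable reference ids."""

    patterns: dict[str, Pattern]
    trajectory: pd.DataFrame            # proteins x timepoints, mean ratio
    ultra_stable: tuple[str, ...]
    design: ExperimentDesign


def planted_trajectory(
    pattern: Pattern, design: ExperimentDesign, fold: float
) -> dict[str, float]:
    """Mean expression ratio (relative to baseline) at each condition."""
    tps = design.timepoints
    isch = design.ischemia_labels
    if pattern.kind in ("stable", "unregulated"):
        return {t: 1.0 for t in tps}
    if pattern.kind == "de_novo":
        if pattern.at not in tps:
            raise ValueError(f"de_novo onset {pattern.at!r} not in design")
        on = tps.index(pattern.at)
        return {t: (1.0 if i >= on else 0.0) for i, t in enumerate(tps)}
    if pattern.kind == "burst_collapse":
        if pattern.at not in isch[1:]:
            raise ValueError(
                f"collapse time {pattern.at!r} must be an ischemia condition"
            )
        out, v = {tps[0]: 1.0}, 1.0
        for t in tps[1:]:
            if t in isch:
                v = fold if isch.index(t) <= isch.index(pattern.at) else v / fold
            else:
                v = v / fold  # further drop at reoxygenation
            out[t] = v
        return out
    if pattern.kind == "energy_rebound":
        plateau_end = pattern.at or isch[min(3, len(isch) - 1)]
        if plateau_end not in isch:
            raise ValueError(f"plateau end {plateau_end!r} not an ischemia label")
        out, v = {tps[0]: 1.0}, 1.0
        for t in tps[1:]:
            if t not in isch:
                v = v * fold  # major increase at reoxygenation
            else:
                i = isch.index(t)
                if i == 1:
                    v = 1.0 / fold
                elif i == 2:
                    v = 1.0
                elif i > isch.index(plateau_end):
                    v = v / fold
            out[t] = v
        return out
    raise ValueError(f"unknown pattern kind {pattern.kind!r}")


def default_pattern_assignment(
    cfg: SimulationConfig,
) -> tuple[dict[str, Pattern], pd.DataFrame, tuple[str, ...]]:
    """Protein ids, patterns and ontology families for the default layout.

    The four headline families receive burst_collapse proteins with
    staggered collapse times (transcription/translation earliest, then
    ionic balance, then cytoskeleton) or the energy-metabolism rebound;
    a small de-novo group and an unregulated background fill the rest.
    Reference proteins are left unannotated so family kinetics are not
    diluted by the normalization pool.
    """
    n = cfg.n_proteins
    refs = list(REF_SYMBOLS[: cfg.n_stable_refs])
    refs += [f"REF{i:02d}" for i in range(len(refs), cfg.n_stable_refs)]
    ultra = tuple(
        ([refs[0], refs[-1]] + refs[1:-1])[: cfg.n_ultra_stable]
    )
    isch = cfg.design.ischemia_labels
    collapse_times = {  # staggered onsets, earliest to latest
        FAMILY_TRANSCRIPTION: isch[1],
        FAMILY_IONIC: isch[min(3, len(isch) - 1)],
        FAMILY_CYTOSKELETON: isch[min(4, len(isch) - 1)],
    }
    # group sizes as fractions of the default 174-protein inventory
    budget = n - len(refs)
    sizes = {
        FAMILY_TRANSCRIPTION: round(budget * 30 / 164),
        FAMILY_IONIC: round(budget * 20 / 164),
        FAMILY_CYTOSKELETON: round(budget * 20 / 164),
        FAMILY_ENERGY: round(budget * 20 / 164),
        FAMILY_ENVIRONMENT: round(budget * 12 / 164),  # de novo group
    }
    patterns: dict[str, Pattern] = {r: Pattern("stable") for r in refs}
    ann_rows: list[tuple[str, str]] = []
    i = 0

    def next_id() -> str:
        nonlocal i
        i += 1
        return f"P{i:03d}"

    for fam, T in collapse_times.items():
        for _ in range(min(sizes[fam], budget - (i))):
            pid = next_id()
            patterns[pid] = Pattern("burst_collapse", T)
            ann_rows.append((pid, fam))
    for _ in range(min(sizes[FAMILY_ENERGY], budget - i)):
        pid = next_id()
        patterns[pid] = Pattern("energy_rebound", isch[min(3, len(isch) - 1)])
        ann_rows.append((pid, FAMILY_ENERGY))
    for _ in range(min(sizes[FAMILY_ENVIRONMENT], budget - i)):
        pid = next_id()
        patterns[pid] = Pattern("de_novo", cfg.design.timepoints[1])
        ann_rows.append((pid, FAMILY_ENVIRONMENT))
    j = 0
    while i < budget:
        pid = next_id()
        patterns[pid] = Pattern("unregulated")
        ann_rows.append((pid, MISC_FAMILIES[j % len(MISC_FAMILIES)]))
        j += 1
    ann = pd.DataFrame(ann_rows, columns=["protein_id", "family"])
    return patterns, ann, ultra


def simulate(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns ``(intensities, ground_truth, annotation)``: a proteins x
    samples intensity DataFrame with NaN for not-detected cells, the
    planted truth, and the protein -> family annotation table.  The same
    seed yields bit-identical output.
    """
    design = cfg.design
    if cfg.pattern_assignment is None:
        patterns, ann, ultra = default_pattern_assignment(cfg)
    else:
        patterns = dict(cfg.pattern_assignment)
        if len(patterns) != cfg.n_proteins:
            raise ValueError("pattern_assignment size differs from n_proteins")
        ann = (
            cfg.annotation
            if cfg.annotation is not None
            else pd.DataFrame(columns=["protein_id", "family"])
        )
        stable_ids = [p for p, pat in patterns.items() if pat.kind == "stable"]
        ultra = tuple(sorted(stable_ids)[: cfg.n_ultra_stable])
    ids = list(patterns)
    traj = pd.DataFrame(
        {
            pid: planted_trajectory(patterns[pid], design, cfg.fold_amplitude)
            for pid in ids
        }
    ).T.reindex(columns=list(design.timepoints))
    traj.index.name = "protein_id"

    rng = np.random.default_rng(cfg.seed)
    # base abundances: log-uniform over 3 decades; references drawn from
    # the upper 2 decades so the pool cannot be lost to dropout
    base = 10.0 ** rng.uniform(4.0, 7.0, size=len(ids))
    is_stable = np.array([patterns[p].kind == "stable" for p in ids])
    base[is_stable] = 10.0 ** rng.uniform(5.0, 7.0, size=int(is_stable.sum()))

    cols = design.sample_keys()
    tp_of = {c: design.parse_sample_key(c)[0] for c in cols}
    mean = pd.DataFrame(
        {c: base * traj[tp_of[c]].to_numpy() for c in cols}, index=ids
    )
    cv = np.where(np.isin(ids, ultra), cfg.ref_noise_cv, cfg.noise_cv)
    sigma = np.sqrt(np.log1p(cv**2))
    noise = np.exp(rng.normal(0.0, 1.0, size=mean.shape) * sigma[:, None])
    intensities = mean * noise

    # missing-at-low-abundance: mask the lowest planted means
    flat = mean.to_numpy().ravel()
    threshold = (
        np.quantile(flat, cfg.dropout_quantile)
        if cfg.dropout_quantile > 0
        else 0.0
    )
    intensities = intensities.mask(mean <= threshold)
    intensities.index.name = "protein_id"

    gt = GroundTruth(
        patterns=patterns, trajectory=traj, ultra_stable=ultra, design=design
    )
    return intensities, gt, ann


def truth_transition_classes(
    gt: GroundTruth, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Planted per-transition labels — the oracle for recovery tests.

    ``up``/``down`` when the planted log10 fold crosses the threshold,
    ``de_novo``/``lost`` on planted appearance/disappearance, otherwise
    ``unchanged``.
    """
    thr = np.log10(fold_threshold)
    rows = []
    for pid in gt.trajectory.index:
        tr = gt.trajectory.loc[pid]
        for a, b in gt.design.transitions():
            ra, rb = tr[a], tr[b]
            if ra == 0 and rb > 0:
                label = "de_novo"
            elif rb == 0 and ra > 0:
                label = "lost"
            elif ra == 0 and rb == 0:
                label = "unchanged"
            else:
                lf = np.log10(rb / ra)
                label = "up" if lf > thr else "down" if lf < -thr else "unchanged"
            rows.append(
                {"protein_id": pid, "transition": f"{a}->{b}", "true_class": label}
            )
    return pd.DataFrame(rows)


def stable_pool_config(
    n_noisy: int = 8,
    *,
    noise_cv: float = 0.15,
    ref_noise_cv: float = 0.02,
    seed: int = 0,
    design: ExperimentDesign | None = None,
) -> SimulationConfig:
    """A small all-stable pool (2 ultra-stable + ``n_noisy`` ordinary) used
    to benchmark reference recovery."""
    design = design or default_design()
    n = n_noisy + 2
    ids = [f"S{i:02d}" for i in range(n)]
    patterns = {pid: Pattern("stable") for pid in ids}
    return SimulationConfig(
        n_proteins=n,
        design=design,
        n_stable_refs=n,
        n_ultra_stable=2,
        noise_cv=noise_cv,
        ref_noise_cv=ref_noise_cv,
        dropout_quantile=0.0,
        pattern_assignment=patterns,
        seed=seed,
    )
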