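"""One-shot reproducible pipeline: simulate (or read) -> normalize ->
segregate -> kinetics, writing every intermediate artifact plus a JSON
manifest with file hashes and the full parameter set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .design import ExperimentDesign, default_design
from .model import TimecourseModel
from .simulate import SimulationConfig, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("proteokinetics")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters of one run.

    Either ``intensity_path`` (with optional ``annotation_path``) or a
    simulation block; every random choice flows from ``seed``.
    """

    outdir: str | Path = "pipeline_out"
    seed: int = 0
    intensity_path: str | None = None
    annotation_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    shortlist_size: int = 10
    stop_size: int = 2
    ref_mean: str = "geometric"
    fold_threshold: float = 2.0
    alpha: float = 0.1
    tau: float = 0.05
    altered_only: bool = False
    design: ExperimentDesign = field(default_factory=default_design)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = (
            ExperimentDesign.from_json(json.dumps(raw.pop("design")))
            if "design" in raw
            else default_design()
        )
        return cls(design=design, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the output manifest.

    Identical config + seed produce byte-identical artifacts (and hence
    identical manifest hashes).  Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def write(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        artifacts[name] = path

    # -- input stage ---------------------------------------------------
    if cfg.intensity_path is not None:
        try:
            intensities = pio.read_intensity_table(cfg.intensity_path, cfg.design)
            annotation = (
                pio.read_annotation(cfg.annotation_path)
                if cfg.annotation_path
                else None
            )
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise PipelineError("read_intensity_table", e) from e
    else:
        try:
            sim_cfg = SimulationConfig(
                design=cfg.design, seed=cfg.seed, **cfg.simulate
            )
            intensities, truth, annotation = simulate(sim_cfg)
            write("intensity.tsv",
                  lambda p: pio.write_intensity_table(intensities, p))
            write("truth_trajectory.tsv",
                  lambda p: pio.write_intensity_table(truth.trajectory, p))
            write("annotation.tsv",
                  lambda p: pio.write_annotation(annotation, p))
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", e) from e

    write("design.json", lambda p: p.write_text(cfg.design.to_json()))

    # -- analysis stages ----------------------------------------------
    try:
        model = TimecourseModel(intensities, cfg.design, annotation)
        res = model.fit(
            shortlist_size=cfg.shortlist_size,
            stop_size=cfg.stop_size,
            ref_mean=cfg.ref_mean,
            fold_threshold=cfg.fold_threshold,
            alpha=cfg.alpha,
            tau=cfg.tau,
            altered_only=cfg.altered_only,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", e) from e

    write("ratios.tsv", lambda p: pio.write_intensity_table(res.ratios, p))
    write(
        "stability_report.json",
        lambda p: p.write_text(json.dumps(res.stability.to_dict(), indent=2)),
    )
    write("normalized.tsv",
          lambda p: pio.write_intensity_table(res.normalized, p))
    write(
        "transitions.tsv",
        lambda p: res.transitions.to_csv(p, sep="\t", index=False,
                                         float_format="%.10g"),
    )
    write(
        "protocol_class.tsv",
        lambda p: res.protocol_class.to_csv(p, sep="\t"),
    )
    write("heatmap.tsv", lambda p: pio.write_intensity_table(res.heatmap, p))
    write(
        "kinetics.tsv",
        lambda p: res.kinetics_frame().to_csv(p, sep="\t", index=False,
                                              float_format="%.10g"),
    )
    write(
        "family_patterns.tsv",
        lambda p: res.family_patterns.rename_axis("family").to_csv(p, sep="\t"),
    )
    write("summary.txt", lambda p: p.write_text(res.summary() + "\n"))
    if cfg.make_plots and res.kinetic_profiles:
        write("kinetics.png", lambda p: res.plot_kinetics(p))

    manifest = {
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in vars(cfg).items()
            if k not in ("design", "outdir") and not isinstance(v, Path)
        },
        "design": json.loads(cfg.design.to_json()),
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
            if p.suffix != ".png"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
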