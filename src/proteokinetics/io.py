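"""Readers and writers for wide intensity tables and annotation tables.

An intensity table is delimited text (tab or comma), first column the
protein identifier, remaining columns one per sample keyed
``<timepoint>_r<k>``.  Empty cells, ``NA`` and (by default) ``0`` mean
"not detected"; in memory, not-detected cells are ``NaN`` in a float
DataFrame indexed by protein id.

An annotation table is two-column delimited text mapping protein id to
an ontology family; a protein may appear on several rows (multi-family
membership).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_annotation",
    "write_annotation",
]

logger = logging.getLogger("proteokinetics")

NA_STRINGS = ("", "NA", "NaN", "nan", "na")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_intensity_table(
    path: str | Path,
    design: ExperimentDesign,
    *,
    zero_is_missing: bool = True,
    allow_negative: bool = False,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a wide intensity table and validate it against the design.

    Returns a float DataFrame (proteins x samples) with columns in
    design order and NaN marking not-detected cells.

    Raises
    ------
    ValueError
        on a sample column not resolvable against the design, a
        duplicated protein id, or a negative intensity.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(NA_STRINGS),
        keep_default_na=False, dtype=str,
    )
    for col in df.columns:
        design.parse_sample_key(str(col))  # raises KeyError naming the column
    expected = design.sample_keys()
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"table lacks sample columns {missing_cols}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate protein id(s): {dup}")
    values = df[expected].apply(pd.to_numeric, errors="raise").astype(float)
    if not allow_negative and (values < 0).any().any():
        bad = values.index[(values < 0).any(axis=1)].tolist()
        raise ValueError(f"negative intensities for protein(s): {bad}")
    if zero_is_missing:
        values = values.mask(values == 0)
    values.index.name = "protein_id"
    return values


def write_intensity_table(
    m: pd.DataFrame, path: str | Path, *, sep: str = "\t"
) -> None:
    """Write an intensity (or ratio / normalized) matrix; NaN cells are
    written empty so a round trip preserves the missingness mask."""
    out = m.copy()
    out.index.name = out.index.name or "protein_id"
    out.to_csv(path, sep=sep, na_rep="", float_format="%.10g")


def read_annotation(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a two-column protein -> ontology-family table (long format)."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    ann = pd.read_csv(path, sep=sep, dtype=str)
    if ann.shape[1] < 2:
        raise ValueError("annotation table needs columns (protein_id, family)")
    ann = ann.iloc[:, :2]
    ann.columns = ["protein_id", "family"]
    if (ann["family"].str.strip() == "").any():
        raise ValueError("empty ontology family name in annotation table")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    ann.to_csv(path, sep=sep, index=False)


def ratio_to_baseline(
    m: pd.DataFrame,
    design: ExperimentDesign,
    *,
    detection_floor: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Express every signal as a ratio to the protein's mean baseline signal.

    The baseline mean uses detected baseline replicates only.  Proteins
    with no detected baseline replicate ("de novo" candidates) are given
    a pseudo-baseline equal to ``detection_floor`` (default: half the
    smallest detected intensity in the whole matrix) so their ratios stay
    finite; they are flagged in the returned boolean Series.  Proteins
    detected nowhere are dropped with a warning.

    Returns
    -------
    (ratios, baseline_absent)
        ``ratios``: DataFrame with the same axes, NaN where not detected;
        ``baseline_absent``: boolean Series over the retained proteins.
    """
    base_cols = design.sample_keys(design.baseline)
    all_absent = m.isna().all(axis=1)
    if all_absent.any():
        dropped = m.index[all_absent].tolist()
        logger.warning("dropping %d protein(s) detected nowhere: %s",
                       len(dropped), dropped)
        m = m.loc[~all_absent]
    if detection_floor is None:
        detection_floor = float(np.nanmin(m.values)) / 2.0
    base_mean = m[base_cols].mean(axis=1, skipna=True)  # detected reps only
    baseline_absent = base_mean.isna()
    denom = base_mean.fillna(detection_floor)
    ratios = m.div(denom, axis=0)
    ratios.index.name = "protein_id"
    return ratios, baseline_absent
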