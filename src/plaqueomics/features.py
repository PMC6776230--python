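"""Assembly of the 1919-feature radiomic vector and the cohort table.

Per lesion: 44 first-order statistics on raw HU values, 114 co-occurrence
features on each of the 6 discretized images (684), 11 run-length features
on each (66), and 1125 surface/fractal geometry features, concatenated in
fixed block order fo | glcm | glrlm | geom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discretize import SCHEMES, discretize_all
from .firstorder import FIRSTORDER_NAMES, compute_firstorder
from .geometry import compute_geometry_block, geometry_feature_names
from .glcm import compute_glcm_block, glcm_feature_names
from .glrlm import compute_glrlm_block, glrlm_feature_names
from .io import VoxelLesion

__all__ = [
    "feature_names",
    "extract_features",
    "extract_cohort",
    "filter_cohort",
    "BLOCK_SIZES",
]

_CODES = tuple(("ew" if s == "equal_width" else "ep") + str(b) for s, b in SCHEMES)

#: Number of features per block: first-order, GLCM, GLRLM, geometry.
BLOCK_SIZES: dict[str, int] = {"fo": 44, "glcm": 684, "glrlm": 66, "geom": 1125}


def feature_names() -> list[str]:
    """The 1919 feature names in canonical (block) order."""
    names = list(FIRSTORDER_NAMES)
    for code in _CODES:
        names.extend(glcm_feature_names(code))
    for code in _CODES:
        names.extend(glrlm_feature_names(code))
    names.extend(geometry_feature_names(_CODES))
    return names


def extract_features(lesion: VoxelLesion) -> pd.Series:
    """The full 1919-entry radiomic feature vector of one lesion."""
    dlesions = discretize_all(lesion)
    out: dict[str, float] = {}
    out.update(compute_firstorder(lesion))
    for dl in dlesions:
        out.update(compute_glcm_block(dl))
    for dl in dlesions:
        out.update(compute_glrlm_block(dl))
    out.update(compute_geometry_block(lesion, dlesions))
    series = pd.Series(out, name=lesion.lesion_id, dtype=np.float64)
    assert len(series) == sum(BLOCK_SIZES.values())
    return series


def extract_cohort(lesions) -> pd.DataFrame:
    """Feature matrix (lesions x 1919) indexed by lesion_id."""
    rows = [extract_features(lesion) for lesion in lesions]
    df = pd.DataFrame(rows)
    df.index.name = "lesion_id"
    return df


def filter_cohort(records: pd.DataFrame,
                  no_plaque_col: str = "no_visible_plaque",
                  calcified_col: str = "purely_calcified",
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop cross sections without visible plaque or with purely calcified
    plaque, mirroring the cohort-accounting step of the analysis.

    Returns the analyzed table and a report of counts removed per reason
    (a record flagged for both reasons counts under ``no_visible_plaque``).
    """
    for col in (no_plaque_col, calcified_col):
        if col not in records.columns:
            raise KeyError(f"missing flag column {col!r}")
    no_plaque = records[no_plaque_col].astype(bool)
    calcified = records[calcified_col].astype(bool) & ~no_plaque
    keep = ~(no_plaque | calcified)
    report = {
        "total": int(len(records)),
        "removed_no_visible_plaque": int(no_plaque.sum()),
        "removed_purely_calcified": int(calcified.sum()),
        "analyzed": int(keep.sum()),
    }
    return records.loc[keep].copy(), report
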