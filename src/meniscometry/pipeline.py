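"""Glue between the measurement operators and the tabular layer."""

from __future__ import annotations

import pandas as pd

from .classify import DEFAULT_THRESHOLDS, Thresholds, classify
from .morphometry import DEFAULT_BODY_FRACTION, compute_indices
from .volume_io import LabelVolume


def measure_knee(
    vol: LabelVolume,
    subject_id: str,
    group: str = "na",
    tear: str = "na",
    body_fraction: float = DEFAULT_BODY_FRACTION,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """One measurement-table row: lengths, indices and classification."""
    res = compute_indices(vol, body_fraction=body_fraction)
    cls = classify(res, thresholds)
    return {
        "subject_id": subject_id,
        "group": group,
        "tear": tear,
        "dlm_type": cls.dlm_type,
        "a_mm": res.a_body_min_width_mm,
        "b_mm": res.b_tibia_max_width_mm,
        "c_mm": res.c_anterior_horn_mm,
        "d_mm": res.d_posterior_horn_mm,
        "e_mm": res.e_max_ap_diameter_mm,
        "L_mm": res.L_lateral_ap_mm,
        "M_mm": res.M_medial_ap_mm,
        "rmt": res.rmt,
        "pcm": res.pcm,
        "lm_ratio": res.lm_ratio,
        "is_dlm": cls.is_dlm,
        "pcm_positive": cls.pcm_positive,
        "reliable": res.reliable,
    }


def measure_knees(knees, **kwargs) -> pd.DataFrame:
    """Measure a sampled cohort (iterable of CohortKnee) into a table."""
    rows = [
        measure_knee(k.volume, subject_id=k.subject_id, group=k.group, **kwargs)
        for k in knees
    ]
    return pd.DataFrame(rows)
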