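"""Threshold-based discoid-lateral-meniscus classification.

Boundary semantics are deliberately asymmetric and match the published
criteria verbatim: discoid at ``rmt >= 0.20`` (inclusive), complete discoid
at ``rmt > 0.32`` (strict), auxiliary coverage flag at ``pcm >= 0.75``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .morphometry import MorphometryResult


@dataclass(frozen=True)
class Thresholds:
    rmt_dlm: float = 0.20
    rmt_complete: float = 0.32
    pcm_cut: float = 0.75


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class Classification:
    is_dlm: bool
    dlm_type: str  # 'complete' | 'incomplete' | 'na'
    pcm_positive: bool
    thresholds: Thresholds

    def __post_init__(self) -> None:
        if (self.dlm_type != "na") != self.is_dlm:
            raise ValueError("dlm_type must be 'na' exactly when is_dlm is False")


def classify(res: MorphometryResult, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Classification:
    """Classify one measured knee. RMT is the primary criterion; the PCM flag
    is auxiliary and never changes the DLM call."""
    if math.isnan(res.rmt) or math.isnan(res.pcm):
        raise ValueError("cannot classify NaN indices")
    is_dlm = res.rmt >= thresholds.rmt_dlm
    if not is_dlm:
        dlm_type = "na"
    elif res.rmt > thresholds.rmt_complete:
        dlm_type = "complete"
    else:
        dlm_type = "incomplete"
    return Classification(
        is_dlm=is_dlm,
        dlm_type=dlm_type,
        pcm_positive=res.pcm >= thresholds.pcm_cut,
        thresholds=thresholds,
    )
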