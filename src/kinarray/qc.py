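"""Replicate-concordance QC via pairwise Pearson correlation.

Array runs are judged by the Pearson product-moment correlation of
log-transformed spot foreground between every pair of reactions within a
condition; a profile set passes if both the technical-pair mean and the
biological-pair mean reach the gate threshold (0.85 by default).

Correlations are computed on ``log1p(foreground_density)`` — before
background correction and calling, so the gate reflects raw run quality —
over spots flagged ``ok`` in both members of a pair. ``log1p`` rather than
``log`` keeps zero-intensity spots finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .array_model import ArrayLayout, ReplicateQuantification

__all__ = ["CorrelationReport", "replicate_correlations", "qc_gate", "QCError"]

logger = logging.getLogger(__name__)

#: Minimum shared ok spots for a pair's correlation to be defined.
MIN_SHARED_SPOTS = 3


class QCError(ValueError):
    """Raised when no replicate correlation can be computed."""


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations within one condition.

    ``pairwise`` is symmetric with unit diagonal; an entry is NaN when the
    pair shared fewer than three usable spots. ``mean_technical_r``
    averages pairs sharing a biological replicate, ``mean_biological_r``
    pairs from different biological replicates (NaN when no such pair is
    defined).
    """

    condition: str
    reaction_keys: tuple[tuple[int, int], ...]  # (bio_rep, tech_rep)
    pairwise: np.ndarray
    mean_technical_r: float
    mean_biological_r: float

    def passes(self, threshold: float = 0.85) -> bool:
        means = [
            m
            for m in (self.mean_technical_r, self.mean_biological_r)
            if not np.isnan(m)
        ]
        return bool(means) and min(means) >= threshold


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def replicate_correlations(
    quants: list[ReplicateQuantification], layout: ArrayLayout
) -> CorrelationReport:
    """Pairwise Pearson r of log1p foreground across one condition's reactions.

    All reactions must belong to one condition and be aligned with the
    layout. Pairs with fewer than three shared ok spots are excluded with
    a warning; if every pair is undefined the report cannot be formed.
    """
    if len(quants) < 2:
        raise QCError("need at least two reactions to compute correlations")
    conditions = {q.condition for q in quants}
    if len(conditions) != 1:
        raise QCError(f"reactions span multiple conditions: {sorted(conditions)}")
    keys = [(q.bio_rep, q.tech_rep) for q in quants]
    if len(set(keys)) != len(keys):
        raise QCError("duplicate (bio_rep, tech_rep) among reactions")
    for q in quants:
        q.check_aligned(layout)

    n = len(quants)
    logs = [np.log1p(q.foreground) for q in quants]
    mat = np.eye(n)
    tech, bio = [], []
    for i in range(n):
        for j in range(i + 1, n):
            shared = quants[i].ok & quants[j].ok
            if int(shared.sum()) < MIN_SHARED_SPOTS:
                logger.warning(
                    "pair %s/%s shares fewer than %d usable spots; correlation "
                    "undefined",
                    keys[i],
                    keys[j],
                    MIN_SHARED_SPOTS,
                )
                r = float("nan")
            else:
                r = _pearson(logs[i][shared], logs[j][shared])
            mat[i, j] = mat[j, i] = r
            if not np.isnan(r):
                (tech if keys[i][0] == keys[j][0] else bio).append(r)
    if not tech and not bio:
        raise QCError("no replicate pair had enough shared usable spots")
    mean_tech = float(np.mean(tech)) if tech else float("nan")
    mean_bio = float(np.mean(bio)) if bio else float("nan")
    return CorrelationReport(
        condition=quants[0].condition,
        reaction_keys=tuple(keys),
        pairwise=mat,
        mean_technical_r=mean_tech,
        mean_biological_r=mean_bio,
    )


def qc_gate(report: CorrelationReport, threshold: float = 0.85) -> bool:
    """Advisory pass/fail at ``threshold`` (default 0.85).

    The pipeline refuses to proceed to scoring on failure unless an
    override flag is set; the gate itself only reports.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return report.passes(threshold)
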