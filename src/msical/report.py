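"""Cohort-level evaluation: rank samples by MSI score and measure AUC."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .calling import MsiCall
from .dms import rank_auc

logger = logging.getLogger(__name__)


def evaluate_cohort(
    calls: Sequence[MsiCall], labels: Mapping[str, str]
) -> tuple[float, list[tuple[float, float, float]]]:
    """AUC of the MSI score separating labeled MSI from MSS samples.

    Uses the same rank-based estimator as per-site AUC (ties half).
    Samples with an undefined score (no covered site) are excluded with a
    warning.  Returns (auc, roc) where roc is a list of
    (threshold, false-positive rate, true-positive rate) points.
    """
    msi_scores, mss_scores = [], []
    for call in calls:
        label = labels.get(call.sample_id)
        if label not in ("MSI", "MSS"):
            continue
        if call.msi_score is None:
            logger.warning("sample %s has undefined MSI score; excluded from evaluation", call.sample_id)
            continue
        (msi_scores if label == "MSI" else mss_scores).append(call.msi_score)
    if not msi_scores or not mss_scores:
        raise ValueError("cohort evaluation needs at least one scored sample per class")
    auc = rank_auc(msi_scores, mss_scores)

    pos = np.asarray(msi_scores)
    neg = np.asarray(mss_scores)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    roc = [(float("inf"), 0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        roc.append((float(t), fpr, tpr))
    return auc, roc
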