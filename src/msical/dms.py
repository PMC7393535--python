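"""Discriminative microsatellite site (DMS) selection.

Each site's contribution to MSI classification is the area under the ROC
curve for its per-sample deletion probability ``p`` separating labeled MSI
from MSS samples: the probability that a randomly chosen MSI sample shows
a higher ``p`` at the site than a randomly chosen MSS sample, ties counted
half.  This is the normalized Mann-Whitney U statistic, computed from
ranks.  Sites with AUC strictly above a threshold (default 0.65) form the
DMS panel, ranked by descending AUC for top-k sub-panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class SiteAuc:
    site_id: str
    auc: float
    n_msi: int
    n_mss: int


def rank_auc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """P(random positive > random negative) + 0.5 P(tie), via mid-ranks.

    Equals U / (n_pos * n_neg) with U the tie-corrected Mann-Whitney
    statistic, and equals the trapezoidal area under the ROC curve.
    """
    n_pos, n_neg = len(positives), len(negatives)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with an empty class")
    combined = np.concatenate([np.asarray(positives, float), np.asarray(negatives, float)])
    ranks = rankdata(combined)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def site_auc(p_values_msi: Sequence[float], p_values_mss: Sequence[float]) -> float:
    """Per-site AUC of p separating MSI from MSS samples."""
    return rank_auc(p_values_msi, p_values_mss)


def score_sites(
    estimates_by_sample: Mapping[str, Mapping[str, "object"]],
    labels: Mapping[str, str],
    coverage_min: int = 20,
) -> list[SiteAuc]:
    """Compute per-site AUCs over a labeled cohort of estimate tables.

    ``estimates_by_sample`` maps sample_id -> {site_id -> SlippageEstimate};
    ``labels`` maps sample_id -> 'MSI' | 'MSS'.  Only samples with coverage
    m > ``coverage_min`` at a site contribute; sites where either class is
    empty are skipped (their AUC is undefined, not 0.5).
    """
    site_ids: dict[str, None] = {}
    for table in estimates_by_sample.values():
        for sid in table:
            site_ids.setdefault(sid)
    out: list[SiteAuc] = []
    for sid in site_ids:
        msi_p, mss_p = [], []
        for sample_id, table in estimates_by_sample.items():
            label = labels.get(sample_id)
            if label not in ("MSI", "MSS"):
                continue
            est = table.get(sid)
            if est is None or est.m <= coverage_min:
                continue
            (msi_p if label == "MSI" else mss_p).append(est.p)
        if not msi_p or not mss_p:
            continue
        out.append(SiteAuc(site_id=sid, auc=rank_auc(msi_p, mss_p), n_msi=len(msi_p), n_mss=len(mss_p)))
    return out


def select_dms(site_aucs: Sequence[SiteAuc], auc_threshold: float = 0.65) -> list[SiteAuc]:
    """Sites with AUC strictly above the threshold, by descending AUC.

    Ties break on site_id for a deterministic ranking; the head of the
    returned list is the 'top-k' panel.
    """
    kept = [s for s in site_aucs if s.auc > auc_threshold]
    kept.sort(key=lambda s: (-s.auc, s.site_id))
    return kept
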