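"""Tumor-only MSI calling against a panel-of-normals baseline.

A covered baseline site is *unstable* in the tumor when its estimated
per-unit deletion probability strictly exceeds the baseline threshold
``mu + 3 sigma``.  The MSI score is the percentage of unstable sites among
covered baseline sites; samples are ranked by this score, and a
configurable cutoff (default 10%, a package choice — the underlying method
is rank-based) attaches a binary MSI/MSS label for convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .baseline import BaselineEntry
from .model import SlippageEstimate

logger = logging.getLogger(__name__)

STABLE = "stable"
UNSTABLE = "unstable"


@dataclass(frozen=True)
class SiteVerdict:
    site_id: str
    p: float
    threshold: float
    verdict: str


@dataclass(frozen=True)
class MsiCall:
    """Per-sample MSI call."""

    sample_id: str
    sites_covered: int
    sites_unstable: int
    per_site: tuple[SiteVerdict, ...] = ()
    score_cutoff: float = 10.0

    @property
    def msi_score(self) -> float | None:
        """Percentage of unstable sites among covered sites; None when no
        site is covered (flagged, not an error)."""
        if self.sites_covered == 0:
            return None
        return 100.0 * self.sites_unstable / self.sites_covered

    @property
    def label(self) -> str:
        score = self.msi_score
        if score is None:
            return "undetermined"
        return "MSI" if score >= self.score_cutoff else "MSS"


def classify_site(estimate: SlippageEstimate, baseline_entry: BaselineEntry) -> str:
    """Unstable iff p strictly exceeds the baseline mu + 3 sigma."""
    if estimate.m < 1:
        raise ValueError("cannot classify a site with no supporting reads")
    return UNSTABLE if estimate.p > baseline_entry.threshold else STABLE


def call_msi(
    tumor_estimates: Mapping[str, SlippageEstimate],
    baseline: Sequence[BaselineEntry],
    coverage_min: int = 20,
    score_cutoff: float = 10.0,
    sample_id: str = "sample",
    tumor_hash: str | None = None,
    baseline_hash: str | None = None,
) -> MsiCall:
    """Score one tumor sample against the baseline.

    A baseline site counts as covered ("detected") when the tumor has
    m > ``coverage_min`` supporting reads there, mirroring the baseline's
    own inclusion rule.  Tumor sites absent from the baseline are excluded
    from both numerator and denominator.  When both site-list hashes are
    supplied they must match, preventing a baseline from being applied to
    estimates derived from a different site panel.
    """
    if tumor_hash is not None and baseline_hash is not None and tumor_hash != baseline_hash:
        raise ValueError(
            f"site-list hash mismatch: tumor estimates {tumor_hash} vs baseline {baseline_hash}"
        )
    covered = 0
    unstable = 0
    verdicts: list[SiteVerdict] = []
    for entry in baseline:
        est = tumor_estimates.get(entry.site_id)
        if est is None or est.m <= coverage_min:
            continue
        covered += 1
        verdict = classify_site(est, entry)
        if verdict == UNSTABLE:
            unstable += 1
        verdicts.append(SiteVerdict(entry.site_id, est.p, entry.threshold, verdict))
    if covered == 0:
        logger.warning("sample %s: no baseline site covered; MSI score undefined", sample_id)
    return MsiCall(
        sample_id=sample_id,
        sites_covered=covered,
        sites_unstable=unstable,
        per_site=tuple(verdicts),
        score_cutoff=score_cutoff,
    )
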