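"""Panel-of-normals baseline for tumor-only MSI calling.

For each microsatellite the baseline records the mean and standard
deviation of the per-unit deletion probability ``p`` estimated across a
panel of normal (non-tumor) samples.  A site enters the baseline only when
it has sufficient read coverage (m > ``coverage_min``, default 20) in
strictly more than ``support_fraction`` (default half) of the panel, and
its summary statistics are computed over exactly the coverage-passing
samples.  The instability threshold per site is ``mu + 3 sigma``; the
panel is treated as the reference population, so sigma is the population
standard deviation (divide by k) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .model import SlippageEstimate

logger = logging.getLogger(__name__)

N_SIGMA = 3.0


@dataclass(frozen=True)
class BaselineEntry:
    """Per-site baseline: mean/SD of p across supporting normals."""

    site_id: str
    mu: float
    sigma: float
    k: int

    @property
    def threshold(self) -> float:
        return self.mu + N_SIGMA * self.sigma


def build_baseline(
    estimate_tables: Sequence[Mapping[str, SlippageEstimate]],
    coverage_min: int = 20,
    support_fraction: float = 0.5,
    ddof: int = 0,
    site_order: Sequence[str] | None = None,
) -> list[BaselineEntry]:
    """Build the per-site baseline from per-normal-sample estimate tables.

    Each table maps site_id -> SlippageEstimate for one normal sample
    (absent or m = 0 sites count as uncovered).  A site is retained iff
    its coverage exceeds ``coverage_min`` in strictly more than
    ``support_fraction`` of the panel; mu and sigma are then computed over
    the coverage-passing samples only.  Sites with fewer than two
    supporting samples are dropped (sigma is undefined from one point).
    """
    if len(estimate_tables) < 2:
        raise ValueError("a baseline needs at least 2 normal samples")
    n_samples = len(estimate_tables)
    if site_order is None:
        seen: dict[str, None] = {}
        for table in estimate_tables:
            for sid in table:
                seen.setdefault(sid)
        site_order = list(seen)
    entries: list[BaselineEntry] = []
    for sid in site_order:
        p_vals = [
            table[sid].p
            for table in estimate_tables
            if sid in table and table[sid].m > coverage_min
        ]
        k = len(p_vals)
        if k <= support_fraction * n_samples:
            continue
        if k < 2:
            logger.warning("site %s retained by coverage rule but has <2 supporting samples; dropped", sid)
            continue
        arr = np.asarray(p_vals, dtype=float)
        entries.append(
            BaselineEntry(site_id=sid, mu=float(arr.mean()), sigma=float(arr.std(ddof=ddof)), k=k)
        )
    return entries


# ---------------------------------------------------------------------------
# baseline TSV: site_id expanded into identity columns + mu, sigma, threshold, k

BASELINE_COLUMNS = ("chrom", "start", "motif", "mu", "sigma", "threshold", "k")


def write_baseline(
    entries: Iterable[BaselineEntry],
    handle: TextIO,
    sites_hash: str = "",
    extra_header: dict | None = None,
) -> None:
    handle.write(f"# msical baseline sites_hash={sites_hash}\n")
    if extra_header:
        for key, val in extra_header.items():
            handle.write(f"# {key}={val}\n")
    handle.write("#" + "\t".join(BASELINE_COLUMNS) + "\n")
    for e in entries:
        chrom, start, motif = e.site_id.split(":")
        handle.write(
            f"{chrom}\t{int(start) + 1}\t{motif}\t{e.mu:.8g}\t{e.sigma:.8g}\t{e.threshold:.8g}\t{e.k}\n"
        )


def read_baseline(handle: TextIO) -> list[BaselineEntry]:
    entries = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, start, motif, mu, sigma, _thr, k = line.split("\t")
        entries.append(
            BaselineEntry(
                site_id=f"{chrom}:{int(start) - 1}:{motif}",
                mu=float(mu),
                sigma=float(sigma),
                k=int(k),
            )
        )
    return entries
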