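"""Extract per-site repeat-length distributions from aligned reads.

The unit of evidence for a microsatellite genotype is a *spanning read*:
a primary, well-mapped read whose alignment covers the whole repeat tract
plus at least ``anchor`` bases of flank on both sides.  For each spanning
read the observed repeat length ``y`` (in whole motif copies, truncated
toward zero) is measured and the per-site multiset of lengths is the input
to the slippage model.

Two measurement paths are provided:

* flank re-anchoring (default): the tract is re-located inside the read by
  exact match of the reference flanks, then motif copies are counted
  between the anchors.  Alignment of indels inside a tandem repeat is
  ambiguous (left-alignment conventions differ across mappers), so
  trusting the flanks rather than the CIGAR placement is the established
  remedy.  A read in which either flank cannot be found exactly is
  discarded.
* CIGAR arithmetic (``use_flank_anchors=False``): the query bases aligned
  within the tract interval (including insertions arising inside it) are
  collected and motif copies counted.  Kept as a cross-check of the
  anchoring path on error-free data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import pysam

from .sites import MicrosatelliteSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleLengthDistribution:
    """Multiset of observed repeat lengths (in motif copies) at one site."""

    site_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(y < 0 or c < 0 for y, c in self.counts.items()):
            raise ValueError("negative length or count in allele distribution")
        # drop zero-count entries so `counts empty iff m == 0` holds
        object.__setattr__(self, "counts", {y: c for y, c in self.counts.items() if c > 0})

    @property
    def m(self) -> int:
        """Total number of supporting reads."""
        return sum(self.counts.values())

    def expand(self) -> list[int]:
        """Flat list of per-read lengths, ascending."""
        out: list[int] = []
        for y in sorted(self.counts):
            out.extend([y] * self.counts[y])
        return out


@dataclass(frozen=True)
class ExtractionConfig:
    min_mapq: int = 20
    anchor: int = 5  # bases of exact flank required on each side
    use_flank_anchors: bool = True


def _count_motif_copies(seq: str, motif: str) -> int:
    """Leading whole copies of motif in seq; a non-motif base stops counting."""
    k = len(motif)
    copies = 0
    pos = 0
    while seq[pos : pos + k] == motif:
        copies += 1
        pos += k
    return copies


def _measure_by_anchors(read: pysam.AlignedSegment, site: MicrosatelliteSite,
                        left_anchor: str, right_anchor: str, slack: int) -> int | None:
    """Re-locate the tract in the read by exact flank match; None = discard.

    The left anchor is the occurrence (within ``slack`` of the
    CIGAR-implied tract start) that ends closest to the implied start —
    flank sequence can recur by chance near a repeat, so neither the
    leftmost nor the rightmost occurrence is safe.  Copies are then
    counted in motif phase from the anchor; the right anchor need only be
    present downstream of the counted copies (a non-motif insertion stops
    the count but the read still spans)."""
    seq = read.query_sequence
    if seq is None:
        return None
    # query position the alignment implies for the tract start
    qpos = None
    for q, r in read.get_aligned_pairs(matches_only=True):
        if r is not None and r >= site.start:
            qpos = q
            break
    if qpos is None:
        return None
    a = len(left_anchor)
    lo = max(0, qpos - a - slack)
    hi = min(len(seq), qpos + slack)
    best = None
    at = seq.find(left_anchor, lo, hi)
    while at >= 0:
        if best is None or abs(at + a - qpos) < abs(best + a - qpos):
            best = at
        at = seq.find(left_anchor, at + 1, hi)
    if best is None:
        return None
    tract_start = best + a
    copies = _count_motif_copies(seq[tract_start:], site.motif)
    stop = tract_start + copies * len(site.motif)
    if seq.find(right_anchor, stop) < 0:
        return None
    return copies


def _measure_by_cigar(read: pysam.AlignedSegment, site: MicrosatelliteSite) -> int | None:
    """Collect query bases aligned within the tract (insertions included)
    and count motif copies."""
    seq = read.query_sequence
    if seq is None:
        return None
    tract_bases = []
    inside = False
    for q, r in read.get_aligned_pairs():
        if r is not None:
            inside = site.start <= r < site.end
            if inside and q is not None:
                tract_bases.append(seq[q])
        elif inside and q is not None:  # insertion while inside the tract
            tract_bases.append(seq[q])
    return _count_motif_copies("".join(tract_bases), site.motif)


def extract_site_distribution(
    alignments: pysam.AlignmentFile,
    site: MicrosatelliteSite,
    config: ExtractionConfig | None = None,
    reference: "object | None" = None,
) -> AlleleLengthDistribution:
    """Observed repeat-length distribution at one site.

    Reads must be primary, mapped with MAPQ >= ``config.min_mapq``, not
    duplicate/QC-fail, and span ``[start - anchor, end + anchor)``.  No
    base-quality filter is applied.

    ``reference`` optionally supplies flank sequence (a pyfaidx Fasta);
    otherwise the site's recorded flanks are used, truncated to ``anchor``.
    """
    if config is None:
        config = ExtractionConfig()
    if site.chrom not in alignments.references:
        logger.warning("chromosome %s absent from alignment header; site skipped", site.chrom)
        return AlleleLengthDistribution(site_id=site.site_id, counts={})

    a = config.anchor
    if reference is not None:
        chrom_seq = reference[site.chrom]
        left_anchor = str(chrom_seq[max(0, site.start - a) : site.start]).upper()
        right_anchor = str(chrom_seq[site.end : site.end + a]).upper()
    else:
        left_anchor = site.left_flank[-a:] if a else ""
        right_anchor = site.right_flank[:a] if a else ""
    if config.use_flank_anchors and (len(left_anchor) < a or len(right_anchor) < a):
        logger.warning("site %s too close to a contig edge for %d bp anchors", site.site_id, a)
        return AlleleLengthDistribution(site_id=site.site_id, counts={})

    slack = site.end - site.start
    counts: dict[int, int] = {}
    for read in alignments.fetch(site.chrom, max(0, site.start - a), site.end + a):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.is_qcfail
            or read.mapping_quality < config.min_mapq
        ):
            continue
        if read.reference_start > site.start - a or read.reference_end < site.end + a:
            continue  # does not span tract + anchors
        if config.use_flank_anchors:
            y = _measure_by_anchors(read, site, left_anchor, right_anchor, slack)
        else:
            y = _measure_by_cigar(read, site)
        if y is None:
            continue
        counts[y] = counts.get(y, 0) + 1
    return AlleleLengthDistribution(site_id=site.site_id, counts=dict(sorted(counts.items())))


def extract_all(
    alignments: pysam.AlignmentFile,
    site_list: Iterable[MicrosatelliteSite],
    config: ExtractionConfig | None = None,
    reference: "object | None" = None,
) -> Iterator[AlleleLengthDistribution]:
    """One distribution per site, in site-list order; uncovered sites are
    emitted with m = 0 so callers can apply their own coverage rules."""
    for site in site_list:
        yield extract_site_distribution(alignments, site, config, reference)


# ---------------------------------------------------------------------------
# distribution TSV: site identity columns, then space-separated y:count pairs, then m

DIST_COLUMNS = ("chrom", "start", "motif", "n", "dist", "m")


def write_distributions(
    dists: Iterable[tuple[MicrosatelliteSite, AlleleLengthDistribution]],
    handle: TextIO,
    sites_hash: str = "",
    extra_header: dict | None = None,
) -> None:
    handle.write(f"# msical distributions sites_hash={sites_hash}\n")
    if extra_header:
        for key, val in extra_header.items():
            handle.write(f"# {key}={val}\n")
    handle.write("#" + "\t".join(DIST_COLUMNS) + "\n")
    for site, dist in dists:
        pairs = " ".join(f"{y}:{c}" for y, c in sorted(dist.counts.items())) or "."
        handle.write(f"{site.chrom}\t{site.start + 1}\t{site.motif}\t{site.n}\t{pairs}\t{dist.m}\n")


def read_distributions(handle: TextIO) -> list[tuple[MicrosatelliteSite, AlleleLengthDistribution]]:
    out = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, start, motif, n, pairs, m = line.split("\t")
        site = MicrosatelliteSite(chrom=chrom, start=int(start) - 1, motif=motif, n=int(n))
        counts: dict[int, int] = {}
        if pairs != ".":
            for pair in pairs.split(" "):
                y, c = pair.split(":")
                counts[int(y)] = int(c)
        dist = AlleleLengthDistribution(site_id=site.site_id, counts=counts)
        if dist.m != int(m):
            raise ValueError(f"corrupt distribution row for {site.site_id}: m mismatch")
        out.append((site, dist))
    return out


def read_header_value(path: str, key: str) -> str:
    """Pull a key=value pair out of a '#' TSV header."""
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if token.startswith(f"{key}="):
                    return token.split("=", 1)[1]
    return ""
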