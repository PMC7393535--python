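"""Microsatellite discovery: scan a reference genome for maximal tandem repeats.

A microsatellite locus is a maximal run of ``n`` complete copies of a
primitive 1-5 bp motif.  "Primitive" means the motif is not itself a
repetition of a shorter unit (``ATAT`` is recorded as two extra copies of
``AT``, never as motif ``ATAT``); "maximal" means the periodic run extends
neither left nor right, not even by a partial copy, so every locus has a
unique leftmost start and motif phase.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterator, Iterable, TextIO

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class MicrosatelliteSite:
    """One reference repeat locus.

    Coordinates are 0-based; the repeat tract occupies
    ``[start, start + n * len(motif))`` on ``chrom``.
    """

    chrom: str
    start: int
    motif: str
    n: int
    left_flank: str = ""
    right_flank: str = ""

    @property
    def end(self) -> int:
        """0-based exclusive end of the repeat tract."""
        return self.start + self.n * len(self.motif)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.motif}"

    @property
    def tract(self) -> str:
        return self.motif * self.n


@dataclass(frozen=True)
class ScanConfig:
    """Scanner thresholds.

    min_repeats maps motif length -> minimum number of complete copies.
    Defaults require homopolymer runs of >= 5 bases and >= 3 copies for
    motifs of 2-5 bp, the conventional sensitivity range of MSI panels.
    """

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 5, 2: 3, 3: 3, 4: 3, 5: 3}
    )
    flank_len: int = 5

    @property
    def motif_lengths(self) -> list[int]:
        return sorted(self.min_repeats)


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def scan_sequence(chrom: str, seq: str, config: ScanConfig | None = None) -> list[MicrosatelliteSite]:
    """Find all maximal microsatellites in one sequence.

    Scanning is case-insensitive; any character outside ACGT (N, ambiguity
    codes) breaks repeat runs at that position.  Runs of a longer motif
    that contain shorter-motif repeats (a homopolymer inside an AAT run,
    say) are reported independently at each motif length.
    """
    if config is None:
        config = ScanConfig()
    seq = seq.upper()
    L = len(seq)
    out: list[MicrosatelliteSite] = []
    for k in config.motif_lengths:
        min_n = config.min_repeats[k]
        i = 0
        while i + k <= L:
            if seq[i] not in _VALID:
                i += 1
                continue
            # extend the period-k match region starting at i
            j = i
            while j + k < L and seq[j + k] == seq[j] and seq[j] in _VALID:
                j += 1
            run_len = (j - i) + k  # total bases with period k starting at i
            n = run_len // k
            if n >= min_n:
                motif = seq[i : i + k]
                if _is_primitive(motif) and all(c in _VALID for c in motif):
                    out.append(
                        MicrosatelliteSite(
                            chrom=chrom,
                            start=i,
                            motif=motif,
                            n=n,
                            left_flank=seq[max(0, i - config.flank_len) : i],
                            right_flank=seq[i + n * k : i + n * k + config.flank_len],
                        )
                    )
            # runs are maximal intervals of the predicate s[x] == s[x+k];
            # the next interval cannot start before j + 1
            i = j + 1
    out.sort(key=lambda s: (s.chrom, s.start, len(s.motif)))
    return out


def scan_reference(fasta_path: str, config: ScanConfig | None = None) -> Iterator[MicrosatelliteSite]:
    """Scan every sequence of a FASTA file; yields sites sorted by (chrom, start)."""
    if config is None:
        config = ScanConfig()
    try:
        fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    except Exception as exc:  # pragma: no cover - pyfaidx error classes vary
        raise IOError(f"cannot read FASTA {fasta_path!r}: {exc}") from exc
    for name in fa.keys():
        seq = str(fa[name][:])
        yield from scan_sequence(name, seq, config)


# ---------------------------------------------------------------------------
# site-list TSV contract: 1-based inclusive start on disk, 0-based in memory

SITE_COLUMNS = ("chrom", "start", "motif", "n", "left_flank", "right_flank")


def sites_hash(sites: Iterable[MicrosatelliteSite]) -> str:
    """Content hash of a site list; embedded in downstream files so a
    baseline can never be applied to estimates from a different panel."""
    h = hashlib.sha256()
    for s in sites:
        h.update(f"{s.chrom}\t{s.start}\t{s.motif}\t{s.n}\n".encode())
    return h.hexdigest()[:16]


def write_sites(sites: list[MicrosatelliteSite], handle: TextIO, extra_header: dict | None = None) -> None:
    handle.write(f"# msical sites sites_hash={sites_hash(sites)}\n")
    if extra_header:
        for key, val in extra_header.items():
            handle.write(f"# {key}={val}\n")
    handle.write("#" + "\t".join(SITE_COLUMNS) + "\n")
    for s in sites:
        handle.write(
            f"{s.chrom}\t{s.start + 1}\t{s.motif}\t{s.n}\t{s.left_flank}\t{s.right_flank}\n"
        )


def read_sites(handle: TextIO) -> list[MicrosatelliteSite]:
    sites = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, start, motif, n, lf, rf = (line.split("\t") + ["", ""])[:6]
        sites.append(
            MicrosatelliteSite(
                chrom=chrom, start=int(start) - 1, motif=motif, n=int(n),
                left_flank=lf, right_flank=rf,
            )
        )
    return sites
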