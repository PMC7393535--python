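"""Synthetic cohorts with known ground truth.

Generates a small reference genome with planted maximal microsatellites,
per-site slippage parameters, and per-sample reads (as aligned BAM/SAM
records or directly as allele-length distribution tables) for three sample
roles:

* ``normal`` — reads drawn at each site's base (p, q);
* ``mss``    — a microsatellite-stable tumor, identical to normal;
* ``msi``    — an unstable tumor: at a configured fraction of sites the
  deletion probability p is elevated by a multiplicative effect
  (default x5), emulating mismatch-repair deficiency.

Tumor purity is emulated by drawing each read from tumor parameters with
probability pi and from the base parameters otherwise; sequencing depth by
Poisson coverage with a configurable mean and down-scaling factor.  Reads
are error-free with exact reference flanks, so extraction ground truth is
unambiguous; repeat-length changes are encoded in the CIGAR as a single
insertion or deletion at the tract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pysam

from .extraction import AlleleLengthDistribution
from .model import SlippageParams, pmf_vector
from .sites import MicrosatelliteSite, ScanConfig, scan_sequence

_BASES = "ACGT"

DEFAULT_MOTIF_MIX = {1: 0.50, 2: 0.25, 3: 0.15, 4: 0.07, 5: 0.03}
DEFAULT_N_RANGE = {1: (8, 20), 2: (4, 10), 3: (3, 8), 4: (3, 6), 5: (3, 5)}


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic cohort.

    Defaults describe a modest targeted panel: 500 microsatellites
    (homopolymer-dominated motif mix), 20 normals and 20 tumors per class,
    mean 50x spanning coverage, base deletion probability p in
    [0.001, 0.05] increasing with reference repeat count, insertion
    probability q = p/5, and MSI tumors with p elevated x5 at 30% of
    sites.
    """

    n_sites: int = 500
    motif_mix: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_MOTIF_MIX))
    n_range: Mapping[int, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_N_RANGE))
    n_normals: int = 20
    n_msi: int = 20
    n_mss: int = 20
    p_range: tuple[float, float] = (0.001, 0.05)
    q_ratio: float = 0.2
    msi_effect: float = 5.0
    msi_site_fraction: float = 0.3
    coverage: float = 50.0
    purity: float = 1.0
    spacer_len: int = 30
    read_margin: int = 15
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.coverage < 0:
            raise ValueError("counts and coverage must be non-negative")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if self.spacer_len < 20:
            raise ValueError("planted sites need >= 20 bp of non-repetitive spacer")


@dataclass(frozen=True)
class SiteTruth:
    site: MicrosatelliteSite
    base_params: SlippageParams
    msi_affected: bool


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    reference: str  # single-chromosome sequence
    truth: tuple[SiteTruth, ...]

    @property
    def sites(self) -> list[MicrosatelliteSite]:
        return [t.site for t in self.truth]

    def site_params(self, truth: SiteTruth, role: str) -> SlippageParams:
        """Effective (p, q) at one site for a sample role."""
        if role == "msi" and truth.msi_affected:
            p = truth.base_params.p * self.spec.msi_effect
            q = truth.base_params.q
            if p + q > 0.9:  # keep probabilities valid after elevation
                p = 0.9 - q
            return SlippageParams(p=p, q=q)
        return truth.base_params


def _random_primitive_motif(k: int, rng: np.random.Generator) -> str:
    while True:
        motif = "".join(rng.choice(list(_BASES), size=k))
        periodic = any(
            k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
        )
        if not periodic:
            return motif


def _spacer_ok(prev_tail: str, spacer: str, next_tract: str, config: ScanConfig) -> bool:
    """A spacer is acceptable when scanning the local window recovers
    exactly the planted tracts, unshifted, and nothing else."""
    window = prev_tail + spacer + next_tract
    found = {(s.start, s.motif, s.n) for s in scan_sequence("w", window, config)}
    expected = set()
    if prev_tail:
        # prev_tail is a complete planted tract placed at window offset 0
        k = _tract_motif_len(prev_tail)
        expected.add((0, prev_tail[:k], len(prev_tail) // k))
    if next_tract:
        k = _tract_motif_len(next_tract)
        expected.add((len(prev_tail) + len(spacer), next_tract[:k], len(next_tract) // k))
    # only sites meeting the scan minimums are expected
    expected = {
        (start, motif, n)
        for (start, motif, n) in expected
        if n >= config.min_repeats.get(len(motif), 10**9)
    }
    return found == expected


def _tract_motif_len(tract: str) -> int:
    for k in range(1, 6):
        if len(tract) % k == 0 and tract == tract[:k] * (len(tract) // k):
            return k
    return len(tract)


def generate_reference(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> Cohort:
    """Build the synthetic reference and its ground-truth site list.

    Planted repeats are separated by random non-repetitive spacers; each
    spacer is rejection-sampled until a scan of the local window finds
    exactly the planted tracts, so scanning the full chromosome provably
    recovers the truth list.  Per-site base p interpolates across
    ``p_range`` with the reference repeat count (longer repeats slip
    more), with a +/-20% jitter; q = p * q_ratio.  MSI-affected sites are
    drawn once per cohort.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )
    config = ScanConfig()
    lengths = sorted(spec.motif_mix)
    mix = np.array([spec.motif_mix[k] for k in lengths], dtype=float)
    mix = mix / mix.sum() if mix.sum() > 0 else mix

    # plan the tracts
    tracts: list[tuple[str, int]] = []  # (motif, n)
    for _ in range(spec.n_sites):
        k = int(gen.choice(lengths, p=mix))
        lo, hi = spec.n_range[k]
        n = int(gen.integers(lo, hi + 1))
        tracts.append((_random_primitive_motif(k, gen), n))

    # assemble sequence: spacer, tract, spacer, tract, ..., spacer
    parts: list[str] = []
    truth_sites: list[MicrosatelliteSite] = []
    pos = 0
    prev_tract = ""
    for motif, n in tracts:
        tract = motif * n
        for _attempt in range(200):
            spacer = "".join(gen.choice(list(_BASES), size=spec.spacer_len))
            if _spacer_ok(prev_tract, spacer, tract, config):
                break
        else:  # pragma: no cover - rejection virtually always succeeds quickly
            raise RuntimeError("could not place a non-repetitive spacer after 200 draws")
        parts.append(spacer)
        pos += len(spacer)
        start = pos
        parts.append(tract)
        pos += len(tract)
        truth_sites.append(
            MicrosatelliteSite(chrom=spec.chrom, start=start, motif=motif, n=n)
        )
        prev_tract = tract
    for _attempt in range(200):
        spacer = "".join(gen.choice(list(_BASES), size=spec.spacer_len))
        if _spacer_ok(prev_tract, spacer, "", config):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not place the terminal spacer")
    parts.append(spacer)
    seq = "".join(parts)

    # attach flanks now that the sequence is final
    flanked = [
        MicrosatelliteSite(
            chrom=s.chrom, start=s.start, motif=s.motif, n=s.n,
            left_flank=seq[max(0, s.start - config.flank_len) : s.start],
            right_flank=seq[s.end : s.end + config.flank_len],
        )
        for s in truth_sites
    ]

    # per-site slippage parameters and MSI-affected flags
    p_lo, p_hi = spec.p_range
    truth: list[SiteTruth] = []
    affected = gen.random(spec.n_sites) < spec.msi_site_fraction
    for i, site in enumerate(flanked):
        lo, hi = spec.n_range[len(site.motif)]
        frac = 0.5 if hi == lo else (site.n - lo) / (hi - lo)
        p = (p_lo + (p_hi - p_lo) * frac) * gen.uniform(0.8, 1.2)
        p = float(np.clip(p, p_lo, p_hi))
        truth.append(
            SiteTruth(
                site=site,
                base_params=SlippageParams(p=p, q=p * spec.q_ratio),
                msi_affected=bool(affected[i]),
            )
        )
    return Cohort(spec=spec, reference=seq, truth=tuple(truth))


# ---------------------------------------------------------------------------
# sampling


def _draw_site_counts(
    cohort: Cohort,
    truth: SiteTruth,
    role: str,
    purity: float,
    m: int,
    gen: np.random.Generator,
) -> dict[int, int]:
    """Multiset of read lengths at one site: reads are tumor-derived with
    probability ``purity`` (role parameters) and normal-derived otherwise."""
    n = truth.site.n
    tumor_params = cohort.site_params(truth, role)
    base_params = truth.base_params
    m_tumor = int(gen.binomial(m, purity)) if role in ("msi", "mss") else m
    counts = np.zeros(2 * n + 1, dtype=int)
    for params, size in ((tumor_params, m_tumor), (base_params, m - m_tumor)):
        if size == 0:
            continue
        probs = pmf_vector(n, params)
        counts += gen.multinomial(size, probs / probs.sum())
    return {int(y): int(c) for y, c in enumerate(counts) if c > 0}


def generate_sample(
    cohort: Cohort,
    role: str,
    purity: float | None = None,
    depth_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, AlleleLengthDistribution]:
    """Draw one sample directly as per-site allele-length distributions.

    This is the fast path that skips read construction entirely; coverage
    at each site is Poisson(coverage * depth_scale).  ``purity`` defaults
    to the cohort spec's value and is ignored for normals.
    """
    if role not in ("normal", "msi", "mss"):
        raise ValueError(f"unknown sample role {role!r}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pi = cohort.spec.purity if purity is None else purity
    out: dict[str, AlleleLengthDistribution] = {}
    mean_cov = cohort.spec.coverage * depth_scale
    for truth in cohort.truth:
        m = int(gen.poisson(mean_cov))
        counts = _draw_site_counts(cohort, truth, role, pi, m, gen) if m else {}
        out[truth.site.site_id] = AlleleLengthDistribution(
            site_id=truth.site.site_id, counts=counts
        )
    return out


def write_reference_fasta(cohort: Cohort, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cohort.spec.chrom}\n")
        seq = cohort.reference
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_sample_bam(
    cohort: Cohort,
    role: str,
    bam_path: str,
    purity: float | None = None,
    depth_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sample",
) -> dict[str, AlleleLengthDistribution]:
    """Write one sample as a coordinate-sorted, indexed BAM of error-free
    aligned reads; returns the planted per-site length distributions
    (the extraction ground truth).

    Each read covers the tract plus ``read_margin`` reference bases on
    both sides; a net repeat-length change appears as one I or D operation
    at the tract boundary.
    """
    if role not in ("normal", "msi", "mss"):
        raise ValueError(f"unknown sample role {role!r}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pi = cohort.spec.purity if purity is None else purity
    margin = cohort.spec.read_margin
    seq = cohort.reference
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cohort.spec.chrom, "LN": len(seq)}],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    planted: dict[str, AlleleLengthDistribution] = {}
    mean_cov = cohort.spec.coverage * depth_scale
    with pysam.AlignmentFile(bam_path, "wb", header=dict(header)) as bam:
        for s_idx, truth in enumerate(cohort.truth):
            site = truth.site
            k = len(site.motif)
            m = int(gen.poisson(mean_cov))
            counts = _draw_site_counts(cohort, truth, role, pi, m, gen) if m else {}
            planted[site.site_id] = AlleleLengthDistribution(site_id=site.site_id, counts=counts)
            left = seq[site.start - margin : site.start]
            right = seq[site.end : site.end + margin]
            r_idx = 0
            for y in sorted(counts):
                for _ in range(counts[y]):
                    read = pysam.AlignedSegment()
                    read.query_name = f"{sample_id}_s{s_idx}_r{r_idx}_y{y}"
                    read.query_sequence = left + site.motif * y + right
                    read.flag = 0
                    read.reference_id = 0
                    read.reference_start = site.start - margin
                    read.mapping_quality = 60
                    if y == site.n:
                        cig = [(0, margin + site.n * k + margin)]
                    elif y < site.n:
                        cig = [(0, margin + y * k), (2, (site.n - y) * k), (0, margin)]
                    else:
                        cig = [(0, margin + site.n * k), (1, (y - site.n) * k), (0, margin)]
                    read.cigartuples = cig
                    read.set_tag("RG", sample_id)
                    bam.write(read)
                    r_idx += 1
    pysam.index(bam_path)
    return planted


def write_labels(labels: Mapping[str, tuple[str, str]], path: str) -> None:
    """Labels TSV: sample_id, label in {MSI, MSS}, split in {discovery, test}."""
    with open(path, "w") as fh:
        fh.write("#sample_id\tlabel\tsplit\n")
        for sample_id, (label, split) in labels.items():
            fh.write(f"{sample_id}\t{label}\t{split}\n")


def write_run_config(spec: CohortSpec, path: str) -> None:
    with open(path, "w") as fh:
        payload = asdict(spec)
        payload["motif_mix"] = {str(k): v for k, v in spec.motif_mix.items()}
        payload["n_range"] = {str(k): list(v) for k, v in spec.n_range.items()}
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
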