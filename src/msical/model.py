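"""Multinomial model of polymerase slippage at a microsatellite.

Replication of each of the ``n`` reference repeat units is a three-outcome
draw: the unit is deleted with probability ``p`` (hysteresis synthesis),
duplicated with probability ``q`` (pre-synthesis), or copied faithfully
with probability ``1 - p - q``.  Slippage events are independent across
units, so the observed repeat length ``y`` is the sum of per-unit outcomes
and its minimal-path probability has two closed-form branches:

    y <= n :  C(n, n-y) (1-p-q)^y     p^(n-y)      (net deletion)
    y >  n :  C(n, y-n) (1-p-q)^(2n-y) q^(y-n)     (net insertion)

Paths that reach the same ``y`` through extra compensating steps carry a
much smaller probability and are deliberately ignored, so the pmf sums to
``(1-q)^n + (1-p)^n - (1-p-q)^n`` (slightly below 1 when both p, q > 0)
rather than exactly 1.  The simulator renormalizes over the support
``0..2n`` so draws form a proper distribution.

Given ``m`` spanning reads with lengths ``y_1..y_m``, the likelihood of the
minimal-path pmf is maximized in closed form by

    p_hat = sum_{y_i <= n} (n - y_i) / (n m)
    q_hat = sum_{y_i >  n} (y_i - n) / (n m)

which is the per-unit deletion (insertion) rate averaged over reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Mapping

import numpy as np
from scipy import stats

from .extraction import AlleleLengthDistribution


@dataclass(frozen=True)
class SlippageParams:
    """Per-repeat-unit slippage probabilities (p: deletion, q: insertion)."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p and 0.0 <= self.q and self.p + self.q <= 1.0 + 1e-12):
            raise ValueError(f"invalid slippage parameters p={self.p}, q={self.q}")


@dataclass(frozen=True)
class SlippageEstimate:
    """Closed-form (p, q) estimate at one site, with supporting coverage m."""

    params: SlippageParams
    m: int
    site_id: str = ""

    @property
    def p(self) -> float:
        return self.params.p

    @property
    def q(self) -> float:
        return self.params.q


def multinoulli_pmf(x: int, params: SlippageParams) -> float:
    """Probability of one per-unit outcome: 0 = deletion, 1 = faithful copy,
    2 = insertion."""
    if x == 0:
        return params.p
    if x == 1:
        return 1.0 - params.p - params.q
    if x == 2:
        return params.q
    raise ValueError(f"outcome must be in {{0, 1, 2}}, got {x}")


def repeat_length_pmf(y: int, n: int, params: SlippageParams) -> float:
    """Minimal-path probability of observing y motif copies at a site with
    n reference copies; zero outside the support 0..2n."""
    if y < 0:
        raise ValueError(f"observed length must be >= 0, got {y}")
    if n < 1:
        raise ValueError(f"reference repeat count must be >= 1, got {n}")
    p, q = params.p, params.q
    r = 1.0 - p - q
    if y <= n:
        return math.comb(n, n - y) * r**y * p ** (n - y)
    if y <= 2 * n:
        return math.comb(n, y - n) * r ** (2 * n - y) * q ** (y - n)
    return 0.0


def pmf_vector(n: int, params: SlippageParams) -> np.ndarray:
    """Unnormalized pmf over the full support y = 0..2n."""
    return np.array([repeat_length_pmf(y, n, params) for y in range(2 * n + 1)])


def log_likelihood(dist: AlleleLengthDistribution, n: int, params: SlippageParams) -> float:
    """Log-likelihood of the read-length distribution under the minimal-path
    pmf; -inf if any observed length has zero probability (including y > 2n,
    possible in noisy data but impossible under the model)."""
    if dist.m == 0:
        raise ValueError("log-likelihood undefined for an empty distribution")
    total = 0.0
    for y, count in dist.counts.items():
        prob = repeat_length_pmf(y, n, params)
        if prob <= 0.0:
            return -math.inf
        total += count * math.log(prob)
    return total


def estimate_slippage(dist: AlleleLengthDistribution, n: int) -> SlippageEstimate:
    """Closed-form maximum-likelihood estimate of (p, q) from read lengths.

    Reads at or below the reference length contribute their per-unit
    deletion count to p_hat; longer reads contribute insertions to q_hat.
    Estimates are clamped to [0, 1] (reads with y > 2n can push the raw
    insertion sum past 1).
    """
    if dist.m == 0:
        raise ValueError("cannot estimate slippage with zero supporting reads")
    if n < 1:
        raise ValueError(f"reference repeat count must be >= 1, got {n}")
    del_sum = 0
    ins_sum = 0
    for y, count in dist.counts.items():
        if y <= n:
            del_sum += (n - y) * count
        else:
            ins_sum += (y - n) * count
    denom = n * dist.m
    p_hat = min(1.0, max(0.0, del_sum / denom))
    q_hat = min(1.0, max(0.0, ins_sum / denom))
    return SlippageEstimate(
        params=SlippageParams(p=p_hat, q=min(q_hat, 1.0 - p_hat)),
        m=dist.m,
        site_id=dist.site_id,
    )


def simulate_allele_distribution(
    n: int,
    params: SlippageParams,
    m: int,
    rng: np.random.Generator | int | None = None,
) -> AlleleLengthDistribution:
    """Draw m read lengths from the pmf renormalized over 0..2n."""
    if m < 1:
        raise ValueError("need at least one read to simulate")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = pmf_vector(n, params)
    total = probs.sum()
    if total <= 0.0:
        raise ValueError("degenerate pmf: zero total mass")
    draws = gen.choice(2 * n + 1, size=m, p=probs / total)
    return AlleleLengthDistribution(site_id="", counts=dict(sorted(Counter(draws.tolist()).items())))


def ks_fitness(
    observed: AlleleLengthDistribution,
    n: int,
    params: SlippageParams,
    m_sim: int | None = None,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov comparison of an observed read-length
    distribution against a fresh simulation from the model.

    Returns (statistic, p-value, fitted) where ``fitted`` is True when the
    test does not reject at ``alpha`` -- the data are consistent with the
    model.  The asymptotic p-value on tied integer data is conservative,
    which only makes the fitted call more lenient.  By default the
    simulated sample is size-matched to the observed one.
    """
    if observed.m < 1:
        raise ValueError("ks_fitness requires at least one observed read")
    if m_sim is None:
        m_sim = observed.m
    sim = simulate_allele_distribution(n, params, m_sim, rng)
    obs_vals = observed.expand()
    sim_vals = sim.expand()
    if len(set(obs_vals)) == 1 and obs_vals[0:1] == list(set(sim_vals)):
        return 0.0, 1.0, True
    stat, pval = stats.ks_2samp(obs_vals, sim_vals, method="asymp")
    return float(stat), float(pval), bool(pval >= alpha)


def truncated_mass(n: int, params: SlippageParams) -> float:
    """Closed form for the total minimal-path mass over 0..2n:
    (1-q)^n + (1-p)^n - (1-p-q)^n."""
    p, q = params.p, params.q
    return (1 - q) ** n + (1 - p) ** n - (1 - p - q) ** n


# ---------------------------------------------------------------------------
# estimates TSV: site identity columns + p, q, m

ESTIMATE_COLUMNS = ("chrom", "start", "motif", "n", "p", "q", "m")


def write_estimates(estimates, handle, sites_hash: str = "", extra_header: dict | None = None) -> None:
    """Write per-site (p, q, m) rows; ``estimates`` yields
    (MicrosatelliteSite, SlippageEstimate | None) pairs, None for
    uncovered sites ('.' fields)."""
    handle.write(f"# msical estimates sites_hash={sites_hash}\n")
    if extra_header:
        for key, val in extra_header.items():
            handle.write(f"# {key}={val}\n")
    handle.write("#" + "\t".join(ESTIMATE_COLUMNS) + "\n")
    for site, est in estimates:
        if est is None:
            handle.write(f"{site.chrom}\t{site.start + 1}\t{site.motif}\t{site.n}\t.\t.\t0\n")
        else:
            handle.write(
                f"{site.chrom}\t{site.start + 1}\t{site.motif}\t{site.n}\t"
                f"{est.p:.8g}\t{est.q:.8g}\t{est.m}\n"
            )


def read_estimates(handle) -> dict[str, SlippageEstimate]:
    """Read an estimates TSV into {site_id: SlippageEstimate}; uncovered
    sites (m = 0) are omitted."""
    out: dict[str, SlippageEstimate] = {}
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, start, motif, _n, p, q, m = line.split("\t")
        if p == "." or int(m) == 0:
            continue
        site_id = f"{chrom}:{int(start) - 1}:{motif}"
        out[site_id] = SlippageEstimate(
            params=SlippageParams(p=float(p), q=float(q)), m=int(m), site_id=site_id
        )
    return out


def grid_log_likelihood(
    dist: AlleleLengthDistribution, n: int, step: float = 0.005, max_pq: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized log-likelihood surface on a (p, q) lattice.

    Returns (p_grid, q_grid, loglik) with loglik = -inf where p + q > max_pq
    or any observed length has zero probability.  Used as an independent
    check that the closed-form estimator sits at the likelihood maximum.
    """
    vals = np.arange(0.0, max_pq + step / 2, step)
    P, Q = np.meshgrid(vals, vals, indexing="ij")
    R = 1.0 - P - Q
    valid = R >= -1e-12
    R = np.clip(R, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.log(P)
        logQ = np.log(Q)
        logR = np.log(R)
    ll = np.zeros_like(P)
    with np.errstate(invalid="ignore"):  # 0 * -inf at lattice edges
        for y, count in dist.counts.items():
            if y <= n:
                term = math.log(math.comb(n, n - y)) + y * logR + (n - y) * logP
            elif y <= 2 * n:
                term = math.log(math.comb(n, y - n)) + (2 * n - y) * logR + (y - n) * logQ
            else:
                ll[:] = -np.inf
                break
            ll = ll + count * np.where(np.isnan(term), -np.inf, term)
    ll = np.where(valid, ll, -np.inf)
    return P, Q, ll
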