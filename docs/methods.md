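# Methods

## The slippage model

Polymerase slippage at a tandem repeat is treated as an iterative,
independently accumulating process: replication of each of the *n*
reference repeat units is a three-outcome (multinoulli) draw — delete the
unit with probability *p*, insert an extra copy with probability *q*, copy
faithfully with probability 1 − p − q. The observed repeat length *y* of a
read is the sum of per-unit outcomes, so its distribution has a deletion
branch (y ≤ n) and an insertion branch (y > n), each a binomial-type
minimal-path term. Trajectories that reach the same *y* through extra
compensating steps (a deletion cancelled by an insertion, multi-step
paths) are ignored: their probability is of higher order in p and q and
has no closed form. In consequence the pmf over the support 0..2n sums to
(1−q)ⁿ + (1−p)ⁿ − (1−p−q)ⁿ, slightly below one when both p and q are
positive (0.9995 at n = 15, p = 0.05, q = 0.01). Assumptions worth
stating: slippage probabilities are uniform across units of a site,
strand-symmetric, and independent across reads and across sites; the model
is per-site, so motif composition enters only through the fitted (p, q).

Given the multiset Y = {y₁…y_m} of lengths from *m* spanning reads, the
likelihood of the minimal-path pmf is maximized in closed form by

  p̂ = Σ_{yᵢ≤n} (n − yᵢ)/(n·m),  q̂ = Σ_{yᵢ>n} (yᵢ − n)/(n·m),

i.e. the average per-unit deletion and insertion rates. One published
statement of the insertion-side sum indexes it "i = n+1..m", which is not
a well-formed read index; the implementation sums over reads with yᵢ > n,
the only reading consistent with the pmf's two branches (and the exact
stationary point of the likelihood — verified by grid search in the
tests). Estimates are clamped to [0, 1]; reads with y > 2n (impossible
under the model, possible in noisy data) still contribute to q̂ but carry
zero likelihood.

The simulator draws from the pmf renormalized over 0..2n so that draws
form a proper distribution; whether to renormalize is this package's
choice. Because the minimal-path estimator is applied to renormalized
draws it carries a small bias, E[p̂] = p(1−q)^{n−1}/Z with Z the truncated
mass — about −0.003 at (n=15, p=0.05, q=0.01) — which is well inside the
0.01 recovery tolerance the tests enforce and vanishes as p, q → 0.

Model fit at a site is assessed by a two-sample Kolmogorov–Smirnov test
between the observed lengths and a fresh, size-matched simulation at the
fitted parameters (asymptotic p-value). A site is *fitted* when the test
does not reject at α = 0.05. One published description words this as
sites with "no significant difference (P < 0.05)"; that phrasing is
self-contradictory and is implemented as fitted ⇔ P ≥ 0.05. On tied
integer data the asymptotic KS test is conservative, so the realized
false-rejection rate sits well below the nominal 5% (≈0.1–1% in the
acceptance runs).

## Site discovery and read-level measurement

The scanner reports every maximal run of ≥ 5 copies of a homopolymer or
≥ 3 copies of a primitive 2–5 bp motif (a delegated upstream scanner's
thresholds are not published; these mirror common MSI-panel practice and
are configurable). Runs are found as maximal intervals of the period-k
match predicate s[x] = s[x+k], which guarantees a unique leftmost start
and motif phase; N or ambiguity codes break runs; scanning is
case-insensitive. Nested repeats (a homopolymer inside a trinucleotide
run) are reported independently per motif length. On-disk site lists are
1-based inclusive; in memory everything is 0-based half-open.

How *y* is measured from a read is not published either, and is
re-specified here. A read supports a site when it is primary, MAPQ ≥ 20
(no base-quality filter), not duplicate/QC-fail, and aligns across the
tract plus ≥ `anchor` (default 5) bases of flank on both sides. By
default the tract is re-located in the read by exact match of the
reference flanks — indel placement inside a repeat is alignment-ambiguous,
so the CIGAR's opinion of where the tract starts is not trusted — and *y*
is the number of whole motif copies counted in phase from the left
anchor (partial copies truncate toward zero; a non-motif inserted base
stops the count; the right anchor must still be present downstream, else
the read is discarded). Because flank sequence can recur by chance next
to a repeat, the anchor occurrence nearest the alignment-implied position
is used, not the first or last. A pure-CIGAR path (query bases aligned
within the tract interval) is kept as a cross-check; the two paths agree
exactly on error-free reads.

## Baseline and calling

The per-site baseline over a panel of ≥ 2 normal samples retains a site
when coverage exceeds 20 reads in strictly more than half of the panel
(both inequalities strict, following the published wording), and computes
μᵢ, σᵢ of p̂ over exactly the coverage-passing samples — whether the
original procedure restricts to passing samples is unstated; restricting
is this package's choice, since a 5-read p̂ is mostly noise. σ uses the
population formula (divide by k; the panel is the reference population),
configurable via `ddof`. A tumor site with p̂ > μᵢ + 3σᵢ (strict) is
unstable; the MSI score is 100 × unstable/covered over baseline sites
with tumor coverage > 20. The binary MSI/MSS label uses a 10% score
cutoff — a package convenience, flagged in every output, not a published
value: the method itself is evaluated by ranking scores (AUC). Baseline
files embed a content hash of the site list and calling refuses a
baseline whose hash differs from the estimates', preventing cross-panel
misuse.

Discriminative microsatellite (DMS) selection scores each site by the
rank-based AUC (normalized Mann–Whitney U, ties half) of p̂ between
labeled MSI and MSS samples, over samples covered at the site, and keeps
sites with AUC strictly above the threshold. The published threshold is
0.65 in one place and 0.75 in another; 0.65 is the default and both are
one flag away. The selector operates on an explicit discovery split to
avoid evaluating on the samples that chose the panel.

## Synthetic cohorts

The generator plants maximal repeats (motif mix 50/25/15/7/3% for lengths
1–5, repeat counts 8–20 for homopolymers down to 3–5 for pentamers) in
random sequence, separated by ≥ 20 bp spacers that are rejection-sampled
until a scan of the local window recovers exactly the planted site — so
scanner ground truth is exact by construction. Base deletion probability
p interpolates over [0.001, 0.05] with repeat count (longer repeats slip
more, matching the flattening of observed length distributions) with
±20% jitter; q = p/5. Default study design: 500 sites, 20 normals, 20 MSI
and 20 MSS tumors, Poisson 50× spanning coverage, MSI tumors with p
elevated ×5 at 30% of sites (clamped to p + q ≤ 0.9), purity 1.0. Purity
π mixes tumor- and base-parameter reads binomially per site; depth
scaling thins the Poisson mean. Reads are error-free with exact flanks
and correct CIGARs (length changes as one I/D at the tract), written as
coordinate-sorted indexed BAM, or the per-site length distributions are
emitted directly for fast model-level work.

What the generator does **not** emulate: sequencing error, mapping
ambiguity and soft-clipping, PCR stutter (which in real data adds
non-slippage length noise that inflates baseline σ), GC/coverage bias,
motif-specific slippage chemistry, and subclonal heterogeneity. Passing
tests therefore demonstrate correctness of the algorithms and the
statistical behaviour of the pipeline under the model's own assumptions,
not calling accuracy on real tumors.

## Numerical and design choices

- pmf terms use exact integer binomial coefficients with float powers;
  accurate and overflow-free for the n ≤ ~50 range of panel repeats. The
  likelihood grid search (tests) works in log space on a 0.005 lattice.
- Degenerate inputs: m = 0 sites are emitted but never estimated
  (callers treat them as uncovered); a KS comparison of two identical
  one-point samples returns statistic 0, fitted.
- DMS ranking breaks AUC ties by site id for determinism.
- Every simulation accepts a `numpy` Generator or integer seed; equal
  seeds give byte-identical outputs.
- Problem sizes in the test and acceptance runs (500-site default cohort,
  60-site/100× end-to-end BAM runs, 1000-site KS sweeps, 100-replicate
  recovery) were chosen so the whole suite completes in well under a
  minute while keeping Monte-Carlo noise far from the asserted margins.
- Depth-sweep evaluations score every covered site (minimum-coverage 0)
  uniformly across depths; at 5× mean coverage the default >20-read
  detection rule would leave no site detected and the score undefined.

## Known limitations

- The minimal-path pmf under-weights long repeats with both p and q
  large; the ignored multi-step mass grows with n·p·q.
- The closed-form estimator's small renormalization bias (above) is not
  corrected; an exact MLE under the renormalized pmf is out of scope.
- Tumor purity is not modelled in calling (only in simulation); low
  purity dilutes p̂ toward the baseline and lowers sensitivity, as the
  purity-sweep tests quantify.
- Interrupted/compound repeats and motifs > 5 bp are not scanned.
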