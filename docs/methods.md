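# Methods

## Count model

Pool *j*'s read count in window *w* is modelled as negative binomial with
mean μ_wj = μ_w·s_j and variance μ + φμ², where μ_w is the window's expected
coverage, s_j a pool-specific size factor, and φ a single *common
dispersion* shared by all windows. A common φ (rather than per-window or
trended dispersion) is the deliberate choice for pooled designs with three
replicates per group: per-window estimates at n = 3 are too noisy to
moderate sensibly, and the downstream caller consumes one p-value per window
with no moderation stage.

### Normalization

Columns are scaled proportionally to the mean library size and rounded
half-to-even, keeping counts integer so the exact test stays valid. This is
a deliberate simplification of count-model normalization (no TMM or quantile
adjustment): it is fully specified, exactly invertible in expectation, and
under the simulation's log-uniform size factors (0.7–1.4) it equalizes
library sizes to within rounding. Columns with library size 0 are left
untouched. The rounding perturbs each count by at most 0.5, negligible
against Poisson noise at the depths of interest.

### Common-dispersion estimation

φ maximizes the summed within-group conditional log-likelihood: for a group
of n pools with window counts y₁…y_n and total T, the conditional
probability of the split given T depends only on φ (the NB success
probability cancels), giving per window

  ℓ(φ) = Σᵢ log Γ(yᵢ + r) − n log Γ(r) − log Γ(T + nr) + log Γ(nr),  r = 1/φ

up to φ-free terms. The sum over windows and groups is maximized on a
41-point log grid spanning [10⁻⁶, 5], refined by bounded scalar minimization
between the best grid point's neighbours. All-zero windows carry no signal
and are excluded; groups with a single pool have a degenerate conditional
likelihood and are skipped. Poisson data drive the estimate to the grid
floor (≈10⁻⁶ ≙ 0); simulated φ = 0.5 at 10⁴ windows is recovered within
±0.01 in practice (±0.1 asserted).

### Exact conditional test

With equalized library sizes, group totals satisfy Y_A ~ NB(size n_A/φ) and
Y_B ~ NB(size n_B/φ) with a common success probability, so conditional on
s = Y_A + Y_B the split follows a negative hypergeometric that is free of
the unknown mean — Binomial(s, n_A/(n_A+n_B)) in the φ→0 limit. The
two-sided p-value uses the *minimum-likelihood* rule (sum of probabilities
of all splits no more likely than the observed one) rather than tail
doubling: it is well defined for unequal group sizes and matches classic
exact-test practice. p = 1 when s = 0.

Numerics: the conditional log-weights are accumulated as
Σ_k log((r+k)/(k+1)) via cumulative sums rather than gammaln differences.
The two forms are algebraically identical, but at the very large sizes r
produced by small φ the gammaln form loses ~10⁻⁶ of relative precision,
enough to break the exact probability ties (y ↔ s−y for equal group sizes)
that the minimum-likelihood rule must group; the cumulative form keeps those
ties bit-exact and is accurate to ~10⁻¹² at s ≤ 200. Ties are grouped with
relative tolerance 10⁻¹², and the tail mass is normalized by the summed pmf
so the modal split yields exactly p = 1. Per-window p-values are cached by
window total, so a 10⁵-window track costs only as many pmf evaluations as
there are distinct totals. The implementation agrees with brute-force
enumeration to < 10⁻⁹ (measured ~4·10⁻¹⁵) for all splits at s ≤ 200 and
with edgeR's `exactTest(rejection.region="smallp")` to 10⁻⁹ at equal
library sizes.

The log₂ fold change is log₂((Y_B/n_B + ½)/(Y_A/n_A + ½)); the half
pseudo-count avoids division by zero and shrinks extreme ratios at tiny
counts.

## DMR calling

Windows with p < 10⁻³ are core windows; maximal runs of adjacent cores seed
DMRs. Edges extend while any window with p < 0.1 lies within 1000 bp of the
span, measured edge-to-edge and *boundary-inclusive* (gap = 1000 extends;
1100 does not). Extension iterates to a fixed point so chains of qualifying
windows are absorbed, and spans that come to touch or overlap merge (core
windows pooled). Classification uses the *longest run of adjacent* core
windows, not the total core count: a merged DMR holding two isolated cores
is still single-window class. Both the boundary convention and merging are
config-exposed (`extend_gap`, `merge_touching`) since either reading of
"within 1000 bp" is defensible; extension never crosses a chromosome
boundary. Note that the DMR count is not monotone in the core threshold
(loosening it can both create new DMRs and merge old ones); what is
invariant, and property-tested, is that every DMR called at a stricter
threshold lies inside one called at a looser threshold.

## Cluster scan

A cluster_window (2 Mb) slides at cluster_step (50 kb) along each
chromosome; the DMR midpoints inside are counted and tested against
λ = (total DMRs / total genome length) × cluster_window with the exact
Poisson upper tail. λ is genome-wide because per-chromosome rates are
unstable at realistic DMR counts. A raw per-window α would be an
uncorrected scan over thousands of correlated positions — with 20 DMRs
scattered uniformly over 100 Mb it flags a spurious cluster in about two
thirds of replicates — so the p-value is Bonferroni-corrected, by default
over the number of scanned positions genome-wide. This is conservative
(overlapping windows are strongly correlated), which suits the screening
role: measured specificity is 0/200 spurious clusters under uniform
placement, while a planted 5-DMR cluster within 100 kb on an otherwise
empty 100 Mb genome is still detected at adjusted p ≈ 1.5·10⁻⁴. The
correction is config-exposed ("positions", "windows", "none"). Windows
truncated at chromosome ends keep the full-window λ (conservative there).
Merged significant windows form a cluster if they hold ≥ 3 member DMRs; the
reported span is trimmed to the first-to-last member extent. The "3–10 DMRs
spanning 2–7 Mb" phrasing of such analyses is treated as a description of
typical results, not a filter; only the ≥ 3 floor is enforced.

## Annotation

CpG density is CG-dinucleotide count × 100 / span length over the *extended*
DMR span; density classes are floor(density) with everything below 1 in
class 0 (the CpG-desert class). A CG pair straddling the span edge is not
counted. Gene association adds a symmetric flank (default 10 kb) to the DMR
and lists every gene whose body overlaps the flanked interval by ≥ 1 bp;
strand is ignored because the flank is symmetric. Associations are monotone
in the flank (property-tested).

## Validation utilities

Set overlap counts a DMR as shared if it overlaps ≥ 1 bp (configurable) of
any DMR in the other set; both sides' shared counts are reported since
overlaps need not be 1:1. Within-population validation runs every unordered
1-vs-1 pool pair inside a group with the same configuration and the
between-group dispersion estimate (a 1-vs-1 comparison cannot estimate its
own), then intersects each pair's DMRs with the between-group set; on
simulations with a strong planted between-group effect and exchangeable
pools within groups, ≤ 10% of between-group multiple-window DMRs reappear in
any within-group pair. The chi-square test is Pearson's on the category
table (no continuity correction, df = (r−1)(c−1)); Bonferroni is min(1, mp);
power uses the noncentral t with δ = d/√(1/n₁+1/n₂) and df = n₁+n₂−2. The
power convention is one-sided at α = 0.05 — the sidedness of the original
morphology power analysis is not documented, and this convention reproduces
its printed range (0.69–0.91 at d = 0.256/0.358, n = 171/121), so it is the
default and flagged here as inferred.

## Synthetic data

The generator emulates the pooled two-group design: 2 groups × 3 pools
(5 individuals per pool, metadata only), NB window counts with common
dispersion, pool size factors log-uniform in [0.7, 1.4] (so normalization
has real work), and a CpG-density-dependent baseline
μ_w = depth × cpg_effect^density_w. Defaults: depth 100 reads/window — a
multi-window DMR with extension then spans a few hundred to > 1000 reads,
the coverage regime such studies report; φ = 0.3 (between-pool CV ≈ 55%, a
deliberately noisy setting for pooled biological replicates); cpg_effect
1.2 per CpG/100 bp unit (modest MeDIP enrichment growth with CpG density).
Planted DMRs multiply group-B means by 2^lfc over 1–5 aligned core windows;
cluster directives place 3–10 such DMRs evenly over a span. Genomes are
random sequence with all CG dinucleotides broken, then exact numbers of CG
pairs planted at non-adjacent positions — background density defaults to
1 CpG/100 bp with optional dense segments, so CpG-desert and CpG-dense
density classes are both populated. An optional reads mode emits BED reads
whose midpoints land in the generating window (count with extension 0 to
recover the matrix exactly).

What the generator does *not* model: antibody-enrichment chemistry,
fragment-size distributions beyond the fixed extension, sequencing error,
mappability or GC bias, and spatial correlation of methylation outside the
planted regions. Passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to real-data artifacts.

## Measured operating characteristics

At the default study conditions (10⁵-window null, φ = 0.3, depth 100, 3v3),
the pipeline's fraction of windows at p < 10⁻³ is ≈ 1·10⁻³ (the exact test
is slightly conservative) and false multiple-window DMR calls are ≈ 0–1 per
10⁵ windows. Sensitivity for planted 2–5-window DMRs at 8-fold change and
depth 100 is ≈ 77–82%, not higher: with φ = 0.3 the group-total log-scale
sd is ≈ √(2φ/3) ≈ 0.45, an 8-fold change is a ≈ 4.7σ effect, and per-window
power at the 10⁻³ threshold caps near 0.9 even at unbounded depth, so
two-window cores cap near 0.8. Recovery exceeds 95% at 16-fold changes or
at φ ≤ 0.15; detecting subtler changes at φ = 0.3 requires more pools, not
more depth. These figures are recomputed, not assumed, by
`scripts/acceptance.py` and the test suite at the problem sizes stated
there (10⁴–10⁵ windows, 20 scan replicates), chosen so the full suite runs
in well under a minute of simulation time.

## Known limitations

- No CpG-coupling normalization of MeDIP enrichment (the coverage→
  methylation mapping is left implicit, as in threshold-based window
  pipelines); CpG density enters only as annotation and as a simulation
  knob.
- Raw p-value thresholds throughout; no FDR control. The multiple-window
  requirement and within-population validation stand in for it.
- Midpoint counting assigns each read to exactly one window; reads near
  window boundaries are not split.
- The cluster statistic assumes uniformly placed DMRs under the null;
  nonuniform window eligibility (assembly gaps, unmappable regions) would
  inflate λ locally.
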