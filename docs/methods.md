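# Methods

This note documents the models and procedures implemented in
`threedfunc`, the assumptions behind them, the parameters that matter,
and the design choices made where the underlying method left the design
open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open `[start, end)`.
Converters sit at every I/O boundary: BED/BEDPE pass through unchanged,
VCF and 1-based TSV positions are shifted on read and back on write.
Chromosome names are never munged (no implicit `chr` prefixing); stores,
tracks and variant files must agree on naming. Gene symbols are compared
exactly after uppercasing, with no alias expansion — symbol
reconciliation across source databases is out of scope, so fusion-pair
merging may undercount pairs recorded under diverged aliases.

## Contact store and rectangle queries

The store keeps one sparse symmetric matrix per resolution per
chromosome pair. A rectangle query `query_if(A, B, W)` **sums** the
normalized contact values over all bin pairs at resolution `W` whose
bins intersect regions A and B. Sum (rather than mean) was chosen as the
aggregate because it makes the flexible IF a containment ratio bounded
by [0, 1]; a mean variant is available behind `agg="mean"` for users who
want rectangle-size-independent signal. Bins that merely touch a region
boundary count fully — the simplest rule that keeps queries additive
over bin-aligned partitions; fractional weighting was rejected because
it breaks the clean containment-bound argument and adds a parameter
(the weighting kernel) the data cannot identify.

Matrices are assumed balanced upstream (e.g. ICE); no normalization is
implemented. Virtual-4C profiles are row sums over the viewpoint's bins,
self-bin included, so `sum(profile) == query_if(viewpoint, whole
chromosome)` holds as an identity.

## Flexible IF

Each candidate region selects the available resolution nearest to its
own length. "Nearest" compares against the region length; ties break
toward the smaller resolution to preserve detail (a tie can occur, e.g.
length 3000 against {1000, 5000}). The window is the finer of the two
chosen resolutions. The extension coefficient is
`α = max(R_a, R_b)/min(R_a, R_b)`, defined as 1 when the resolutions are
equal (the two-branch ratio definition omits this case; 1 is its
continuous limit).

Both background regions are extended symmetrically by `R·α` per side and
clamped to the chromosome. Clamping can shrink the background but never
the core, so `0 ≤ flexible_IF ≤ 1` always holds in the default mode. A
published variant of the formula *shifts* the b-side end point left by
`R_b·α` instead of extending it; we read that as a typographical sign
slip, because it breaks the symmetry of the a-side and can produce a
background that excludes the core. The
`strict_asymmetric_extension` flag reproduces that variant exactly for
comparison; in that mode the [0, 1] bound is not guaranteed and an empty
background raises an error.

A core rectangle with zero signal yields flexible IF 0 by convention,
including the 0/0 case: loci with no measured contacts score as "no
interaction" rather than undefined.

## Layer disruption rules

**SV curation.** Length within 10 kb–10 Mb inclusive AND population
frequency strictly greater than 1%. Both bounds of the length window are
inclusive (the stated range "10k to 10 M" names its endpoints); the
frequency rule is strict ("larger than 1%").

**Compartments.** The left breakpoint is `start`, the right is
`end − 1`: under half-open coordinates an SV ending exactly at a
compartment transition belongs to the interval on its left. The ordered
label pair gives A–A/A–B/B–A/B–B; a breakpoint in a track gap gives
`unmapped`. Distances to the nearest compartment transition are reported
with each call. A–A and B–B are *stable*, A–B and B–A *switching*; the
dosage-sensitive gene count uses the (SV, gene) overlap pair as its
counting unit, so one gene hit by two SVs counts twice.

**TADs.** Breakpoints are assigned to insulation domains or boundary
intervals. intra-TAD: same domain. inter-TAD1: one boundary, one
domain. inter-TAD2: both in boundary intervals — read as *any* boundary
intervals, not necessarily the same one, since that is the only reading
that generalizes. inter-TAD3: two different domains. SVs longer than 50%
of the local TAD are excluded so large events do not skew within-domain
statistics; "local" is the domain containing the left breakpoint, the
mean of the two domains for inter-TAD3, the single involved domain for
inter-TAD1, and no exclusion applies to inter-TAD2 (no containing domain
exists). The raw category is retained next to the `excluded` flag.

**Territories.** Exact-duplicate ICT records (same breakpoints and gene
symbols) are removed before counting; gene pairs are unordered; a pair
is recurrent when its deduplicated count is strictly greater than 10.
Fusion pairs are bucketed by mean per-cell-line flexible IF into
`none` (exactly 0), `weak` (below `t_strong`) and `strong`
(at/above). The strong/weak boundary is not derivable from the method
description, so it is a required configuration parameter; the default
`t_strong = 0.5` sits halfway along the flexible-IF scale and should be
calibrated per store by users who care about the split.

**Loops.** A SNP is extended 1000 bp on both sides (clamped at 0) and
paired with every gene reachable through a loop with one anchor on the
extended locus and the other on the gene body, either orientation. A
loop is a cancer-specific loop (CSL) when every tissue's cancer-SNP set
hits an anchor, a normal-specific loop (NSL) when none does, otherwise
an overlap loop (OL) — the per-tissue SNP-set reading; these three are
exclusive and exhaustive by construction. Loop typing checks
enhancer–promoter anchors first (E–P loops are rarer and more
informative, so they take priority), then CTCF peaks on either anchor,
else `other`. E–P identification is an explicit interval-overlap rule
against supplied enhancer and promoter tracks — a deliberate,
documented substitution for model-based loop classification, which is
out of scope here.

**SNP coding annotation.** Coding ⇔ the position lies in a CDS interval
or within 10 bp (inclusive) of a splice-site coordinate.

## Expression change

EC is the lower-tail CDF of the Welch statistic with sample standard
deviations (ddof = 1) and Welch–Satterthwaite degrees of freedom; the
statistic's printed form gives the standard error but not the df, and
Welch–Satterthwaite is the standard companion for unequal group sizes
(the reference design is 20 cancer vs 15 normal cell lines). Degenerate
cases: both variances zero returns 1.0/0.0/0.5 by the sign of the mean
difference; fewer than two samples per group is an error. The
implementation is vectorized over genes and is checked in tests against
an independent reference (`scipy.stats.ttest_ind(..., equal_var=False,
alternative="less")`) to 1e-10.

FPKM is `counts·10⁹ / (length · library size)`. The upper-quartile
variant replaces the library size with the per-sample 75th percentile of
nonzero gene counts times 10³; the extra factor keeps the two variants
on a comparable scale, since an upper-quartile count is typically about
three orders of magnitude below a library size.

## Two-phase scoring

`IC = |C_i − N_i|` with both flexible IFs required non-negative. The
per-cell-line decay `EC = A·e^(−IC/τ)` is fitted with a bounded
trust-region least-squares solver using the analytic Jacobian, over
`A ∈ (0, 1.5]` and `τ ∈ (0, 100·max(IC)]`. The τ cap keeps the flat-EC
degenerate case finite: constant EC drives τ to the cap and the fit is
flagged non-converged rather than diverging. Default initialisation
`A₀ = max(EC)`, `τ₀ = mean(IC)`. `residual_sd = sqrt(RSS/(n−2))` (two
fitted parameters). At least 3 pairs with at least 2 distinct IC values
are required — otherwise the decay constant is unidentifiable.

The score is the **absolute** residual `|expected − observed|`; the
method description says only "difference", and the absolute value
sidesteps the sign ambiguity while the signed residual is retained in
every output so users can distinguish over- from under-expression
relative to the 3D expectation. Significance: `z = signed_residual /
residual_sd`, `p = P(χ²₁ > z²)` — the chi-square construction is our
interpretation of an otherwise unspecified test, and is documented as
such. Reference thresholds are exposed as configuration: high-confidence
`score ≥ 0.9, p < 0.05`; network-filter `score > 0.5, p < 0.05`.

Ranking: descending score, ties broken by stable input order; the top
decile is `rank ≤ ceil(0.10·n)`. Ranking quality is reported as the
causal fraction of the top decile plus AUROC and AUPRC
(scikit-learn's rank statistic and step-integrated precision–recall).

## Synthetic data: what it emulates, and what it does not

The generators produce three ~2 Mb chromosomes at 5/25/100-kb
resolutions with: power-law distance decay (exponent −1, the canonical
interphase scaling), a 250-kb A/B checkerboard with a 2× same-phase
factor, 20 domains of 95 kb per chromosome separated by 5-kb boundaries
with a 3× within-domain factor, planted loop peaks (+30 on the anchor
bin pair), sparse inter-chromosomal background (density 0.05, level
0.2), and an elevated block (+5) between one designated fusion gene
pair. Strengths were chosen so classifier truth is unambiguous at toy
scale. Expression is log-normal with per-gene log-means drawn from
U(1, 4) and log-SD 0.25 — small enough that the two-group Welch CDF is
uniform under the null at n = 2000 genes, which the calibration test
verifies — across 20 cancer and 15 normal samples; planted differential
genes shift the cancer log-mean by ±2. Variant–gene pairs draw
IC ~ U(0, 2) with EC on the decay curve (A = 0.9, τ = 0.5) plus
N(0, 0.02) noise; 5% of pairs are displaced by ±0.4 (direction chosen
toward the side with room in (0, 1)) and labelled causal.

Every generator is a pure function of the configuration including its
seed: identical configs give byte-identical fixture trees.

What passing on these fixtures does **not** show: real Hi-C matrices
have sequencing noise, coverage biases and unbalanced bins that the
generator omits; real compartments and TADs are not clean tilings; real
expression has batch structure, count noise at low abundance and
heavier tails; and curated variant databases carry ascertainment biases
no simulation reproduces. Results at desk scale validate the machinery,
not the biology — quantities that depend on external curated databases
(genome-wide variant counts, database-level category percentages,
benchmark AUROC values) are inputs-dependent and are not reproduced
here.

## Numerical and scale choices

* Problem sizes throughout (three 2-Mb chromosomes, 60 domains, 200
  variant–gene pairs per cell line, 2000 genes for calibration, 20
  replicate seeds for recovery statistics) are the package's default
  study conditions; they keep the full suite and the acceptance script
  fast while leaving every statistic comfortably powered.
* The null-ranking AUROC is reported as the mean over 20 replicate
  seeds: a single draw with 10 positives among 200 has an AUROC
  standard deviation near 0.09, so only the replicate mean is a
  meaningful calibration check.
* Oracle comparisons use 1e-9 absolute tolerance (sums of ~tens of
  values of magnitude ~1); Welch-CDF cross-checks use 1e-10.
* Duplicate coordinates in a COO file are summed (standard COO
  semantics); intra-chromosomal entries are stored once per unordered
  pair and mirrored on load.
* TSV/JSON outputs carry the tool version and a 12-hex config hash; no
  timestamps are written anywhere, so rerunning a stage is
  byte-reproducible.

## Known limitations

* Adapters for community binary Hi-C formats (`.hic`, `.cool`) are not
  included; the native text COO store is the interchange format.
* `merge_fusion_pairs` trusts gene symbols as given (uppercased); no
  alias tables.
* The chi-square significance model assumes homoscedastic residuals
  along the curve; heavy heteroscedasticity (e.g. EC variance shrinking
  near 0/1) would miscalibrate p-values.
* `count_dosage_sensitive` counts overlap pairs, not unique genes; both
  conventions are defensible and the choice is documented at the API.
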