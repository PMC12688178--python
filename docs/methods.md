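# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## Harmonization

Public expression matrices arrive in mixed states, so each cohort is
inspected and corrected only where needed. A matrix is called linear-scale
iff its 99th percentile exceeds a cutoff (default 30, configurable): log2
microarray/RNA-seq values rarely exceed ~25 while linear intensities reach
the thousands. Linear matrices are background-shifted so their minimum is at
least a floor (default 0), then log2(x + 1)-transformed. Quantile
normalization forces every sample onto the mean order-statistic
distribution; tied values within a sample receive the mean reference value
over their rank span (deterministic). The chain is idempotent and never
changes dimensions or identifiers. Probe-to-gene collapsing and
cross-cohort batch correction are out of scope — every screen statistic is
computed within one cohort.

## Moderated differential expression

Each contrast is a two-group means model per gene. With pooled within-group
variance s²_g on df = n_a + n_b − 2 degrees of freedom, the hierarchical
model s²|σ² ~ σ²χ²_df/df, 1/σ² ~ χ²_d0/(d0·s0²) implies
log s² = log s0² + log(χ²_df/df) − log(χ²_d0/d0), so the prior is estimated
by moment matching on e_g = log s²_g − ψ(df/2) + log(df/2): the excess of
Var(e) over ψ′(df/2) identifies ψ′(d0/2) (inverted by monotone
root-finding, tolerance 1e−12), and s0² follows from the mean. When the
dispersion shows no excess the variances are treated as exchangeable:
d0 = ∞ and every gene receives the geometric mean of the observed s² (so
identical input variances come back unchanged). Genes with s² = 0 are
shrunk like any other — they get d0·s0²/(d0+df) — but are excluded from
hyperparameter fitting. The moderated t uses df + d0 total degrees of
freedom (normal when infinite). This estimator is cross-checked in the test
suite against Bioconductor limma on a shared matrix. No trend/robust
variants, array weights, or count models: the screen's contrasts run on
already-normalized log2 matrices.

## Prognostic screening

The endpoint is biochemical recurrence. Samples are split at the empirical
quartiles by stable rank order; the screen's convention names **Q1 the
highest** expression quarter and Q4 the lowest, and codes Q1 = 1 vs Q4 = 0
so that HR > 1 always reads "high expression, faster recurrence". The Cox
partial likelihood uses the Efron tie correction by default (recurrence
times tie at the 0.1-month resolution the generator emulates; Breslow is
available by flag) and is maximized by Newton–Raphson with step-halving
(tolerance 1e−8 on the step, 50 iterations, covariates centered for
conditioning). Monotone likelihood (separation) is detected by a coefficient
cap (|β| > 15) and flagged `converged = False` rather than raised; the
screen counts non-converged fits as non-significant. The per-gene test is a
likelihood-ratio χ²₁ against the null partial likelihood.

Smooth log-HR curves use a natural cubic spline basis (linear beyond
boundary knots at the 5th/95th percentiles; df − 1 interior knots at
equally spaced quantiles in between; df = 1 is the linear fit). Candidate
df ∈ {1,2,3,4} are compared by AIC = −2·loglik + 2·df; non-converged
candidates are excluded; ties go to the smaller df; the curve is anchored
to 0 at mean expression. A known property of this textbook-AIC selector is
its fixed ~24% probability of preferring df > 1 under a truly linear
hazard (the spurious loglik gains follow their nominal χ² laws, and
P(χ²_k < 2k jointly for k = 1,2,3) ≈ 0.76); this is the selector the
procedure specifies, so the package documents rather than "fixes" it.

## The screen

All stringency knobs live in one config. Defaults: two-sided moderated-t
p < 0.05 per cohort for DE (raw p, switchable to FDR), significance required
in **all** cohorts per arm with global sign concordance, initiation
exclusion only for genes concordantly significant in PT-vs-N in **all**
cohorts (the strict reading of "consistently altered"), hazard direction
required to match fold-change direction, epithelial percent-expressing
≥ 10% **and** at least every stromal compartment's percent (compartment
specificity, switchable off). Relaxing a cut-off never shrinks the list it
gates; the shared DE p-cut feeds both the metastasis and the
initiation-exclusion arms, so joint monotonicity holds when both are
relaxed together. The screen is a pure function of its input tables:
identical inputs give identical results regardless of gene order.

## Enrichment

Mean-split assigns boundary samples (= mean) to "high". The ranking metric
is signal-to-noise (mean difference over the sum of per-group SDs, each SD
floored at max(0.2·|mean|, 0.2)), with deterministic lexicographic
tie-breaks; groups under 3 samples fall back to the mean-difference metric.
The ES walk weights hits by |score|^p (p = 1 default; p = 0 kept for
closed-form checks) normalized over hits, and misses by 1/(N − |S|). The
null is phenotype permutation (exhaustive when fewer distinct label
assignments exist than requested); NES divides the ES by the mean |permuted
ES| of matching sign, the permutation p is the same-sign exceedance
fraction, and q follows the sign-stratified NES-comparison convention.
Signature activity is the unweighted mean of gene-wise z-scores (constant
genes dropped) — the minimal convention, declared here because the scoring
scheme behind published signature plots is typically unstated. Spearman
correlation uses average ranks and the t-approximation.

## Synthetic study conditions

The generator emulates a five-cohort meta-analysis at desk scale: 2000
genes (the screens it emulates run ~22k; size was scaled so the full study
re-runs in seconds-to-minutes) over cohorts of (N, PT, M) =
(29, 131, 19), (52, 200, 25), (20, 92, 25), (18, 112, 23), (28, 59, 35) —
sizes in the range of the public prostate cohorts such analyses draw on —
with follow-up in the first four and two cohorts exported on a linear scale
to exercise harmonization.

Planted classes (fractions of genes): prognostic_up 0.5%, prognostic_down
0.4%, met_up 1%, met_down 0.8%, initiation 1%; a quarter of the met genes
also carry hazard — those 5 up + 4 down genes are the truth the full screen
must recover. Expression is Normal(μ_g + effects, σ²_g) in log2 units with
μ_g ~ U(4, 12) and σ²_g from a scaled-inverse-χ²(d0 = 4, s0² = 0.25) prior,
giving the EB step true hyperparameters to recover. Metastasis genes shift
M samples by ±1.5 log2 units; initiation genes shift PT by 1.5 and M by
2.25 (progressive), so they pass the M-vs-PT filter and must be removed by
the initiation-exclusion arm rather than trivially absent from it.

Survival uses an exponential proportional-hazards model: for PT samples of
follow-up cohorts, hazard = λ₀·exp(Σ_g β_g z_g) over the hazard-carrying
genes, λ₀ set so the median time at η = 0 is half the 120-month horizon.
Censoring is uniform on [0, horizon] for half the samples (administrative
at the horizon otherwise) and times are rounded to 0.1 months so ties occur
as in real recurrence data. Hazard genes co-load (loading 0.85, sign by
class) on one latent "aggressiveness" factor, each contributing a small
per-gene coefficient (|β_g| = 0.045): with ~27 hazard genes the composite
risk score has SD ≈ 1 (per-SD HR ≈ e), and each gene — being a good
marginal readout of the program — shows a Q1-vs-Q4 HR of roughly 3–7, the
strong-candidate regime these screens target. This co-expression geometry
is deliberate: with *independent* per-gene hazards, any per-gene effect
large enough to detect marginally would, summed over tens of genes, give
the composite predictor an unrealistic variance whose frailty then swamps
every marginal effect; correlated prognostic programs are also what real
tumors show. A second latent factor carries the androgen-receptor program:
31 signature genes load +0.75 on it and one metastasis-and-prognosis gene
(the TCF19-like candidate) loads −0.6 (with aggressiveness loading 0.7),
reproducing the inverse gene-vs-signature correlation. Two of the
metastasis-and-prognosis up genes (including that candidate) are marked
epithelial; the compartment table draws their epithelial percent-expressing
from U(40, 90) and concentrates every other gene in a random stromal
compartment (percent U(0, 8) elsewhere).

All randomness derives from one master seed via fixed spawn-key offsets
(truth = 1, cohort c = (2, c), compartments = 3, permutations = 4), so
every artifact is bitwise reproducible and cohorts are independent given
the seed.

**What the generator does not emulate** — probe-level artifacts, platform
batch effects, count noise, dependence between censoring and risk,
non-proportional hazards, and realistic correlation among null genes.
Passing tests therefore demonstrate that the decision logic and estimators
are correct and calibrated under a faithful proportional-hazards/Normal
world, not that the screen's stringency choices are optimal for any real
cohort; the screen's numeric funnel on real data (hundreds of prognostic
genes, dozens of metastasis genes) depends on cohorts this package does not
ship and is deliberately not asserted.

## Degenerate inputs and tie-breaks (summary)

Constant expression vectors: quartile stratification, mean split and
Spearman raise; scale detection warns and assumes log2. Quartile and
ranking ties break by stable sample order / lexicographic gene id. A gene
set covering the whole ranked universe is rejected (misses undefined); hit
weights that are all zero fall back to equal steps. Genes missing from a
cohort's table count as non-significant in voting and are logged. LRT
statistics below −1e−8 raise; small negative rounding is clamped to 0.
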