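# Methods

## Data model

A corpus is a question schema plus participant records. Each of the Q = 13
questions has a closed answer vocabulary; the shipped default schema uses
the published per-question vocabulary sizes (39, 15, 3, 14, 3, 21, 3, 3, 3,
6, 23, 64, 5; concatenated size 202) with placeholder token names, since the
real vocabularies are not public. Answers are stored as (token, count)
multisets: the model is exchangeable over observations within a participant,
so token order and timestamps carry no information; timestamps survive only
as a per-participant count of distinct tracking days. Participants with zero
observations are retained in corpora but excluded (and logged) by modelling
operations — they carry no likelihood.

The per-question day columns of the summary table attribute a participant's
global `days_tracked` to every question that participant answered at least
once. True per-question day counts are not representable once answers are
aggregated to multisets; this proxy keeps the summary's totals consistent
under independent recounting and is the only place the limitation shows.

## Generative model and inference

Participant proportions θ_d ~ Dir(α·1_K); per phenotype and question,
answer distributions φ_k^q ~ Dir(β·1_{V_q}); each token draws z ~ Cat(θ_d),
w ~ Cat(φ_z^q). Collapsing θ and φ gives the token-label conditional
P(z=k|rest) ∝ (c_dk+α)(c_kqv+β)/(c_kq+V_q β); the concatenated-vocabulary
baseline (vanilla LDA) is the identical sampler run on the single-question
view, where the smoothing denominator uses Σ_q V_q. On single-question
corpora the two models coincide exactly, which the tests assert.

Sampling is systematic-scan collapsed Gibbs with a fixed token visit order
(participant, then question schema order, then vocabulary order) so runs are
bit-reproducible given a seed; each sweep's inner loop draws its RNG stream
from a seed generated by the state's seeded generator. Estimates of φ and θ
are Rao-Blackwellized count ratios averaged over post-burn-in sweeps at a
thinning interval (defaults n_iter = 2000, burn_in = 1000, thin = 10; the
tests and analysis drivers use shorter chains — 100–600 sweeps — which on
the well-separated synthetic cohorts reach the same fixed points, as the
recovery tests show). Ties in any argmax break to the lowest index.

The sampler's correctness is established two ways: exact count-conservation
oracles (recounting z reproduces all sufficient-count tables after any
sweep), and distributional exactness on enumerable instances — on corpora
of ≤ 8 tokens the empirical distribution of the full label vector over
50,000 sweeps matches the brute-force collapsed posterior within total
variation 0.02.

## Held-out likelihood

Exact scoring marginalizes θ analytically per label vector (a
Dirichlet-multinomial weight times emission terms) and sums over all K^N
assignments; it is the oracle for documents up to ~10 tokens. The workhorse
is a left-to-right sequential particle estimator extended to per-question
vocabularies: tokens are laid out in a fixed order; at each position every
particle rejuvenates the earlier labels with one Gibbs pass given Φ,
records the predictive probability of the current token under its own
question's φ (θ-counts shared across questions within the document), and
extends itself by sampling the new label.

Particle aggregation is the proper importance-weight form: each particle's
running product of predictives is a valid importance weight, and the
estimate is log of the particle mean of these products (computed by
logsumexp). The alternative aggregation that sums log particle-mean
predictives per position carries a small O(1/R) upward bias that is
detectable against the enumeration oracle at R = 200; the product form is
unbiased on the likelihood scale, matches the oracle within Monte-Carlo
error, and passes a paired sign test under particle doubling. Default
R = 20 particles.

The hyperparameter harness realizes "10-fold cross-validation with an 80/20
train/test ratio" as 10 repeated random 80/20 participant-level splits
(Monte-Carlo cross-validation) — the two stated numbers are inconsistent as
a literal disjoint partition, and repeated splits honor both. Both models
are fit and scored on identical splits and seeds for paired comparison;
test-set log-likelihoods are summed over participants, and zero-token test
participants contribute 0.

## Phenotype summaries

Hard assignment takes argmax θ_d with a clear-assignment flag at threshold
0.9. Answer-cloud weights condition on the minimal prefix of the
descending-sorted posterior reaching 80% cumulative mass (≥ at the
boundary) and renormalize; prefix minimality is property-tested. The
volume diagnostic reports Spearman rank correlations (with permutation
p-values, 499 permutations by default) between membership and each of days
tracked, observation count, and observations per day; zero-day participants
are excluded from the ratio. Spearman with permutation p-values was chosen
because tracking volumes are heavy-tailed; constant inputs report ρ = 0,
p = 1 by a degenerate-variance rule.

One caveat the diagnostic exposes: the per-phenotype *probability* rows
rank-correlate with document length whenever a cohort contains essentially
single-phenotype participants, because a non-dominant phenotype's posterior
membership is then exactly α/(N_d + Kα) — a deterministic decreasing
function of N_d. This is a smoothing artifact in probabilities of order
1e-4 and below, not structure in the learned phenotypes; the decorrelation
property is therefore asserted on the hard (max-posterior) assignment,
which is clean (|ρ| ≈ 0.05 at D = 1000 with volume decoupled), and the
coupled positive control is asserted on the probability rows, where the
effect is real and large.

## Synthetic cohorts

The generator draws from the model's own generative process, so parameter
recovery is well-posed. Defaults emulate the study conditions: K_true = 4;
θ from a sparse Dirichlet (α_true = 0.01, which puts >90% of participants
above 0.9 maximum membership, matching the observed sharply-assigned
cohort); per-question observation counts negative-binomial with means set
to the published per-question means (total ≈ 173 per participant) and
dispersion 0.25, giving the max/mean ratios of order 100 seen in real
tracking volumes; distinct tracking days Poisson(45), independent of
phenotype unless volume-phenotype coupling is switched on (a mean
multiplier for phenotype 1, the positive control). The "well-separated"
preset draws φ from Dir(0.01) per question so phenotypes are identifiable
at desk scale. Survey covariates draw from per-phenotype level
distributions (categorical) or location-shifted normals (continuous) given
each participant's dominant phenotype, with explicit missingness.

What the generator does not emulate: day-level clustering of observations
within participants, temporal/menstrual-cycle dynamics, real demographic
marginals, and real survey covariate frequencies. Passing tests therefore
show correctness of the pipeline under the model's own assumptions, not
robustness to their violation on real data.

## Problem sizes and test design

The test battery runs at desk scale, chosen so each stage's property is
detectable with margin: sampler exactness on a 5-token corpus (50,000
sweeps); estimator agreement on ≤ 6-token documents (50 replicates of
R = 200 against the enumeration oracle, 2 standard errors); parameter
recovery at K_true = 4, D = 500, ~100 tokens/participant (Hungarian-aligned
total variation < 0.1 per phenotype, adjusted Rand > 0.9); the
model-vs-baseline likelihood ordering on 5 cohorts of D = 300 (the
multi-modal model must also pay for question identity less than the
baseline does, so the ordering is decisive — it wins all 36 grid cells in
the analysis run); review-panel selection at D = 400 with Poisson(13)
per-question volumes so both certainty strata are well populated; and
type-I calibration of both association tests at 2000 null replicates
(acceptance band [0.03, 0.07] at nominal 0.05).

## Known limitations

Single chain by default (independent seeds can be run and aligned by the
Hungarian matcher; phenotype labels are only identified up to permutation).
Symmetric scalar priors only; no hyperparameter optimization, no
variational or streaming inference. The review panel pools the uncertain
stratum across phenotypes rather than stratifying it. The association
screen applies no multiple-testing correction by default (matching the
reported protocol); a Benjamini–Hochberg flag exists. Expert labelings for
purity comparisons enter as label tables; no annotation tooling is
provided. Answer-cloud and heatmap rendering is out of scope — the numeric
weight tables are the tested artifact.
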