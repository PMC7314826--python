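# endopheno

Unsupervised phenotyping of endometriosis from self-tracked symptom data.

Endometriosis is a chronic, poorly characterized condition with no accepted
clinical subtyping. Patients who track their signs, symptoms, treatments and
quality of life through a self-tracking app produce, per participant, a bag
of categorical answers to a fixed set of questions — each question with its
own closed vocabulary (pain locations, severity levels, medication classes,
…). This package learns data-driven disease subtypes from such data and
validates them, end to end, on synthetic cohorts drawn from the assumed
generative process.

## The model

Each participant *d* is a mixture over *K* shared latent phenotypes with
participant-specific proportions θ_d ~ Dirichlet(α); each phenotype *k* owns
one categorical answer distribution φ_k^q ~ Dirichlet(β) per question *q*.
Every observation draws a phenotype label z ~ Cat(θ_d) and then an answer
w ~ Cat(φ_z^q). This is a multi-modal mixed-membership (topic) model: unlike
vanilla LDA on the concatenated vocabulary (size Σ_q V_q, the baseline), it
normalizes each phenotype's answer distribution within each question, so
co-occurrence structure is learned per question and across questions.

Inference is collapsed Gibbs sampling over token labels,

    P(z = k | rest) ∝ (c_dk + α) · (c_kqv + β) / (c_kq + V_q β),

with posterior means of φ and θ averaged over retained sweeps. Held-out
participants are scored with a left-to-right sequential particle estimator
of log p(w_d | Φ, α) (exact enumeration is available as an oracle for short
documents), and hyperparameters are compared by Monte-Carlo cross-validation
over K ∈ {2,3,4,5}, α, β ∈ {0.1, 0.01, 0.001}.

Validation layers mirror the study design: cluster purity against expert
groupings via confusion matrices (including the published 4×4 and 2×2
expert-agreement tables, which ship with the package), a stratified
40-participant review panel (8 clearly-assigned participants per phenotype
plus 8 uncertain ones, all passing a 30-day / 100-observation activity
filter), and an association screen of survey covariates (chi-square for
categorical, Kruskal–Wallis for continuous, α = 0.05).

## Worked example

```python
import endopheno as ep

cfg = ep.well_separated_config(K_true=4, D=500, seed=3,
    volume_model=ep.VolumeModel(family="poisson", means=8.0))
corpus, truth = ep.sample_corpus(cfg)

hyper = ep.Hyperparameters(K=4, alpha=0.001, beta=0.001)
model, posterior, _ = ep.fit(corpus, hyper, n_iter=400, burn_in=200, seed=0)

assignments = ep.hard_assign(posterior, threshold=0.9)
print(f"{assignments.table['clear'].mean():.1%} clearly assigned")

print(ep.purity(ep.load_expert_confusions()["expert1_severe"]))
```

prints

```
95.0% clearly assigned
0.9
```

i.e. on a well-separated synthetic cohort nearly all participants receive a
single phenotype with membership probability above 0.9, and the published
severe-case expert comparison has cluster purity 0.9 (36 of 40 panel
participants fall in their model cluster's majority expert group).

The `analysis/` directory holds the full narrative pipeline as numbered
drivers — `01_simulate_cohort.py` through `05_validate.py` (simulate → fit →
held-out grid → summarize → validate) — each printing what it found and
writing its tables under `results/`.

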