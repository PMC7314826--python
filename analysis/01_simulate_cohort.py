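"""Simulate a self-tracking cohort and its survey table.

Draws a synthetic cohort from the generative model under the default study
conditions (13 questions with the published vocabulary sizes, K_true = 4
phenotypes, sparse memberships, negative-binomial tracking volumes
calibrated to the published per-question means), plus survey covariates with
one strong phenotype-linked binary covariate and otherwise null effects.

Writes results/corpus.json, results/survey.csv, results/corpus_summary.tsv.
"""

from pathlib import Path

import endopheno as ep
from endopheno.synthetic import null_covariates, strong_binary_covariate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240901


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = ep.well_separated_config(K_true=4, D=600, seed=SEED)
    corpus, truth = ep.sample_corpus(cfg)
    ep.write_corpus(corpus, OUT / "corpus.json")

    specs = null_covariates(truth.K, n_categorical=4, n_continuous=3)
    specs.append(strong_binary_covariate(truth.K, name="limited_daily_activity"))
    survey = ep.sample_survey(truth, specs, seed=SEED + 1)
    survey.to_csv(OUT / "survey.csv", index=False)

    summary = ep.corpus_summary(corpus)
    summary.to_csv(OUT / "corpus_summary.tsv", sep="\t", index=False, float_format="%.2f")

    total = summary.set_index("question_id").loc["Total"]
    print(f"cohort: D={corpus.n_participants}, {corpus.total_observations} observations")
    print(f"mean observations per participant: {total.n_obs_mean:.1f} "
          f"(max {int(total.n_obs_max)})")
    print(f"survey: {survey.shape[1] - 1} covariates for {len(survey)} participants")
    print(f"wrote {OUT / 'corpus.json'}, survey.csv, corpus_summary.tsv")


if __name__ == "__main__":
    main()
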