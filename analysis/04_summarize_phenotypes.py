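"""Summarize the fitted phenotypes.

From the fitted posteriors: hard assignments with the 0.9 clear-assignment
flag, top-10 answers per (phenotype, question), answer-cloud weights at the
80% posterior-mass threshold, and the membership-vs-tracking-volume rank
correlations with permutation p-values.

Reads results/corpus.json, phi.csv, theta.csv; writes results/assignments.csv,
topn.csv, clouds.csv, volume_corr.tsv.
"""

from pathlib import Path

import pandas as pd

import endopheno as ep
from endopheno.corpus import Corpus
from endopheno.inference import MembershipPosterior, PhenotypeModel
from endopheno.summary import all_cloud_weights

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    corpus = ep.load_corpus(OUT / "corpus.json")
    model = PhenotypeModel.from_frame(pd.read_csv(OUT / "phi.csv"))
    posterior = MembershipPosterior.from_frame(pd.read_csv(OUT / "theta.csv"))

    assignments = ep.hard_assign(posterior, threshold=0.9)
    assignments.table.to_csv(OUT / "assignments.csv", index=False, float_format="%.10g")

    topn = pd.DataFrame(
        [
            (k, qid, rank + 1, token, prob)
            for qid in model.question_ids
            for k in range(1, model.K + 1)
            for rank, (token, prob) in enumerate(ep.top_answers(model, qid, k, n=10))
        ],
        columns=["phenotype", "question_id", "rank", "token", "probability"],
    )
    topn.to_csv(OUT / "topn.csv", index=False, float_format="%.10g")

    clouds = all_cloud_weights(model, mass=0.8)
    clouds.to_csv(OUT / "clouds.csv", index=False, float_format="%.10g")

    modelled = Corpus(schema=corpus.schema,
                      participants=corpus.nonempty_participants())
    corr = ep.volume_correlation(assignments, modelled, n_perm=499, seed=1)
    corr.to_csv(OUT / "volume_corr.tsv", sep="\t", index=False, float_format="%.4f")

    clear = assignments.table["clear"].mean()
    label_rows = corr[corr.assignment == "hard_label"]
    print(f"{clear:.1%} of participants clearly assigned at threshold 0.9")
    print("hard-label vs volume Spearman rho (all should be near 0):")
    for _, r in label_rows.iterrows():
        print(f"  {r.measure}: rho={r.spearman_rho:+.3f} (p={r.p_value:.3f})")
    print(f"wrote assignments.csv, topn.csv, clouds.csv, volume_corr.tsv to {OUT}")


if __name__ == "__main__":
    main()
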