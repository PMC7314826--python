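"""Extrinsic validation: expert agreement and survey associations.

Computes cluster purity for the six published expert-vs-model confusion
matrices (the 4-way comparisons and their severe/mild binary collapses),
selects a 40-participant review panel from the fitted synthetic cohort, and
screens the survey covariates for association with the learned phenotypes
(chi-square for categorical, Kruskal-Wallis for continuous, alpha = 0.05).

Reads results/corpus.json, theta.csv, survey.csv; writes results/purity.tsv
and results/associations.tsv.
"""

from pathlib import Path

import pandas as pd

import endopheno as ep
from endopheno.inference import MembershipPosterior
from endopheno.validation import association_frame

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 23


def main() -> None:
    corpus = ep.load_corpus(OUT / "corpus.json")
    posterior = MembershipPosterior.from_frame(pd.read_csv(OUT / "theta.csv"))
    assignments = ep.hard_assign(posterior)

    tables = ep.load_expert_confusions()
    purity_rows = [
        {"comparison": name, "purity": ep.purity(m), "n": m.total}
        for name, m in tables.items()
    ]
    purity_table = pd.DataFrame(purity_rows)
    purity_table.to_csv(OUT / "purity.tsv", sep="\t", index=False, float_format="%.4g")
    print("cluster purity of the published expert comparisons:")
    for _, r in purity_table.iterrows():
        print(f"  {r.comparison}: {r.purity:.3f} (n={int(r.n)})")

    panel = ep.select_review_panel(assignments, corpus, seed=SEED)
    print(f"review panel: {panel.size} participants "
          f"({len(panel.certain)} certain strata of 8 + {len(panel.uncertain)} uncertain)")

    survey = pd.read_csv(OUT / "survey.csv")
    results = ep.association_screen(assignments, survey, alpha=0.05)
    frame = association_frame(results)
    frame.to_csv(OUT / "associations.tsv", sep="\t", index=False, float_format="%.4g")
    sig = frame[frame.significant]
    print(f"association screen: {len(frame)} covariates tested, "
          f"{len(sig)} significant at 0.05: {', '.join(sig.covariate) or 'none'}")
    print(f"wrote purity.tsv, associations.tsv to {OUT}")


if __name__ == "__main__":
    main()
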