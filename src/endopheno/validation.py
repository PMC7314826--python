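"""Extrinsic validation: expert agreement and survey associations.

Two checks complement the intrinsic likelihood evaluation.  First, a review
panel of participants (certain and uncertain model assignments, subject to
an activity filter) is compared against independent expert groupings via
confusion matrices and cluster purity.  Second, the learned hard phenotype
assignments are screened for association with survey covariates: chi-square
tests of independence for categorical covariates, Kruskal-Wallis H-tests
for continuous ones, reported at a fixed significance level with no
multiple-testing correction (a Benjamini-Hochberg option exists, off by
default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus
from .summary import AssignmentTable

logger = logging.getLogger(__name__)


class ValidationInputError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """Model clusters (rows) against reference clusters (columns)."""

    cells: np.ndarray  # (r, c) nonnegative integers
    row_labels: list[str]
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if (self.cells < 0).any():
            raise ValidationInputError("confusion cells must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels,
                            columns=self.column_labels)


def load_expert_confusions() -> dict[str, ConfusionMatrix]:
    """The six published expert-agreement confusion matrices (the 4-way
    comparisons for each expert plus their severe- and mild-case collapses)."""
    text = (resources.files("endopheno") / "data" / "expert_confusion.json").read_text()
    raw = json.loads(text)
    return {
        name: ConfusionMatrix(
            cells=np.array(entry["cells"]),
            row_labels=entry["rows"],
            column_labels=entry["columns"],
        )
        for name, entry in raw.items()
    }


def confusion(model_labels: pd.Series, reference_labels: pd.Series) -> ConfusionMatrix:
    """Cross-tabulate two labelings of the same participants."""
    ml = pd.Series(model_labels)
    rl = pd.Series(reference_labels)
    if set(ml.index) != set(rl.index):
        raise ValidationInputError("model and reference labels cover different ids")
    rl = rl.loc[ml.index]
    tab = pd.crosstab(ml, rl)
    return ConfusionMatrix(
        cells=tab.to_numpy(),
        row_labels=[str(x) for x in tab.index],
        column_labels=[str(x) for x in tab.columns],
    )


def purity(m: ConfusionMatrix) -> float:
    """Cluster purity: sum over model clusters of the largest overlap with
    any reference cluster, divided by the total count."""
    if m.total == 0:
        raise ValidationInputError("empty confusion matrix")
    return float(m.cells.max(axis=1).sum() / m.total)


def collapse_to_binary(
    m: ConfusionMatrix, positive_row: str, positive_columns: list[str]
) -> ConfusionMatrix:
    """Collapse to positive-vs-rest on both axes (e.g. severe vs non-severe)."""
    if positive_row not in m.row_labels:
        raise ValidationInputError(f"unknown row label {positive_row!r}")
    unknown = set(positive_columns) - set(m.column_labels)
    if unknown:
        raise ValidationInputError(f"unknown column label(s) {sorted(unknown)}")
    ri = m.row_labels.index(positive_row)
    ci = [m.column_labels.index(c) for c in positive_columns]
    row_pos = np.zeros(len(m.row_labels), dtype=bool)
    row_pos[ri] = True
    col_pos = np.zeros(len(m.column_labels), dtype=bool)
    col_pos[ci] = True
    cells = np.array(
        [
            [m.cells[row_pos][:, col_pos].sum(), m.cells[row_pos][:, ~col_pos].sum()],
            [m.cells[~row_pos][:, col_pos].sum(), m.cells[~row_pos][:, ~col_pos].sum()],
        ]
    )
    return ConfusionMatrix(
        cells=cells,
        row_labels=["positive", "rest"],
        column_labels=["positive", "rest"],
    )


# ---------------------------------------------------------------------------
# Review-panel selection


@dataclass
class ReviewPanel:
    """Participants selected for expert review: per phenotype, participants
    the model assigns with near certainty, plus a pooled uncertain stratum."""

    certain: dict[int, list[str]]  # phenotype (1-based) -> ids
    uncertain: list[str]

    @property
    def participant_ids(self) -> list[str]:
        out = [pid for ids in self.certain.values() for pid in ids]
        return out + list(self.uncertain)

    @property
    def size(self) -> int:
        return len(self.participant_ids)


def select_review_panel(
    assignments: AssignmentTable,
    corpus: Corpus,
    seed: int = 0,
    n_per_stratum: int = 8,
    certain_threshold: float = 0.95,
    shared_mass: float = 0.8,
    min_days: int = 30,
    min_observations: int = 100,
) -> ReviewPanel:
    """Seeded uniform sampling of the review panel.

    Eligibility requires at least ``min_days`` active days and more than
    ``min_observations`` tracked observations.  A participant is "certain"
    for phenotype k when its membership probability exceeds
    ``certain_threshold``; "uncertain" when no phenotype reaches that bar
    but the top two phenotypes jointly hold at least ``shared_mass`` of the
    membership.  For K=4 and 8 per stratum the panel has 40 members.
    """
    by_id = {p.participant_id: p for p in corpus.participants}
    probs = assignments.probabilities()
    K = assignments.K
    ids = assignments.participant_ids
    eligible = np.array(
        [
            by_id[pid].days_tracked >= min_days
            and by_id[pid].n_observations > min_observations
            for pid in ids
        ]
    )
    top = probs.max(axis=1)
    top2 = np.sort(probs, axis=1)[:, -2:].sum(axis=1)
    labels = probs.argmax(axis=1)
    rng = np.random.default_rng(seed)
    certain: dict[int, list[str]] = {}
    for k in range(K):
        pool = [
            ids[i]
            for i in range(len(ids))
            if eligible[i] and labels[i] == k and top[i] > certain_threshold
        ]
        if len(pool) < n_per_stratum:
            raise ValidationInputError(
                f"certain stratum for phenotype {k + 1}: only {len(pool)} eligible "
                f"participant(s), need {n_per_stratum}"
            )
        certain[k + 1] = sorted(rng.choice(pool, size=n_per_stratum, replace=False))
    uncertain_pool = [
        ids[i]
        for i in range(len(ids))
        if eligible[i] and top[i] <= certain_threshold and top2[i] >= shared_mass
    ]
    if len(uncertain_pool) < n_per_stratum:
        raise ValidationInputError(
            f"uncertain stratum: only {len(uncertain_pool)} eligible "
            f"participant(s), need {n_per_stratum}"
        )
    uncertain = sorted(rng.choice(uncertain_pool, size=n_per_stratum, replace=False))
    return ReviewPanel(certain=certain, uncertain=list(uncertain))


# ---------------------------------------------------------------------------
# Association screen


@dataclass
class AssociationResult:
    covariate: str
    test: str  # "chi_square" | "kruskal_wallis"
    statistic: float
    dof: int | None
    p_value: float
    significant: bool
    low_expected_count: bool = False
    n: int = 0


def chi_square_independence(
    table: np.ndarray, alpha: float = 0.05, covariate: str = ""
) -> AssociationResult:
    """Pearson chi-square test of independence on an r x c contingency
    table (no continuity correction); flags expected counts below 5."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationInputError("contingency table must be at least 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationInputError("contingency table has a zero marginal")
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        covariate=covariate,
        test="chi_square",
        statistic=float(stat),
        dof=int(dof),
        p_value=float(p),
        significant=bool(p < alpha),
        low_expected_count=bool((expected < 5).any()),
        n=int(table.sum()),
    )


def kruskal_wallis(
    groups: list[np.ndarray], alpha: float = 0.05, covariate: str = ""
) -> AssociationResult:
    """Kruskal-Wallis H-test (tie-corrected) across independent samples;
    p-value from the chi-square approximation with K-1 dof."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValidationInputError("need at least 2 nonempty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 2 or np.all(pooled == pooled[0]):
        raise ValidationInputError("degenerate input: all values identical")
    stat, p = stats.kruskal(*groups)
    return AssociationResult(
        covariate=covariate,
        test="kruskal_wallis",
        statistic=float(stat),
        dof=len(groups) - 1,
        p_value=float(p),
        significant=bool(p < alpha),
        n=int(pooled.size),
    )


def association_screen(
    assignments: AssignmentTable,
    survey: pd.DataFrame,
    alpha: float = 0.05,
    covariate_types: dict[str, str] | None = None,
    bh_correction: bool = False,
) -> list[AssociationResult]:
    """Screen survey covariates for association with hard phenotype labels.

    Categorical covariates -> chi-square on the phenotype x level table;
    continuous -> Kruskal-Wallis across phenotype groups.  Missing cells are
    dropped per covariate; covariates with a single observed level (or
    otherwise degenerate) are skipped with a logged warning.  By default no
    multiple-testing correction is applied.
    """
    if "participant_id" not in survey.columns:
        raise ValidationInputError("survey table must have a participant_id column")
    merged = assignments.table[["participant_id", "hard_label"]].merge(
        survey, on="participant_id", how="inner"
    )
    if merged.empty:
        raise ValidationInputError("no shared participant ids")
    results: list[AssociationResult] = []
    for col in survey.columns:
        if col == "participant_id":
            continue
        sub = merged[["hard_label", col]].dropna()
        if covariate_types and col in covariate_types:
            kind = covariate_types[col]
            if kind not in ("categorical", "continuous"):
                raise ValidationInputError(f"covariate {col!r}: unknown type {kind!r}")
        else:
            kind = (
                "continuous"
                if pd.api.types.is_numeric_dtype(sub[col])
                else "categorical"
            )
        try:
            if kind == "categorical":
                tab = pd.crosstab(sub["hard_label"], sub[col])
                if tab.shape[1] < 2 or tab.shape[0] < 2:
                    logger.warning("skipping covariate %r: single observed level", col)
                    continue
                results.append(
                    chi_square_independence(tab.to_numpy(), alpha=alpha, covariate=col)
                )
            else:
                groups = [g.to_numpy() for _, g in sub.groupby("hard_label")[col]]
                results.append(kruskal_wallis(groups, alpha=alpha, covariate=col))
        except ValidationInputError as exc:
            logger.warning("skipping covariate %r: %s", col, exc)
    if bh_correction and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        thresh = 0.0
        for rank, i in enumerate(order, start=1):
            if results[i].p_value <= alpha * rank / m:
                thresh = results[i].p_value
        for r in results:
            r.significant = r.p_value <= thresh
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate, "test": r.test, "statistic": r.statistic,
                "dof": r.dof, "p_value": r.p_value, "significant": r.significant,
                "low_expected_count": r.low_expected_count, "n": r.n,
            }
            for r in results
        ]
    )
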