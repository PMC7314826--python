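"""Phenotype descriptions from fitted posteriors.

Turns the fitted per-question answer distributions and per-participant
membership proportions into the pipeline's reporting artifacts: hard
assignments with a clear-assignment flag, top-n answer tables, answer-cloud
weights (the minimal high-probability answer set covering a fixed fraction
of posterior mass, renormalized), and the membership-vs-tracking-volume
diagnostic that checks the learned phenotypes are not engagement artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus import Corpus
from .inference import MembershipPosterior, PhenotypeModel

logger = logging.getLogger(__name__)


@dataclass
class AssignmentTable:
    """Per-participant membership probabilities, hard label and clear flag."""

    table: pd.DataFrame  # participant_id, p1..pK, hard_label (1-based), clear
    threshold: float

    @property
    def K(self) -> int:
        return sum(c.startswith("p") and c[1:].isdigit() for c in self.table.columns)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.table["participant_id"])

    def probabilities(self) -> np.ndarray:
        return self.table[[f"p{k + 1}" for k in range(self.K)]].to_numpy()

    def hard_labels(self) -> np.ndarray:
        return self.table["hard_label"].to_numpy()


def hard_assign(theta: MembershipPosterior, threshold: float = 0.9) -> AssignmentTable:
    """Hard label = argmax theta_d (ties -> lowest index); clear iff the
    maximum membership probability exceeds ``threshold``."""
    probs = theta.theta
    labels = probs.argmax(axis=1) + 1
    clear = probs.max(axis=1) > threshold
    table = pd.DataFrame({"participant_id": theta.participant_ids})
    for k in range(theta.K):
        table[f"p{k + 1}"] = probs[:, k]
    table["hard_label"] = labels
    table["clear"] = clear
    return AssignmentTable(table=table, threshold=threshold)


def top_answers(
    model: PhenotypeModel, question_id: str, phenotype: int, n: int = 10
) -> list[tuple[str, float]]:
    """The n most probable answers of one phenotype's posterior for one
    question, descending; ties keep vocabulary order.  ``phenotype`` is
    1-based."""
    if n < 1:
        raise ValueError("n must be >= 1")
    qi = model.question_index(question_id)
    if not 1 <= phenotype <= model.K:
        raise KeyError(f"phenotype {phenotype} out of range 1..{model.K}")
    row = model.phi[qi][phenotype - 1]
    order = np.argsort(-row, kind="stable")[:n]
    vocab = model.vocabularies[qi]
    return [(vocab[v], float(row[v])) for v in order]


@dataclass
class CloudWeights:
    """Answer-cloud entry: minimal top-probability prefix covering the mass
    threshold, with weights renormalized to sum to 1."""

    question_id: str
    phenotype: int
    mass: float
    entries: list[tuple[str, float]]


def cloud_weights(
    model: PhenotypeModel, question_id: str, phenotype: int, mass: float = 0.8
) -> CloudWeights:
    """Condition on the answers covering ``mass`` of the posterior: take the
    minimal prefix of the descending-sorted posterior whose cumulative
    probability reaches the threshold (>=), and renormalize."""
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    qi = model.question_index(question_id)
    row = model.phi[qi][phenotype - 1]
    order = np.argsort(-row, kind="stable")
    cum = np.cumsum(row[order])
    n_keep = int(np.searchsorted(cum, mass - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    kept = order[:n_keep]
    weights = row[kept] / row[kept].sum()
    vocab = model.vocabularies[qi]
    return CloudWeights(
        question_id=question_id,
        phenotype=phenotype,
        mass=mass,
        entries=[(vocab[v], float(w)) for v, w in zip(kept, weights)],
    )


def all_cloud_weights(model: PhenotypeModel, mass: float = 0.8) -> pd.DataFrame:
    rows = []
    for qid in model.question_ids:
        for k in range(1, model.K + 1):
            for token, w in cloud_weights(model, qid, k, mass).entries:
                rows.append((k, qid, token, w))
    return pd.DataFrame(rows, columns=["phenotype", "question_id", "token", "weight"])


# ---------------------------------------------------------------------------
# Assignment-vs-volume diagnostic


def _spearman_perm(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_perm: int
) -> tuple[float, float]:
    """Spearman rho with a permutation p-value; degenerate variance -> (0, 1)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho) - 1e-15:
            count += 1
    return rho, (1 + count) / (1 + n_perm)


def volume_correlation(
    assignments: AssignmentTable,
    corpus: Corpus,
    n_perm: int = 499,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank correlations between membership and tracking volume.

    For each phenotype's membership probability, and for the hard label,
    reports the Spearman correlation with days tracked, observation count
    and observations per day, each with a permutation p-value.  Zero-day
    participants are excluded from the ratio statistic.
    """
    by_id = {p.participant_id: p for p in corpus.participants}
    missing = [pid for pid in assignments.participant_ids if pid not in by_id]
    if missing:
        raise ValueError(f"participants missing from corpus: {missing[:3]}...")
    records = [by_id[pid] for pid in assignments.participant_ids]
    days = np.array([p.days_tracked for p in records], dtype=float)
    n_obs = np.array([p.n_observations for p in records], dtype=float)
    ratio_ok = days > 0
    n_excluded = int((~ratio_ok).sum())
    if n_excluded:
        logger.info("excluding %d zero-day participant(s) from ratio statistic",
                    n_excluded)
    measures = {
        "days_tracked": (days, np.ones_like(ratio_ok, dtype=bool)),
        "n_observations": (n_obs, np.ones_like(ratio_ok, dtype=bool)),
        "obs_per_day": (np.divide(n_obs, days, out=np.zeros_like(n_obs),
                                  where=ratio_ok), ratio_ok),
    }
    probs = assignments.probabilities()
    series: list[tuple[str, np.ndarray]] = [
        (f"phenotype_{k + 1}", probs[:, k]) for k in range(assignments.K)
    ]
    series.append(("hard_label", assignments.hard_labels().astype(float)))
    rng = np.random.default_rng(seed)
    rows = []
    for name, values in series:
        for mname, (m, mask) in measures.items():
            rho, p = _spearman_perm(values[mask], m[mask], rng, n_perm)
            rows.append(
                {"assignment": name, "measure": mname, "spearman_rho": rho,
                 "p_value": p, "n": int(mask.sum())}
            )
    return pd.DataFrame(rows)
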