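import numpy as np
import pytest

import endopheno as ep
from endopheno.corpus import Corpus, ParticipantRecord, QuestionSchema


@pytest.fixture
def tiny_schema():
    return [
        QuestionSchema("q1", "First question", ("a", "b", "c")),
        QuestionSchema("q2", "Second question", ("x", "y")),
    ]


@pytest.fixture
def tiny_corpus(tiny_schema):
    participants = [
        ParticipantRecord("p1", {"q1": {"a": 2, "b": 1}, "q2": {"x": 1}}, days_tracked=3),
        ParticipantRecord("p2", {"q1": {"c": 5}}, days_tracked=2),
        ParticipantRecord("p3", {}, days_tracked=0),
    ]
    return Corpus(schema=tiny_schema, participants=participants)


@pytest.fixture
def small_model(tiny_schema):
    """A fixed 2-phenotype model over the tiny schema."""
    rng = np.random.default_rng(7)
    phi = [
        rng.dirichlet(np.ones(q.size), size=2) for q in tiny_schema
    ]
    return ep.PhenotypeModel(
        question_ids=[q.question_id for q in tiny_schema],
        vocabularies=[q.vocabulary for q in tiny_schema],
        phi=phi,
    )


@pytest.fixture(scope="session")
def separated_fit():
    """A well-separated synthetic cohort and its fit, shared across tests.

    K_true = 4, D = 500, ~100 tokens per participant.
    """
    cfg = ep.well_separated_config(
        K_true=4, D=500, seed=3,
        volume_model=ep.VolumeModel(family="poisson", means=8.0),
    )
    corpus, truth = ep.sample_corpus(cfg)
    hyper = ep.Hyperparameters(K=4, alpha=0.1, beta=0.01)
    model, posterior, state = ep.fit(
        corpus, hyper, n_iter=400, burn_in=200, seed=0, thin=10
    )
    return corpus, truth, model, posterior, state


def align_phenotypes(model, truth):
    """Hungarian matching of fitted to true phenotypes by mean total-variation
    distance across questions; returns (row_ind, col_ind, tv_matrix)."""
    from scipy.optimize import linear_sum_assignment

    K = truth.K
    tv = np.zeros((K, K))
    for q in range(len(model.phi)):
        for a in range(K):
            for b in range(K):
                tv[a, b] += 0.5 * np.abs(model.phi[q][a] - truth.phi_true[q][b]).sum()
    tv /= len(model.phi)
    r, c = linear_sum_assignment(tv)
    return r, c, tv
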