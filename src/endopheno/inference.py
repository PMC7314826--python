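"""Multi-modal mixed-membership model with collapsed Gibbs inference.

Each participant d is a mixture over K shared phenotypes with proportions
theta_d ~ Dirichlet(alpha); each phenotype k owns one categorical answer
distribution phi_k^q ~ Dirichlet(beta) per question q.  Collapsing theta and
phi analytically leaves token-level labels z with the standard conditional

    P(z = k | rest) ~ (c_dk + alpha) (c_kqv + beta) / (c_kq + V_q beta),

the multi-modal twist being that the smoothing denominator uses the
vocabulary size of the token's own question.  The vanilla-LDA baseline is
the same sampler run on the concatenated single-question view, where the
denominator uses sum_q V_q instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import gibbs_sweep_kernel
from .corpus import Corpus, concatenate_view


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class Hyperparameters:
    """Symmetric Dirichlet hyperparameters of the mixed-membership model."""

    K: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise InferenceError("K must be an integer >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise InferenceError("alpha and beta must be > 0")


@dataclass
class TokenTable:
    """Flattened token-level view of a corpus (zero-observation participants
    excluded); the sampler and estimators operate on these arrays."""

    participant_ids: list[str]
    question_ids: list[str]
    vocabularies: list[tuple[str, ...]]
    Vq: np.ndarray          # (Q,) vocabulary sizes
    q_offset: np.ndarray    # (Q,) offsets into the concatenated vocabulary
    d_idx: np.ndarray       # (N,)
    q_idx: np.ndarray       # (N,)
    v_idx: np.ndarray       # (N,) global answer index (offset + local index)
    N_d: np.ndarray         # (D,)

    @property
    def n_tokens(self) -> int:
        return self.d_idx.shape[0]

    @property
    def D(self) -> int:
        return len(self.participant_ids)

    @property
    def Q(self) -> int:
        return len(self.question_ids)

    @property
    def V_total(self) -> int:
        return int(self.Vq.sum())


def build_token_table(corpus: Corpus) -> TokenTable:
    """Expand a corpus into flat token arrays in the canonical visit order:
    participant order, then question schema order, then vocabulary order."""
    participants = corpus.nonempty_participants()
    if not participants:
        raise InferenceError("corpus has no tokens")
    qids = corpus.question_ids
    vocabs = [corpus.question(q).vocabulary for q in qids]
    vindex = [{t: i for i, t in enumerate(v)} for v in vocabs]
    Vq = np.array([len(v) for v in vocabs], dtype=np.int64)
    q_offset = np.concatenate([[0], np.cumsum(Vq)[:-1]]).astype(np.int64)
    d_list, q_list, v_list = [], [], []
    N_d = np.zeros(len(participants), dtype=np.int64)
    for d, p in enumerate(participants):
        for qi, qid in enumerate(qids):
            counts = p.answers.get(qid, {})
            for token in vocabs[qi]:
                c = counts.get(token, 0)
                if c:
                    v_global = q_offset[qi] + vindex[qi][token]
                    d_list.extend([d] * c)
                    q_list.extend([qi] * c)
                    v_list.extend([v_global] * c)
                    N_d[d] += c
    return TokenTable(
        participant_ids=[p.participant_id for p in participants],
        question_ids=qids,
        vocabularies=vocabs,
        Vq=Vq,
        q_offset=q_offset,
        d_idx=np.array(d_list, dtype=np.int64),
        q_idx=np.array(q_list, dtype=np.int64),
        v_idx=np.array(v_list, dtype=np.int64),
        N_d=N_d,
    )


@dataclass
class GibbsState:
    """Token labels plus the collapsed model's sufficient-count tables."""

    tokens: TokenTable
    hyper: Hyperparameters
    z: np.ndarray       # (N,)
    c_dk: np.ndarray    # (D, K)
    c_kv: np.ndarray    # (K, V_total)
    c_kq: np.ndarray    # (K, Q)
    rng: np.random.Generator

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Independent tallies of z (the bookkeeping oracle)."""
        t, K = self.tokens, self.hyper.K
        c_dk = np.zeros((t.D, K), dtype=np.int64)
        c_kv = np.zeros((K, t.V_total), dtype=np.int64)
        c_kq = np.zeros((K, t.Q), dtype=np.int64)
        np.add.at(c_dk, (t.d_idx, self.z), 1)
        np.add.at(c_kv, (self.z, t.v_idx), 1)
        np.add.at(c_kq, (self.z, t.q_idx), 1)
        return c_dk, c_kv, c_kq

    def counts_consistent(self) -> bool:
        a, b, c = self.recount()
        return (
            np.array_equal(a, self.c_dk)
            and np.array_equal(b, self.c_kv)
            and np.array_equal(c, self.c_kq)
        )


def init_state(corpus: Corpus, hyper: Hyperparameters, seed: int) -> GibbsState:
    """Uniform random token assignments with consistent count tables."""
    tokens = build_token_table(corpus)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, hyper.K, size=tokens.n_tokens)
    state = GibbsState(
        tokens=tokens,
        hyper=hyper,
        z=z.astype(np.int64),
        c_dk=np.zeros((tokens.D, hyper.K), dtype=np.int64),
        c_kv=np.zeros((hyper.K, tokens.V_total), dtype=np.int64),
        c_kq=np.zeros((hyper.K, tokens.Q), dtype=np.int64),
        rng=rng,
    )
    state.c_dk, state.c_kv, state.c_kq = state.recount()
    return state


def gibbs_conditional(state: GibbsState, token_index: int) -> np.ndarray:
    """Normalized conditional distribution of one token's label.

    Reference implementation of the same formula the sweep kernel applies;
    the current token is excluded from all counts.
    """
    t, h = state.tokens, state.hyper
    d, q, v = t.d_idx[token_index], t.q_idx[token_index], t.v_idx[token_index]
    k_old = state.z[token_index]
    c_dk = state.c_dk[d].astype(float).copy()
    c_kv = state.c_kv[:, v].astype(float).copy()
    c_kq = state.c_kq[:, q].astype(float).copy()
    c_dk[k_old] -= 1
    c_kv[k_old] -= 1
    c_kq[k_old] -= 1
    p = (c_dk + h.alpha) * (c_kv + h.beta) / (c_kq + t.Vq[q] * h.beta)
    return p / p.sum()


def gibbs_sweep(state: GibbsState) -> GibbsState:
    """One in-place systematic-scan sweep over all tokens (fixed order)."""
    sweep_seed = int(state.rng.integers(0, 2**31 - 1))
    gibbs_sweep_kernel(
        state.z,
        state.tokens.d_idx,
        state.tokens.q_idx,
        state.tokens.v_idx,
        state.tokens.Vq,
        state.c_dk,
        state.c_kv,
        state.c_kq,
        float(state.hyper.alpha),
        float(state.hyper.beta),
        sweep_seed,
    )
    return state


@dataclass
class PhenotypeModel:
    """Per-phenotype, per-question answer distributions phi_k^q."""

    question_ids: list[str]
    vocabularies: list[tuple[str, ...]]
    phi: list[np.ndarray]  # per question: (K, V_q), rows sum to 1

    @property
    def K(self) -> int:
        return self.phi[0].shape[0]

    def question_index(self, question_id: str) -> int:
        try:
            return self.question_ids.index(question_id)
        except ValueError:
            raise KeyError(f"unknown question {question_id!r}") from None

    def phi_flat(self) -> np.ndarray:
        """(K, sum_q V_q) concatenation of the per-question phi blocks."""
        return np.concatenate(self.phi, axis=1)

    def to_frame(self):
        import pandas as pd

        rows = []
        for qid, vocab, phi_q in zip(self.question_ids, self.vocabularies, self.phi):
            for k in range(self.K):
                for v, token in enumerate(vocab):
                    rows.append((k + 1, qid, token, phi_q[k, v]))
        return pd.DataFrame(
            rows, columns=["phenotype", "question_id", "token", "probability"]
        )

    @classmethod
    def from_frame(cls, frame) -> "PhenotypeModel":
        """Rebuild from the long-format table written by ``to_frame``;
        question and token order follow first appearance in the frame."""
        question_ids = list(dict.fromkeys(frame["question_id"]))
        vocabularies, phi = [], []
        K = int(frame["phenotype"].max())
        for qid in question_ids:
            sub = frame[frame["question_id"] == qid]
            vocab = tuple(dict.fromkeys(sub["token"]))
            mat = np.empty((K, len(vocab)))
            vindex = {t: i for i, t in enumerate(vocab)}
            for _, r in sub.iterrows():
                mat[int(r["phenotype"]) - 1, vindex[r["token"]]] = r["probability"]
            vocabularies.append(vocab)
            phi.append(mat)
        return cls(question_ids=question_ids, vocabularies=vocabularies, phi=phi)


@dataclass
class MembershipPosterior:
    """Per-participant phenotype proportions theta_d."""

    participant_ids: list[str]
    theta: np.ndarray  # (D, K), rows sum to 1

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    def to_frame(self):
        import pandas as pd

        rows = [
            (pid, k + 1, self.theta[d, k])
            for d, pid in enumerate(self.participant_ids)
            for k in range(self.K)
        ]
        return pd.DataFrame(rows, columns=["participant_id", "phenotype", "probability"])

    @classmethod
    def from_frame(cls, frame) -> "MembershipPosterior":
        """Rebuild from the long-format table written by ``to_frame``."""
        pivot = frame.pivot(index="participant_id", columns="phenotype",
                            values="probability")
        pivot = pivot.loc[list(dict.fromkeys(frame["participant_id"]))]
        return cls(participant_ids=list(pivot.index), theta=pivot.to_numpy())


def _phi_estimate(state: GibbsState) -> list[np.ndarray]:
    t, h = state.tokens, state.hyper
    out = []
    for qi in range(t.Q):
        lo, hi = t.q_offset[qi], t.q_offset[qi] + t.Vq[qi]
        num = state.c_kv[:, lo:hi] + h.beta
        den = (state.c_kq[:, qi] + t.Vq[qi] * h.beta)[:, None]
        out.append(num / den)
    return out


def _theta_estimate(state: GibbsState) -> np.ndarray:
    t, h = state.tokens, state.hyper
    return (state.c_dk + h.alpha) / (t.N_d[:, None] + h.K * h.alpha)


def fit(
    corpus: Corpus,
    hyper: Hyperparameters,
    n_iter: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    thin: int = 10,
) -> tuple[PhenotypeModel, MembershipPosterior, GibbsState]:
    """Run collapsed Gibbs and return posterior-mean estimates.

    phi and theta are Rao-Blackwellized count-ratio statistics averaged over
    the post-burn-in sweeps retained at the thinning interval.
    """
    if not n_iter > burn_in >= 0:
        raise InferenceError("need n_iter > burn_in >= 0")
    state = init_state(corpus, hyper, seed)
    t = state.tokens
    phi_acc = [np.zeros((hyper.K, int(v))) for v in t.Vq]
    theta_acc = np.zeros((t.D, hyper.K))
    n_kept = 0
    for it in range(n_iter):
        gibbs_sweep(state)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for qi, est in enumerate(_phi_estimate(state)):
                phi_acc[qi] += est
            theta_acc += _theta_estimate(state)
            n_kept += 1
    model = PhenotypeModel(
        question_ids=t.question_ids,
        vocabularies=t.vocabularies,
        phi=[a / n_kept for a in phi_acc],
    )
    posterior = MembershipPosterior(
        participant_ids=t.participant_ids, theta=theta_acc / n_kept
    )
    return model, posterior, state


def fit_baseline(
    corpus: Corpus,
    hyper: Hyperparameters,
    n_iter: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    thin: int = 10,
) -> tuple[PhenotypeModel, MembershipPosterior, GibbsState]:
    """Vanilla-LDA baseline: the same sampler on the concatenated view."""
    return fit(concatenate_view(corpus), hyper, n_iter, burn_in, seed, thin)
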