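"""Synthetic self-tracking cohorts from the assumed generative process.

The generator draws, for each participant, sparse phenotype proportions
theta_d ~ Dirichlet(alpha_true), per-question observation counts from a
volume model calibrated to the real cohort's printed per-question means
(heavily right-skewed negative binomial by default), and each token's
phenotype label z ~ Cat(theta_d) followed by an answer drawn from that
phenotype's per-question answer distribution phi_k^q.  Survey covariates
are drawn conditionally on the participant's dominant phenotype so the
association screen has controllable positive and null cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    Corpus,
    ParticipantRecord,
    QuestionSchema,
    default_question_means,
    default_schema,
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class VolumeModel:
    """Distribution of per-participant, per-question observation counts.

    ``family`` is one of ``negative_binomial`` (default; dispersion gives
    max/mean ratios of order 100, matching the wide spread of real tracking
    volumes), ``poisson``, or ``fixed``.  ``means`` maps question_id to the
    expected count; a scalar applies to every question.
    """

    family: str = "negative_binomial"
    means: dict[str, float] | float | None = None
    dispersion: float = 0.25
    days_mean: float = 45.0

    def mean_for(self, question_id: str) -> float:
        if self.means is None:
            return float(default_question_means().get(question_id, 5.0))
        if isinstance(self.means, dict):
            return float(self.means[question_id])
        return float(self.means)

    def sample_counts(self, rng: np.random.Generator, question_id: str,
                      n: int, scale: np.ndarray) -> np.ndarray:
        """n per-participant counts for one question; ``scale`` multiplies means."""
        mean = self.mean_for(question_id) * scale
        if self.family == "poisson":
            return rng.poisson(mean)
        if self.family == "fixed":
            return np.round(mean).astype(np.int64)
        if self.family == "negative_binomial":
            r = self.dispersion
            # numpy parameterization: p = r / (r + mean)
            return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))
        raise ConfigurationError(f"unknown volume family {self.family!r}")


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the synthetic cohort."""

    K_true: int = 4
    alpha_true: float = 0.01
    beta_true: float = 0.1
    D: int = 500
    volume_model: VolumeModel = field(default_factory=VolumeModel)
    volume_phenotype_coupling: float = 1.0  # mean multiplier for phenotype 1; 1.0 = off
    phi_true: list[np.ndarray] | None = None  # optional explicit per-question phi
    seed: int = 0

    def validate(self) -> None:
        if self.K_true < 1:
            raise ConfigurationError("K_true must be >= 1")
        if self.alpha_true <= 0 or self.beta_true <= 0:
            raise ConfigurationError("Dirichlet concentrations must be > 0")
        if self.D < 1:
            raise ConfigurationError("D must be >= 1")
        if self.volume_phenotype_coupling <= 0:
            raise ConfigurationError("volume_phenotype_coupling must be > 0")


def well_separated_config(**overrides) -> GeneratorConfig:
    """Preset with phi ~ Dirichlet(0.01): phenotypes identifiable at desk scale."""
    cfg = GeneratorConfig(beta_true=0.01, **overrides)
    return cfg


@dataclass
class SyntheticGroundTruth:
    """Latent variables behind a sampled corpus."""

    phi_true: list[np.ndarray]      # per question: (K, V_q), rows sum to 1
    theta_true: np.ndarray          # (D, K), rows sum to 1
    z_counts: np.ndarray            # (D, K) token tallies per phenotype
    dominant_phenotype: np.ndarray  # (D,) argmax of theta_true, ties -> lowest index
    participant_ids: list[str]

    @property
    def K(self) -> int:
        return self.theta_true.shape[1]

    def majority_label(self) -> np.ndarray:
        """Per-participant majority phenotype of the true token labels."""
        return self.z_counts.argmax(axis=1)


def sample_corpus(
    config: GeneratorConfig, schema: list[QuestionSchema] | None = None
) -> tuple[Corpus, SyntheticGroundTruth]:
    """Draw a corpus and its ground truth from the generative model."""
    config.validate()
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(config.seed)
    K = config.K_true

    if config.phi_true is not None:
        phi = [np.asarray(p, dtype=float) for p in config.phi_true]
        for q, p in zip(schema, phi):
            if p.shape != (K, q.size):
                raise ConfigurationError(
                    f"phi_true for question {q.question_id!r} must be (K, V_q)"
                )
    else:
        phi = [
            rng.dirichlet(np.full(q.size, config.beta_true), size=K) for q in schema
        ]

    theta = rng.dirichlet(np.full(K, config.alpha_true), size=config.D)
    dominant = theta.argmax(axis=1)

    # Per-question volumes; optional coupling doubles (etc.) the mean for
    # participants whose dominant phenotype is phenotype 1 (index 0).
    scale = np.ones(config.D)
    if config.volume_phenotype_coupling != 1.0:
        scale = np.where(dominant == 0, config.volume_phenotype_coupling, 1.0)
    counts_per_q = {
        q.question_id: config.volume_model.sample_counts(
            rng, q.question_id, config.D, scale
        )
        for q in schema
    }

    ids = [f"p{d:05d}" for d in range(config.D)]
    z_counts = np.zeros((config.D, K), dtype=np.int64)
    participants: list[ParticipantRecord] = []
    for d in range(config.D):
        answers: dict[str, dict[str, int]] = {}
        for qi, q in enumerate(schema):
            n = int(counts_per_q[q.question_id][d])
            if n == 0:
                continue
            z = rng.choice(K, size=n, p=theta[d])
            np.add.at(z_counts[d], z, 1)
            tokens: dict[str, int] = {}
            for k in range(K):
                nk = int((z == k).sum())
                if nk == 0:
                    continue
                v_counts = rng.multinomial(nk, phi[qi][k])
                for v in np.nonzero(v_counts)[0]:
                    tok = q.vocabulary[v]
                    tokens[tok] = tokens.get(tok, 0) + int(v_counts[v])
            answers[q.question_id] = tokens
        n_obs = sum(c for t in answers.values() for c in t.values())
        days = int(max(1, rng.poisson(config.volume_model.days_mean))) if n_obs else 0
        participants.append(
            ParticipantRecord(participant_id=ids[d], answers=answers, days_tracked=days)
        )

    truth = SyntheticGroundTruth(
        phi_true=phi,
        theta_true=theta,
        z_counts=z_counts,
        dominant_phenotype=dominant,
        participant_ids=ids,
    )
    return Corpus(schema=list(schema), participants=participants), truth


# ---------------------------------------------------------------------------
# Survey covariates


@dataclass
class CovariateSpec:
    """One survey covariate and how its distribution shifts by phenotype.

    Categorical: ``levels`` plus per-phenotype level probabilities (K, L);
    effect_size 0 collapses all rows to the base distribution.  Continuous:
    normal with per-phenotype location shift of ``effect_size`` standard
    deviations for phenotype 1 (index 0).
    """

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] | None = None
    level_probs: np.ndarray | None = None  # (K, L)
    mean: float = 0.0
    sd: float = 1.0
    effect_size: float = 0.0
    missingness: float = 0.0

    def validate(self, K: int) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ConfigurationError(f"unknown covariate type {self.kind!r}")
        if not 0 <= self.missingness < 1:
            raise ConfigurationError("missingness must be in [0, 1)")
        if self.kind == "categorical":
            probs = np.asarray(self.level_probs, dtype=float)
            if probs.shape != (K, len(self.levels)):
                raise ConfigurationError(
                    f"covariate {self.name!r}: level_probs must be (K, L)"
                )
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigurationError(
                    f"covariate {self.name!r}: level distributions must be simplices"
                )


def null_covariates(K: int, n_categorical: int = 3, n_continuous: int = 2,
                    n_levels: int = 3) -> list[CovariateSpec]:
    """Covariates with zero phenotype effect (type-I-error fixtures)."""
    base = np.full(n_levels, 1.0 / n_levels)
    specs = [
        CovariateSpec(
            name=f"cat{i}",
            kind="categorical",
            levels=tuple(f"l{j}" for j in range(n_levels)),
            level_probs=np.tile(base, (K, 1)),
        )
        for i in range(n_categorical)
    ]
    specs += [
        CovariateSpec(name=f"num{i}", kind="continuous", mean=0.0, sd=1.0)
        for i in range(n_continuous)
    ]
    return specs


def strong_binary_covariate(K: int, name: str = "flag",
                            p_pheno1: float = 0.9) -> CovariateSpec:
    """Binary covariate with probability ``p_pheno1`` under phenotype 1 and
    ``1 - p_pheno1`` under every other phenotype."""
    probs = np.full((K, 2), (1 - p_pheno1, p_pheno1))
    probs[0] = (p_pheno1, 1 - p_pheno1)
    probs[:, 1] = 1 - probs[:, 0]
    return CovariateSpec(
        name=name, kind="categorical", levels=("yes", "no"),
        level_probs=probs, effect_size=1.0,
    )


def sample_survey(
    truth: SyntheticGroundTruth, specs: list[CovariateSpec], seed: int
) -> pd.DataFrame:
    """Survey table keyed by participant_id; missing cells are NaN."""
    rng = np.random.default_rng(seed)
    K = truth.K
    dom = truth.dominant_phenotype
    D = len(dom)
    data: dict[str, object] = {"participant_id": truth.participant_ids}
    for spec in specs:
        spec.validate(K)
        if spec.kind == "categorical":
            probs = np.asarray(spec.level_probs, dtype=float)
            col = np.array(
                [spec.levels[rng.choice(len(spec.levels), p=probs[dom[d]])]
                 for d in range(D)],
                dtype=object,
            )
        else:
            shift = np.where(dom == 0, spec.effect_size * spec.sd, 0.0)
            col = rng.normal(spec.mean + shift, spec.sd)
        if spec.missingness > 0:
            mask = rng.random(D) < spec.missingness
            col = pd.array(col)
            col[mask] = pd.NA if spec.kind == "categorical" else np.nan
        data[spec.name] = col
    return pd.DataFrame(data)
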