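"""Data model and I/O for multi-question self-tracking corpora.

A corpus holds, per participant, a bag of categorical answers to each of Q
questions, where each question has its own closed vocabulary.  This is the
"documents" view of self-tracked symptom data: the model downstream is
exchangeable over tokens, so answers are stored as (token, count) multisets
and any timestamps in the raw data survive only as a per-participant count
of distinct tracking days.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus file or record."""


class ValidationError(CorpusError):
    """A record violates a corpus invariant (e.g. out-of-vocabulary token)."""


@dataclass(frozen=True)
class QuestionSchema:
    """One question: its identifier, prompt and closed answer vocabulary."""

    question_id: str
    prompt: str
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        if len(self.vocabulary) < 2:
            raise ValidationError(
                f"question {self.question_id!r}: vocabulary must have >= 2 entries"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValidationError(
                f"question {self.question_id!r}: duplicate vocabulary entries"
            )

    @property
    def size(self) -> int:
        return len(self.vocabulary)


@dataclass
class ParticipantRecord:
    """One participant's answer multisets plus tracking-volume metadata.

    ``answers`` maps question_id -> {token: count}; ``n_observations`` is
    always the sum of all counts.
    """

    participant_id: str
    answers: dict[str, dict[str, int]] = field(default_factory=dict)
    days_tracked: int = 0

    @property
    def n_observations(self) -> int:
        return sum(c for q in self.answers.values() for c in q.values())

    def question_count(self, question_id: str) -> int:
        return sum(self.answers.get(question_id, {}).values())


@dataclass
class Corpus:
    """A question schema plus a list of participant records."""

    schema: list[QuestionSchema]
    participants: list[ParticipantRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        qids = [q.question_id for q in self.schema]
        if len(qids) == 0:
            raise ValidationError("schema must contain at least one question")
        if len(set(qids)) != len(qids):
            raise ValidationError("question_ids must be unique within a schema")
        vocab = {q.question_id: set(q.vocabulary) for q in self.schema}
        seen_ids: set[str] = set()
        for p in self.participants:
            if p.participant_id in seen_ids:
                raise ValidationError(f"duplicate participant_id {p.participant_id!r}")
            seen_ids.add(p.participant_id)
            if p.days_tracked < 0:
                raise ValidationError(
                    f"participant {p.participant_id!r}: days_tracked < 0"
                )
            for qid, counts in p.answers.items():
                if qid not in vocab:
                    raise ValidationError(
                        f"participant {p.participant_id!r}: unknown question {qid!r}"
                    )
                for token, count in counts.items():
                    if token not in vocab[qid]:
                        raise ValidationError(
                            f"participant {p.participant_id!r}, question {qid!r}: "
                            f"token {token!r} not in vocabulary"
                        )
                    if not isinstance(count, int) or count < 1:
                        raise ValidationError(
                            f"participant {p.participant_id!r}, question {qid!r}, "
                            f"token {token!r}: count must be a positive integer"
                        )

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_questions(self) -> int:
        return len(self.schema)

    @property
    def total_observations(self) -> int:
        return sum(p.n_observations for p in self.participants)

    @property
    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.schema]

    def question(self, question_id: str) -> QuestionSchema:
        for q in self.schema:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)

    def nonempty_participants(self) -> list[ParticipantRecord]:
        """Participants with at least one observation (the modelled subset)."""
        kept = [p for p in self.participants if p.n_observations > 0]
        dropped = len(self.participants) - len(kept)
        if dropped:
            logger.info("excluding %d participant(s) with zero observations", dropped)
        return kept


# The study's 13 tracked questions.  The answer vocabularies themselves are
# not public; placeholder tokens are generated with the correct per-question
# sizes (summing to 202).  MEAN_OBSERVATIONS carries the printed per-question
# mean observation counts used to calibrate the synthetic volume model.
DEFAULT_QUESTIONS: list[tuple[str, str, int, float]] = [
    ("pain_location", "Where is the pain?", 39, 31.0),
    ("pain_description", "Describe the pain.", 15, 29.0),
    ("pain_severity", "How severe is the pain?", 3, 10.0),
    ("other_symptom", "What are you experiencing?", 14, 9.0),
    ("symptom_severity", "How severe is the symptom?", 3, 5.0),
    ("period_flow", "Describe your period flow.", 21, 3.0),
    ("bleeding_kind", "What kind of bleeding.", 3, 2.0),
    ("gi_gu", "Describe GI/GU system.", 3, 7.0),
    ("gi_gu_severity", "How severe is it?", 3, 6.0),
    ("sex", "Describe sex.", 6, 1.0),
    ("difficult_activity", "Activities difficult to perform.", 23, 42.0),
    ("medication", "Medications/hormones taken.", 64, 15.0),
    ("day_quality", "How was your day?", 5, 13.0),
]


def default_schema() -> list[QuestionSchema]:
    """The 13-question self-tracking schema with placeholder vocabularies."""
    return [
        QuestionSchema(
            question_id=qid,
            prompt=prompt,
            vocabulary=tuple(f"{qid}_a{i:02d}" for i in range(size)),
        )
        for qid, prompt, size, _ in DEFAULT_QUESTIONS
    ]


def default_question_means() -> dict[str, float]:
    """Per-question mean observation counts used as volume-model defaults."""
    return {qid: mean for qid, _, _, mean in DEFAULT_QUESTIONS}


# ---------------------------------------------------------------------------
# I/O


def _schema_to_json(schema: list[QuestionSchema]) -> list[dict]:
    return [
        {"question_id": q.question_id, "prompt": q.prompt, "vocabulary": list(q.vocabulary)}
        for q in schema
    ]


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus to the documented JSON format (UTF-8)."""
    payload = {
        "schema": _schema_to_json(corpus.schema),
        "participants": [
            {
                "participant_id": p.participant_id,
                "days_tracked": p.days_tracked,
                "answers": {q: dict(c) for q, c in p.answers.items() if c},
            }
            for p in corpus.participants
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_corpus(path: str | Path) -> Corpus:
    """Load and validate a corpus from its JSON file format."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusError(f"{path}: not valid JSON ({exc})") from exc
    try:
        schema = [
            QuestionSchema(q["question_id"], q.get("prompt", ""), tuple(q["vocabulary"]))
            for q in payload["schema"]
        ]
        participants = [
            ParticipantRecord(
                participant_id=p["participant_id"],
                answers={q: {t: int(c) for t, c in counts.items()}
                         for q, counts in p.get("answers", {}).items()},
                days_tracked=int(p.get("days_tracked", 0)),
            )
            for p in payload["participants"]
        ]
    except (KeyError, TypeError) as exc:
        raise CorpusError(f"{path}: malformed corpus record ({exc!r})") from exc
    return Corpus(schema=schema, participants=participants)


# ---------------------------------------------------------------------------
# Summary statistics and the concatenated-vocabulary view


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """Per-question summary table of observation and tracking-day counts.

    One row per question plus a ``Total`` row; means are taken over all
    participants, counting zeros.  Day statistics attribute a participant's
    ``days_tracked`` to every question that participant answered at least
    once (per-question day-level detail is not retained in the bag-of-answers
    data model).
    """
    rows = []
    D = max(corpus.n_participants, 1)
    total = {"n_obs_mean": 0.0, "n_obs_max": 0, "n_days_mean": 0.0, "n_days_max": 0}
    for q in corpus.schema:
        obs = [p.question_count(q.question_id) for p in corpus.participants]
        days = [
            p.days_tracked if p.question_count(q.question_id) > 0 else 0
            for p in corpus.participants
        ]
        if not obs:
            obs, days = [0], [0]
        row = {
            "question_id": q.question_id,
            "n_obs_mean": sum(obs) / D,
            "n_obs_max": max(obs),
            "n_days_mean": sum(days) / D,
            "n_days_max": max(days),
        }
        rows.append(row)
        for k in total:
            total[k] += row[k]
    rows.append({"question_id": "Total", **total})
    return pd.DataFrame(rows)


def concatenate_view(corpus: Corpus) -> Corpus:
    """Single-question view with the concatenation of all vocabularies.

    This is the input representation of the vanilla-LDA baseline: every
    participant becomes one multinomial over a vocabulary of size sum_q V_q,
    with tokens namespaced ``questionid.token`` to keep them globally unique.
    """
    vocab = tuple(
        f"{q.question_id}.{token}" for q in corpus.schema for token in q.vocabulary
    )
    question = QuestionSchema(
        question_id="all",
        prompt="All questions, concatenated vocabularies.",
        vocabulary=vocab,
    )
    participants = [
        ParticipantRecord(
            participant_id=p.participant_id,
            answers={
                "all": {
                    f"{qid}.{token}": count
                    for qid, counts in p.answers.items()
                    for token, count in counts.items()
                }
            }
            if p.answers
            else {},
            days_tracked=p.days_tracked,
        )
        for p in corpus.participants
    ]
    return Corpus(schema=[question], participants=participants)
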