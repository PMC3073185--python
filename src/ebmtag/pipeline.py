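"""Experiment orchestration: tasks, folds, training, prediction, CV.

Two classification tasks are supported: *six-way* labels every sentence
(including non-key sentences as Other); *five-way* labels key sentences only
— the Other component is dropped from every gold set, sentences left with no
gold label are removed from the sequence, and emptied abstracts disappear.

Cross-validation splits at the abstract level (an abstract's sentences never
straddle folds) and pools every test-instance prediction into one
micro-averaged report.

When direct sequential features are active the classifier is a two-stage
stack: a base CRF trained on the basic feature set B supplies predicted
previous-sentence labels, which are appended as features for the stage-two
CRF.  During training those base predictions come from internal 5-fold
prediction over the training set — never from gold labels, which would make
the feature unrealistically reliable at training time and useless at test
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import crf
from .corpus import Abstract, Corpus, KEY_LABELS, LABELS, Label, Sentence
from .crf import CRFModel, IndexedSequence, TrainSettings
from .features import FeatureConfig, FeatureVector, Resources, assemble_sequence, build_preset
from .evaluation import EvalReport, score_predictions

Mode = Literal["six_way", "five_way"]
Partition = Literal["S", "U", "all"]

DEFAULT_FOLD_SEED = 13
_BASE_PRESET = "B"  # feature set of the stacked base learner
_STACK_FOLDS = 5  # internal folds for base-learner predictions


@dataclass(frozen=True)
class TaskSpec:
    mode: Mode = "six_way"
    partition: Partition = "all"
    config: FeatureConfig = field(default_factory=lambda: build_preset("1.P"))
    folds: int = 10
    seed: int = DEFAULT_FOLD_SEED
    train_settings: TrainSettings = field(default_factory=TrainSettings)

    @property
    def labels(self) -> tuple[Label, ...]:
        return LABELS if self.mode == "six_way" else KEY_LABELS


def make_task_dataset(corpus: Corpus, spec: TaskSpec) -> Corpus:
    """Project a corpus onto the task's label set.

    six_way: identity.  five_way: Other is removed from every gold set;
    sentences whose gold set becomes empty are dropped and indices re-packed;
    abstracts emptied entirely are dropped.
    """
    if spec.mode == "six_way":
        return corpus
    abstracts: list[Abstract] = []
    for abstract in corpus:
        kept: list[Sentence] = []
        for sent in abstract.sentences:
            gold = [l for l in sent.gold_labels if l is not Label.OTHER]
            if not gold:
                continue
            kept.append(
                Sentence(
                    index=len(kept),
                    text=sent.text,
                    tokens=list(sent.tokens),
                    heading=sent.heading,
                    gold_labels=gold,
                    predicted_label=sent.predicted_label,
                )
            )
        if kept:
            abstracts.append(
                Abstract(
                    id=abstract.id,
                    sentences=kept,
                    is_structured=abstract.is_structured,
                )
            )
    return Corpus(abstracts, provenance=f"{corpus.provenance} [5-way]")


def assign_folds(corpus: Corpus, folds: int, seed: int) -> dict[str, int]:
    """Abstract-level fold assignment; sizes differ by at most one.

    A pure function of the abstract ids and the seed: ids are shuffled by a
    seeded generator and dealt round-robin.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids = [a.id for a in corpus]
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} abstracts for {folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    return {ids[int(pos)]: i % folds for i, pos in enumerate(order)}


# ---------------------------------------------------------------------------
# Feature indexing
# ---------------------------------------------------------------------------


def _build_index(vector_seqs: Sequence[Sequence[FeatureVector]]) -> dict[str, int]:
    names = sorted({f for seq in vector_seqs for vec in seq for f in vec})
    return {name: i for i, name in enumerate(names)}


def _to_indexed(
    vectors: Sequence[FeatureVector],
    golds: Sequence[Label],
    feature_index: dict[str, int],
    label_pos: dict[Label, int],
) -> IndexedSequence:
    feats = tuple(
        tuple(sorted(feature_index[f] for f in vec if f in feature_index))
        for vec in vectors
    )
    return IndexedSequence(feats, tuple(label_pos[g] for g in golds))


@dataclass
class ModelBundle:
    """A trained classifier: one CRF, or a (base, stage-two) stacked pair."""

    spec: TaskSpec
    model: CRFModel
    base_model: CRFModel | None = None
    base_config: FeatureConfig | None = None

    @property
    def models(self) -> list[CRFModel]:
        return [m for m in (self.base_model, self.model) if m is not None]

    @property
    def labels(self) -> tuple[Label, ...]:
        return self.spec.labels


def _train_single(
    abstracts: Sequence[Abstract],
    config: FeatureConfig,
    labels: Sequence[Label],
    resources: Resources,
    settings: TrainSettings,
    base_predictions: dict[str, list[Label]] | None = None,
) -> CRFModel:
    label_pos = {lab: i for i, lab in enumerate(labels)}
    vector_seqs = [
        assemble_sequence(
            a,
            config,
            resources,
            base_predictions[a.id] if base_predictions is not None else None,
        )
        for a in abstracts
    ]
    feature_index = _build_index(vector_seqs)
    data = [
        _to_indexed(vecs, [s.primary_gold for s in a.sentences], feature_index, label_pos)
        for a, vecs in zip(abstracts, vector_seqs)
    ]
    return crf.train(data, [l.value for l in labels], feature_index, settings)


def _decode(
    model: CRFModel,
    abstract: Abstract,
    config: FeatureConfig,
    labels: Sequence[Label],
    resources: Resources,
    base_prediction: list[Label] | None = None,
) -> list[Label]:
    vectors = assemble_sequence(abstract, config, resources, base_prediction)
    label_pos = {lab: i for i, lab in enumerate(labels)}
    seq = _to_indexed(
        vectors, [labels[0]] * len(vectors), model.feature_index, label_pos
    )
    path, _ = crf.viterbi(model, seq)
    return [labels[i] for i in path]


def train_stage(
    corpus: Corpus,
    spec: TaskSpec,
    resources: Resources | None = None,
) -> ModelBundle:
    """Train the classifier described by ``spec`` on the whole given corpus.

    Without direct features this is one CRF over the assembled features.
    With them, the returned bundle holds a base CRF (basic set B, trained on
    all of ``corpus``) and a stage-two CRF whose training vectors were
    augmented with direct features computed from internal 5-fold base-learner
    predictions over the training set.
    """
    resources = resources or Resources()
    labels = spec.labels
    abstracts = list(corpus)
    if not abstracts:
        raise ValueError("cannot train on an empty corpus")

    if spec.config.direct_window == 0:
        model = _train_single(
            abstracts, spec.config, labels, resources, spec.train_settings
        )
        return ModelBundle(spec=spec, model=model)

    if len(abstracts) < _STACK_FOLDS:
        raise ValueError(
            f"two-stage training needs >= {_STACK_FOLDS} abstracts for "
            "internal stacking folds"
        )
    base_config = replace(build_preset(_BASE_PRESET), preset_name=None)

    # Internal 5-fold predictions over the training set: the base learner
    # never sees the abstract it predicts, mirroring its test-time behavior.
    inner = assign_folds(corpus, _STACK_FOLDS, spec.seed + 1)
    base_predictions: dict[str, list[Label]] = {}
    for k in range(_STACK_FOLDS):
        train_k = [a for a in abstracts if inner[a.id] != k]
        test_k = [a for a in abstracts if inner[a.id] == k]
        model_k = _train_single(
            train_k, base_config, labels, resources, spec.train_settings
        )
        for a in test_k:
            base_predictions[a.id] = _decode(
                model_k, a, base_config, labels, resources
            )

    base_model = _train_single(
        abstracts, base_config, labels, resources, spec.train_settings
    )
    stage2 = _train_single(
        abstracts,
        spec.config,
        labels,
        resources,
        spec.train_settings,
        base_predictions=base_predictions,
    )
    return ModelBundle(
        spec=spec, model=stage2, base_model=base_model, base_config=base_config
    )


def predict(
    bundle: ModelBundle,
    abstract: Abstract,
    resources: Resources | None = None,
) -> list[Label]:
    """One label per sentence by Viterbi decoding.

    For stacked bundles the base model decodes first and its labels feed the
    direct features of the stage-two decoder; direct features of sentence i
    therefore depend on base predictions only, never on stage-two outputs.
    """
    resources = resources or Resources()
    labels = bundle.labels
    base_prediction = None
    if bundle.base_model is not None:
        base_prediction = _decode(
            bundle.base_model, abstract, bundle.base_config, labels, resources
        )
    return _decode(
        bundle.model, abstract, bundle.spec.config, labels, resources, base_prediction
    )


def cross_validate(
    corpus: Corpus,
    spec: TaskSpec,
    resources: Resources | None = None,
) -> EvalReport:
    """Abstract-level k-fold CV, pooling all test predictions (micro-average).

    For each fold the classifier (including any internal stacking) is trained
    on the remaining folds only, then decodes the held-out abstracts; pooled
    gold sets and predictions go through the standard scorer.
    """
    resources = resources or Resources()
    task_corpus = make_task_dataset(corpus, spec)
    folds = assign_folds(task_corpus, spec.folds, spec.seed)
    gold_sets: list[list[Label]] = []
    predictions: list[Label] = []
    for k in range(spec.folds):
        train_k = Corpus(
            [a for a in task_corpus if folds[a.id] != k],
            provenance=f"fold {k} train",
        )
        bundle = train_stage(train_k, spec, resources)
        for abstract in (a for a in task_corpus if folds[a.id] == k):
            pred = predict(bundle, abstract, resources)
            for sent, p in zip(abstract.sentences, pred):
                gold_sets.append(list(sent.gold_labels))
                predictions.append(p)
    return score_predictions(
        gold_sets,
        predictions,
        labels=spec.labels,
        metadata={
            "mode": spec.mode,
            "partition": spec.partition,
            "preset": spec.config.preset_name,
            "folds": spec.folds,
            "seed": spec.seed,
        },
    )
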