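import numpy as np
import pytest
from hypothesis import settings

import ebmtag as et
from ebmtag.corpus import Abstract, Corpus, Label, Sentence, Token, default_tagger, tokenize
from ebmtag.crf import TrainSettings
from ebmtag.synthetic import GeneratorConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_sentence(text, labels, index=0, heading=None):
    """Tokenized, tagged sentence with the given gold labels."""
    surfaces = tokenize(text)
    tags = default_tagger(surfaces) if surfaces else []
    return Sentence(
        index=index,
        text=text,
        tokens=[Token(s, t) for s, t in zip(surfaces, tags)],
        heading=heading,
        gold_labels=[Label(l) if isinstance(l, str) else l for l in labels],
    )


def make_abstract(rows, abstract_id="a1"):
    """rows: list of (text, labels) or (text, labels, heading)."""
    sentences = [
        make_sentence(row[0], row[1], index=i, heading=row[2] if len(row) > 2 else None)
        for i, row in enumerate(rows)
    ]
    return Abstract(
        id=abstract_id,
        sentences=sentences,
        is_structured=any(s.heading for s in sentences),
    )


@pytest.fixture(scope="session")
def fast_settings():
    return TrainSettings(max_iterations=60)


@pytest.fixture(scope="session")
def paperlike_corpus():
    """120 abstracts from the default realistic generator settings."""
    config = et.default_paperlike_config(n_abstracts=120, seed=5)
    corpus, ledger = et.generate_corpus(config)
    return corpus, ledger


def separable_config(n_abstracts=30, seed=1):
    """Each label emits a unique indicator word and all labels are equally
    frequent: Bayes error is zero and every CV fold sees every label."""
    L = len(et.LABELS)
    uniform = np.full((L + 1, L), 1.0 / L)
    return GeneratorConfig(
        n_abstracts=n_abstracts,
        sentences_per_abstract=(4, 8),
        label_transition=uniform,
        vocab_per_class={lab: {f"ind{i}": 1.0} for i, lab in enumerate(et.LABELS)},
        shared_vocab=("filler",),
        words_per_sentence=(3, 5),
        class_word_prob=1.0,
        p_structured=0.0,
        p_multilabel=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def separable_corpus():
    corpus, _ = et.generate_corpus(separable_config())
    return corpus


def random_crf_model(rng, L, F, scale=1.0):
    from ebmtag.crf import CRFModel

    return CRFModel(
        labels=[f"l{i}" for i in range(L)],
        feature_index={f"f{i}": i for i in range(F)},
        state_weights=scale * rng.normal(size=(F, L)),
        transition_weights=scale * rng.normal(size=(L + 1, L)),
    )


def random_indexed_sequence(rng, n, L, F, max_active=3):
    from ebmtag.crf import IndexedSequence

    feats = tuple(
        tuple(
            sorted(
                rng.choice(F, size=rng.integers(0, max_active + 1), replace=False)
                .astype(int)
                .tolist()
            )
        )
        for _ in range(n)
    )
    labels = tuple(int(x) for x in rng.integers(0, L, size=n))
    return IndexedSequence(feats, labels)
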