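"""Scoring for EBM sentence classification.

The scoring semantics follow the multi-label evaluation convention for this
task: every sentence receives exactly one predicted label but may carry
several gold labels.  A prediction is a true positive for class c iff it
equals c and c is in the sentence's gold set.  Per-class precision divides
true positives by the number of sentences *predicted* as the class; recall
divides by the number of gold label *instances* of the class (so a sentence
with two gold labels contributes twice to the gold totals, which is why
micro-averaged recall can fall below micro precision).  Micro averages pool
counts over all test instances before dividing; the f-score is the harmonic
mean of precision and recall.

Confusion matrices are single-gold: each sentence is attributed to its
primary (first-listed) gold label, so row sums equal per-class primary
sentence counts.  Two published six-way benchmark confusion matrices (one
for structured, one for unstructured abstracts) ship as package fixtures.

Cohen's kappa measures chance-corrected agreement between two annotators,
computed per class from 2x2 presence/absence tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import LABEL_NAMES, Label


def round2(x: float) -> float:
    """Round half-up to 2 decimals, as printed in reports."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _prf_raw(tp: int, predicted: int, gold: int) -> tuple[float, float, float]:
    p = 100.0 * tp / predicted if predicted else 0.0
    r = 100.0 * tp / gold if gold else 0.0
    f = 2.0 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


def class_prf(tp: int, predicted: int, gold: int) -> tuple[float, float, float]:
    """Per-class precision, recall, f-score as percents (2 decimals).

    Zero denominators yield 0.0 rather than an error.  Internally unrounded
    values are used everywhere; rounding happens only here, at the reporting
    surface.
    """
    if tp < 0 or tp > min(predicted, gold):
        raise ValueError("tp must satisfy 0 <= tp <= min(predicted, gold)")
    return tuple(round2(v) for v in _prf_raw(tp, predicted, gold))


@dataclass
class ClassCounts:
    label: Label
    tp: int = 0
    predicted: int = 0
    gold: int = 0

    @property
    def prf(self) -> tuple[float, float, float]:
        return class_prf(self.tp, self.predicted, self.gold)


@dataclass
class ConfusionMatrix:
    """L x L single-gold matrix: cell (i, j) = gold class i predicted as j."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        L = len(self.labels)
        if self.counts.shape != (L, L):
            raise ValueError("confusion matrix must be square over the label axis")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> dict[str, int]:
        return {l: int(s) for l, s in zip(self.labels, self.counts.sum(axis=1))}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ConfusionMatrix":
        """Read a TSV with a header row/column of label names ('#' comments)."""
        text = Path(path).read_text(encoding="utf-8")
        return cls._from_text(text)

    @classmethod
    def _from_text(cls, text: str) -> "ConfusionMatrix":
        rows = [
            r
            for r in csv.reader(text.splitlines(), delimiter="\t")
            if r and not r[0].startswith("#")
        ]
        header = rows[0][1:]
        labels, counts = [], []
        for row in rows[1:]:
            labels.append(row[0])
            counts.append([int(v) for v in row[1:]])
        if labels != header:
            raise ValueError("row and column label order must agree")
        return cls(labels=labels, counts=np.array(counts, dtype=int))

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.counts):
                fh.write(label + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def load_benchmark_matrix(kind: str) -> ConfusionMatrix:
    """Load a bundled published benchmark matrix: 'structured'|'unstructured'."""
    names = {
        "structured": "confusion_structured_6way.tsv",
        "unstructured": "confusion_unstructured_6way.tsv",
    }
    try:
        fname = names[kind]
    except KeyError:
        raise KeyError(f"kind must be one of {sorted(names)}") from None
    ref = importlib_resources.files("ebmtag.data") / fname
    return ConfusionMatrix._from_text(ref.read_text(encoding="utf-8"))


@dataclass
class EvalReport:
    per_class: list[ClassCounts]
    matrix: ConfusionMatrix
    metadata: dict = field(default_factory=dict)

    @property
    def micro_counts(self) -> tuple[int, int, int]:
        return (
            sum(c.tp for c in self.per_class),
            sum(c.predicted for c in self.per_class),
            sum(c.gold for c in self.per_class),
        )

    @property
    def micro_precision(self) -> float:
        return round2(_prf_raw(*self.micro_counts)[0])

    @property
    def micro_recall(self) -> float:
        return round2(_prf_raw(*self.micro_counts)[1])

    @property
    def micro_f(self) -> float:
        return round2(_prf_raw(*self.micro_counts)[2])

    def to_json(self) -> dict:
        per_class = {}
        for c in self.per_class:
            p, r, f = c.prf
            per_class[c.label.value] = {
                "tp": c.tp,
                "predicted": c.predicted,
                "gold": c.gold,
                "precision": p,
                "recall": r,
                "f": f,
            }
        return {
            "per_class": per_class,
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f": self.micro_f,
            },
            "confusion": {
                "labels": self.matrix.labels,
                "counts": self.matrix.counts.tolist(),
            },
            "metadata": self.metadata,
        }


def score_predictions(
    gold: Sequence[Iterable[Label]],
    predicted: Sequence[Label],
    labels: Sequence[Label] | None = None,
    metadata: dict | None = None,
) -> EvalReport:
    """Score one prediction per sentence against (possibly multi-) gold sets.

    ``gold[i]`` is the ordered gold label set of sentence i (first element
    primary), ``predicted[i]`` the single predicted label.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    labels = list(labels) if labels is not None else list(Label)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = {lab: ClassCounts(lab) for lab in labels}
    matrix = np.zeros((len(labels), len(labels)), dtype=int)
    for gold_set, pred in zip(gold, predicted):
        gold_list = list(gold_set)
        if not gold_list:
            raise ValueError("gold sets must be non-empty")
        counts[pred].predicted += 1
        for g in gold_list:
            counts[g].gold += 1
        if pred in gold_list:
            counts[pred].tp += 1
        matrix[idx[gold_list[0]], idx[pred]] += 1
    return EvalReport(
        per_class=[counts[lab] for lab in labels],
        matrix=ConfusionMatrix(labels=[l.value for l in labels], counts=matrix),
        metadata=metadata or {},
    )


def prf_from_matrix(
    matrix: ConfusionMatrix,
) -> dict[str, tuple[float, float, float]]:
    """Per-class (P, R, F) percents from a single-gold confusion matrix.

    tp = diagonal cell, predicted = column sum, gold = row sum.  Valid only
    for single-gold data, where each sentence carries exactly one gold label.
    """
    out: dict[str, tuple[float, float, float]] = {}
    col = matrix.counts.sum(axis=0)
    row = matrix.counts.sum(axis=1)
    for i, label in enumerate(matrix.labels):
        out[label] = class_prf(int(matrix.counts[i, i]), int(col[i]), int(row[i]))
    return out


@dataclass(frozen=True)
class AgreementTable:
    """2x2 presence/absence table for one class between two annotators.

    a = both annotators marked the class, b = first only, c = second only,
    d = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("agreement table must cover at least one sentence")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o = (a + d) / n; p_e = ((a+b)(a+c) + (c+d)(b+d)) / n^2.  When both
    annotators agree perfectly and chance agreement is also 1 (degenerate
    one-sided table), kappa is defined as 1.0.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_per_class(
    first: Sequence[Iterable[Label]],
    second: Sequence[Iterable[Label]],
    labels: Sequence[Label] | None = None,
) -> tuple[dict[Label, float], float]:
    """Per-class kappa between two annotations plus the unweighted mean.

    ``first[i]``/``second[i]`` are the label sets each annotator assigned to
    sentence i; each class is scored on its own presence/absence table.
    """
    if len(first) != len(second):
        raise ValueError("annotations must cover the same sentences")
    if not first:
        raise ValueError("no doubly-annotated sentences")
    labels = list(labels) if labels is not None else list(Label)
    per: dict[Label, float] = {}
    for lab in labels:
        a = b = c = d = 0
        for s1, s2 in zip(first, second):
            in1, in2 = lab in set(s1), lab in set(s2)
            a += in1 and in2
            b += in1 and not in2
            c += in2 and not in1
            d += not in1 and not in2
        per[lab] = cohens_kappa(AgreementTable(a, b, c, d))
    return per, float(np.mean(list(per.values())))
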