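"""Reference linear-chain conditional random field.

A first-order chain CRF over sentences: the label at each position depends on
that position's sparse binary features (state weights) and on the previous
label (transition weights, with a dedicated begin-of-sequence row).  The
conditional probability of a label path y given observations x is

    P(y | x) = exp(score(x, y)) / Z(x),
    score(x, y) = sum_t [ sum_{f in x_t} w_state[f, y_t] + w_trans[y_{t-1}, y_t] ]

with y_{-1} the begin symbol and Z(x) the sum of exp-scores over all L^n
paths, computed by the forward recursion in log space.  Training minimizes
the negative log-likelihood with a Gaussian prior (L2 penalty ||w||^2 / 2s^2)
by deterministic quasi-Newton (L-BFGS) from zero initialization; decoding is
Viterbi with ties broken toward the lowest label id.

Everything here is dense-in-labels, sparse-in-features: feature ids are dense
integers from the model's feature index, and unseen test-time features are
simply dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexedSequence:
    """One training/decoding sequence in dense-id form.

    ``features[t]`` is the sorted tuple of active feature ids at position t;
    ``labels[t]`` the gold label id (ignored at decode time).
    """

    features: tuple[tuple[int, ...], ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValueError("sequence must have length >= 1")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class TrainSettings:
    max_iterations: int = 500
    convergence_tol: float = 1e-5  # on the gradient norm
    prior_variance: float = 1.0  # Gaussian prior sigma^2
    seed: int = 0  # unused by the deterministic optimizer; kept for the contract
    record_trace: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.convergence_tol <= 0 or self.prior_variance <= 0:
            raise ValueError("convergence_tol and prior_variance must be positive")


@dataclass
class CRFModel:
    """Trained chain-CRF parameters.

    ``transition_weights`` has shape (L+1, L): rows 0..L-1 are label-to-label
    transitions, row L is the begin-of-sequence transition.
    """

    labels: list[str]
    feature_index: dict[str, int]
    state_weights: np.ndarray  # (F, L)
    transition_weights: np.ndarray  # (L+1, L)
    prior_variance: float = 1.0
    trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        L = len(self.labels)
        F = len(self.feature_index)
        self.state_weights = np.asarray(self.state_weights, dtype=float)
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        if self.state_weights.shape != (F, L):
            raise ValueError("state_weights must be (F, L)")
        if self.transition_weights.shape != (L + 1, L):
            raise ValueError("transition_weights must be (L+1, L)")
        if not (
            np.all(np.isfinite(self.state_weights))
            and np.all(np.isfinite(self.transition_weights))
        ):
            raise ValueError("weights must be finite")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def begin_row(self) -> int:
        return len(self.labels)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "labels": self.labels,
            "feature_index": self.feature_index,
            "state_weights": self.state_weights.tolist(),
            "transition_weights": self.transition_weights.tolist(),
            "prior_variance": self.prior_variance,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CRFModel":
        if obj.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(
            labels=list(obj["labels"]),
            feature_index={str(k): int(v) for k, v in obj["feature_index"].items()},
            state_weights=np.array(obj["state_weights"], dtype=float),
            transition_weights=np.array(obj["transition_weights"], dtype=float),
            prior_variance=float(obj["prior_variance"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CRFModel":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def _state_scores(model: CRFModel, seq: IndexedSequence) -> np.ndarray:
    """(n, L) matrix of summed state weights for the active features."""
    n, L = len(seq), model.n_labels
    scores = np.zeros((n, L))
    W = model.state_weights
    for t, fids in enumerate(seq.features):
        if fids:
            scores[t] = W[list(fids)].sum(axis=0)
    return scores


def score_sequence(
    model: CRFModel, seq: IndexedSequence, labels: Sequence[int]
) -> float:
    """Unnormalized log-potential of a label path."""
    L = model.n_labels
    if len(labels) != len(seq):
        raise ValueError("path length must equal sequence length")
    if any(not 0 <= y < L for y in labels):
        raise ValueError("label id out of range")
    state = _state_scores(model, seq)
    total = 0.0
    prev = model.begin_row
    for t, y in enumerate(labels):
        total += state[t, y] + model.transition_weights[prev, y]
        prev = y
    return float(total)


def log_partition(model: CRFModel, seq: IndexedSequence) -> float:
    """log Z(x) via the forward recursion in log space."""
    alpha = _forward(model, _state_scores(model, seq))
    return float(logsumexp(alpha[-1]))


def _forward(model: CRFModel, state: np.ndarray) -> np.ndarray:
    n, L = state.shape
    T = model.transition_weights
    alpha = np.empty((n, L))
    alpha[0] = T[model.begin_row] + state[0]
    for t in range(1, n):
        # alpha[t, y] = logsumexp_y'(alpha[t-1, y'] + T[y', y]) + state[t, y]
        alpha[t] = logsumexp(alpha[t - 1][:, None] + T[:L], axis=0) + state[t]
    return alpha


def _backward(model: CRFModel, state: np.ndarray) -> np.ndarray:
    n, L = state.shape
    T = model.transition_weights
    beta = np.zeros((n, L))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(T[:L] + (state[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def gradient(
    model: CRFModel, data: Sequence[IndexedSequence]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalized negative log-likelihood and its gradient.

    Returns ``(objective, grad_state (F,L), grad_transition (L+1,L))`` where
    objective = -sum_i log P(y_i | x_i) + ||w||^2 / (2 sigma^2) and the
    gradient is (model expectations - empirical counts) + w / sigma^2,
    computed with forward-backward marginals.
    """
    if not data:
        raise ValueError("data must be non-empty")
    L = model.n_labels
    Ws, Wt = model.state_weights, model.transition_weights
    grad_s = np.zeros_like(Ws)
    grad_t = np.zeros_like(Wt)
    nll = 0.0
    for seq in data:
        state = _state_scores(model, seq)
        alpha = _forward(model, state)
        beta = _backward(model, state)
        logZ = logsumexp(alpha[-1])
        nll += logZ - score_sequence(model, seq, seq.labels)
        node_marg = np.exp(alpha + beta - logZ)  # (n, L)
        n = len(seq)
        for t, fids in enumerate(seq.features):
            if fids:
                delta = node_marg[t].copy()
                delta[seq.labels[t]] -= 1.0
                np.add.at(grad_s, list(fids), delta)
        # begin-of-sequence edge
        grad_t[model.begin_row] += node_marg[0]
        grad_t[model.begin_row, seq.labels[0]] -= 1.0
        # interior edges: xi[t](y', y) marginals
        for t in range(1, n):
            edge = alpha[t - 1][:, None] + Wt[:L] + (state[t] + beta[t])[None, :]
            grad_t[:L] += np.exp(edge - logZ)
            grad_t[seq.labels[t - 1], seq.labels[t]] -= 1.0
    obj = nll + (np.sum(Ws**2) + np.sum(Wt**2)) / (2.0 * model.prior_variance)
    grad_s += Ws / model.prior_variance
    grad_t += Wt / model.prior_variance
    return float(obj), grad_s, grad_t


def train(
    data: Sequence[IndexedSequence],
    labels: Sequence[str],
    feature_index: dict[str, int],
    settings: TrainSettings = TrainSettings(),
) -> CRFModel:
    """Fit chain-CRF weights by penalized maximum likelihood.

    Deterministic: zero initialization and batch L-BFGS, stopping on the
    projected-gradient norm (``convergence_tol``) or ``max_iterations``.
    """
    if not data:
        raise ValueError("training data must be non-empty")
    L, F = len(labels), len(feature_index)
    for seq in data:
        if any(f >= F for fids in seq.features for f in fids):
            raise ValueError("feature id outside the feature index")
        if any(not 0 <= y < L for y in seq.labels):
            raise ValueError("label id outside the label set")

    model = CRFModel(
        labels=list(labels),
        feature_index=dict(feature_index),
        state_weights=np.zeros((F, L)),
        transition_weights=np.zeros((L + 1, L)),
        prior_variance=settings.prior_variance,
    )
    if settings.max_iterations == 0:
        return model

    n_state = F * L

    def unpack(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return w[:n_state].reshape(F, L), w[n_state:].reshape(L + 1, L)

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        model.state_weights, model.transition_weights = unpack(w)
        obj, gs, gt = gradient(model, data)
        return obj, np.concatenate([gs.ravel(), gt.ravel()])

    trace: list[float] = []

    def callback(wk: np.ndarray) -> None:
        if settings.record_trace:
            trace.append(objective(wk)[0])

    w0 = np.zeros(n_state + (L + 1) * L)
    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=callback if settings.record_trace else None,
        options={
            "maxiter": settings.max_iterations,
            "gtol": settings.convergence_tol,
            "ftol": 1e-12,
        },
    )
    model.state_weights, model.transition_weights = unpack(res.x)
    model.trace = trace
    return model


def viterbi(model: CRFModel, seq: IndexedSequence) -> tuple[list[int], float]:
    """Most probable label path and its unnormalized score.

    Ties are broken toward the lowest label id at every backpointer (argmax
    returns the first maximum), so an all-zero model decodes to all zeros.
    """
    state = _state_scores(model, seq)
    n, L = state.shape
    T = model.transition_weights
    delta = T[model.begin_row] + state[0]
    back = np.zeros((n, L), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + T[:L]  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(L)] + state[t]
    best_last = int(np.argmax(delta))
    path = [best_last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(delta[best_last])


class CRFBackend(Protocol):
    """Contract for pluggable sequence-labeling backends.

    The bundled reference implementation fulfils this contract; an external
    CRF toolkit can be swapped in by implementing the same two methods and
    must produce identical Viterbi paths on separable data.
    """

    def fit(
        self,
        data: Sequence[IndexedSequence],
        labels: Sequence[str],
        feature_index: dict[str, int],
        settings: TrainSettings,
    ) -> "CRFModel": ...

    def decode(self, model: "CRFModel", seq: IndexedSequence) -> list[int]: ...


class ReferenceBackend:
    """The in-package penalized-ML trainer and Viterbi decoder."""

    def fit(self, data, labels, feature_index, settings=TrainSettings()):
        return train(data, labels, feature_index, settings)

    def decode(self, model, seq):
        return viterbi(model, seq)[0]
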