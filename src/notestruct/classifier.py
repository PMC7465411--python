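"""Sentence-level multiclass subject-heading classifier.

Two interchangeable backends sit behind one estimator interface:

``bow_softmax``
    Multinomial logistic regression on bag-of-words counts, trained
    full-batch with Adam.  Fast enough for desk-scale experiments and CI;
    its output weight matrix has one row per heading of width ``|vocab|``.

``recurrent``
    A bidirectional Elman recurrent network over pretrained word
    embeddings: per-direction hidden state of width ``hidden_dim``, final
    states of the two directions concatenated and fed to a softmax output
    layer, trained with backpropagation through time and Adam.  Its output
    weight matrix has one row per heading of width ``2 * hidden_dim``.

In both cases the rows of the output layer act as learned semantic
representations of the subject headings: two headings with similar rows
receive similar probabilities for any input sentence, so headings used for
similar sentences end up close in this space.  :func:`heading_vectors`
extracts them for the downstream paragraph-merging and taxonomy analyses.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with a trailing
underscore) and is deterministic on CPU at a fixed ``seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from notestruct.corpus import LabeledCorpus, Sentence

__all__ = [
    "UNK",
    "ClassifierConfig",
    "ConfidenceProfile",
    "HeadingVectorSpace",
    "HeadingClassifier",
    "pretrain_embeddings",
    "train_classifier",
    "predict_confidences",
    "top_k",
    "heading_vectors",
]

UNK = "<unk>"


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters of the sentence classifier.

    ``embedding_dim`` and ``hidden_dim_per_direction`` default to the
    production-scale settings (300-d embeddings, 600-d per direction); tests
    and desk-scale runs shrink them.
    """

    embedding_dim: int = 300
    hidden_dim_per_direction: int = 600
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    backend: str = "recurrent"
    learning_rate: float = 0.01
    l2: float = 1e-4
    freeze_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.hidden_dim_per_direction < 1:
            raise ValueError("dimensions must be >= 1")
        if self.backend not in ("recurrent", "bow_softmax"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True, eq=False)
class ConfidenceProfile:
    """The classifier's probability distribution over all headings for one
    sentence."""

    heading_ids: tuple[str, ...]
    probs: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfidenceProfile):
            return NotImplemented
        return self.heading_ids == other.heading_ids and np.array_equal(self.probs, other.probs)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (len(self.heading_ids),):
            raise ValueError("probs must align with heading_ids")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")

    def prob_of(self, heading: str) -> float:
        return float(self.probs[self.heading_ids.index(heading)])

    def top(self) -> tuple[str, float]:
        h, p = top_k(self, 1)[0]
        return h, p


@dataclass(frozen=True)
class HeadingVectorSpace:
    """One real vector per heading, rows of the classifier's output layer."""

    heading_ids: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 2 or v.shape[0] != len(self.heading_ids):
            raise ValueError("vectors must be a (n_headings, width) matrix")
        if v.shape[1] < 1:
            raise ValueError("zero-width heading vectors")
        if len(set(self.heading_ids)) != len(self.heading_ids):
            raise ValueError("duplicate heading ids")

    def vector(self, heading: str) -> np.ndarray:
        return self.vectors[self.heading_ids.index(heading)]

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity between two heading vectors."""
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError(f"zero vector for heading {a if na == 0 else b!r}")
        return float(va @ vb / (na * nb))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for h, row in zip(self.heading_ids, self.vectors):
                fh.write(h + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Embedding pretraining (count-based: PPMI + truncated SVD)
# ---------------------------------------------------------------------------

def pretrain_embeddings(
    corpus: LabeledCorpus,
    dim: int,
    seed: int = 0,
    window: int = 5,
) -> tuple[list[str], np.ndarray]:
    """Pretrain word embeddings from sentence co-occurrence statistics.

    Builds a symmetric windowed co-occurrence matrix over the corpus
    vocabulary, applies positive pointwise mutual information (PPMI) and
    factorizes it with a truncated SVD; rows scaled by the square root of
    the singular values are the embeddings.  Tokens appearing in identical
    contexts receive identical vectors.  The reserved unknown token ``<unk>``
    (index 0) gets the zero vector.

    Returns ``(vocab, matrix)`` where ``vocab[0] == "<unk>"`` and ``matrix``
    has one row of width ``dim`` per vocabulary entry.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not corpus.records:
        raise ValueError("empty corpus")

    vocab_counts: dict[str, int] = {}
    for r in corpus.records:
        for t in r.sentence.tokens:
            vocab_counts[t] = vocab_counts.get(t, 0) + 1
    words = sorted(vocab_counts)
    vocab = [UNK] + words
    index = {w: i for i, w in enumerate(words)}
    V = len(words)

    cooc = np.zeros((V, V))
    for r in corpus.records:
        idx = [index[t] for t in r.sentence.tokens]
        for i, wi in enumerate(idx):
            for wj in idx[max(0, i - window) : i]:
                cooc[wi, wj] += 1.0
                cooc[wj, wi] += 1.0

    total = cooc.sum()
    if total == 0:  # single-token sentences only: fall back to identity-ish
        cooc = np.eye(V)
        total = V
    row = cooc.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    k = min(dim, V)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    emb_words = u[:, :k] * np.sqrt(s[:k])
    # deterministic sign convention: largest-|.| entry of each column positive
    for j in range(emb_words.shape[1]):
        col = emb_words[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            emb_words[:, j] = -col
    if k < dim:
        emb_words = np.hstack([emb_words, np.zeros((V, dim - k))])

    matrix = np.vstack([np.zeros((1, dim)), emb_words])
    return vocab, matrix


# ---------------------------------------------------------------------------
# Adam optimizer (shared by both backends)
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class HeadingClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass subject-heading classifier over tokenized sentences.

    Parameters
    ----------
    backend : {"bow_softmax", "recurrent"}
        Model family; see module docstring.
    embedding_dim, hidden_dim : int
        Embedding width and per-direction hidden width (recurrent backend).
    max_epochs, patience : int
        Optimization budget and early-stopping patience.  When a development
        set is passed to :meth:`fit`, the stopping metric is dev top-1
        accuracy and the best-epoch parameters are restored.
    learning_rate, l2 : float
        Adam step size and L2 penalty on the output layer.
    pretrained_embeddings : optional (vocab, matrix) pair
        Output of :func:`pretrain_embeddings`; used to initialize the
        embedding table of the recurrent backend.
    freeze_embeddings : bool
        Keep the embedding table fixed during training.
    seed : int
        Seed for parameter initialization and epoch shuffling.

    Attributes
    ----------
    classes_ : ndarray of heading ids (sorted)
    vocab_ : list of tokens, ``vocab_[0] == "<unk>"``
    output_weights_ : ndarray, one row per heading
        Width ``|vocab_|`` for bow_softmax, ``2 * hidden_dim`` for recurrent.
    history_ : list of per-epoch dicts (loss, dev accuracy)
    """

    def __init__(
        self,
        backend: str = "bow_softmax",
        embedding_dim: int = 300,
        hidden_dim: int = 600,
        max_epochs: int = 50,
        patience: int = 5,
        learning_rate: float = 0.01,
        l2: float = 1e-4,
        batch_size: int = 32,
        pretrained_embeddings: tuple[list[str], np.ndarray] | None = None,
        freeze_embeddings: bool = False,
        seed: int = 0,
    ):
        self.backend = backend
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.l2 = l2
        self.batch_size = batch_size
        self.pretrained_embeddings = pretrained_embeddings
        self.freeze_embeddings = freeze_embeddings
        self.seed = seed

    # -- vocabulary / featurization ------------------------------------

    def _build_vocab(self, X: Sequence[Sequence[str]]) -> None:
        tokens = sorted({t for toks in X for t in toks})
        self.vocab_ = [UNK] + tokens
        self._tok2idx = {t: i for i, t in enumerate(self.vocab_)}

    def _indices(self, tokens: Sequence[str]) -> np.ndarray:
        t2i = self._tok2idx
        return np.array([t2i.get(t, 0) for t in tokens], dtype=np.intp)

    def _bow_matrix(self, X: Sequence[Sequence[str]]) -> sp.csr_matrix:
        V = len(self.vocab_)
        indptr, indices, data = [0], [], []
        for toks in X:
            counts: dict[int, float] = {}
            for t in toks:
                i = self._tok2idx.get(t, 0)
                counts[i] = counts.get(i, 0.0) + 1.0
            for i in sorted(counts):
                indices.append(i)
                data.append(counts[i])
            indptr.append(len(indices))
        return sp.csr_matrix((data, indices, indptr), shape=(len(X), V))

    # -- fit -----------------------------------------------------------

    def fit(
        self,
        X: Sequence[Sequence[str]],
        y: Sequence[str],
        dev: tuple[Sequence[Sequence[str]], Sequence[str]] | None = None,
    ) -> "HeadingClassifier":
        if self.backend not in ("bow_softmax", "recurrent"):
            raise ValueError(f"unknown backend {self.backend!r}")
        X = [tuple(toks) for toks in X]
        y = list(y)
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be non-empty and aligned")
        self.classes_ = np.array(sorted(set(y)))
        if dev is not None:
            extra = set(dev[1]) - set(self.classes_)
            if extra:
                raise ValueError(f"dev headings absent from train: {sorted(extra)[:5]}")
        self._cls2idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([self._cls2idx[c] for c in y], dtype=np.intp)
        self._build_vocab(X)
        self.history_ = []

        if self.backend == "bow_softmax":
            self._fit_bow(X, y_idx, dev)
        else:
            self._fit_rnn(X, y_idx, dev)
        return self

    def _dev_accuracy(self, dev) -> float:
        Xd, yd = dev
        pred = self.predict(Xd)
        return float(np.mean([p == t for p, t in zip(pred, yd)]))

    def _fit_bow(self, X, y_idx, dev) -> None:
        n, V, C = len(X), len(self.vocab_), len(self.classes_)
        Xm = self._bow_matrix(X)
        Y = np.zeros((n, C))
        Y[np.arange(n), y_idx] = 1.0
        params = {"W": np.zeros((V, C)), "b": np.zeros(C)}
        self._params = params
        opt = _Adam(params, self.learning_rate)
        best_metric, best_params, since_best = -np.inf, None, 0
        for epoch in range(self.max_epochs):
            P = _softmax(Xm @ params["W"] + params["b"])
            loss = float(-np.mean(np.log(np.clip(P[np.arange(n), y_idx], 1e-12, None))))
            dL = (P - Y) / n
            grads = {"W": np.asarray(Xm.T @ dL) + self.l2 * params["W"], "b": dL.sum(axis=0)}
            opt.step(params, grads)
            metric = self._dev_accuracy(dev) if dev is not None else -loss
            self.history_.append({"epoch": epoch, "loss": loss, "dev_accuracy": metric if dev is not None else None})
            if metric > best_metric + 1e-12:
                best_metric, since_best = metric, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            params.update(best_params)
        self.output_weights_ = params["W"].T.copy()

    # -- recurrent backend ---------------------------------------------

    def _init_rnn(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        V, d, h, C = len(self.vocab_), self.embedding_dim, self.hidden_dim, len(self.classes_)
        E = rng.normal(0, 0.1, size=(V, d))
        if self.pretrained_embeddings is not None:
            pvocab, pmat = self.pretrained_embeddings
            if pmat.shape[1] != d:
                raise ValueError("pretrained embedding width does not match embedding_dim")
            lookup = {t: i for i, t in enumerate(pvocab)}
            for i, t in enumerate(self.vocab_):
                if t in lookup:
                    E[i] = pmat[lookup[t]]
        scale = lambda fan: 1.0 / np.sqrt(fan)  # noqa: E731
        p = {"E": E, "bo": np.zeros(C), "Wo": rng.normal(0, scale(2 * h), size=(2 * h, C))}
        for tag in ("f", "b"):
            p[f"Wx_{tag}"] = rng.normal(0, scale(d), size=(d, h))
            p[f"Wh_{tag}"] = rng.normal(0, scale(h), size=(h, h))
            p[f"bh_{tag}"] = np.zeros(h)
        return p

    def _rnn_states(self, p, idx: np.ndarray, tag: str) -> np.ndarray:
        """Hidden states for one direction; idx already ordered for the pass."""
        h = self.hidden_dim
        xs = p["E"][idx]
        hs = np.zeros((len(idx), h))
        prev = np.zeros(h)
        for t in range(len(idx)):
            prev = np.tanh(xs[t] @ p[f"Wx_{tag}"] + prev @ p[f"Wh_{tag}"] + p[f"bh_{tag}"])
            hs[t] = prev
        return hs

    def _encode(self, p, idx: np.ndarray) -> np.ndarray:
        """Concatenated final states of the two directions (width 2h)."""
        hf = self._rnn_states(p, idx, "f")[-1]
        hb = self._rnn_states(p, idx[::-1], "b")[-1]
        return np.concatenate([hf, hb])

    def _rnn_backward_dir(self, p, idx, hs, dh_last, tag, grads) -> None:
        xs = p["E"][idx]
        T = len(idx)
        dh = dh_last
        dE = grads["E"]
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[t] ** 2)
            prev = hs[t - 1] if t > 0 else np.zeros(self.hidden_dim)
            grads[f"Wx_{tag}"] += np.outer(xs[t], da)
            grads[f"Wh_{tag}"] += np.outer(prev, da)
            grads[f"bh_{tag}"] += da
            if not self.freeze_embeddings:
                dE[idx[t]] += da @ p[f"Wx_{tag}"].T
            dh = da @ p[f"Wh_{tag}"].T

    def _fit_rnn(self, X, y_idx, dev) -> None:
        rng = np.random.default_rng(self.seed)
        p = self._init_rnn(rng)
        self._params = p
        seqs = [self._indices(toks) if toks else np.array([0], dtype=np.intp) for toks in X]
        opt = _Adam(p, self.learning_rate)
        n, h = len(seqs), self.hidden_dim
        best_metric, best_params, since_best = -np.inf, None, 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                grads = {k: np.zeros_like(v) for k, v in p.items()}
                for i in batch:
                    idx = seqs[i]
                    hs_f = self._rnn_states(p, idx, "f")
                    hs_b = self._rnn_states(p, idx[::-1], "b")
                    z = np.concatenate([hs_f[-1], hs_b[-1]])
                    probs = _softmax(z @ p["Wo"] + p["bo"])
                    total_loss -= float(np.log(max(probs[y_idx[i]], 1e-12)))
                    dlog = probs.copy()
                    dlog[y_idx[i]] -= 1.0
                    grads["Wo"] += np.outer(z, dlog)
                    grads["bo"] += dlog
                    dz = p["Wo"] @ dlog
                    self._rnn_backward_dir(p, idx, hs_f, dz[:h], "f", grads)
                    self._rnn_backward_dir(p, idx[::-1], hs_b, dz[h:], "b", grads)
                for k in grads:
                    grads[k] /= len(batch)
                grads["Wo"] += self.l2 * p["Wo"]
                if self.freeze_embeddings:
                    grads["E"][:] = 0.0
                opt.step(p, grads)
            loss = total_loss / n
            metric = self._dev_accuracy(dev) if dev is not None else -loss
            self.history_.append({"epoch": epoch, "loss": loss, "dev_accuracy": metric if dev is not None else None})
            if metric > best_metric + 1e-12:
                best_metric, since_best = metric, 0
                best_params = {k: v.copy() for k, v in p.items()}
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            p.update(best_params)
        self.output_weights_ = p["Wo"].T.copy()

    # -- inference -----------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise NotFittedError("classifier is not fitted")

    def _canonical(self, toks: Sequence[str]) -> Sequence[str]:
        """OOV-only sentences collapse to the canonical single-unknown input
        so that any two fully out-of-vocabulary sentences share a profile."""
        if toks and all(t not in self._tok2idx for t in toks):
            return (UNK,)
        return toks

    def predict_proba(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        self._check_fitted()
        C = len(self.classes_)
        X = [self._canonical(toks) for toks in X]
        out = np.empty((len(X), C))
        if self.backend == "bow_softmax":
            nonempty = [i for i, toks in enumerate(X) if len(toks) > 0]
            if nonempty:
                Xm = self._bow_matrix([X[i] for i in nonempty])
                P = _softmax(Xm @ self._params["W"] + self._params["b"])
                out[nonempty] = P
            for i, toks in enumerate(X):
                if len(toks) == 0:
                    out[i] = np.full(C, 1.0 / C)
        else:
            p = self._params
            for i, toks in enumerate(X):
                if len(toks) == 0:
                    out[i] = np.full(C, 1.0 / C)
                    continue
                z = self._encode(p, self._indices(toks))
                out[i] = _softmax(z @ p["Wo"] + p["bo"])
        return out

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: Sequence[Sequence[str]], y: Sequence[str]) -> float:
        pred = self.predict(X)
        return float(np.mean([p == t for p, t in zip(pred, y)]))

    # -- persistence ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Save the fitted model as a directory: config + vocabulary +
        heading inventory + parameter arrays."""
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = self.get_params()
        cfg.pop("pretrained_embeddings")
        (d / "config.json").write_text(json.dumps(cfg, indent=1))
        (d / "vocab.txt").write_text("\n".join(self.vocab_), encoding="utf-8")
        (d / "headings.txt").write_text("\n".join(self.classes_), encoding="utf-8")
        np.savez(d / "params.npz", **self._params)

    @classmethod
    def load(cls, directory: str | Path) -> "HeadingClassifier":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        model = cls(**cfg)
        model.vocab_ = (d / "vocab.txt").read_text(encoding="utf-8").split("\n")
        model._tok2idx = {t: i for i, t in enumerate(model.vocab_)}
        model.classes_ = np.array((d / "headings.txt").read_text(encoding="utf-8").split("\n"))
        model._cls2idx = {c: i for i, c in enumerate(model.classes_)}
        with np.load(d / "params.npz") as npz:
            model._params = {k: npz[k].copy() for k in npz.files}
        key = "W" if model.backend == "bow_softmax" else "Wo"
        model.output_weights_ = model._params[key].T.copy()
        model.history_ = []
        return model


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train_classifier(
    train: LabeledCorpus,
    dev: LabeledCorpus,
    config: ClassifierConfig,
) -> HeadingClassifier:
    """Train a :class:`HeadingClassifier` on labeled corpora.

    Raises if a dev heading is absent from train.  With a single-heading
    inventory a (trivially perfect) constant model is still fitted.
    """
    Xtr = [r.sentence.tokens for r in train.records]
    ytr = [r.heading for r in train.records]
    Xdv = [r.sentence.tokens for r in dev.records]
    ydv = [r.heading for r in dev.records]
    pre = None
    if config.backend == "recurrent":
        pre = pretrain_embeddings(train, config.embedding_dim, seed=config.seed)
    model = HeadingClassifier(
        backend=config.backend,
        embedding_dim=config.embedding_dim,
        hidden_dim=config.hidden_dim_per_direction,
        max_epochs=config.max_epochs,
        patience=config.patience,
        learning_rate=config.learning_rate,
        l2=config.l2,
        pretrained_embeddings=pre,
        freeze_embeddings=config.freeze_embeddings,
        seed=config.seed,
    )
    dev_pair = (Xdv, ydv) if Xdv else None
    model.fit(Xtr, ytr, dev=dev_pair)
    return model


def predict_confidences(model: HeadingClassifier, sentence: Sentence) -> ConfidenceProfile:
    """Full probability profile of one sentence over the heading inventory.

    A sentence with no tokens gets the uniform profile (with a warning):
    narratives do contain such lines and they should not crash the pipeline.
    """
    if len(sentence.tokens) == 0:
        warnings.warn(f"sentence {sentence.note_id}:{sentence.index} has no tokens; uniform profile")
    probs = model.predict_proba([sentence.tokens])[0]
    return ConfidenceProfile(heading_ids=tuple(str(c) for c in model.classes_), probs=probs)


def top_k(profile: ConfidenceProfile, k: int) -> list[tuple[str, float]]:
    """Top-``k`` headings sorted by descending probability, ties broken by
    heading id."""
    n = len(profile.heading_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    order = sorted(range(n), key=lambda i: (-profile.probs[i], profile.heading_ids[i]))
    return [(profile.heading_ids[i], float(profile.probs[i])) for i in order[:k]]


def heading_vectors(model: HeadingClassifier) -> HeadingVectorSpace:
    """Extract the output-layer weight rows as heading representations.

    The output bias is excluded: it encodes class priors, not usage
    semantics.  Width is ``2 * hidden_dim`` for the recurrent backend and
    ``|vocab|`` for bow_softmax.
    """
    model._check_fitted()
    return HeadingVectorSpace(
        heading_ids=tuple(str(c) for c in model.classes_), vectors=model.output_weights_.copy()
    )
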