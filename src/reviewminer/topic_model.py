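"""Collapsed-Gibbs LDA and labeled-LDA: training, fold-in inference, per-word
perplexity and topic-number selection.

Model
-----
LDA draws, for each document d, a topic mixture theta_d ~ Dir(alpha) and, for
each token, a topic z ~ Cat(theta_d) and a word w ~ Cat(phi_z), with topic-word
distributions phi_k ~ Dir(beta).  Collapsed Gibbs sampling integrates theta and
phi out and resamples each token's topic from

    p(z_i = k | z_-i, w) ∝ (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

where the counts exclude token i.  Labeled-LDA is the same sampler with each
document's admissible topics restricted to its label set, so topics coincide
with human-interpretable taxonomy labels; with full label sets it degenerates
to LDA exactly (bit-identical trajectories under a shared seed, since both run
the same code path).

Defaults follow common collapsed-Gibbs practice: alpha = 50/K, beta = 0.01,
1000 sweeps with 500 burn-in, and Rao-Blackwellized theta/phi estimates
averaged over post-burn-in samples taken every ``sample_lag`` sweeps.

Reproducibility: sweeps visit documents in corpus order and tokens in sequence
order, consuming a self-contained xorshift64* random stream seeded from the
user seed, so runs are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .corpus_io import Taxonomy

__all__ = [
    "LdaState", "TopicModelResult", "PerplexityCurve",
    "fit_lda", "fit_labeled_lda", "estimate_theta_phi", "infer_theta",
    "per_word_perplexity", "perplexity_from_theta", "select_num_topics",
    "top_words", "gibbs_conditional", "greedy_topic_match",
]


# ---------------------------------------------------------------------------
# Random stream (xorshift64*), shared by initialization and sweeps
# ---------------------------------------------------------------------------

_XS_MULT = np.uint64(2685821657736338717)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=False)
def _rand(state):
    """Uniform double in [0, 1) from a 1-element uint64 state array."""
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state[0] = s
    return np.float64((s * _XS_MULT) >> np.uint64(11)) * _INV_2_53


def _seed_state(seed: int) -> np.ndarray:
    s = np.uint64((int(seed) * 6364136223846793005 + 1442695040888963407)
                  % (1 << 64))
    if s == np.uint64(0):
        s = np.uint64(0x9E3779B97F4A7C15)
    return np.array([s], dtype=np.uint64)


@njit(cache=False)
def _init_assignments(token_doc, token_word, z, n_dk, n_kw, n_k, mask, state):
    K = n_k.shape[0]
    for t in range(token_doc.shape[0]):
        d = token_doc[t]
        # uniform over the document's admissible topics
        n_allowed = 0
        for k in range(K):
            if mask[d, k] > 0.0:
                n_allowed += 1
        r = int(_rand(state) * n_allowed)
        if r >= n_allowed:
            r = n_allowed - 1
        k_new = -1
        seen = 0
        for k in range(K):
            if mask[d, k] > 0.0:
                if seen == r:
                    k_new = k
                    break
                seen += 1
        z[t] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, token_word[t]] += 1
        n_k[k_new] += 1


@njit(cache=False)
def _run_sweeps(token_doc, token_word, z, n_dk, n_kw, n_k, mask,
                alpha, beta, n_sweeps, burn_in, sample_lag,
                acc_ndk, acc_nkw, state):
    """In-place Gibbs sweeps; returns the number of accumulated samples."""
    T = token_doc.shape[0]
    K = n_k.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    p = np.empty(K, dtype=np.float64)
    n_samples = 0
    for sweep in range(n_sweeps):
        for t in range(T):
            d = token_doc[t]
            w = token_word[t]
            k_old = z[t]
            n_dk[d, k_old] -= 1
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            total = 0.0
            for k in range(K):
                pk = mask[d, k] * (n_dk[d, k] + alpha) \
                    * (n_kw[k, w] + beta) / (n_k[k] + vbeta)
                p[k] = pk
                total += pk
            u = _rand(state) * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if u < acc:
                    k_new = k
                    break
            z[t] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
        if sweep >= burn_in and (sweep - burn_in) % sample_lag == 0:
            n_samples += 1
            for d in range(n_dk.shape[0]):
                for k in range(K):
                    acc_ndk[d, k] += n_dk[d, k]
            for k in range(K):
                for w in range(V):
                    acc_nkw[k, w] += n_kw[k, w]
    return n_samples


@njit(cache=False)
def _fold_in(token_doc, token_word, z, n_dk, phi,
             alpha, n_sweeps, burn_in, sample_lag, acc_ndk, state):
    """Gibbs fold-in for new documents with phi held fixed."""
    T = token_doc.shape[0]
    K = phi.shape[0]
    p = np.empty(K, dtype=np.float64)
    n_samples = 0
    for sweep in range(n_sweeps):
        for t in range(T):
            d = token_doc[t]
            w = token_word[t]
            k_old = z[t]
            n_dk[d, k_old] -= 1
            total = 0.0
            for k in range(K):
                pk = (n_dk[d, k] + alpha) * phi[k, w]
                p[k] = pk
                total += pk
            u = _rand(state) * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if u < acc:
                    k_new = k
                    break
            z[t] = k_new
            n_dk[d, k_new] += 1
        if sweep >= burn_in and (sweep - burn_in) % sample_lag == 0:
            n_samples += 1
            for d in range(n_dk.shape[0]):
                for k in range(K):
                    acc_ndk[d, k] += n_dk[d, k]
    return n_samples


# ---------------------------------------------------------------------------
# State and result containers
# ---------------------------------------------------------------------------

@dataclass
class LdaState:
    """Sampler state: token-level assignments and sufficient-statistic counts."""

    K: int
    V: int
    alpha: float
    beta: float
    token_doc: np.ndarray      # int32 [T]
    token_word: np.ndarray     # int32 [T]
    z: np.ndarray              # int32 [T]
    n_dk: np.ndarray           # int64 [M, K]
    n_kw: np.ndarray           # int64 [K, V]
    n_k: np.ndarray            # int64 [K]
    label_mask: np.ndarray     # float64 [M, K]; 1 = admissible
    seed: int
    iterations: int
    burn_in: int
    sample_lag: int
    topic_labels: Optional[list[str]] = None
    acc_n_dk: Optional[np.ndarray] = None
    acc_n_kw: Optional[np.ndarray] = None
    n_samples: int = 0

    @property
    def M(self) -> int:
        return self.n_dk.shape[0]

    @property
    def N_d(self) -> np.ndarray:
        return self.n_dk.sum(axis=1)

    def check_counts(self) -> None:
        """Exact integer consistency of counts with the assignment vector."""
        M, K, V = self.M, self.K, self.V
        n_dk = np.zeros((M, K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        np.add.at(n_dk, (self.token_doc, self.z), 1)
        np.add.at(n_kw, (self.z, self.token_word), 1)
        if not (np.array_equal(n_dk, self.n_dk)
                and np.array_equal(n_kw, self.n_kw)
                and np.array_equal(n_kw.sum(axis=1), self.n_k)):
            raise AssertionError("Gibbs counts inconsistent with assignments")
        if (self.n_dk < 0).any() or (self.n_kw < 0).any():
            raise AssertionError("negative Gibbs counts")
        for t in range(len(self.z)):
            if self.label_mask[self.token_doc[t], self.z[t]] == 0.0:
                raise AssertionError("token assigned outside its label set")


@dataclass
class TopicModelResult:
    """Point estimates: theta (M x K, document-topic) and phi (K x V,
    topic-word), both row-stochastic and strictly positive (smoothed)."""

    theta: np.ndarray
    phi: np.ndarray
    topic_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        for name, mat in (("theta", self.theta), ("phi", self.phi)):
            if mat.size and not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if mat.size and (mat <= 0).any():
                raise ValueError(f"{name} entries must be positive (smoothed)")

    def save(self, path: str | Path) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "phi": self.phi.tolist(),
            "topic_labels": self.topic_labels,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TopicModelResult":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(np.asarray(payload["theta"], dtype=float),
                   np.asarray(payload["phi"], dtype=float),
                   payload.get("topic_labels"))


@dataclass
class PerplexityCurve:
    """Held-out per-word perplexity as a function of the topic count K."""

    points: list[tuple[int, float]]
    held_out_fraction: float
    seed: int
    threshold: float
    recommended_k: int
    estimator: str = "fold-in with fixed phi"

    def as_dict(self) -> dict:
        return {
            "points": self.points,
            "held_out_fraction": self.held_out_fraction,
            "seed": self.seed,
            "threshold": self.threshold,
            "recommended_k": self.recommended_k,
            "estimator": self.estimator,
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _flatten(bows: Sequence[Sequence[int]], V: int):
    token_doc, token_word = [], []
    for d, bow in enumerate(bows):
        for w in bow:
            if not 0 <= w < V:
                raise ValueError(f"token index {w} outside vocabulary of size {V}")
            token_doc.append(d)
            token_word.append(w)
    return (np.asarray(token_doc, dtype=np.int32),
            np.asarray(token_word, dtype=np.int32))


def _fit(bows, V, K, mask, alpha, beta, iterations, burn_in, sample_lag,
         seed, topic_labels):
    if K < 2:
        raise ValueError("K must be >= 2")
    if len(bows) == 0:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = 50.0 / K
    token_doc, token_word = _flatten(bows, V)
    if token_doc.size == 0:
        raise ValueError("corpus contains no tokens")
    M = len(bows)
    z = np.zeros(token_doc.shape[0], dtype=np.int32)
    n_dk = np.zeros((M, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    acc_ndk = np.zeros((M, K), dtype=np.float64)
    acc_nkw = np.zeros((K, V), dtype=np.float64)
    state = _seed_state(seed)
    _init_assignments(token_doc, token_word, z, n_dk, n_kw, n_k, mask, state)
    n_samples = _run_sweeps(
        token_doc, token_word, z, n_dk, n_kw, n_k, mask,
        float(alpha), float(beta), int(iterations), int(burn_in),
        int(sample_lag), acc_ndk, acc_nkw, state,
    )
    return LdaState(
        K=K, V=V, alpha=float(alpha), beta=float(beta),
        token_doc=token_doc, token_word=token_word, z=z,
        n_dk=n_dk, n_kw=n_kw, n_k=n_k, label_mask=mask,
        seed=int(seed), iterations=int(iterations), burn_in=int(burn_in),
        sample_lag=int(sample_lag), topic_labels=topic_labels,
        acc_n_dk=acc_ndk if n_samples else None,
        acc_n_kw=acc_nkw if n_samples else None,
        n_samples=n_samples,
    )


def fit_lda(
    bows: Sequence[Sequence[int]],
    V: int,
    K: int = 30,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 500,
    sample_lag: int = 10,
    seed: int = 0,
) -> LdaState:
    """Train unsupervised LDA by collapsed Gibbs sampling.

    ``bows`` are per-document token-index sequences over a vocabulary of size
    ``V``.  The default K of 30 matches the exploratory setting used to scan
    review corpora for interpretable themes; ``alpha`` defaults to 50/K.
    """
    mask = np.ones((len(bows), K), dtype=np.float64)
    return _fit(bows, V, K, mask, alpha, beta, iterations, burn_in,
                sample_lag, seed, topic_labels=None)


def fit_labeled_lda(
    bows: Sequence[Sequence[int]],
    V: int,
    label_sets: Sequence[Iterable[str]],
    taxonomy: Taxonomy,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 500,
    sample_lag: int = 10,
    seed: int = 0,
) -> LdaState:
    """Train labeled-LDA: one topic per taxonomy label (K = L), with each
    document's topic assignments restricted to its annotated label set.

    The annotated label sets supply the supervision; a document labeled with
    every taxonomy label is unconstrained, so a fully-labeled corpus yields the
    same sampler trajectory as :func:`fit_lda` under the same seed.
    """
    K = taxonomy.L
    if len(label_sets) != len(bows):
        raise ValueError("label_sets must parallel bows")
    mask = np.zeros((len(bows), K), dtype=np.float64)
    for d, labels in enumerate(label_sets):
        labels = set(labels)
        if not labels:
            raise ValueError(f"document {d} has an empty label set")
        for lab in labels:
            mask[d, taxonomy.index(lab)] = 1.0
    return _fit(bows, V, K, mask, alpha, beta, iterations, burn_in,
                sample_lag, seed, topic_labels=taxonomy.label_ids)


def gibbs_conditional(state: LdaState, t: int) -> np.ndarray:
    """The collapsed conditional p(z_t = k | z_-t, w) for token ``t``.

    Pure-python mirror of one sampler step, exposed for verification against
    direct evaluation of the collapsed posterior.
    """
    d, w, k_old = state.token_doc[t], state.token_word[t], state.z[t]
    n_dk = state.n_dk[d].astype(float).copy()
    n_kw = state.n_kw[:, w].astype(float).copy()
    n_k = state.n_k.astype(float).copy()
    n_dk[k_old] -= 1
    n_kw[k_old] -= 1
    n_k[k_old] -= 1
    p = state.label_mask[d] * (n_dk + state.alpha) * (n_kw + state.beta) \
        / (n_k + state.V * state.beta)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Estimation and inference
# ---------------------------------------------------------------------------

def estimate_theta_phi(state: LdaState, averaged: bool = True) -> TopicModelResult:
    """Rao-Blackwellized estimates theta[d,k] = (n_dk+alpha)/(N_d+K*alpha) and
    phi[k,w] = (n_kw+beta)/(n_k+V*beta).

    With ``averaged=True`` (default) the counts are means over the post-burn-in
    samples recorded every ``sample_lag`` sweeps, giving lower-variance
    estimates; otherwise the final sweep's counts are used.  An empty document
    gets the uniform prior row 1/K.
    """
    if averaged and state.n_samples > 0:
        n_dk = state.acc_n_dk / state.n_samples
        n_kw = state.acc_n_kw / state.n_samples
    else:
        n_dk = state.n_dk.astype(np.float64)
        n_kw = state.n_kw.astype(np.float64)
    N_d = n_dk.sum(axis=1)
    theta = (n_dk + state.alpha) / (N_d + state.K * state.alpha)[:, None]
    n_k = n_kw.sum(axis=1)
    phi = (n_kw + state.beta) / (n_k + state.V * state.beta)[:, None]
    return TopicModelResult(theta, phi, state.topic_labels)


def infer_theta(
    bows: Sequence[Sequence[int]],
    phi: np.ndarray,
    alpha: Optional[float] = None,
    iterations: int = 200,
    burn_in: int = 100,
    sample_lag: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Fold-in inference: estimate theta for new documents with phi fixed.

    Documents that are empty (or fully out-of-vocabulary, hence empty here)
    receive the uniform prior row, with a warning.
    """
    K = phi.shape[0]
    if alpha is None:
        alpha = 50.0 / K
    M = len(bows)
    token_doc, token_word = _flatten(bows, phi.shape[1])
    n_dk = np.zeros((M, K), dtype=np.int64)
    acc_ndk = np.zeros((M, K), dtype=np.float64)
    state = _seed_state(seed)
    n_samples = 0
    if token_doc.size:
        z = np.zeros(token_doc.shape[0], dtype=np.int32)
        mask = np.ones((M, K), dtype=np.float64)
        n_kw = np.zeros((K, phi.shape[1]), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        _init_assignments(token_doc, token_word, z, n_dk, n_kw, n_k, mask, state)
        n_samples = _fold_in(
            token_doc, token_word, z, n_dk, np.ascontiguousarray(phi, dtype=np.float64),
            float(alpha), int(iterations), int(burn_in), int(sample_lag),
            acc_ndk, state,
        )
    mean_ndk = acc_ndk / n_samples if n_samples else n_dk.astype(np.float64)
    N_d = mean_ndk.sum(axis=1)
    if (N_d == 0).any():
        warnings.warn(
            f"{int((N_d == 0).sum())} empty/out-of-vocabulary document(s); "
            "their theta rows are the uniform prior"
        )
    theta = (mean_ndk + alpha) / (N_d + K * alpha)[:, None]
    return theta


# ---------------------------------------------------------------------------
# Perplexity and topic-number selection
# ---------------------------------------------------------------------------

def perplexity_from_theta(
    theta: np.ndarray, phi: np.ndarray, bows: Sequence[Sequence[int]]
) -> float:
    """exp(-sum_d log p(w_d) / sum_d N_d) with p(w) = sum_k theta_dk * phi_kw."""
    log_lik = 0.0
    n_tokens = 0
    for d, bow in enumerate(bows):
        if not bow:
            continue
        pw = theta[d] @ phi[:, list(bow)]
        log_lik += float(np.log(pw).sum())
        n_tokens += len(bow)
    if n_tokens == 0:
        raise ValueError("held-out set contains no tokens")
    return float(math.exp(-log_lik / n_tokens))


def per_word_perplexity(
    model: TopicModelResult | LdaState,
    held_out: Sequence[Sequence[int]],
    alpha: Optional[float] = None,
    iterations: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> float:
    """Held-out per-word perplexity; lower means better predictive fit.

    Held-out document mixtures are obtained by Gibbs fold-in against the
    model's phi (the simplest well-defined estimator for the per-word
    likelihood p(w) = sum_k theta_dk phi_kw).
    """
    if isinstance(model, LdaState):
        model = estimate_theta_phi(model)
    if alpha is None:
        alpha = 50.0 / model.phi.shape[0]
    theta = infer_theta(held_out, model.phi, alpha=alpha,
                        iterations=iterations, burn_in=burn_in, seed=seed)
    return perplexity_from_theta(theta, model.phi, held_out)


def select_num_topics(
    bows: Sequence[Sequence[int]],
    V: int,
    grid: Sequence[int],
    held_out_fraction: float = 0.2,
    seed: int = 0,
    threshold: float = 0.05,
    **fit_kwargs,
) -> PerplexityCurve:
    """Scan a K grid, scoring each model by held-out per-word perplexity.

    The recommended K is the smallest grid point whose relative perplexity
    improvement over the previous grid point falls below ``threshold`` (elbow
    rule); if none does, the largest grid point is recommended.  The full
    curve is always reported — the elbow is a starting point, and the final
    choice should weigh interpretability of the learned topics.
    """
    grid = sorted(int(k) for k in grid)
    if len(grid) < 2:
        raise ValueError("grid needs at least 2 values of K")
    if any(k < 2 for k in grid):
        raise ValueError("all grid entries must be >= 2")
    rng = np.random.default_rng(seed)
    M = len(bows)
    n_held = max(1, int(round(held_out_fraction * M)))
    if n_held >= M:
        raise ValueError("held_out_fraction leaves no training documents")
    held_idx = set(rng.choice(M, size=n_held, replace=False).tolist())
    train = [bows[d] for d in range(M) if d not in held_idx]
    held = [bows[d] for d in range(M) if d in held_idx]

    points: list[tuple[int, float]] = []
    for K in grid:
        state = fit_lda(train, V, K=K, seed=seed, **fit_kwargs)
        ppl = per_word_perplexity(state, held, seed=seed)
        points.append((K, ppl))

    recommended = grid[-1]
    for i in range(1, len(points)):
        prev, cur = points[i - 1][1], points[i][1]
        improvement = max(0.0, (prev - cur) / prev)
        if improvement < threshold:
            recommended = points[i][0]
            break
    return PerplexityCurve(points, held_out_fraction, int(seed),
                           float(threshold), int(recommended))


def greedy_topic_match(phi_est: np.ndarray, phi_true: np.ndarray
                       ) -> list[tuple[int, int, float]]:
    """Greedily pair estimated and reference topics by cosine similarity.

    Returns (estimated index, reference index, cosine) triples, one per topic,
    pairing the globally most similar unmatched rows first.  Used in recovery
    experiments to score phi estimates against generator ground truth.
    """
    a = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    sim = a @ b.T
    K = sim.shape[0]
    free_a, free_b = set(range(K)), set(range(sim.shape[1]))
    pairs: list[tuple[int, int, float]] = []
    while free_a and free_b:
        i, j = max(((i, j) for i in free_a for j in free_b),
                   key=lambda ij: sim[ij])
        pairs.append((i, j, float(sim[i, j])))
        free_a.discard(i)
        free_b.discard(j)
    return pairs


def top_words(result: TopicModelResult, k: int, n: int,
              vocab=None) -> list:
    """The ``n`` highest-probability words of topic ``k``; ties broken by
    vocabulary index.  Returns tokens when a vocabulary is given, else indices."""
    phi_k = result.phi[k]
    V = phi_k.shape[0]
    if n > V:
        raise ValueError(f"n={n} exceeds vocabulary size {V}")
    order = np.lexsort((np.arange(V), -phi_k))[:n]
    if vocab is None:
        return order.tolist()
    return [vocab.token(int(i)) for i in order]
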