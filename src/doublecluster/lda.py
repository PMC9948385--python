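"""Collapsed Gibbs sampler for latent Dirichlet allocation over count data.

Patients are documents and cell types are words.  The generative model places
symmetric Dirichlet priors on the per-document topic mixture theta ~ Dir(alpha)
and the per-topic word distribution phi ~ Dir(beta); with theta and phi
integrated out, the conditional for token i being assigned topic j is

    P(z_i = j | z_-i, w_i, d_i)
        ∝ (C^WK[w,j] + beta) / (sum_w C^WK[w,j] + W*beta)
          * (C^DK[d,j] + alpha) / (sum_k C^DK[d,k] + K*alpha)

evaluated with token i removed from the word-topic (C^WK) and document-topic
(C^DK) count matrices.  theta and phi are estimated from the smoothed counts,
averaged over post-burn-in samples of a single chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._gibbs import gibbs_sweep_kernel
from .celltyping import CountMatrix

__all__ = [
    "LDAHyperparams",
    "GibbsState",
    "TopicModel",
    "counts_to_tokens",
    "conditional_topic_probs",
    "gibbs_sweep",
    "fit_lda",
    "log_likelihood",
    "sample_corpus",
]


@dataclass(frozen=True)
class LDAHyperparams:
    """Sampler configuration.

    alpha is the document-topic concentration (higher -> documents spread over
    more topics), beta the topic-word concentration (higher -> topics spread
    over more words).  Defaults: mild document smoothing (alpha=1) and a small
    beta (0.1) favouring crisp cell-type/topic association.
    """

    K: int
    alpha: float = 1.0
    beta: float = 0.1
    n_iterations: int = 500
    n_burnin: int = 200
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("require 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GibbsState:
    """Token-level assignments plus the count matrices the conditional reads.

    ``Cwk`` (W x K) and ``Cdk`` (D x K) are exactly recomputable from
    ``(token_words, token_docs, z)``; :meth:`recount` does so for invariant
    checks.  Tokens are stored flat in canonical doc-major order.
    """

    token_words: np.ndarray
    token_docs: np.ndarray
    z: np.ndarray
    Cwk: np.ndarray
    Cdk: np.ndarray
    topic_totals: np.ndarray
    doc_totals: np.ndarray

    @classmethod
    def from_tokens(
        cls,
        tokens: list[np.ndarray],
        z: np.ndarray,
        W: int,
        K: int,
    ) -> "GibbsState":
        words = (
            np.concatenate(tokens).astype(np.int64)
            if tokens
            else np.empty(0, np.int64)
        )
        docs = np.repeat(
            np.arange(len(tokens), dtype=np.int64),
            [len(t) for t in tokens],
        )
        z = np.asarray(z, np.int64)
        if z.shape != words.shape:
            raise ValueError("z must have one entry per token")
        Cwk = np.zeros((W, K), np.int64)
        Cdk = np.zeros((len(tokens), K), np.int64)
        np.add.at(Cwk, (words, z), 1)
        np.add.at(Cdk, (docs, z), 1)
        return cls(
            token_words=words,
            token_docs=docs,
            z=z,
            Cwk=Cwk,
            Cdk=Cdk,
            topic_totals=Cwk.sum(axis=0),
            doc_totals=Cdk.sum(axis=1),
        )

    @property
    def tokens(self) -> list[np.ndarray]:
        """Per-document word-id lists, reconstructed from the flat storage."""
        d = self.Cdk.shape[0]
        return [self.token_words[self.token_docs == i] for i in range(d)]

    def recount(self) -> tuple[np.ndarray, np.ndarray]:
        """Recompute (Cwk, Cdk) from scratch from (tokens, z)."""
        W, K = self.Cwk.shape
        Cwk = np.zeros((W, K), np.int64)
        Cdk = np.zeros_like(self.Cdk)
        np.add.at(Cwk, (self.token_words, self.z), 1)
        np.add.at(Cdk, (self.token_docs, self.z), 1)
        return Cwk, Cdk


@dataclass
class TopicModel:
    """Estimated conditional distributions: theta (D x K), phi (K x W)."""

    theta: np.ndarray
    phi: np.ndarray
    loglik_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        self.phi = np.asarray(self.phi, float)
        for name, m in (("theta", self.theta), ("phi", self.phi)):
            if np.any(m <= 0):
                raise ValueError(f"{name} must be strictly positive (smoothed)")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")

    @property
    def assignments(self) -> np.ndarray:
        """Per-document hard cluster: argmax of theta (ties -> lowest index)."""
        return self.theta.argmax(axis=1)


def counts_to_tokens(counts: CountMatrix) -> list[np.ndarray]:
    """Expand each count row into its token list (word ids, ascending)."""
    w = np.arange(counts.W)
    return [np.repeat(w, row).astype(np.int64) for row in counts.counts]


def conditional_topic_probs(
    state: GibbsState, d: int, w: int, hp: LDAHyperparams
) -> np.ndarray:
    """Normalized topic conditional for a token of word ``w`` in document ``d``.

    ``state`` must hold the minus-i counts (the current token already
    decremented); negative counts signal a bookkeeping bug and raise.
    """
    if (
        np.any(state.Cwk[w] < 0)
        or np.any(state.Cdk[d] < 0)
        or np.any(state.topic_totals < 0)
    ):
        raise ValueError("negative -i count: decrement bookkeeping bug")
    W, K = state.Cwk.shape
    word_term = (state.Cwk[w] + hp.beta) / (state.topic_totals + W * hp.beta)
    doc_term = (state.Cdk[d] + hp.alpha) / (state.Cdk[d].sum() + K * hp.alpha)
    p = word_term * doc_term
    return p / p.sum()


def gibbs_sweep(
    state: GibbsState, hp: LDAHyperparams, rng: np.random.Generator
) -> GibbsState:
    """Resample every token once, in canonical doc-major order (in place)."""
    u = rng.random(state.token_words.shape[0])
    gibbs_sweep_kernel(
        state.token_words,
        state.token_docs,
        state.z,
        state.Cwk,
        state.Cdk,
        state.topic_totals,
        float(hp.alpha),
        float(hp.beta),
        u,
    )
    return state


def _point_estimates(
    state: GibbsState, hp: LDAHyperparams
) -> tuple[np.ndarray, np.ndarray]:
    W, K = state.Cwk.shape
    theta = (state.Cdk + hp.alpha) / (
        state.doc_totals[:, None] + K * hp.alpha
    )
    phi = (state.Cwk.T + hp.beta) / (state.topic_totals[:, None] + W * hp.beta)
    return theta, phi


def fit_lda(
    counts: CountMatrix, hp: LDAHyperparams
) -> tuple[TopicModel, GibbsState]:
    """Run the collapsed Gibbs chain and estimate theta and phi.

    Topic assignments start i.i.d. uniform from ``hp.seed``; after
    ``n_burnin`` sweeps the smoothed-count estimates are averaged over every
    ``thin``-th sweep.  Deterministic given ``hp``.
    """
    tokens = counts_to_tokens(counts)
    total = int(counts.counts.sum())
    if total == 0:
        raise ValueError("all-empty corpus: nothing to fit")
    rng = np.random.default_rng(hp.seed)
    z0 = rng.integers(0, hp.K, size=total)
    state = GibbsState.from_tokens(tokens, z0, counts.W, hp.K)

    theta_acc = np.zeros((counts.n_patients, hp.K))
    phi_acc = np.zeros((hp.K, counts.W))
    n_kept = 0
    trace = np.empty(hp.n_iterations)
    for it in range(hp.n_iterations):
        gibbs_sweep(state, hp, rng)
        trace[it] = log_likelihood(state, hp)
        if it >= hp.n_burnin and (it - hp.n_burnin) % hp.thin == 0:
            theta, phi = _point_estimates(state, hp)
            theta_acc += theta
            phi_acc += phi
            n_kept += 1
    model = TopicModel(
        theta=theta_acc / n_kept, phi=phi_acc / n_kept, loglik_trace=trace
    )
    return model, state


def log_likelihood(state: GibbsState, hp: LDAHyperparams) -> float:
    """Collapsed joint log P(w, z | alpha, beta).

    The product of Dirichlet-multinomial normalizers for the K topic-word
    urns and the D document-topic urns, in log-gamma form.
    """
    W, K = state.Cwk.shape
    a, b = hp.alpha, hp.beta
    word = (
        gammaln(W * b)
        - gammaln(state.topic_totals + W * b)
        + (gammaln(state.Cwk + b) - gammaln(b)).sum(axis=0)
    ).sum()
    doc = (
        gammaln(K * a)
        - gammaln(state.doc_totals + K * a)
        + (gammaln(state.Cdk + a) - gammaln(a)).sum(axis=1)
    ).sum()
    return float(word + doc)


def sample_corpus(
    theta: np.ndarray,
    phi: np.ndarray,
    doc_lengths: np.ndarray,
    rng: np.random.Generator,
    patient_ids: list[str] | None = None,
) -> CountMatrix:
    """Draw a corpus from a known topic model (for parameter-recovery checks).

    Each document's word counts are multinomial with mixture probabilities
    ``theta[d] @ phi`` — equivalent to drawing a topic then a word per token.
    """
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    D = theta.shape[0]
    W = phi.shape[1]
    rows = np.stack(
        [rng.multinomial(int(n), theta[d] @ phi) for d, n in enumerate(doc_lengths)]
    )
    ids = patient_ids or [f"D{d:04d}" for d in range(D)]
    return CountMatrix(counts=rows, patient_ids=ids, W=W)
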