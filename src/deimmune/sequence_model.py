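"""Miniature structure-conditioned autoregressive sequence-design model.

The model follows the inverse-folding contract of message-passing design
networks (ProteinMPNN-style): a backbone encoder turns N/CA/C/O coordinates
into per-residue node embeddings and per-neighbor edge embeddings over a
k-nearest-neighbor CA graph, and an arbitrary-order autoregressive decoder
emits a 21-way distribution (20 amino acids + input-only ``X``) for one
position at a time, conditioning on the structure and on the residues decoded
so far under a uniformly random decoding order.

Two deliberate departures from the full-scale architecture keep the model
trainable on a single CPU with exact gradients and no deep-learning
dependency:

* the encoder and decoder context builder form a **frozen random-feature
  trunk** — weights drawn once from a seeded generator and never trained;
* all learning happens in a **two-layer softmax readout head** whose
  gradients are written out analytically.

The featurization uses only pairwise distances and sequence separations, so
every model output is invariant under rigid motions of the input backbone.
The output layer initializes to zero, so a fresh model emits the uniform
1/21 distribution everywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Union

import numpy as np
from scipy.special import log_softmax, softmax

from ._optim import Adam, clip_grad_norm
from .alphabet import VOCAB_INDEX, decode_tokens, encode_sequence
from .structure import BackboneStructure

__all__ = [
    "ModelConfig",
    "BatchConfig",
    "Encoding",
    "SampleResult",
    "InverseFoldingModel",
    "pretrain",
]

VOCAB_SIZE = 21
_MASK = VOCAB_SIZE  # index of the "not yet decoded" context token
_X_INDEX = VOCAB_INDEX["X"]
_TOKEN_DIM = 16
_NODE_FEATS = 10
_EDGE_FEATS = 23
_RBF_CENTERS = np.linspace(2.0, 22.0, 16)
_RBF_SIGMA = 1.25


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``vocab_size`` is fixed at 21 (20 amino acids plus ``X``).  The defaults
    are desk-scale; :meth:`full_scale` carries the published full-size values
    (feature dimension 128, 48 neighbors) as a preset.
    """

    feature_dim: int = 64
    n_neighbors: int = 16
    encoder_layers: int = 2
    decoder_layers: int = 2
    hidden_dim: int = 64
    featurizer_seed: int = 0

    vocab_size: int = field(default=VOCAB_SIZE)

    def __post_init__(self) -> None:
        if self.vocab_size != VOCAB_SIZE:
            raise ValueError("vocab_size is fixed at 21 (20 AA + 'X')")
        if self.feature_dim < 1 or self.n_neighbors < 1:
            raise ValueError("feature_dim and n_neighbors must be >= 1")
        if self.encoder_layers < 1 or self.decoder_layers < 1:
            raise ValueError("layer counts must be >= 1")

    @classmethod
    def full_scale(cls) -> "ModelConfig":
        """Full-size preset: D=128, 48 neighbors, deeper trunk."""
        return cls(feature_dim=128, n_neighbors=48, encoder_layers=3, decoder_layers=3)


@dataclass(frozen=True)
class BatchConfig:
    """Token-budget constraint for batching: ``B * S <= max_tokens``."""

    max_tokens_per_batch: int = 10_000
    max_sequence_length: int = 10_000

    def check(self, batch_size: int, max_len: int) -> None:
        if batch_size * max_len > self.max_tokens_per_batch:
            raise ValueError(
                f"batch of {batch_size} sequences x max length {max_len} exceeds "
                f"the {self.max_tokens_per_batch}-token budget"
            )


class Encoding(NamedTuple):
    """Backbone encoding: per-residue node embeddings and neighbor data."""

    node_emb: np.ndarray  # (R, D)
    edge_emb: np.ndarray  # (R, K, D)
    nbr_idx: np.ndarray  # (R, K) neighbor residue indices
    edge_lin: np.ndarray  # (R, K, D) edge part of the decoder message
    structure: BackboneStructure

    @property
    def n_residues(self) -> int:
        return len(self.node_emb)


class SampleResult(NamedTuple):
    """A sampled design with its decoding order and per-position log-probs."""

    sequence: str
    order: np.ndarray
    log_probs: np.ndarray  # (R,), log pi(token at position p), full softmax

    @property
    def log_prob(self) -> float:
        return float(self.log_probs.sum())


def _rigid_invariant_node_features(coords: np.ndarray) -> np.ndarray:
    """Local-geometry node features (distances/angles only)."""
    ca = coords[:, 1]
    n = len(ca)
    f = np.zeros((n, _NODE_FEATS))
    if n > 2:
        d = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
        f[1:-1, 0] = d / 10.0
        v1 = ca[:-2] - ca[1:-1]
        v2 = ca[2:] - ca[1:-1]
        cosang = (v1 * v2).sum(1) / np.maximum(
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1), 1e-8
        )
        f[1:-1, 2] = cosang
    if n > 4:
        f[2:-2, 1] = np.linalg.norm(ca[4:] - ca[:-4], axis=1) / 10.0
    if n > 3:
        b1 = ca[1:-2] - ca[:-3]
        b2 = ca[2:-1] - ca[1:-2]
        b3 = ca[3:] - ca[2:-1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=1, keepdims=True), 1e-8))
        x = (n1 * n2).sum(1)
        y = (m1 * n2).sum(1)
        dih = np.arctan2(y, x)
        f[1:-2, 3] = np.sin(dih)
        f[1:-2, 4] = np.cos(dih)
    f[:, 5] = np.linalg.norm(coords[:, 0] - coords[:, 3], axis=1) / 5.0  # N–O
    f[:, 6] = np.linalg.norm(coords[:, 1] - coords[:, 3], axis=1) / 5.0  # CA–O
    f[0, 7] = 1.0
    f[-1, 8] = 1.0
    f[:, 9] = 1.0
    return f


def _edge_features(coords: np.ndarray, nbr_idx: np.ndarray) -> np.ndarray:
    """Pairwise invariant edge features for each residue's neighbors."""
    r, k = nbr_idx.shape
    ca = coords[:, 1]
    i_idx = np.repeat(np.arange(r), k)
    j_idx = nbr_idx.reshape(-1)
    d_ca = np.linalg.norm(ca[i_idx] - ca[j_idx], axis=1)
    rbf = np.exp(-((d_ca[:, None] - _RBF_CENTERS[None, :]) ** 2) / (2 * _RBF_SIGMA**2))
    extra = np.stack(
        [
            np.linalg.norm(coords[i_idx, 0] - coords[j_idx, 0], axis=1) / 10.0,
            np.linalg.norm(coords[i_idx, 2] - coords[j_idx, 2], axis=1) / 10.0,
            np.linalg.norm(coords[i_idx, 3] - coords[j_idx, 3], axis=1) / 10.0,
            np.linalg.norm(coords[i_idx, 1] - coords[j_idx, 3], axis=1) / 10.0,
        ],
        axis=1,
    )
    sep = (j_idx - i_idx).astype(float)
    seq = np.stack(
        [np.sign(sep), np.minimum(np.abs(sep), 32.0) / 32.0, np.ones_like(sep)],
        axis=1,
    )
    feats = np.concatenate([rbf, extra, seq], axis=1)
    return feats.reshape(r, k, _EDGE_FEATS)


class _Featurizer:
    """Frozen random-feature trunk shared by all models of one config."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        d = config.feature_dim
        rng = np.random.default_rng(config.featurizer_seed)

        def w(n_out: int, n_in: int) -> np.ndarray:
            return rng.standard_normal((n_out, n_in)) / math.sqrt(n_in)

        self.Wn = w(d, _NODE_FEATS)
        self.We = w(d, _EDGE_FEATS)
        self.enc_msg = [w(d, 2 * d) for _ in range(config.encoder_layers)]
        self.enc_upd = [w(d, 2 * d) for _ in range(config.encoder_layers)]
        self.tok_emb = rng.standard_normal((VOCAB_SIZE + 1, _TOKEN_DIM)) / math.sqrt(
            _TOKEN_DIM
        )
        self.Wt_tok = w(d, _TOKEN_DIM)
        self.Wt_edge = w(d, d)
        self.Wc = w(d, 3 * d)
        self.dec_blocks = [w(d, d) for _ in range(config.decoder_layers - 1)]
        # Token part of the decoder message, precomputed for all 22 symbols.
        self.tok_lin = self.tok_emb @ self.Wt_tok.T  # (22, D)

    # ------------------------------------------------------------- encoding
    def encode(self, structure: BackboneStructure) -> Encoding:
        coords = structure.coords
        r = len(structure)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite backbone coordinates")
        k = min(self.config.n_neighbors, max(r - 1, 0))
        ca = coords[:, 1]
        d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if k > 0:
            nbr_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        else:
            nbr_idx = np.empty((r, 0), dtype=int)
        h = np.tanh(_rigid_invariant_node_features(coords) @ self.Wn.T)
        if k > 0:
            e = np.tanh(_edge_features(coords, nbr_idx) @ self.We.T)  # (R,K,D)
            for Wm, Wh in zip(self.enc_msg, self.enc_upd):
                hj = h[nbr_idx]  # (R,K,D)
                m = np.tanh(np.concatenate([hj, e], axis=-1) @ Wm.T)
                agg = m.mean(axis=1)
                h = np.tanh(np.concatenate([h, agg], axis=-1) @ Wh.T)
            edge_lin = e @ self.Wt_edge.T
        else:
            e = np.empty((r, 0, self.config.feature_dim))
            edge_lin = e
        return Encoding(h, e, nbr_idx, edge_lin, structure)

    # ----------------------------------------------------- decoder contexts
    def _finish_context(self, pre: np.ndarray) -> np.ndarray:
        c = np.tanh(pre @ self.Wc.T)
        for Wd in self.dec_blocks:
            c = np.tanh(c @ Wd.T) + c
        return c

    def contexts_teacher_forced(
        self, enc: Encoding, tokens: np.ndarray, order: np.ndarray
    ) -> np.ndarray:
        """Decoder context for every position under one decoding order.

        Row p conditions exactly on the tokens of positions decoded before p
        in *order* (teacher-forced); all later positions appear as the mask
        symbol.  Returns an (R, D) array.
        """
        r = enc.n_residues
        k = enc.nbr_idx.shape[1]
        rank = np.empty(r, dtype=int)
        rank[order] = np.arange(r)
        if k > 0:
            decoded = rank[enc.nbr_idx] < rank[:, None]  # (R, K)
            sym = np.where(decoded, tokens[enc.nbr_idx], _MASK)
            m = np.tanh(self.tok_lin[sym] + enc.edge_lin)  # (R, K, D)
            agg_dec = np.where(decoded[..., None], m, 0.0).sum(1) / k
            agg_und = np.where(~decoded[..., None], m, 0.0).sum(1) / k
        else:
            agg_dec = np.zeros_like(enc.node_emb)
            agg_und = np.zeros_like(enc.node_emb)
        pre = np.concatenate([enc.node_emb, agg_dec, agg_und], axis=1)
        return self._finish_context(pre)

    def context_single(
        self, enc: Encoding, tokens: np.ndarray, decoded: np.ndarray, position: int
    ) -> np.ndarray:
        """Decoder context for one position given the current decoded mask."""
        k = enc.nbr_idx.shape[1]
        if k > 0:
            nbrs = enc.nbr_idx[position]
            dec = decoded[nbrs]
            sym = np.where(dec, tokens[nbrs], _MASK)
            m = np.tanh(self.tok_lin[sym] + enc.edge_lin[position])  # (K, D)
            agg_dec = np.where(dec[:, None], m, 0.0).sum(0) / k
            agg_und = np.where(~dec[:, None], m, 0.0).sum(0) / k
        else:
            agg_dec = np.zeros(self.config.feature_dim)
            agg_und = np.zeros(self.config.feature_dim)
        pre = np.concatenate([enc.node_emb[position], agg_dec, agg_und])
        return self._finish_context(pre[None, :])[0]


_FEATURIZER_CACHE: dict[ModelConfig, _Featurizer] = {}


def _featurizer_for(config: ModelConfig) -> _Featurizer:
    if config not in _FEATURIZER_CACHE:
        _FEATURIZER_CACHE[config] = _Featurizer(config)
    return _FEATURIZER_CACHE[config]


class InverseFoldingModel:
    """Structure-conditioned arbitrary-order autoregressive design model.

    The trainable state is the readout head (two dense layers); the trunk is
    deterministic given :attr:`config`.  Use :meth:`initialize` for a fresh
    model, :meth:`sample_sequence` to design, :meth:`sequence_log_prob` for
    policy log-likelihoods.
    """

    def __init__(self, config: ModelConfig, head: dict[str, np.ndarray]) -> None:
        self.config = config
        self.head = head
        self._featurizer = _featurizer_for(config)
        self._encode_cache: dict[int, Encoding] = {}

    # ------------------------------------------------------------ lifecycle
    @classmethod
    def initialize(
        cls, config: ModelConfig | None = None, seed: int = 0
    ) -> "InverseFoldingModel":
        """Fresh model: random first head layer, zeroed output layer.

        The zero output layer makes the initial next-token distribution
        exactly uniform over the 21-symbol vocabulary.
        """
        config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        d, h = config.feature_dim, config.hidden_dim
        head = {
            "W1": rng.standard_normal((h, d)) / math.sqrt(d),
            "b1": np.zeros(h),
            "W2": np.zeros((VOCAB_SIZE, h)),
            "b2": np.zeros(VOCAB_SIZE),
        }
        return cls(config, head)

    def copy(self) -> "InverseFoldingModel":
        return InverseFoldingModel(
            self.config, {k: v.copy() for k, v in self.head.items()}
        )

    # -------------------------------------------------------------- encode
    def encode_backbone(self, structure: BackboneStructure) -> Encoding:
        """Node and edge embeddings for *structure* (memoized per object)."""
        key = id(structure)
        if key not in self._encode_cache:
            if len(self._encode_cache) > 256:
                self._encode_cache.clear()
            self._encode_cache[key] = self._featurizer.encode(structure)
        return self._encode_cache[key]

    def _as_encoding(self, x: Union[BackboneStructure, Encoding]) -> Encoding:
        return x if isinstance(x, Encoding) else self.encode_backbone(x)

    # ---------------------------------------------------------------- head
    def logits(self, contexts: np.ndarray) -> np.ndarray:
        z = np.tanh(contexts @ self.head["W1"].T + self.head["b1"])
        return z @ self.head["W2"].T + self.head["b2"]

    def _log_prob_and_grad_from_contexts(
        self, contexts: np.ndarray, tokens: np.ndarray, want_grad: bool = True
    ) -> tuple[float, dict[str, np.ndarray] | None]:
        z = np.tanh(contexts @ self.head["W1"].T + self.head["b1"])
        logits = z @ self.head["W2"].T + self.head["b2"]
        logp = log_softmax(logits, axis=1)
        rows = np.arange(len(tokens))
        value = float(logp[rows, tokens].sum())
        if not want_grad:
            return value, None
        p = np.exp(logp)
        g_logits = -p
        g_logits[rows, tokens] += 1.0  # d sum log p / d logits
        gW2 = g_logits.T @ z
        gb2 = g_logits.sum(0)
        dz = (g_logits @ self.head["W2"]) * (1 - z * z)
        gW1 = dz.T @ contexts
        gb1 = dz.sum(0)
        return value, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    # ------------------------------------------------------------ contract
    def next_token_distribution(
        self,
        structure: Union[BackboneStructure, Encoding],
        partial_sequence,
        order: np.ndarray,
        step: int,
    ) -> np.ndarray:
        """Probability vector over the 21 symbols for the next position.

        *partial_sequence* may be a string or a list with ``None`` at
        positions not yet decoded; every position decoded before *step* in
        *order* must be filled.  The distribution depends only on those
        positions (causality under the decoding order).
        """
        enc = self._as_encoding(structure)
        r = enc.n_residues
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(r)):
            raise ValueError("order must be a permutation of the residue positions")
        if not 0 <= step < r:
            raise ValueError(f"step {step} out of range for {r} residues")
        tokens = np.zeros(r, dtype=np.int64)
        decoded = np.zeros(r, dtype=bool)
        for t in range(step):
            p = order[t]
            symbol = partial_sequence[p]
            if symbol is None:
                raise ValueError(
                    f"partial sequence is inconsistent with the order: position {p} "
                    f"(decoded at step {t}) is unset"
                )
            tokens[p] = VOCAB_INDEX[symbol]
            decoded[p] = True
        c = self._featurizer.context_single(enc, tokens, decoded, int(order[step]))
        return softmax(self.logits(c[None, :])[0])

    def sample_sequence(
        self,
        structure: Union[BackboneStructure, Encoding],
        temperature: float = 0.1,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        order: np.ndarray | None = None,
    ) -> SampleResult:
        """Sample a design under a uniformly random decoding order.

        Tokens are drawn from the temperature-scaled distribution with the
        ``X`` symbol masked out (it is input-only).  The returned per-position
        log-probabilities are the unscaled model log-likelihoods
        ``log pi(token | context)``, so their sum equals
        :meth:`sequence_log_prob` for the same order.
        """
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        enc = self._as_encoding(structure)
        r = enc.n_residues
        if rng is None:
            rng = np.random.default_rng(seed)
        if order is None:
            order = rng.permutation(r)
        else:
            order = np.asarray(order, dtype=int)
        tokens = np.zeros(r, dtype=np.int64)
        decoded = np.zeros(r, dtype=bool)
        log_probs = np.zeros(r)
        for step in range(r):
            p = int(order[step])
            c = self._featurizer.context_single(enc, tokens, decoded, p)
            logits = self.logits(c[None, :])[0]
            full_logp = log_softmax(logits)
            masked = logits.copy()
            masked[_X_INDEX] = -np.inf  # 'X' is input-only, never emitted
            probs = softmax(masked / temperature)
            tok = int(rng.choice(VOCAB_SIZE, p=probs))
            tokens[p] = tok
            decoded[p] = True
            log_probs[p] = full_logp[tok]
        return SampleResult(decode_tokens(tokens), order, log_probs)

    def sequence_log_prob(
        self,
        structure: Union[BackboneStructure, Encoding],
        sequence: str,
        order: np.ndarray,
    ) -> float:
        """log pi(sequence | structure) under the given decoding order."""
        enc = self._as_encoding(structure)
        if len(sequence) != enc.n_residues:
            raise ValueError(
                f"sequence length {len(sequence)} does not match the "
                f"{enc.n_residues}-residue backbone"
            )
        tokens = encode_sequence(sequence)
        contexts = self._featurizer.contexts_teacher_forced(
            enc, tokens, np.asarray(order, dtype=int)
        )
        value, _ = self._log_prob_and_grad_from_contexts(contexts, tokens, want_grad=False)
        return value

    def decoding_contexts(
        self,
        structure: Union[BackboneStructure, Encoding],
        sequence: str,
        order: np.ndarray,
    ) -> np.ndarray:
        """Teacher-forced decoder contexts for (sequence, order).

        The trunk is frozen, so these can be cached and reused across
        training steps; only the readout head changes.
        """
        enc = self._as_encoding(structure)
        return self._featurizer.contexts_teacher_forced(
            enc, encode_sequence(sequence), np.asarray(order, dtype=int)
        )

    def log_prob_from_contexts(
        self, contexts: np.ndarray, tokens: np.ndarray, want_grad: bool = False
    ):
        """Sequence log-prob (and optionally head gradients) from cached contexts."""
        value, grad = self._log_prob_and_grad_from_contexts(contexts, tokens, want_grad)
        return (value, grad) if want_grad else value

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "format": "deimmune-model-v1",
            "config": asdict(self.config),
            "head": {k: v.tolist() for k, v in self.head.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "InverseFoldingModel":
        config = ModelConfig(**d["config"])
        head = {k: np.asarray(v, dtype=float) for k, v in d["head"].items()}
        return cls(config, head)

    @classmethod
    def load(cls, path: str | Path) -> "InverseFoldingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def pretrain(
    model: InverseFoldingModel,
    structures: list[BackboneStructure],
    epochs: int = 150,
    learning_rate: float = 1e-2,
    seed: int = 0,
    grad_clip: float = 1.0,
) -> list[float]:
    """Supervised pretraining on native sequences (the foundation stage).

    Minimizes per-token cross-entropy of each structure's native sequence
    under a fresh uniformly random decoding order per epoch, with Adam on
    the readout head.  Returns the per-epoch mean cross-entropy history.
    """
    for s in structures:
        if s.sequence is None:
            raise ValueError("all structures need a native sequence to pretrain on")
    rng = np.random.default_rng(seed)
    opt = Adam(learning_rate)
    encs = [model.encode_backbone(s) for s in structures]
    toks = [encode_sequence(s.sequence) for s in structures]
    history: list[float] = []
    for _ in range(epochs):
        total_ce = 0.0
        total_tokens = 0
        grads = {k: np.zeros_like(v) for k, v in model.head.items()}
        for enc, tok in zip(encs, toks):
            order = rng.permutation(enc.n_residues)
            contexts = model._featurizer.contexts_teacher_forced(enc, tok, order)
            logp, g = model._log_prob_and_grad_from_contexts(contexts, tok)
            total_ce -= logp
            total_tokens += len(tok)
            for k in grads:
                grads[k] -= g[k]  # maximize log-likelihood
        grads = {k: v / total_tokens for k, v in grads.items()}
        grads = clip_grad_norm(grads, grad_clip)
        opt.step(model.head, grads)
        history.append(total_ce / total_tokens)
    return history
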