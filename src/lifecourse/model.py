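"""A GPT-style transformer over (age, token) event streams.

Three modifications distinguish this architecture from a standard
decoder-only text transformer:

1. **Continuous-age encoding.**  The learned positional embedding is
   replaced by a fixed sinusoidal basis evaluated on the event *age*
   (days from birth), mixed by one trainable linear map.  No parameter
   is tied to a sequence position, so inputs of arbitrary length are
   accepted.
2. **Same-time attention masking.**  Causal attention is tightened so a
   query may only attend keys with strictly smaller age (plus itself):
   co-occurring events carry no order information and must not leak
   into each other's predictions.
3. **Rate-valued logits.**  Each predictable token's logit is read as
   the natural log of an event rate per day; a single logits vector
   feeds both the categorical (softmax) and exponential waiting-time
   likelihood terms.

The published full-scale configuration (embedding 120, 12 layers,
12 heads, vocabulary 1,270, tied embeddings, bias-free linear maps)
counts 2.2 million trainable parameters; a desk-scale profile is
provided for experiments on synthetic cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .trajectory import DAYS_PER_YEAR, Trajectory
from .vocab import TokenVocabulary

#: additive mask value standing in for -inf inside softmax paths
NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``age_basis_count`` sinusoidal components (sin/cos pairs at
    geometrically spaced periods from 100 years down to 2 days) feed the
    trainable age projection.  ``use_biases=False`` and
    ``tie_weights=True`` are the pinned published choices.
    """

    vocab_size: int
    embed_dim: int = 120
    n_layers: int = 12
    n_heads: int = 12
    age_basis_count: int = 120
    max_block_tokens: int = 256
    dropout: float = 0.0
    tie_weights: bool = True
    use_biases: bool = False
    learned_positions: bool = False  # ablation: plain GPT positional table

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.age_basis_count % 2:
            raise ValueError("age_basis_count must be even")
        if self.vocab_size < 14:
            raise ValueError("vocab_size below the structural minimum of 14")

    @classmethod
    def paper_scale(cls, vocab_size: int = 1270) -> "ModelConfig":
        return cls(vocab_size=vocab_size)

    @classmethod
    def desk_scale(cls, vocab_size: int, **kw) -> "ModelConfig":
        kw.setdefault("embed_dim", 32)
        kw.setdefault("n_layers", 4)
        kw.setdefault("n_heads", 4)
        kw.setdefault("age_basis_count", 32)
        kw.setdefault("max_block_tokens", 64)
        # mild dropout: small-cohort fits otherwise over-disperse their
        # predicted rates in the upper tail
        kw.setdefault("dropout", 0.1)
        return cls(vocab_size=vocab_size, **kw)


# ---------------------------------------------------------------------
# age encoding
# ---------------------------------------------------------------------

def age_basis_periods(age_basis_count: int) -> np.ndarray:
    """Geometric ladder of periods (days), longest to shortest.

    Spans 100 years down to 2 days over ``age_basis_count / 2`` sin-cos
    pairs, covering both lifetime-scale and sub-year structure; the
    trainable mixing map downstream makes the model insensitive to the
    exact ladder.
    """
    n_pairs = age_basis_count // 2
    return np.geomspace(100 * DAYS_PER_YEAR, 2.0, n_pairs)


def encode_age(ages_days: np.ndarray, age_basis_count: int) -> np.ndarray:
    """Sinusoidal age basis, shape ``ages.shape + (age_basis_count,)``.

    Component ``2k`` is ``sin(2*pi*age/P_k)`` and ``2k+1`` is the
    matching cosine; age 0 maps to all-zero sines and all-one cosines.
    Raises on negative or non-finite ages.
    """
    ages = np.asarray(ages_days, dtype=np.float64)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if np.any(ages < 0):
        raise ValueError("negative age")
    periods = age_basis_periods(age_basis_count)
    phase = 2.0 * np.pi * ages[..., None] / periods
    out = np.empty(ages.shape + (age_basis_count,), dtype=np.float64)
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out


# ---------------------------------------------------------------------
# attention mask
# ---------------------------------------------------------------------

def build_attention_mask(
    ages: np.ndarray, key_padding: np.ndarray | None = None
) -> np.ndarray:
    """Boolean (query x key) mask: True where attention is allowed.

    Query ``i`` may attend key ``j`` iff ``age_j < age_i`` or ``j == i``
    (self-attention is retained so no row is fully masked; prediction
    sources are selected downstream, so self-identity cannot leak into a
    co-occurring target).  Keys flagged in ``key_padding`` are masked
    for every other query.  ``ages`` must be sorted non-decreasing.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1:
        raise ValueError("ages must be 1-D")
    if np.any(np.diff(ages) < 0):
        raise ValueError("ages must be sorted non-decreasing")
    allowed = ages[None, :] < ages[:, None]
    np.fill_diagonal(allowed, True)
    if key_padding is not None:
        pad = np.asarray(key_padding, dtype=bool)
        allowed = allowed & ~pad[None, :]
        np.fill_diagonal(allowed, True)
    return allowed


def _batched_mask_bias(
    ages: np.ndarray, key_padding: np.ndarray | None, dtype
) -> np.ndarray:
    """Additive (B, 1, T, T) attention bias: 0 allowed / NEG_INF masked."""
    B, T = ages.shape
    allowed = ages[:, None, :] < ages[:, :, None]
    eye = np.eye(T, dtype=bool)
    if key_padding is not None:
        allowed &= ~key_padding[:, None, :]
    allowed |= eye[None, :, :]
    bias = np.where(allowed, 0.0, NEG_INF).astype(dtype)
    return bias[:, None, :, :]


# ---------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------

def count_parameters(config: ModelConfig) -> int:
    """Exact count of trainable scalars for a configuration."""
    d, V, K, L = (
        config.embed_dim,
        config.vocab_size,
        config.age_basis_count,
        config.n_layers,
    )
    b = 1 if config.use_biases else 0
    n = V * d  # token embedding
    if config.learned_positions:
        n += config.max_block_tokens * d
    else:
        n += K * d + b * d  # age projection
    per_layer = (
        d + b * d  # ln1 gain (+bias)
        + 3 * d * d + b * 3 * d  # q, k, v
        + d * d + b * d  # attention output projection
        + d + b * d  # ln2
        + d * 4 * d + b * 4 * d  # mlp up
        + 4 * d * d + b * d  # mlp down
    )
    n += L * per_layer
    n += d + b * d  # final layer norm
    if not config.tie_weights:
        n += V * d
    return n


class TrajectoryTransformer:
    """The network: parameter store plus forward pass.

    Parameters are float32 by default; pass ``dtype=np.float64`` for
    finite-difference gradient checking.
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab: TokenVocabulary,
        seed: int = 0,
        dtype=np.float32,
    ):
        if len(vocab) != config.vocab_size:
            raise ValueError("config.vocab_size must match the vocabulary")
        self.config = config
        self.vocab = vocab
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))
        # -inf additive mask excluding sex/lifestyle/pad from likelihoods
        self.predictable_bias = np.where(
            vocab.predictable_mask, 0.0, NEG_INF
        ).astype(dtype)
        self.predictable_f = vocab.predictable_mask.astype(dtype)

    # -- parameters ---------------------------------------------------
    def _p(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array.astype(self.dtype), requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, V, K = cfg.embed_dim, cfg.vocab_size, cfg.age_basis_count
        std = 0.02
        # residual-path projections get the depth-scaled GPT-2 init
        res_std = std / np.sqrt(2 * cfg.n_layers) if cfg.n_layers else std
        self._p("wte", rng.normal(0, std, (V, d)))
        if cfg.learned_positions:
            self._p("wpe", rng.normal(0, std, (cfg.max_block_tokens, d)))
        else:
            self._p("age_proj", rng.normal(0, std, (K, d)))
            if cfg.use_biases:
                self._p("age_bias", np.zeros(d))
        for i in range(cfg.n_layers):
            self._p(f"h{i}.ln1", np.ones(d))
            self._p(f"h{i}.wq", rng.normal(0, std, (d, d)))
            self._p(f"h{i}.wk", rng.normal(0, std, (d, d)))
            self._p(f"h{i}.wv", rng.normal(0, std, (d, d)))
            self._p(f"h{i}.wo", rng.normal(0, res_std, (d, d)))
            self._p(f"h{i}.ln2", np.ones(d))
            self._p(f"h{i}.fc", rng.normal(0, std, (d, 4 * d)))
            self._p(f"h{i}.proj", rng.normal(0, res_std, (4 * d, d)))
            if cfg.use_biases:
                for nm, width in (
                    ("ln1_b", d), ("bq", d), ("bk", d), ("bv", d), ("bo", d),
                    ("ln2_b", d), ("fc_b", 4 * d), ("proj_b", d),
                ):
                    self._p(f"h{i}.{nm}", np.zeros(width))
        self._p("lnf", np.ones(d))
        if cfg.use_biases:
            self._p("lnf_b", np.zeros(d))
        if not cfg.tie_weights:
            self._p("lm_head", rng.normal(0, std, (d, V)))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward ------------------------------------------------------
    def _linear(self, x: Tensor, w: str, b: str | None = None) -> Tensor:
        out = x @ self.params[w]
        if self.config.use_biases and b is not None and b in self.params:
            out = out + self.params[b]
        return out

    def _ln(self, x: Tensor, g: str, b: str | None = None) -> Tensor:
        y = ad.layer_norm(x, self.params[g])
        if self.config.use_biases and b is not None and b in self.params:
            y = y + self.params[b]
        return y

    def forward(
        self,
        tokens: np.ndarray,
        ages: np.ndarray,
        key_padding: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
        attention_sink: list | None = None,
    ) -> Tensor:
        """Logits over the vocabulary at every position.

        Parameters
        ----------
        tokens : (B, T) int array of vocabulary indices.
        ages : (B, T) float array of ages in days, sorted within rows.
        key_padding : (B, T) bool, True at block-padding positions.
        train : enable dropout (requires ``rng``).

        Returns a ``(B, T, vocab)`` Tensor of raw logits.  Non-
        predictable tokens are *not* masked here; loss and sampling
        apply the -inf convention via :attr:`predictable_bias`.
        """
        cfg = self.config
        tokens = np.asarray(tokens, dtype=np.int64)
        ages = np.asarray(ages, dtype=float)
        if tokens.ndim == 1:
            tokens, ages = tokens[None, :], ages[None, :]
            if key_padding is not None:
                key_padding = np.asarray(key_padding, bool)[None, :]
        if tokens.min(initial=0) < 0 or tokens.max(initial=0) >= cfg.vocab_size:
            raise ValueError("token index out of range")
        B, T = tokens.shape
        drop_rng = rng if (train and cfg.dropout > 0) else None

        x = ad.embedding(self.params["wte"], tokens)
        if cfg.learned_positions:
            if T > cfg.max_block_tokens:
                raise ValueError("learned positions cap sequence length")
            x = x + ad.embedding(self.params["wpe"], np.arange(T))
        else:
            basis = encode_age(ages, cfg.age_basis_count).astype(self.dtype)
            age_emb = Tensor(basis) @ self.params["age_proj"]
            if cfg.use_biases:
                age_emb = age_emb + self.params["age_bias"]
            x = x + age_emb
        x = ad.dropout(x, cfg.dropout, drop_rng)

        bias = _batched_mask_bias(ages, key_padding, self.dtype)
        nh, hd = cfg.n_heads, cfg.embed_dim // cfg.n_heads
        scale = 1.0 / np.sqrt(hd)
        for i in range(cfg.n_layers):
            h = self._ln(x, f"h{i}.ln1", f"h{i}.ln1_b")
            q = self._linear(h, f"h{i}.wq", f"h{i}.bq")
            k = self._linear(h, f"h{i}.wk", f"h{i}.bk")
            v = self._linear(h, f"h{i}.wv", f"h{i}.bv")
            q = q.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, nh, hd).transpose(0, 2, 3, 1)
            v = v.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
            att = ad.masked_softmax((q @ k) * scale, bias)
            if attention_sink is not None:
                attention_sink.append(att.data.copy())
            att = ad.dropout(att, cfg.dropout, drop_rng)
            y = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, cfg.embed_dim)
            y = self._linear(y, f"h{i}.wo", f"h{i}.bo")
            x = x + ad.dropout(y, cfg.dropout, drop_rng)
            h = self._ln(x, f"h{i}.ln2", f"h{i}.ln2_b")
            m = self._linear(h, f"h{i}.fc", f"h{i}.fc_b").gelu()
            m = self._linear(m, f"h{i}.proj", f"h{i}.proj_b")
            x = x + ad.dropout(m, cfg.dropout, drop_rng)

        x = self._ln(x, "lnf", "lnf_b")
        if cfg.tie_weights:
            logits = x @ self.params["wte"].transpose(1, 0)
        else:
            logits = x @ self.params["lm_head"]
        return logits

    # -- inference helpers -------------------------------------------
    def attention_maps(
        self, tokens: np.ndarray, ages: np.ndarray,
        key_padding: np.ndarray | None = None,
    ) -> list[np.ndarray]:
        """Per-layer attention weights, each (B, heads, query, key)."""
        sink: list[np.ndarray] = []
        self.forward(tokens, ages, key_padding, attention_sink=sink)
        return sink

    def logits(self, tokens: np.ndarray, ages: np.ndarray) -> np.ndarray:
        """Eval-mode logits with the -inf mask applied, as an ndarray."""
        out = self.forward(tokens, ages).data
        return out + self.predictable_bias

    def rate_vector(self, traj: Trajectory) -> np.ndarray:
        """Per-token event rates (events/day) at the last position.

        Non-predictable entries are exactly zero.
        """
        logits = self.forward(traj.tokens, traj.ages).data[0, -1]
        rates = np.exp(logits.astype(np.float64))
        rates[~self.vocab.predictable_mask] = 0.0
        return rates

    # -- persistence --------------------------------------------------
    def save(self, directory) -> None:
        """Weights as .npz plus a text sidecar with config + vocab checksum."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **{k: v.data for k, v in self.params.items()})
        sidecar = dict(asdict(self.config), vocab_checksum=self.vocab.checksum())
        (directory / "config.json").write_text(json.dumps(sidecar, indent=1))
        self.vocab.write_tsv(directory / "vocab.tsv")

    @classmethod
    def load(cls, directory, vocab: TokenVocabulary | None = None) -> "TrajectoryTransformer":
        directory = Path(directory)
        sidecar = json.loads((directory / "config.json").read_text())
        checksum = sidecar.pop("vocab_checksum")
        if vocab is None:
            vocab = TokenVocabulary.read_tsv(directory / "vocab.tsv")
        if vocab.checksum() != checksum:
            raise ValueError("vocabulary checksum mismatch")
        model = cls(ModelConfig(**sidecar), vocab)
        with np.load(directory / "weights.npz") as z:
            for k in model.params:
                model.params[k].data = z[k].astype(model.dtype)
        return model
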