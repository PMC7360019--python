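"""The sentence-boundary tagging network and its configuration.

Per token, a 300-d word vector is summed with an "adjustment vector"
produced by a character CNN (30-d character embeddings, one convolutional
layer of 300 width-4 filters, global max pooling) over the token's
character context; the result is batch-normalized, run through a
bidirectional LSTM, batch-normalized again, and scored by a single
sigmoid dense unit whose weights carry an L1 penalty.  The sigmoid output
is the probability that the token begins a sentence (tag ``B``); O
positions are masked everywhere, so the network only ever discriminates
B from I.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .features import Vocab

__all__ = [
    "ModelConfig",
    "Tower",
    "Head",
    "SBDNetwork",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    Dimensions (300-d word vectors summed with 300 CNN filters over 30-d
    character embeddings, width-4 filters, 7-char context, sequences of 32
    words in batches of 32, early-stopping patience 5) follow the
    published architecture; knobs the publication leaves open (LSTM units,
    dropout rates, L1 strength, Adam settings) have stated defaults here
    and are recorded in run logs.
    """

    word_dim: int = 300
    char_dim: int = 30
    cnn_filters: int = 300
    cnn_width: int = 4
    context_chars: int = 7
    lstm_units: int = 200  # per direction
    dropout: float = 0.5
    recurrent_dropout: float = 0.25
    l1: float = 1e-5
    sequence_length: int = 32
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 5
    learning_rate: float = 1e-3
    decision_threshold: float = 0.5
    class_weighting: bool = True
    freeze_base: bool = True  # ensemble stacking: keep the source tower fixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.word_dim != self.cnn_filters:
            raise ValueError(
                "cnn_filters must equal word_dim: the CNN output is an "
                "adjustment vector summed with the word vector"
            )
        for name in ("dropout", "recurrent_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.l1 < 0:
            raise ValueError("l1 must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _init_lstm(rng, in_dim: int, units: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    w_x = nn.glorot_uniform(rng, (in_dim, 4 * units))
    w_h = np.concatenate(
        [nn.orthogonal(rng, (units, units)) for _ in range(4)], axis=1
    )
    bias = np.zeros(4 * units)
    bias[units : 2 * units] = 1.0  # forget-gate bias
    return w_x, w_h, bias


class Tower:
    """Word-representation layer + bidirectional LSTM encoder.

    One tower maps (word ids, char-context ids) to contextual word
    representations of dimension ``2 * lstm_units``.  The stacking
    ensemble sums the outputs of two towers before a shared prediction
    layer.
    """

    def __init__(
        self,
        config: ModelConfig,
        char_vocab_size: int,
        word_vocab_size: int,
        rng: np.random.Generator,
        word_vectors: Optional[np.ndarray] = None,
    ):
        self.config = config
        self.char_vocab_size = char_vocab_size
        self.word_vocab_size = word_vocab_size
        c = config
        self.params: Dict[str, np.ndarray] = {}
        p = self.params
        p["char_emb"] = rng.uniform(-0.05, 0.05, (char_vocab_size, c.char_dim))
        p["char_emb"][0] = 0.0  # PAD
        p["conv_w"] = nn.glorot_uniform(rng, (c.cnn_width * c.char_dim, c.cnn_filters))
        p["conv_b"] = np.zeros(c.cnn_filters)
        if word_vectors is not None:
            if word_vectors.shape != (word_vocab_size, c.word_dim):
                raise ValueError(
                    f"word vector table shape {word_vectors.shape} does not match "
                    f"({word_vocab_size}, {c.word_dim})"
                )
            self.fixed_word_vectors: Optional[np.ndarray] = word_vectors.astype(np.float64)
        else:
            self.fixed_word_vectors = None
            p["word_emb"] = rng.uniform(-0.05, 0.05, (word_vocab_size, c.word_dim))
            p["word_emb"][0] = 0.0
        p["bn1_gamma"] = np.ones(c.word_dim)
        p["bn1_beta"] = np.zeros(c.word_dim)
        p["fwd_wx"], p["fwd_wh"], p["fwd_b"] = _init_lstm(rng, c.word_dim, c.lstm_units)
        p["bwd_wx"], p["bwd_wh"], p["bwd_b"] = _init_lstm(rng, c.word_dim, c.lstm_units)
        p["bn2_gamma"] = np.ones(2 * c.lstm_units)
        p["bn2_beta"] = np.zeros(2 * c.lstm_units)
        self.buffers = {
            "bn1": {"mean": np.zeros(c.word_dim), "var": np.ones(c.word_dim)},
            "bn2": {"mean": np.zeros(2 * c.lstm_units), "var": np.ones(2 * c.lstm_units)},
        }

    # -- stage 1: per-token word representation --------------------------

    def word_representation(
        self,
        word_ids: np.ndarray,
        char_ids: np.ndarray,
        training: bool = False,
    ) -> Tuple[np.ndarray, dict]:
        """(B, T) word ids + (B, T, L) char-context ids -> (B, T, D)."""
        p = self.params
        b, t = word_ids.shape
        if self.fixed_word_vectors is not None:
            wv = self.fixed_word_vectors[word_ids]
        else:
            wv = p["word_emb"][word_ids]
        flat_chars = char_ids.reshape(b * t, -1)
        ce = p["char_emb"][flat_chars]
        pooled, conv_cache = nn.conv1d_maxpool_forward(ce, p["conv_w"], p["conv_b"])
        summed = wv + pooled.reshape(b, t, -1)
        flat = summed.reshape(b * t, -1)
        normed, bn_cache = nn.batchnorm_forward(
            flat, p["bn1_gamma"], p["bn1_beta"], self.buffers["bn1"], training
        )
        cache = {
            "word_ids": word_ids,
            "char_ids": flat_chars,
            "conv": conv_cache,
            "bn1": bn_cache,
            "shape": (b, t),
        }
        return normed.reshape(b, t, -1), cache

    def _backward_word_representation(
        self, d_x: np.ndarray, cache: dict, grads: Dict[str, np.ndarray]
    ) -> None:
        p = self.params
        b, t = cache["shape"]
        flat = d_x.reshape(b * t, -1)
        d_sum, d_g, d_b = nn.batchnorm_backward(flat, cache["bn1"])
        grads["bn1_gamma"] += d_g
        grads["bn1_beta"] += d_b
        d_pooled = d_sum  # (B*T, F)
        d_wv = d_sum.reshape(b, t, -1)
        d_ce, d_kernel, d_cbias = nn.conv1d_maxpool_backward(
            d_pooled, p["conv_w"], cache["conv"]
        )
        grads["conv_w"] += d_kernel
        grads["conv_b"] += d_cbias
        grads["char_emb"] += nn.embedding_backward(
            d_ce, cache["char_ids"], self.char_vocab_size
        )
        if self.fixed_word_vectors is None:
            grads["word_emb"] += nn.embedding_backward(
                d_wv, cache["word_ids"], self.word_vocab_size
            )

    # -- stage 2: bidirectional context encoding -------------------------

    def encode_context(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        """(B, T, D) word representations -> (B, T, 2H) contextual embeddings."""
        p = self.params
        c = self.config
        b, t, d = x.shape
        in_mask = rec_mask_f = rec_mask_b = None
        if training and rng is not None:
            in_mask = nn.dropout_mask(rng, (b, 1, d), c.dropout)
            rec_mask_f = nn.dropout_mask(rng, (b, c.lstm_units), c.recurrent_dropout)
            rec_mask_b = nn.dropout_mask(rng, (b, c.lstm_units), c.recurrent_dropout)
        xd = x if in_mask is None else x * in_mask
        h_f, cache_f = nn.lstm_forward(xd, p["fwd_wx"], p["fwd_wh"], p["fwd_b"], rec_mask_f)
        x_rev = xd[:, ::-1, :]
        h_r, cache_b = nn.lstm_forward(x_rev, p["bwd_wx"], p["bwd_wh"], p["bwd_b"], rec_mask_b)
        h_b = h_r[:, ::-1, :]
        concat = np.concatenate([h_f, h_b], axis=2)
        flat = concat.reshape(b * t, -1)
        normed, bn_cache = nn.batchnorm_forward(
            flat, p["bn2_gamma"], p["bn2_beta"], self.buffers["bn2"], training
        )
        cache = {
            "lstm_f": cache_f,
            "lstm_b": cache_b,
            "in_mask": in_mask,
            "rec_f": rec_mask_f,
            "rec_b": rec_mask_b,
            "bn2": bn_cache,
            "shape": (b, t, d),
        }
        return normed.reshape(b, t, -1), cache

    def _backward_encode_context(
        self, d_h: np.ndarray, cache: dict, grads: Dict[str, np.ndarray]
    ) -> np.ndarray:
        p = self.params
        c = self.config
        b, t, d = cache["shape"]
        flat = d_h.reshape(b * t, -1)
        d_concat, d_g, d_b = nn.batchnorm_backward(flat, cache["bn2"])
        grads["bn2_gamma"] += d_g
        grads["bn2_beta"] += d_b
        d_concat = d_concat.reshape(b, t, -1)
        d_hf = d_concat[:, :, : c.lstm_units]
        d_hb = d_concat[:, :, c.lstm_units :]
        dx_f, d_wx, d_wh, d_bias = nn.lstm_backward(
            d_hf, cache["lstm_f"], p["fwd_wx"], p["fwd_wh"], cache["rec_f"]
        )
        grads["fwd_wx"] += d_wx
        grads["fwd_wh"] += d_wh
        grads["fwd_b"] += d_bias
        dx_r, d_wx, d_wh, d_bias = nn.lstm_backward(
            np.ascontiguousarray(d_hb[:, ::-1, :]),
            cache["lstm_b"],
            p["bwd_wx"],
            p["bwd_wh"],
            cache["rec_b"],
        )
        grads["bwd_wx"] += d_wx
        grads["bwd_wh"] += d_wh
        grads["bwd_b"] += d_bias
        dx = dx_f + dx_r[:, ::-1, :]
        if cache["in_mask"] is not None:
            dx = dx * cache["in_mask"]
        return dx

    # -- full tower ------------------------------------------------------

    def forward(
        self,
        word_ids: np.ndarray,
        char_ids: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        x, cache1 = self.word_representation(word_ids, char_ids, training)
        h, cache2 = self.encode_context(x, training, rng)
        return h, {"wr": cache1, "ctx": cache2}

    def backward(self, d_h: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dx = self._backward_encode_context(d_h, cache["ctx"], grads)
        self._backward_word_representation(dx, cache["wr"], grads)
        grads["char_emb"][0] = 0.0
        if "word_emb" in grads:
            grads["word_emb"][0] = 0.0
        return grads

    def remap_ids(self, word_ids: np.ndarray, char_ids: np.ndarray):
        """Clamp ids from an extended vocabulary to this tower's tables
        (unseen symbols -> UNK, id 1)."""
        w = np.where(word_ids < self.word_vocab_size, word_ids, 1)
        c = np.where(char_ids < self.char_vocab_size, char_ids, 1)
        return w, c


class Head:
    """Sigmoid dense prediction layer shared across towers."""

    def __init__(self, in_dim: int, rng: np.random.Generator):
        self.params = {
            "head_w": nn.glorot_uniform(rng, (in_dim, 1))[:, 0],
            "head_b": np.zeros(1),
        }

    def forward(self, h: np.ndarray) -> Tuple[np.ndarray, dict]:
        z = h @ self.params["head_w"] + self.params["head_b"][0]
        return nn.sigmoid(z), {"h": h}

    def backward(self, d_z: np.ndarray, cache: dict) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        h = cache["h"]
        d_w = np.einsum("btd,bt->d", h, d_z)
        d_b = np.array([d_z.sum()])
        d_h = d_z[:, :, None] * self.params["head_w"][None, None, :]
        return d_h, {"head_w": d_w, "head_b": d_b}


class SBDNetwork:
    """One or more towers summed into a shared sigmoid prediction layer.

    The single-tower case is the plain tagger; the two-tower case is the
    stacking ensemble (a frozen source-domain tower plus a trainable
    correction tower).  Frozen towers run in inference mode (stored batch
    statistics, no dropout) and receive no gradient.
    """

    def __init__(self, towers: List[Tower], trainable: List[bool], head: Head,
                 config: ModelConfig):
        if len(towers) != len(trainable):
            raise ValueError("towers and trainable flags must align")
        dims = {2 * t.config.lstm_units for t in towers}
        if len(dims) != 1:
            raise ValueError(f"towers have mismatched output dimensions: {dims}")
        self.towers = towers
        self.trainable = trainable
        self.head = head
        self.config = config

    def forward(
        self,
        word_ids: np.ndarray,
        char_ids: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[np.ndarray, dict]:
        h_sum = None
        caches = []
        for tower, is_trainable in zip(self.towers, self.trainable):
            w, ch = tower.remap_ids(word_ids, char_ids)
            mode = training and is_trainable
            h, cache = tower.forward(w, ch, mode, rng if mode else None)
            caches.append(cache if is_trainable else None)
            h_sum = h if h_sum is None else h_sum + h
        prob, head_cache = self.head.forward(h_sum)
        return prob, {"towers": caches, "head": head_cache}

    def backward(self, d_z: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        d_h, head_grads = self.head.backward(d_z, cache["head"])
        grads: Dict[str, np.ndarray] = dict(head_grads)
        # L1 (lasso) penalty on the prediction-layer weights
        grads["head_w"] = grads["head_w"] + self.config.l1 * np.sign(
            self.head.params["head_w"]
        )
        for i, (tower, is_trainable) in enumerate(zip(self.towers, self.trainable)):
            if not is_trainable:
                continue
            tower_grads = tower.backward(d_h, cache["towers"][i])
            for k, v in tower_grads.items():
                grads[f"tower{i}.{k}"] = v
        return grads

    def l1_penalty(self) -> float:
        return float(self.config.l1 * np.abs(self.head.params["head_w"]).sum())

    def trainable_params(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = dict(self.head.params)
        for i, (tower, is_trainable) in enumerate(zip(self.towers, self.trainable)):
            if is_trainable:
                for k, v in tower.params.items():
                    out[f"tower{i}.{k}"] = v
        return out

    def all_arrays(self) -> Dict[str, np.ndarray]:
        """Every parameter and batch-norm buffer, for serialization."""
        out: Dict[str, np.ndarray] = {}
        for i, tower in enumerate(self.towers):
            for k, v in tower.params.items():
                out[f"tower{i}.{k}"] = v
            if tower.fixed_word_vectors is not None:
                out[f"tower{i}.fixed_word_vectors"] = tower.fixed_word_vectors
            for bn, stats in tower.buffers.items():
                out[f"tower{i}.{bn}_mean"] = stats["mean"]
                out[f"tower{i}.{bn}_var"] = stats["var"]
        out["head.head_w"] = self.head.params["head_w"]
        out["head.head_b"] = self.head.params["head_b"]
        return out

    def n_parameters(self, trainable_only: bool = False) -> int:
        arrays = self.trainable_params() if trainable_only else {
            **{f"t{i}.{k}": v for i, t in enumerate(self.towers) for k, v in t.params.items()},
            **self.head.params,
        }
        return int(sum(v.size for v in arrays.values()))


def count_parameters(
    config: ModelConfig,
    char_vocab_size: int,
    word_vocab_size: int,
    trainable_word_embedding: bool = True,
    n_towers: int = 1,
) -> int:
    """Closed-form parameter count of the architecture (excl. BN buffers)."""
    c = config
    d, h = c.word_dim, c.lstm_units
    tower = char_vocab_size * c.char_dim
    tower += c.cnn_width * c.char_dim * c.cnn_filters + c.cnn_filters
    if trainable_word_embedding:
        tower += word_vocab_size * d
    tower += 2 * d  # bn1
    tower += 2 * (d * 4 * h + h * 4 * h + 4 * h)  # both directions
    tower += 2 * (2 * h)  # bn2
    head = 2 * h + 1
    return n_towers * tower + head


# ---------------------------------------------------------------------------
# Checkpoint I/O


def save_checkpoint(
    path,
    network: SBDNetwork,
    char_vocab: Vocab,
    word_vocab: Vocab,
    extra_meta: Optional[dict] = None,
) -> Path:
    """Serialize a network + vocabularies to one ``.npz`` checkpoint."""
    path = Path(path)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": network.config.to_dict(),
        "char_vocab": char_vocab.symbols,
        "word_vocab": word_vocab.symbols,
        "n_towers": len(network.towers),
        "trainable": list(network.trainable),
        "tower_vocab_sizes": [
            [t.char_vocab_size, t.word_vocab_size] for t in network.towers
        ],
        "tower_fixed_word": [t.fixed_word_vectors is not None for t in network.towers],
    }
    if extra_meta:
        meta["extra"] = extra_meta
    arrays = network.all_arrays()
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.asarray(json.dumps(meta)), **arrays)
    return path


def load_checkpoint(path) -> Tuple[SBDNetwork, Vocab, Vocab, dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig.from_dict(meta["config"])
    rng = np.random.default_rng(0)
    towers = []
    for i, (cv_size, wv_size) in enumerate(meta["tower_vocab_sizes"]):
        fixed = None
        if meta["tower_fixed_word"][i]:
            fixed = arrays[f"tower{i}.fixed_word_vectors"]
        tower = Tower(config, cv_size, wv_size, rng, word_vectors=fixed)
        for k in list(tower.params):
            tower.params[k] = arrays[f"tower{i}.{k}"].astype(np.float64)
        for bn in ("bn1", "bn2"):
            tower.buffers[bn]["mean"] = arrays[f"tower{i}.{bn}_mean"].astype(np.float64)
            tower.buffers[bn]["var"] = arrays[f"tower{i}.{bn}_var"].astype(np.float64)
        towers.append(tower)
    head = Head(2 * config.lstm_units, rng)
    head.params["head_w"] = arrays["head.head_w"].astype(np.float64)
    head.params["head_b"] = arrays["head.head_b"].astype(np.float64)
    network = SBDNetwork(towers, list(meta["trainable"]), head, config)
    char_vocab = Vocab(meta["char_vocab"])
    word_vocab = Vocab(meta["word_vocab"])
    return network, char_vocab, word_vocab, meta.get("extra", {})
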