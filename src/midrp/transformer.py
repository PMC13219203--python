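"""Causally masked transformer over timestamped diagnosis sequences.

Events are embedded as the sum of a learnable type embedding and a sinusoidal
temporal encoding of the admission time, then passed through a stack of
masked multi-head attention + feed-forward blocks. Each position's hidden
row is conditioned only on events at or before it, so the per-position
next-event / next-time heads define a causal language-modelling objective.

Training runs on plain numpy via reverse-mode autodiff (``autograd``) with a
hand-rolled Adam loop — adequate for the CPU-scale corpora this package
targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .sequence_io import EventSequence, EventVocabulary, clip_pad

__all__ = [
    "ModelConfig",
    "TransformerState",
    "temporal_encode",
    "embed_sequence",
    "causal_mask",
    "masked_attention_layer",
    "feed_forward",
    "forward",
    "forward_with_attention",
    "predict_next",
    "loss_time",
    "loss_event",
    "total_loss",
    "init_state",
    "pretrain",
    "extract_representation",
    "save_checkpoint",
    "load_checkpoint",
]

_MASK_PENALTY = -1e9
_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the reference setting: 4 layers, 4 heads, query/key
    width 128, feed-forward width 256. ``d_model`` equals the query/key
    width so the printed residual-free block stacking is dimensionally
    consistent; ``use_residual`` optionally switches to standard
    residual + layer-norm blocks.
    """

    vocab_size: int
    n_layers: int = 4
    n_heads: int = 4
    d_model: int = 128
    d_qk: int = 128
    d_ff: int = 256
    max_len: int = 32
    alpha_event: float = 1.0
    alpha_time: float = 0.01
    use_residual: bool = False
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0
    pad_id: int = 0

    def __post_init__(self) -> None:
        for name in ("vocab_size", "n_layers", "n_heads", "d_model", "d_qk", "d_ff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.alpha_event < 0 or self.alpha_time < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def d_v(self) -> int:
        """Per-head value width; heads concatenate back to ``d_model``."""
        return self.d_model // self.n_heads


@dataclass
class TransformerState:
    """All learnable weights plus the config they were created under."""

    params: dict
    config: ModelConfig

    def copy(self) -> "TransformerState":
        flat, unflatten = flatten(self.params)
        return TransformerState(params=unflatten(flat.copy()), config=self.config)


def init_state(config: ModelConfig, seed: int | None = None) -> TransformerState:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    M, Mk, Mv, Mh, K = (
        config.d_model,
        config.d_qk,
        config.d_v,
        config.d_ff,
        config.vocab_size,
    )

    def xavier(*shape):
        scale = np.sqrt(2.0 / (shape[-2] + shape[-1]))
        return rng.normal(0.0, scale, size=shape)

    layers = []
    for _ in range(config.n_layers):
        layer = {
            "WQ": xavier(config.n_heads, M, Mk),
            "WK": xavier(config.n_heads, M, Mk),
            "WV": xavier(config.n_heads, M, Mv),
            "W1": xavier(M, Mh),
            "b1": np.zeros(Mh),
            "W2": xavier(Mh, M),
            "b2": np.zeros(M),
        }
        if config.use_residual:
            layer.update(
                ln1_g=np.ones(M), ln1_b=np.zeros(M),
                ln2_g=np.ones(M), ln2_b=np.zeros(M),
            )
        layers.append(layer)
    params = {
        "U": rng.normal(0.0, 0.02, size=(M, K)),
        "layers": layers,
        "W_time": rng.normal(0.0, 0.02, size=M),
        "W_event": xavier(M, K),
    }
    return TransformerState(params=params, config=config)


# ---------------------------------------------------------------------------
# building blocks (autograd-traceable; accept batched or single inputs)
# ---------------------------------------------------------------------------

def temporal_encode(t, M: int):
    """Sinusoidal encoding of time ``t`` into an ``M``-vector.

    Component ``j`` (1-based) is ``cos(t / 10000**((j-1)/M))`` for odd ``j``
    and ``sin(t / 10000**(j/M))`` for even ``j``. Accepts scalar or array
    ``t``; an extra trailing axis of size ``M`` is appended.
    """
    if M < 1:
        raise ValueError("encoding dimension must be >= 1")
    j = np.arange(1, M + 1)
    odd = j % 2 == 1
    exponent = np.where(odd, (j - 1) / M, j / M)
    denom = 10000.0 ** exponent
    arg = anp.expand_dims(anp.asarray(t, dtype=float), -1) / denom
    return anp.where(odd, anp.cos(arg), anp.sin(arg))


def embed_sequence(ids, times, state: TransformerState):
    """Rows of ``X``: type embedding ``U k_i`` plus temporal encoding ``z(t_i)``."""
    U = state.params["U"]
    ids = np.asarray(ids)
    if ids.min() < 0 or ids.max() >= state.config.vocab_size:
        raise ValueError(
            f"token id out of range [0, {state.config.vocab_size}): "
            f"{ids.min()}..{ids.max()}"
        )
    return U.T[ids] + temporal_encode(times, state.config.d_model)


def causal_mask(L: int) -> np.ndarray:
    """Boolean ``L x L`` matrix: True where attention must be blocked (j > i)."""
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    return np.triu(np.ones((L, L), dtype=bool), k=1)


def _visibility(mask: np.ndarray, valid: np.ndarray | None) -> np.ndarray:
    """(…, L, L) boolean: True where position i may attend to position j.

    j must not be in the future (causal mask) and must be a real event;
    padded query rows keep self-visibility so their softmax stays defined.
    """
    vis = ~mask
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        vis = vis & valid[..., None, :]
        L = mask.shape[-1]
        vis = vis | np.eye(L, dtype=bool)
    return vis


def _softmax(x, axis=-1):
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=axis, keepdims=True)


def masked_attention_layer(X, layer_params, mask, valid=None, config: ModelConfig = None,
                           return_attention: bool = False):
    """Multi-head masked attention.

    Per head ``A_h = softmax(Q_h K_h^T / sqrt(d_qk) + penalty)``; the head
    outputs ``A_h V_h`` are concatenated. Rows of every ``A_h`` sum to one
    over visible positions and carry zero weight on masked ones.
    """
    n_heads = layer_params["WQ"].shape[0]
    d_qk = layer_params["WQ"].shape[-1]
    vis = _visibility(np.asarray(mask, dtype=bool), valid)
    outs, attns = [], []
    for h in range(n_heads):
        Q = anp.matmul(X, layer_params["WQ"][h])
        K = anp.matmul(X, layer_params["WK"][h])
        V = anp.matmul(X, layer_params["WV"][h])
        E = anp.matmul(Q, anp.swapaxes(K, -1, -2)) / np.sqrt(d_qk)
        E = anp.where(vis, E, _MASK_PENALTY)
        A = _softmax(E, axis=-1)
        attns.append(A)
        outs.append(anp.matmul(A, V))
    S = anp.concatenate(outs, axis=-1)
    if return_attention:
        return S, attns
    return S


def feed_forward(S, layer_params):
    """Row-wise two-layer network: ``relu(S W1 + b1) W2 + b2``."""
    inner = anp.maximum(anp.matmul(S, layer_params["W1"]) + layer_params["b1"], 0.0)
    return anp.matmul(inner, layer_params["W2"]) + layer_params["b2"]


def _layer_norm(x, g, b, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def _forward_params(params, config: ModelConfig, ids, times, valid,
                    collect_attention: bool = False):
    """Hidden states from raw parameter pytree (autograd-traceable)."""
    ids = np.asarray(ids)
    X = params["U"].T[ids] + temporal_encode(times, config.d_model)
    L = ids.shape[-1]
    mask = causal_mask(L)
    all_attn = []
    for layer in params["layers"]:
        S = masked_attention_layer(X, layer, mask, valid, config,
                                   return_attention=collect_attention)
        if collect_attention:
            S, attns = S
            all_attn.append(attns)
        if config.use_residual:
            X = _layer_norm(X + S, layer["ln1_g"], layer["ln1_b"])
            X = _layer_norm(X + feed_forward(X, layer), layer["ln2_g"], layer["ln2_b"])
        else:
            X = feed_forward(S, layer)
    if collect_attention:
        return X, all_attn
    return X


def forward(ids, times, state: TransformerState, valid=None):
    """Hidden representations ``H``; row i is conditioned on events <= i."""
    return _forward_params(state.params, state.config, ids, times, valid)


def forward_with_attention(ids, times, state: TransformerState, valid=None):
    """As :func:`forward`, also returning per-layer, per-head attention matrices."""
    H, attn = _forward_params(
        state.params, state.config, ids, times, valid, collect_attention=True
    )
    return H, attn


def predict_next(H, state: TransformerState):
    """Next-time scalar and next-event probability row for every position.

    Row i of the outputs predicts the event at position i+1.
    """
    t_hat = anp.matmul(H, state.params["W_time"])
    probs = _softmax(anp.matmul(H, state.params["W_event"]), axis=-1)
    return t_hat, probs


def loss_time(times, t_hat, valid=None):
    """Sum over positions i >= 2 of ``(t_i - t̂_i)^2``; padding excluded."""
    times = anp.asarray(times, dtype=float)
    tgt = times[..., 1:]
    pred = t_hat[..., :-1]
    sq = (tgt - pred) ** 2
    if valid is not None:
        sq = sq * np.asarray(valid, dtype=float)[..., 1:]
    return anp.sum(sq)


def loss_event(ids, probs, valid=None):
    """Sum over positions i >= 2 of ``-log p̂_i[c_i]``; padding excluded."""
    ids = np.asarray(ids)
    K = probs.shape[-1]
    onehot = np.eye(K)[ids[..., 1:]]
    p_true = anp.sum(probs[..., :-1, :] * onehot, axis=-1)
    nll = -anp.log(anp.maximum(p_true, _LOG_FLOOR))
    if valid is not None:
        nll = nll * np.asarray(valid, dtype=float)[..., 1:]
    return anp.sum(nll)


def _batch_loss(params, config: ModelConfig, ids, times, valid):
    H = _forward_params(params, config, ids, times, valid)
    t_hat = anp.matmul(H, params["W_time"])
    logits = anp.matmul(H, params["W_event"])
    tgt_valid = np.asarray(valid, dtype=float)[..., 1:]
    # event term: cross entropy via log-sum-exp for stability
    shifted = logits[..., :-1, :]
    lse = anp.log(anp.sum(anp.exp(shifted - anp.max(shifted, axis=-1, keepdims=True)),
                          axis=-1)) + anp.max(shifted, axis=-1)
    onehot = np.eye(config.vocab_size)[np.asarray(ids)[..., 1:]]
    true_logit = anp.sum(shifted * onehot, axis=-1)
    l_event = anp.sum((lse - true_logit) * tgt_valid)
    l_time = anp.sum((anp.asarray(times)[..., 1:] - t_hat[..., :-1]) ** 2 * tgt_valid)
    return config.alpha_event * l_event + config.alpha_time * l_time


def total_loss(batch, state: TransformerState):
    """Joint objective ``sum_n alpha_event L_event(S_n) + alpha_time L_time(S_n)``.

    ``batch`` is an ``(ids, times, valid)`` triple of stacked arrays.
    """
    ids, times, valid = batch
    return float(_batch_loss(state.params, state.config, ids, times, valid))


def sequences_to_batch(
    sequences: Sequence[EventSequence], vocab: EventVocabulary, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack sequences into fixed-length ``(ids, times, valid)`` arrays."""
    ids, times, valid = [], [], []
    for seq in sequences:
        i, t, m = clip_pad(seq, vocab, config.max_len, pad_id=config.pad_id)
        ids.append(i)
        times.append(t)
        valid.append(m)
    return np.stack(ids), np.stack(times), np.stack(valid)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def pretrain(
    sequences: Sequence[EventSequence],
    vocab: EventVocabulary,
    config: ModelConfig,
    verbose: bool = False,
) -> tuple[TransformerState, list[float]]:
    """Minimize the joint next-event/next-time loss with Adam.

    Returns the trained state and the per-epoch mean loss trajectory.
    Deterministic for a fixed ``config.seed``.
    """
    if not sequences:
        raise ValueError("pretrain requires at least one sequence")
    state = init_state(config)
    ids, times, valid = sequences_to_batch(sequences, vocab, config)
    n = len(sequences)
    rng = np.random.default_rng(config.seed)

    flat, unflatten = flatten(state.params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    def objective(params, sl):
        return _batch_loss(params, config, ids[sl], times[sl], valid[sl]) / len(
            range(*sl.indices(n))
        )

    vag = value_and_grad(objective)
    trajectory: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ids, times, valid = ids[order], times[order], valid[order]
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sl = slice(start, min(start + config.batch_size, n))
            params = unflatten(flat)
            loss, grads = vag(params, sl)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {n_batches} "
                    f"(lr={config.lr}); reduce the learning rate or loss weights"
                )
            g, _ = flatten(grads)
            step += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** step)
            vh = v / (1 - b2 ** step)
            flat = flat - config.lr * mh / (np.sqrt(vh) + eps)
            epoch_loss += float(loss)
            n_batches += 1
        trajectory.append(epoch_loss / n_batches)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: loss {trajectory[-1]:.4f}")
    state = TransformerState(params=unflatten(flat), config=config)
    return state, trajectory


def extract_representation(
    seq: EventSequence,
    target_code: str,
    is_case: bool,
    state: TransformerState,
    vocab: EventVocabulary,
) -> np.ndarray:
    """Leak-free per-patient embedding for downstream risk modelling.

    Cases: the hidden row of the event immediately preceding the first
    target-disease diagnosis; a zero vector when the target is the very
    first event. Controls: the hidden row of the last event. The forward
    pass only ever sees events strictly before the first target diagnosis,
    so the extraction cannot use future information.
    """
    codes = seq.codes
    has_target = target_code in codes
    if is_case and not has_target:
        raise ValueError(
            f"sample {seq.sample_id!r} marked as case but never diagnosed "
            f"with {target_code!r}"
        )
    if not is_case and has_target:
        raise ValueError(
            f"sample {seq.sample_id!r} marked as control but carries a "
            f"{target_code!r} diagnosis"
        )
    if is_case:
        j = codes.index(target_code)
        if j == 0:
            return np.zeros(state.config.d_model)
        events = seq.events[:j]
    else:
        events = seq.events
    prefix = EventSequence(sample_id=seq.sample_id, events=list(events))
    keep = min(len(prefix), state.config.max_len)
    ids = vocab.encode_sequence(prefix)[-keep:]
    times = prefix.times[-keep:]
    H = forward(ids[None, :], times[None, :], state)
    return np.asarray(H[0, keep - 1])


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: TransformerState, vocab: EventVocabulary) -> None:
    flat, _ = flatten(state.params)
    np.savez(
        path,
        flat_params=flat,
        config=json.dumps(asdict(state.config)),
        vocab=vocab.to_json(),
    )


def load_checkpoint(path) -> tuple[TransformerState, EventVocabulary]:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(data["config"])))
    vocab = EventVocabulary.from_json(str(data["vocab"]))
    template = init_state(config)
    _, unflatten = flatten(template.params)
    state = TransformerState(params=unflatten(data["flat_params"]), config=config)
    return state, vocab
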