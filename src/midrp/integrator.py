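"""Posterior-regularized fusion of PRS, non-genetic factors and embeddings.

Two branches are trained jointly: a logistic branch P on the scalar PRS, and
a factor branch Q that maps every non-genetic factor (the learned
medical-history embedding being one factor among them) through a tanh layer
to a two-component score, weights the stacked scores by a learnable matrix,
and softmaxes the per-class sums. A KL(Q || P) penalty keeps the two
posteriors close; the final risk score is the sum of the two class-1 logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

__all__ = [
    "SampleRecord",
    "MidrpParams",
    "genetic_logit",
    "genetic_prob",
    "factor_transform",
    "nongenetic_logits",
    "nongenetic_logit",
    "q_distribution",
    "kl_regularizer",
    "total_objective",
    "init_params",
    "train_midrp",
    "risk_score",
    "records_to_arrays",
]

_EPS = 1e-12


@dataclass
class SampleRecord:
    """One labelled sample: PRS scalar, ordered factor vectors, binary label."""

    sample_id: str
    x_s: float
    factors: list[np.ndarray]
    y: int


@dataclass
class MidrpParams:
    """Learnable parameters plus the loss weights they were trained with."""

    params: dict  # {"w_s", "b_s", "W": [d_j x 2 ...], "gamma": N x 2}
    alpha: float = 1.0
    beta: float = 1.0

    @property
    def n_factors(self) -> int:
        return len(self.params["W"])


def records_to_arrays(
    records: Sequence[SampleRecord],
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Stack records into (x_s, [factor matrices], y) arrays."""
    x_s = np.array([r.x_s for r in records], dtype=float)
    y = np.array([r.y for r in records], dtype=int)
    n_factors = len(records[0].factors)
    factors = [
        np.stack([np.atleast_1d(np.asarray(r.factors[j], dtype=float))
                  for r in records])
        for j in range(n_factors)
    ]
    return x_s, factors, y


# ---------------------------------------------------------------------------
# forward pieces (autograd-traceable; vectorized over samples)
# ---------------------------------------------------------------------------

def genetic_logit(x_s, params: dict):
    """Linear PRS logit ``w_s * x_s + b_s``."""
    return params["w_s"] * anp.asarray(x_s, dtype=float) + params["b_s"]


def genetic_prob(x_s, params: dict):
    """Sigmoid of the PRS logit; returns (P(y=1), P(y=0))."""
    p1 = 1.0 / (1.0 + anp.exp(-genetic_logit(x_s, params)))
    return p1, 1.0 - p1


def factor_transform(x_j, w_j):
    """Per-factor two-component score ``tanh(x_j @ w_j)``, bounded in (-1, 1)."""
    x_j = anp.asarray(x_j, dtype=float)
    if x_j.shape[-1] != anp.shape(w_j)[0]:
        raise ValueError(
            f"factor dimension {x_j.shape[-1]} does not match weight rows "
            f"{anp.shape(w_j)[0]}"
        )
    return anp.tanh(anp.matmul(x_j, w_j))


def _phi_stack(factors, params: dict):
    """(n, N, 2) stack of per-factor transforms."""
    phis = [factor_transform(x_j, w_j) for x_j, w_j in zip(factors, params["W"])]
    return anp.stack(phis, axis=-2)


def nongenetic_logits(factors, params: dict):
    """Per-class logits: column ``c`` of Γ ⊙ Φ summed over factors.

    Returns an (n, 2) array; column 0 is the class-0 logit, column 1 the
    class-1 logit.
    """
    phi = _phi_stack(factors, params)
    return anp.sum(phi * params["gamma"], axis=-2)


def nongenetic_logit(factors, params: dict):
    """Scalar ``Sum(Γ ⊙ Concat φ_j)`` — all entries of the weighted stack."""
    return anp.sum(nongenetic_logits(factors, params), axis=-1)


def q_distribution(factors, params: dict):
    """Two-class softmax of the per-class non-genetic logits: (Q(y=1), Q(y=0))."""
    logits = nongenetic_logits(factors, params)
    shifted = logits - anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(shifted)
    q = e / anp.sum(e, axis=-1, keepdims=True)
    return q[..., 1], q[..., 0]


def kl_regularizer(x_s, factors, params: dict):
    """Mean over samples of ``KL(Q(y|X) || P(y|x_s))``; zero iff Q == P."""
    p1, p0 = genetic_prob(x_s, params)
    q1, q0 = q_distribution(factors, params)
    kl = q1 * anp.log((q1 + _EPS) / (p1 + _EPS)) + q0 * anp.log(
        (q0 + _EPS) / (p0 + _EPS)
    )
    return anp.mean(kl)


def _bce(p1, y):
    y = anp.asarray(y, dtype=float)
    return -anp.mean(
        y * anp.log(p1 + _EPS) + (1.0 - y) * anp.log(1.0 - p1 + _EPS)
    )


def total_objective(x_s, factors, y, params: dict, alpha: float = 1.0,
                    beta: float = 1.0):
    """``L_P + alpha * L_KL + beta * L_Q`` (each term a per-sample mean)."""
    p1, _ = genetic_prob(x_s, params)
    q1, _ = q_distribution(factors, params)
    return (
        _bce(p1, y)
        + alpha * kl_regularizer(x_s, factors, params)
        + beta * _bce(q1, y)
    )


def risk_score(x_s, factors, params: dict):
    """Fused risk ``R = L_genetic(y=1) + L_non-genetic(y=1)``."""
    logits = nongenetic_logits(factors, params)
    return genetic_logit(x_s, params) + logits[..., 1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def init_params(factor_dims: Sequence[int], seed: int = 0) -> dict:
    """Antisymmetric initialization: per factor, the class-0 weight column is
    the negative of the class-1 column and the Γ entries are equal, so
    ``L0 = -L1`` at the start of training. The softmax objective only pins
    the difference ``L1 - L0``, and the gradient field preserves this
    manifold exactly, so the additive risk score's class-1 logit stays
    identified throughout training.
    """
    rng = np.random.default_rng(seed)
    W = []
    for d in factor_dims:
        col = rng.normal(0.0, 0.1, size=d)
        W.append(np.stack([-col, col], axis=1))
    g = rng.normal(0.0, 0.1, size=len(factor_dims))
    return {
        "w_s": np.array(rng.normal(0.0, 0.1)),
        "b_s": np.array(0.0),
        "W": W,
        "gamma": np.stack([g, g], axis=1),
    }


def train_midrp(
    x_s: np.ndarray,
    factors: Sequence[np.ndarray],
    y: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    lr: float = 0.05,
    n_iter: int = 500,
    seed: int = 0,
    weight_decay: float = 1e-3,
) -> tuple[MidrpParams, list[float]]:
    """Joint full-batch Adam minimization of the regularized objective.

    A small ridge penalty on the factor-branch weights pins the direction
    the softmax objective leaves free (only the class-logit difference
    L1 - L0 is identified by the data; the minimal-norm solution splits it
    antisymmetrically across the two columns, which is what the additive
    risk score relies on). Deterministic for a fixed seed; aborts on a
    non-finite loss. Returns the fitted parameters and the loss trajectory.
    """
    factor_dims = [np.atleast_2d(f).shape[-1] for f in factors]
    params = init_params(factor_dims, seed=seed)
    flat, unflatten = flatten(params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8

    def objective(p):
        loss = total_objective(x_s, factors, y, p, alpha=alpha, beta=beta)
        if weight_decay:
            ridge = anp.sum(p["gamma"] ** 2)
            for w in p["W"]:
                ridge = ridge + anp.sum(w**2)
            loss = loss + weight_decay * ridge
        return loss

    vag = value_and_grad(objective)
    trajectory: list[float] = []
    for step in range(1, n_iter + 1):
        loss, grads = vag(unflatten(flat))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite objective {loss} at iteration {step} (lr={lr})"
            )
        g, _ = flatten(grads)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        flat = flat - lr * (m / (1 - b1**step)) / (np.sqrt(v / (1 - b2**step)) + eps)
        trajectory.append(float(loss))
    return MidrpParams(params=unflatten(flat), alpha=alpha, beta=beta), trajectory
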