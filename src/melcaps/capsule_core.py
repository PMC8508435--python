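"""Core capsule arithmetic: squash, votes, routing-by-agreement, margin loss.

A capsule is a group of neurons whose activity vector represents the
instantiation parameters of one entity; the vector's Euclidean norm encodes
the probability that the entity is present.  Everything here is pure numpy
operating on arrays shaped

* ``(N, D)`` for a set of N capsule vectors of dimension D,
* ``(N_in, N_out, D_in, D_out)`` for the transformation weights between two
  consecutive capsule layers, and
* ``(N_in, N_out, D_out)`` for the prediction ("vote") tensor.

These functions are the reference implementation that the trainable network
composes; they are also what the loop oracles in the test suite check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarginLossParams",
    "RoutingState",
    "squash",
    "compute_votes",
    "routing_softmax",
    "dynamic_routing",
    "margin_loss",
    "capsule_lengths",
]

#: Regulariser in the squash denominator; keeps squash(0) = 0 exact and the
#: backward pass finite at the origin.
_SQUASH_EPS = 1e-12


@dataclass(frozen=True)
class MarginLossParams:
    """Margins and down-weighting of the separate margin loss.

    ``m_plus`` is the norm a present-class capsule is pushed above,
    ``m_minus`` the norm an absent-class capsule is pushed below, and
    ``lambda_down`` down-weights the absent-class terms so early training
    does not shrink every capsule.  The margins are 0.9 / 0.1; the
    down-weighting constant follows the original capsule-network convention
    of 0.5.
    """

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.m_minus < self.m_plus <= 1.0):
            raise ValueError(
                f"require 0 < m_minus < m_plus <= 1, got "
                f"m_plus={self.m_plus}, m_minus={self.m_minus}"
            )
        if self.lambda_down <= 0:
            raise ValueError(f"lambda_down must be > 0, got {self.lambda_down}")


@dataclass
class RoutingState:
    """Final state of the routing loop.

    Attributes
    ----------
    logits : ndarray of shape (N_in, N_out)
        Agreement log-priors b_ij (zero before the first iteration).
    coefficients : ndarray of shape (N_in, N_out)
        Coupling coefficients c_ij; each row is a softmax over output
        capsules and sums to one.
    r_done : int
        Number of routing iterations performed.
    """

    logits: np.ndarray
    coefficients: np.ndarray
    r_done: int


def _check_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def squash(s: np.ndarray) -> np.ndarray:
    """Shrink capsule vectors to norm < 1 while preserving direction.

    v = (||s||^2 / (1 + ||s||^2)) * s / ||s||, applied along the last axis.
    Zero vectors map to zero vectors.
    """
    s = _check_finite(s, "squash input")
    norm = np.linalg.norm(s, axis=-1, keepdims=True)
    # (n^2/(1+n^2)) * s/n simplifies to s * n/(1+n^2): no 0/0 at the origin,
    # the eps keeps the gradient path finite for the training engine.
    return s * (norm / (1.0 + norm**2 + _SQUASH_EPS))


def compute_votes(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Prediction vectors u_hat[i, j] = W[i, j] @ u[i].

    Parameters
    ----------
    u : (N_in, D_in) input capsule vectors.
    W : (N_in, N_out, D_in, D_out) transformation weights.
    """
    u = _check_finite(u, "capsule input")
    W = _check_finite(W, "transform weights")
    if u.ndim != 2 or W.ndim != 4 or W.shape[0] != u.shape[0] or W.shape[2] != u.shape[1]:
        raise ValueError(
            f"shape mismatch: u {u.shape} vs W {W.shape} "
            "(expected W of shape (N_in, N_out, D_in, D_out))"
        )
    return np.einsum("ijde,id->ije", W, u)


def routing_softmax(b: np.ndarray) -> np.ndarray:
    """Coupling coefficients c_ij = exp(b_ij) / sum_k exp(b_ik).

    The softmax runs across output capsules for each input capsule
    (axis -1), max-stabilised so large logits do not overflow.
    """
    b = _check_finite(b, "routing logits")
    z = b - b.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dynamic_routing(votes: np.ndarray, iterations: int = 1) -> tuple[np.ndarray, RoutingState]:
    """Routing-by-agreement between two capsule layers.

    Starting from zero logits, each iteration computes coupling
    coefficients by :func:`routing_softmax`, aggregates
    ``s_j = sum_i c_ij * u_hat[i, j]``, squashes to ``v_j``, and — on all
    but the last iteration — reinforces the logits with the scalar
    agreement ``b_ij += u_hat[i, j] . v_j``.  With ``iterations=1`` the
    coefficients therefore stay uniform.

    Returns the output capsules ``v`` of shape (N_out, D_out) and the
    final :class:`RoutingState`.
    """
    votes = _check_finite(votes, "votes")
    if votes.ndim != 3:
        raise ValueError(f"votes must have shape (N_in, N_out, D_out), got {votes.shape}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")

    n_in, n_out, _ = votes.shape
    b = np.zeros((n_in, n_out))
    c = routing_softmax(b)
    v = None
    for r in range(iterations):
        c = routing_softmax(b)
        s = np.einsum("ij,ijd->jd", c, votes)
        v = squash(s)
        if r < iterations - 1:
            b = b + np.einsum("ijd,jd->ij", votes, v)
    return v, RoutingState(logits=b, coefficients=c, r_done=iterations)


def capsule_lengths(v: np.ndarray) -> np.ndarray:
    """Euclidean norm of each capsule vector (the class score)."""
    v = _check_finite(v, "capsule vectors")
    return np.linalg.norm(v, axis=-1)


def margin_loss(
    lengths: np.ndarray,
    targets: np.ndarray,
    params: MarginLossParams | None = None,
) -> float:
    """Separate margin loss summed over class capsules.

    L_k = T_k * max(0, m+ - ||v_k||)^2
          + lambda * (1 - T_k) * max(0, ||v_k|| - m-)^2

    where T_k = 1 iff class k is present.  The total loss is the sum over
    the class capsules (nevus and melanoma in the binary case).
    """
    if params is None:
        params = MarginLossParams()
    lengths = _check_finite(np.atleast_1d(lengths), "capsule lengths")
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if lengths.shape != targets.shape:
        raise ValueError(f"lengths {lengths.shape} and targets {targets.shape} differ")
    if np.any(lengths < 0) or np.any(lengths > 1):
        raise ValueError("capsule lengths must lie in [0, 1]")
    present = np.maximum(0.0, params.m_plus - lengths) ** 2
    absent = np.maximum(0.0, lengths - params.m_minus) ** 2
    per_class = targets * present + params.lambda_down * (1.0 - targets) * absent
    return float(per_class.sum())
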