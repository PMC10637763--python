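"""Training objectives for composition regression.

Two objectives are supported for mapping raw model scores ``z`` to a predicted
composition on the simplex:

* softmax + Kullback–Leibler divergence: ``KL(q || softmax(z))`` with the
  target composition ``q``; standard for fitting categorical distributions but
  never produces exact zeros;
* sparsemax + its companion loss: ``sparsemax(z)`` is the Euclidean projection
  of ``z`` onto the simplex, which assigns exact zero probability to
  low-scoring categories — attractive because most real mixes contain only a
  few of the cataloged varieties.

Both losses have the same convenient gradient structure with respect to the
scores: ``softmax(z) - q`` and ``sparsemax(z) - q`` respectively, which is what
the training loop uses.  Batch reduction is mean over images, sum over
categories.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "log_softmax",
    "softmax_kldiv_loss",
    "softmax_kldiv_grad",
    "sparsemax",
    "sparsemax_loss",
    "sparsemax_loss_grad",
    "LOSSES",
]


def _as_2d(z) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        return z[None, :], True
    return z, False


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    m = z.max(axis=-1, keepdims=True)
    shifted = z - m
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def softmax(z: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(z))


def softmax_kldiv_loss(z, target) -> float:
    """KL divergence ``sum_v q_v (log q_v - log p_v)`` with ``p = softmax(z)``.

    Uses the ``0 * log 0 = 0`` convention on the target side and a fused
    log-softmax so zero predicted probabilities cannot occur numerically.
    For batched inputs the mean over rows is returned.
    """
    z2, _ = _as_2d(z)
    q2, _ = _as_2d(target)
    logp = log_softmax(z2)
    with np.errstate(divide="ignore", invalid="ignore"):
        qlogq = np.where(q2 > 0, q2 * np.log(np.where(q2 > 0, q2, 1.0)), 0.0)
    per_row = (qlogq - q2 * logp).sum(axis=-1)
    return float(per_row.mean())


def softmax_kldiv_grad(z, target) -> np.ndarray:
    """Gradient of :func:`softmax_kldiv_loss` w.r.t. ``z``: ``softmax(z) - q``."""
    z2, was_1d = _as_2d(z)
    q2, _ = _as_2d(target)
    g = softmax(z2) - q2
    if was_1d:
        return g[0]
    return g / z2.shape[0]


def _sparsemax_tau(z2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Water-filling threshold tau and support size k per row (sort-based)."""
    z_sorted = np.sort(z2, axis=-1)[:, ::-1]
    cssv = np.cumsum(z_sorted, axis=-1) - 1.0
    ks = np.arange(1, z2.shape[-1] + 1, dtype=float)
    support = z_sorted * ks > cssv
    k = support.sum(axis=-1)
    tau = cssv[np.arange(z2.shape[0]), k.astype(int) - 1] / k
    return tau, k


def sparsemax(z):
    """Euclidean projection of score vector(s) onto the probability simplex.

    ``sparsemax(z) = argmin_p ||p - z||^2  s.t.  p >= 0, sum p = 1``.
    Shift-invariant (``z + c`` projects identically) and sparse: entries with
    ``z_j <= tau(z)`` come out exactly zero.
    """
    z2, was_1d = _as_2d(z)
    tau, _ = _sparsemax_tau(z2)
    p = np.maximum(z2 - tau[:, None], 0.0)
    return p[0] if was_1d else p


def sparsemax_loss(z, target) -> float:
    """Sparsemax companion loss.

    ``L(z; q) = -q.z + 1/2 sum_{j in S(z)} (z_j^2 - tau(z)^2) + 1/2 ||q||^2``
    where ``S(z)`` is the support of ``sparsemax(z)``.  Nonnegative, zero iff
    ``sparsemax(z) = q``, with gradient ``sparsemax(z) - q``.  Mean over rows
    for batched inputs.
    """
    z2, _ = _as_2d(z)
    q2, _ = _as_2d(target)
    tau, _ = _sparsemax_tau(z2)
    in_support = z2 > tau[:, None]
    quad = np.where(in_support, z2**2 - tau[:, None] ** 2, 0.0).sum(axis=-1)
    per_row = -(q2 * z2).sum(axis=-1) + 0.5 * quad + 0.5 * (q2**2).sum(axis=-1)
    # float rounding can leave a tiny negative residue at the optimum
    return float(np.maximum(per_row, 0.0).mean())


def sparsemax_loss_grad(z, target) -> np.ndarray:
    """Gradient of :func:`sparsemax_loss` w.r.t. ``z``: ``sparsemax(z) - q``."""
    z2, was_1d = _as_2d(z)
    q2, _ = _as_2d(target)
    g = sparsemax(z2) - q2
    if was_1d:
        return g[0]
    return g / z2.shape[0]


#: loss name -> (loss, gradient, inference transform)
LOSSES = {
    "kldiv": (softmax_kldiv_loss, softmax_kldiv_grad, softmax),
    "sparsemax": (sparsemax_loss, sparsemax_loss_grad, sparsemax),
}
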