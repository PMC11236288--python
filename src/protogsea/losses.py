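"""Training objectives for the prototype network.

Two regimes are supported. Without biological labels the geometry terms
use nearest-prototype assignments recomputed from the current embeddings;
with per-cell labels q (e.g. cell types, one prototype per label) the
assignment is fixed by (phenotype, label) and the prototype-to-prototype
separation penalty is replaced by a label-classification term on the
prototype-assignment probabilities.

Conventions shared by all terms:

- cross-entropy terms that sum over gene sets divide by the number of
  cells only (so a T-set model contributes T times the per-set loss);
- probabilities are floored at 1e-12 inside logarithms;
- the separation penalty counts ordered pairs l != t (a lone prototype,
  B = 1, contributes zero rather than a constant offset);
- assignment index sets are treated as constants within a step
  (no gradient flows through the argmin that built them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from ._autograd import Tensor
from .network import EPS, PrototypeNetwork

P_FLOOR = 1e-12


@dataclass
class LossWeights:
    """Weights lambda_1..lambda_5 for the combined objective.

    ``stage`` 1 forces the final-prediction term off (lambda_2 treated as
    0) so the per-set encoders and prototypes are learned first.
    """

    clf: float = 1.0
    final: float = 1.0
    p2p: float = 0.1
    c2p: float = 0.1
    p2c: float = 0.1
    stage: int = 1

    def __post_init__(self):
        if min(self.clf, self.final, self.p2p, self.c2p, self.p2c) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


def _log(p: Tensor) -> Tensor:
    return p.clamp(lo=P_FLOOR).log()


def loss_clf(posteriors: Tensor, y: np.ndarray) -> Tensor:
    """Per-set classification loss: -(1/n) sum_j sum_i ln P(y_i | z_i^j)."""
    n, T, _ = posteriors.shape
    i_ix = np.repeat(np.arange(n), T)
    j_ix = np.tile(np.arange(T), n)
    k_ix = np.repeat(np.asarray(y) - 1, T)
    picked = _log(posteriors)[i_ix, j_ix, k_ix]
    return -picked.sum() / float(n)


def loss_final(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Final-prediction cross-entropy: -(1/n) sum_i ln y_hat_i[y_i]."""
    n = y_hat.shape[0]
    picked = _log(y_hat)[np.arange(n), np.asarray(y) - 1]
    return -picked.sum() / float(n)


def loss_p2p(net: PrototypeNetwork) -> Tensor:
    """Separation hinge between same-class prototypes.

    (1/(T C B^2)) sum_{j,k} sum_{l != t} max(0, d_min - ||p_l - p_t||)^2.
    Identically zero when B = 1.
    """
    T, C, B = net.T, net.C, net.B
    if B == 1:
        return Tensor(0.0)
    p = net.centers                                    # (T, C, B, z)
    zd = net.spec.z_dim
    diff = p.reshape(T, C, B, 1, zd) - p.reshape(T, C, 1, B, zd)
    dist = (diff * diff).sum(axis=-1).sqrt()           # (T, C, B, B)
    hinge = (net.d_min - dist).relu() ** 2
    off_diag = 1.0 - np.eye(B)[None, None, :, :]
    return (hinge * off_diag).sum() / float(T * C * B * B)


def loss_c2p(z: Tensor, net: PrototypeNetwork, y: np.ndarray) -> Tensor:
    """Cell-to-prototype pull: mean over cells and sets of the squared
    distance to the nearest prototype of the cell's own phenotype."""
    d2 = net.sq_dists(z)                               # (n, T, C, B)
    n, T = d2.shape[0], net.T
    i_ix = np.repeat(np.arange(n), T)
    j_ix = np.tile(np.arange(T), n)
    k_ix = np.repeat(np.asarray(y) - 1, T)
    own = d2[i_ix, j_ix, k_ix].reshape(n, T, net.B)    # (n, T, B)
    return own.min(axis=2).sum() / float(n * T)


def loss_c2p_labeled(z: Tensor, net: PrototypeNetwork, y: np.ndarray,
                     q: np.ndarray) -> Tensor:
    """Labeled variant: distance to the (phenotype, label)-indexed
    prototype, with no minimum taken."""
    d2 = net.sq_dists(z)
    n, T = d2.shape[0], net.T
    i_ix = np.repeat(np.arange(n), T)
    j_ix = np.tile(np.arange(T), n)
    k_ix = np.repeat(np.asarray(y) - 1, T)
    l_ix = np.repeat(np.asarray(q) - 1, T)
    own = d2[i_ix, j_ix, k_ix, l_ix].reshape(n, T)
    return own.sum() / float(n * T)


def build_assignments(z_data: np.ndarray, net: PrototypeNetwork,
                      y: np.ndarray, q: Optional[np.ndarray] = None
                      ) -> np.ndarray:
    """Binary membership array w (n, T, C, B): w[i,j,k,l] = 1 iff cell i
    belongs to index set A_l^{j,k}.

    Unlabeled regime: k is the cell's phenotype and l the nearest
    prototype of that class under the current (detached) embeddings,
    lowest index on ties. Labeled regime: (k, l) = (y_i, q_i) for every
    set. Within each (j, k) the sets partition the class-k cells.
    """
    n, T = z_data.shape[0], net.T
    C, B = net.C, net.B
    w = np.zeros((n, T, C, B))
    y0 = np.asarray(y) - 1
    if q is not None:
        q0 = np.asarray(q) - 1
        w[np.arange(n)[:, None], np.arange(T)[None, :],
          y0[:, None], q0[:, None]] = 1.0
        return w
    centers = net.centers.data                         # (T, C, B, z)
    diff = z_data[:, :, None, None, :] - centers[None]
    d2 = (diff * diff).sum(axis=-1)                    # (n, T, C, B)
    own = d2[np.arange(n)[:, None], np.arange(T)[None, :], y0[:, None]]
    lstar = np.argmin(own, axis=2)                     # (n, T)
    w[np.arange(n)[:, None], np.arange(T)[None, :],
      y0[:, None], lstar] = 1.0
    return w


def loss_p2c(z: Tensor, net: PrototypeNetwork,
             assignments: np.ndarray) -> Tensor:
    """Prototype-to-center pull.

    (1/(T C B)) sum_{j,k,l} || (1/(|A|+eps)) sum_{i in A} (p - z_i) ||^2.
    An empty index set contributes ~0 through the eps guard.
    """
    n, T, C, B = assignments.shape
    zd = net.spec.z_dim
    cnt = assignments.sum(axis=0)                      # (T, C, B) constant
    w = Tensor(assignments.reshape(n, T, C, B, 1))
    sum_z = (w * z.reshape(n, T, 1, 1, zd)).sum(axis=0)   # (T, C, B, z)
    resid = (net.centers * cnt[..., None] - sum_z) / (cnt[..., None] + EPS)
    return (resid * resid).sum() / float(T * C * B)


def loss_p2p_labeled(u: Tensor, q: np.ndarray) -> Tensor:
    """Label classification on assignment probabilities:
    -(1/n) sum_j sum_i ln u_i^j[q_i]."""
    n, T, _ = u.shape
    i_ix = np.repeat(np.arange(n), T)
    j_ix = np.tile(np.arange(T), n)
    l_ix = np.repeat(np.asarray(q) - 1, T)
    picked = _log(u)[i_ix, j_ix, l_ix]
    return -picked.sum() / float(n)


def combined_loss(parts: Dict[str, Tensor], w: LossWeights) -> Tensor:
    """Weighted sum lambda_1 Lclf + lambda_2 Lf + lambda_3 Lp2p +
    lambda_4 Lc2p + lambda_5 Lp2c; stage 1 drops the Lf term."""
    total = Tensor(0.0)
    lam_final = 0.0 if w.stage == 1 else w.final
    for key, lam in (("clf", w.clf), ("final", lam_final), ("p2p", w.p2p),
                     ("c2p", w.c2p), ("p2c", w.p2c)):
        if lam != 0.0 and key in parts:
            total = total + parts[key] * lam
    return total
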