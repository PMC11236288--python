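"""The prototype network: shared backbone, per-set heads, prototype bank.

Architecture
------------
Each gene set j gets its own latent space. A cell profile x is masked to
the set's member genes, encoded by a shared multilayer backbone E into a
hidden vector, and projected by a one-layer set-specific head h_j:

    z^j = h_j(E(x * m_j))

In each latent space the model keeps, for every phenotype class k, B
prototype centers p_l^{j,k} with learnable variances (sigma_l^{j,k})^2.
Under a Gaussian-mixture view of each class's latent distribution, the
similarity of a cell to class k is the prior-weighted density at the
nearest prototype:

    s_j[k] = eta_k * exp( -min_l ||z^j - p_l^{j,k}||^2 / (2 sigma^2) )

where eta_k is the empirical class proportion and sigma^2 belongs to the
minimising prototype. Normalising s_j over classes gives the per-set
posterior P(class k | z^j); the final phenotype prediction aggregates all
sets through positive weights:

    y_hat = softmax( omega_0 + ln sum_j omega_j * s_j ).

The exponent is clamped at -50 before exponentiation so similarities stay
strictly positive in floating point; ties in the min are broken toward
the lowest prototype index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from ._autograd import Tensor, no_grad, parameter

EXP_CLAMP = -50.0
EPS = 1e-16


@dataclass
class EncoderSpec:
    """Backbone/head dimensions. ``z_dim >= 2`` keeps latents visualizable."""

    input_dim: int
    hidden_layers: List[int] = field(default_factory=lambda: [256])
    h_dim: int = 64
    z_dim: int = 16
    activation: str = "tanh"

    def __post_init__(self):
        if self.z_dim < 2:
            raise ValueError("z_dim must be >= 2")
        if any(w < 1 for w in self.hidden_layers) or self.h_dim < 1:
            raise ValueError("layer widths must be >= 1")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class SimilarityTensor:
    """Per-cell outputs of the network in inference mode.

    ``s``: (n, T, C) similarities; ``posterior``: (n, T, C) per-set class
    posteriors; ``u``: (n, T, B) prototype-assignment probabilities;
    ``y_hat``: (n, C) final class probabilities; ``z``: (n, T, z_dim)
    latent embeddings.
    """

    s: np.ndarray
    posterior: np.ndarray
    u: np.ndarray
    y_hat: np.ndarray
    z: np.ndarray


class PrototypeNetwork:
    """Trainable prototype classifier over a fixed mask bank.

    Parameters
    ----------
    masks : ndarray (T, N)
        Binary gene-set masks.
    C : int
        Number of phenotype classes.
    spec : EncoderSpec
        Backbone/head dimensions (``spec.input_dim`` must equal N).
    B : int
        Prototypes per class (1 by default; set to the number of biological
        labels in cell-type-informed training).
    priors : ndarray (C,), optional
        Class priors eta_k; estimated train-split frequencies. Uniform if
        omitted; set via :meth:`set_priors` at fit time.
    """

    def __init__(self, masks: np.ndarray, C: int, spec: EncoderSpec,
                 B: int = 1, priors: Optional[np.ndarray] = None,
                 d_min: float = 1.0, seed: int = 0):
        masks = np.asarray(masks, dtype=np.float64)
        if masks.ndim != 2 or masks.shape[1] != spec.input_dim:
            raise ValueError("masks must be (T, N) with N = spec.input_dim")
        if B < 1:
            raise ValueError("B must be >= 1")
        self.masks = masks
        self.spec = spec
        self.C = int(C)
        self.B = int(B)
        self.d_min = float(d_min)
        self.set_priors(np.full(C, 1.0 / C) if priors is None else priors)

        rng = np.random.default_rng(seed)
        T, N = masks.shape
        widths = [spec.input_dim] + list(spec.hidden_layers) + [spec.h_dim]
        self.backbone = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            W = parameter(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in))
            b = parameter(np.zeros(fan_out))
            self.backbone.append((W, b))
        self.head_W = parameter(
            rng.standard_normal((T, spec.h_dim, spec.z_dim)) / np.sqrt(spec.h_dim))
        self.head_b = parameter(np.zeros((T, 1, spec.z_dim)))
        self.centers = parameter(
            rng.standard_normal((T, C, B, spec.z_dim)) * 0.1)
        self.log_var = parameter(np.zeros((T, C, B)))  # sigma initialised to 1
        self.omega0 = parameter(np.zeros(C))
        # softplus(omega_raw) ~= 1 at init so aggregation starts near-uniform
        self.omega_raw = parameter(np.full((T, C), np.log(np.e - 1.0)))

    # -- parameter groups --------------------------------------------

    @property
    def T(self) -> int:
        return self.masks.shape[0]

    def encoder_parameters(self) -> List[Tensor]:
        ps: List[Tensor] = []
        for W, b in self.backbone:
            ps += [W, b]
        ps += [self.head_W, self.head_b]
        return ps

    def prototype_parameters(self) -> List[Tensor]:
        return [self.centers, self.log_var]

    def aggregation_parameters(self) -> List[Tensor]:
        return [self.omega0, self.omega_raw]

    def parameters(self) -> List[Tensor]:
        return (self.encoder_parameters() + self.prototype_parameters()
                + self.aggregation_parameters())

    def set_priors(self, priors: np.ndarray) -> None:
        priors = np.asarray(priors, dtype=np.float64)
        if priors.shape != (self.C,) or np.any(priors < 0):
            raise ValueError("priors must be a nonnegative C-vector")
        if abs(priors.sum() - 1.0) > 1e-8:
            raise ValueError("priors must sum to 1")
        self.priors = priors

    # -- differentiable forward passes --------------------------------

    def _act(self, t: Tensor) -> Tensor:
        return t.tanh() if self.spec.activation == "tanh" else t.relu()

    def latent(self, X: np.ndarray) -> Tensor:
        """Latent embeddings z (n, T, z_dim) for a batch of profiles."""
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        n = X.shape[0]
        masked = X[:, None, :] * self.masks[None, :, :]
        h = Tensor(masked.reshape(n * self.T, self.spec.input_dim))
        for W, b in self.backbone:
            h = self._act(h @ W + b)
        h = h.reshape(n, self.T, self.spec.h_dim).transpose(1, 0, 2)
        z = h @ self.head_W + self.head_b          # (T, n, z_dim)
        return z.transpose(1, 0, 2)

    def sq_dists(self, z: Tensor) -> Tensor:
        """Squared distances to every prototype: (n, T, C, B)."""
        n = z.shape[0]
        diff = z.reshape(n, self.T, 1, 1, self.spec.z_dim) - self.centers
        return (diff * diff).sum(axis=-1)

    def _min_exponent(self, z: Tensor):
        """Clamped exponent e (n, T, C) of the nearest-prototype Gaussian.

        The prototype l minimising the raw squared distance also supplies
        the variance in the denominator; ties take the lowest index.
        """
        d2 = self.sq_dists(z)                       # (n, T, C, B)
        lstar = np.argmin(d2.data, axis=3)          # (n, T, C)
        n = d2.shape[0]
        d2min = d2.take_along_axis(lstar[..., None], axis=3).reshape(
            n, self.T, self.C)
        t_ix, c_ix = np.meshgrid(np.arange(self.T), np.arange(self.C),
                                 indexing="ij")
        lv = self.log_var[t_ix[None].repeat(n, 0), c_ix[None].repeat(n, 0),
                          lstar]                    # (n, T, C)
        e = -d2min / (lv.exp() * 2.0)
        return e.clamp(lo=EXP_CLAMP)

    def log_similarity(self, z: Tensor) -> Tensor:
        """ln s (n, T, C): log prior plus clamped Gaussian exponent."""
        return self._min_exponent(z) + np.log(np.maximum(self.priors, 1e-300))

    def similarity(self, z: Tensor) -> Tensor:
        """Similarity s (n, T, C); strictly positive by construction."""
        return self.log_similarity(z).exp()

    def log_posterior(self, z: Tensor) -> Tensor:
        """ln P(class | z^j) (n, T, C); softmax of log-similarities."""
        return self.log_similarity(z).log_softmax(axis=2)

    def assignment(self, z: Tensor) -> Tensor:
        """Prototype-assignment probabilities u (n, T, B).

        Dual of the similarity: for each prototype index l, take the min
        over classes k of the variance-scaled squared distance, then
        softmax over l.
        """
        d2 = self.sq_dists(z)                       # (n, T, C, B)
        q = d2 / (self.log_var.exp().reshape(1, self.T, self.C, self.B) * 2.0)
        qmin = q.min(axis=2)                        # (n, T, B)
        return (-qmin).log_softmax(axis=2).exp()

    def predict_proba_t(self, s: Tensor) -> Tensor:
        """Final class probabilities (n, C) from similarities (n, T, C)."""
        omega = self.omega_raw.softplus()           # (T, C) positive
        agg = (s * omega.reshape(1, self.T, self.C)).sum(axis=1)
        return (self.omega0 + agg.log()).log_softmax(axis=1).exp()

    # -- inference API -------------------------------------------------

    def encode(self, X: np.ndarray, j: Optional[int] = None) -> np.ndarray:
        """Latent embeddings; all sets (n, T, z_dim) or one set (n, z_dim)."""
        if j is not None and not (0 <= j < self.T):
            raise IndexError(f"set index {j} out of range [0, {self.T})")
        with no_grad():
            z = self.latent(X).data
        return z if j is None else z[:, j, :]

    def forward(self, X: np.ndarray) -> SimilarityTensor:
        """Full inference pass over a batch of cell profiles."""
        with no_grad():
            z = self.latent(X)
            log_s = self.log_similarity(z)
            s = log_s.exp()
            post = log_s.log_softmax(axis=2).exp()
            u = self.assignment(z)
            y_hat = self.predict_proba_t(s)
        return SimilarityTensor(s=s.data, posterior=post.data, u=u.data,
                                y_hat=y_hat.data, z=z.data)

    # -- persistence ---------------------------------------------------

    CHECKPOINT_VERSION = 1

    def state_arrays(self) -> dict:
        arrays = {"head_W": self.head_W.data, "head_b": self.head_b.data,
                  "centers": self.centers.data, "log_var": self.log_var.data,
                  "omega0": self.omega0.data, "omega_raw": self.omega_raw.data,
                  "priors": self.priors, "masks": self.masks}
        for i, (W, b) in enumerate(self.backbone):
            arrays[f"backbone_W{i}"] = W.data
            arrays[f"backbone_b{i}"] = b.data
        return arrays

    def save(self, path: str | Path, *, gene_names: Sequence[str] = (),
             set_names: Sequence[str] = (), extra_meta: Optional[dict] = None
             ) -> None:
        """Write a versioned .npz checkpoint with a JSON metadata entry."""
        meta = {"version": self.CHECKPOINT_VERSION, "spec": asdict(self.spec),
                "C": self.C, "B": self.B, "d_min": self.d_min,
                "gene_names": list(gene_names), "set_names": list(set_names)}
        if extra_meta:
            meta.update(extra_meta)
        arrays = self.state_arrays()
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PrototypeNetwork":
        with np.load(Path(path)) as npz:
            meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
            spec = EncoderSpec(**meta["spec"])
            net = cls(npz["masks"], meta["C"], spec, B=meta["B"],
                      priors=npz["priors"], d_min=meta["d_min"])
            for i, (W, b) in enumerate(net.backbone):
                W.data = npz[f"backbone_W{i}"].copy()
                b.data = npz[f"backbone_b{i}"].copy()
            net.head_W.data = npz["head_W"].copy()
            net.head_b.data = npz["head_b"].copy()
            net.centers.data = npz["centers"].copy()
            net.log_var.data = npz["log_var"].copy()
            net.omega0.data = npz["omega0"].copy()
            net.omega_raw.data = npz["omega_raw"].copy()
            net.meta = meta
        return net


# -- standalone functional forms (used directly in tests/diagnostics) ----

def posterior_from_similarity(s: np.ndarray) -> np.ndarray:
    """P(class k | z) = s[k] / sum_c s[c] along the last axis."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("similarities must be strictly positive")
    return s / s.sum(axis=-1, keepdims=True)


def similarity_from_latent(z: np.ndarray, centers: np.ndarray,
                           log_var: np.ndarray,
                           priors: np.ndarray) -> np.ndarray:
    """Similarity vector for one latent z against a (C, B, z_dim) bank."""
    d2 = ((z[None, None, :] - centers) ** 2).sum(axis=-1)      # (C, B)
    lstar = np.argmin(d2, axis=1)
    d2min = np.take_along_axis(d2, lstar[:, None], axis=1)[:, 0]
    var = np.exp(np.take_along_axis(log_var, lstar[:, None], axis=1))[:, 0]
    e = np.maximum(-d2min / (2 * var), EXP_CLAMP)
    return priors * np.exp(e)
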