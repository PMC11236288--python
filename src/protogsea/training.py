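"""Two-stage model training with stratified K-fold cross-validation.

Stage 1 trains the backbone, heads, prototypes and variances with the
final-prediction loss switched off; stage 2 freezes those and tunes only
the aggregation bias and weights. Class priors eta are fixed to the
empirical phenotype frequencies of each training split. Prototype
centers are initialised at latent class centroids after a short
encoder-only warm-up, which avoids dead prototypes far from the data.

All randomness (fold splits, parameter init, batch order) derives from a
single integer seed, so a run is bit-reproducible on CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import losses as L
from ._autograd import Adam, no_grad
from .data import ExpressionDataset
from .genesets import GeneSetCollection
from .losses import LossWeights
from .network import EncoderSpec, PrototypeNetwork, SimilarityTensor

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization schedule and fold layout.

    ``labeled_mode`` uses the per-cell biological labels q: B becomes the
    number of labels and the label-aware loss variants are used.
    ``stage2_joint`` additionally fine-tunes all parameters in stage 2
    (ablation toggle); by default stage 2 updates aggregation weights only.
    """

    stage1_epochs: int = 50
    stage2_epochs: int = 20
    warmup_epochs: int = 1
    batch_size: int = 128
    learning_rate: float = 1e-3
    K: int = 5
    seed: int = 0
    labeled_mode: bool = False
    stage2_joint: bool = False
    B: int = 1
    weights: LossWeights = field(default_factory=LossWeights)
    test_fraction: float = 0.2   # used only when K == 1

    def __post_init__(self):
        if self.stage1_epochs < 1:
            raise ValueError("stage1_epochs must be >= 1")
        if self.stage2_epochs < 0 or self.warmup_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FoldResult:
    """Everything the enrichment stage needs from one fold."""

    fold: int
    net: PrototypeNetwork
    sim: SimilarityTensor            # held-out cells, inference mode
    test_idx: np.ndarray
    train_idx: np.ndarray
    y_test: np.ndarray
    q_test: Optional[np.ndarray]
    set_accuracy: np.ndarray         # per-set held-out accuracy
    history: List[Dict[str, float]]  # per-epoch loss components


def _fold_seed(seed: int, fold: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _batched_forward(net: PrototypeNetwork, X: np.ndarray,
                     batch: int = 512) -> SimilarityTensor:
    parts = [net.forward(X[i:i + batch]) for i in range(0, X.shape[0], batch)]
    return SimilarityTensor(
        s=np.concatenate([p.s for p in parts]),
        posterior=np.concatenate([p.posterior for p in parts]),
        u=np.concatenate([p.u for p in parts]),
        y_hat=np.concatenate([p.y_hat for p in parts]),
        z=np.concatenate([p.z for p in parts]))


def _init_prototypes(net: PrototypeNetwork, X: np.ndarray, y: np.ndarray,
                     q: Optional[np.ndarray], rng: np.random.Generator) -> None:
    """Place each prototype at its group's latent centroid.

    Group is (phenotype k) for B=1 / unlabeled training, (phenotype k,
    label l) otherwise; empty groups fall back to a small random vector.
    """
    z = _batched_forward(net, X).z                  # (n, T, z)
    for k in range(net.C):
        for l in range(net.B):
            if q is not None and net.B > 1:
                sel = (y == k + 1) & (q == l + 1)
            else:
                sel = (y == k + 1)
            if sel.any():
                net.centers.data[:, k, l, :] = z[sel].mean(axis=0)
            else:
                net.centers.data[:, k, l, :] = rng.standard_normal(
                    (net.T, net.spec.z_dim)) * 0.1


def _epoch(net: PrototypeNetwork, X: np.ndarray, y: np.ndarray,
           q: Optional[np.ndarray], cfg: TrainConfig, weights: LossWeights,
           opt: Adam, rng: np.random.Generator, labeled: bool
           ) -> Dict[str, float]:
    """One optimization epoch over shuffled minibatches."""
    n = X.shape[0]
    order = rng.permutation(n)
    totals: Dict[str, float] = {}
    n_batches = 0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        xb, yb = X[idx], y[idx]
        qb = None if q is None else q[idx]
        z = net.latent(xb)
        log_s = net.log_similarity(z)
        s = log_s.exp()
        posteriors = log_s.log_softmax(axis=2).exp()
        parts = {"clf": L.loss_clf(posteriors, yb),
                 "c2p": (L.loss_c2p_labeled(z, net, yb, qb) if labeled
                         else L.loss_c2p(z, net, yb))}
        if labeled:
            parts["p2p"] = L.loss_p2p_labeled(net.assignment(z), qb)
        else:
            parts["p2p"] = L.loss_p2p(net)
        assign = L.build_assignments(z.data, net, yb, qb if labeled else None)
        parts["p2c"] = L.loss_p2c(z, net, assign)
        if weights.stage == 2 and weights.final != 0.0:
            parts["final"] = L.loss_final(net.predict_proba_t(s), yb)
        total = L.combined_loss(parts, weights)
        opt.zero_grad()
        total.backward()
        opt.step()
        for key, t in parts.items():
            totals[key] = totals.get(key, 0.0) + t.item()
        totals["total"] = totals.get("total", 0.0) + total.item()
        n_batches += 1
    return {k: v / max(n_batches, 1) for k, v in totals.items()}


def train_one_fold(ds: ExpressionDataset, sets: GeneSetCollection,
                   cfg: TrainConfig, spec: Optional[EncoderSpec] = None,
                   train_idx: Optional[np.ndarray] = None,
                   test_idx: Optional[np.ndarray] = None,
                   fold: int = 0, seed: Optional[int] = None) -> FoldResult:
    """Train on one train/test split and score the held-out cells."""
    if train_idx is None or test_idx is None:
        train_idx, test_idx = _split_indices(ds, cfg)[0]
    seed = _fold_seed(cfg.seed, fold) if seed is None else seed
    labeled = cfg.labeled_mode
    if labeled and ds.q is None:
        raise ValueError("labeled_mode requires per-cell biological labels q")
    y_tr = ds.y[train_idx]
    for k in range(1, ds.C + 1):
        if not np.any(y_tr == k):
            raise ValueError(f"phenotype class {k} absent from training split")
    if spec is None:
        spec = EncoderSpec(input_dim=ds.N)
    B = ds.n_labels if labeled else cfg.B
    net = PrototypeNetwork(sets.masks, ds.C, spec, B=max(B, 1), seed=seed)
    net.set_priors(np.bincount(y_tr, minlength=ds.C + 1)[1:] / len(y_tr))

    X_tr = ds.X[train_idx]
    q_tr = None if ds.q is None else ds.q[train_idx]
    rng = np.random.default_rng(seed)
    history: List[Dict[str, float]] = []

    # warm-up: encoder only, then drop prototypes onto latent centroids
    stage1_w = replace(cfg.weights, stage=1)
    if cfg.warmup_epochs > 0:
        opt = Adam(net.encoder_parameters(), lr=cfg.learning_rate)
        for _ in range(cfg.warmup_epochs):
            history.append(_epoch(net, X_tr, y_tr, q_tr, cfg, stage1_w, opt,
                                  rng, labeled))
    _init_prototypes(net, X_tr, y_tr, q_tr, rng)

    # stage 1: encoders + prototypes, final-prediction loss off
    opt = Adam(net.encoder_parameters() + net.prototype_parameters(),
               lr=cfg.learning_rate)
    for _ in range(cfg.stage1_epochs):
        history.append(_epoch(net, X_tr, y_tr, q_tr, cfg, stage1_w, opt,
                              rng, labeled))

    # stage 2: aggregation weights only (optionally joint fine-tune)
    stage2_w = replace(cfg.weights, stage=2)
    stage2_params = (net.parameters() if cfg.stage2_joint
                     else net.aggregation_parameters())
    opt = Adam(stage2_params, lr=cfg.learning_rate)
    for _ in range(cfg.stage2_epochs):
        history.append(_epoch(net, X_tr, y_tr, q_tr, cfg, stage2_w, opt,
                              rng, labeled))

    sim = _batched_forward(net, ds.X[test_idx])
    y_te = ds.y[test_idx]
    pred = np.argmax(sim.posterior, axis=2) + 1       # (n_test, T)
    set_acc = (pred == y_te[:, None]).mean(axis=0)
    return FoldResult(fold=fold, net=net, sim=sim,
                      test_idx=np.asarray(test_idx),
                      train_idx=np.asarray(train_idx), y_test=y_te,
                      q_test=None if ds.q is None else ds.q[test_idx],
                      set_accuracy=set_acc, history=history)


def _split_indices(ds: ExpressionDataset, cfg: TrainConfig
                   ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices; (phenotype, label) pairs where feasible."""
    strat = ds.y
    if ds.q is not None:
        pair = ds.y * 1000 + ds.q
        counts = np.bincount(pair)
        if counts[counts > 0].min() >= max(cfg.K, 2):
            strat = pair
    if cfg.K == 1:
        tr, te = train_test_split(
            np.arange(ds.n), test_size=cfg.test_fraction,
            stratify=strat, random_state=cfg.seed % (2 ** 31))
        return [(np.sort(tr), np.sort(te))]
    class_min = np.bincount(ds.y)[1:].min()
    if cfg.K > class_min:
        raise ValueError(
            f"K={cfg.K} exceeds the smallest phenotype class ({class_min})")
    skf = StratifiedKFold(n_splits=cfg.K, shuffle=True,
                          random_state=cfg.seed % (2 ** 31))
    return [(tr, te) for tr, te in skf.split(np.zeros(ds.n), strat)]


def fit_kfold(ds: ExpressionDataset, sets: GeneSetCollection,
              cfg: TrainConfig, spec: Optional[EncoderSpec] = None
              ) -> List[FoldResult]:
    """Train one model per stratified fold; held-out sets partition cells."""
    results = []
    for fold, (tr, te) in enumerate(_split_indices(ds, cfg)):
        logger.info("training fold %d (%d train / %d test cells)",
                    fold, len(tr), len(te))
        results.append(train_one_fold(ds, sets, cfg, spec=spec, train_idx=tr,
                                      test_idx=te, fold=fold))
    return results
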