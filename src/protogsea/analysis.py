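"""Model/Results interface for prototype-based gene-set enrichment.

:class:`ProtoGSEA` is built from an expression dataset and a gene-set
collection, holds the architecture and training configuration, and
``fit()`` runs the full pipeline (preprocessing is the caller's choice;
stratified K-fold training; rank-based significance testing), returning a
:class:`ProtoGSEAResults` with the enrichment table, per-fold models and
diagnostics, a ``summary()`` table, and plotting hooks.

Example
-------
>>> from protogsea import SimConfig, simulate_dataset, preprocess, ProtoGSEA
>>> ds, sets, truth = simulate_dataset(SimConfig(seed=7))
>>> model = ProtoGSEA(preprocess(ds), sets, K=2, stage1_epochs=10)
>>> res = model.fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionDataset, preprocess, read_expression
from .enrichment import EnrichmentTable, score_gene_sets
from .genesets import GeneSetCollection, read_gmt
from .network import EncoderSpec
from .training import FoldResult, TrainConfig, fit_kfold


class ProtoGSEA:
    """Prototype-network gene-set enrichment model.

    Parameters
    ----------
    dataset : ExpressionDataset
        Preprocessed (typically library-size normalized, log1p) cells x
        genes data with phenotype labels.
    gene_sets : GeneSetCollection
        Sets to test, with masks over ``dataset.gene_names``.
    labeled : bool, optional
        Use per-cell biological labels (``dataset.q``) to inform the
        prototypes (one per label). Defaults to True when labels exist.
    hidden_layers, h_dim, z_dim, activation :
        Encoder architecture (see :class:`EncoderSpec`).
    subsample_per_class : int
        Cap on held-out cells per phenotype entering each fold's test.
    Remaining keyword arguments configure :class:`TrainConfig`
    (``K``, ``stage1_epochs``, ``stage2_epochs``, ``batch_size``,
    ``learning_rate``, ``weights``, ...).
    """

    def __init__(self, dataset: ExpressionDataset,
                 gene_sets: GeneSetCollection, *,
                 labeled: Optional[bool] = None,
                 hidden_layers: Sequence[int] = (256,),
                 h_dim: int = 64, z_dim: int = 16, activation: str = "tanh",
                 subsample_per_class: int = 500,
                 **train_kwargs):
        if gene_sets.masks.shape[1] != dataset.N:
            raise ValueError("gene set masks do not match the dataset's "
                             "gene axis")
        self.dataset = dataset
        self.gene_sets = gene_sets
        if labeled is None:
            labeled = dataset.q is not None
        if labeled and dataset.q is None:
            raise ValueError("labeled=True requires per-cell labels q")
        self.spec = EncoderSpec(input_dim=dataset.N,
                                hidden_layers=list(hidden_layers),
                                h_dim=h_dim, z_dim=z_dim,
                                activation=activation)
        self.config = TrainConfig(labeled_mode=labeled, **train_kwargs)
        self.subsample_per_class = int(subsample_per_class)

    @classmethod
    def from_files(cls, expression: str | Path, gmt: str | Path, *,
                   format: str = "delimited", pheno_key: str = "phenotype",
                   celltype_key: Optional[str] = None,
                   metadata: Optional[str | Path] = None,
                   normalize: bool = True, log1p: bool = True,
                   scale_factor: float = 1e4, min_genes: int = 1,
                   max_genes: Optional[int] = None,
                   **kwargs) -> "ProtoGSEA":
        """Build a model straight from an expression file and a GMT file."""
        ds = read_expression(expression, format=format, pheno_key=pheno_key,
                             celltype_key=celltype_key, metadata=metadata)
        ds = preprocess(ds, normalize=normalize, log1p=log1p,
                        scale_factor=scale_factor)
        sets = read_gmt(gmt, ds, min_genes=min_genes, max_genes=max_genes)
        return cls(ds, sets, **kwargs)

    def fit(self, seed: Optional[int] = None) -> "ProtoGSEAResults":
        """Train K folds and test enrichment on their held-out cells."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        folds = fit_kfold(self.dataset, self.gene_sets, cfg, spec=self.spec)
        enrich = score_gene_sets(folds, self.gene_sets.names,
                                 self.gene_sets.sizes,
                                 subsample_per_class=self.subsample_per_class,
                                 seed=cfg.seed)
        return ProtoGSEAResults(self, cfg, folds, enrich)


class ProtoGSEAResults:
    """Fitted folds, enrichment table and diagnostics.

    Attributes
    ----------
    enrichment : pandas.DataFrame
        One row per gene set, sorted by q-value: per-class and per-fold
        p-values, Pearson-combined p, BH-adjusted q.
    folds : list of FoldResult
        Per-fold networks, held-out similarity tensors and accuracies.
    """

    def __init__(self, model: ProtoGSEA, config: TrainConfig,
                 folds: List[FoldResult], enrich: EnrichmentTable):
        self.model = model
        self.config = config
        self.folds = folds
        self._enrich = enrich

    @property
    def enrichment(self) -> pd.DataFrame:
        return self._enrich.table

    @property
    def class_p(self) -> np.ndarray:
        """Raw per-class p-values, shape (T sets, K folds, C classes)."""
        return self._enrich.class_p

    def combined_p(self, set_name: str) -> float:
        row = self.enrichment.loc[self.enrichment["set"] == set_name]
        if row.empty:
            raise KeyError(f"unknown gene set {set_name!r}")
        return float(row["combined_p"].iloc[0])

    def q_value(self, set_name: str) -> float:
        row = self.enrichment.loc[self.enrichment["set"] == set_name]
        if row.empty:
            raise KeyError(f"unknown gene set {set_name!r}")
        return float(row["q_value"].iloc[0])

    @property
    def set_accuracy(self) -> pd.DataFrame:
        """Held-out per-set phenotype accuracy, folds as columns."""
        acc = np.stack([fr.set_accuracy for fr in self.folds], axis=1)
        return pd.DataFrame(
            acc, index=self.model.gene_sets.names,
            columns=[f"fold{fr.fold}" for fr in self.folds])

    @property
    def phenotype_accuracy(self) -> float:
        """Accuracy of the aggregated prediction over all held-out cells."""
        hits = total = 0
        for fr in self.folds:
            pred = np.argmax(fr.sim.y_hat, axis=1) + 1
            hits += int((pred == fr.y_test).sum())
            total += len(fr.y_test)
        return hits / total

    def summary(self, top: int = 20) -> str:
        """Human-readable report of the most significant gene sets."""
        from statsmodels.iolib.table import SimpleTable

        df = self.enrichment.head(top)
        acc = self.set_accuracy.mean(axis=1)
        rows = [[name, f"{ng:d}", f"{p:.3g}", f"{q:.3g}",
                 f"{acc[name]:.3f}"]
                for name, ng, p, q in zip(df["set"], df["n_genes"],
                                          df["combined_p"], df["q_value"])]
        table = SimpleTable(
            rows,
            headers=["gene set", "genes", "combined p", "q value",
                     "mean fold acc"],
            title=(f"Prototype GSE analysis: {self.model.dataset.n} cells, "
                   f"{self.model.dataset.C} classes, "
                   f"{self.model.gene_sets.T} sets, K={self.config.K}"))
        extra = (f"\nAggregated phenotype accuracy (held-out): "
                 f"{self.phenotype_accuracy:.3f}\n"
                 f"Subsample per class per test: "
                 f"{self._enrich.subsample_per_class}; seed {self.config.seed}")
        return str(table) + extra

    def save(self, out_dir: str | Path, metadata: Optional[dict] = None
             ) -> Path:
        """Write results.tsv (+ metadata sidecar) and fold checkpoints."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._enrich.write(out / "results.tsv", metadata=metadata)
        for fr in self.folds:
            fr.net.save(out / f"fold{fr.fold}.npz",
                        gene_names=self.model.dataset.gene_names,
                        set_names=self.model.gene_sets.names,
                        extra_meta={"fold": fr.fold,
                                    "seed": self.config.seed,
                                    "test_idx": fr.test_idx.tolist()})
        return out / "results.tsv"

    def plot_latent(self, set_name: str, out: str | Path, *,
                    color_by: str = "phenotype",
                    celltype_panels: bool = False, seed: int = 0):
        """Latent-space figure for one gene set (see :mod:`.viz`)."""
        from .viz import plot_latent

        return plot_latent(self, set_name, out, color_by=color_by,
                           celltype_panels=celltype_panels, seed=seed)
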