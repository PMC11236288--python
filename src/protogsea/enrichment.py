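"""Rank-based significance testing of gene-set enrichment.

For each gene set and phenotype class the held-out similarity scores of
class-k cells are compared with those of all other cells by a one-sided
Mann-Whitney U test (alternative: class-k cells score higher on their own
class similarity; U/(n1*n2) is exactly the auROC of the scores against
the class indicator). The C per-class p-values share the null hypothesis
of equal mean ranks, so they are combined by Fisher's method
(chi-squared with 2C df on -2*sum(ln p), sensitive to the smallest p).
P-values from the K cross-validation folds are combined by Pearson's
method (chi-squared lower tail on -2*sum(ln(1-p)), sensitive to the
largest p, i.e. every fold must agree). Benjamini-Hochberg correction is
applied across gene sets.

To keep test power comparable across datasets of very different sizes,
each fold's test is run on a subsample of at most ``subsample_per_class``
held-out cells per phenotype (a single seeded draw without replacement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .training import FoldResult

P_TINY = 1e-300
EXACT_MAX_N = 12


def mwu_test(a: Sequence[float], b: Sequence[float],
             alternative: str = "greater") -> float:
    """One-sided Mann-Whitney U p-value for ``a`` stochastically larger.

    Uses the exact permutation distribution when n_a + n_b <= 12 with no
    ties, and the tie-corrected normal approximation with continuity
    correction otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be nonempty")
    if alternative != "greater":
        raise ValueError("only the 'greater' alternative is supported")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def fisher_combine(ps: Sequence[float]) -> float:
    """Fisher's method: chi^2_{2C} upper tail at -2 sum ln p."""
    ps = np.clip(np.asarray(ps, dtype=np.float64), P_TINY, 1.0)
    statistic = -2.0 * np.log(ps).sum()
    return float(np.clip(stats.chi2.sf(statistic, df=2 * ps.size), 0.0, 1.0))


def pearson_combine(ps: Sequence[float]) -> float:
    """Pearson's method: chi^2_{2K} lower tail at -2 sum ln(1 - p).

    Small only when every input p is small, hence sensitive to the
    largest p across folds.
    """
    ps = np.clip(np.asarray(ps, dtype=np.float64), 0.0, 1.0 - 1e-16)
    statistic = -2.0 * np.log1p(-ps).sum()
    return float(np.clip(stats.chi2.cdf(statistic, df=2 * ps.size), 0.0, 1.0))


def bh_adjust(ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    ps = np.asarray(ps, dtype=np.float64)
    if ps.size == 0:
        return ps
    return multipletests(ps, method="fdr_bh")[1]


@dataclass
class EnrichmentTable:
    """Per-set enrichment results plus run metadata.

    ``table`` is sorted ascending by q-value then combined p-value and has
    one row per gene set: name, retained gene count, per-class per-fold
    p-values, per-fold Fisher-combined p-values, the Pearson-combined
    p-value across folds, and the BH-adjusted q-value.
    ``class_p`` is the raw (T, K, C) array of per-class p-values.
    """

    table: pd.DataFrame
    class_p: np.ndarray
    subsample_per_class: int
    seed: int

    def write(self, path: str | Path, metadata: Optional[dict] = None) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        meta = {"subsample_per_class": self.subsample_per_class,
                "seed": self.seed, "n_sets": int(self.table.shape[0])}
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _subsample(idx: np.ndarray, cap: int, rng: np.random.Generator
               ) -> np.ndarray:
    if idx.size <= cap:
        return idx
    return rng.choice(idx, size=cap, replace=False)


def score_gene_sets(fold_results: List[FoldResult],
                    set_names: Sequence[str],
                    set_sizes: Sequence[int],
                    subsample_per_class: int = 500,
                    seed: int = 0) -> EnrichmentTable:
    """Full testing pipeline over trained folds.

    For each fold and gene set j: subsample held-out cells per phenotype,
    run the per-class one-sided MWU tests on the class-k similarity
    column s[:, j, k], Fisher-combine over classes; then Pearson-combine
    each set's fold p-values and BH-adjust across sets.
    """
    if not fold_results:
        raise ValueError("at least one trained fold is required")
    T = len(set_names)
    K = len(fold_results)
    C = fold_results[0].sim.s.shape[2]
    class_p = np.ones((T, K, C))
    fold_p = np.ones((T, K))
    for f, fr in enumerate(fold_results):
        y = fr.y_test
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(f,)))
        for k in range(1, C + 1):
            if not np.any(y == k):
                raise ValueError(
                    f"fold {fr.fold} has no held-out cells of class {k}")
        keep = np.concatenate([
            _subsample(np.flatnonzero(y == k), subsample_per_class, rng)
            for k in range(1, C + 1)])
        keep.sort()
        s = fr.sim.s[keep]
        yk = y[keep]
        for j in range(T):
            for k in range(1, C + 1):
                scores = s[:, j, k - 1]
                class_p[j, f, k - 1] = mwu_test(scores[yk == k],
                                                scores[yk != k])
            fold_p[j, f] = fisher_combine(class_p[j, f])
    combined = np.array([pearson_combine(fold_p[j]) for j in range(T)])
    qvals = bh_adjust(combined)

    cols = {"set": list(set_names), "n_genes": list(map(int, set_sizes))}
    for f in range(K):
        for k in range(C):
            cols[f"p_class{k + 1}_fold{f}"] = class_p[:, f, k]
    for f in range(K):
        cols[f"p_fold{f}"] = fold_p[:, f]
    cols["combined_p"] = combined
    cols["q_value"] = qvals
    table = pd.DataFrame(cols).sort_values(
        ["q_value", "combined_p", "set"], kind="mergesort").reset_index(drop=True)
    return EnrichmentTable(table=table, class_p=class_p,
                           subsample_per_class=subsample_per_class, seed=seed)
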