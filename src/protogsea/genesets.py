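"""Gene set collections, GMT parsing, and gene-set feature masking.

A gene set is represented against a fixed gene axis (the dataset's
``gene_names``) as a binary mask m_j of length N. The feature the model
sees for set j is the element-wise product f_j(x) = x * m_j: the cell's
profile with every non-member gene zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .data import ExpressionDataset

logger = logging.getLogger(__name__)


class GeneSetError(ValueError):
    """Raised for malformed GMT input or empty collections."""


@dataclass
class GeneSetCollection:
    """Named gene sets with binary masks over a fixed gene axis."""

    names: List[str]
    members: List[List[str]]          # members present in the gene axis
    masks: np.ndarray                 # (T, N) binary
    gene_names: List[str] = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> np.ndarray:
        """Retained member count per set (equals each mask's sum)."""
        return self.masks.sum(axis=1).astype(int)

    @classmethod
    def from_members(cls, sets: Dict[str, Sequence[str]],
                     gene_names: Sequence[str],
                     min_genes: int = 1,
                     max_genes: Optional[int] = None) -> "GeneSetCollection":
        """Build masks by intersecting each set with ``gene_names``.

        Matching is exact and case-sensitive. Sets with fewer than
        ``min_genes`` members present (or more than ``max_genes``) are
        dropped with a logged count.
        """
        index = {g: i for i, g in enumerate(gene_names)}
        N = len(gene_names)
        names, members, rows = [], [], []
        n_small = n_large = 0
        for name, genes in sets.items():
            present = [g for g in dict.fromkeys(genes) if g in index]
            if len(present) < min_genes:
                n_small += 1
                continue
            if max_genes is not None and len(present) > max_genes:
                n_large += 1
                continue
            mask = np.zeros(N, dtype=np.float64)
            mask[[index[g] for g in present]] = 1.0
            names.append(name)
            members.append(present)
            rows.append(mask)
        if n_small or n_large:
            logger.info("dropped %d set(s) below min_genes=%d and %d above "
                        "max_genes", n_small, min_genes, n_large)
        if not names:
            raise GeneSetError("no gene sets retained after filtering")
        return cls(names=names, members=members,
                   masks=np.stack(rows), gene_names=list(gene_names))

    def write_gmt(self, path: str | Path,
                  descriptions: Optional[Sequence[str]] = None) -> None:
        lines = []
        for i, (name, genes) in enumerate(zip(self.names, self.members)):
            desc = descriptions[i] if descriptions else "na"
            lines.append("\t".join([name, desc] + list(genes)))
        Path(path).write_text("\n".join(lines) + "\n")


def parse_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Parse a GMT file (name, description, tab-separated genes)."""
    sets: Dict[str, List[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise GeneSetError(f"malformed GMT line {ln}: fewer than 2 fields")
        name = fields[0]
        sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise GeneSetError(f"no gene sets found in {path}")
    return sets


def read_gmt(path: str | Path, ds: ExpressionDataset, *,
             min_genes: int = 1,
             max_genes: Optional[int] = None) -> GeneSetCollection:
    """Read a GMT file and intersect it with a dataset's gene axis.

    ``min_genes`` defaults to 1: a set is kept as long as at least one
    associated gene is present in the data.
    """
    return GeneSetCollection.from_members(parse_gmt(path), ds.gene_names,
                                          min_genes=min_genes,
                                          max_genes=max_genes)


def gene_set_feature(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked feature f_j(x) = x * m_j (element-wise product)."""
    x = np.asarray(x, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if x.shape[-1] != mask.shape[-1]:
        raise GeneSetError(
            f"profile length {x.shape[-1]} != mask length {mask.shape[-1]}")
    return x * mask
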