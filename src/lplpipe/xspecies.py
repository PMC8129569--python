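"""Cross-species signature extraction and branch coherency.

Mouse tumor fold changes are intersected with a human cohort through
ortholog pairs; genes selected in both species with the same fold-change
sign form the coherent signature (per-gene direction = the shared sign).
Branch coherency then asks whether two independent Ward clusterings of the
signature genes -- one per cohort -- separate the up and down genes into
the same two dendrogram branches.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexpr import log2_fold_changes
from .matrix import ExpressionMatrix

__all__ = [
    "Signature",
    "collapse_probesets",
    "map_orthologs",
    "coherent_signature",
    "branch_coherency",
]

log = logging.getLogger(__name__)


@dataclass
class Signature:
    """Sign-coherent cross-species gene list with per-gene direction."""

    entries: list[tuple[str, str, str]]  # (mouse_gene, human_gene, direction)

    @property
    def n_up(self) -> int:
        return sum(1 for *_, d in self.entries if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for *_, d in self.entries if d == "down")

    def __len__(self) -> int:
        return len(self.entries)

    def mouse_genes(self) -> list[str]:
        return [m for m, *_ in self.entries]

    def human_genes(self) -> list[str]:
        return [h for _, h, _ in self.entries]

    def direction_of(self, species: str) -> dict[str, str]:
        idx = 0 if species == "mouse" else 1
        return {e[idx]: e[2] for e in self.entries}

    def to_tsv(self, path: Path | str) -> None:
        pd.DataFrame(
            self.entries, columns=["mouse_gene", "human_gene", "direction"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Path | str) -> "Signature":
        df = pd.read_csv(path, sep="\t")
        return cls([tuple(r) for r in df[["mouse_gene", "human_gene", "direction"]].itertuples(index=False)])


def collapse_probesets(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probeset-keyed matrix to genes, keeping per gene the
    probeset with highest mean expression.  Unmapped probesets are dropped
    with a logged count."""
    if not probe_to_gene:
        raise ValueError("empty probeset-to-gene mapping")
    mapped = [p for p in matrix.gene_ids if p in probe_to_gene]
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        log.info("collapse_probesets: dropped %d unmapped probesets", dropped)
    sub = matrix.values.loc[mapped]
    means = sub.mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = list(best)
    collapsed = sub.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(collapsed, matrix.species, dict(matrix.class_of_sample))


def map_orthologs(
    mouse_genes: Sequence[str],
    human_genes: Sequence[str],
    explicit_map: pd.DataFrame | None = None,
) -> list[tuple[str, str]]:
    """Pair mouse and human gene symbols.

    With an explicit two-column table it is used verbatim (duplicate mouse
    genes rejected); otherwise pairing is by case-insensitive symbol
    equality (the title-case/upper-case convention of mouse vs human
    symbols), unique per mouse gene.
    """
    if explicit_map is not None:
        mcol, hcol = explicit_map.columns[:2]
        if explicit_map[mcol].duplicated().any():
            dup = explicit_map[mcol][explicit_map[mcol].duplicated()].iloc[0]
            raise ValueError(f"duplicate mouse gene in explicit map: {dup!r}")
        wanted = set(mouse_genes)
        have = set(human_genes)
        return [
            (m, h)
            for m, h in zip(explicit_map[mcol], explicit_map[hcol])
            if m in wanted and h in have
        ]
    by_lower: dict[str, str] = {}
    for h in human_genes:
        by_lower.setdefault(h.lower(), h)
    pairs = []
    for m in mouse_genes:
        h = by_lower.get(m.lower())
        if h is not None:
            pairs.append((m, h))
    return pairs


def coherent_signature(
    mouse_de: pd.DataFrame,
    human_de: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> Signature:
    """Keep ortholog pairs selected in both species with concordant
    fold-change sign; record the shared direction."""
    if not pairs:
        warnings.warn("empty ortholog pair list; empty signature")
        return Signature([])
    entries = []
    for m, h in pairs:
        if m not in mouse_de.index or h not in human_de.index:
            continue
        mrow, hrow = mouse_de.loc[m], human_de.loc[h]
        if not (bool(mrow["selected"]) and bool(hrow["selected"])):
            continue
        if np.sign(mrow["log2fc"]) != np.sign(hrow["log2fc"]) or mrow["log2fc"] == 0:
            continue
        entries.append((m, h, "up" if mrow["log2fc"] > 0 else "down"))
    return Signature(entries)


def _branch_labels(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    contrast: tuple[str, str],
) -> pd.Series:
    """Two-branch Ward cut of signature-gene profiles, branches labeled
    up/down by the sign of their mean contrast."""
    sub = matrix.subset_genes(genes)
    profiles = sub.standardized().to_numpy()
    branches = fcluster(linkage(profiles, method="ward"), t=2, criterion="maxclust")
    fc = log2_fold_changes(sub, *contrast)
    labels = {}
    for b in np.unique(branches):
        mean_fc = fc[branches == b].mean()
        if mean_fc == 0:
            ups = int((fc[branches == b] > 0).sum())
            downs = int((fc[branches == b] < 0).sum())
            log.warning("branch %d has zero mean contrast; majority vote", b)
            labels[b] = "up" if ups >= downs else "down"
        else:
            labels[b] = "up" if mean_fc > 0 else "down"
    return pd.Series([labels[b] for b in branches], index=list(genes))


def branch_coherency(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    signature: Signature,
    contrast_a: tuple[str, str],
    contrast_b: tuple[str, str],
) -> float:
    """Fraction of signature genes placed in same-direction branches by
    independent two-branch Ward clusterings of the two matrices."""
    if not signature.entries:
        raise ValueError("empty signature")
    genes_a = [m if matrix_a.species == "mouse" else h for m, h, _ in signature.entries]
    genes_b = [m if matrix_b.species == "mouse" else h for m, h, _ in signature.entries]
    la = _branch_labels(matrix_a, genes_a, contrast_a).to_numpy()
    lb = _branch_labels(matrix_b, genes_b, contrast_b).to_numpy()
    return float((la == lb).mean())


def overlap_counts(signature: Signature, path: Path | str | None = None) -> dict:
    """Venn-style up/down overlap counts; optionally written as JSON."""
    counts = {
        "n_entries": len(signature),
        "n_up": signature.n_up,
        "n_down": signature.n_down,
    }
    if path is not None:
        Path(path).write_text(json.dumps(counts, indent=1))
    return counts
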