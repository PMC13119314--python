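"""Localization index and temporal clustering.

The localization index of gene g compares its editing efficiency under a
compartment-anchored reporter with the matched cytoplasmic reference:

    LI_g = log2( (E_comp,g / R_comp,g) / (E_cyt,g / R_cyt,g) )

Genes with zero edits or zero reads in either sample are excluded by
default (an optional pseudocount mode adds 0.5 to both edit counts
instead). Time courses of LI are row z-scored and clustered by UPGMA with
correlation distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantification import GeneEditProfile


@dataclass
class LocalizationRecord:
    gene_id: str
    li: float
    efficiency_compartment: float
    efficiency_cytoplasm: float


@dataclass
class Dendrogram:
    """UPGMA result: scipy linkage matrix plus derived views."""

    linkage: np.ndarray
    leaf_ids: list[str]
    labels: pd.Series  # flat cluster label per leaf id

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});" \
            if not tree.is_leaf() else f"{self.leaf_ids[tree.id]};"


def localization_index(
    compartment: list[GeneEditProfile],
    cytoplasm: list[GeneEditProfile],
    policy: str = "exclude",
    pseudocount: float = 0.5,
) -> tuple[list[LocalizationRecord], pd.DataFrame]:
    """Per-gene LI for genes present in both samples.

    ``policy`` is "exclude" (drop genes with zero edits in either sample) or
    "pseudocount" (add ``pseudocount`` to both edit counts). Genes with zero
    reads in either sample are always excluded. Returns the records and a
    table of exclusions with reasons.
    """
    if policy not in ("exclude", "pseudocount"):
        raise ValueError(f"unknown zero-handling policy {policy!r}")
    comp = {p.gene_id: p for p in compartment}
    cyt = {p.gene_id: p for p in cytoplasm}
    records: list[LocalizationRecord] = []
    excluded: list[dict] = []
    for gene in sorted(set(comp) | set(cyt)):
        if gene not in comp or gene not in cyt:
            excluded.append({"gene_id": gene, "reason": "missing_sample"})
            continue
        pc, py = comp[gene], cyt[gene]
        if pc.read_count == 0 or py.read_count == 0:
            excluded.append({"gene_id": gene, "reason": "zero_reads"})
            continue
        ec, ey = float(pc.edit_count), float(py.edit_count)
        if policy == "pseudocount":
            ec += pseudocount
            ey += pseudocount
        elif ec == 0 or ey == 0:
            excluded.append({"gene_id": gene, "reason": "zero_edits"})
            continue
        eff_c = ec / pc.read_count
        eff_y = ey / py.read_count
        records.append(
            LocalizationRecord(
                gene_id=gene,
                li=math.log2(eff_c / eff_y),
                efficiency_compartment=eff_c,
                efficiency_cytoplasm=eff_y,
            )
        )
    return records, pd.DataFrame(excluded, columns=["gene_id", "reason"])


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0, SD 1 (n-1 denominator).

    Rows with zero variance cannot be standardized; they are dropped and
    their ids returned. Requires >= 2 columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 timepoints per row")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    z = (values[~constant] - values[~constant].mean(axis=1, keepdims=True)) \
        / sd[~constant, None]
    out = pd.DataFrame(z, index=matrix.index[~constant], columns=matrix.columns)
    return out, list(matrix.index[constant])


def upgma_cluster(
    matrix: pd.DataFrame,
    k: int,
    metric: str = "correlation",
) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of rows under correlation distance
    (d = 1 - Pearson r by default), cut into ``k`` flat clusters."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = matrix.to_numpy(dtype=float)
    if metric == "correlation" and np.any(values.std(axis=1) == 0):
        raise ValueError("constant rows must be removed before clustering")
    dist = pdist(values, metric=metric)
    linkage = hierarchy.linkage(dist, method="average")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.index, name="cluster")
    return Dendrogram(linkage=linkage, leaf_ids=list(matrix.index), labels=labels)


def cluster_trajectories(
    matrix: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-cluster mean and SD trajectory over the matrix columns."""
    if not set(matrix.index) <= set(labels.index):
        raise ValueError("labels must cover every row of the matrix")
    rows = []
    for cluster, members in matrix.groupby(labels.reindex(matrix.index)):
        for col in matrix.columns:
            vals = members[col].to_numpy(dtype=float)
            rows.append(
                {"cluster": cluster, "timepoint": col, "n": len(members),
                 "mean": float(vals.mean()),
                 "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
            )
    return pd.DataFrame(rows)


def records_to_frame(records: list[LocalizationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "li": r.li,
             "efficiency_compartment": r.efficiency_compartment,
             "efficiency_cytoplasm": r.efficiency_cytoplasm}
            for r in records
        ]
    )
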