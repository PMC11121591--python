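"""Grade-stratified radiogenomic correlation maps with hierarchical clustering.

For one grade group (or the pooled cohort) the map holds, per (gene, feature)
cell, the Pearson correlation between the gene's signed copy-number score and
the texture feature over the group's samples, together with the two-sided
p-value and the per-cell n.  Cells where either side is constant are set to
r = 0, p = 1 and flagged rather than left undefined.

Rows and columns are ordered for display by agglomerative clustering
(average linkage, Euclidean distance on the rows/columns of the r matrix);
the r values themselves are never altered by clustering.  No correction is
applied across the genes x features grid by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

__all__ = ["CorrelationMap", "correlate", "cluster_map", "export_heatmap"]


@dataclass
class CorrelationMap:
    grade_group: int | None
    r: pd.DataFrame  # genes x features
    p: pd.DataFrame
    n: pd.DataFrame
    degenerate: pd.DataFrame  # bool: cell had zero variance on either side
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)

    def clustered(self, matrix: str = "r") -> pd.DataFrame:
        m = getattr(self, matrix)
        if not self.row_order or not self.col_order:
            return m
        return m.iloc[self.row_order, self.col_order]


def correlate(
    gene_scores: pd.DataFrame,
    features: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    grade_group: int | None = None,
    min_samples: int = 3,
) -> CorrelationMap:
    """Pearson correlation of every gene score against every feature.

    ``gene_scores`` (samples x genes) and ``features`` (samples x features)
    are joined on their index (patient id).  ``grade_group`` restricts the
    samples via ``metadata`` (columns patient_id, grade_group); ``None``
    pools all joined samples.
    """
    ids = gene_scores.index.intersection(features.index)
    if grade_group is not None:
        if metadata is None:
            raise ValueError("metadata is required when stratifying by grade group")
        meta = metadata.set_index("patient_id") if "patient_id" in metadata.columns else metadata
        in_group = meta.index[meta["grade_group"] == grade_group].astype(str)
        ids = ids.intersection(in_group)
    if len(ids) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples for correlation, got {len(ids)}"
            + (f" in grade group {grade_group}" if grade_group is not None else "")
        )
    g = gene_scores.loc[ids].astype(float)
    f = features.loc[ids].astype(float)
    genes, feats = list(g.columns), list(f.columns)
    r = pd.DataFrame(0.0, index=genes, columns=feats)
    p = pd.DataFrame(1.0, index=genes, columns=feats)
    n = pd.DataFrame(len(ids), index=genes, columns=feats, dtype=int)
    degen = pd.DataFrame(False, index=genes, columns=feats)
    for gene in genes:
        gv = g[gene].to_numpy()
        for feat in feats:
            fv = f[feat].to_numpy()
            if np.ptp(gv) == 0 or np.ptp(fv) == 0:
                degen.loc[gene, feat] = True
                continue
            res = stats.pearsonr(gv, fv)
            r.loc[gene, feat] = float(res.statistic)
            p.loc[gene, feat] = float(res.pvalue)
    return CorrelationMap(grade_group=grade_group, r=r, p=p, n=n, degenerate=degen)


def cluster_map(cmap: CorrelationMap) -> CorrelationMap:
    """Fill in row/column leaf orders by average-linkage clustering of r.

    A single row or column keeps the identity order.  The correlation values
    are unchanged; only the display permutation is recorded.
    """
    r = cmap.r.to_numpy()

    def _order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        d = pdist(mat, metric="euclidean")
        return [int(i) for i in leaves_list(average(d))]

    cmap.row_order = _order(r)
    cmap.col_order = _order(r.T)
    return cmap


def export_heatmap(
    cmap: CorrelationMap,
    out_prefix: Path | str,
    render: bool = True,
    annotate_alpha: float = 0.05,
) -> list[Path]:
    """Write the clustered r and p matrices as CSV and render the heatmap.

    Cells with p <= ``annotate_alpha`` are marked with an asterisk on the
    rendered figure.  Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if not cmap.row_order or not cmap.col_order:
        cluster_map(cmap)
    r = cmap.clustered("r")
    p = cmap.clustered("p")
    paths = [Path(f"{out_prefix}.csv"), Path(f"{out_prefix}_p.csv")]
    r.to_csv(paths[0])
    p.to_csv(paths[1])
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        annot = p.map(lambda v: "*" if v <= annotate_alpha else "")
        fig, ax = plt.subplots(
            figsize=(2.0 + 0.6 * r.shape[1], 2.0 + 0.5 * r.shape[0]),
            layout="constrained",
        )
        sns.heatmap(
            r, vmin=-1, vmax=1, cmap="RdBu_r", annot=annot, fmt="", ax=ax,
            cbar_kws={"label": "Pearson r"},
        )
        title = "pooled" if cmap.grade_group is None else f"grade group {cmap.grade_group}"
        ax.set_title(f"Radiogenomic correlation map ({title})")
        png = Path(f"{out_prefix}.png")
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths.append(png)
    return paths
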