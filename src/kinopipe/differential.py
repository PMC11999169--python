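"""Per-chip log2 fold changes, hit selection and direction-of-change scores.

Fold changes are computed within each technical-replicate chip (the chip is
the blocking unit) as log2 of the treatment-to-control ratio of group mean
signals per peptide, then averaged across chips. Two independent hit flags
are carried: |mean log2FC| > 0.2 (the plotting threshold) and a >= 15%
change on the linear fold-change scale, |2^log2FC - 1| >= 0.15 (the input
criterion for upstream-kinase analysis). The ternary kinase score maps
each substrate's log2FC to {-1, 0, +1} at the +/-0.2 boundaries (strict
inequalities) and averages over a kinase's substrates; the sign of the
mean is the direction of change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .krsa import KinaseSubstrateMap
from .qc import PeptideSignalMatrix

LOGFC_FLAG_THRESHOLD = 0.2
HIT_FRACTION = 0.15


def log2_fold_change(matrix: PeptideSignalMatrix, group_a: str, group_b: str,
                     flag_threshold: float = LOGFC_FLAG_THRESHOLD,
                     hit_fraction: float = HIT_FRACTION) -> pd.DataFrame:
    """Per-chip and replicate-averaged log2 fold changes (b over a).

    group_b is the treatment by convention. Chips missing either group are
    skipped with a warning; peptides with a non-positive group-mean signal
    on any usable chip are excluded with a warning.
    """
    values = matrix.values
    sample_group = matrix.sample_groups
    per_chip: dict[str, pd.Series] = {}
    for chip in matrix.chips:
        sub = values[chip]
        cols_a = [s for s in sub.columns if sample_group.get(s) == group_a]
        cols_b = [s for s in sub.columns if sample_group.get(s) == group_b]
        if not cols_a or not cols_b:
            warnings.warn(f"chip {chip}: group missing, skipped")
            continue
        mean_a = sub[cols_a].mean(axis=1)
        mean_b = sub[cols_b].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_chip[chip] = np.log2(mean_b / mean_a)
    if not per_chip:
        raise ValueError("no chip carries both groups")

    fc = pd.DataFrame(per_chip)
    bad = ~np.isfinite(fc).all(axis=1)
    if bad.any():
        warnings.warn(f"peptides with non-positive signals excluded: "
                      f"{sorted(fc.index[bad])}")
        fc = fc[~bad]
    fc.columns = [f"log2fc_{c}" for c in fc.columns]
    fc["mean_log2fc"] = fc.mean(axis=1)
    fc["flagged"] = fc["mean_log2fc"].abs() > flag_threshold
    # tolerance keeps an exact 15% ratio a hit despite log/exp round-trip
    fc["hit15"] = np.abs(2.0 ** fc["mean_log2fc"] - 1.0) >= hit_fraction - 1e-12
    fc.index.name = "peptide_id"
    return fc


def ternary_score(fc: pd.DataFrame, kmap: KinaseSubstrateMap) -> pd.DataFrame:
    """Direction-of-change score per kinase (family).

    Substrate log2FC > 0.2 scores +1, < -0.2 scores -1, otherwise 0
    (boundaries inclusive of 0). The substrate scores are averaged; a
    positive mean is direction "up", negative "down", zero "no_change".
    Kinases with no mapped substrate surviving QC are reported with
    direction "no_data".
    """
    log2fc = fc["mean_log2fc"]
    rows = []
    for kin in kmap.names:
        subs = sorted(set(kmap.sets[kin]) & set(log2fc.index))
        if not subs:
            rows.append((kin, 0, np.nan, "no_data"))
            continue
        vals = np.select([log2fc[subs] > 0.2, log2fc[subs] < -0.2], [1, -1], 0)
        mean = float(vals.mean())
        direction = "up" if mean > 0 else "down" if mean < 0 else "no_change"
        rows.append((kin, len(subs), mean, direction))
    return pd.DataFrame(rows, columns=["kinase", "n_substrates", "mean_value",
                                       "direction"]).set_index("kinase")


@dataclass
class HeatmapMatrix:
    """Row-normalized matrix plus hierarchical row/column orderings."""

    values: pd.DataFrame
    row_order: list[str]
    col_order: list
    row_normalized: bool
    metric: str = "euclidean"
    linkage: str = "average"

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.row_order, self.col_order]


def heatmap_matrix(matrix: PeptideSignalMatrix | pd.DataFrame,
                   row_normalize: bool = True) -> HeatmapMatrix:
    """Row-z-scored matrix with agglomerative row/column orderings.

    Normalization is (x - row mean) / row SD; constant rows normalize to
    zeros with a warning. Ordering comes from average-linkage hierarchical
    clustering on Euclidean distances of the (normalized) values; no image
    is produced, only the plot-ready matrix and dendrogram leaf orders.
    """
    df = matrix.values if isinstance(matrix, PeptideSignalMatrix) else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("heatmap needs at least 2 rows and 2 columns")
    vals = df.to_numpy(float)
    if row_normalize:
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(f"zero-variance rows normalized to zeros: "
                          f"{sorted(df.index[flat])}")
        sd[sd == 0] = 1.0
        vals = (vals - mean) / sd
    norm = pd.DataFrame(vals, index=df.index, columns=df.columns)

    def leaf_order(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return [0]
        link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        return list(hierarchy.leaves_list(link))

    rows = [norm.index[i] for i in leaf_order(vals)]
    cols = [norm.columns[i] for i in leaf_order(vals.T)]
    return HeatmapMatrix(norm, rows, cols, row_normalize)
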