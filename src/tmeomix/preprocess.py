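"""Normalization and exploratory preprocessing of expression matrices.

The study design has six liver cell × condition groups — sinusoidal
endothelial (E), Ito (I) and Kupffer (K) cells, each control (C) or
tumor-microenvironment (T) — plus optional primary-tumor (TP) and liver
metastasis (TM) sample groups.  All layers are quantile-normalized on the
log2 scale; transcript probes collapse to genes by maximal variance; sample
structure is explored with covariance PCA and average-linkage clustering on
one-minus-Pearson-correlation distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io_formats import ExpressionTable, FormatError, UsageError

CELL_TYPES = ("E", "I", "K")
CELL_GROUPS = ("EC", "ET", "IC", "IT", "KC", "KT")
TUMOR_GROUPS = ("TP", "TM")
ALL_GROUPS = CELL_GROUPS + TUMOR_GROUPS


@dataclass
class SampleDesign:
    """Maps each sample id to its (cell type, condition) and group label.

    Cell types are E/I/K for the liver cells or ``tumor`` for the TP/TM
    groups; the group label is the concatenation (EC … KT) or the tumor
    group name itself.
    """

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, (cell, cond) in self.assignments.items():
            if cell in CELL_TYPES and cond in ("C", "T"):
                continue
            if cell == "tumor" and cond in TUMOR_GROUPS:
                continue
            raise UsageError(
                f"sample {sample!r}: invalid (cell, condition) = ({cell!r}, {cond!r})"
            )

    def add(self, sample: str, cell: str, condition: str) -> None:
        self.assignments[sample] = (cell, condition)
        self.__post_init__()

    def group(self, sample: str) -> str:
        cell, cond = self.assignments[sample]
        return cond if cell == "tumor" else cell + cond

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.assignments if self.group(s) == group]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "cell_type": c, "condition": k, "group": self.group(s)}
            for s, (c, k) in self.assignments.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        return cls(
            {
                str(r["sample"]): (str(r["cell_type"]), str(r["condition"]))
                for _, r in frame.iterrows()
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def validate_table(self, table: ExpressionTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.assignments]
        if missing:
            raise UsageError(f"samples without design entries: {missing}")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Quantile-normalize samples to a common (mean-of-order-statistics)
    reference distribution.

    Complete columns end up with identical sorted value multisets.  Ties
    within a column receive the mean of the reference values over their rank
    span.  Missing values (protein layer) stay missing: a column's observed
    values are ranked among themselves and mapped onto the reference
    quantile function by linear interpolation, so partially observed columns
    are normalized over observed values only.
    """
    if table.data.size == 0:
        raise UsageError("cannot normalize an empty table")
    X = table.values.copy()
    n_rows, n_cols = X.shape
    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])

    # reference = mean across samples of each column's quantile function
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        col = X[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            raise UsageError(f"sample {table.sample_ids[j]!r} has no observed values")
        if obs.size == 1:
            ref += obs[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs)
    ref /= n_cols

    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        col = X[:, j]
        mask = ~np.isnan(col)
        obs = col[mask]
        m = obs.size
        order = np.argsort(obs, kind="mergesort")
        pos = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        mapped_sorted = np.interp(pos, grid, ref) if n_rows > 1 else np.full(m, ref[0])
        mapped = np.empty(m)
        # ties: average the reference values across the tied rank span
        i = 0
        sorted_obs = obs[order]
        while i < m:
            k = i
            while k + 1 < m and sorted_obs[k + 1] == sorted_obs[i]:
                k += 1
            mapped[order[i : k + 1]] = mapped_sorted[i : k + 1].mean()
            i = k + 1
        out[mask, j] = mapped
    frame = pd.DataFrame(out, index=table.molecule_ids, columns=table.sample_ids)
    return ExpressionTable(frame, table.layer)


# ---------------------------------------------------------------------------
# probe collapsing


def collapse_probes(table: ExpressionTable, probe_map: dict[str, str]) -> ExpressionTable:
    """Collapse probes to genes, keeping the probe with the highest
    expression variance across all samples (ties: lexicographically
    smallest probe id)."""
    unmapped = [p for p in table.molecule_ids if p not in probe_map]
    if unmapped:
        raise UsageError(f"probes without gene mapping: {unmapped}")
    variances = table.data.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in sorted(table.molecule_ids):  # lexicographic order fixes ties
        gene = probe_map[probe]
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    frame = table.data.loc[[best[g] for g in genes]].copy()
    frame.index = genes
    return ExpressionTable(frame, table.layer)


# ---------------------------------------------------------------------------
# PCA


def pca_samples(table: ExpressionTable) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariance PCA of samples on the row-centered matrix.

    Returns sample coordinates (samples × components) and the fractions of
    variance explained (summing to 1).  Rows are centered but not scaled to
    unit variance.
    """
    if len(table.sample_ids) < 2:
        raise UsageError("PCA needs at least 2 samples")
    if np.isnan(table.values).any():
        raise UsageError("PCA requires complete rows; filter missing values first")
    X = table.values - table.values.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = (s[:, None] * Vt).T  # samples × components
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.full_like(var, 1.0 / var.size)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=table.sample_ids, columns=cols), explained


# ---------------------------------------------------------------------------
# hierarchical clustering


def correlation_distance_matrix(table: ExpressionTable, axis: str) -> tuple[list[str], np.ndarray]:
    """Pairwise 1 − Pearson r distances between samples or molecules."""
    if axis == "samples":
        M = table.values.T
        labels = table.sample_ids
    elif axis == "molecules":
        M = table.values
        labels = table.molecule_ids
    else:
        raise UsageError(f"axis must be 'samples' or 'molecules', got {axis!r}")
    sd = M.std(axis=1, ddof=0)
    zero = [labels[i] for i in np.flatnonzero(sd == 0)]
    if zero:
        raise UsageError(f"zero-variance vectors cannot be correlated: {zero}")
    corr = np.corrcoef(M)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return labels, dist


def hclust_correlation(table: ExpressionTable, axis: str = "samples") -> tuple[list[str], np.ndarray]:
    """UPGMA (unweighted average linkage) on 1 − Pearson r distances.

    Returns the leaf labels and a scipy linkage matrix whose merge heights
    are non-decreasing.
    """
    labels, dist = correlation_distance_matrix(table, axis)
    condensed = dist[np.triu_indices(len(labels), k=1)]
    linkage = sch.linkage(condensed, method="average")
    return labels, linkage


def linkage_to_newick(labels: list[str], linkage: np.ndarray) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    root = (
        f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
        if not tree.is_leaf()
        else f"{labels[tree.id]};"
    )
    return root


# ---------------------------------------------------------------------------
# RT-qPCR relative quantification


def relative_expression_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference gene) in each condition;
    ΔΔCt = ΔCt(case) − ΔCt(control); returns 2**(−ΔΔCt).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise UsageError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def group_means(table: ExpressionTable, design: SampleDesign, groups=None) -> pd.DataFrame:
    """Per-group mean expression (NaN-aware), molecules × groups."""
    design.validate_table(table)
    groups = list(groups) if groups is not None else [
        g
        for g in ALL_GROUPS
        if any(s in table.data.columns for s in design.samples_in_group(g))
    ]
    out = {}
    for g in groups:
        cols = [s for s in design.samples_in_group(g) if s in table.data.columns]
        if not cols:
            raise UsageError(f"group {g!r} has no samples in the table")
        out[g] = table.data[cols].mean(axis=1)
    return pd.DataFrame(out)
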