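"""Differential expression with a joint effect-size + FDR threshold.

A molecule is called differentially expressed between two groups when the
absolute difference of group means on the log2 scale reaches θ (defaults:
4 for genes and miRNAs, 2 for proteins) *and* its Benjamini–Hochberg
adjusted two-sided Student's-t p-value is at most α (default 0.001).  The
θ thresholds are differences of log2 means, i.e. 16-fold / 4-fold linear
changes; a linear-fold interpretation is selectable for sensitivity
analyses.  Molecules with fewer than two observed values on either side
(structural proteomics missingness) are reported as untested and excluded
from the BH family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionTable, GeneSetCollection, UsageError
from .preprocess import SampleDesign

DEFAULT_THETA = {"mrna": 4.0, "mirna": 4.0, "protein": 2.0}
DEFAULT_ALPHA = 1e-3


@dataclass
class DEThresholds:
    """Joint selection threshold: |Δ log2 mean| ≥ theta and BH q ≤ alpha."""

    theta: float = 4.0
    alpha: float = DEFAULT_ALPHA
    #: interpret theta as log2-mean difference ("log2", default) or as a
    #: linear fold change ("linear", i.e. |Δ log2| ≥ log2(theta))
    theta_scale: str = "log2"

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise UsageError("theta must be non-negative")
        if not (0 < self.alpha <= 1):
            raise UsageError("alpha must be in (0, 1]")
        if self.theta_scale not in ("log2", "linear"):
            raise UsageError(f"unknown theta_scale {self.theta_scale!r}")

    @property
    def log2_theta(self) -> float:
        return self.theta if self.theta_scale == "log2" else float(np.log2(self.theta))

    @classmethod
    def for_layer(cls, layer: str, alpha: float = DEFAULT_ALPHA) -> "DEThresholds":
        return cls(theta=DEFAULT_THETA[layer], alpha=alpha)


@dataclass
class DEResult:
    """Per-molecule differential statistics for one contrast of one layer.

    ``table`` columns: mean_diff, t, p, q, direction (up/down), passes,
    tested.  mean_diff is mean(test) − mean(reference).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]  # (reference group, test group)
    layer: str
    thresholds: DEThresholds = field(default_factory=DEThresholds)

    @property
    def label(self) -> str:
        return f"{self.contrast[1]} vs {self.contrast[0]}"

    def passing(self, direction: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["passes"]]
        if direction is not None:
            if direction not in ("up", "down"):
                raise UsageError(f"direction must be 'up' or 'down', got {direction!r}")
            sub = sub[sub["direction"] == direction]
        return sub


def student_t_de(
    table: ExpressionTable,
    design: SampleDesign,
    contrast: tuple[str, str],
    thresholds: DEThresholds | None = None,
) -> DEResult:
    """Equal-variance two-sample t-test per molecule for (reference, test).

    mean_diff = mean(test) − mean(reference); two-sided p; BH q across all
    tested molecules of the contrast; pass flag per the joint threshold.
    """
    ref_group, test_group = contrast
    thresholds = thresholds or DEThresholds.for_layer(table.layer)
    design.validate_table(table)
    ref_cols = [s for s in design.samples_in_group(ref_group) if s in table.data.columns]
    test_cols = [s for s in design.samples_in_group(test_group) if s in table.data.columns]
    if not ref_cols or not test_cols:
        raise UsageError(
            f"contrast groups {contrast} not found in the table "
            f"(ref n={len(ref_cols)}, test n={len(test_cols)})"
        )
    A = table.data[ref_cols].to_numpy()  # reference
    B = table.data[test_cols].to_numpy()  # test

    nA = np.sum(~np.isnan(A), axis=1)
    nB = np.sum(~np.isnan(B), axis=1)
    tested = (nA >= 2) & (nB >= 2)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mA = np.nanmean(A, axis=1)
        mB = np.nanmean(B, axis=1)
        vA = np.nanvar(A, axis=1, ddof=1)
        vB = np.nanvar(B, axis=1, ddof=1)
    mean_diff = mB - mA
    df = nA + nB - 2
    pooled = np.where(df > 0, ((nA - 1) * vA + (nB - 1) * vB) / np.maximum(df, 1), np.nan)
    se = np.sqrt(pooled * (1.0 / np.maximum(nA, 1) + 1.0 / np.maximum(nB, 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_diff / se
    # identical groups (zero pooled variance, zero difference): t = 0, p = 1
    t = np.where((se == 0) & (mean_diff == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * st.t.sf(np.abs(t), np.maximum(df, 1)))

    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    passes = (
        tested
        & (np.abs(mean_diff) >= thresholds.log2_theta)
        & (q <= thresholds.alpha)
    )
    out = pd.DataFrame(
        {
            "mean_diff": np.where(tested, mean_diff, np.nan),
            "t": np.where(tested, t, np.nan),
            "p": np.where(tested, p, np.nan),
            "q": q,
            "direction": np.where(mean_diff >= 0, "up", "down"),
            "passes": passes,
            "tested": tested,
        },
        index=table.molecule_ids,
    )
    out.loc[~tested, "direction"] = ""
    return DEResult(out, contrast, table.layer, thresholds)


def top_ranked(result: DEResult, direction: str, n: int = 20) -> list[str]:
    """Top-n passing molecules of one direction, in decreasing significance.

    Ascending p, ties broken by |mean_diff| descending, then molecule id.
    Returns fewer than n when fewer pass.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    sub = result.passing(direction).copy()
    sub["abs_diff"] = sub["mean_diff"].abs()
    sub["_id"] = sub.index
    sub = sub.sort_values(["p", "abs_diff", "_id"], ascending=[True, False, True])
    return list(sub.index[:n])


def shared_de(
    results: dict[str, DEResult], direction: str
) -> pd.DataFrame:
    """Molecules passing in every cell type's contrast, with a shared score.

    ``results`` maps cell type → DEResult for the same layer.  The score is
    −log10 of the mean raw p across the contrasts (as annotated on the
    shared-molecule heatmaps).  Returns a frame indexed by molecule with a
    ``score`` column, sorted by score descending.
    """
    layers = {r.layer for r in results.values()}
    if len(layers) != 1:
        raise UsageError(f"results mix layers: {sorted(layers)}")
    sets = [set(r.passing(direction).index) for r in results.values()]
    common = sorted(set.intersection(*sets)) if sets else []
    rows = {}
    tiny = np.finfo(float).tiny  # p can underflow to 0 at extreme t
    for mol in common:
        ps = [r.table.loc[mol, "p"] for r in results.values()]
        rows[mol] = -np.log10(max(np.mean(ps), tiny))
    frame = pd.DataFrame({"score": pd.Series(rows, dtype=float)})
    return frame.sort_values("score", ascending=False)


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation per gene set (BH across sets)."""

    table: pd.DataFrame  # index: set name; columns: overlap, set_size, query_size, universe_size, p, q


def hypergeom_enrich(
    query: set[str], collection: GeneSetCollection, universe: set[str]
) -> EnrichmentResult:
    """One-sided over-representation test of a query against each gene set.

    p = P(X ≥ overlap) with X ~ Hypergeometric(|universe|, |set ∩ universe|,
    |query|); set members outside the universe are ignored; BH across sets.
    """
    offenders = query - universe
    if offenders:
        raise UsageError(f"query genes outside the universe: {sorted(offenders)}")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        K = len(inset)
        k = len(inset & query)
        p = float(st.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((name, k, K, N, M, p))
    frame = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"]
    ).set_index("set")
    if len(frame):
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["q"] = []
    return EnrichmentResult(frame)
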