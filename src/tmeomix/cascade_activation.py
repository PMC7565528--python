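"""Monotone cell-activation-sequence inference and gene-set activation
profiling.

A transcript follows an activation sequence (a, b, c) of the three liver
cell types when its group mean rises by at least a step threshold (default
2 log2 units, i.e. 4-fold) from a to b *and* from b to c within one
condition; "down" transcripts fall by at least the step at both
transitions, which makes the down list of (a, b, c) exactly the up list of
(c, b, a).  Activation profiling categorizes each gene of a named set as
low/mid/high per group against full-matrix quantile cutpoints and flags
"last activated" genes — low in every control group but high in every TME
group while most of the set is already high throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, UsageError
from .preprocess import CELL_TYPES, SampleDesign, group_means

DEFAULT_SEQUENCES = (("E", "I", "K"), ("E", "K", "I"), ("I", "E", "K"))


@dataclass
class CascadeParams:
    step: float = 2.0  # minimal per-step log2 group-mean difference
    sequences: tuple[tuple[str, str, str], ...] = DEFAULT_SEQUENCES
    condition: str = "T"

    def __post_init__(self) -> None:
        if self.step < 0:
            raise UsageError("step must be non-negative")
        for seq in self.sequences:
            if sorted(seq) != sorted(CELL_TYPES):
                raise UsageError(f"sequence must permute {CELL_TYPES}: {seq}")
        if self.condition not in ("T", "C"):
            raise UsageError("condition must be 'T' or 'C'")


@dataclass
class CascadeResult:
    """Per sequence × direction, the monotone transcript lists."""

    lists: dict[tuple[tuple[str, str, str], str], list[str]]
    params: CascadeParams
    group_mean_table: pd.DataFrame = field(repr=False, default=None)

    def transcripts(self, sequence: tuple[str, str, str], direction: str) -> list[str]:
        return self.lists.get((tuple(sequence), direction), [])

    def counts(self) -> pd.DataFrame:
        rows = [
            {"sequence": "->".join(seq), "direction": d, "n": len(mols)}
            for (seq, d), mols in self.lists.items()
        ]
        return pd.DataFrame(rows)


def find_cascades(
    table: ExpressionTable, design: SampleDesign, params: CascadeParams | None = None
) -> CascadeResult:
    """Transcripts monotonically up-/down-regulated along each sequence.

    Evaluated per transcript/probe without gene collapsing, so multiple
    probes of one gene are counted separately.  Boundary inclusive: a step
    difference equal to the threshold qualifies.
    """
    params = params or CascadeParams()
    groups = [cell + params.condition for cell in CELL_TYPES]
    for g in groups:
        if not design.samples_in_group(g):
            raise UsageError(f"group {g!r} has no samples in the design")
    gm = group_means(table, design, groups)
    lists: dict[tuple[tuple[str, str, str], str], list[str]] = {}
    for seq in params.sequences:
        a, b, c = (gm[cell + params.condition] for cell in seq)
        step1, step2 = b - a, c - b
        up = (step1 >= params.step) & (step2 >= params.step)
        down = (step1 <= -params.step) & (step2 <= -params.step)
        lists[(tuple(seq), "up")] = sorted(gm.index[up])
        lists[(tuple(seq), "down")] = sorted(gm.index[down])
    return CascadeResult(lists, params, gm)


def cross_condition_check(
    result: CascadeResult, table: ExpressionTable, design: SampleDesign
) -> pd.Series:
    """Per cascade transcript: is its mean over all TME samples strictly
    above its mean over all control samples?"""
    t_samples = [
        s
        for s in table.sample_ids
        if design.assignments.get(s, ("", ""))[0] in CELL_TYPES
        and design.assignments[s][1] == "T"
    ]
    c_samples = [
        s
        for s in table.sample_ids
        if design.assignments.get(s, ("", ""))[0] in CELL_TYPES
        and design.assignments[s][1] == "C"
    ]
    members = sorted({m for mols in result.lists.values() for m in mols})
    t_mean = table.data.loc[members, t_samples].mean(axis=1)
    c_mean = table.data.loc[members, c_samples].mean(axis=1)
    return t_mean > c_mean


@dataclass
class ActivationProfile:
    """Low/mid/high category per (gene, group) for one gene set."""

    set_name: str
    categories: pd.DataFrame  # genes × groups of {"low", "mid", "high"}
    cutpoints: tuple[float, float]
    absent: list[str]


def categorize_expression(
    table: ExpressionTable,
    design: SampleDesign,
    gene_set: set[str],
    set_name: str = "set",
    cutpoints: tuple[float, float] | None = None,
    quantiles: tuple[float, float] = (1 / 3, 2 / 3),
) -> ActivationProfile:
    """Categorize group-mean expression of a gene set as low/mid/high.

    Cutpoints default to the given quantiles of the full-matrix value
    distribution; explicit log2 cutpoints override the quantiles.
    """
    values = table.values[~np.isnan(table.values)]
    if cutpoints is None:
        cutpoints = (
            float(np.quantile(values, quantiles[0])),
            float(np.quantile(values, quantiles[1])),
        )
    lo, hi = cutpoints
    if lo > hi:
        raise UsageError(f"cutpoints out of order: {cutpoints}")
    present = sorted(g for g in gene_set if g in table.data.index)
    absent = sorted(g for g in gene_set if g not in table.data.index)
    gm = group_means(table, design).loc[present]
    cats = gm.apply(
        lambda col: pd.cut(
            col, bins=[-np.inf, lo, hi, np.inf], labels=["low", "mid", "high"], right=False
        ).astype(str)
    )
    # pd.cut(right=False): low < lo <= mid < hi <= high
    return ActivationProfile(set_name, cats, cutpoints, absent)


def last_activated(profile: ActivationProfile) -> list[str]:
    """Genes low in every control group and high in every TME group.

    The list is only reported when at least half of the set's (present)
    genes are high in both conditions — the "already active" background
    that makes a late switch interpretable.
    """
    cats = profile.categories
    c_groups = [g for g in cats.columns if g.endswith("C") and len(g) == 2]
    t_groups = [g for g in cats.columns if g.endswith("T") and len(g) == 2]
    if not c_groups or not t_groups:
        raise UsageError("profile must cover both control and TME groups")
    high_everywhere = (
        (cats[c_groups] == "high").all(axis=1) & (cats[t_groups] == "high").all(axis=1)
    )
    switchers = (cats[c_groups] == "low").all(axis=1) & (cats[t_groups] == "high").all(axis=1)
    if len(cats) == 0 or high_everywhere.sum() < len(cats) / 2:
        return []
    return sorted(cats.index[switchers])
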