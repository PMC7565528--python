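"""Association of BRCA1 co-expression status with metastasis timing.

Patients' liver metastases are grouped by timing (synchronous: detected
within six months of the primary diagnosis; metachronous: later) and by
BRCA1 co-expression status in the three TME cell types (positive:
co-expressed in endothelial, Ito and Kupffer cells; negative: absent from
all three).  The module consumes the resulting count table and tests
independence with Pearson's χ²; the per-patient immunostaining scores that
produce the counts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import UsageError


@dataclass
class ContingencyTable:
    """Timing groups × co-expression status counts."""

    counts: pd.DataFrame  # rows: timing groups; columns: status

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise UsageError("contingency table must be at least 2x2")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise UsageError("counts must be non-negative integers")

    @classmethod
    def from_array(cls, rows, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(rows)
        frame = pd.DataFrame(
            arr,
            index=row_labels or [f"group{i}" for i in range(arr.shape[0])],
            columns=col_labels or [f"status{j}" for j in range(arr.shape[1])],
        )
        return cls(frame)

    @classmethod
    def read_tsv(cls, path) -> "ContingencyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def chisq_association(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson χ² test of independence: (statistic, df, upper-tail p).

    Continuity (Yates) correction is off by default and only applies to
    2×2 tables.  Zero row or column margins leave expected counts
    undefined and raise an error.
    """
    arr = table.counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UsageError("a zero margin makes expected counts undefined")
    stat, p, df, _ = st.chi2_contingency(arr, correction=continuity_correction)
    return float(stat), int(df), float(p)
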