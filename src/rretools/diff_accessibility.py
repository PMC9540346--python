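"""Per-peak differential accessibility testing.

Two-sided Wilcoxon rank-sum (normal approximation with midranks,
tie-corrected variance and 0.5 continuity correction) per peak, plus a
pseudocounted log2 fold change on group means and a detection-fraction
filter. A peak passes when p < 0.1, avg_log2FC >= 0.25 and
max(pct1, pct2) >= 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

P_THRESHOLD = 0.1
LOGFC_THRESHOLD = 0.25
MIN_PCT = 0.025


@dataclass(frozen=True)
class DiffTestResult:
    peak_id: str
    p_value: float
    avg_log2fc: float
    pct1: float
    pct2: float

    @property
    def passes(self) -> bool:
        return (
            self.p_value < P_THRESHOLD
            and self.avg_log2fc >= LOGFC_THRESHOLD
            and max(self.pct1, self.pct2) >= MIN_PCT
        )


@dataclass
class CountMatrix:
    """Dense cells x peaks count matrix with per-cell group labels."""

    counts: np.ndarray
    cell_ids: List[str]
    peak_ids: List[str]
    groups: List[str]  # one label per cell; exactly two distinct labels

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x peaks)")
        n_cells, n_peaks = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(self.peak_ids) != n_peaks:
            raise ValueError(f"{len(self.peak_ids)} peak ids for {n_peaks} columns")
        if len(self.groups) != n_cells:
            raise ValueError("every cell needs a group label")
        if np.any(self.counts < 0):
            bad = self.peak_ids[int(np.argwhere(self.counts < 0)[0][1])]
            raise ValueError(f"negative count in peak {bad}")

    def group_masks(self, group1: str, group2: str) -> Tuple[np.ndarray, np.ndarray]:
        g = np.asarray(self.groups)
        m1, m2 = g == group1, g == group2
        if m1.sum() == 0 or m2.sum() == 0:
            raise ValueError(f"empty group among ({group1!r}, {group2!r})")
        return m1, m2


def wilcoxon_rank_sum(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns (U statistic for group 1, two-sided p). Uses midranks for ties,
    the tie-corrected normal approximation and a 0.5 continuity correction.
    When every value is identical across both groups the p-value is 1.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u1), float(min(max(p, 0.0), 1.0))


def average_log_fc(values_group1, values_group2) -> float:
    """log2((mean1 + 1) / (mean2 + 1)) on raw per-cell counts."""
    m1 = float(np.mean(values_group1))
    m2 = float(np.mean(values_group2))
    return float(np.log2((m1 + 1.0) / (m2 + 1.0)))


def call_differential_peaks(
    matrix: CountMatrix, group1: str, group2: str
) -> List[DiffTestResult]:
    """Test every peak for group1-vs-group2 differential accessibility.

    Results are sorted by ascending p-value (ties broken by peak id for
    determinism under input reordering).
    """
    m1, m2 = matrix.group_masks(group1, group2)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need >=2 cells per group")
    results: List[DiffTestResult] = []
    c1 = matrix.counts[m1]
    c2 = matrix.counts[m2]
    for j, peak_id in enumerate(matrix.peak_ids):
        v1, v2 = c1[:, j], c2[:, j]
        _, p = wilcoxon_rank_sum(v1, v2)
        results.append(
            DiffTestResult(
                peak_id=peak_id,
                p_value=p,
                avg_log2fc=average_log_fc(v1, v2),
                pct1=float((v1 > 0).mean()),
                pct2=float((v2 > 0).mean()),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.peak_id))
    return results


def results_to_frame(results: Sequence[DiffTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in results],
            "p_value": [r.p_value for r in results],
            "avg_log2FC": [r.avg_log2fc for r in results],
            "pct1": [r.pct1 for r in results],
            "pct2": [r.pct2 for r in results],
            "passes": [r.passes for r in results],
        }
    )


def passing_ids(results: Sequence[DiffTestResult]) -> List[str]:
    return [r.peak_id for r in results if r.passes]


def read_groups_tsv(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
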