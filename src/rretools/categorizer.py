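"""PWM scanning and Sox/Six four-category enhancer partitioning.

Scanning is log-odds against a uniform background (log2 scale, pseudocount
1e-3 added to motif probabilities and renormalized), both strands, with a
hit threshold expressed as a fraction of the PWM's maximum achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .motiflib import BASES, revcomp_pwm
from .peak_gene import PeakGeneLink

CATEGORIES = ("sox_only", "six_only", "both", "neither")

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PWMHit:
    sequence_id: str
    motif_id: str
    start: int  # leftmost base of the hit on the forward strand
    strand: str
    score: float  # log-odds, bits


def _log_odds(pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    p = np.asarray(pwm, dtype=float) + 1e-3
    p /= p.sum(axis=0, keepdims=True)
    return np.log2(p / background)


def _scan_one_strand(seq_idx, valid, lom: np.ndarray) -> np.ndarray:
    """Per-position log-odds scores; N positions contribute 0."""
    w = lom.shape[1]
    n_pos = len(seq_idx) - w + 1
    scores = np.zeros(n_pos)
    for j in range(w):
        col = lom[:, j]
        idx = seq_idx[j : j + n_pos]
        ok = valid[j : j + n_pos]
        scores += np.where(ok, col[np.clip(idx, 0, 3)], 0.0)
    return scores


def scan_pwm(
    sequence: str,
    pwm: np.ndarray,
    motif_id: str = "motif",
    sequence_id: str = "seq",
    threshold_fraction: float = 0.8,
    background: float = 0.25,
) -> List[PWMHit]:
    """Scan both strands; hit iff score >= threshold_fraction * max achievable."""
    pwm = np.asarray(pwm, dtype=float)
    w = pwm.shape[1]
    seq = sequence.upper()
    if w > len(seq):
        return []
    lom = _log_odds(pwm, background)
    max_score = float(lom.max(axis=0).sum())
    threshold = threshold_fraction * max_score - 1e-9  # tolerate fp rounding

    seq_idx = np.array([_BASE_IDX.get(b, -1) for b in seq], dtype=np.int64)
    valid = seq_idx >= 0

    hits: List[PWMHit] = []
    fwd = _scan_one_strand(seq_idx, valid, lom)
    rev = _scan_one_strand(seq_idx, valid, _log_odds(revcomp_pwm(pwm), background))
    for pos in range(len(fwd)):
        if fwd[pos] >= threshold:
            hits.append(PWMHit(sequence_id, motif_id, pos, "+", float(fwd[pos])))
        if rev[pos] >= threshold:
            hits.append(PWMHit(sequence_id, motif_id, pos, "-", float(rev[pos])))
    return hits


def categorize_peaks(
    sequences: Mapping[str, str],
    sox_pwms: Mapping[str, np.ndarray],
    six_pwms: Mapping[str, np.ndarray],
    threshold_fraction: float = 0.8,
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Assign each peak sequence to one of sox_only/six_only/both/neither.

    Returns (peak_id -> category, category -> count); counts always
    partition the input set.
    """
    if not sox_pwms and not six_pwms:
        raise ValueError("at least one Sox or Six PWM is required")

    def any_hit(seq_id: str, seq: str, pwms: Mapping[str, np.ndarray]) -> bool:
        return any(
            scan_pwm(seq, pwm, motif_id=mid, sequence_id=seq_id,
                     threshold_fraction=threshold_fraction)
            for mid, pwm in pwms.items()
        )

    categories: Dict[str, str] = {}
    counts = dict.fromkeys(CATEGORIES, 0)
    for seq_id, seq in sequences.items():
        sox = any_hit(seq_id, seq, sox_pwms)
        six = any_hit(seq_id, seq, six_pwms)
        cat = "both" if (sox and six) else "sox_only" if sox else "six_only" if six else "neither"
        categories[seq_id] = cat
        counts[cat] += 1
    return categories, counts


def category_gene_counts(
    categories: Mapping[str, str],
    links: Sequence[PeakGeneLink],
    de_genes: Iterable[str],
) -> pd.DataFrame:
    """Per-category count of DE genes linked to >=1 peak of that category.

    A DE gene linked to peaks of several categories counts once in each.
    """
    de: Set[str] = set(de_genes)
    genes_per_cat: Dict[str, Set[str]] = {c: set() for c in CATEGORIES}
    linked_de: Set[str] = set()
    for link in links:
        if link.gene_id not in de or link.peak_id not in categories:
            continue
        genes_per_cat[categories[link.peak_id]].add(link.gene_id)
        linked_de.add(link.gene_id)
    total = len(linked_de)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "n_de_genes": [len(genes_per_cat[c]) for c in CATEGORIES],
            "fraction_of_linked_de": [
                len(genes_per_cat[c]) / total if total else 0.0 for c in CATEGORIES
            ],
        }
    )
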