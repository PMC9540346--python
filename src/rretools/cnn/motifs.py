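"""De novo motif extraction, known-motif matching, and co-occurrence testing.

De novo motifs are PWMs built from the 9-mers that strongly activate one
first-layer filter (activation >= activation_fraction x the filter's maximum
over the positive set). Co-occurrence of two motifs is read off the third
conv layer's spatial geometry: each conv3 unit sees a 90 bp receptive field
advancing in 12 bp jumps, and a pair co-occurs in a sequence when one such
window contains an activating hit of both filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ..motiflib import BASES, revcomp_pwm
from .model import CROP, ELEMENT_LENGTH, INPUT_LENGTH, Network, encode_batch

CONV1_KERNEL = 9
CONV1_STRIDE = 3
CONV3_LENGTH = 18
CONV3_RF = 90
CONV3_JUMP = 12
_CONV1_PER_WINDOW = 28  # conv1 positions covered by one conv3 unit

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class DeNovoMotif:
    filter_index: int
    pwm: np.ndarray  # 4 x 9, column-stochastic
    n_sites: int
    information_content: float


@dataclass(frozen=True)
class MotifMatch:
    filter_index: int
    known_id: str
    offset: int
    strand: str
    score: float
    p_value: float
    is_best: bool = False


@dataclass(frozen=True)
class CooccurrencePair:
    motif_a: int
    motif_b: int
    count_pos: int
    n_pos: int
    count_bg: int
    n_bg: int
    p_value: float

    @property
    def significant(self) -> bool:
        return (
            self.p_value < 0.001
            and self.count_pos / self.n_pos > self.count_bg / self.n_bg
        )


def conv3_receptive_field(unit_index: int) -> Tuple[int, int]:
    """Input-coordinate interval [start, start+90) seen by one conv3 unit."""
    if not 0 <= unit_index < CONV3_LENGTH:
        raise ValueError(f"conv3 unit index must be in [0, {CONV3_LENGTH}), got {unit_index}")
    start = CONV3_JUMP * unit_index
    return (start, start + CONV3_RF)


# ---------------------------------------------------------------------------
# de novo motif extraction


def _filter_max_activations(model: Network, sequences: Sequence[str]) -> np.ndarray:
    acts = model.conv1_activations(encode_batch(sequences))
    return acts.max(axis=(0, 2))


def extract_denovo_motifs(
    model: Network,
    positive_sequences: Sequence[str],
    activation_fraction: float = 0.7,
    min_sites: int = 10,
) -> List[DeNovoMotif]:
    """Derive <=64 PWMs from the first-layer filters.

    Every 9-mer window (stride 3, inside the central 300 bp) whose activation
    reaches activation_fraction x the filter's maximum over the positive set
    contributes to that filter's count matrix; a pseudocount of 1 per base
    per column is added before column normalization. Filters with fewer than
    `min_sites` contributing 9-mers are dropped.
    """
    x = encode_batch(positive_sequences)
    acts = model.conv1_activations(x)  # (N, 64, 98)
    max_per_filter = acts.max(axis=(0, 2))
    if max_per_filter.max() <= 0:
        raise ValueError("model appears untrained: zero first-layer activation everywhere")

    cores = [s.upper()[CROP : ELEMENT_LENGTH - CROP] for s in positive_sequences]
    motifs: List[DeNovoMotif] = []
    for f in range(acts.shape[1]):
        if max_per_filter[f] <= 0:
            continue
        hit_seq, hit_pos = np.nonzero(acts[:, f, :] >= activation_fraction * max_per_filter[f])
        counts = np.zeros((4, CONV1_KERNEL))
        n_sites = 0
        for si, wj in zip(hit_seq, hit_pos):
            kmer = cores[si][CONV1_STRIDE * wj : CONV1_STRIDE * wj + CONV1_KERNEL]
            n_sites += 1
            for col, base in enumerate(kmer):
                row = _BASE_IDX.get(base)
                if row is not None:
                    counts[row, col] += 1
        if n_sites < min_sites:
            continue
        counts += 1.0  # pseudocount per base per column
        pwm = counts / counts.sum(axis=0, keepdims=True)
        ic = float((2.0 + (pwm * np.log2(pwm)).sum(axis=0)).sum())
        motifs.append(DeNovoMotif(f, pwm, n_sites, ic))
    return motifs


# ---------------------------------------------------------------------------
# PWM-vs-PWM matching


def _normalized_columns(pwm: np.ndarray) -> np.ndarray:
    """Center columns at the uniform mean and scale to unit norm; zero-variance
    columns become zero vectors (their correlation contributes 0)."""
    c = np.asarray(pwm, dtype=float) - 0.25
    norms = np.linalg.norm(c, axis=0)
    safe = np.where(norms > 1e-12, norms, 1.0)
    return np.where(norms > 1e-12, c / safe, 0.0)


def _alignment_offsets(w_a: int, w_b: int, min_overlap: int) -> List[Tuple[np.ndarray, np.ndarray, int]]:
    out = []
    for off in range(-(w_a - min_overlap), w_b - min_overlap + 1):
        i = np.arange(max(0, -off), min(w_a, w_b - off))
        j = i + off
        if len(i) >= min_overlap:
            out.append((i, j, off))
    return out


def score_pwm_pair(
    pwm_a: np.ndarray, pwm_b: np.ndarray, min_overlap: int = 5
) -> Tuple[float, int, str]:
    """Best mean per-column Pearson correlation over offsets and strands."""
    best = (0.0, 0, "+")
    a_n = _normalized_columns(pwm_a)
    for strand, b in (("+", pwm_b), ("-", revcomp_pwm(pwm_b))):
        b_n = _normalized_columns(b)
        corr = a_n.T @ b_n  # (w_a, w_b) column correlations
        for i, j, off in _alignment_offsets(a_n.shape[1], b_n.shape[1], min_overlap):
            score = float(corr[i, j].mean())
            if score > best[0]:
                best = (score, off, strand)
    return best


def match_known_motifs(
    denovo: Sequence[DeNovoMotif],
    known_library: Mapping[str, np.ndarray],
    n_null: int = 1000,
    alpha: float = 1e-5,
    seed: int = 0,
    min_overlap: int = 5,
) -> List[MotifMatch]:
    """Match each de novo PWM against a known-motif library.

    The null distribution for each (de novo, known) pair is the score of
    column-shuffled copies of the de novo PWM; the p-value is the upper tail
    of a Gaussian fit to those null scores on the Fisher z (arctanh) scale,
    which is the natural scale for correlation-valued scores — on the raw
    scale a perfect match is never far enough from the shuffle null of a
    low-complexity PWM to clear 1e-5. Matches with p < alpha are emitted;
    the best match per de novo motif is flagged.
    """
    if not known_library:
        raise ValueError("known motif library is empty")
    rng = np.random.default_rng(seed)
    matches: List[MotifMatch] = []
    for dn in denovo:
        w = dn.pwm.shape[1]
        perms = np.array([rng.permutation(w) for _ in range(n_null)])
        candidates: List[MotifMatch] = []
        for known_id, kpwm in known_library.items():
            score, offset, strand = score_pwm_pair(dn.pwm, kpwm, min_overlap)
            null_scores = np.array(
                [score_pwm_pair(dn.pwm[:, perm], kpwm, min_overlap)[0] for perm in perms]
            )
            z_obs = np.arctanh(np.clip(score, -0.9999, 0.9999))
            z_null = np.arctanh(np.clip(null_scores, -0.9999, 0.9999))
            mu, sd = float(z_null.mean()), float(z_null.std(ddof=1))
            if sd < 1e-12:
                p = 0.0 if z_obs > mu + 1e-12 else 1.0
            else:
                p = float(stats.norm.sf((z_obs - mu) / sd))
            if p < alpha:
                candidates.append(MotifMatch(dn.filter_index, known_id, offset, strand, score, p))
        if candidates:
            candidates.sort(key=lambda m: (m.p_value, -m.score))
            best = candidates[0]
            candidates[0] = MotifMatch(
                best.filter_index, best.known_id, best.offset, best.strand,
                best.score, best.p_value, is_best=True,
            )
            matches.extend(candidates)
    return matches


# ---------------------------------------------------------------------------
# co-occurrence


def _window_hits(hits: np.ndarray) -> np.ndarray:
    """(N, n_filters, 98) hit mask -> (N, n_filters, 18) per-conv3-window any-hit."""
    n, f, _ = hits.shape
    out = np.zeros((n, f, CONV3_LENGTH), dtype=bool)
    for i in range(CONV3_LENGTH):
        lo = 4 * i
        out[:, :, i] = hits[:, :, lo : lo + _CONV1_PER_WINDOW].any(axis=2)
    return out


def detect_cooccurrence(
    model: Network,
    motifs: Sequence[DeNovoMotif],
    positives: Sequence[str],
    controls: Sequence[str],
    alpha: float = 0.001,
    activation_fraction: float = 0.7,
) -> List[CooccurrencePair]:
    """Test every extracted-motif pair for receptive-field co-occurrence.

    A pair (a, b) co-occurs in a sequence iff some conv3 receptive-field
    window contains an activating first-layer hit of both filters. Positive
    and control frequencies are compared with a one-sided Fisher exact test
    on the 2x2 table; no multiple-testing correction is applied.
    """
    if not positives or not controls:
        raise ValueError("both positive and background sequence sets are required")
    if not motifs:
        return []
    filt = np.array([m.filter_index for m in motifs])
    thresholds = activation_fraction * _filter_max_activations(model, positives)[filt]

    def windowed(sequences: Sequence[str]) -> np.ndarray:
        acts = model.conv1_activations(encode_batch(sequences))[:, filt, :]
        return _window_hits(acts >= thresholds[None, :, None])

    win_pos = windowed(positives)
    win_bg = windowed(controls)
    n_pos, n_bg = len(positives), len(controls)

    pairs: List[CooccurrencePair] = []
    for ai in range(len(motifs)):
        for bi in range(ai + 1, len(motifs)):
            co_pos = int((win_pos[:, ai, :] & win_pos[:, bi, :]).any(axis=1).sum())
            co_bg = int((win_bg[:, ai, :] & win_bg[:, bi, :]).any(axis=1).sum())
            table = [[co_pos, n_pos - co_pos], [co_bg, n_bg - co_bg]]
            _, p = stats.fisher_exact(table, alternative="greater")
            pairs.append(
                CooccurrencePair(
                    motif_a=int(filt[ai]), motif_b=int(filt[bi]),
                    count_pos=co_pos, n_pos=n_pos,
                    count_bg=co_bg, n_bg=n_bg, p_value=float(p),
                )
            )
    return pairs
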