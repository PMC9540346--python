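"""PWM utilities and the packaged fixture motif library.

PWMs are 4 x W column-stochastic numpy arrays with rows ordered A, C, G, T.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import numpy as np

BASES = "ACGT"
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    """Reverse-complement a PWM: complement rows and reverse columns."""
    return np.asarray(pwm)[_COMPLEMENT_IDX, ::-1].copy()


def consensus(pwm: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.asarray(pwm).argmax(axis=0))


def information_content(pwm: np.ndarray) -> float:
    """Total IC in bits relative to uniform background."""
    p = np.clip(np.asarray(pwm, dtype=float), 1e-12, 1.0)
    return float((2.0 + (p * np.log2(p)).sum(axis=0)).sum())


def sample_site(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one binding-site sequence from a PWM, column by column."""
    pwm = np.asarray(pwm)
    idx = [rng.choice(4, p=pwm[:, j] / pwm[:, j].sum()) for j in range(pwm.shape[1])]
    return "".join(BASES[i] for i in idx)


def builtin_motifs() -> Dict[str, np.ndarray]:
    """Load the packaged fixture PFMs (SOXLIKE, SIXLIKE, CREBLIKE, ETSLIKE)."""
    from .io import read_jaspar_pfms

    ref = resources.files("rretools").joinpath("data/motifs.jaspar")
    with resources.as_file(ref) as path:
        return read_jaspar_pfms(path)
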