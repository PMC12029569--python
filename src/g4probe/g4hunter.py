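"""G4Hunter propensity scoring.

The G4Hunter score measures G-richness and G-skewness of a DNA sequence:
every position inside a maximal run of k consecutive guanines scores
+min(k, 4), every position inside a run of k cytosines scores -min(k, 4),
and A/T positions score 0.  The sequence score is the arithmetic mean of
the per-base scores; values above ~1 indicate likely quadruplex formation.
Short synthetic oligos (24-28-mers here) are scored over their full
length; a sliding window is available for longer sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .sequences import OligoSequence

__all__ = ["G4HunterResult", "g4hunter_score", "per_base_scores"]


@dataclass(frozen=True)
class G4HunterResult:
    per_base_scores: np.ndarray  # int, in [-4, 4], one per base
    mean_score: float
    window: int | None = None
    window_scores: np.ndarray | None = None


def per_base_scores(bases: str) -> np.ndarray:
    """Per-base G4Hunter scores (run-length capped at 4)."""
    if not bases:
        raise InputError("cannot score an empty sequence")
    bases = bases.upper()
    scores = np.zeros(len(bases), dtype=int)
    i = 0
    while i < len(bases):
        b = bases[i]
        j = i
        while j < len(bases) and bases[j] == b:
            j += 1
        if b == "G":
            scores[i:j] = min(j - i, 4)
        elif b == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def g4hunter_score(
    seq: OligoSequence | str, window: int | None = None
) -> G4HunterResult:
    """Score a sequence; mean over the full length unless ``window`` is set.

    When ``window`` is given and shorter than the sequence, per-window
    means are returned in ``window_scores`` and ``mean_score`` is still
    the full-length mean (the quantity used to rank whole oligos).
    """
    bases = seq.bases if isinstance(seq, OligoSequence) else seq
    scores = per_base_scores(bases)
    mean = float(scores.mean())
    window_scores = None
    if window is not None:
        if window < 1:
            raise InputError("window must be >= 1")
        if window < len(scores):
            kernel = np.ones(window) / window
            window_scores = np.convolve(scores, kernel, mode="valid")
        else:
            window = None  # window covers everything: same as full-length
    return G4HunterResult(
        per_base_scores=scores,
        mean_score=mean,
        window=window,
        window_scores=window_scores,
    )
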