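"""Affine-gap global alignment and the CF (complementarity) factor.

The CF factor quantifies how much of a FRET probe a competitor oligo could
sequester by direct Watson-Crick hybridization rather than by quadruplex
competition: the competitor is globally aligned (Needleman-Wunsch with
affine gaps, Gotoh three-state recursion) against the reverse complement
of the probe under the NUC4.4 nucleotide matrix, and the number of
identically aligned positions — expected duplex base pairs — is divided by
the probe length.  CF near 1 flags a competitor that is simply the probe's
complement; CF near 0 rules hybridization out.

Gap convention follows EMBOSS/NCBI global alignment: a gap of length L
costs gap_open + (L-1) * gap_extend, with end gaps penalized.  Traceback
ties are broken deterministically (diagonal, then vertical, then
horizontal) so matched-pair counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .sequences import OligoSequence, reverse_complement

__all__ = ["AlignmentResult", "global_align", "cf_factor", "nuc44"]

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_NEG_INF = float("-inf")


@lru_cache(maxsize=1)
def nuc44():
    """The NCBI NUC4.4 nucleotide substitution matrix (+5 match, -4 mismatch)."""
    return substitution_matrices.load("NUC.4.4")


@dataclass(frozen=True)
class AlignmentResult:
    seq_a_aligned: str
    seq_b_aligned: str
    score: float
    matched_pairs: int
    cf_factor: float | None = None

    def __post_init__(self) -> None:
        assert len(self.seq_a_aligned) == len(self.seq_b_aligned)


def _lookup(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        raise InputError(f"substitution matrix has no entry for pair ({a}, {b})")


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of ``a`` against ``b`` with affine gaps.

    ``gap_open`` is the (positive) cost of the first position of a gap and
    ``gap_extend`` of each further position.  Returns the optimum score and
    one optimal alignment chosen by the deterministic tie-break.
    """
    if not a or not b:
        raise InputError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    matrix = nuc44() if matrix is None else matrix
    n, m = len(a), len(b)
    sub = np.empty((n, m))
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            sub[i, j] = _lookup(matrix, ca, cb)

    # Three-state DP: M diagonal, X gap in b (a consumed, vertical move),
    # Y gap in a (b consumed, horizontal move).
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend

    # Pointers record the predecessor state for each cell/state.
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M, 1=X, 2=Y
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_X[1:, 0] = 1
    ptr_Y[0, 1:] = 2

    def best(cands: tuple[float, ...]) -> tuple[float, int]:
        # Tie-break by listed order: M before X before Y.
        k = int(np.argmax(cands))
        return cands[k], k

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j], ptr_M[i, j] = best(
                (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            )
            M[i, j] += sub[i - 1, j - 1]
            X[i, j], ptr_X[i, j] = best(
                (M[i - 1, j] - gap_open,
                 X[i - 1, j] - gap_extend,
                 Y[i - 1, j] - gap_open)
            )
            Y[i, j], ptr_Y[i, j] = best(
                (M[i, j - 1] - gap_open,
                 X[i, j - 1] - gap_open,
                 Y[i, j - 1] - gap_extend)
            )

    score, state = best((M[n, m], X[n, m], Y[n, m]))

    # Traceback.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = ptr_M[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = ptr_X[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = ptr_Y[i, j]
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matched = sum(
        1 for ca, cb in zip(aligned_a, aligned_b) if ca == cb and ca != "-"
    )
    return AlignmentResult(
        seq_a_aligned=aligned_a,
        seq_b_aligned=aligned_b,
        score=float(score),
        matched_pairs=matched,
    )


def cf_factor(
    competitor: OligoSequence | str,
    probe: OligoSequence | str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> AlignmentResult:
    """CF factor of a competitor against a probe.

    Aligns the competitor with the reverse complement of the probe and
    returns the alignment with ``cf_factor`` = matched pairs / probe
    length, clipped to [0, 1].
    """
    comp = competitor.bases if isinstance(competitor, OligoSequence) else competitor
    probe_bases = probe.bases if isinstance(probe, OligoSequence) else probe
    target = reverse_complement(probe_bases)
    res = global_align(comp, target, gap_open=gap_open, gap_extend=gap_extend)
    cf = min(1.0, max(0.0, res.matched_pairs / len(probe_bases)))
    return AlignmentResult(
        seq_a_aligned=res.seq_a_aligned,
        seq_b_aligned=res.seq_b_aligned,
        score=res.score,
        matched_pairs=res.matched_pairs,
        cf_factor=cf,
    )
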