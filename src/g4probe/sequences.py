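"""Oligonucleotide records and rule-based derivative design.

AS1411 is a 26-mer G-rich DNA aptamer, d(GGTGGTGGTGGTTGTGGTGGTGGTGG),
that binds nucleolin but folds into a polymorphic mixture of G-quadruplex
topologies.  The derivative family implemented here reduces that
polymorphism by three kinds of edit, each tracked as provenance on the
resulting record:

* substitution of G14 by T, turning the sequence into a perfect palindrome
  with a central four-thymine linker (AT14);
* deletion of one or two thymines from that central linker (AT14-T1,
  AT14-T2), which shortens the loop and stabilizes the fold;
* addition of a thymine at both the 5' and 3' ends (the AT14T series),
  which blocks end-to-end quadruplex stacking at the cost of stability.

Coordinates in edit records are 1-based, matching how positions are spoken
about at the bench ("G14").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import InputError

__all__ = [
    "AS1411",
    "OligoSequence",
    "Substitution",
    "Deletion",
    "TerminalAddition",
    "apply_edits",
    "reverse_complement",
    "as1411_family",
]

#: Parent aptamer, 5'->3'.
AS1411 = "GGTGGTGGTGGTTGTGGTGGTGGTGG"

_ALPHABET = frozenset("ACGT")


def _validate_bases(bases: str) -> str:
    if not bases:
        raise InputError("sequence must be non-empty")
    bases = bases.upper()
    bad = set(bases) - _ALPHABET
    if bad:
        raise InputError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return bases


@dataclass(frozen=True)
class Substitution:
    """Replace the base at 1-based ``position`` with ``new``.

    ``expected`` optionally declares the original base; a mismatch is an
    error, guarding against coordinate drift between design notes and
    sequence files.
    """

    position: int
    new: str
    expected: str | None = None


@dataclass(frozen=True)
class Deletion:
    """Delete the base at 1-based ``position`` (in the current sequence)."""

    position: int
    expected: str | None = None


@dataclass(frozen=True)
class TerminalAddition:
    """Append ``base`` at ``end`` ('5' or '3')."""

    end: str  # '5' or '3'
    base: str = "T"


Edit = Substitution | Deletion | TerminalAddition


@dataclass(frozen=True)
class OligoSequence:
    """A 5'->3' DNA oligo with identity and design provenance."""

    id: str
    bases: str
    parent_id: str | None = None
    edits: tuple[Edit, ...] = field(default_factory=tuple)
    labeled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> str:
        return reverse_complement(self.bases)


def reverse_complement(bases: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(_validate_bases(bases)).reverse_complement())


def _check_position(bases: str, position: int) -> None:
    if not 1 <= position <= len(bases):
        raise InputError(
            f"position {position} outside sequence of length {len(bases)}"
        )


def _check_expected(bases: str, position: int, expected: str | None) -> None:
    if expected is not None and bases[position - 1] != expected.upper():
        raise InputError(
            f"expected {expected!r} at position {position}, "
            f"found {bases[position - 1]!r}"
        )


def apply_edits(
    parent: OligoSequence,
    edits: Iterable[Edit],
    *,
    new_id: str,
    labeled: bool | None = None,
) -> OligoSequence:
    """Apply an edit list to ``parent`` and return the derived oligo.

    Edits are applied in class order — substitutions, then deletions, then
    terminal additions — and within each class in the order given.
    Deletion positions refer to the sequence as it stands when the deletion
    is applied.  The returned record stores the parent id and the edit
    tuple so the derivation can be replayed and verified.
    """
    edits = tuple(edits)
    order = {Substitution: 0, Deletion: 1, TerminalAddition: 2}
    ordered = sorted(edits, key=lambda e: order[type(e)])
    bases = parent.bases
    for edit in ordered:
        if isinstance(edit, Substitution):
            _check_position(bases, edit.position)
            _check_expected(bases, edit.position, edit.expected)
            new = edit.new.upper()
            if new not in _ALPHABET:
                raise InputError(f"substitution base {edit.new!r} not in ACGT")
            bases = bases[: edit.position - 1] + new + bases[edit.position :]
        elif isinstance(edit, Deletion):
            _check_position(bases, edit.position)
            _check_expected(bases, edit.position, edit.expected)
            bases = bases[: edit.position - 1] + bases[edit.position :]
        else:  # TerminalAddition
            if edit.end not in ("5", "3"):
                raise InputError(f"terminal end must be '5' or '3', got {edit.end!r}")
            base = edit.base.upper()
            if base not in _ALPHABET:
                raise InputError(f"terminal base {edit.base!r} not in ACGT")
            bases = base + bases if edit.end == "5" else bases + base
    return OligoSequence(
        id=new_id,
        bases=bases,
        parent_id=parent.id,
        edits=edits,
        labeled=parent.labeled if labeled is None else labeled,
    )


def verify_provenance(child: OligoSequence, parent: OligoSequence) -> bool:
    """Replay ``child.edits`` against ``parent`` and compare the result."""
    if child.parent_id != parent.id:
        return False
    replayed = apply_edits(parent, child.edits, new_id=child.id)
    return replayed.bases == child.bases


def as1411_family() -> list[OligoSequence]:
    """Construct AS1411 and its six designed derivatives.

    Returns, in design order: AS1411, AT14, AT14-T1, AT14-T2, AT14T,
    AT14T-T1, AT14T-T2.  The central linker of AT14 spans positions 12-15
    (TTTT); core deletions remove thymines from it, and the AT14T series
    adds a terminal thymine at each end of the corresponding core variant.
    """
    parent = OligoSequence(id="AS1411", bases=AS1411)
    at14 = apply_edits(
        parent, [Substitution(14, "T", expected="G")], new_id="AT14"
    )
    at14_t1 = apply_edits(at14, [Deletion(14, expected="T")], new_id="AT14-T1")
    at14_t2 = apply_edits(
        at14, [Deletion(14, expected="T"), Deletion(14, expected="T")],
        new_id="AT14-T2",
    )
    caps = [TerminalAddition("5", "T"), TerminalAddition("3", "T")]
    at14t = apply_edits(at14, caps, new_id="AT14T")
    at14t_t1 = apply_edits(at14_t1, caps, new_id="AT14T-T1")
    at14t_t2 = apply_edits(at14_t2, caps, new_id="AT14T-T2")
    return [parent, at14, at14_t1, at14_t2, at14t, at14t_t1, at14t_t2]
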