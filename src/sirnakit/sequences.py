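"""Nucleic-acid primitives for siRNA guide strands.

A guide strand is the 19-nt antisense core of an siRNA duplex, written 5'->3'
with positions numbered 1..19 from the 5' end.  The synthetic dTdT overhang is
a fixed DNA dinucleotide appended at the 3' end; it is carried for reporting
but never enters position arithmetic, seed extraction or complementarity
counts.  Guides may contain the degenerate base N ("an even mixture of
A, U/T, G and C"), which expands to a pool of concrete sequences.

Complementarity is strict Watson-Crick (A:U/A:T, C:G); G:U wobble pairs are
not counted, and N never matches a concrete base when scanning transcripts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Literal

from .errors import ValidationError

Alphabet = Literal["RNA", "DNA"]

_LEGAL = {"RNA": frozenset("ACGUN"), "DNA": frozenset("ACGTN")}
_COMPLEMENT = {
    "RNA": str.maketrans("ACGUN", "UGCAN"),
    "DNA": str.maketrans("ACGTN", "TGCAN"),
}
_RNA_TO_DNA = str.maketrans("U", "T")
_DNA_TO_RNA = str.maketrans("T", "U")

#: Fixed 3' overhang on every synthesized strand (DNA thymidine dimer).
OVERHANG = "dTdT"

#: Guide positions (1-based) of the seed region driving miRNA-like off-targets.
SEED_START, SEED_END = 2, 8

#: Deterministic expansion order for the degenerate base N.
N_EXPANSION_ORDER = "ACGU"


@dataclass(frozen=True)
class NucSeq:
    """An immutable nucleotide sequence over {A,C,G,U,T,N}.

    Parameters
    ----------
    residues
        Sequence letters, 5'->3'.  Case-insensitive on input, stored upper.
    alphabet
        ``"RNA"`` (U legal, T illegal) or ``"DNA"`` (T legal, U illegal).
    """

    residues: str
    alphabet: Alphabet = "RNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValidationError("empty sequence")
        legal = _LEGAL.get(self.alphabet)
        if legal is None:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - legal
        if bad:
            raise ValidationError(
                f"illegal {self.alphabet} residue(s) {sorted(bad)} in {self.residues!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def position(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self):
            raise ValidationError(f"position {pos} outside 1..{len(self)}")
        return self.residues[pos - 1]

    def subseq(self, start: int, end: int) -> "NucSeq":
        """Closed-interval 1-based slice ``[start, end]``."""
        if not 1 <= start <= end <= len(self):
            raise ValidationError(
                f"interval [{start},{end}] outside 1..{len(self)}"
            )
        return NucSeq(self.residues[start - 1 : end], self.alphabet)

    def complement(self) -> "NucSeq":
        return NucSeq(self.residues.translate(_COMPLEMENT[self.alphabet]), self.alphabet)

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(
            self.residues.translate(_COMPLEMENT[self.alphabet])[::-1], self.alphabet
        )

    def to_rna(self) -> "NucSeq":
        if self.alphabet == "RNA":
            return self
        return NucSeq(self.residues.translate(_DNA_TO_RNA), "RNA")

    def to_dna(self) -> "NucSeq":
        if self.alphabet == "DNA":
            return self
        return NucSeq(self.residues.translate(_RNA_TO_DNA), "DNA")

    @property
    def n_positions(self) -> tuple[int, ...]:
        """1-based positions holding the degenerate base N."""
        return tuple(i + 1 for i, c in enumerate(self.residues) if c == "N")

    @property
    def is_concrete(self) -> bool:
        return "N" not in self.residues


def reverse_complement(s: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement; N maps to N, alphabet preserved."""
    return s.reverse_complement()


@dataclass(frozen=True)
class GuideStrand:
    """A 19-nt siRNA guide strand (5'->3') with its fixed dTdT overhang.

    Positions are 1-based over the 19-nt core; the overhang is never indexed.
    """

    core: NucSeq

    CORE_LENGTH = 19
    overhang: str = field(default=OVERHANG, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.core.alphabet != "RNA":
            raise ValidationError("guide core must be RNA")
        if len(self.core) != self.CORE_LENGTH:
            raise ValidationError(
                f"guide core must be {self.CORE_LENGTH} nt, got {len(self.core)}"
            )

    @classmethod
    def from_string(cls, residues: str) -> "GuideStrand":
        """Build from a plain 19-mer string (T accepted and converted to U)."""
        return cls(NucSeq(residues, "DNA" if "T" in residues.upper() else "RNA").to_rna())

    def __str__(self) -> str:
        return self.core.residues

    @property
    def with_overhang(self) -> str:
        """Display form including the synthetic overhang, e.g. for reports."""
        return f"{self.core.residues}{self.overhang}"

    @property
    def is_concrete(self) -> bool:
        return self.core.is_concrete

    @property
    def n_positions(self) -> tuple[int, ...]:
        return self.core.n_positions

    def substitute(self, position: int, base: str) -> "GuideStrand":
        """Return a copy with ``base`` at 1-based core ``position``."""
        if not 1 <= position <= self.CORE_LENGTH:
            raise ValidationError(f"position {position} outside 1..{self.CORE_LENGTH}")
        r = self.core.residues
        return GuideStrand(NucSeq(r[: position - 1] + base + r[position:], "RNA"))


def seed(g: GuideStrand) -> NucSeq:
    """The 7-mer seed region, guide core positions 2-8 inclusive (1-based).

    Partial complementarity of a transcript 3'UTR to this region drives
    miRNA-like off-target repression.
    """
    return g.core.subseq(SEED_START, SEED_END)


@dataclass(frozen=True)
class DegeneratePool:
    """All concretizations of a guide template containing degenerate Ns."""

    template: GuideStrand
    members: tuple[GuideStrand, ...]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[GuideStrand]:
        return iter(self.members)


def expand_pool(g: GuideStrand) -> DegeneratePool:
    """Enumerate every concrete guide a degenerate template encodes.

    The pool has 4^k members for k N-positions, enumerated deterministically:
    each N runs through A<C<G<U, leftmost N varying slowest, so member indices
    are stable across runs.  A template without N yields itself.
    """
    ns = g.n_positions
    members = []
    for combo in itertools.product(N_EXPANSION_ORDER, repeat=len(ns)):
        m = g
        for pos, base in zip(ns, combo):
            m = m.substitute(pos, base)
        members.append(m)
    return DegeneratePool(template=g, members=tuple(members))


def diff_positions(a: GuideStrand, b: GuideStrand) -> list[int]:
    """Sorted 1-based core positions where two guides differ.

    N counts as differing from any concrete base; two Ns agree.
    """
    if len(a.core) != len(b.core):
        raise ValidationError("guides must have equal core length")
    return [
        i + 1
        for i, (x, y) in enumerate(zip(a.core.residues, b.core.residues))
        if x != y
    ]
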