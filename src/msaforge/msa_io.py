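"""Query-anchored multiple sequence alignments in the A3M convention.

An A3M alignment is FASTA-like: uppercase letters and ``-`` are match-state
characters occupying the query's columns, lowercase letters are insertions
relative to the query and carry no column. The first record is the query
itself; it defines the match-column count ``L`` and contains neither gaps
nor insertions. All identity measures here are *query identities* ("qid"):
the denominator is always L, so a short or gappy member scores low even if
every residue it does align is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

_MATCH_CHARS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")
_INSERT_CHARS = frozenset("abcdefghijklmnopqrstuvwxyz")


class A3mFormatError(ValueError):
    """Raised when an alignment violates the A3M convention."""


@dataclass(frozen=True)
class AlignedSequence:
    """One MSA member: a header and an A3M sequence string.

    ``seq`` mixes match-state characters (uppercase, ``-``) with lowercase
    insertion characters. ``match_string`` strips the insertions, leaving
    exactly the L query-column characters.
    """

    id: str
    seq: str

    @property
    def match_string(self) -> str:
        return "".join(c for c in self.seq if c not in _INSERT_CHARS)

    @property
    def n_match(self) -> int:
        return sum(1 for c in self.seq if c not in _INSERT_CHARS)

    def validate(self) -> None:
        bad = set(self.seq) - _MATCH_CHARS - _INSERT_CHARS
        if bad:
            raise A3mFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Msa:
    """Query-anchored alignment: the query first, then its homologs.

    Invariants (enforced by :func:`parse_a3m` and :meth:`validate`):
    the query has no gaps and no insertions, its length equals the
    match-column count ``L``, and every member carries exactly L
    match-state characters.
    """

    query_id: str
    members: tuple[AlignedSequence, ...]
    L: int = field(default=0)

    def __post_init__(self):
        if self.L == 0 and self.members:
            object.__setattr__(self, "L", len(self.members[0].seq))

    @property
    def query(self) -> AlignedSequence:
        return self.members[0]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_hits(self) -> int:
        return len(self.members) - 1

    def __len__(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        if not self.members:
            raise A3mFormatError("MSA has no members")
        q = self.members[0]
        if "-" in q.seq or q.seq != q.seq.upper():
            raise A3mFormatError("query sequence must contain no gaps or insertions")
        if len(q.seq) != self.L:
            raise A3mFormatError(
                f"query length {len(q.seq)} != match-column count L={self.L}"
            )
        for m in self.members:
            m.validate()
            if m.n_match != self.L:
                raise A3mFormatError(
                    f"record {m.id!r}: {m.n_match} match-state characters, expected {self.L}"
                )


def _records(text: str) -> Iterator[tuple[str, str]]:
    # Null bytes separate concatenated A3M dumps in some pipeline outputs.
    text = text.replace("\x00", "\n")
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise A3mFormatError("sequence data before first '>' header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def parse_a3m(text: str) -> Msa:
    """Parse A3M/aligned-FASTA text into an :class:`Msa`.

    The first record is taken as the query. Raises :class:`A3mFormatError`
    on empty input, a gapped/lowercase query, or any member whose
    match-state count disagrees with the query length (the offending
    record is named in the message).
    """
    members = tuple(AlignedSequence(h, s) for h, s in _records(text))
    if not members:
        raise A3mFormatError("empty alignment input")
    msa = Msa(query_id=members[0].id, members=members, L=len(members[0].seq))
    msa.validate()
    return msa


def read_a3m(handle: TextIO | str) -> Msa:
    """Read an A3M file from a path or an open text handle."""
    if isinstance(handle, str):
        with open(handle, "r", encoding="utf-8") as fh:
            return parse_a3m(fh.read())
    return parse_a3m(handle.read())


def write_a3m(msa: Msa, width: int = 80) -> str:
    """Serialize an :class:`Msa` back to A3M text.

    Sequence lines are wrapped at ``width`` characters; ``parse_a3m``
    of the output reproduces the input object exactly.
    """
    out: list[str] = []
    for m in msa.members:
        out.append(f">{m.id}")
        for i in range(0, len(m.seq), width):
            out.append(m.seq[i : i + width])
        if not m.seq:
            out.append("")
    return "\n".join(out) + "\n"


def sequence_identity(msa: Msa, index: int) -> float:
    """Identity of member ``index`` to the query over all L match columns.

    Counts columns where the member's match-state character equals the
    query residue; insertions are ignored, ``-`` is a mismatch, and an
    unknown residue ``X`` matches nothing. A member whose match-state
    string equals the query exactly (including the query itself at
    index 0) scores 1.0.
    """
    if not 0 <= index < len(msa.members):
        raise IndexError(f"member index {index} out of range")
    q = msa.query.seq
    s = msa.members[index].match_string
    if len(s) != len(q):
        raise A3mFormatError(
            f"record {msa.members[index].id!r}: match length {len(s)} != L={len(q)}"
        )
    if s == q:
        return 1.0
    same = sum(1 for a, b in zip(q, s) if a == b and a != "-" and a != "X")
    return same / len(q)
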