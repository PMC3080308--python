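"""Sequence sets: validated multi-record inputs with 1-based coordinates.

A :class:`SequenceSet` is the package's in-memory container for one or more
sequence records over a fixed alphabet (DNA by default).  All user-facing
coordinates are 1-based and closed; gapped-factor distances never cross a
record boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return s.translate(_COMPLEMENT)[::-1]


class InvalidResidueError(ValueError):
    """A residue outside the declared alphabet, with its location."""

    def __init__(self, record_id: str, position: int, residue: str):
        self.record_id = record_id
        self.position = position
        self.residue = residue
        super().__init__(
            f"invalid residue {residue!r} at {record_id}:{position} "
            f"(1-based); not in alphabet"
        )


@dataclass(frozen=True)
class SequenceSet:
    """A set of sequence records over a common alphabet.

    Parameters
    ----------
    records
        List of ``(id, residues)`` pairs.  Residues are uppercased on
        construction via :meth:`from_strings`.
    alphabet
        Allowed residue symbols; terminal markers used internally by the
        suffix index are never part of the alphabet.
    """

    records: tuple[tuple[str, str], ...]
    alphabet: frozenset[str] = field(default=DNA_ALPHABET)

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty sequence set")
        for rid, seq in self.records:
            for i, c in enumerate(seq):
                if c not in self.alphabet:
                    raise InvalidResidueError(rid, i + 1, c)

    @classmethod
    def from_strings(
        cls,
        seqs: Sequence[str] | str,
        ids: Sequence[str] | None = None,
        alphabet: Iterable[str] = DNA_ALPHABET,
        on_invalid: str = "reject",
    ) -> "SequenceSet":
        """Build from raw strings (uppercased).

        ``on_invalid`` is ``"reject"`` (raise on symbols outside the
        alphabet, the default — ambiguity codes would corrupt i.i.d.
        background estimates) or ``"split"`` (treat each invalid symbol as
        a record breaker, so no gapped factor spans it).
        """
        if isinstance(seqs, str):
            seqs = [seqs]
        alphabet = frozenset(c.upper() for c in alphabet)
        if ids is None:
            ids = [f"seq{i + 1}" for i in range(len(seqs))]
        records: list[tuple[str, str]] = []
        for rid, raw in zip(ids, seqs):
            seq = raw.upper()
            if on_invalid == "split":
                parts = _split_on_invalid(seq, alphabet)
                if len(parts) == 1:
                    records.append((rid, parts[0]))
                else:
                    records.extend(
                        (f"{rid}/{j + 1}", p) for j, p in enumerate(parts)
                    )
            elif on_invalid == "reject":
                records.append((rid, seq))
            else:
                raise ValueError(f"unknown on_invalid policy {on_invalid!r}")
        records = [(rid, seq) for rid, seq in records if seq]
        return cls(tuple(records), alphabet)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        alphabet: Iterable[str] = DNA_ALPHABET,
        on_invalid: str = "reject",
    ) -> "SequenceSet":
        """Read a (multi-record, wrapped-line) FASTA file."""
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_strings(
            [str(r.seq) for r in recs],
            ids=[r.id for r in recs],
            alphabet=alphabet,
            on_invalid=on_invalid,
        )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(seq) for _, seq in self.records)

    def sequence(self, record: int) -> str:
        return self.records[record][1]

    def with_reverse_complements(self) -> "SequenceSet":
        """Append the reverse complement of every record (both-strand scans)."""
        extra = tuple(
            (f"{rid}|rc", reverse_complement(seq)) for rid, seq in self.records
        )
        return SequenceSet(self.records + extra, self.alphabet)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.records:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _split_on_invalid(seq: str, alphabet: frozenset[str]) -> list[str]:
    parts: list[str] = []
    cur: list[str] = []
    for c in seq:
        if c in alphabet:
            cur.append(c)
        elif cur:
            parts.append("".join(cur))
            cur = []
    if cur:
        parts.append("".join(cur))
    return parts or [""]
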