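"""Synthetic sequence sets: i.i.d. backgrounds and planted spaced dyads.

Emulates the structure of a promoter/upstream sequence collection: a set
of records drawn from a monadic background, with a dyad y-gap-z written
into a fraction of the records at a random admissible position.  Planting
overwrites in place (record lengths stay constant, so background
statistics remain comparable); the spacer content is left as background.
All randomness flows through one integer seed (numpy PCG64), so outputs
are fully reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import SequenceSet

__all__ = ["PlantSpec", "gen_background", "plant", "write_plants_tsv"]


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: dyad components, spacer length, penetrance, seed."""

    y: str
    z: str
    gap: int
    insert_fraction: float
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.insert_fraction <= 1.0):
            raise ValueError("insert_fraction must lie in [0, 1]")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not self.y or not self.z:
            raise ValueError("components must be non-empty")

    @property
    def span(self) -> int:
        return len(self.y) + self.gap + len(self.z)


def gen_background(n_records: int, record_len: int,
                   probs: Sequence[float] | dict[str, float] | None = None,
                   seed: int = 0,
                   alphabet: str = "ACGT") -> SequenceSet:
    """i.i.d. background records; default uniform over ACGT."""
    if isinstance(probs, dict):
        alphabet = "".join(sorted(probs))
        pvec = np.array([probs[c] for c in alphabet], dtype=float)
    elif probs is None:
        pvec = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        pvec = np.asarray(probs, dtype=float)
    if len(pvec) != len(alphabet) or np.any(pvec < 0) or \
            not np.isclose(pvec.sum(), 1.0):
        raise ValueError("probs must be a normalized vector over the alphabet")
    if n_records < 1 or record_len < 1:
        raise ValueError("need n_records >= 1 and record_len >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    records = []
    for i in range(n_records):
        draw = rng.choice(len(letters), size=record_len, p=pvec)
        records.append((f"synth{i + 1}", "".join(letters[draw])))
    return SequenceSet(tuple(records), frozenset(alphabet))


def plant(seqs: SequenceSet, spec: PlantSpec
          ) -> tuple[SequenceSet, list[tuple[int, int]]]:
    """Overwrite the dyad into a fraction of records; return ground truth.

    The number of planted records is round(insert_fraction * n_records);
    records and positions are chosen uniformly at random (seeded).  The
    spacer positions keep their background content.  Returns the modified
    set and a list of (record index, 1-based start of y) truth coordinates.
    """
    span = spec.span
    if any(span > len(s) for _, s in seqs.records):
        raise ValueError("dyad span exceeds a record length")
    rng = np.random.default_rng(spec.seed)
    n_plant = int(round(spec.insert_fraction * seqs.n_records))
    chosen = sorted(rng.choice(seqs.n_records, size=n_plant, replace=False))
    truth: list[tuple[int, int]] = []
    records = list(seqs.records)
    for r in chosen:
        rid, s = records[r]
        start = int(rng.integers(0, len(s) - span + 1))  # 0-based
        chars = list(s)
        chars[start: start + len(spec.y)] = list(spec.y)
        zpos = start + len(spec.y) + spec.gap
        chars[zpos: zpos + len(spec.z)] = list(spec.z)
        records[r] = (rid, "".join(chars))
        truth.append((r, start + 1))
    return SequenceSet(tuple(records), seqs.alphabet), truth


def write_plants_tsv(seqs: SequenceSet, spec: PlantSpec,
                     truth: list[tuple[int, int]],
                     path: str | Path) -> None:
    """BED-like TSV of ground-truth plant coordinates (1-based, closed)."""
    with open(path, "w") as fh:
        fh.write("# record\tstart\tend\tdyad\n")
        for r, start in truth:
            fh.write(f"{seqs.ids[r]}\t{start}\t{start + spec.span - 1}\t"
                     f"{spec.y}-n{spec.gap}-{spec.z}\n")
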