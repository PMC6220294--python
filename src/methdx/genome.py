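"""Reference genome container.

A genome here is a set of named A/C/G/T sequences, each flagged as a placed
chromosome or an unplaced scaffold.  The placement flag matters downstream:
unconverted-cytosine artifacts in bisulfite data concentrate in unplaced,
repeat-like scaffolds, and the diagnostics partition shared artifact sites by
placement.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

CHROMOSOME = "chromosome"
UNPLACED = "unplaced"
_PLACEMENTS = {CHROMOSOME, UNPLACED}
_ALPHABET = frozenset("ACGT")
_CHROM_NAME = re.compile(r"^(chr|Chr|CHR|LG|ChLG)")


def _infer_placement(name: str) -> str:
    return CHROMOSOME if _CHROM_NAME.match(name) else UNPLACED


@dataclass
class ReferenceGenome:
    """Named nucleotide sequences with a chromosome/unplaced flag each.

    Parameters
    ----------
    sequences
        Mapping of sequence name to an upper-case A/C/G/T string.
    placement
        Mapping of sequence name to ``"chromosome"`` or ``"unplaced"``.
        Names absent from the mapping are inferred from the name (a
        ``chr``/``LG`` prefix marks a chromosome).
    """

    sequences: dict[str, str]
    placement: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(
                    f"sequence {name!r} contains non-ACGT characters: {sorted(extra)!r}"
                )
        unknown = set(self.placement) - set(self.sequences)
        if unknown:
            raise ValueError(f"placement given for unknown sequences: {sorted(unknown)}")
        for name in self.sequences:
            self.placement.setdefault(name, _infer_placement(name))
        bad = {n: p for n, p in self.placement.items() if p not in _PLACEMENTS}
        if bad:
            raise ValueError(f"invalid placement flags: {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def is_placed(self, name: str) -> bool:
        return self.placement[name] == CHROMOSOME

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        """Write sequences as FASTA, 60-column wrapped, with the placement
        flag recorded in the description line."""
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name} placement={self.placement[name]}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        placement: Mapping[str, str] | None = None,
    ) -> "ReferenceGenome":
        """Read a FASTA file.

        Placement is taken from an explicit mapping if given, otherwise from a
        ``placement=`` token in the description line, otherwise inferred from
        the sequence name.
        """
        seqs: dict[str, str] = {}
        flags: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
            m = re.search(r"placement=(\S+)", rec.description)
            if placement is not None and rec.id in placement:
                flags[rec.id] = placement[rec.id]
            elif m:
                flags[rec.id] = m.group(1)
        return cls(seqs, flags)


def chrom_order(genome: ReferenceGenome) -> dict[str, int]:
    """Stable ordering of sequence names, as listed in the genome."""
    return {name: i for i, name in enumerate(genome.sequences)}
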