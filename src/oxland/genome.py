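"""Genome sequences as chromosome-keyed, numpy-backed containers.

Sequences are plain upper-case strings; per-chromosome uint8 views are cached
for vectorised base arithmetic (GC masks, defined-base masks, trinucleotide
coding). Anything that is not A/C/G/T counts as undefined sequence.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Mapping

import numpy as np

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")

#: ASCII codes used throughout the package.
CODE_A, CODE_C, CODE_G, CODE_T, CODE_N = (ord(b) for b in "ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


class Genome:
    """A set of chromosome sequences with cached numeric views."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}
        self._codes: Dict[str, np.ndarray] = {}

    # -- container protocol -------------------------------------------------
    @property
    def chroms(self) -> List[str]:
        return list(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    # -- sequence access ----------------------------------------------------
    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 ASCII view of a chromosome (cached, do not mutate)."""
        if chrom not in self._codes:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = arr
        return self._codes[chrom]

    def defined_mask(self, chrom: str) -> np.ndarray:
        c = self.codes(chrom)
        return (c == CODE_A) | (c == CODE_C) | (c == CODE_G) | (c == CODE_T)

    def gc_mask(self, chrom: str) -> np.ndarray:
        c = self.codes(chrom)
        return (c == CODE_C) | (c == CODE_G)

    def gc_fraction(self) -> float:
        """Genome-wide GC fraction over defined bases."""
        gc = sum(int(self.gc_mask(c).sum()) for c in self)
        defined = sum(int(self.defined_mask(c).sum()) for c in self)
        if defined == 0:
            raise ValueError("genome has no defined sequence")
        return gc / defined

    # -- I/O ------------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=c, description="") for c, s in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def mirrored(self) -> "Genome":
        """Reverse-complemented genome (coordinate x maps to L-1-x).

        Used by strand-symmetry tests: mirroring the genome together with all
        stranded annotations must leave every profile unchanged.
        """
        return Genome({c: revcomp(s) for c, s in self._seqs.items()})
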