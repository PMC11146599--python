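"""In-memory genome container backed by numpy uint8 code arrays.

Sequences are stored as arrays of base codes (A=0, C=1, G=2, T=3, N=4) so
structural operations (reverse complement, excision, insertion) are cheap
array manipulations.  Coordinates are 0-based half-open everywhere inside the
package; conversion to 1-based happens only in text writers.
"""

from __future__ import annotations

from collections.abc import Iterator
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import decode_seq, encode_seq


class Genome:
    """An ordered set of chromosome sequences for one individual/species."""

    def __init__(self, chroms: dict[str, np.ndarray] | None = None):
        self.chroms: dict[str, np.ndarray] = dict(chroms or {})

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def __len__(self) -> int:
        return sum(len(a) for a in self.chroms.values())

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def lengths(self) -> dict[str, int]:
        return {n: len(a) for n, a in self.chroms.items()}

    def seq(self, name: str, start: int | None = None, end: int | None = None) -> str:
        return decode_seq(self.chroms[name][start:end])

    def codes(self, name: str) -> np.ndarray:
        return self.chroms[name]

    def set_seq(self, name: str, seq: str | np.ndarray) -> None:
        if isinstance(seq, str):
            seq = encode_seq(seq)
        self.chroms[name] = np.asarray(seq, dtype=np.uint8)

    def copy(self) -> "Genome":
        return Genome({n: a.copy() for n, a in self.chroms.items()})

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.names == other.names and all(
            np.array_equal(self.chroms[n], other.chroms[n]) for n in self.chroms
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        g = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            g.set_seq(rec.id, str(rec.seq))
        return g

    def to_fasta(self, path: str | Path, line_width: int = 80) -> None:
        records = [
            SeqRecord(Seq(self.seq(n)), id=n, description="") for n in self.names
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)
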