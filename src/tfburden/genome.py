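"""Random-access genome sequence backed by an indexed FASTA or an in-memory dict.

Sequences are exposed uppercase over the alphabet {A, C, G, T, N}; coordinates
are 0-based half-open, matching BED convention.
"""

from __future__ import annotations

import numpy as np

_BASE_TO_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Per-chromosome uppercase DNA with random access by (chrom, start, end).

    Chromosome strings are cached in memory on first access; genomes used here
    are at most tens of megabases.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return exactly ``end - start`` uppercase bases (0-based half-open)."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]) or end < start:
            raise ValueError(
                f"range [{start}, {end}) outside {chrom} "
                f"(length {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start:end]

    def base_codes(self, chrom: str) -> np.ndarray:
        """Whole-chromosome base codes: A=0, C=1, G=2, T=3, other=-1."""
        raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
        return _BASE_TO_CODE[raw]

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
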