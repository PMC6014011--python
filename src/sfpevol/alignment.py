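"""In-frame codon alignments."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import decode_codons, encode_codons


class FrameError(ValueError):
    """Alignment is not a valid in-frame codon alignment."""


class CodonAlignment:
    """Equal-length, in-frame coding sequences keyed by taxon name.

    Internally stores a ``(n_taxa, n_codons)`` int matrix of codon state
    indices with -1 for gap/ambiguous codons.  Internal stop codons are
    rejected at construction.
    """

    def __init__(self, names: list[str], codon_idx: np.ndarray):
        self.names = list(names)
        self.codon_idx = np.asarray(codon_idx, dtype=np.int16)
        if self.codon_idx.ndim != 2 or len(self.names) != self.codon_idx.shape[0]:
            raise FrameError("codon matrix must be (n_taxa, n_codons)")
        if len(set(self.names)) != len(self.names):
            raise FrameError("duplicate sequence names")
        self.index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "CodonAlignment":
        names = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise FrameError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not divisible by 3")
        rows = []
        for name in names:
            try:
                rows.append(encode_codons(seqs[name]))
            except ValueError as exc:
                raise FrameError(f"{name}: {exc}") from exc
        return cls(names, np.vstack(rows) if rows else np.empty((0, 0), np.int16))

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FrameError(f"no sequences in {path}")
        return cls.from_strings({r.id: str(r.seq) for r in records})

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(decode_codons(self.codon_idx[i])), id=n, description="")
            for i, n in enumerate(self.names)
        ]
        SeqIO.write(records, str(path), "fasta")

    @property
    def n_taxa(self) -> int:
        return self.codon_idx.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codon_idx.shape[1]

    def sequence(self, name: str) -> str:
        return decode_codons(self.codon_idx[self.index[name]])

    def subset(self, names: list[str]) -> "CodonAlignment":
        rows = [self.index[n] for n in names]
        return CodonAlignment(list(names), self.codon_idx[rows])

    def is_constant(self) -> bool:
        """True when no column shows more than one distinct observed codon."""
        M = self.codon_idx
        for j in range(M.shape[1]):
            col = M[:, j]
            obs = col[col >= 0]
            if obs.size and np.unique(obs).size > 1:
                return False
        return True
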