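"""FASTA-backed per-species protein sets."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .align import encode


class Proteome:
    """An ordered set of amino-acid sequences with unique identifiers.

    Record order is preserved (it is part of the on-disk FASTA layout and of
    the deterministic tie-breaking downstream).  Encoded (uint8) sequences
    are cached because every search scans the full proteome.
    """

    def __init__(self, species: str, records: list[tuple[str, str]]):
        self.species = species
        self._ids: list[str] = []
        self._seqs: dict[str, str] = {}
        for rid, seq in records:
            if rid in self._seqs:
                raise ValueError(f"duplicate record id {rid!r} in proteome {species!r}")
            self._ids.append(rid)
            self._seqs[rid] = seq
        self._encoded: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, rid: str) -> bool:
        return rid in self._seqs

    def __iter__(self):
        return iter(self._ids)

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def sequence(self, rid: str) -> str:
        return self._seqs[rid]

    def encoded(self, rid: str) -> np.ndarray:
        enc = self._encoded.get(rid)
        if enc is None:
            enc = encode(self._seqs[rid])
            self._encoded[rid] = enc
        return enc

    @property
    def residue_count(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    # ----------------------------------------------------------------- FASTA
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid in self._ids:
                fh.write(f">{rid}\n")
                seq = self._seqs[rid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, species: str | None = None) -> "Proteome":
        from Bio import SeqIO

        if species is None:
            species = Path(path).stem
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(species, records)
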