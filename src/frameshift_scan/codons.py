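"""Genetic-code primitives and validated coding sequences.

All coordinates are 0-based and half-open. The internal alphabet is DNA
(ACGT); RNA input is normalized with U -> T on construction, so the rare
leucine codons discussed throughout (UUA, CUA) appear internally as TTA
and CTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

# Standard genetic code, DNA alphabet. Stops map to "*".
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
ALL_CODONS = tuple(sorted(GENETIC_CODE))

_VALID_NT = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised when a nucleotide or coding sequence violates its contract."""


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def translate(nt_seq: str, stop_policy: str = "halt_at_stop") -> str:
    """Translate a nucleotide string with the standard genetic code.

    A trailing partial codon (1-2 nt) is dropped. Under ``halt_at_stop``
    translation ends at (and excludes) the first stop codon; under
    ``error_on_stop`` a stop raises :class:`InvalidSequenceError`.
    """
    seq = normalize_nt(nt_seq)
    bad = set(seq) - _VALID_NT
    if bad:
        raise InvalidSequenceError(f"non-ACGT character(s) in sequence: {sorted(bad)}")
    if stop_policy not in ("halt_at_stop", "error_on_stop"):
        raise ValueError(f"unknown stop_policy: {stop_policy!r}")
    residues: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        aa = GENETIC_CODE[seq[i : i + 3]]
        if aa == "*":
            if stop_policy == "error_on_stop":
                raise InvalidSequenceError(
                    f"stop codon {seq[i:i + 3]} at nt {i} under error_on_stop"
                )
            break
        residues.append(aa)
    return "".join(residues)


@dataclass(frozen=True)
class CodingSequence:
    """A complete ORF: ATG start, canonical terminal stop, no internal stop.

    The sequence lives in its own coordinate system (nt 0 is the A of the
    initiator ATG). Construction validates the full contract; use
    :meth:`from_raw` to normalize RNA/lowercase input first.
    """

    id: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        s = self.seq
        bad = set(s) - _VALID_NT
        if bad:
            raise InvalidSequenceError(f"{self.id}: non-ACGT character(s): {sorted(bad)}")
        if len(s) == 0 or len(s) % 3 != 0:
            raise InvalidSequenceError(f"{self.id}: length {len(s)} is not a positive multiple of 3")
        if s[:3] != "ATG":
            raise InvalidSequenceError(f"{self.id}: does not start with ATG")
        if s[-3:] not in STOP_CODONS:
            raise InvalidSequenceError(f"{self.id}: terminal codon {s[-3:]} is not a stop")
        for i in range(0, len(s) - 3, 3):
            if s[i : i + 3] in STOP_CODONS:
                raise InvalidSequenceError(f"{self.id}: internal in-frame stop at codon {i // 3}")

    @classmethod
    def from_raw(cls, id: str, seq: str) -> "CodingSequence":
        return cls(id=id, seq=normalize_nt(seq))

    @property
    def n_codons(self) -> int:
        """Total codons including the terminal stop."""
        return len(self.seq) // 3

    @property
    def n_sense_codons(self) -> int:
        return self.n_codons - 1

    def codon(self, index: int) -> str:
        if not 0 <= index < self.n_codons:
            raise IndexError(f"codon index {index} out of range for {self.id}")
        return self.seq[3 * index : 3 * index + 3]

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def protein(self) -> str:
        """In-frame translation (stop excluded)."""
        return translate(self.seq)


def find_target_codons(cds: CodingSequence, targets: Iterable[str]) -> list[int]:
    """0-based indices of in-frame (frame-0) occurrences of ``targets``.

    Only codon-aligned occurrences count: a TTA straddling two frame-0
    codons is invisible to the ribosome's reading frame and is ignored.
    """
    target_set = {normalize_nt(t) for t in targets}
    unknown = target_set - set(GENETIC_CODE)
    if unknown:
        raise ValueError(f"not codons: {sorted(unknown)}")
    seq = cds.seq
    return [k for k in range(len(seq) // 3) if seq[3 * k : 3 * k + 3] in target_set]
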