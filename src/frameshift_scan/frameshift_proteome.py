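"""In silico frameshift and truncation databases at target leucine codons.

A +1 or -1 ribosomal frameshift at an in-frame target codon (TTA or CTA by
default) yields a trans-frame product: the in-frame residues upstream of
the target codon followed by the out-of-frame translation until the first
stop in the new frame. If the first codon read after a +1 shift is itself a
stop (for TTA/CTA this happens for half of the possible next nucleotides:
TA+A and TA+G), translation terminates on the spot and the product is the
truncated in-frame prefix alone.

Conventions: the target codon contributes no residue to the product; the
+1 frame starts at nucleotide 3k+1 and the -1 frame at 3k-1, where k is
the 0-based codon index of the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .codons import (
    GENETIC_CODE,
    STOP_CODONS,
    CodingSequence,
    InvalidSequenceError,
    find_target_codons,
    normalize_nt,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_TARGETS = ("TTA", "CTA")

TRANS_FRAME = "trans_frame"
TRUNCATED = "truncated"


@dataclass(frozen=True)
class FrameshiftRecord:
    """One frameshift product at one target-codon occurrence."""

    source_id: str
    codon_index: int
    target_codon: str
    direction: int  # +1 or -1
    product_class: str  # trans_frame | truncated
    product_seq: str
    prefix_len: int
    ran_off_end: bool

    @property
    def extension(self) -> str:
        """Out-of-frame part of the product (empty for truncated)."""
        return self.product_seq[self.prefix_len :]

    def header(self) -> str:
        """FASTA header: fs|<id>|codon<1-based>|<codon>|<p1|m1>|<class>."""
        d = "p1" if self.direction == 1 else "m1"
        cls = "chimera" if self.product_class == TRANS_FRAME else "truncated"
        return f"fs|{self.source_id}|codon{self.codon_index + 1}|{self.target_codon}|{d}|{cls}"


@dataclass(frozen=True)
class ChimericWindow:
    """Chimeric immunopeptidome window around a +1 frameshift site.

    Up to 10 in-frame residues immediately before the target codon joined
    to up to 10 out-of-frame residues after it; both parts are non-empty,
    so immediate-stop (truncated) occurrences and codon-0 targets yield no
    window.
    """

    source_id: str
    codon_index: int
    target_codon: str
    in_frame_part: str
    out_of_frame_part: str

    @property
    def window_seq(self) -> str:
        return self.in_frame_part + self.out_of_frame_part

    def header(self) -> str:
        return f"win|{self.source_id}|codon{self.codon_index + 1}|{self.target_codon}"


def frameshift_translate(cds: CodingSequence, codon_index: int, direction: int) -> FrameshiftRecord:
    """Translate the product of a +1/-1 frameshift at ``codon_index``.

    The in-frame prefix is the translation of codons 0..k-1; the new frame
    begins at nt 3k+1 (+1 shift) or 3k-1 (-1 shift) and is read until the
    first stop (excluded) or, failing that, the end of the sequence
    (``ran_off_end``, trailing partial codon dropped).
    """
    if direction not in (1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    k = codon_index
    if not 0 <= k < cds.n_codons:
        raise InvalidSequenceError(f"{cds.id}: codon index {k} out of range")
    target = cds.codon(k)
    if target in STOP_CODONS:
        raise InvalidSequenceError(f"{cds.id}: codon {k} is a stop codon")
    if direction == -1 and k < 1:
        raise InvalidSequenceError(f"{cds.id}: -1 frameshift needs codon index >= 1")

    prefix = translate(cds.seq[: 3 * k])
    start = 3 * k + 1 if direction == 1 else 3 * k - 1
    new_frame = cds.seq[start:]

    first = new_frame[:3]
    if direction == 1 and len(first) == 3 and first in STOP_CODONS:
        # +1 shift at TTA/CTA reads TA+N; N in {A, G} gives an immediate stop.
        return FrameshiftRecord(
            source_id=cds.id, codon_index=k, target_codon=target, direction=1,
            product_class=TRUNCATED, product_seq=prefix, prefix_len=k, ran_off_end=False,
        )

    extension = translate(new_frame)
    # ran_off_end: no stop was seen before the sequence (minus partial codon) ended
    ran_off_end = 3 * len(extension) + 2 >= len(new_frame)
    return FrameshiftRecord(
        source_id=cds.id, codon_index=k, target_codon=target, direction=direction,
        product_class=TRANS_FRAME, product_seq=prefix + extension, prefix_len=k,
        ran_off_end=ran_off_end,
    )


def fraction_immediate_stop(target_codon: str, direction: int) -> float:
    """Fraction of the 4 next nucleotides making the first shifted codon a stop.

    For a +1 shift the first new-frame codon is the target's last two
    nucleotides plus the next one; for -1 it is the preceding nucleotide
    plus the target's first two. TTA and CTA both give 0.5 for +1 (TAA and
    TAG) and 0.0 for -1 (NTT / NCT is never a stop).
    """
    codon = normalize_nt(target_codon)
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a codon: {target_codon!r}")
    if direction == 1:
        shifted = [codon[1:] + n for n in "ACGT"]
    elif direction == -1:
        shifted = [n + codon[:2] for n in "ACGT"]
    else:
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    return sum(c in STOP_CODONS for c in shifted) / 4.0


def build_frameshift_database(
    cds_set: Iterable[CodingSequence],
    targets: Sequence[str] = DEFAULT_TARGETS,
    directions: Sequence[int] = (1, -1),
) -> list[FrameshiftRecord]:
    """One record per (CDS, in-frame target occurrence, direction).

    Records whose product is empty (a codon-0 target truncating
    immediately) are omitted; for -1 shifts codon 0 has no upstream
    nucleotide and is skipped. Output order is deterministic: CDS input
    order, then codon index, then +1 before -1.
    """
    records: list[FrameshiftRecord] = []
    for cds in cds_set:
        for k in find_target_codons(cds, targets):
            for direction in sorted(directions, reverse=True):
                if direction == -1 and k < 1:
                    continue
                rec = frameshift_translate(cds, k, direction)
                if not rec.product_seq:
                    continue
                records.append(rec)
    return records


def build_frameshift_database_checked(
    cds_set: Iterable[tuple[str, str]],
    targets: Sequence[str] = DEFAULT_TARGETS,
    directions: Sequence[int] = (1, -1),
) -> tuple[list[FrameshiftRecord], int]:
    """As :func:`build_frameshift_database` from raw (id, seq) pairs.

    Invalid coding sequences are skipped with a logged warning; returns
    (records, n_skipped).
    """
    valid: list[CodingSequence] = []
    skipped = 0
    for seq_id, seq in cds_set:
        try:
            valid.append(CodingSequence.from_raw(seq_id, seq))
        except InvalidSequenceError as exc:
            logger.warning("skipping invalid CDS %s: %s", seq_id, exc)
            skipped += 1
    return build_frameshift_database(valid, targets, directions), skipped


def build_chimeric_windows(
    cds_set: Iterable[CodingSequence],
    targets: Sequence[str] = DEFAULT_TARGETS,
    flank: int = 10,
) -> list[ChimericWindow]:
    """Chimeric +/-``flank``-residue windows at each +1 frameshift site.

    Only +1 shifts are considered. Occurrences whose +1 extension is empty
    (immediate stop, i.e. the truncated class) or whose in-frame prefix is
    empty (target at codon 0) are excluded: a chimera needs residues on
    both sides of the junction.
    """
    windows: list[ChimericWindow] = []
    for cds in cds_set:
        for k in find_target_codons(cds, targets):
            rec = frameshift_translate(cds, k, 1)
            ext = rec.extension
            if rec.prefix_len == 0 or not ext:
                continue
            prefix = rec.product_seq[: rec.prefix_len]
            windows.append(
                ChimericWindow(
                    source_id=cds.id,
                    codon_index=k,
                    target_codon=rec.target_codon,
                    in_frame_part=prefix[-flank:],
                    out_of_frame_part=ext[:flank],
                )
            )
    return windows


def write_decoys(records: Iterable[FrameshiftRecord]) -> list[tuple[str, str]]:
    """Reversed-sequence decoys as (header, sequence) pairs, headers 'rev_'-prefixed."""
    return [(f"rev_{rec.header()}", rec.product_seq[::-1]) for rec in records]
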