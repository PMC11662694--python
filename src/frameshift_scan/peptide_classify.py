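"""Post-search filtration of identified peptides against the frameshift DB.

Identified peptides are (1) mapped back to the canonical proteome — an
exact-substring hit means the peptide could originate from an in-frame
sequence and disqualifies it; (2) located within frameshift products and
classified by where they sit relative to the frameshift junction; (3)
filtered for replicate presence per condition; and (4) summarized as
treatment-specific induced peptides per target codon.

Only trans-frame chimeras — peptides straddling the junction with at
least one residue on each side — evidence a codon-specific frameshift;
in proteome mode, C-terminal peptides of truncated products ending
exactly at the junction are additionally accepted as evidence of
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .frameshift_proteome import TRANS_FRAME, TRUNCATED, FrameshiftRecord

CANONICAL_AMBIGUOUS = "canonical_ambiguous"
TRANS_FRAME_CHIMERA = "trans_frame_chimera"
OUT_OF_FRAME_ONLY = "out_of_frame_only"
TRUNCATION_CONSISTENT = "truncation_consistent"
UNMATCHED = "unmatched"

# precedence when a peptide maps to several records: the strongest
# frameshift evidence wins the primary class
_CLASS_RANK = {
    TRANS_FRAME_CHIMERA: 0,
    TRUNCATION_CONSISTENT: 1,
    OUT_OF_FRAME_ONLY: 2,
    CANONICAL_AMBIGUOUS: 3,
    UNMATCHED: 4,
}

PROTEOME_MODE = "proteome"
IMMUNO_MODE = "immuno"


@dataclass(frozen=True)
class ClassifiedPeptide:
    sequence: str
    peptide_class: str
    junction_residues: tuple[int, int] | None = None  # (n_in_frame, n_out_of_frame)
    target_codon: str | None = None
    matched_records: tuple[str, ...] = ()
    multi_mapping: bool = False


class CanonicalProteome:
    """Searchable canonical protein collection for exact-substring map-back.

    With ``il_equivalent`` both the proteome and queries collapse I to L,
    since mass spectrometry cannot distinguish the isobaric pair.
    """

    def __init__(self, proteins: Mapping[str, str] | Iterable[str], il_equivalent: bool = False):
        seqs = proteins.values() if isinstance(proteins, Mapping) else proteins
        self.il_equivalent = il_equivalent
        joined = "|".join(s.upper() for s in seqs)
        self._haystack = joined.replace("I", "L") if il_equivalent else joined

    def contains(self, sequence: str) -> bool:
        query = sequence.upper()
        if self.il_equivalent:
            query = query.replace("I", "L")
        return query in self._haystack


def map_to_canonical(
    sequence: str,
    canonical_proteome: CanonicalProteome | Mapping[str, str] | Iterable[str],
    il_equivalent: bool = False,
) -> bool:
    """True iff the peptide is an exact substring of any canonical protein."""
    if not isinstance(canonical_proteome, CanonicalProteome):
        canonical_proteome = CanonicalProteome(canonical_proteome, il_equivalent=il_equivalent)
    return canonical_proteome.contains(sequence)


def _classify_against_record(sequence: str, rec: FrameshiftRecord) -> list[tuple[str, tuple[int, int] | None]]:
    """All (class, junction_residues) assignments of a peptide within one record."""
    out: list[tuple[str, tuple[int, int] | None]] = []
    j = rec.prefix_len
    start = rec.product_seq.find(sequence)
    while start != -1:
        end = start + len(sequence)
        if rec.product_class == TRUNCATED:
            if end == j == len(rec.product_seq) and start < j:
                out.append((TRUNCATION_CONSISTENT, None))
            else:
                out.append((CANONICAL_AMBIGUOUS, None))
        elif start < j and end > j:
            out.append((TRANS_FRAME_CHIMERA, (j - start, end - j)))
        elif start >= j:
            out.append((OUT_OF_FRAME_ONLY, None))
        else:  # wholly on the in-frame side: could arise from normal translation
            out.append((CANONICAL_AMBIGUOUS, None))
        start = rec.product_seq.find(sequence, start + 1)
    return out


def classify_peptide(sequence: str, records: Sequence[FrameshiftRecord]) -> ClassifiedPeptide:
    """Locate a peptide in frameshift products and assign its primary class.

    A peptide spanning the junction (residues on both sides of index
    ``prefix_len``) is a trans-frame chimera. Peptides matching several
    records keep the strongest class and are flagged multi-mapping.
    """
    sequence = sequence.upper()
    best: tuple[str, tuple[int, int] | None] = (UNMATCHED, None)
    best_codon: str | None = None
    matched: list[str] = []
    for rec in records:
        assignments = _classify_against_record(sequence, rec)
        if assignments:
            matched.append(rec.header())
        for cls, junction in assignments:
            if _CLASS_RANK[cls] < _CLASS_RANK[best[0]]:
                best = (cls, junction)
                best_codon = rec.target_codon
    return ClassifiedPeptide(
        sequence=sequence,
        peptide_class=best[0],
        junction_residues=best[1],
        target_codon=best_codon if best[0] in (TRANS_FRAME_CHIMERA, TRUNCATION_CONSISTENT, OUT_OF_FRAME_ONLY) else None,
        matched_records=tuple(matched),
        multi_mapping=len(matched) > 1,
    )


def classify_hits(
    hits: pd.DataFrame,
    records: Sequence[FrameshiftRecord],
    canonical_proteome: CanonicalProteome,
    min_prob: float | None = None,
) -> dict[str, ClassifiedPeptide]:
    """Classify every distinct peptide sequence in a hit table.

    Canonical map-back runs first: any peptide that is a substring of the
    canonical proteome is canonical_ambiguous regardless of its frameshift
    matches. ``min_prob`` drops rows below a search-engine probability
    column when present.
    """
    if min_prob is not None and "probability" in hits.columns:
        hits = hits[hits["probability"] >= min_prob]
    out: dict[str, ClassifiedPeptide] = {}
    for seq in sorted(hits["sequence"].str.upper().unique()):
        if canonical_proteome.contains(seq):
            out[seq] = ClassifiedPeptide(sequence=seq, peptide_class=CANONICAL_AMBIGUOUS)
        else:
            out[seq] = classify_peptide(seq, records)
    return out


def filter_by_replicates(
    hits: pd.DataFrame,
    mode: str = PROTEOME_MODE,
    n_replicates: int | None = None,
    min_present: int | None = None,
) -> dict[str, set[str]]:
    """Replicate-presence filter; survival recorded per condition.

    Proteome mode keeps a sequence in a condition when it is present in
    ALL replicates of that condition (default 2); immuno mode when it is
    present in at least 2 of the (default 3) replicates. Returns
    {condition: surviving sequences}.
    """
    if mode not in (PROTEOME_MODE, IMMUNO_MODE):
        raise ValueError(f"unknown mode: {mode!r}")
    default_reps = 2 if mode == PROTEOME_MODE else 3
    n_reps = default_reps if n_replicates is None else n_replicates
    required = n_reps if mode == PROTEOME_MODE else (2 if min_present is None else min_present)
    minimum = 2 if mode == PROTEOME_MODE else required
    if n_reps < minimum:
        raise ValueError(
            f"{mode} mode requires at least {minimum} replicates, got {n_reps}"
        )

    survivors: dict[str, set[str]] = {}
    hits = hits.assign(sequence=hits["sequence"].str.upper())
    for cond, grp in hits.groupby("condition", sort=True):
        observed_reps = grp["replicate"].nunique()
        if observed_reps > n_reps:
            raise ValueError(
                f"condition {cond!r} has {observed_reps} replicates, expected <= {n_reps}"
            )
        pres = grp.groupby("sequence")["replicate"].nunique()
        survivors[str(cond)] = set(pres.index[pres >= required])
    return survivors


def summarize_induction(
    classified: Mapping[str, ClassifiedPeptide],
    survivors: Mapping[str, set[str]],
    treated: str = "treated",
    control: str = "control",
    mode: str = IMMUNO_MODE,
    target_codons: Sequence[str] = ("TTA", "CTA"),
) -> pd.DataFrame:
    """Treatment-specific induced peptides per target codon.

    A peptide counts when it survives the replicate filter in the treated
    condition but not in control, and its class is accepted by the mode:
    immuno mode accepts trans-frame chimeras only; proteome mode also
    accepts truncation-consistent peptides. Returns one row per target
    codon with the distinct-sequence count and the sequences themselves.
    """
    accepted = {TRANS_FRAME_CHIMERA}
    if mode == PROTEOME_MODE:
        accepted.add(TRUNCATION_CONSISTENT)
    treated_set = survivors.get(treated, set())
    control_set = survivors.get(control, set())
    specific = treated_set - control_set

    per_codon: dict[str, list[str]] = {c: [] for c in target_codons}
    for seq in sorted(specific):
        cp = classified.get(seq)
        if cp is None or cp.peptide_class not in accepted:
            continue
        if cp.target_codon in per_codon:
            per_codon[cp.target_codon].append(seq)
    return pd.DataFrame(
        [
            {
                "target_codon": codon,
                "n_induced": len(seqs),
                "sequences": ";".join(seqs),
            }
            for codon, seqs in per_codon.items()
        ]
    )
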