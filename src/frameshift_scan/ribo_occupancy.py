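"""Differential A-site codon occupancy and per-codon footprint density.

Ribosome-protected fragments (RPFs) are assigned an A-site codon at a
fixed +15 nt offset from the footprint's 5' end. Profiles of A-site codon
frequencies are compared between two conditions (e.g. leucine depletion
versus control) over genes passing a per-gene read-count floor in every
condition, in the style of differential ribosome codon reading. A second,
occurrence-level view normalizes the footprint count at each codon
occurrence by the gene's mean per-codon coverage and compares mean codon
densities between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .codons import GENETIC_CODE, STOP_CODONS, CodingSequence

A_SITE_OFFSET = 15  # nt from RPF 5' end to the A-site


class NoGenesPassFilterError(ValueError):
    """No gene met the per-gene minimum read count in every condition."""


@dataclass(frozen=True)
class RpfAlignment:
    """One footprint on a CDS: 0-based 5'-end offset and read length."""

    transcript_id: str
    five_prime_pos: int
    read_length: int


@dataclass
class CodonOccupancyProfile:
    """A-site codon counts for one condition over the retained gene set."""

    condition: str
    counts: dict[str, int]
    genes_retained: frozenset[str]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        if self.total == 0:
            raise ValueError(f"profile {self.condition!r} has zero total count")
        return {c: n / self.total for c, n in self.counts.items()}


def asite_codon(rpf: RpfAlignment, cds: CodingSequence, include_stop: bool = False) -> str | None:
    """Codon under the ribosomal A-site, or None if the assignment is invalid.

    The A-site nucleotide is ``five_prime_pos + 15``; the codon index is
    its floor division by 3 (off-frame footprints are floored onto the
    codon containing the A-site nucleotide). Returns None when the A-site
    falls before the CDS, past its last sense codon (or past the stop when
    ``include_stop``), or outside the read itself.
    """
    if A_SITE_OFFSET >= rpf.read_length:
        return None
    p = rpf.five_prime_pos + A_SITE_OFFSET
    if p < 0:
        return None
    idx = p // 3
    limit = cds.n_codons if include_stop else cds.n_sense_codons
    if idx >= limit:
        return None
    return cds.codon(idx)


def _asite_codon_indices(
    positions: np.ndarray, read_lengths: np.ndarray, n_codons_limit: int
) -> np.ndarray:
    """Vectorized A-site codon index per read; -1 where rejected."""
    p = positions + A_SITE_OFFSET
    idx = np.floor_divide(p, 3)
    ok = (p >= 0) & (idx < n_codons_limit) & (read_lengths > A_SITE_OFFSET)
    return np.where(ok, idx, -1)


def _assign_asites(
    alignments: pd.DataFrame, cds_set: Mapping[str, CodingSequence]
) -> pd.DataFrame:
    """Per-read A-site codon assignment; rejected reads dropped.

    Returns columns transcript_id, condition, codon_index, codon.
    """
    parts = []
    for tid, grp in alignments.groupby("transcript_id", sort=True):
        cds = cds_set.get(tid)
        if cds is None:
            continue
        idx = _asite_codon_indices(
            grp["five_prime_pos"].to_numpy(int),
            grp["read_length"].to_numpy(int),
            cds.n_sense_codons,
        )
        keep = idx >= 0
        if not keep.any():
            continue
        codon_arr = np.array(cds.codons(), dtype=object)
        sub = pd.DataFrame(
            {
                "transcript_id": tid,
                "condition": grp.loc[keep, "condition"].to_numpy(),
                "codon_index": idx[keep],
                "codon": codon_arr[idx[keep]],
            }
        )
        parts.append(sub)
    if not parts:
        return pd.DataFrame(columns=["transcript_id", "condition", "codon_index", "codon"])
    return pd.concat(parts, ignore_index=True)


def _retained_genes(assigned: pd.DataFrame, min_gene_reads: int) -> frozenset[str]:
    """Genes with >= min_gene_reads assigned reads in EVERY condition."""
    conditions = assigned["condition"].unique()
    per_gene = assigned.groupby(["transcript_id", "condition"]).size().unstack(fill_value=0)
    per_gene = per_gene.reindex(columns=conditions, fill_value=0)
    retained = per_gene.index[(per_gene >= min_gene_reads).all(axis=1)]
    if len(retained) == 0:
        raise NoGenesPassFilterError(
            f"no genes have >= {min_gene_reads} assigned reads in all conditions"
        )
    return frozenset(retained)


def count_asite_codons(
    alignments: pd.DataFrame,
    cds_set: Mapping[str, CodingSequence],
    min_gene_reads: int = 100,
    exclude_stop_codons: bool = True,
) -> dict[str, CodonOccupancyProfile]:
    """A-site codon occupancy profile per condition.

    Replicates are pooled within a condition. A gene is retained only if
    its assigned-read count reaches ``min_gene_reads`` in every condition,
    so all profiles share one retained-gene set. Stop codons never receive
    reads here (the A-site assignment stops at the last sense codon);
    ``exclude_stop_codons`` controls only which keys appear in the counts.
    """
    assigned = _assign_asites(alignments, cds_set)
    if assigned.empty:
        raise NoGenesPassFilterError("no reads could be assigned an A-site codon")
    retained = _retained_genes(assigned, min_gene_reads)
    assigned = assigned[assigned["transcript_id"].isin(retained)]

    codon_universe = [
        c for c in sorted(GENETIC_CODE) if not (exclude_stop_codons and c in STOP_CODONS)
    ]
    profiles: dict[str, CodonOccupancyProfile] = {}
    for cond, grp in assigned.groupby("condition", sort=True):
        counts = grp["codon"].value_counts().to_dict()
        profiles[str(cond)] = CodonOccupancyProfile(
            condition=str(cond),
            counts={c: int(counts.get(c, 0)) for c in codon_universe},
            genes_retained=retained,
        )
    return profiles


def differential_occupancy(
    profile_treat: CodonOccupancyProfile,
    profile_ctrl: CodonOccupancyProfile,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-codon log2 shift in A-site occupancy frequency, treated vs control.

    ``log2_shift = log2((f_treat + eps) / (f_ctrl + eps))``. The default
    pseudocount is 0.5/total per condition; pass 0 to disable (zero-count
    codons then give infinite shifts). Sorted by codon; includes the
    amino-acid grouping.
    """
    if profile_treat.genes_retained != profile_ctrl.genes_retained:
        raise ValueError("profiles were not built over the same retained genes")
    f_t = profile_treat.frequencies()
    f_c = profile_ctrl.frequencies()
    eps_t = 0.5 / profile_treat.total if pseudocount is None else pseudocount
    eps_c = 0.5 / profile_ctrl.total if pseudocount is None else pseudocount
    rows = []
    for codon in sorted(set(f_t) | set(f_c)):
        ft, fc = f_t.get(codon, 0.0), f_c.get(codon, 0.0)
        rows.append(
            {
                "codon": codon,
                "aa": GENETIC_CODE[codon],
                "count_ctrl": profile_ctrl.counts.get(codon, 0),
                "count_treat": profile_treat.counts.get(codon, 0),
                "freq_ctrl": fc,
                "freq_treat": ft,
                "log2_shift": math.log2((ft + eps_t) / (fc + eps_c)),
            }
        )
    return pd.DataFrame(rows)


def density_comparison(
    alignments: pd.DataFrame,
    cds_set: Mapping[str, CodingSequence],
    min_gene_reads: int = 25,
    treat: str | None = None,
    ctrl: str | None = None,
) -> pd.DataFrame:
    """Mean normalized per-occurrence codon density per condition and log2 ratio.

    For each retained gene (>= ``min_gene_reads`` assigned reads in every
    condition) the density of a codon occurrence is its A-site read count
    divided by the gene's mean reads per sense codon, so a uniform gene
    has density 1 everywhere and the measure is depth-invariant. Densities
    are averaged per codon type over all occurrences in retained genes.
    ``treat``/``ctrl`` name the conditions for the ratio (defaults: the
    lexicographically last / first condition).
    """
    assigned = _assign_asites(alignments, cds_set)
    if assigned.empty:
        raise NoGenesPassFilterError("no reads could be assigned an A-site codon")
    retained = _retained_genes(assigned, min_gene_reads)
    conditions = sorted(assigned["condition"].unique())
    if ctrl is None:
        ctrl = conditions[0]
    if treat is None:
        treat = conditions[-1]

    # occurrence-level densities: every sense-codon occurrence of every retained gene
    per_cond_occ: dict[str, list[pd.DataFrame]] = {c: [] for c in conditions}
    for tid in sorted(retained):
        cds = cds_set[tid]
        n_sense = cds.n_sense_codons
        occ_codons = pd.Series(cds.codons()[:n_sense], name="codon")
        gene_reads = assigned[assigned["transcript_id"] == tid]
        for cond in conditions:
            cond_reads = gene_reads[gene_reads["condition"] == cond]
            counts = np.bincount(cond_reads["codon_index"].to_numpy(int), minlength=n_sense)
            mean_cov = counts.sum() / n_sense
            dens = counts / mean_cov if mean_cov > 0 else np.zeros(n_sense)
            per_cond_occ[cond].append(pd.DataFrame({"codon": occ_codons, "density": dens}))

    rows = []
    occ_t = pd.concat(per_cond_occ[treat], ignore_index=True)
    occ_c = pd.concat(per_cond_occ[ctrl], ignore_index=True)
    mean_t = occ_t.groupby("codon")["density"].mean()
    mean_c = occ_c.groupby("codon")["density"].mean()
    n_occ = occ_t.groupby("codon").size()
    n_genes_per_codon = {
        codon: sum(codon in cds_set[tid].codons()[: cds_set[tid].n_sense_codons] for tid in retained)
        for codon in mean_t.index
    }
    for codon in sorted(mean_t.index):
        mt, mc = mean_t[codon], mean_c.get(codon, 0.0)
        ratio = math.log2(mt / mc) if mt > 0 and mc > 0 else float("nan")
        rows.append(
            {
                "codon": codon,
                "aa": GENETIC_CODE[codon],
                "mean_density_ctrl": mc,
                "mean_density_treat": mt,
                "log2_ratio": ratio,
                "n_occurrences": int(n_occ[codon]),
                "n_genes": n_genes_per_codon[codon],
            }
        )
    return pd.DataFrame(rows)
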