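"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the data shapes of a codon-stalling study without
any downloads: coding sequences with controlled in-frame TTA/CTA
placement, ribosome footprints whose A-site codons are drawn multinomially
with an elevated weight on the stall codon in the treated condition,
identified-peptide tables with planted trans-frame chimeras and canonical
peptides over a replicate layout, and paired negative-binomial mRNA counts
with log-normal protein intensities whose treated-condition effect can
depend on a gene's UUA content.

Every sub-generator draws from its own RNG stream spawned from the master
seed, so outputs are byte-identical for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, STOP_CODONS, CodingSequence
from .frameshift_proteome import TRANS_FRAME, FrameshiftRecord
from .ribo_occupancy import A_SITE_OFFSET

CONTROL = "control"
TREATED = "treated"


@dataclass(frozen=True)
class PeptidePlan:
    """Planted peptide layout for the classification pipeline.

    ``n_true_chimeras`` per target codon defaults to 8 TTA and 1 CTA
    treated-specific chimeras, the asymmetry characteristic of
    UUA-biased frameshift induction. Canonical peptides are substrings of
    the canonical proteome present in both conditions.
    """

    n_true_chimeras: Mapping[str, int] = field(
        default_factory=lambda: {"TTA": 8, "CTA": 1}
    )
    n_canonical: int = 5
    n_replicates: int = 3
    peptide_length: int = 9
    dropout: float = 0.0


@dataclass(frozen=True)
class ExpressionPlan:
    """Negative-binomial mRNA counts paired with log-normal intensities.

    Dispersion 0.1 and a log-normal replicate scale of 0.5 resemble bulk
    RNA-seq and label-free proteomics spread. ``te_effect`` multiplies the
    treated-condition protein intensity as a function of the gene's UUA
    count (identity 1.0 = null).
    """

    n_replicates: int = 2
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    intensity_log_mean: float = np.log(1e6)
    intensity_log_scale: float = 0.5
    te_effect: Callable[[int], float] | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the standard stalling scenario: 200 genes, 1,000
    footprints per gene per condition, a 5-fold A-site stalling weight on
    TTA in the treated condition, footprint lengths 28-30 nt, and two
    planted in-frame occurrences of each rare leucine codon per gene.
    """

    seed: int = 42
    n_genes: int = 200
    cds_length_range: tuple[int, int] = (60, 120)  # total codons incl. stop
    planted_targets: Mapping[str, int] = field(
        default_factory=lambda: {"TTA": 2, "CTA": 2}
    )
    stall_codon: str = "TTA"
    stall_factor: float = 5.0
    reads_per_gene: int = 1000
    read_length_range: tuple[int, int] = (28, 30)
    frame_jitter_probs: tuple[float, float, float] = (0.9, 0.05, 0.05)  # P(0), P(+1), P(-1)
    peptides: PeptidePlan = field(default_factory=PeptidePlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("cds", "rpf", "peptides", "expression")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_MIN_TARGET_CODON_INDEX = 6  # keep planted targets clear of the first codons


def generate_cds_set(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[CodingSequence]:
    """Valid coding sequences with exact planted in-frame target counts.

    Body codons are drawn uniformly from sense codons excluding the
    target codons, so each gene contains exactly the planted number of
    in-frame TTA/CTA, placed at codon indices >= 6 so A-site reads can
    cover them.
    """
    if rng is None:
        rng = config.streams()["cds"]
    targets = dict(config.planted_targets)
    total_planted = sum(targets.values())
    lo, hi = config.cds_length_range
    if lo - 2 - _MIN_TARGET_CODON_INDEX + 1 < total_planted:
        raise ValueError("cds_length_range too short for the planted target count")
    body_codons = np.array([c for c in SENSE_CODONS if c not in targets], dtype=object)
    stops = sorted(STOP_CODONS)
    out: list[CodingSequence] = []
    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        # codon indices 1 .. n_codons-2 are free sense positions
        codons = ["ATG"] + list(rng.choice(body_codons, size=n_codons - 2)) + [stops[int(rng.integers(3))]]
        slots = np.arange(_MIN_TARGET_CODON_INDEX, n_codons - 1)
        chosen = rng.choice(slots, size=total_planted, replace=False)
        flat_targets = [t for t, n in sorted(targets.items()) for _ in range(n)]
        for pos, codon in zip(chosen, flat_targets):
            codons[int(pos)] = codon
        out.append(CodingSequence(id=f"gene{g:04d}", seq="".join(codons)))
    return out


def simulate_rpf(
    cds_set: Sequence[CodingSequence],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Footprint table for control (stall weight 1) and treated conditions.

    Per gene and condition, A-site codon indices are drawn multinomially
    over codons 5..last-sense with weight ``stall_factor`` on the stall
    codon (treated only); the 5'-end position is 3*index - 15 plus a
    small frame jitter, and read lengths are uniform on the configured
    range.
    """
    if rng is None:
        rng = config.streams()["rpf"]
    jitter_vals = np.array([0, 1, -1])
    jp = np.asarray(config.frame_jitter_probs, dtype=float)
    jp = jp / jp.sum()
    len_lo, len_hi = config.read_length_range
    rows = []
    for cds in cds_set:
        codons = np.array(cds.codons()[: cds.n_sense_codons], dtype=object)
        candidates = np.arange(5, cds.n_sense_codons)
        is_stall = codons[candidates] == config.stall_codon
        for condition, factor in ((CONTROL, 1.0), (TREATED, config.stall_factor)):
            w = np.where(is_stall, factor, 1.0)
            counts = rng.multinomial(config.reads_per_gene, w / w.sum())
            idx = np.repeat(candidates, counts)
            jitter = jitter_vals[rng.choice(3, size=idx.size, p=jp)]
            five_prime = 3 * idx - A_SITE_OFFSET + jitter
            lengths = rng.integers(len_lo, len_hi + 1, size=idx.size)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": cds.id,
                        "five_prime_pos": five_prime,
                        "read_length": lengths,
                        "condition": condition,
                        "replicate": 1,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class PeptidePlantingError(RuntimeError):
    """No junction-spanning peptide could be planted for a record set."""


def _sample_chimeric_peptide(
    records: Sequence[FrameshiftRecord],
    codon: str,
    length: int,
    forbidden_in: str,
    taken: set[str],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    pool = [
        r
        for r in records
        if r.product_class == TRANS_FRAME
        and r.target_codon == codon
        and r.prefix_len >= 1
        and len(r.extension) >= 1
        and len(r.product_seq) >= length
    ]
    if not pool:
        raise PeptidePlantingError(f"no trans-frame products available for {codon}")
    for _ in range(max_tries):
        rec = pool[int(rng.integers(len(pool)))]
        j = rec.prefix_len
        lo = max(0, j - length + 1)
        hi = min(j - 1, len(rec.product_seq) - length)
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        pep = rec.product_seq[start : start + length]
        if pep in taken or pep in forbidden_in:
            continue
        # unambiguous planting: the peptide must not span a junction in any
        # record of a different target codon
        spanned = set()
        for other in records:
            j = other.prefix_len
            s = other.product_seq.find(pep)
            while s != -1:
                if s < j < s + length:
                    spanned.add(other.target_codon)
                s = other.product_seq.find(pep, s + 1)
        if spanned != {codon}:
            continue
        return pep
    raise PeptidePlantingError(
        f"could not plant a unique junction-spanning {length}-mer for {codon}"
    )


def simulate_peptides(
    frameshift_db: Sequence[FrameshiftRecord],
    canonical_proteome: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-hit table plus the planted truth table.

    True chimeras are junction-spanning substrings of trans-frame
    products, checked absent from the canonical proteome, planted only in
    treated replicates; canonical peptides are substrings of canonical
    proteins planted in both conditions. Each planned presence survives a
    replicate with probability 1 - dropout.
    """
    if rng is None:
        rng = config.streams()["peptides"]
    plan = config.peptides
    haystack = "|".join(canonical_proteome[k] for k in sorted(canonical_proteome))
    taken: set[str] = set()

    truth_rows = []
    for codon in sorted(plan.n_true_chimeras):
        for _ in range(plan.n_true_chimeras[codon]):
            pep = _sample_chimeric_peptide(
                frameshift_db, codon, plan.peptide_length, haystack, taken, rng
            )
            taken.add(pep)
            truth_rows.append(
                {
                    "sequence": pep,
                    "planted_class": "trans_frame_chimera",
                    "target_codon": codon,
                    "treated_specific": True,
                }
            )
    protein_ids = sorted(canonical_proteome)
    for _ in range(plan.n_canonical):
        for _ in range(200):
            prot = canonical_proteome[protein_ids[int(rng.integers(len(protein_ids)))]]
            if len(prot) < plan.peptide_length:
                continue
            start = int(rng.integers(0, len(prot) - plan.peptide_length + 1))
            pep = prot[start : start + plan.peptide_length]
            if pep not in taken:
                break
        else:
            raise PeptidePlantingError("could not plant a unique canonical peptide")
        taken.add(pep)
        truth_rows.append(
            {
                "sequence": pep,
                "planted_class": "canonical_ambiguous",
                "target_codon": "",
                "treated_specific": False,
            }
        )
    truth = pd.DataFrame(truth_rows)

    hit_rows = []
    for row in truth.itertuples(index=False):
        conditions = (TREATED,) if row.treated_specific else (CONTROL, TREATED)
        for cond in conditions:
            for rep in range(1, plan.n_replicates + 1):
                if rng.random() < plan.dropout:
                    continue
                hit_rows.append(
                    {
                        "sequence": row.sequence,
                        "sample_id": f"{cond}_rep{rep}",
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    hits = pd.DataFrame(
        hit_rows, columns=["sequence", "sample_id", "condition", "replicate"]
    )
    return hits, truth


def simulate_expression(
    uua_counts: Mapping[str, int],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and intensity tables for control/treated with replicates.

    Counts are negative-binomial around a gene-specific mean; intensities
    are log-normal around a gene-specific level, multiplied in the
    treated condition by ``te_effect(uua_count)`` when configured.
    """
    if rng is None:
        rng = config.streams()["expression"]
    plan = config.expression
    genes = sorted(uua_counts)
    n = len(genes)
    disp = plan.nb_dispersion
    nb_n = 1.0 / disp

    gene_mean = plan.nb_mean * rng.lognormal(0.0, 0.5, size=n)
    gene_level = rng.lognormal(plan.intensity_log_mean, 1.0, size=n)
    effect = np.array(
        [plan.te_effect(uua_counts[g]) if plan.te_effect else 1.0 for g in genes]
    )

    count_rows, intens_rows = [], []
    for cond in (CONTROL, TREATED):
        for rep in range(1, plan.n_replicates + 1):
            p = nb_n / (nb_n + gene_mean)
            counts = rng.negative_binomial(nb_n, p)
            mult = effect if cond == TREATED else 1.0
            intens = gene_level * mult * rng.lognormal(0.0, plan.intensity_log_scale, size=n)
            count_rows.append(
                pd.DataFrame(
                    {"gene_id": genes, "condition": cond, "replicate": rep, "count": counts}
                )
            )
            intens_rows.append(
                pd.DataFrame(
                    {"gene_id": genes, "condition": cond, "replicate": rep, "intensity": intens}
                )
            )
    return pd.concat(count_rows, ignore_index=True), pd.concat(intens_rows, ignore_index=True)


def simulate_uua_counts(
    n_genes: int,
    rng: np.random.Generator,
    mean: float = 1.2,
) -> dict[str, int]:
    """Poisson-distributed per-gene UUA counts for expression-only runs."""
    draws = rng.poisson(mean, size=n_genes)
    return {f"gene{g:04d}": int(u) for g, u in enumerate(draws)}


def te_effect_threshold(uua_min: int, multiplier: float) -> Callable[[int], float]:
    """Treated-condition TE multiplier applied to genes with uua >= uua_min."""

    def effect(uua: int) -> float:
        return multiplier if uua >= uua_min else 1.0

    return effect


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
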