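"""Translation-efficiency integration binned by UUA codon content.

Per-gene protein intensities and (floored) normalized mRNA counts are
combined into a translation-efficiency (TE) ratio per condition,
TE = mean protein intensity / mean floored mRNA count, and the
treated/control TE ratio is reported on the log2 scale. Each gene carries
the in-frame TTA (UUA) codon count of its canonical transcript — the
longest transcript with an intact ORF — and per-gene log2 ratios are
binned by UUA content for a rank-based comparison against the 0-UUA bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CodingSequence, InvalidSequenceError, find_target_codons

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 10.0
PRESENCE_SCHEME = "presence"
CONTENT_SCHEME = "content_bins"
DEFAULT_CONTENT_EDGES = (0, 1, 2, 3)  # bins {0, 1, 2, 3, >=4}


@dataclass(frozen=True)
class CanonicalAssignment:
    gene_id: str
    transcript_id: str
    cds_length: int
    uua_count: int


def select_canonical(
    gene_id: str, transcripts: Iterable[tuple[str, str]]
) -> CanonicalAssignment | None:
    """Pick the gene's canonical transcript: longest valid ORF, ties by id.

    ``transcripts`` are (transcript_id, nucleotide seq) pairs. Transcripts
    without a valid ORF (ATG start, terminal stop, no internal stop) are
    ignored; a gene with none is dropped (returns None, warning logged).
    """
    candidates: list[tuple[int, str, CodingSequence]] = []
    for tid, seq in transcripts:
        try:
            cds = CodingSequence.from_raw(tid, seq)
        except InvalidSequenceError:
            continue
        candidates.append((len(cds.seq), tid, cds))
    if not candidates:
        logger.warning("gene %s: no transcript with a valid ORF; dropped", gene_id)
        return None
    candidates.sort(key=lambda t: (-t[0], t[1]))
    length, tid, cds = candidates[0]
    return CanonicalAssignment(
        gene_id=gene_id,
        transcript_id=tid,
        cds_length=length,
        uua_count=len(find_target_codons(cds, {"TTA"})),
    )


def assign_canonical(
    gene_map: pd.DataFrame, cds_set: Mapping[str, CodingSequence]
) -> pd.DataFrame:
    """Canonical assignment for every gene in a gene_id/transcript_id map."""
    rows = []
    for gene_id, grp in gene_map.groupby("gene_id", sort=True):
        pairs = [
            (tid, cds_set[tid].seq)
            for tid in grp["transcript_id"]
            if tid in cds_set
        ]
        ca = select_canonical(str(gene_id), pairs)
        if ca is not None:
            rows.append(vars(ca))
    return pd.DataFrame(rows)


def floor_counts(counts, floor: float = DEFAULT_FLOOR):
    """Replace every count by max(count, floor); idempotent, rejects negatives."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts are not valid read counts")
    floored = np.maximum(arr, floor)
    if np.isscalar(counts) or arr.ndim == 0:
        return float(floored)
    return floored


def _condition_means(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Mean of value_col over replicates, per gene x condition (wide)."""
    return (
        df.groupby(["gene_id", "condition"])[value_col].mean().unstack("condition")
    )


def translation_efficiency(
    counts: pd.DataFrame,
    intensities: pd.DataFrame,
    treated: str = "treated",
    control: str = "control",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-gene TE per condition and the log2 treated/control TE ratio.

    ``counts``/``intensities`` are long tables (gene_id, condition,
    replicate, count|intensity). mRNA counts are floored before averaging;
    intensities are not. Genes missing either measurement in either
    condition are dropped; genes with zero mean control intensity get a
    NaN ratio and are flagged.
    """
    counts = counts.assign(count=floor_counts(counts["count"].to_numpy(), floor))
    mean_counts = _condition_means(counts, "count")
    mean_intens = _condition_means(intensities, "intensity")
    for df, name in ((mean_counts, "counts"), (mean_intens, "intensities")):
        for cond in (treated, control):
            if cond not in df.columns:
                raise ValueError(f"{name} table has no condition {cond!r}")

    genes = mean_counts.index.intersection(mean_intens.index)
    mc = mean_counts.loc[genes]
    mi = mean_intens.loc[genes]
    complete = mc[[treated, control]].notna().all(axis=1) & mi[[treated, control]].notna().all(axis=1)
    mc, mi = mc[complete], mi[complete]

    te_treat = mi[treated] / mc[treated]
    te_ctrl = mi[control] / mc[control]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = te_treat / te_ctrl
        log2_ratio = np.log2(ratio)
    out = pd.DataFrame(
        {
            "gene_id": mc.index,
            "mean_count_ctrl": mc[control].to_numpy(),
            "mean_count_treat": mc[treated].to_numpy(),
            "mean_intensity_ctrl": mi[control].to_numpy(),
            "mean_intensity_treat": mi[treated].to_numpy(),
            "te_ctrl": te_ctrl.to_numpy(),
            "te_treat": te_treat.to_numpy(),
            "log2_te_ratio": log2_ratio.to_numpy(),
        }
    ).reset_index(drop=True)
    out["ratio_undefined"] = ~np.isfinite(out["log2_te_ratio"])
    return out


def rna_log2_ratio(
    counts: pd.DataFrame,
    treated: str = "treated",
    control: str = "control",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-gene log2 ratio of mean floored counts, treated / control."""
    counts = counts.assign(count=floor_counts(counts["count"].to_numpy(), floor))
    means = _condition_means(counts, "count")
    for cond in (treated, control):
        if cond not in means.columns:
            raise ValueError(f"counts table has no condition {cond!r}")
    means = means.dropna(subset=[treated, control])
    return pd.DataFrame(
        {
            "gene_id": means.index,
            "log2_ratio": np.log2(means[treated] / means[control]).to_numpy(),
        }
    ).reset_index(drop=True)


def _bin_label(uua: int, scheme: str, edges: Sequence[int]) -> str:
    if scheme == PRESENCE_SCHEME:
        return "0" if uua == 0 else ">=1"
    last = edges[-1]
    for e in edges:
        if uua == e:
            return str(e)
    return f">={last + 1}"


def bin_and_compare(
    values: pd.DataFrame,
    uua_counts: Mapping[str, int] | pd.Series,
    scheme: str = PRESENCE_SCHEME,
    edges: Sequence[int] = DEFAULT_CONTENT_EDGES,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Bin per-gene log2 ratios by UUA content and test each bin vs 0 UUA.

    ``values`` has gene_id plus one value column (auto-detected from
    log2_te_ratio / log2_ratio unless ``value_col`` is given). Presence
    scheme bins {0, >=1}; content scheme bins {0, 1, 2, 3, >=4} by
    default. Each non-reference bin is compared to the 0-UUA bin with a
    two-sided Wilcoxon rank-sum test; empty bins report n=0 and no test.
    """
    if scheme not in (PRESENCE_SCHEME, CONTENT_SCHEME):
        raise ValueError(f"unknown binning scheme: {scheme!r}")
    if value_col is None:
        for cand in ("log2_te_ratio", "log2_ratio", "value"):
            if cand in values.columns:
                value_col = cand
                break
        else:
            raise ValueError("could not infer value column")
    uua = pd.Series(dict(uua_counts)) if not isinstance(uua_counts, pd.Series) else uua_counts

    df = values[["gene_id", value_col]].copy()
    df = df[np.isfinite(df[value_col])]
    df["uua_count"] = df["gene_id"].map(uua)
    df = df.dropna(subset=["uua_count"])
    df["bin"] = [
        _bin_label(int(u), scheme, edges) for u in df["uua_count"]
    ]

    if scheme == PRESENCE_SCHEME:
        bin_order = ["0", ">=1"]
    else:
        bin_order = [str(e) for e in edges] + [f">={edges[-1] + 1}"]
    ref = df.loc[df["bin"] == "0", value_col].to_numpy()

    rows = []
    for label in bin_order:
        vals = df.loc[df["bin"] == label, value_col].to_numpy()
        row = {
            "bin": label,
            "n": len(vals),
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "q1": float(np.quantile(vals, 0.25)) if len(vals) else np.nan,
            "q3": float(np.quantile(vals, 0.75)) if len(vals) else np.nan,
            "p_vs_zero_bin": np.nan,
        }
        if label != "0" and len(vals) and len(ref):
            row["p_vs_zero_bin"] = float(stats.ranksums(vals, ref).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
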