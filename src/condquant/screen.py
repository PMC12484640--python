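"""Pooled CRISPR screen scoring.

Guide counts from two timepoints (T0 and a late passage) per cell line are
normalized to counts-per-hundred-thousand, converted to per-sgRNA
log2 fold changes log2(T_late / T0) with a pseudocount guard, aggregated to
gene level by the median across a gene's guides, and partitioned into
shared and cell-line-specific depleted candidates at a log2FC cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenCounts",
    "CandidateSets",
    "normalize_counts",
    "sgrna_log2fc",
    "gene_score",
    "classify_candidates",
    "score_screen",
    "tumor_volume",
]

NORMALIZATION_SCALE = 100_000.0


@dataclass
class ScreenCounts:
    """sgRNA x sample count matrix with a guide-to-gene map and sample sheet.

    ``counts`` is indexed by sgRNA id with one integer column per sample;
    ``guide_map`` maps each sgRNA to exactly one gene; ``samples`` has one
    row per sample with columns ``sample``, ``cell_line``, ``timepoint``
    (timepoint in {"T0", "T_late"}).
    """

    counts: pd.DataFrame
    guide_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.guide_map.index)
        if missing:
            raise ValueError(f"sgRNAs without a gene mapping: {sorted(missing)[:5]}")
        bad_tp = set(self.samples["timepoint"]) - {"T0", "T_late"}
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        for line, grp in self.samples.groupby("cell_line"):
            if set(grp["timepoint"]) != {"T0", "T_late"}:
                raise ValueError(f"cell line {line!r} lacks both timepoints")

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   samples: pd.DataFrame) -> "ScreenCounts":
        """Build from a long table with ``sgrna``/``gene`` + count columns."""
        counts = table.set_index("sgrna").drop(columns=["gene"])
        guide_map = table.set_index("sgrna")["gene"]
        return cls(counts=counts, guide_map=guide_map, samples=samples)

    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_line"]))


@dataclass
class CandidateSets:
    """Shared and per-line-specific depleted gene sets plus the scatter table."""

    shared: frozenset[str]
    specific: dict[str, frozenset[str]]
    table: pd.DataFrame  # gene, <line> score columns, category
    cutoff: float


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-hundred-thousand: 100,000 * count / column total.

    Every normalized column sums to 100,000; a zero-total column is an
    error naming the sample.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero total read count in sample(s): {zero}")
    return counts / totals * NORMALIZATION_SCALE


def sgrna_log2fc(normalized: pd.DataFrame, samples: pd.DataFrame,
                 cell_line: str, pseudocount: float = 1.0) -> pd.Series:
    """Per-sgRNA log2((T_late + pc) / (T0 + pc)) for one cell line.

    Replicate columns within a timepoint are averaged on the normalized
    scale before the fold change.
    """
    line = samples[samples["cell_line"] == cell_line]
    if line.empty:
        raise KeyError(f"unknown cell line {cell_line!r}")
    t0_cols = line.loc[line["timepoint"] == "T0", "sample"].tolist()
    late_cols = line.loc[line["timepoint"] == "T_late", "sample"].tolist()
    t0 = normalized[t0_cols].mean(axis=1)
    late = normalized[late_cols].mean(axis=1)
    lfc = np.log2((late + pseudocount) / (t0 + pseudocount))
    lfc.name = f"{cell_line}_log2fc"
    return lfc


def gene_score(sgrna_lfc: pd.Series, guide_map: pd.Series) -> pd.DataFrame:
    """Gene-level aggregate: median of the gene's sgRNA log2FCs.

    Also reports the mean and the number of guides; genes without guides are
    simply absent.
    """
    df = pd.DataFrame({"log2fc": sgrna_lfc, "gene": guide_map.loc[sgrna_lfc.index]})
    agg = df.groupby("gene")["log2fc"].agg(
        median_log2fc="median", mean_log2fc="mean", n_sgrna="size"
    )
    agg["n_sgrna"] = agg["n_sgrna"].astype(int)
    return agg.reset_index()


def classify_candidates(gene_scores: dict[str, pd.DataFrame],
                        depletion_cutoff: float = -1.0) -> CandidateSets:
    """Partition depleted genes into shared and cell-line-specific sets.

    A gene is a hit in a line when its median log2FC is at most
    ``depletion_cutoff``; shared = hit in every line, specific = hit in
    exactly one.  The returned table underlies a per-line scatter plot.
    """
    if len(gene_scores) < 2:
        raise ValueError("need scores for at least 2 cell lines")
    lines = list(gene_scores)
    merged: pd.DataFrame | None = None
    for line in lines:
        part = gene_scores[line][["gene", "median_log2fc"]].rename(
            columns={"median_log2fc": line}
        )
        merged = part if merged is None else merged.merge(part, on="gene", how="outer")
    assert merged is not None
    hit = merged[lines] <= depletion_cutoff
    n_hits = hit.sum(axis=1)
    category = np.where(
        n_hits == len(lines), "shared",
        np.where(n_hits == 0, "none",
                 [f"{lines[int(row.argmax())]}_specific" if n == 1 else "partial"
                  for n, row in zip(n_hits, hit.values)]),
    )
    merged = merged.assign(category=category)
    shared = frozenset(merged.loc[merged["category"] == "shared", "gene"])
    specific = {
        line: frozenset(
            merged.loc[merged["category"] == f"{line}_specific", "gene"]
        )
        for line in lines
    }
    return CandidateSets(shared=shared, specific=specific, table=merged,
                         cutoff=depletion_cutoff)


def score_screen(counts: ScreenCounts, pseudocount: float = 1.0,
                 depletion_cutoff: float = -1.0
                 ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], CandidateSets]:
    """Normalize, fold-change and classify in one pass.

    Returns (normalized matrix, per-line gene score tables, candidate sets).
    """
    normalized = normalize_counts(counts.counts)
    scores = {
        line: gene_score(
            sgrna_log2fc(normalized, counts.samples, line, pseudocount),
            counts.guide_map,
        )
        for line in counts.lines()
    }
    candidates = classify_candidates(scores, depletion_cutoff)
    return normalized, scores, candidates


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft tumor volume: length x width^2 x 0.52 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be non-negative")
    return length_mm * width_mm**2 * 0.52
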