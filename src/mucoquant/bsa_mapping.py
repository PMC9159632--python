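"""Pooled-segregant mapping of a causal locus (bulk segregant analysis).

Given per-site read counts for a mutant-phenotype pool and a wildtype pool,
each site is scored with the **allelic contrast** — the difference of pool
alt-allele frequencies — which is 0 where the two pools segregate alike and
approaches 1 at a site where the mutant pool is fixed for the alt allele and
the wildtype pool for the reference.  Scores are smoothed per chromosome
with a centred sliding window, normalized to a genome-wide maximum of 1,
scanned for the peak region, and the region is refiltered for candidate
variants in which the mutant (but not the wildtype) pool looks homozygous,
ranked by predicted functional impact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InputError, MeasurementError

logger = logging.getLogger(__name__)

IMPACT_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3, "NONE": 4}


def contrast_score(mut_alt: int, mut_depth: int, wt_alt: int, wt_depth: int) -> float:
    """Pool allele-frequency difference ``mut_alt/mut_depth - wt_alt/wt_depth``.

    In [-1, 1]; antisymmetric under swapping the pools.  Raises on zero depth
    in either pool (such sites carry no frequency information).
    """
    if mut_depth <= 0 or wt_depth <= 0:
        raise MeasurementError("contrast undefined at zero depth")
    return mut_alt / mut_depth - wt_alt / wt_depth


@dataclass
class LinkageTrack:
    """Per-site raw, smoothed and genome-normalized contrast scores.

    ``data`` has columns ``chrom, pos, raw, smoothed, normalized`` sorted by
    (chromosome appearance order, position); ``normalized`` peaks at exactly
    1 when any smoothed score is positive.
    """

    data: pd.DataFrame
    min_depth: int
    window_bp: int

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]


def _sliding_window_mean(positions: np.ndarray, values: np.ndarray, window_bp: int) -> np.ndarray:
    """Centred mean of ``values`` over sites within +/- window_bp/2 of each site."""
    half = window_bp / 2.0
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    return (csum[hi] - csum[lo]) / (hi - lo)


def build_linkage_track(
    sites: pd.DataFrame, min_depth: int = 100, window_bp: int = 200_000
) -> LinkageTrack:
    """Coverage-filter sites and build the smoothed, normalized contrast track.

    Sites with depth below ``min_depth`` in either pool are excluded (the
    exclusion count is logged).  Smoothing is a centred sliding-window mean
    of width ``window_bp`` per chromosome; normalization divides by the
    genome-wide maximum of the smoothed score (an all-nonpositive genome
    stays all zeros rather than dividing).
    """
    required = {"chrom", "pos", "mut_depth", "mut_alt", "wt_depth", "wt_alt"}
    if not required.issubset(sites.columns):
        raise InputError(f"sites table missing columns {sorted(required - set(sites.columns))}")
    kept = sites[(sites["mut_depth"] >= min_depth) & (sites["wt_depth"] >= min_depth)].copy()
    logger.info("coverage filter (>= %dx both pools): %d of %d sites kept",
                min_depth, len(kept), len(sites))
    if kept.empty:
        raise EmptyResultError(f"no sites with >= {min_depth}x coverage in both pools")
    chrom_order = {c: i for i, c in enumerate(pd.unique(kept["chrom"]))}
    kept["_order"] = kept["chrom"].map(chrom_order)
    kept = kept.sort_values(["_order", "pos"], kind="mergesort").drop(columns="_order")
    kept["raw"] = kept["mut_alt"] / kept["mut_depth"] - kept["wt_alt"] / kept["wt_depth"]
    smoothed = np.empty(len(kept))
    start = 0
    for _, group in kept.groupby("chrom", sort=False):
        n = len(group)
        smoothed[start : start + n] = _sliding_window_mean(
            group["pos"].to_numpy(float), group["raw"].to_numpy(float), window_bp
        )
        start += n
    kept["smoothed"] = smoothed
    peak = smoothed.max()
    kept["normalized"] = smoothed / peak if peak > 0 else 0.0
    columns = ["chrom", "pos", "raw", "smoothed", "normalized"]
    return LinkageTrack(kept.reset_index(drop=True)[columns + ["mut_depth", "mut_alt", "wt_depth", "wt_alt"]],
                        min_depth=min_depth, window_bp=window_bp)


def find_peak_region(track: LinkageTrack, frac_of_max: float = 0.9) -> tuple[str, int, int]:
    """Peak region: the longest contiguous run of sites at >= ``frac_of_max``
    of the genome maximum, on the chromosome carrying that maximum.

    Among equally long runs the one containing the global maximum wins,
    otherwise the leftmost.  Returns ``(chrom, start_bp, end_bp)`` with
    inclusive 1-based bounds.
    """
    data = track.data
    if data.empty or data["normalized"].max() <= 0:
        raise EmptyResultError("track has no positive signal; no peak to report")
    top_idx = int(data["normalized"].idxmax())
    chrom = data.at[top_idx, "chrom"]
    sub = track.chromosome(chrom).reset_index()
    above = (sub["normalized"] >= frac_of_max).to_numpy()
    pos_in_sub = int(np.flatnonzero(sub["index"] == top_idx)[0])
    # enumerate contiguous runs of above-threshold sites
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive index bounds
    lengths = ends - starts + 1
    best = lengths.max()
    candidates = np.flatnonzero(lengths == best)
    chosen = candidates[0]
    for c in candidates:
        if starts[c] <= pos_in_sub <= ends[c]:
            chosen = c
            break
    return (
        str(chrom),
        int(sub.at[int(starts[chosen]), "pos"]),
        int(sub.at[int(ends[chosen]), "pos"]),
    )


def candidate_variants(
    sites: pd.DataFrame,
    region: tuple[str, int, int],
    min_depth: int = 5,
    hom_threshold: float = 0.9,
) -> pd.DataFrame:
    """Candidate causal variants inside the peak region, ranked by impact.

    Keeps sites with depth >= ``min_depth`` in both pools whose mutant-pool
    alt frequency reaches ``hom_threshold`` (mutant pool homozygous-looking)
    while the wildtype pool's stays below it; sorts by impact severity
    (HIGH > MODERATE > LOW > MODIFIER > NONE), then descending contrast,
    then position.
    """
    chrom, start, end = region
    sel = sites[
        (sites["chrom"] == chrom)
        & (sites["pos"] >= start)
        & (sites["pos"] <= end)
        & (sites["mut_depth"] >= min_depth)
        & (sites["wt_depth"] >= min_depth)
    ].copy()
    if sel.empty:
        return sel.assign(mut_alt_freq=[], wt_alt_freq=[], contrast=[], impact_rank=[])
    sel["mut_alt_freq"] = sel["mut_alt"] / sel["mut_depth"]
    sel["wt_alt_freq"] = sel["wt_alt"] / sel["wt_depth"]
    sel = sel[(sel["mut_alt_freq"] >= hom_threshold) & (sel["wt_alt_freq"] < hom_threshold)]
    sel["contrast"] = sel["mut_alt_freq"] - sel["wt_alt_freq"]
    impact = sel.get("impact", pd.Series("NONE", index=sel.index))
    sel["impact_rank"] = impact.map(IMPACT_RANK).fillna(IMPACT_RANK["NONE"]).astype(int)
    sel = sel.sort_values(
        ["impact_rank", "contrast", "pos"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return sel.reset_index(drop=True)


def region_to_bed(region: tuple[str, int, int]) -> str:
    """Format a peak region as a one-line BED record (0-based half-open)."""
    chrom, start, end = region
    return f"{chrom}\t{start - 1}\t{end}\n"
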