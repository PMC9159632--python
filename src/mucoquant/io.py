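"""File input/output and the core image container.

Micrographs travel as 3-page TIFFs (page 0 = Grl channel, page 1 = Mdl
channel, page 2 = cell mask as 0/255) with the pixel size stored as JSON in
the first page description.  Pooled variant tables travel as VCF 4.2 with two
samples, ``MUT`` and ``WT``, per-sample ``DP``/``AD`` and an ``IMPACT`` INFO
field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import tifffile

from .errors import InputError

#: canonical column order of a pooled variant-site table
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "mut_depth",
    "mut_alt",
    "wt_depth",
    "wt_alt",
    "impact",
]

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER", "NONE")


@dataclass
class Micrograph:
    """Two registered fluorescence channels plus the cell outline.

    Attributes
    ----------
    grl_channel, mdl_channel
        2-D non-negative float intensity arrays of identical shape.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    cell_mask
        Boolean array marking the cell interior; at least one True pixel.
    """

    grl_channel: np.ndarray
    mdl_channel: np.ndarray
    pixel_size: float
    cell_mask: np.ndarray

    def __post_init__(self) -> None:
        self.grl_channel = np.asarray(self.grl_channel, dtype=float)
        self.mdl_channel = np.asarray(self.mdl_channel, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.grl_channel.ndim != 2:
            raise InputError("channels must be 2-D")
        if not (self.grl_channel.shape == self.mdl_channel.shape == self.cell_mask.shape):
            raise InputError("channels and cell mask must share one shape")
        for name in ("grl_channel", "mdl_channel"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise InputError(f"{name} contains non-finite intensities")
            if arr.min() < 0:
                raise InputError(f"{name} contains negative intensities")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")
        if not self.cell_mask.any():
            raise InputError("cell mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grl_channel.shape


def write_micrograph(micrograph: Micrograph, path: str | Path) -> None:
    """Write a micrograph as a 3-page TIFF (Grl, Mdl, mask as 0/255)."""
    meta = json.dumps({"pixel_size_um": micrograph.pixel_size})
    with tifffile.TiffWriter(str(path)) as tif:
        tif.write(micrograph.grl_channel.astype(np.float32), description=meta)
        tif.write(micrograph.mdl_channel.astype(np.float32))
        tif.write((micrograph.cell_mask.astype(np.uint8)) * 255)


def read_micrograph(path: str | Path, pixel_size: float | None = None) -> Micrograph:
    """Read a micrograph written by :func:`write_micrograph`.

    ``pixel_size`` overrides the value stored in the file (required if the
    file carries none).
    """
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) < 3:
            raise InputError(f"{path}: expected 3 pages (grl, mdl, mask)")
        grl = tif.pages[0].asarray()
        mdl = tif.pages[1].asarray()
        mask = tif.pages[2].asarray() > 0
        if pixel_size is None:
            desc = tif.pages[0].description or ""
            try:
                pixel_size = float(json.loads(desc)["pixel_size_um"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise InputError(
                    f"{path}: no pixel size stored; pass pixel_size explicitly"
                ) from exc
    return Micrograph(grl, mdl, pixel_size, mask)


def write_pool_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    chromosomes: list[tuple[str, int]] | None = None,
) -> None:
    """Write a pooled variant-site table as uncompressed VCF 4.2.

    Parameters
    ----------
    sites
        DataFrame with :data:`SITE_COLUMNS`.
    chromosomes
        Optional ``(name, length)`` contig declarations; inferred from the
        maximum position per chromosome when omitted.
    """
    sites = sites.reset_index(drop=True)
    if chromosomes is None:
        lengths = sites.groupby("chrom", sort=False)["pos"].max()
        chromosomes = [(str(c), int(p)) for c, p in lengths.items()]
    header = pysam.VariantHeader()
    for name, length in chromosomes:
        header.contigs.add(name, length=length)
    header.info.add("IMPACT", 1, "String", "Predicted functional impact category")
    header.formats.add("DP", 1, "Integer", "Total read depth in the pool")
    header.formats.add("AD", "R", "Integer", "Read depths for the ref and alt alleles")
    header.add_sample("MUT")
    header.add_sample("WT")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sites.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["IMPACT"] = str(row.impact)
            rec.samples["MUT"]["DP"] = int(row.mut_depth)
            rec.samples["MUT"]["AD"] = (
                int(row.mut_depth) - int(row.mut_alt),
                int(row.mut_alt),
            )
            rec.samples["WT"]["DP"] = int(row.wt_depth)
            rec.samples["WT"]["AD"] = (
                int(row.wt_depth) - int(row.wt_alt),
                int(row.wt_alt),
            )
            vcf.write(rec)


def read_pool_vcf(path: str | Path) -> pd.DataFrame:
    """Read a two-sample (MUT, WT) pooled VCF into a variant-site table.

    Sites missing either sample's depth get depth 0 (downstream filters drop
    them); a missing IMPACT defaults to ``NONE``.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if "MUT" not in samples or "WT" not in samples:
            raise InputError(f"{path}: VCF must carry samples named MUT and WT")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # only biallelic sites are scored
            impact = rec.info.get("IMPACT", "NONE")
            if isinstance(impact, tuple):
                impact = impact[0]
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "impact": str(impact) if impact else "NONE",
            }
            for sample, prefix in (("MUT", "mut"), ("WT", "wt")):
                fmt = rec.samples[sample]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                alt = int(ad[1]) if ad is not None and ad[1] is not None else 0
                if dp is None and ad is not None and ad[0] is not None:
                    dp = int(ad[0]) + alt
                row[f"{prefix}_depth"] = int(dp) if dp is not None else 0
                row[f"{prefix}_alt"] = alt
            rows.append(row)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
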