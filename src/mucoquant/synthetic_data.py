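"""Synthetic micrographs and pooled-segregant variant tables with ground truth.

Two generators make every downstream stage testable without access to real
data:

``generate_cell_image``
    Draws an elliptical cell containing elongated elliptical "Grl" organelles
    (mucocysts) and one small "Mdl" punctum per organelle, placed along the
    organelle's major axis toward a designated tip with a configurable bias
    ``tip_bias``.  In ``docked`` mode the organelles sit in the peripheral
    band of the cell with their long axes perpendicular to the local cell
    boundary, emulating docked mucocysts imaged at the cell midsection; in
    ``cytoplasmic`` mode positions and orientations are uniform.  Channels
    are blurred with a Gaussian point-spread function and corrupted with
    Poisson and/or Gaussian noise; the returned ground truth records the
    pre-noise geometry.

``generate_pool_counts``
    Emulates bulk segregant sequencing of two phenotype-selected pools of
    whole-genome-homozygote F2 clones.  Each clone inherits a single
    recombinant chromatid per chromosome; crossovers follow a Poisson process
    (Haldane's map function, no interference), so a marker at physical
    distance d Mb from the causal site recombines with frequency
    ``r = (1 - exp(-2 d c / 100)) / 2`` for a map density of c cM/Mb.
    Pool read counts are Poisson depths with binomially sampled alt reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ParameterError, PlacementError
from .geometry import ellipse_mask
from .io import SITE_COLUMNS, Micrograph

MAX_PLACEMENT_ATTEMPTS = 500

# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------


@dataclass
class ImageSimParams:
    """Parameters of the synthetic two-channel micrograph.

    Lengths are in micrometres unless the name says pixels.  Defaults emulate
    a 100x widefield image of a Tetrahymena cell midsection: a ~36 x 24 um
    cell, ~1 um elongated mucocysts docked at the periphery, and one
    diffraction-limited Mdl punctum per mucocyst near its outward-facing tip.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.08
    cell_semi_axes: tuple[float, float] = (18.0, 12.0)
    mode: str = "docked"  # "docked" | "cytoplasmic"
    n_mucocysts: int = 25
    muc_semi_axes: tuple[float, float] = (0.5, 0.25)
    tip_bias: float = 0.9
    punctum_radius: float = 0.15
    psf_sigma: float = 0.08
    gauss_noise_sd: float = 0.02
    poisson_scale: float = 0.0
    n_autofluor_blobs: int = 4
    seed: int = 0

    def validate(self) -> None:
        a, b = self.muc_semi_axes
        A, B = self.cell_semi_axes
        if min(self.pixel_size, a, b, A, B, self.punctum_radius) <= 0:
            raise ParameterError("all lengths must be positive")
        if a <= b:
            raise ParameterError("mucocyst semi-major axis must exceed semi-minor")
        if not 0.0 <= self.tip_bias <= 1.0:
            raise ParameterError("tip_bias must be in [0, 1]")
        if self.n_mucocysts < 0 or self.n_autofluor_blobs < 0:
            raise ParameterError("counts must be >= 0")
        if self.mode not in ("docked", "cytoplasmic"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.psf_sigma < 0 or self.gauss_noise_sd < 0 or self.poisson_scale < 0:
            raise ParameterError("noise parameters must be >= 0")
        rows, cols = self.image_shape
        if 2 * A / self.pixel_size >= cols or 2 * B / self.pixel_size >= rows:
            raise ParameterError("image too small to contain the cell ellipse")


@dataclass
class ImageGroundTruth:
    """Pre-noise geometry of every simulated mucocyst, plus the cell mask.

    ``mucocysts`` has one row per organelle with centroid/tip/punctum
    coordinates in pixels, semi-axes in pixels, orientation in degrees, the
    true normalized tip offset (equal to ``tip_bias``) and the true angle to
    the major axis (0 for any positive offset, NaN when the punctum sits on
    the centroid).
    """

    mucocysts: pd.DataFrame
    cell_mask: np.ndarray


GROUND_TRUTH_COLUMNS = [
    "centroid_row",
    "centroid_col",
    "semi_major_px",
    "semi_minor_px",
    "orientation_deg",
    "tip_row",
    "tip_col",
    "punctum_row",
    "punctum_col",
    "offset_norm",
    "angle_deg",
]


def _place_mucocysts(params: ImageSimParams, cell: np.ndarray, rng: np.random.Generator):
    """Place non-overlapping mucocyst ellipses; returns (records, occupancy)."""
    rows, cols = params.image_shape
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])  # (row, col)
    A = params.cell_semi_axes[0] / params.pixel_size  # along columns
    B = params.cell_semi_axes[1] / params.pixel_size  # along rows
    a = params.muc_semi_axes[0] / params.pixel_size
    b = params.muc_semi_axes[1] / params.pixel_size
    margin = 2.0  # px kept between the organelle tip and the cell boundary
    occupancy = np.zeros(params.image_shape, dtype=bool)
    records = []
    for _ in range(params.n_mucocysts):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            if params.mode == "docked":
                t = rng.uniform(0.0, 2.0 * np.pi)
                boundary = center + np.array([B * np.sin(t), A * np.cos(t)])
                normal = np.array([np.sin(t) / B, np.cos(t) / A])
                normal /= np.hypot(*normal)
                centroid = boundary - normal * (a + margin)
                tip_dir = normal  # outward, toward the plasma membrane
            else:
                centroid = center + np.array(
                    [rng.uniform(-B, B), rng.uniform(-A, A)]
                )
                theta = rng.uniform(0.0, np.pi)
                tip_dir = np.array([np.sin(theta), np.cos(theta)])
                if rng.random() < 0.5:
                    tip_dir = -tip_dir
            orientation = float(np.degrees(np.arctan2(tip_dir[0], tip_dir[1])) % 180.0)
            muc = ellipse_mask(params.image_shape, tuple(centroid), (a, b), orientation)
            if not muc.any():
                continue
            if not cell[muc].all():
                continue
            if (occupancy & muc).any():
                continue
            occupancy |= muc
            tip = centroid + tip_dir * a
            records.append(
                {
                    "centroid_row": centroid[0],
                    "centroid_col": centroid[1],
                    "semi_major_px": a,
                    "semi_minor_px": b,
                    "orientation_deg": orientation,
                    "tip_row": tip[0],
                    "tip_col": tip[1],
                }
            )
            break
        else:
            raise PlacementError(
                f"could not place non-overlapping mucocyst inside the cell after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (mode={params.mode})"
            )
    return records, occupancy


def generate_cell_image(params: ImageSimParams) -> tuple[Micrograph, ImageGroundTruth]:
    """Simulate one two-channel micrograph; bit-identical under a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    A = params.cell_semi_axes[0] / params.pixel_size
    B = params.cell_semi_axes[1] / params.pixel_size
    cell = ellipse_mask(params.image_shape, center, (A, B), 0.0)

    records, occupancy = _place_mucocysts(params, cell, rng)
    grl = occupancy.astype(float)

    mdl = np.zeros(params.image_shape, dtype=float)
    r_px = params.punctum_radius / params.pixel_size
    for rec in records:
        centroid = np.array([rec["centroid_row"], rec["centroid_col"]])
        tip = np.array([rec["tip_row"], rec["tip_col"]])
        a = rec["semi_major_px"]
        direction = (tip - centroid) / a
        punctum = centroid + params.tip_bias * a * direction
        spot = ellipse_mask(params.image_shape, tuple(punctum), (max(r_px, 0.71),) * 2, 0.0)
        mdl[spot] = 1.0
        rec["punctum_row"] = punctum[0]
        rec["punctum_col"] = punctum[1]
        rec["offset_norm"] = params.tip_bias
        rec["angle_deg"] = 0.0 if params.tip_bias > 0 else np.nan

    # dim autofluorescent blobs visible in both channels
    if params.n_autofluor_blobs > 0:
        blob_sigma_px = 0.25 / params.pixel_size
        impulses = np.zeros(params.image_shape, dtype=float)
        in_cell = np.argwhere(cell)
        idx = rng.integers(0, len(in_cell), size=params.n_autofluor_blobs)
        amp = 0.35 * 2.0 * np.pi * blob_sigma_px**2  # peak height 0.35 after blur
        for r, c in in_cell[idx]:
            impulses[r, c] += amp
        blobs = ndimage.gaussian_filter(impulses, blob_sigma_px)
        grl += blobs
        mdl += blobs

    psf_px = params.psf_sigma / params.pixel_size
    if psf_px > 0:
        grl = ndimage.gaussian_filter(grl, psf_px)
        mdl = ndimage.gaussian_filter(mdl, psf_px)
    if params.poisson_scale > 0:
        grl = rng.poisson(np.clip(grl, 0, None) * params.poisson_scale) / params.poisson_scale
        mdl = rng.poisson(np.clip(mdl, 0, None) * params.poisson_scale) / params.poisson_scale
    if params.gauss_noise_sd > 0:
        grl = grl + rng.normal(0.0, params.gauss_noise_sd, size=grl.shape)
        mdl = mdl + rng.normal(0.0, params.gauss_noise_sd, size=mdl.shape)
    grl = np.clip(grl, 0.0, None)
    mdl = np.clip(mdl, 0.0, None)

    truth = ImageGroundTruth(
        mucocysts=pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS),
        cell_mask=cell,
    )
    return Micrograph(grl, mdl, params.pixel_size, cell), truth


# ---------------------------------------------------------------------------
# pooled-segregant cross simulation
# ---------------------------------------------------------------------------

DEFAULT_CHROMOSOMES = (
    ("chr1", 10_000_000),
    ("chr2", 10_000_000),
    ("chr3", 10_000_000),
    ("chr4", 10_000_000),
    ("chr5", 10_000_000),
)

DEFAULT_IMPACT_PROBS = {"HIGH": 0.05, "MODERATE": 0.20, "LOW": 0.25, "MODIFIER": 0.50}

_BASES = np.array(list("ACGT"))


@dataclass
class CrossSimParams:
    """Parameters of the pooled-segregant (bulk segregant) cross simulation.

    Two pools of ``pool_size`` whole-genome-homozygote F2 clones are selected
    by phenotype: every correctly phenotyped mutant-pool clone is homozygous
    for the causal allele, every wildtype-pool clone for the reference allele.
    ``phenotyping_error`` is the probability a clone lands in the wrong pool.
    Markers are evenly spaced variants segregating 1:1; the causal variant is
    inserted at ``causal_pos`` with impact ``causal_impact``, and a fraction
    ``background_variant_rate`` of markers carry mutagenesis-induced alleles
    annotated with an impact drawn from ``impact_probs`` (all other markers
    are annotated ``NONE``).
    """

    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    marker_spacing: int = 10_000
    causal_chrom: str = "chr4"
    causal_pos: int = 5_364_873
    recomb_rate: float = 1.0  # cM/Mb
    pool_size: int = 32
    mean_depth: float = 90.0
    phenotyping_error: float = 0.01
    background_variant_rate: float = 0.002
    impact_probs: dict = field(default_factory=lambda: dict(DEFAULT_IMPACT_PROBS))
    causal_impact: str = "HIGH"
    seed: int = 0

    def validate(self) -> None:
        lengths = dict((str(n), int(L)) for n, L in self.chromosomes)
        if self.causal_chrom not in lengths:
            raise ConfigurationError(f"causal chromosome {self.causal_chrom!r} not simulated")
        if not 1 <= self.causal_pos <= lengths[self.causal_chrom]:
            raise ConfigurationError("causal_pos outside its chromosome")
        if any(self.marker_spacing > L for L in lengths.values()):
            raise ConfigurationError("marker_spacing exceeds a chromosome length")
        if not 0.0 <= self.phenotyping_error < 0.5:
            raise ConfigurationError("phenotyping_error must be in [0, 0.5)")
        if self.pool_size < 1 or self.mean_depth <= 0:
            raise ConfigurationError("pool_size >= 1 and mean_depth > 0 required")
        if self.recomb_rate < 0 or not 0.0 <= self.background_variant_rate <= 1.0:
            raise ConfigurationError("invalid recombination or background rate")


@dataclass
class CrossTruth:
    """Ground truth of one simulated cross.

    ``expected`` holds the analytic marginal pool allele frequencies per
    marker (Haldane map function applied to the distance from the causal
    site, mixed with the phenotyping error).
    """

    causal_chrom: str
    causal_pos: int
    expected: pd.DataFrame  # chrom, pos, exp_mut_freq, exp_wt_freq


def haldane_recombination_fraction(distance_bp: np.ndarray, recomb_rate: float) -> np.ndarray:
    """Recombination fraction for a physical distance under Haldane's map.

    ``r = (1 - exp(-2 d c / 100)) / 2`` with d in Mb and c in cM/Mb; assumes
    crossovers are a Poisson process (no interference).
    """
    d_mb = np.asarray(distance_bp, dtype=float) / 1e6
    return 0.5 * (1.0 - np.exp(-2.0 * d_mb * recomb_rate / 100.0))


def _marker_positions(params: CrossSimParams) -> dict[str, np.ndarray]:
    positions = {}
    for name, length in params.chromosomes:
        pos = np.arange(params.marker_spacing, length + 1, params.marker_spacing, dtype=np.int64)
        if name == params.causal_chrom and params.causal_pos not in pos:
            pos = np.sort(np.append(pos, np.int64(params.causal_pos)))
        positions[str(name)] = pos
    return positions


def _clone_chromatid(
    rng: np.random.Generator,
    markers: np.ndarray,
    length: int,
    anchor_pos: int,
    anchor_allele: int,
    rate_per_bp: float,
) -> np.ndarray:
    """Genotype of one recombinant chromatid at ``markers``.

    The chromatid carries ``anchor_allele`` at ``anchor_pos``; Poisson
    crossovers flip the parental phase, so the allele at a marker is the
    anchor allele XOR the parity of the number of breakpoints between them.
    """
    n_bp = rng.poisson(rate_per_bp * length)
    if n_bp == 0:
        return np.full(markers.shape, anchor_allele, dtype=np.int8)
    breakpoints = np.sort(rng.uniform(0.0, length, size=n_bp))
    crossings = np.searchsorted(breakpoints, markers.astype(float))
    anchor_crossings = np.searchsorted(breakpoints, float(anchor_pos))
    parity = np.abs(crossings - anchor_crossings) % 2
    return (anchor_allele ^ parity).astype(np.int8)


def generate_pool_counts(params: CrossSimParams) -> tuple[pd.DataFrame, CrossTruth]:
    """Simulate per-site pooled read counts for the MUT and WT pools.

    Returns the variant-site table (columns :data:`mucoquant.io.SITE_COLUMNS`)
    and the :class:`CrossTruth`.  Deterministic under a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lengths = dict((str(n), int(L)) for n, L in params.chromosomes)
    markers = _marker_positions(params)
    rate_per_bp = params.recomb_rate / 100.0 / 1e6  # Morgans per bp

    # pool allele frequencies from explicit clone chromatids
    freqs: dict[str, dict[str, np.ndarray]] = {}
    for pool in ("mut", "wt"):
        want_mutant = pool == "mut"
        counts = {name: np.zeros(len(pos), dtype=float) for name, pos in markers.items()}
        for _ in range(params.pool_size):
            truly_mutant = want_mutant ^ (rng.random() < params.phenotyping_error)
            for name, pos in markers.items():
                if name == params.causal_chrom:
                    anchor_pos = params.causal_pos
                    anchor_allele = 1 if truly_mutant else 0
                else:
                    anchor_pos = 0
                    anchor_allele = int(rng.integers(0, 2))
                counts[name] += _clone_chromatid(
                    rng, pos, lengths[name], anchor_pos, anchor_allele, rate_per_bp
                )
        freqs[pool] = {name: c / params.pool_size for name, c in counts.items()}

    rows = []
    expected_rows = []
    e = params.phenotyping_error
    impact_names = list(params.impact_probs)
    impact_p = np.array([params.impact_probs[k] for k in impact_names], dtype=float)
    impact_p = impact_p / impact_p.sum()
    for name, pos in markers.items():
        n = len(pos)
        mut_depth = rng.poisson(params.mean_depth, size=n)
        wt_depth = rng.poisson(params.mean_depth, size=n)
        mut_alt = rng.binomial(mut_depth, freqs["mut"][name])
        wt_alt = rng.binomial(wt_depth, freqs["wt"][name])
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        is_causal = (name == params.causal_chrom) & (pos == params.causal_pos)
        background = rng.random(n) < params.background_variant_rate
        impacts = np.where(
            background, rng.choice(impact_names, size=n, p=impact_p), "NONE"
        ).astype(object)
        impacts[is_causal] = params.causal_impact

        if name == params.causal_chrom:
            r = haldane_recombination_fraction(np.abs(pos - params.causal_pos), params.recomb_rate)
            exp_mut = (1.0 - e) * (1.0 - r) + e * r
            exp_wt = e * (1.0 - r) + (1.0 - e) * r
        else:
            exp_mut = np.full(n, 0.5)
            exp_wt = np.full(n, 0.5)

        for i in range(n):
            rows.append(
                {
                    "chrom": name,
                    "pos": int(pos[i]),
                    "ref": _BASES[ref_idx[i]],
                    "alt": _BASES[alt_idx[i]],
                    "mut_depth": int(mut_depth[i]),
                    "mut_alt": int(mut_alt[i]),
                    "wt_depth": int(wt_depth[i]),
                    "wt_alt": int(wt_alt[i]),
                    "impact": str(impacts[i]),
                }
            )
            expected_rows.append(
                {
                    "chrom": name,
                    "pos": int(pos[i]),
                    "exp_mut_freq": float(exp_mut[i]),
                    "exp_wt_freq": float(exp_wt[i]),
                }
            )

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    truth = CrossTruth(
        causal_chrom=params.causal_chrom,
        causal_pos=params.causal_pos,
        expected=pd.DataFrame(expected_rows),
    )
    return sites, truth


def write_ground_truth_csv(truth: ImageGroundTruth | CrossTruth, path: str | Path) -> None:
    """Write either generator's ground truth as CSV."""
    if isinstance(truth, ImageGroundTruth):
        truth.mucocysts.to_csv(path, index=False)
    else:
        df = truth.expected.copy()
        df.insert(0, "causal_chrom", truth.causal_chrom)
        df.insert(1, "causal_pos", truth.causal_pos)
        df.to_csv(path, index=False)
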