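"""Synthetic en-face NMJ micrographs with ground-truth masks.

Healthy mammalian endplates viewed en face show a branched, ribbon-like
("pretzel") acetylcholine-receptor distribution.  The generator draws a
random smooth branching skeleton, dilates it to the ribbon width, and paints
intensities on the 8-bit gray scale:

* bright, crisply bordered ribbons for healthy receptor label;
* contiguous *dim* sub-regions (a chosen fraction of the AChR area) whose
  intensities occupy a broad low band just above the 40-gray-level
  background cutoff, emulating reduced receptor expression;
* *floccular* (granular) patches where small sub-resolution holes are
  punched to background level, emulating disease-associated speckling;
* small, dim *extrajunctional* satellite clusters a few µm beyond the main
  perimeter.

Disease severity per age x genotype follows published trajectories (see
``presets/image_scenarios.json``): the dim-area fraction plateaus near 40%
in wildtype and rises to 60% at the early-symptomatic stage in hSOD1-G93A,
with floccular and satellite incidences to match.  Every image returns the
exact masks used to paint it, so downstream estimators can be validated
against pixel-level truth.

Images are written as 16-bit TIFF by default (8-bit export available); all
intensities are arbitrary units -- no absolute fluorescence calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageScenario",
    "NMJImage",
    "GroundTruthMask",
    "build_image_scenario",
    "generate_nmj",
    "load_image_presets",
    "write_image",
    "read_image",
    "IMAGE_AGES",
]

#: Imaging was performed from 4 weeks on; "sym" = 18-22 weeks (both genotypes).
IMAGE_AGES = (4, 8, 12, 16, 18, 19, 20, 21, 22)


@dataclass(frozen=True)
class ImageScenario:
    """Generator parameter set for one age x genotype imaging group.

    ``dim_fraction`` is the target fraction of AChR pixels painted with the
    reduced-intensity band.  ``floccular_fraction`` fixed to a value forces
    that fraction of the AChR area to be granular; ``None`` samples a
    per-image category from the incidence probabilities
    (``p_floccular_small``/``p_floccular_large``).  Likewise
    ``n_extrajunctional=None`` samples presence at ``p_extrajunctional``.
    """

    age_weeks: int
    genotype: str
    image_size: int = 512
    pixel_size: float = 0.16          # µm/px
    endplate_scale: float = 32.0      # µm, nominal endplate extent
    ribbon_width: float = 2.5         # µm
    n_branches: int = 5
    bright_intensity: float = 185.0   # gray levels (8-bit scale)
    bright_spread: float = 15.0
    dim_intensity: float = 91.0       # centre of the reduced-intensity band
    dim_spread: float = 59.0          # half-width; band = centre +/- half-width
    dim_fraction: float = 0.4
    floccular_fraction: Optional[float] = None
    floccular_fraction_small: float = 0.25
    floccular_fraction_large: float = 0.70
    p_floccular_small: float = 0.0
    p_floccular_large: float = 0.0
    n_extrajunctional: Optional[int] = None
    p_extrajunctional: float = 0.0
    satellite_intensity_lo: float = 0.40   # fraction of bright_intensity
    satellite_intensity_hi: float = 0.60
    background_level: float = 15.0
    noise_sd: float = 4.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.dim_fraction <= 1:
            raise ValueError("dim_fraction must be in [0, 1]")
        if self.floccular_fraction is not None and not 0 <= self.floccular_fraction <= 1:
            raise ValueError("floccular_fraction must be in [0, 1]")
        if self.dim_intensity >= self.bright_intensity:
            raise ValueError("dim_intensity must be below bright_intensity")
        if self.background_level >= 40:
            raise ValueError("background_level must stay below the 40-gray-level cutoff")
        if self.endplate_scale / self.pixel_size > self.image_size:
            raise ValueError("endplate larger than the image field")


@dataclass
class NMJImage:
    """A single-NMJ grayscale micrograph with known pixel size."""

    pixels: np.ndarray          # uint16 (or uint8)
    pixel_size: float           # µm/px
    metadata: dict = field(default_factory=dict)


@dataclass
class GroundTruthMask:
    """Pixel-level truth for one synthetic NMJ image."""

    achr_mask: np.ndarray          # bool: receptor-labelled ribbon
    endplate_mask: np.ndarray      # bool: filled synaptic footprint
    dim_mask: np.ndarray           # bool, subset of achr_mask
    floccular_mask: np.ndarray     # bool, subset of achr_mask
    satellite_labels: np.ndarray   # int labels, disjoint from endplate_mask

    @property
    def dim_area_fraction(self) -> float:
        a = int(self.achr_mask.sum())
        return float(self.dim_mask.sum()) / a if a else 0.0

    @property
    def floccular_area_fraction(self) -> float:
        a = int(self.achr_mask.sum())
        return float(self.floccular_mask.sum()) / a if a else 0.0


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def load_image_presets() -> dict:
    text = resources.files("nmjkit.presets").joinpath("image_scenarios.json").read_text()
    return json.loads(text)


def build_image_scenario(age_weeks: int, genotype: str) -> ImageScenario:
    """Preset imaging scenario for one age x genotype group.

    Raises ``ValueError`` for combinations outside the imaging design
    (imaging starts at 4 weeks; 18-22 weeks map to the symptomatic group).
    """
    if genotype not in ("WT", "SOD1"):
        raise ValueError(f"unknown genotype {genotype!r}; expected 'WT' or 'SOD1'")
    if age_weeks not in IMAGE_AGES:
        raise ValueError(
            f"no imaging group at {age_weeks} weeks; valid ages are 4, 8, 12, 16 or 18-22"
        )
    key = "sym" if age_weeks >= 18 else str(age_weeks)
    presets = load_image_presets()
    entry = dict(presets[genotype][key])
    d = presets["defaults"]

    return ImageScenario(
        age_weeks=age_weeks,
        genotype=genotype,
        image_size=d["image_size"],
        pixel_size=d["pixel_size"],
        endplate_scale=d["endplate_scale"],
        ribbon_width=d["ribbon_width"],
        n_branches=d["n_branches"],
        bright_intensity=d["bright_intensity"],
        bright_spread=d["bright_spread"],
        dim_intensity=d["dim_intensity"],
        dim_spread=d["dim_spread"],
        dim_fraction=entry["dim_fraction"],
        floccular_fraction_small=d["floccular_fraction_small"],
        floccular_fraction_large=d["floccular_fraction_large"],
        p_floccular_small=entry["p_floccular_small"],
        p_floccular_large=entry["p_floccular_large"],
        p_extrajunctional=entry["p_extrajunctional"],
        satellite_intensity_lo=d["satellite_intensity_lo"],
        satellite_intensity_hi=d["satellite_intensity_hi"],
        background_level=d["background_level"],
        noise_sd=d["noise_sd"],
        label=f"{genotype}-{key}",
    )


# ---------------------------------------------------------------------------
# skeleton and region machinery
# ---------------------------------------------------------------------------

def _pretzel_skeleton(scenario: ImageScenario, rng: np.random.Generator) -> np.ndarray:
    """Random smooth branching curve confined to the endplate footprint.

    Branches are correlated random walks with a weak radial pull toward an
    annulus, which produces the looping, ring-like habit of real pretzels.
    """
    size = scenario.image_size
    c = size / 2.0
    radius = scenario.endplate_scale / scenario.pixel_size / 2.0
    canvas = np.zeros((size, size), dtype=bool)

    # seed points for branches: first from the centre, later from the skeleton
    points = [np.array([c, c])]
    step = 0.5 / scenario.pixel_size  # 0.5 µm steps, pixel-size invariant
    for b in range(scenario.n_branches):
        start = points[rng.integers(len(points))].copy()
        heading = rng.uniform(0, 2 * np.pi)
        pos = start.copy()
        n_steps = int(rng.integers(60, 110))
        for _ in range(n_steps):
            # weak pull toward an annulus at 0.55 * radius keeps loops open
            rel = pos - c
            r = np.hypot(*rel) + 1e-9
            target = 0.55 * radius
            radial = np.arctan2(rel[0], rel[1])
            pull = np.sign(target - r) * 0.25
            heading += rng.normal(0.0, 0.35) + pull * np.sin(heading - radial)
            nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
            rel_n = nxt - c
            if np.hypot(*rel_n) > radius:
                heading += np.pi / 2  # bounce off the footprint boundary
                continue
            rr, cc = _line(pos, nxt)
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[ok], cc[ok]] = True
            pos = nxt
            points.append(pos.copy())
    return canvas


def _line(p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = int(max(abs(p1 - p0))) * 2 + 2
    rr = np.round(np.linspace(p0[0], p1[0], n)).astype(int)
    cc = np.round(np.linspace(p0[1], p1[1], n)).astype(int)
    return rr, cc


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Spatially correlated field with zero mean and unit (empirical) SD."""
    z = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    return (z - z.mean()) / z.std()


def _uniform_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Spatially smooth field with a uniform(0, 1) marginal (Gaussian copula)."""
    from scipy.special import ndtr
    return ndtr(_smooth_field(rng, size, sigma))


def _disk(radius_px: float) -> np.ndarray:
    r = max(1, int(round(radius_px)))
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def _grow_region(achr: np.ndarray, target_px: int, rng: np.random.Generator,
                 n_seeds: int) -> np.ndarray:
    """Contiguous-ish sub-region of ``achr`` of exactly ``target_px`` pixels.

    Pixels are ranked by Euclidean distance to a few random seed points on
    the mask and the nearest ``target_px`` are taken, which yields compact
    blobs that respect the ribbon geometry.
    """
    out = np.zeros_like(achr)
    if target_px <= 0:
        return out
    coords = np.argwhere(achr)
    seeds = coords[rng.choice(len(coords), size=min(n_seeds, len(coords)), replace=False)]
    seed_mask = np.zeros_like(achr)
    seed_mask[seeds[:, 0], seeds[:, 1]] = True
    dist = ndimage.distance_transform_edt(~seed_mask)
    dvals = dist[achr]
    order = np.argsort(dvals, kind="stable")[:target_px]
    sel = coords[order]
    out[sel[:, 0], sel[:, 1]] = True
    return out


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def generate_nmj(scenario: ImageScenario, seed: int) -> tuple[NMJImage, GroundTruthMask]:
    """Generate one synthetic NMJ micrograph and its ground-truth masks.

    Deterministic for a fixed ``(scenario, seed)``.  The dim mask is grown to
    exactly ``round(dim_fraction * AChR area)`` pixels, so mask bookkeeping
    is exact up to rounding.
    """
    rng = np.random.default_rng(seed)
    size = scenario.image_size

    skeleton = _pretzel_skeleton(scenario, rng)
    ribbon_r = scenario.ribbon_width / scenario.pixel_size / 2.0
    achr = ndimage.binary_dilation(skeleton, structure=_disk(ribbon_r))
    achr_area = int(achr.sum())

    # --- regions -----------------------------------------------------------
    dim_target = int(round(scenario.dim_fraction * achr_area))
    dim_mask = _grow_region(achr, dim_target, rng, n_seeds=3)

    floc_fraction = scenario.floccular_fraction
    if floc_fraction is None:
        u = rng.uniform()
        if u < scenario.p_floccular_large:
            floc_fraction = scenario.floccular_fraction_large
        elif u < scenario.p_floccular_large + scenario.p_floccular_small:
            floc_fraction = scenario.floccular_fraction_small
        else:
            floc_fraction = 0.0
    floc_target = int(round(floc_fraction * achr_area))
    floccular_mask = _grow_region(achr, floc_target, rng, n_seeds=2)

    n_sat = scenario.n_extrajunctional
    if n_sat is None:
        n_sat = int(rng.integers(1, 4)) if rng.uniform() < scenario.p_extrajunctional else 0

    # --- intensities -------------------------------------------------------
    img = np.full((size, size), scenario.background_level, dtype=float)

    # Bright ribbon: spatially smooth Gaussian band -> a single tall histogram
    # peak.  Reduced-intensity (dim) regions: spatially smooth field with a
    # *uniform* marginal over [centre - spread, centre + spread]; the dim label
    # therefore forms the broad, flat shoulder between the background cutoff
    # and the bright peak (the "shallow minimum" region of the bimodal
    # histogram), not a second mode of its own.
    bright = scenario.bright_intensity + scenario.bright_spread * _smooth_field(rng, size, 1.0)
    u = _uniform_field(rng, size, 1.5)
    dim_vals = (scenario.dim_intensity - scenario.dim_spread) + 2 * scenario.dim_spread * u
    img[achr] = bright[achr]
    img[dim_mask] = dim_vals[dim_mask]

    # floccular speckle: discrete small (~0.5-1 µm) round holes punched to
    # background level at ~40% coverage of the granular region.  Discrete
    # disks stay compact (no percolation into region-sized components).
    if floc_target > 0:
        coverage = 0.40
        mean_r = 0.35 / scenario.pixel_size
        coords = np.argwhere(floccular_mask)
        n_holes = max(1, int(round(coverage * floc_target / (np.pi * mean_r**2))))
        hole_mask = np.zeros_like(floccular_mask)
        yy, xx = np.ogrid[:size, :size]
        for _ in range(n_holes):
            cy, cx = coords[rng.integers(len(coords))]
            r = rng.uniform(0.7, 1.3) * mean_r
            hole_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        hole_mask &= floccular_mask
        img[hole_mask] = scenario.background_level

    # satellites: small dim clusters 2-10 µm beyond the main perimeter
    satellite_labels = np.zeros((size, size), dtype=int)
    if n_sat > 0:
        endplate_guess = ndimage.binary_fill_holes(
            ndimage.binary_closing(achr, structure=_disk(8))
        )
        dist_out = ndimage.distance_transform_edt(~endplate_guess) * scenario.pixel_size
        band = (dist_out >= 2.0) & (dist_out <= 10.0)
        band_coords = np.argwhere(band)
        placed = 0
        for s in range(n_sat):
            if len(band_coords) == 0:
                break
            yx = band_coords[rng.integers(len(band_coords))]
            r = int(rng.integers(2, 5))
            frac = rng.uniform(scenario.satellite_intensity_lo, scenario.satellite_intensity_hi)
            yy, xx = np.ogrid[:size, :size]
            blob = (yy - yx[0]) ** 2 + (xx - yx[1]) ** 2 <= r * r
            blob &= ~endplate_guess
            if not blob.any():
                continue
            placed += 1
            img[blob] = frac * scenario.bright_intensity
            satellite_labels[blob] = placed

    if scenario.noise_sd > 0:
        img += rng.normal(0.0, scenario.noise_sd, (size, size))
    img = np.clip(img, 0.0, 255.0)

    endplate_mask = ndimage.binary_fill_holes(
        ndimage.binary_closing(achr, structure=_disk(8))
    )

    pixels16 = np.round(img / 255.0 * 65535.0).astype(np.uint16)
    image = NMJImage(
        pixels=pixels16,
        pixel_size=scenario.pixel_size,
        metadata={
            "scenario": scenario.label,
            "seed": seed,
            "dim_fraction": scenario.dim_fraction,
            "floccular_fraction": floc_fraction,
            "n_extrajunctional": n_sat,
            "en_face": True,
        },
    )
    truth = GroundTruthMask(
        achr_mask=achr,
        endplate_mask=endplate_mask,
        dim_mask=dim_mask,
        floccular_mask=floccular_mask,
        satellite_labels=satellite_labels,
    )
    return image, truth


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_image(image: NMJImage, path, bit_depth: int = 16) -> None:
    """Write a TIFF; ``bit_depth=8`` exports with the analysis module's min-max conversion."""
    if bit_depth == 16:
        tifffile.imwrite(path, image.pixels.astype(np.uint16))
    elif bit_depth == 8:
        from .morphometry import to_uint8
        tifffile.imwrite(path, to_uint8(image.pixels))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def read_image(path, pixel_size: float) -> NMJImage:
    """Read an 8- or 16-bit grayscale TIFF with a known pixel size (µm/px)."""
    px = tifffile.imread(path)
    if px.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return NMJImage(pixels=px, pixel_size=pixel_size, metadata={"path": str(path)})


def truth_manifest_row(image: NMJImage, truth: GroundTruthMask) -> dict:
    """One CSV-manifest row of scenario, seed and true area fractions."""
    md = image.metadata
    return {
        "scenario": md.get("scenario"),
        "seed": md.get("seed"),
        "dim_fraction_target": md.get("dim_fraction"),
        "dim_fraction_true": truth.dim_area_fraction,
        "floccular_fraction_true": truth.floccular_area_fraction,
        "n_satellites": int(truth.satellite_labels.max()),
    }
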