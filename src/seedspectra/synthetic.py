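"""Synthetic seed scenes with known ground truth.

Real acquisitions image dozens of seeds on a cloth background under halogen
light; shadows and mixed border pixels are the main nuisances. The generator
reproduces those ingredients with full ground truth: smooth endmember spectra
(pigmented seed coats carry a red-edge inflection, shadows are uniformly dark),
elliptical seeds with an interior hilum patch, a soft shadow gradient over the
background, 50/50 mixed pixels along each seed rim, and additive Gaussian
sensor noise clipped at zero. Everything is reproducible bit-exactly from the
parameters and an integer seed.

What it does NOT emulate: specular highlights, coat texture (stripes, mottle),
physically based shading, or chromatic sensor response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (SeedFeatures, build_feature_table, classify_shape,
                       classify_size, vegetation_indices)
from .io_envi import Hypercube
from .spectral_similarity import Spectrum, sam
from .unmixing import AbundanceStack, EndmemberSet

__all__ = [
    "SceneTruth",
    "make_endmember_library",
    "make_mixture_cube",
    "make_scene",
    "make_cohort",
]


@dataclass
class SceneTruth:
    """Ground truth for one generated scene."""

    endmembers: EndmemberSet
    abundance: AbundanceStack
    seed_masks: list[np.ndarray]
    coat_masks: list[np.ndarray]
    hilum_masks: list[np.ndarray]
    seed_params: list[dict]
    noise_sd: float
    seed: int
    meta: dict = field(default_factory=dict)


def _smooth_spectrum(rng: np.random.Generator, wl: np.ndarray, family: str
                     ) -> np.ndarray:
    span = wl[-1] - wl[0]
    n_bumps = rng.integers(2, 5)
    base = rng.uniform(0.05, 0.15)
    slope = rng.uniform(-0.05, 0.1)
    s = base + slope * (wl - wl[0]) / span
    for _ in range(n_bumps):
        center = rng.uniform(wl[0], wl[-1])
        width = rng.uniform(0.05, 0.25) * span
        amp = rng.uniform(0.05, 0.3)
        s = s + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if family == "seedcoat":
        # Red-edge inflection: sigmoidal NIR rise around 700-740 nm.
        edge = rng.uniform(690.0, 740.0)
        height = rng.uniform(0.15, 0.45)
        s = s + height / (1.0 + np.exp(-(wl - edge) / 15.0))
    elif family == "background":
        s = s + rng.uniform(0.3, 0.6)  # bright cloth
    elif family == "shadow":
        s = s * 0.12 / max(s.max(), 1e-9)  # uniformly dark
    else:
        raise ValueError(f"unknown family '{family}'")
    s = np.clip(s, 1e-3, None)
    if family == "shadow":
        s = np.clip(s, None, 0.15)
    return s


def make_endmember_library(p: int, n_bands: int = 60,
                           wl_range: tuple[float, float] = (400.0, 1000.0),
                           family: str = "seedcoat", seed: int = 0,
                           min_sam: float = 0.1) -> EndmemberSet:
    """Generate ``p`` smooth positive endmember spectra of one family.

    Spectra are sums of 2-4 Gaussian bumps on a linear baseline; seed-coat
    spectra add a red-edge sigmoid, shadow spectra are capped at 0.15
    reflectance. Rejection sampling enforces pairwise SAM >= ``min_sam`` rad.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if n_bands < 20:
        raise ValueError("n_bands must be >= 20")
    rng = np.random.default_rng(seed)
    wl = np.linspace(wl_range[0], wl_range[1], n_bands)
    spectra: list[np.ndarray] = []
    attempts = 0
    while len(spectra) < p:
        cand = _smooth_spectrum(rng, wl, family)
        if all(sam(cand, s) >= min_sam for s in spectra):
            spectra.append(cand)
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                f"could not draw {p} spectra with pairwise SAM >= {min_sam} "
                f"after 1000 attempts; lower min_sam or p")
    labels = [f"{family}#{i + 1}" for i in range(p)]
    return EndmemberSet(spectra=np.array(spectra), wavelengths=wl, labels=labels)


def make_mixture_cube(n_endmembers: int = 3, grid: tuple[int, int] = (64, 64),
                      n_bands: int = 50, snr_db: float = 40.0, seed: int = 0,
                      pure_block: int = 3):
    """Smooth convex-mixture cube with at least one pure pixel per endmember.

    Abundance fields are softmax-normalized smooth random surfaces (bilinearly
    upsampled low-resolution noise) — real scenes are spatially coherent, and
    shift-difference noise estimators rely on that. Field contrasts are spread
    geometrically across endmembers so the sources carry well-separated
    energies (distinct eigenvalues), and a ``pure_block`` x ``pure_block``
    patch per endmember is forced to a one-hot abundance. White Gaussian noise
    is added at ``snr_db`` relative to the mean signal power.

    Returns ``(cube, endmembers, abundance)`` with the noise-free abundance
    stack as ground truth.
    """
    from scipy.ndimage import zoom

    rng = np.random.default_rng(seed)
    ems = make_endmember_library(n_endmembers, n_bands=n_bands, seed=seed)
    rows, cols = grid
    scales = np.geomspace(3.0, 0.8, n_endmembers)
    coarse = rng.normal(0.0, 1.0, size=(n_endmembers, 8, 8)) * scales[:, None, None]
    fields = np.stack([zoom(c, (rows / 8, cols / 8), order=1) for c in coarse])
    fields = np.exp(fields)
    ab = (fields / fields.sum(axis=0)).transpose(1, 2, 0)  # (rows, cols, K)

    # One pure patch per endmember, placed on a spread-out diagonal.
    for k in range(n_endmembers):
        r0 = int((k + 0.5) * rows / n_endmembers) - pure_block
        c0 = int(rng.integers(0, cols - pure_block))
        r0 = min(max(r0, 0), rows - pure_block)
        ab[r0:r0 + pure_block, c0:c0 + pure_block, :] = 0.0
        ab[r0:r0 + pure_block, c0:c0 + pure_block, k] = 1.0

    clean = ab.reshape(-1, n_endmembers) @ ems.spectra
    noise_sd = float(np.sqrt(np.mean(clean ** 2) / 10 ** (snr_db / 10.0)))
    data = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    cube = Hypercube(data=data.reshape(rows, cols, n_bands),
                     wavelengths=ems.wavelengths.copy(),
                     meta={"synthetic": True, "snr_db": snr_db,
                           "noise_sd": noise_sd, "seed": seed})
    return cube, ems, AbundanceStack(maps=ab, endmembers=ems)


def _place_seeds(rng: np.random.Generator, n_seeds: int, grid: tuple[int, int],
                 axes_range: tuple[float, float]) -> list[dict]:
    rows, cols = grid
    params: list[dict] = []
    attempts = 0
    while len(params) < n_seeds:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError(
                f"could not place {n_seeds} non-overlapping seeds on a "
                f"{rows}x{cols} grid; use a larger grid")
        a = rng.uniform(*axes_range)  # semi-major
        b = rng.uniform(0.8, 0.95) * a  # semi-minor; seeds within an
        # accession are fairly uniform and roundish (area CV ~10%)
        theta = rng.uniform(0, np.pi)
        margin = a + 2.0
        cr = rng.uniform(margin, rows - margin)
        cc = rng.uniform(margin, cols - margin)
        ok = all(np.hypot(cr - q["center"][0], cc - q["center"][1])
                 > a + q["axes"][0] + 2.0 for q in params)
        if ok:
            params.append({"center": (cr, cc), "axes": (a, b), "theta": theta})
    return params


def _ellipse_field(grid: tuple[int, int], center, axes, theta) -> np.ndarray:
    """Normalized squared ellipse coordinate: <=1 inside the ellipse."""
    rows, cols = grid
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2


def make_scene(n_seeds: int = 12, grid: tuple[int, int] = (128, 128),
               ems: EndmemberSet | None = None, hilum_fraction: float = 0.08,
               noise_sd: float = 0.01, seed: int = 0,
               axes_range: tuple[float, float] = (8.5, 10.0),
               shadow_max: float = 0.4) -> tuple[Hypercube, SceneTruth]:
    """Render a seed scene and its ground truth.

    Seeds are non-overlapping ellipses painted with a coat endmember; each
    carries an interior elliptical hilum patch of area fraction
    ``hilum_fraction`` painted with a different foreground endmember. Seed rim
    pixels mix 50/50 with the local background. The background is a bright
    cloth endmember blended with a dark shadow endmember along a smooth
    left-to-right gradient up to ``shadow_max``. Gaussian noise of standard
    deviation ``noise_sd`` (reflectance units) is added and clipped at zero.
    """
    rng = np.random.default_rng(seed)
    if ems is None:
        coats = make_endmember_library(2, family="seedcoat", seed=seed)
        hilum = make_endmember_library(1, family="seedcoat", seed=seed + 101)
        cloth = make_endmember_library(1, family="background", seed=seed + 202)
        shadow = make_endmember_library(1, family="shadow", seed=seed + 303)
        spectra = np.vstack([coats.spectra, hilum.spectra,
                             cloth.spectra, shadow.spectra])
        ems = EndmemberSet(
            spectra=spectra, wavelengths=coats.wavelengths,
            labels=["EM#1", "EM#2", "EM#3", "EM#4", "EM#5"],
            roles=["foreground", "foreground", "foreground",
                   "background", "background"])
    fg = ems.foreground_indices()
    bg = ems.background_indices()
    if len(fg) < 2 or len(bg) < 1:
        raise ValueError("scene needs >= 2 foreground and >= 1 background "
                         "endmembers (coat, hilum, cloth[, shadow])")
    coat_choices, hilum_em = fg[:-1], fg[-1]
    cloth_em = bg[0]
    shadow_em = bg[1] if len(bg) > 1 else None

    rows, cols = grid
    p = len(ems)
    abundance = np.zeros((rows, cols, p))
    # Background: cloth with a soft shadow gradient.
    if shadow_em is not None:
        s = shadow_max * np.linspace(0.0, 1.0, cols)[None, :] * np.ones((rows, 1))
        abundance[:, :, cloth_em] = 1.0 - s
        abundance[:, :, shadow_em] = s
    else:
        abundance[:, :, cloth_em] = 1.0

    params = _place_seeds(rng, n_seeds, grid, axes_range)
    seed_masks, coat_masks, hilum_masks = [], [], []
    for q in params:
        q["coat_em"] = int(rng.choice(coat_choices))
        q["hilum_em"] = int(hilum_em)
        field_sq = _ellipse_field(grid, q["center"], q["axes"], q["theta"])
        inside = field_sq <= 1.0
        interior = field_sq <= 0.85  # rim pixels stay half-mixed with background
        rim = inside & ~interior
        hil = np.zeros_like(inside)
        if hilum_fraction > 0:
            scale = np.sqrt(hilum_fraction)
            hil_sq = _ellipse_field(grid, q["center"],
                                    (q["axes"][0] * scale, q["axes"][1] * scale),
                                    q["theta"])
            hil = (hil_sq <= 1.0) & interior
        coat = inside & ~hil
        bg_local = abundance[rim].copy()
        abundance[interior] = 0.0
        abundance[interior, q["coat_em"]] = 1.0
        abundance[hil] = 0.0
        abundance[hil, q["hilum_em"]] = 1.0
        abundance[rim] = 0.5 * bg_local
        abundance[rim, q["coat_em"]] += 0.5
        seed_masks.append(inside)
        coat_masks.append(coat)
        hilum_masks.append(hil)

    data = abundance.reshape(-1, p) @ ems.spectra
    data = data.reshape(rows, cols, -1)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    cube = Hypercube(data=data, wavelengths=ems.wavelengths.copy(),
                     meta={"synthetic": True, "n_seeds": n_seeds,
                           "noise_sd": noise_sd, "seed": seed})
    truth = SceneTruth(endmembers=ems,
                       abundance=AbundanceStack(maps=abundance, endmembers=ems),
                       seed_masks=seed_masks, coat_masks=coat_masks,
                       hilum_masks=hilum_masks, seed_params=params,
                       noise_sd=noise_sd, seed=seed)
    return cube, truth


def make_cohort(n_accessions: int = 10, seeds_per_accession: int = 20,
                class_effect: float = 1.0, seed: int = 0, n_bands: int = 60,
                wl_range: tuple[float, float] = (426.0, 970.0),
                within_sd: float = 0.01):
    """Generate a labelled cohort of per-seed feature records.

    Each accession gets its own mean coat spectrum: a shared base spectrum plus
    ``class_effect`` times an accession-specific smooth perturbation (~0.1
    reflectance RMS at effect 1). Individual seeds scatter around it with
    ``within_sd`` spectral noise, plus accession-specific size/shape
    distributions. ``class_effect=0`` makes accessions spectrally and
    morphologically indistinguishable (a null cohort).

    Returns a ``FeatureTable`` ready for the classifier.
    """
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    rng = np.random.default_rng(seed)
    wl = np.linspace(wl_range[0], wl_range[1], n_bands)
    base = _smooth_spectrum(rng, wl, "seedcoat")
    span = wl[-1] - wl[0]
    # Cohort-wide morphology baseline; accessions deviate from it only in
    # proportion to class_effect, so a null cohort is truly exchangeable.
    base_height = rng.uniform(5.0, 8.0)
    base_wl_ratio = rng.uniform(0.75, 0.95)
    base_tw_ratio = rng.uniform(0.8, 1.0)
    base_weight = rng.uniform(0.1, 0.25)

    records: list[SeedFeatures] = []
    for a in range(n_accessions):
        # Smooth accession-level deviation from the shared base spectrum.
        delta = np.zeros_like(wl)
        for _ in range(3):
            center = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(0.08, 0.3) * span
            delta += rng.uniform(-0.12, 0.12) * np.exp(
                -0.5 * ((wl - center) / width) ** 2)
        mu_spec = np.clip(base + class_effect * delta, 1e-3, None)
        height0 = base_height * (1 + class_effect * rng.normal(0, 0.12))
        wl_ratio0 = float(np.clip(
            base_wl_ratio + class_effect * rng.normal(0, 0.05), 0.4, 1.0))
        tw_ratio0 = float(np.clip(
            base_tw_ratio + class_effect * rng.normal(0, 0.06), 0.4, 1.2))
        weight0 = base_weight * (1 + class_effect * rng.normal(0, 0.3))
        for s in range(seeds_per_accession):
            spec_vals = np.clip(
                mu_spec + rng.normal(0.0, within_sd, size=n_bands), 1e-3, None)
            spec = Spectrum(values=spec_vals, wavelengths=wl)
            height = height0 * (1 + class_effect * rng.normal(0, 0.03)
                                + rng.normal(0, 0.02))
            width = height * np.clip(wl_ratio0 + rng.normal(0, 0.02), 0.3, 1.0)
            thickness = width * np.clip(tw_ratio0 + rng.normal(0, 0.02), 0.3, 1.2)
            weight = max(weight0 * (1 + rng.normal(0, 0.05)), 1e-3)
            area = np.pi * (height / 2) * (width / 2)
            ndvi, ari2, tcari = vegetation_indices(spec)
            r = spec_vals[int(np.argmin(np.abs(wl - 640)))]
            g = spec_vals[int(np.argmin(np.abs(wl - 550)))]
            b = spec_vals[int(np.argmin(np.abs(wl - 460)))]
            rgb = tuple(float(np.clip(v, 0, 1)) for v in (r, g, b))
            gray = float(np.dot((0.299, 0.587, 0.114), rgb))
            records.append(SeedFeatures(
                accession=f"acc{a:03d}", seed_id=s, area_mm2=float(area),
                height_mm=float(height), width_mm=float(width),
                thickness_mm=float(thickness), weight_g=float(weight),
                rgb=rgb, gray=gray, mean_reflectance=spec,
                ndvi=ndvi, ari2=ari2, tcari=tcari,
                size_class=classify_size(weight),
                shape_class=classify_shape(width / height, thickness / width)))
    return build_feature_table(records)
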