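"""Single-field synthesis: nuclei, droplets, receptor levels, RNA spots.

Every random draw flows from one seed via named sub-streams (placement,
cell attributes, droplets, spots, and per-channel noise), so identical
``(config, dose, time, seed)`` calls are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from ..core import ImageField, quantize_u16
from ..errors import InvalidParameterError, PlacementError
from ..fourpl import occupancy_fraction, true_response
from ..segmentation import max_project
from .config import FieldConfig, time_factor

CELL_COLUMNS = [
    "field_id", "cell_id", "y", "x", "cls", "semi_major", "semi_minor", "theta",
    "nucleus_area_true_px", "dna_mean_true", "droplet_count_true",
    "rxra_true", "pparg_true", "dose_nM", "time_h", "treatment", "seed",
]
DROPLET_COLUMNS = [
    "field_id", "cell_id", "droplet_id", "y", "x", "radius_px", "area_true_px",
    "dose_nM", "time_h", "treatment", "seed",
]


@dataclass
class FieldGroundTruth:
    """True generative values for one field (one row per cell / droplet)."""

    cells: pd.DataFrame
    droplets: pd.DataFrame


def _ellipse_mask_bbox(shape, cy, cx, a, b, theta):
    h, w = shape
    y0 = max(int(math.floor(cy - a)) - 1, 0)
    y1 = min(int(math.ceil(cy + a)) + 2, h)
    x0 = max(int(math.floor(cx - a)) - 1, 0)
    x1 = min(int(math.ceil(cx + a)) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return None
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    c, s = math.cos(theta), math.sin(theta)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), mask


def _ellipse_boundary_radius(phi, a, b, theta):
    c = math.cos(phi - theta)
    s = math.sin(phi - theta)
    return 1.0 / math.sqrt((c / a) ** 2 + (s / b) ** 2)


def _place_centers(rng, n, shape, spacing, margins):
    """Sequential hard-core placement with bounded retries.

    A draw exceeding the achievable packing drops the unplaceable cells;
    a PlacementError is raised only when fewer than 80% of the requested
    nuclei fit (the field is genuinely too small for the configuration).
    Returns (centers, placed_indices).
    """
    h, w = shape
    placed: list[tuple[float, float]] = []
    kept: list[int] = []
    for i in range(n):
        m = margins[i]
        if h - 2 * m <= 1 or w - 2 * m <= 1:
            raise PlacementError("field too small for the requested nuclei")
        for _ in range(300):
            cy = rng.uniform(m, h - m)
            cx = rng.uniform(m, w - m)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= spacing**2 for py, px in placed):
                placed.append((cy, cx))
                kept.append(i)
                break
    if n and len(placed) < 0.8 * n:
        raise PlacementError(
            f"placed only {len(placed)} of {n} nuclei with spacing {spacing}"
        )
    centers = np.array(placed) if placed else np.empty((0, 2))
    return centers, np.asarray(kept, dtype=int)


def generate_field(
    config: FieldConfig,
    dose_nM: float,
    time_h: float,
    seed,
    *,
    treatment: str = "TBT",
    channels: tuple[str, ...] = ("dna", "lipid", "rxra"),
    lipid_dose_nM: float | None = None,
    receptor_dose_nM: float | None = None,
    spot_group: str | None = None,
    field_id: str = "field_000",
):
    """Render one multi-channel field and return it with its ground truth.

    ``lipid_dose_nM`` / ``receptor_dose_nM`` are the doses effectively seen
    by the lipid and receptor responses (they default to ``dose_nM``); a
    glycolysis-inhibitor co-treatment is modelled by forcing the effective
    lipid dose to zero while the nominal dose is recorded unchanged.
    ``spot_group`` selects vehicle vs treated smFISH spot means for any
    ``spots_<GENE>`` channel requested.
    """
    config.validate()
    if dose_nM < 0:
        raise InvalidParameterError("dose must be non-negative")
    lipid_dose = dose_nM if lipid_dose_nM is None else lipid_dose_nM
    receptor_dose = dose_nM if receptor_dose_nM is None else receptor_dose_nM

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
        seed_label = int(ss.generate_state(1)[0] % (2**31))
    else:
        seed = int(seed)
        ss = np.random.SeedSequence(seed)
        seed_label = seed
    s_place, s_attr, s_drop, s_spot, s_noise = ss.spawn(5)
    rng_place = np.random.default_rng(s_place)
    rng_attr = np.random.default_rng(s_attr)
    rng_drop = np.random.default_rng(s_drop)
    rng_spot = np.random.default_rng(s_spot)
    noise_children = dict(zip(sorted(channels), s_noise.spawn(len(channels))))

    h, w = config.field_size_px
    n = int(rng_place.poisson(config.cells_per_field_mean))

    # --- per-cell attributes ------------------------------------------------
    mu, sd = config.nucleus_semiaxes_px
    cls = rng_attr.choice(
        ["normal", "pyknotic", "mitotic"],
        size=n,
        p=[
            1.0 - config.pyknotic_fraction - config.mitotic_fraction,
            config.pyknotic_fraction,
            config.mitotic_fraction,
        ],
    )
    s1 = np.clip(rng_attr.normal(mu, sd, n), 5.0, None)
    s2 = np.clip(rng_attr.normal(mu, sd, n), 5.0, None)
    major = np.maximum(s1, s2)
    minor = np.minimum(s1, s2)
    theta = rng_attr.uniform(0.0, math.pi, n)
    pyk = cls == "pyknotic"
    mit = cls == "mitotic"
    # pyknotic: condensed (area x 0.35); mitotic: strongly elongated at equal area
    major[pyk] *= math.sqrt(0.35)
    minor[pyk] *= math.sqrt(0.35)
    ecc = rng_attr.uniform(0.93, 0.96, n)
    ratio = np.sqrt(1.0 - ecc[mit] ** 2)
    g = np.sqrt(major[mit] * minor[mit])
    major[mit] = g / np.sqrt(ratio)
    minor[mit] = g * np.sqrt(ratio)

    dna_mean = config.dna_base_intensity * rng_attr.lognormal(0.0, 0.15, n)
    dna_mean[pyk] *= 3.0
    dna_mean[mit] *= 2.0

    # Gaussian copula on latent per-cell multipliers (marginals untouched)
    rho_l = config.copula_rho_rxra_lipid
    rho_p = config.copula_rho_rxra_pparg
    z_r = rng_attr.normal(size=n)
    z_l = rho_l * z_r + math.sqrt(1.0 - rho_l**2) * rng_attr.normal(size=n)
    z_p = rho_p * z_r + math.sqrt(1.0 - rho_p**2) * rng_attr.normal(size=n)
    sig = config.cell_cv_sigma

    # --- placement (draws above the packing limit drop the excess) ---------
    margins = major + 2.0
    centers, kept = _place_centers(
        rng_place, n, (h, w), config.min_center_spacing_px, margins
    )
    n = len(kept)
    cls = cls[kept]
    major, minor, theta = major[kept], minor[kept], theta[kept]
    dna_mean = dna_mean[kept]
    z_r, z_l, z_p = z_r[kept], z_l[kept], z_p[kept]
    rxra_true = (
        config.rxra_base_intensity
        * true_response(receptor_dose, config.rxra_4pl)
        * np.exp(sig * z_r - sig**2 / 2)
    )
    frac_receptor = float(occupancy_fraction(receptor_dose, config.rxra_4pl))
    pparg_true = (
        config.pparg_base_intensity
        * (1.0 + (config.pparg_fold_at_top - 1.0) * frac_receptor)
        * np.exp(sig * z_p - sig**2 / 2)
    )

    # droplet counts: negative binomial around the 4PL x time factor,
    # realized as a Poisson-gamma mixture so the lipid latent can be
    # copula-coupled while keeping the NB marginal exact
    m_count = true_response(lipid_dose, config.droplet_count_4pl) * time_factor(time_h)
    size = config.droplet_count_dispersion
    gamma_mult = sps.gamma.ppf(sps.norm.cdf(z_l), a=size, scale=1.0 / size)
    droplet_count = rng_drop.poisson(m_count * np.asarray(gamma_mult)) if n else np.zeros(0, int)

    frac_lipid = float(occupancy_fraction(lipid_dose, config.droplet_count_4pl))
    area_scale = 1.0 + (config.droplet_area_scale_at_top - 1.0) * frac_lipid

    # --- droplets -----------------------------------------------------------
    # cytoplasm effectively tiles the field: points that would fall nearer a
    # neighboring nucleus are resampled so each cell's content stays in its
    # own territory
    def _own_territory(y: float, x: float, i: int) -> bool:
        if n == 1:
            return True
        d = np.hypot(centers[:, 0] - y, centers[:, 1] - x) - major
        return d[i] <= d.min() + 1e-9

    def _sample_in_annulus(rng, i, max_tries=20):
        cy, cx = centers[i]
        for _ in range(max_tries):
            phi = rng.uniform(0.0, 2 * math.pi)
            off = rng.uniform(1.0, config.cell_body_offset_px)
            rb = _ellipse_boundary_radius(phi, major[i], minor[i], theta[i])
            y = min(max(cy + math.sin(phi) * (rb + off), 1.0), h - 2.0)
            x = min(max(cx + math.cos(phi) * (rb + off), 1.0), w - 2.0)
            if _own_territory(y, x, i):
                return y, x
        return y, x

    drop_rows = []
    for i in range(n):
        k = int(droplet_count[i])
        if k == 0:
            continue
        radii = rng_drop.lognormal(
            config.droplet_radius_meanlog, config.droplet_radius_sdlog, k
        ) * math.sqrt(area_scale)
        for j in range(k):
            y, x = _sample_in_annulus(rng_drop, i)
            drop_rows.append((i + 1, y, x, radii[j]))

    # --- smFISH spots -------------------------------------------------------
    spot_genes = [ch.split("_", 1)[1] for ch in channels if ch.startswith("spots_")]
    spot_means = (
        config.spot_mean_treated if spot_group == "treated" else config.spot_mean_vehicle
    )
    spot_counts: dict[str, np.ndarray] = {}
    spot_positions: dict[str, list[list[tuple[float, float]]]] = {}
    for gene in spot_genes:
        mean = float(spot_means[gene])
        counts = rng_spot.poisson(mean, n) if n else np.zeros(0, int)
        per_cell = []
        for i in range(n):
            pts = []
            cy, cx = centers[i]
            for _ in range(int(counts[i])):
                for _try in range(20):
                    phi = rng_spot.uniform(0.0, 2 * math.pi)
                    rb = _ellipse_boundary_radius(phi, major[i], minor[i], theta[i])
                    rad = math.sqrt(rng_spot.uniform()) * (rb + config.cell_body_offset_px)
                    y = min(max(cy + math.sin(phi) * rad, 1.0), h - 2.0)
                    x = min(max(cx + math.cos(phi) * rad, 1.0), w - 2.0)
                    if _own_territory(y, x, i):
                        break
                pts.append((y, x))
            per_cell.append(pts)
        spot_counts[gene] = counts
        spot_positions[gene] = per_cell

    # --- render -------------------------------------------------------------
    n_slices = config.n_slices
    focal = rng_attr.integers(0, n_slices, n) if n_slices > 1 else np.zeros(n, int)

    def slice_weight(i_cell: int, j_slice: int) -> float:
        if n_slices == 1:
            return 1.0
        return math.exp(-((j_slice - focal[i_cell]) ** 2) / (2 * 0.8**2))

    nucleus_area = np.zeros(n)
    pristine = {
        ch: [np.full((h, w), config.background_level) for _ in range(n_slices)]
        for ch in channels
    }
    for i in range(n):
        res = _ellipse_mask_bbox((h, w), centers[i][0], centers[i][1], major[i], minor[i], theta[i])
        if res is None:
            continue
        sl, mask = res
        nucleus_area[i] = int(mask.sum())
        for j in range(n_slices):
            wgt = slice_weight(i, j)
            if "dna" in pristine:
                pristine["dna"][j][sl][mask] += dna_mean[i] * wgt
            if "rxra" in pristine:
                pristine["rxra"][j][sl][mask] += rxra_true[i] * wgt
            if "pparg" in pristine:
                pristine["pparg"][j][sl][mask] += pparg_true[i] * wgt
    if "lipid" in pristine:
        for cell_id, y, x, r in drop_rows:
            res = _ellipse_mask_bbox((h, w), y, x, r, r, 0.0)
            if res is None:
                continue
            sl, mask = res
            for j in range(n_slices):
                wgt = slice_weight(cell_id - 1, j)
                pristine["lipid"][j][sl][mask] += config.droplet_intensity * wgt
    for gene in spot_genes:
        ch = f"spots_{gene}"
        for i, pts in enumerate(spot_positions[gene]):
            for (y, x) in pts:
                for j in range(n_slices):
                    pristine[ch][j][int(round(y)), int(round(x))] += (
                        config.spot_amplitude * slice_weight(i, j)
                    )

    stacks: dict[str, list[np.ndarray]] = {}
    rendered: dict[str, np.ndarray] = {}
    for ch in channels:
        rng_noise = np.random.default_rng(noise_children[ch])
        out_slices = []
        for j in range(n_slices):
            img = ndi.gaussian_filter(pristine[ch][j], config.psf_sigma_px)
            photons = rng_noise.poisson(np.clip(img * config.photon_scale, 0.0, None))
            noisy = photons / config.photon_scale + rng_noise.normal(
                0.0, config.read_noise_sd, (h, w)
            )
            out_slices.append(quantize_u16(noisy))
        if n_slices > 1:
            stacks[ch] = out_slices
            rendered[ch] = max_project(out_slices)
        else:
            rendered[ch] = out_slices[0]

    metadata = {
        "field_id": field_id,
        "dose_nM": float(dose_nM),
        "lipid_dose_nM": float(lipid_dose),
        "receptor_dose_nM": float(receptor_dose),
        "time_h": float(time_h),
        "treatment": treatment,
        "seed": seed_label,
    }
    image = ImageField(channels=rendered, metadata=metadata, stacks=stacks)

    cells = pd.DataFrame(
        {
            "field_id": field_id,
            "cell_id": np.arange(1, n + 1, dtype=int),
            "y": centers[:, 0] if n else np.zeros(0),
            "x": centers[:, 1] if n else np.zeros(0),
            "cls": cls,
            "semi_major": major,
            "semi_minor": minor,
            "theta": theta,
            "nucleus_area_true_px": nucleus_area,
            "dna_mean_true": dna_mean,
            "droplet_count_true": droplet_count,
            "rxra_true": rxra_true,
            "pparg_true": pparg_true,
            "dose_nM": float(dose_nM),
            "time_h": float(time_h),
            "treatment": treatment,
            "seed": seed_label,
        },
        columns=None if n else CELL_COLUMNS,
    )
    for gene in spot_genes:
        cells[f"spots_{gene}_true"] = spot_counts[gene] if n else np.zeros(0, int)
    droplets = pd.DataFrame(
        [
            {
                "field_id": field_id,
                "cell_id": cid,
                "droplet_id": di + 1,
                "y": y,
                "x": x,
                "radius_px": r,
                "area_true_px": math.pi * r**2,
                "dose_nM": float(dose_nM),
                "time_h": float(time_h),
                "treatment": treatment,
                "seed": seed_label,
            }
            for di, (cid, y, x, r) in enumerate(drop_rows)
        ],
        columns=DROPLET_COLUMNS,
    )
    return image, FieldGroundTruth(cells=cells, droplets=droplets)
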