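"""Configuration of the synthetic microscopy-field generator."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import InvalidParameterError
from ..fourpl import INHIBITION, STIMULATION, FourPLParams


def _default_droplet_count_4pl() -> FourPLParams:
    # droplets per cell at 72 h: ~3 in vehicle rising to ~30 at saturating dose
    return FourPLParams(bottom=3.0, top=30.0, c50=0.46, hill=1.0, mode=STIMULATION)


def _default_rxra_4pl() -> FourPLParams:
    # relative nuclear level: 1.0 in vehicle, 0.35 at saturating dose
    return FourPLParams(bottom=0.35, top=1.0, c50=9.0, hill=1.0, mode=INHIBITION)


@dataclass
class FieldConfig:
    """All knobs of the field generator, with study-condition defaults.

    Dose-response couplings: per-cell droplet counts are negative-binomial
    around a stimulatory 4PL (half-max 0.46 nM); droplet areas are
    log-normal with their scale interpolated toward
    ``droplet_area_scale_at_top`` along the same curve; nuclear RXRA
    follows an inhibitory 4PL (half-max 9 nM); PPARG rises toward
    ``pparg_fold_at_top``. Cross-channel single-cell coupling is a
    Gaussian copula on latent per-cell multipliers, so each marginal is
    unchanged when a correlation is dialed.
    """

    field_size_px: tuple[int, int] = (1104, 1104)
    cells_per_field_mean: float = 150.0
    nucleus_semiaxes_px: tuple[float, float] = (15.0, 2.0)  # mean, sd of each semiaxis
    min_center_spacing_px: float = 40.0
    pyknotic_fraction: float = 0.03
    mitotic_fraction: float = 0.02

    droplet_count_4pl: FourPLParams = field(default_factory=_default_droplet_count_4pl)
    droplet_count_dispersion: float = 5.0  # negative-binomial size
    droplet_radius_meanlog: float = math.log(2.5)  # log-px
    droplet_radius_sdlog: float = 0.35
    droplet_area_scale_at_top: float = 1.6

    rxra_4pl: FourPLParams = field(default_factory=_default_rxra_4pl)
    pparg_fold_at_top: float = 1.3

    spot_mean_vehicle: dict = field(default_factory=lambda: {"SREBF1": 8.0, "FASN": 5.0})
    spot_mean_treated: dict = field(default_factory=lambda: {"SREBF1": 20.0, "FASN": 12.0})

    copula_rho_rxra_lipid: float = 0.0
    copula_rho_rxra_pparg: float = 0.4158
    cell_cv_sigma: float = 0.25  # log-sd of per-cell latent multipliers

    # rendering
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    photon_scale: float = 1.0  # photons per intensity unit for shot noise
    psf_sigma_px: float = 1.2
    bit_depth: int = 16
    n_slices: int = 1  # >1 renders a small z-stack to exercise max projection

    dna_base_intensity: float = 2000.0
    rxra_base_intensity: float = 3000.0
    pparg_base_intensity: float = 3000.0
    droplet_intensity: float = 2000.0
    spot_amplitude: float = 4000.0
    cell_body_offset_px: float = 30.0  # droplets/spots reach this far beyond the nucleus

    def validate(self) -> "FieldConfig":
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise InvalidParameterError("field must be non-empty")
        for name in ("pyknotic_fraction", "mitotic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.pyknotic_fraction + self.mitotic_fraction > 1.0:
            raise InvalidParameterError("outlier fractions sum above 1")
        if self.cells_per_field_mean < 0:
            raise InvalidParameterError("cells_per_field_mean must be >= 0")
        if self.min_center_spacing_px < 0:
            raise InvalidParameterError("min_center_spacing_px must be >= 0")
        if self.droplet_count_dispersion <= 0:
            raise InvalidParameterError("negative-binomial size must be positive")
        for rho in (self.copula_rho_rxra_lipid, self.copula_rho_rxra_pparg):
            if not (-0.999 <= rho <= 0.999):
                raise InvalidParameterError("copula rho must lie in (-1, 1)")
        if self.n_slices < 1:
            raise InvalidParameterError("n_slices must be >= 1")
        self.droplet_count_4pl.validate()
        self.rxra_4pl.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("droplet_count_4pl", "rxra_4pl"):
            d[key] = asdict(getattr(self, key))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FieldConfig":
        d = dict(d)
        for key in ("droplet_count_4pl", "rxra_4pl"):
            if key in d and isinstance(d[key], dict):
                d[key] = FourPLParams(**d[key])
        for key in ("field_size_px", "nucleus_semiaxes_px", "nucleus_area_px"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def time_factor(time_h: float) -> float:
    """Multiplier on the droplet-count response encoding the time course.

    Lipid accumulation is detectable by 24 h and peaks at 72 h; the factor
    rises linearly 0.6 -> 0.8 -> 1.0 over 24/48/72 h and saturates at 1.0
    beyond (a 14-day exposure behaves like the 72 h peak). Below 24 h it
    ramps linearly from 0 at time zero.
    """
    t = float(time_h)
    if t < 0:
        raise InvalidParameterError("time must be non-negative")
    if t < 24.0:
        return 0.6 * t / 24.0
    return float(np.interp(t, [24.0, 48.0, 72.0], [0.6, 0.8, 1.0]))
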