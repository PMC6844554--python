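"""Four-parameter logistic (4PL) dose-response curves.

The 4PL is the standard pharmacological model for graded responses:
``bottom`` and ``top`` are the asymptotes, ``c50`` the dose at half-maximal
response (reported as EC50 for stimulatory and IC50 for inhibitory curves)
and ``hill`` the slope. Doses are in nM throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

STIMULATION = "stimulation"
INHIBITION = "inhibition"


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of a four-parameter logistic curve.

    ``bottom`` is the response at zero dose for a stimulatory curve and at
    infinite dose for an inhibitory one; ``top`` is the opposite asymptote.
    """

    bottom: float
    top: float
    c50: float
    hill: float
    mode: str = STIMULATION

    def validate(self) -> "FourPLParams":
        if self.mode not in (STIMULATION, INHIBITION):
            raise InvalidParameterError(f"unknown 4PL mode {self.mode!r}")
        if not (self.c50 > 0):
            raise InvalidParameterError("c50 must be positive")
        if not (self.hill > 0):
            raise InvalidParameterError("hill slope must be positive")
        if self.bottom == self.top:
            raise InvalidParameterError("bottom == top gives a degenerate curve")
        return self

    @property
    def c50_label(self) -> str:
        return "EC50" if self.mode == STIMULATION else "IC50"


def true_response(dose_nM, params: FourPLParams):
    """Evaluate the 4PL at one or many non-negative doses.

    At dose 0 the curve takes its zero-dose asymptote exactly (``bottom``
    for stimulation, ``top`` for inhibition); at ``dose == c50`` it is the
    midpoint of the two asymptotes.
    """
    params.validate()
    dose = np.asarray(dose_nM, dtype=float)
    if np.any(dose < 0):
        raise InvalidParameterError("dose must be non-negative")
    # occupancy fraction in [0, 1]: d^h / (d^h + c50^h), exactly 0 at d=0
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(dose > 0, (params.c50 / np.maximum(dose, 1e-300)) ** params.hill, np.inf)
    frac = 1.0 / (1.0 + ratio)
    if params.mode == STIMULATION:
        out = params.bottom + (params.top - params.bottom) * frac
    else:
        out = params.top + (params.bottom - params.top) * frac
    if np.isscalar(dose_nM):
        return float(out)
    return out


def occupancy_fraction(dose_nM, params: FourPLParams):
    """Fractional response ``(response - zero asymptote) / (span)`` in [0, 1]."""
    resp = true_response(dose_nM, params)
    zero = params.bottom if params.mode == STIMULATION else params.top
    other = params.top if params.mode == STIMULATION else params.bottom
    return (np.asarray(resp) - zero) / (other - zero)
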