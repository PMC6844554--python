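"""Synthetic RT-qPCR Ct tables for the comparative-Ct analysis.

Models an experiment in which treatment lowers the target-gene Ct by a
known number of cycles while a housekeeping normalizer (beta-actin) is
unchanged, so the downstream 2^-ddCt fold change has a known truth
(``2**shift_cycles`` on average).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError

NORMALIZER = "ACTB"
NORMALIZER_CT_MEAN = 15.0
NORMALIZER_CT_SD = 0.1
TARGET_CT_MEAN = 24.0


def generate_ct_table(
    n_replicates: int,
    shift_cycles: float,
    noise_sd: float,
    seed,
    *,
    genes: tuple[str, ...] = ("SREBF1", "FASN"),
) -> pd.DataFrame:
    """Return a tidy Ct table (sample, group, gene, replicate, ct).

    Every sample carries one normalizer (ACTB) row, drawn from
    N(15, 0.1) in both groups, plus one row per target gene: vehicle
    targets from N(24, noise_sd) and treated targets with the mean
    lowered by ``shift_cycles``.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("vehicle", "treated"):
        shift = shift_cycles if group == "treated" else 0.0
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": NORMALIZER,
                    "replicate": rep,
                    "ct": rng.normal(NORMALIZER_CT_MEAN, NORMALIZER_CT_SD),
                }
            )
            for gene in genes:
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": rng.normal(TARGET_CT_MEAN - shift, noise_sd),
                    }
                )
    table = pd.DataFrame(rows)
    if (table["ct"] <= 0).any():
        raise InvalidParameterError("generated Ct values must be positive")
    return table
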