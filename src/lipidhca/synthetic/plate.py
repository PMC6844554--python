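"""Plate presets: multi-condition experiment layouts with ground truth.

Each preset mirrors one of the assay designs the pipeline analyses:

- ``fig1_14day``    long-exposure lipid accumulation (vehicle, 5, 50 nM; 14 d)
- ``fig2_timedose`` dose x time lipid grid ({0, 0.05, 0.5, 5, 50} nM x {24, 48, 72} h)
- ``fig3_2dg``      glycolysis-inhibitor co-treatment plus smFISH spot channels
- ``fig4_rxra``     nuclear RXRA dose series (inhibitory response)
- ``fig6_dual``     RXRA + lipid dual labelling (vehicle vs 50 nM)
- ``s3_pparg``      RXRA + PPARG dual labelling (vehicle vs 50 nM)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..errors import InvalidParameterError
from .config import FieldConfig
from .field import generate_field

LIPID_DOSES = (0.0, 0.05, 0.5, 5.0, 50.0)


@dataclass(frozen=True)
class Condition:
    dose_nM: float
    time_h: float
    treatment: str
    channels: tuple[str, ...]
    lipid_dose_nM: float | None = None
    receptor_dose_nM: float | None = None
    spot_group: str | None = None


def _lipid_condition(dose, time_h, channels=("dna", "lipid")):
    return Condition(dose, time_h, "vehicle" if dose == 0 else "TBT", tuple(channels))


def _build_presets() -> dict[str, list[Condition]]:
    presets: dict[str, list[Condition]] = {}
    presets["fig1_14day"] = [_lipid_condition(d, 336.0) for d in (0.0, 5.0, 50.0)]
    presets["fig2_timedose"] = [
        _lipid_condition(d, t) for t in (24.0, 48.0, 72.0) for d in LIPID_DOSES
    ]
    fish = ("dna", "lipid", "spots_SREBF1", "spots_FASN")
    presets["fig3_2dg"] = [
        Condition(0.0, 72.0, "vehicle", fish, spot_group="vehicle"),
        Condition(50.0, 72.0, "TBT", fish, spot_group="treated"),
        Condition(50.0, 72.0, "TBT+2DG", ("dna", "lipid"), lipid_dose_nM=0.0),
        Condition(0.0, 72.0, "2DG", ("dna", "lipid"), lipid_dose_nM=0.0),
    ]
    presets["fig4_rxra"] = [
        Condition(d, 72.0, "vehicle" if d == 0 else "TBT", ("dna", "rxra"))
        for d in LIPID_DOSES
    ]
    presets["fig6_dual"] = [
        Condition(d, 72.0, "vehicle" if d == 0 else "TBT", ("dna", "lipid", "rxra"))
        for d in (0.0, 50.0)
    ]
    presets["s3_pparg"] = [
        Condition(d, 72.0, "vehicle" if d == 0 else "TBT", ("dna", "rxra", "pparg"))
        for d in (0.0, 50.0)
    ]
    return presets


PRESETS = _build_presets()


@dataclass
class PlateResult:
    """Manifest plus in-memory fields and pooled ground truth."""

    preset: str
    seed: int
    manifest: pd.DataFrame
    fields: list
    cells: pd.DataFrame
    droplets: pd.DataFrame
    out_dir: Path | None = None


def field_seed(plate_seed: int, index: int) -> int:
    """Deterministic, manifest-recordable per-field seed."""
    return (int(plate_seed) * 1_000_003 + 7919 * index + 1) % (2**31)


def generate_plate(
    preset: str,
    seed: int,
    *,
    config: FieldConfig | None = None,
    n_fields: int = 4,
    out_dir=None,
    condition_filter=None,
) -> PlateResult:
    """Generate every field of a preset (optionally writing TIFFs + CSVs).

    ``condition_filter`` is an optional predicate on :class:`Condition`
    used to restrict a preset to a subset of its conditions (e.g. a single
    time point). ``n_fields`` imaging sites are generated per condition.
    """
    if preset not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    if n_fields < 1:
        raise InvalidParameterError("n_fields must be >= 1")
    config = config or FieldConfig()
    conditions = [c for c in PRESETS[preset] if condition_filter is None or condition_filter(c)]
    if not conditions:
        raise InvalidParameterError("condition filter removed every condition")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    fields = []
    all_cells = []
    all_droplets = []
    idx = 0
    for ci, cond in enumerate(conditions):
        well = f"W{ci + 1:02d}"
        for fi in range(n_fields):
            fid = f"{preset}_{well}_f{fi + 1:02d}"
            fseed = field_seed(seed, idx)
            idx += 1
            image, truth = generate_field(
                config,
                cond.dose_nM,
                cond.time_h,
                fseed,
                treatment=cond.treatment,
                channels=cond.channels,
                lipid_dose_nM=cond.lipid_dose_nM,
                receptor_dose_nM=cond.receptor_dose_nM,
                spot_group=cond.spot_group,
                field_id=fid,
            )
            row = {
                "field_id": fid,
                "well": well,
                "dose_nM": cond.dose_nM,
                "time_h": cond.time_h,
                "treatment": cond.treatment,
                "seed": fseed,
                "channels": ",".join(cond.channels),
            }
            if out_path is not None:
                import tifffile

                for ch in cond.channels:
                    fname = f"{preset}_{well}_f{fi + 1:02d}_{ch}.tif"
                    tifffile.imwrite(out_path / fname, image.channels[ch])
                    row[f"file_{ch}"] = fname
            rows.append(row)
            fields.append((image, truth))
            all_cells.append(truth.cells)
            all_droplets.append(truth.droplets)

    manifest = pd.DataFrame(rows)
    cells = pd.concat(all_cells, ignore_index=True)
    droplets = pd.concat(all_droplets, ignore_index=True)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        cells.to_csv(out_path / "cells.csv", index=False)
        droplets.to_csv(out_path / "droplets.csv", index=False)
    return PlateResult(
        preset=preset,
        seed=int(seed),
        manifest=manifest,
        fields=fields,
        cells=cells,
        droplets=droplets,
        out_dir=out_path,
    )
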