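"""Orchestration: simulate -> segment -> quantify -> statistics.

Stage boundaries are plain files (TIFF rasters, CSV tables, JSON stats)
so every stage is independently runnable and replaceable; `run_experiment`
wires them together for the built-in plate presets with full provenance
(seed, config hash, per-field parameters) and bit-identical reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageField, LabelMask
from .fourpl import INHIBITION, STIMULATION
from .quantify import QCParams, SpotParams, count_spots, measure_objects, qc_filter
from .segmentation import (
    SegmentationParams,
    assign_compartments,
    identify_cells,
    identify_droplets,
    identify_nuclei,
    nearest_nucleus_regions,
)
from .stats import (
    ddct,
    dunn_posttest,
    fit_4pl,
    kruskal_wallis,
    large_droplet_fraction,
    mann_whitney,
    normalize_to_vehicle,
    spearman,
    stratify_high_low,
)
from .synthetic import FieldConfig, generate_ct_table, generate_plate

log = logging.getLogger("lipidhca")

VEHICLE = "vehicle"


@dataclass
class RunConfig:
    """One reproducible experiment: preset, seed, and all stage parameters."""

    preset: str
    seed: int
    out_dir: str | None = None
    n_fields: int = 4
    field_config: FieldConfig = dc_field(default_factory=FieldConfig)
    seg_params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    qc_params: QCParams = dc_field(default_factory=QCParams)
    spot_params: SpotParams = dc_field(default_factory=SpotParams)
    save_images: bool = False
    save_masks: bool = False

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["field_config"] = self.field_config.to_dict()
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        for key in ("out_dir", "save_images", "save_masks"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# segmentation + quantification of whole fields
# --------------------------------------------------------------------------


def segment_field(field: ImageField, params: SegmentationParams | None = None) -> dict:
    """Run the full object hierarchy on one field.

    Returns a dict with ``nuclei``, ``cells``, ``cytoplasm``, ``droplets``
    masks, the ``parent_of`` droplet->cell map, and ``spot_regions`` (the
    distance-capped nearest-nucleus partition used for spot assignment).
    """
    params = (params or SegmentationParams()).validate()
    nuclei = identify_nuclei(field.channels["dna"], params)
    stain = field.channels.get("lipid")
    cells = identify_cells(nuclei, stain, params)
    if stain is not None:
        droplets = identify_droplets(stain, params)
    else:
        droplets = LabelMask(np.zeros(field.shape, dtype=np.int32), "droplets")
    cytoplasm, parent_of = assign_compartments(cells, nuclei, droplets)
    spot_regions = nearest_nucleus_regions(nuclei, params.cell_max_distance_px)
    return {
        "nuclei": nuclei,
        "cells": cells,
        "cytoplasm": cytoplasm,
        "droplets": droplets,
        "parent_of": parent_of,
        "spot_regions": spot_regions,
    }


def process_field(
    field: ImageField,
    seg_params: SegmentationParams | None = None,
    qc_params: QCParams | None = None,
    spot_params: SpotParams | None = None,
):
    """Segment, measure and QC-flag one field. Returns (cells, droplets)."""
    masks = segment_field(field, seg_params)
    cells, droplets = measure_objects(
        field, masks["nuclei"], masks["cells"], masks["cytoplasm"], masks["droplets"],
        masks["parent_of"],
    )
    for ch in field.channels:
        if ch.startswith("spots_"):
            counts = count_spots(field.channels[ch], masks["spot_regions"], spot_params)
            gene = ch.split("_", 1)[1]
            col = counts.reindex(cells["cell_label"]).to_numpy()
            cells[f"spot_count_{gene}"] = col
    cells = qc_filter(cells, qc_params)
    return cells, droplets


def process_plate(plate, seg_params=None, qc_params=None, spot_params=None):
    """Apply `process_field` to every field of a generated plate."""
    all_cells = []
    all_droplets = []
    for image, _truth in plate.fields:
        c, d = process_field(image, seg_params, qc_params, spot_params)
        all_cells.append(c)
        all_droplets.append(d)
    cells = pd.concat(all_cells, ignore_index=True)
    droplets = pd.concat(all_droplets, ignore_index=True)
    return cells, droplets


# --------------------------------------------------------------------------
# condition summaries and per-preset analyses
# --------------------------------------------------------------------------


def _passing(cells: pd.DataFrame) -> pd.DataFrame:
    if "qc_flag" in cells.columns:
        return cells[cells["qc_flag"] == "pass"]
    return cells


def summarize_conditions(cells: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-condition table: n, medians/means, fold change vs time-matched vehicle.

    Conditions are (treatment, dose_nM, time_h) groups of QC-passing
    cells. Fold changes compare each condition's median to the vehicle
    condition at the same time point. Conditions with zero passing cells
    are retained and flagged.
    """
    keys = ["treatment", "dose_nM", "time_h"]
    if design is not None:
        conditions = design[keys].drop_duplicates()
    else:
        conditions = cells[keys].drop_duplicates()
    passing = _passing(cells)
    rows = []
    for _, cond in conditions.iterrows():
        sel = passing[
            (passing["treatment"] == cond["treatment"])
            & (passing["dose_nM"] == cond["dose_nM"])
            & (passing["time_h"] == cond["time_h"])
        ]
        row = dict(cond)
        row["n_cells"] = int(len(sel))
        row["flagged_empty"] = len(sel) == 0
        for col in (
            "total_lipid_integrated_intensity",
            "droplet_count",
            "nuclear_mean_rxra",
            "nuclear_mean_pparg",
        ):
            if col in passing.columns:
                row[f"median_{col}"] = float(sel[col].median()) if len(sel) else float("nan")
                row[f"mean_{col}"] = float(sel[col].mean()) if len(sel) else float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)
    # fold change vs time-matched vehicle
    for col in ("median_total_lipid_integrated_intensity", "median_droplet_count",
                "median_nuclear_mean_rxra"):
        if col not in summary.columns:
            continue
        fold = []
        for _, row in summary.iterrows():
            veh = summary[
                (summary["treatment"] == VEHICLE) & (summary["time_h"] == row["time_h"])
            ]
            ref = float(veh[col].iloc[0]) if len(veh) else float("nan")
            fold.append(row[col] / ref if ref and np.isfinite(ref) and ref != 0 else float("nan"))
        summary[f"fold_{col}"] = fold
    return summary


def lipid_dose_response(
    cells: pd.DataFrame,
    time_h: float = 72.0,
    response: str = "cell_lipid",
    aggregate: str = "median",
):
    """4PL fit of the lipid response across doses at one time point.

    ``response`` selects the per-cell readout: ``cell_lipid`` (integrated
    stain over the whole cytoplasm — the default "total lipid content per
    cell", robust to droplet fusion at high load), ``total_lipid`` (sum
    over segmented child droplets) or ``droplet_count``. The
    per-condition aggregate is the median by default (robust to the
    heavy right tail), mean via ``aggregate="mean"``.
    """
    col = {
        "droplet_count": "droplet_count",
        "total_lipid": "total_lipid_integrated_intensity",
        "cell_lipid": "cytoplasm_lipid_integrated_intensity",
    }.get(response, response)
    passing = _passing(cells)
    sel = passing[
        (passing["time_h"] == time_h) & (passing["treatment"].isin([VEHICLE, "TBT"]))
    ]
    agg = sel.groupby("dose_nM")[col].median() if aggregate == "median" else sel.groupby("dose_nM")[col].mean()
    return fit_4pl(agg.index.to_numpy(float), agg.to_numpy(float), STIMULATION)


def rxra_dose_response(cells: pd.DataFrame, time_h: float = 72.0):
    """Inhibitory 4PL (IC50) fit of median nuclear RXRA across doses."""
    passing = _passing(cells)
    sel = passing[
        (passing["time_h"] == time_h) & (passing["treatment"].isin([VEHICLE, "TBT"]))
    ]
    agg = sel.groupby("dose_nM")["nuclear_mean_rxra"].median()
    return fit_4pl(agg.index.to_numpy(float), agg.to_numpy(float), INHIBITION)


def _condition_values(cells, column, treatment, dose=None):
    passing = _passing(cells)
    sel = passing[passing["treatment"] == treatment]
    if dose is not None:
        sel = sel[sel["dose_nM"] == dose]
    return sel[column].to_numpy(float)


def analyze_preset(preset: str, cells: pd.DataFrame, droplets: pd.DataFrame, seed: int) -> dict:
    """Run the figure-appropriate statistics for a preset's measured tables."""
    out: dict = {"preset": preset}
    if cells.empty or _passing(cells).empty:
        out["status"] = "empty"
        return out
    out["status"] = "ok"
    passing = _passing(cells)

    if preset in ("fig1_14day", "fig2_timedose", "fig3_2dg", "fig6_dual"):
        # pooled droplet-area tail enrichment, vehicle vs top dose
        top_dose = passing["dose_nM"].max()
        veh_fields = passing.loc[passing["treatment"] == VEHICLE, "field_id"].unique()
        trt_fields = passing.loc[
            (passing["treatment"] == "TBT") & (passing["dose_nM"] == top_dose), "field_id"
        ].unique()
        v_areas = droplets.loc[
            droplets["field_id"].isin(veh_fields) & droplets["parent_cell_label"].notna(),
            "area_px",
        ].to_numpy(float)
        t_areas = droplets.loc[
            droplets["field_id"].isin(trt_fields) & droplets["parent_cell_label"].notna(),
            "area_px",
        ].to_numpy(float)
        if v_areas.size >= 2 and t_areas.size:
            out["large_droplet"] = large_droplet_fraction(v_areas, t_areas).to_dict()

    if preset in ("fig1_14day", "fig2_timedose"):
        for t in sorted(passing["time_h"].unique()):
            sub = passing[passing["time_h"] == t]
            groups = [
                g["total_lipid_integrated_intensity"].to_numpy(float)
                for _, g in sub.groupby("dose_nM")
            ]
            if len(groups) >= 2:
                kw = kruskal_wallis(groups)
                kw.pairwise = dunn_posttest(groups) if len(groups) >= 3 else None
                out[f"kruskal_total_lipid_{int(t)}h"] = kw.to_dict()

    if preset == "fig2_timedose" and (passing["time_h"] == 72.0).any():
        out["ec50_fit_cell_lipid"] = lipid_dose_response(cells, 72.0, "cell_lipid").to_dict()
        out["ec50_fit_total_lipid"] = lipid_dose_response(cells, 72.0, "total_lipid").to_dict()
        out["ec50_fit_droplet_count"] = lipid_dose_response(
            cells, 72.0, "droplet_count"
        ).to_dict()

    if preset == "fig3_2dg":
        veh = _condition_values(cells, "total_lipid_integrated_intensity", VEHICLE)
        z_by_treatment = {}
        for trt, g in passing.groupby("treatment"):
            z = normalize_to_vehicle(
                g["total_lipid_integrated_intensity"].to_numpy(float), veh, "zscore"
            )
            z_by_treatment[trt] = float(np.median(z))
        out["zscore_median_total_lipid"] = z_by_treatment
        groups = [
            g["total_lipid_integrated_intensity"].to_numpy(float)
            for _, g in passing.groupby("treatment")
        ]
        kw = kruskal_wallis(groups)
        kw.pairwise = dunn_posttest(groups)
        out["kruskal_treatments"] = kw.to_dict()
        for gene in ("SREBF1", "FASN"):
            col = f"spot_count_{gene}"
            if col in passing.columns:
                a = _condition_values(cells, col, "TBT")
                b = _condition_values(cells, col, VEHICLE)
                a, b = a[~np.isnan(a)], b[~np.isnan(b)]
                if a.size and b.size:
                    out[f"spots_{gene}"] = {
                        "median_vehicle": float(np.median(b)),
                        "median_treated": float(np.median(a)),
                        "mann_whitney": mann_whitney(a, b).to_dict(),
                    }
        ct = generate_ct_table(3, 1.0, 0.2, seed)
        out["ddct"] = ddct(ct).to_dict()

    if preset == "fig4_rxra":
        fit = rxra_dose_response(cells)
        out["ic50_fit_rxra"] = fit.to_dict()
        top_dose = passing["dose_nM"].max()
        veh = _condition_values(cells, "nuclear_mean_rxra", VEHICLE)
        trt = _condition_values(cells, "nuclear_mean_rxra", "TBT", top_dose)
        out["rxra_fold_down_top_dose"] = float(np.median(veh) / np.median(trt))
        out["rxra_mann_whitney"] = mann_whitney(trt, veh).to_dict()
        groups = [
            g["nuclear_mean_rxra"].to_numpy(float) for _, g in passing.groupby("dose_nM")
        ]
        kw = kruskal_wallis(groups)
        kw.pairwise = dunn_posttest(groups)
        out["kruskal_rxra"] = kw.to_dict()

    if preset == "fig6_dual":
        for trt in (VEHICLE, "TBT"):
            sub = passing[passing["treatment"] == trt]
            if len(sub) >= 3:
                out[f"spearman_rxra_lipid_{trt}"] = spearman(
                    sub["nuclear_mean_rxra"], sub["cytoplasm_lipid_integrated_intensity"]
                ).to_dict()
                out[f"spearman_rxra_droplets_{trt}"] = spearman(
                    sub["nuclear_mean_rxra"], sub["droplet_count"]
                ).to_dict()
        veh = passing[passing["treatment"] == VEHICLE]
        ref = (float(veh["nuclear_mean_rxra"].mean()), float(veh["droplet_count"].mean()))
        for trt in (VEHICLE, "TBT"):
            sub = passing[passing["treatment"] == trt]
            if len(sub):
                out[f"stratification_{trt}"] = stratify_high_low(
                    sub["nuclear_mean_rxra"], sub["droplet_count"], ref
                ).to_dict()

    if preset == "s3_pparg":
        for trt in (VEHICLE, "TBT"):
            sub = passing[passing["treatment"] == trt]
            if len(sub) >= 3:
                out[f"spearman_rxra_pparg_{trt}"] = spearman(
                    sub["nuclear_mean_rxra"], sub["nuclear_mean_pparg"]
                ).to_dict()
    return out


# --------------------------------------------------------------------------
# the end-to-end run
# --------------------------------------------------------------------------


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


@dataclass
class ReportBundle:
    """Everything one run produced, with provenance."""

    config: RunConfig
    manifest: pd.DataFrame
    cells: pd.DataFrame
    droplets: pd.DataFrame
    summary: pd.DataFrame
    stats: dict
    truth_cells: pd.DataFrame
    truth_droplets: pd.DataFrame

    @property
    def status(self) -> str:
        return self.stats.get("status", "ok")


def run_experiment(config: RunConfig) -> ReportBundle:
    """Execute simulate -> segment -> quantify -> stats for one config.

    With ``out_dir`` set, writes manifest/cells/droplets/summary CSVs,
    ``stats.json`` and the serialized config (with its hash and seed) —
    reruns with the same config and seed are bit-identical. An empty
    simulation (zero cells) yields a graceful empty report, not an error.
    """
    config.field_config.validate()
    config.seg_params.validate()
    config.qc_params.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    log.info("simulating preset %s (seed %d)", config.preset, config.seed)
    log.info("segmentation parameters: %s", config.seg_params)
    log.info("qc parameters: %s", config.qc_params)
    plate = generate_plate(
        config.preset,
        config.seed,
        config=config.field_config,
        n_fields=config.n_fields,
        out_dir=(out_dir / "images") if (out_dir and config.save_images) else None,
    )
    log.info("segmenting and quantifying %d fields", len(plate.fields))
    try:
        cells, droplets = process_plate(
            plate, config.seg_params, config.qc_params, config.spot_params
        )
    except Exception as exc:  # stage-tagged failure
        raise RuntimeError(f"stage 'segment/quantify' failed: {exc}") from exc

    if out_dir and config.save_masks:
        from . import io as lio

        mask_dir = out_dir / "masks"
        for image, _ in plate.fields:
            masks = segment_field(image, config.seg_params)
            lio.write_masks(mask_dir, image.metadata["field_id"], masks)

    summary = summarize_conditions(cells, plate.manifest) if not cells.empty else pd.DataFrame()
    try:
        stats = analyze_preset(config.preset, cells, droplets, config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
    stats["seed"] = config.seed
    stats["config_hash"] = config.config_hash()
    stats["n_cells_total"] = int(len(cells))
    stats["n_cells_pass"] = int(len(_passing(cells)))

    if out_dir:
        plate.manifest.to_csv(out_dir / "manifest.csv", index=False)
        cells.to_csv(out_dir / "cells.csv", index=False)
        droplets.to_csv(out_dir / "droplets.csv", index=False)
        plate.cells.to_csv(out_dir / "truth_cells.csv", index=False)
        plate.droplets.to_csv(out_dir / "truth_droplets.csv", index=False)
        if not summary.empty:
            summary.to_csv(out_dir / "summary.csv", index=False)
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True, default=_json_default)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
    return ReportBundle(
        config=config,
        manifest=plate.manifest,
        cells=cells,
        droplets=droplets,
        summary=summary,
        stats=stats,
        truth_cells=plate.cells,
        truth_droplets=plate.droplets,
    )
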