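"""End-to-end pre/post-capsaicin comparison and projection-neuron typing.

Composes the stages — preprocessing, responder detection, family
assignment, vector tuning, receptive fields, CICADA profiling/clustering,
capsaicin classification — into a single report of what changed after the
injection: per-family responder percentages, per-cell receptive-field
deltas and fold-changes, and the standardized tuning-angle shift toward
the low-threshold axis, aggregated by CICADA cluster and by
spinoparabrachial (SPB) functional class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cicada import build_profiles, cluster_profiles, cluster_summary
from .config import BASIS_ANGLES_CARDINAL, BASIS_ANGLES_MECHANICAL, PipelineConfig
from .data import LIGANDS, STIMULUS_FAMILIES, DffSet, EventTimeline, RoiTable, TraceSet
from .errors import AlignmentError
from .io import write_report
from .preprocess import preprocess_traces
from .response import (
    assign_family_response,
    build_response_table,
    capsaicin_calls,
)
from .tuning import rf_from_calls, standardize_angles, tuning_from_families

#: Families that count as low-threshold mechanical for SPB classification.
LT_CLASS_FAMILIES = ("brush", "static_LT")

#: Cardinal tuning aggregates families into three modalities.
CARDINAL_MODALITY_MAP = {
    "heat": ("heat",),
    "mechanical": ("brush", "static_LT", "static_HT"),
    "cold": ("cold",),
}

#: Mechanical sub-modality tuning compares the three mechanical families.
MECHANICAL_MODALITY_MAP = {
    "brush": ("brush",),
    "static_LT": ("static_LT",),
    "static_HT": ("static_HT",),
}

#: Basis angle of the static low-threshold axis (allodynia direction).
LT_AXIS_DEG = BASIS_ANGLES_MECHANICAL["static_LT"]


def classify_spbn(
    family_responses: Mapping[str, bool],
    peak_amps: Mapping[str, float],
    wdr_ratio: float = 1.2,
) -> str:
    """Functional class of a projection neuron: WDR, HT, LT, or unclassified.

    Wide-dynamic-range (WDR) cells respond to both low-intensity input
    (brush or the 0.16 g filament) and the 2.0 g filament *and* encode
    intensity: the HT peak must be at least ``wdr_ratio`` times the best
    low-threshold peak.  HT cells respond to the 2.0 g filament but not to
    low-threshold input; LT cells respond only to brush and/or 0.16 g.
    Anything else (e.g. thermal-only cells) is unclassified.
    """
    lt_resp = any(family_responses.get(f, False) for f in LT_CLASS_FAMILIES)
    ht_resp = family_responses.get("static_HT", False)
    if not lt_resp and not ht_resp:
        return "unclassified"
    if lt_resp and ht_resp:
        lt_peak = max(peak_amps.get(f, 0.0) for f in LT_CLASS_FAMILIES)
        ht_peak = peak_amps.get("static_HT", 0.0)
        return "WDR" if ht_peak >= wdr_ratio * lt_peak else "unclassified"
    return "HT" if ht_resp else "LT"


@dataclass
class SensitizationReport:
    """Everything the pre/post comparison produces, as tidy tables."""

    family_deltas: pd.DataFrame
    cell_deltas: pd.DataFrame
    cluster_deltas: pd.DataFrame
    tuning: pd.DataFrame
    rf: pd.DataFrame
    capsaicin: pd.DataFrame
    spbn_classes: pd.DataFrame
    summary: dict = field(default_factory=dict)


def pre_post_deltas(
    family_table: pd.DataFrame,
    rf_table: pd.DataFrame,
    tuning_table: pd.DataFrame,
    capsaicin_table: Optional[pd.DataFrame] = None,
    cluster_labels: Optional[pd.Series] = None,
    spbn_classes: Optional[pd.Series] = None,
    lt_axis_deg: float = LT_AXIS_DEG,
) -> SensitizationReport:
    """Assemble the sensitization report from per-block stage outputs.

    ``family_table``/``rf_table``/``tuning_table`` must contain both blocks
    computed with identical configuration.  The tuning-angle shift is
    reported as movement *toward* the LT axis: the drop in absolute
    standardized angle from pre to post (positive = shifted toward LT).

    Raises
    ------
    AlignmentError
        If the pre and post blocks of the family table cover different
        cells.
    """
    pre_cells = set(family_table.loc[family_table["block"] == "pre", "cell_id"])
    post_cells = set(family_table.loc[family_table["block"] == "post", "cell_id"])
    if post_cells and pre_cells != post_cells:
        missing = sorted(pre_cells ^ post_cells)
        raise AlignmentError(f"pre/post cell sets differ; mismatched: {missing[:10]}")

    # per-family responder percentages and deltas
    fam_rows = []
    for fam in STIMULUS_FAMILIES:
        sub = family_table[family_table["family"] == fam]
        if not len(sub):
            continue
        pct = {
            blk: 100.0 * g["responder"].mean()
            for blk, g in sub.groupby("block")
        }
        fam_rows.append(
            {
                "family": fam,
                "pct_pre": pct.get("pre", np.nan),
                "pct_post": pct.get("post", np.nan),
                "delta_pct": pct.get("post", np.nan) - pct.get("pre", np.nan),
            }
        )
    family_deltas = pd.DataFrame(fam_rows)

    # per-cell RF and tuning deltas
    def _pivot(df: pd.DataFrame, value: str) -> pd.DataFrame:
        if not len(df):
            return pd.DataFrame(columns=["pre", "post"])
        return df.pivot_table(index="cell_id", columns="block", values=value, aggfunc="first")

    rf_lt = rf_table[rf_table["family"] == "static_LT"] if len(rf_table) else rf_table
    rf_piv = _pivot(rf_lt, "size")
    ang_piv = _pivot(tuning_table, "angle_deg")
    cells = sorted(pre_cells | post_cells)
    rows = []
    for cid in cells:
        row: dict = {"cell_id": cid}
        if cid in rf_piv.index:
            pre_size = rf_piv.at[cid, "pre"] if "pre" in rf_piv.columns else np.nan
            post_size = rf_piv.at[cid, "post"] if "post" in rf_piv.columns else np.nan
            row["rf_size_pre"] = pre_size
            row["rf_size_post"] = post_size
            row["rf_delta"] = post_size - pre_size
            row["rf_fold"] = post_size / pre_size if pre_size and pre_size > 0 else np.nan
        if cid in ang_piv.index:
            pre_a = ang_piv.at[cid, "pre"] if "pre" in ang_piv.columns else np.nan
            post_a = ang_piv.at[cid, "post"] if "post" in ang_piv.columns else np.nan
            row["angle_pre"] = pre_a
            row["angle_post"] = post_a
            if np.isfinite(pre_a) and np.isfinite(post_a):
                row["shift_toward_lt"] = abs(standardize_angles(pre_a, lt_axis_deg)) - abs(
                    standardize_angles(post_a, lt_axis_deg)
                )
        if capsaicin_table is not None and len(capsaicin_table):
            sel = capsaicin_table[capsaicin_table["cell_id"] == cid]
            if len(sel):
                row["capsaicin_responder"] = bool(sel["capsaicin_responder"].iloc[0])
        if cluster_labels is not None:
            row["cluster"] = cluster_labels.get(cid, None)
        if spbn_classes is not None:
            row["spb_class"] = spbn_classes.get(cid, None)
        rows.append(row)
    cell_deltas = pd.DataFrame(rows)

    # aggregate per cluster
    clus_rows = []
    if cluster_labels is not None and len(cell_deltas):
        lab = cell_deltas.get("cluster")
        for c in sorted({v for v in (lab.dropna() if lab is not None else []) }):
            ids = set(cell_deltas.loc[cell_deltas["cluster"] == c, "cell_id"])
            sub_fam = family_table[family_table["cell_id"].isin(ids)]
            rec: dict = {"cluster": c, "n_cells": len(ids)}
            for fam in ("static_LT", "static_HT", "heat", "cold", "brush"):
                f = sub_fam[sub_fam["family"] == fam]
                if len(f):
                    pre = 100.0 * f.loc[f["block"] == "pre", "responder"].mean()
                    post = 100.0 * f.loc[f["block"] == "post", "responder"].mean()
                    rec[f"delta_pct_{fam}"] = post - pre
            sub_cells = cell_deltas[cell_deltas["cluster"] == c]
            rec["mean_rf_fold"] = float(sub_cells["rf_fold"].mean()) if "rf_fold" in sub_cells else np.nan
            rec["mean_shift_toward_lt"] = (
                float(sub_cells["shift_toward_lt"].mean())
                if "shift_toward_lt" in sub_cells
                else np.nan
            )
            clus_rows.append(rec)
    cluster_deltas = pd.DataFrame(clus_rows)

    return SensitizationReport(
        family_deltas=family_deltas,
        cell_deltas=cell_deltas,
        cluster_deltas=cluster_deltas,
        tuning=tuning_table,
        rf=rf_table,
        capsaicin=capsaicin_table if capsaicin_table is not None else pd.DataFrame(),
        spbn_classes=pd.DataFrame(
            {"cell_id": list(spbn_classes.index), "spb_class": list(spbn_classes.values)}
        )
        if spbn_classes is not None
        else pd.DataFrame(),
    )


@dataclass
class PipelineResult:
    """All artifacts of a full run, plus the sensitization report."""

    dffset: DffSet
    response_table: pd.DataFrame
    family_table: pd.DataFrame
    tuning_table: pd.DataFrame
    rf_table: pd.DataFrame
    profiles: pd.DataFrame
    cluster_labels: Optional[pd.Series]
    cluster_table: pd.DataFrame
    capsaicin_table: pd.DataFrame
    report: SensitizationReport


def run_pipeline(
    traces: TraceSet,
    timeline: EventTimeline,
    rois: RoiTable,
    config: PipelineConfig | None = None,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Run every analysis stage on one experiment.

    Stages: dF/F + drift QC -> per-event responder calls -> family
    assignment per block -> mechanical sub-modality tuning and LT/HT
    receptive fields per block -> CICADA profiles and K-means clusters
    (responsive cells only, depth-ordered when ROI depths are present) ->
    capsaicin-responder calls -> pre/post deltas.  When ``out_dir`` is
    given, all result tables plus ``report.json`` (with a config echo and
    software version) are written there with a checksummed manifest.
    """
    cfg = config or PipelineConfig()
    rois.validate_against(traces, cfg.geometry.n_planes)
    dffset = preprocess_traces(traces, cfg)
    response_table = build_response_table(dffset, timeline, cfg)
    stim_calls = response_table[response_table["kind"] == "stimulus"]
    family_table = assign_family_response(stim_calls)
    blocks = sorted(family_table["block"].unique()) if len(family_table) else []

    tuning_parts = []
    for block in blocks:
        tuning_parts.append(
            tuning_from_families(
                family_table, MECHANICAL_MODALITY_MAP, BASIS_ANGLES_MECHANICAL, block
            )
        )
    tuning_table = (
        pd.concat(tuning_parts, ignore_index=True)
        if tuning_parts
        else pd.DataFrame(columns=["cell_id", "block", "angle_deg", "magnitude"])
    )
    rf_table = rf_from_calls(stim_calls, cfg.per_site_area_mm2)

    ligand_calls = response_table[response_table["kind"] == "ligand"]
    profiles = build_profiles(ligand_calls, minmax=cfg.minmax_normalization)
    cluster_labels = None
    cluster_table = pd.DataFrame()
    responsive = profiles[profiles["any_responder"]] if len(profiles) else profiles
    if len(responsive) >= cfg.n_clusters and cfg.n_clusters >= 1:
        X = responsive[[f"norm_{lig}" for lig in LIGANDS]].to_numpy()
        depth_by_cell = rois.df.set_index("cell_id")["depth_um"]
        depths = depth_by_cell.reindex(responsive["cell_id"]).to_numpy()
        res = cluster_profiles(
            X, k=cfg.n_clusters, seed=cfg.seed, n_init=cfg.kmeans_n_init,
            depths=depths if np.isfinite(depths).any() else None,
        )
        cluster_labels = pd.Series(res.labels, index=responsive["cell_id"].to_numpy())
        cluster_table = cluster_summary(
            res.labels,
            responsive.reset_index(drop=True),
            depths=depth_by_cell,
            family_table=family_table,
            k=res.k,
        )

    capsaicin_table = capsaicin_calls(dffset, timeline, cfg)

    spbn_series = None
    spb_ids = rois.df.loc[rois.df["is_spbn"], "cell_id"]
    if len(spb_ids) and len(family_table):
        pre = family_table[family_table["block"] == "pre"]
        classes = {}
        for cid in spb_ids:
            g = pre[pre["cell_id"] == cid]
            if not len(g):
                continue
            resp = dict(zip(g["family"], g["responder"]))
            peaks = {
                f: (p if r else 0.0)
                for f, r, p in zip(g["family"], g["responder"], g["max_peak"])
            }
            classes[cid] = classify_spbn(resp, peaks, cfg.wdr_ratio)
        if classes:
            spbn_series = pd.Series(classes)

    report = pre_post_deltas(
        family_table,
        rf_table,
        tuning_table,
        capsaicin_table=capsaicin_table,
        cluster_labels=cluster_labels,
        spbn_classes=spbn_series,
    )
    report.summary = {
        "n_cells": traces.n_cells,
        "n_kept": len(dffset.kept_ids()),
        "n_events": len(timeline),
        "has_capsaicin": timeline.injection is not None,
        "n_clustered": int(len(cluster_labels)) if cluster_labels is not None else 0,
        "seed": cfg.seed,
    }

    if out_dir is not None:
        tables = {
            "responses": response_table,
            "tuning": tuning_table,
            "rf": rf_table,
            "clusters": _clusters_table(profiles, cluster_labels, rois),
            "families": family_table,
            "capsaicin": capsaicin_table,
            "qc": dffset.qc,
            "cell_deltas": report.cell_deltas,
        }
        write_report(tables, report.summary, out_dir, config_echo=cfg.to_dict())

    return PipelineResult(
        dffset=dffset,
        response_table=response_table,
        family_table=family_table,
        tuning_table=tuning_table,
        rf_table=rf_table,
        profiles=profiles,
        cluster_labels=cluster_labels,
        cluster_table=cluster_table,
        capsaicin_table=capsaicin_table,
        report=report,
    )


def _clusters_table(
    profiles: pd.DataFrame, labels: Optional[pd.Series], rois: RoiTable
) -> pd.DataFrame:
    if not len(profiles):
        return pd.DataFrame()
    out = profiles[["cell_id", "any_responder"] + [f"norm_{lig}" for lig in LIGANDS]].copy()
    depth = rois.df.set_index("cell_id")["depth_um"]
    out["depth_um"] = out["cell_id"].map(depth)
    out["cluster"] = out["cell_id"].map(labels) if labels is not None else np.nan
    return out
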