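"""CICADA: pharmacological cell typing from GPCR-agonist response profiles.

Under TTX, a Ca2+ transient evoked by a bath-applied Gq-GPCR agonist marks
receptor-expressing cells, so the 8-ligand amplitude profile of a cell is a
functional fingerprint of its receptor complement.  Profiles of responsive
cells are normalized per cell as (X - X_min) / X_max (the published form;
note its maximum is below 1 whenever X_min > 0) and clustered with K-means
into putative cell types, numbered Ex1..Exk by ascending median depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .data import LIGANDS
from .errors import ConfigError, SelectionError

#: Floor applied to the mean in the non-responder fallback normalization.
_MEAN_FLOOR = 1e-6


@dataclass
class CicadaProfile:
    """One cell's raw and normalized 8-ligand response vector."""

    cell_id: str
    raw: np.ndarray
    any_responder: bool
    normalized: np.ndarray
    flagged_zero: bool = False
    cluster_label: Optional[int] = None


def normalize_profile(
    raw: Sequence[float],
    any_responder: bool,
    minmax: bool = False,
) -> tuple[np.ndarray, bool]:
    """Normalize an 8-ligand amplitude vector; returns (vector, zero_flag).

    Responsive cells: subtract the smallest of the 8 amplitudes so the
    minimum becomes 0, then divide by the cell's (original) maximum —
    ``(X - X_min) / X_max``.  With ``minmax=True`` the conventional
    ``(X - X_min) / (X_max - X_min)`` form is used instead, for
    sensitivity analysis.

    Non-responsive cells would be dominated by noise if scaled by their own
    (tiny) maximum, so they are divided by the mean response across all
    ligands instead, keeping sub-threshold structure in a comparable range.
    An all-zero non-responder returns the zero vector, flagged.
    """
    x = np.asarray(raw, dtype=float)
    if x.size != len(LIGANDS):
        raise ConfigError(f"expected {len(LIGANDS)} ligand amplitudes, got {x.size}")
    if any_responder:
        xmin, xmax = x.min(), x.max()
        denom = (xmax - xmin) if minmax else xmax
        if denom <= 0:
            return np.zeros_like(x), True
        return (x - xmin) / denom, False
    mean = x.mean()
    if mean <= 0:
        return np.zeros_like(x), True
    return x / max(mean, _MEAN_FLOOR), False


def build_profiles(
    ligand_table: pd.DataFrame,
    minmax: bool = False,
) -> pd.DataFrame:
    """Per-cell CICADA profiles from the per-event ligand response table.

    ``ligand_table`` is the response table restricted to ``kind == ligand``
    rows (one application per ligand).  Returns one row per cell with the
    raw and normalized amplitude for each ligand plus ``any_responder``.
    """
    rows = []
    for cid, g in ligand_table.groupby("cell_id", sort=False):
        raw = np.zeros(len(LIGANDS))
        resp = np.zeros(len(LIGANDS), dtype=bool)
        for i, lig in enumerate(LIGANDS):
            sel = g[g["family"] == lig]
            if len(sel):
                raw[i] = float(sel["peak_amp"].max())
                resp[i] = bool(sel["responder"].any())
        any_resp = bool(resp.any())
        normed, flagged = normalize_profile(raw, any_resp, minmax=minmax)
        row = {"cell_id": cid, "any_responder": any_resp, "flagged_zero": flagged}
        for i, lig in enumerate(LIGANDS):
            row[f"raw_{lig}"] = raw[i]
            row[f"norm_{lig}"] = normed[i]
            row[f"resp_{lig}"] = bool(resp[i])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClusterResult:
    """K-means partition of normalized CICADA profiles."""

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    k: int
    depth_ordered: bool = False
    label_order: list[int] = field(default_factory=list)

    def label_names(self) -> list[str]:
        """Ex1..Exk name for each cell (Ex1 is the most superficial)."""
        return [f"Ex{l + 1}" for l in self.labels]


def cluster_profiles(
    normalized: np.ndarray,
    k: int = 7,
    seed: int = 0,
    n_init: int = 25,
    depths: Optional[np.ndarray] = None,
) -> ClusterResult:
    """K-means on normalized ligand profiles (CICADA-responsive cells only).

    Deterministic for a fixed seed.  When ``depths`` are supplied, cluster
    labels are renumbered by ascending median depth so that label 0 (Ex1)
    is the most superficial population, mirroring the dorso-ventral
    ordering convention.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2:
        raise ConfigError("normalized profile matrix must be 2-D")
    n = X.shape[0]
    if k < 1 or k > n:
        raise ConfigError(f"k={k} out of range for {n} cells")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_
    order = list(range(k))
    depth_ordered = False
    if depths is not None and k > 1:
        depths = np.asarray(depths, dtype=float)
        med = np.array(
            [
                np.nanmedian(depths[labels == c]) if np.any(labels == c) else np.inf
                for c in range(k)
            ]
        )
        order = list(np.argsort(med, kind="stable"))
        remap = np.empty(k, dtype=int)
        for new, old in enumerate(order):
            remap[old] = new
        labels = remap[labels]
        centroids = centroids[order]
        depth_ordered = True
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        k=k,
        depth_ordered=depth_ordered,
        label_order=order,
    )


def select_k(
    normalized: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 25,
    low_silhouette: float = 0.25,
) -> tuple[int, pd.DataFrame]:
    """Choose k by silhouette score over a candidate range.

    Returns the argmax k and the full diagnostic table (silhouette and
    inertia per k).  Warns when even the best silhouette is low — a sign
    the profiles carry no real cluster structure.
    """
    X = np.asarray(normalized, dtype=float)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ConfigError("k_range must not be empty")
    n = X.shape[0]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ConfigError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(X, X[0]):
        raise SelectionError("all profiles identical; k selection is degenerate")
    rows = []
    for k in k_range:
        res = cluster_profiles(X, k=k, seed=seed, n_init=n_init)
        if len(np.unique(res.labels)) < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(X, res.labels))
        rows.append({"k": k, "silhouette": sil, "inertia": res.inertia})
    table = pd.DataFrame(rows)
    if len(k_range) == 1:
        return k_range[0], table
    best = table.loc[table["silhouette"].idxmax()]
    if best["silhouette"] < low_silhouette:
        warnings.warn(
            f"best silhouette {best['silhouette']:.3f} is low; "
            "ligand profiles may not contain distinct cell types",
            stacklevel=2,
        )
    return int(best["k"]), table


def cluster_summary(
    labels: np.ndarray,
    profiles: pd.DataFrame,
    depths: Optional[pd.Series] = None,
    family_table: Optional[pd.DataFrame] = None,
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Per-cluster report: radar means, depth summary, abundance, responders.

    ``profiles`` must be the per-cell profile table (``build_profiles``
    output) aligned row-wise with ``labels``.  Abundances are percentages
    of all clustered cells and sum to 100.  ``family_table`` (pre block)
    adds the percentage of each cluster responding to each stimulus family.
    Empty clusters are recorded with zero abundance.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(profiles):
        raise ConfigError("labels and profiles are not aligned")
    k = k if k is not None else (labels.max() + 1 if labels.size else 0)
    norm_cols = [f"norm_{lig}" for lig in LIGANDS]
    cell_ids = profiles["cell_id"].to_numpy()
    rows = []
    for c in range(k):
        in_c = labels == c
        ids = set(cell_ids[in_c])
        row: dict = {
            "cluster": c,
            "name": f"Ex{c + 1}",
            "n_cells": int(in_c.sum()),
            "abundance_pct": 100.0 * in_c.sum() / len(labels) if len(labels) else 0.0,
        }
        for col in norm_cols:
            row[f"mean_{col.removeprefix('norm_')}"] = (
                float(profiles.loc[in_c, col].mean()) if in_c.any() else 0.0
            )
        if depths is not None:
            d = depths.loc[depths.index.isin(ids)].dropna()
            row["depth_median_um"] = float(d.median()) if len(d) else float("nan")
            row["depth_iqr_um"] = (
                float(d.quantile(0.75) - d.quantile(0.25)) if len(d) else float("nan")
            )
        if family_table is not None and in_c.any():
            pre = family_table[family_table["block"] == "pre"]
            for fam, g in pre.groupby("family", sort=False):
                g = g[g["cell_id"].isin(ids)]
                row[f"pct_resp_{fam}"] = (
                    100.0 * g["responder"].mean() if len(g) else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)
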