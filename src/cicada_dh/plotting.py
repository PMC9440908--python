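"""Small report figures: polar tuning plots and CICADA radar charts."""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import LIGANDS


def plot_tuning(
    angles_deg: Sequence[float],
    magnitudes: Sequence[float],
    ax=None,
    mean_arrow: bool = True,
    **line_kw,
):
    """Polar plot of per-cell tuning vectors with an optional mean arrow.

    The dotted unit circle matches the 1-unit-vector convention of the
    tuning analysis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    r = np.asarray(magnitudes, dtype=float)
    for th, rr in zip(theta, r):
        ax.plot([th, th], [0, rr], alpha=line_kw.pop("alpha", 0.3), **line_kw)
    circle = np.linspace(0, 2 * math.pi, 200)
    ax.plot(circle, np.ones_like(circle), ls=":", color="k", lw=0.8)
    if mean_arrow and len(r):
        x = float(np.mean(r * np.cos(theta)))
        y = float(np.mean(r * np.sin(theta)))
        ax.annotate(
            "",
            xy=(math.atan2(y, x), math.hypot(x, y)),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", lw=2, color="C3"),
        )
    return ax


def plot_radar(
    mean_profile: Mapping[str, float] | Sequence[float],
    ax=None,
    label: Optional[str] = None,
    **line_kw,
):
    """Radar chart of a population's mean normalized ligand responses."""
    import matplotlib.pyplot as plt

    if isinstance(mean_profile, Mapping):
        values = [float(mean_profile[lig]) for lig in LIGANDS]
    else:
        values = [float(v) for v in mean_profile]
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.linspace(0, 2 * math.pi, len(LIGANDS), endpoint=False)
    theta = np.concatenate([theta, theta[:1]])
    vals = np.concatenate([values, values[:1]])
    ax.plot(theta, vals, label=label, **line_kw)
    ax.fill(theta, vals, alpha=0.15)
    ax.set_xticks(theta[:-1])
    ax.set_xticklabels(LIGANDS)
    return ax
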