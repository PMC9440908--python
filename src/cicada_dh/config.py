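"""Pipeline configuration: every tunable constant of the analysis in one place.

The defaults reproduce the published analysis conventions for dorsal-horn
population imaging at 1 Hz: a 5-min rolling 30th-percentile baseline, the
125% dF/F / 6-sigma responder rule with 5 s stimulus and 120 s ligand
windows, the 150%-of-pre capsaicin rule on 2-min averages, a 4x4 cutaneous
grid with ~3.75 mm^2 per site, and the 120-degree tuning basis
(heat/brush +90, mechanical/LT +210, cold/HT +330).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Basis angles (degrees CCW from +x) for cardinal-modality tuning.
BASIS_ANGLES_CARDINAL: dict[str, float] = {"heat": 90.0, "mechanical": 210.0, "cold": 330.0}

#: Basis angles for mechanical sub-modality tuning (same geometry, re-labelled).
BASIS_ANGLES_MECHANICAL: dict[str, float] = {"brush": 90.0, "static_LT": 210.0, "static_HT": 330.0}


@dataclass(frozen=True)
class ImagingGeometry:
    """Field-of-view geometry of the multiphoton recordings.

    Three optical planes are acquired simultaneously, 14 um apart, covering
    roughly lamina I through IIi (0-60 um below the dorsal surface).
    """

    fov_um: tuple[float, float] = (528.2, 220.8)
    shape_px: tuple[int, int] = (512, 214)
    n_planes: int = 3
    plane_spacing_um: float = 14.0
    frame_rate_hz: float = 1.0

    @property
    def um_per_px(self) -> float:
        """Pixel pitch along the long (mediolateral) axis, in um/pixel."""
        return self.fov_um[0] / self.shape_px[0]

    @property
    def plane_offsets_um(self) -> tuple[float, ...]:
        """Absolute z offset of each optical plane relative to plane 0."""
        return tuple(i * self.plane_spacing_um for i in range(self.n_planes))


@dataclass
class PipelineConfig:
    """All analysis tunables with their defaults.

    Attributes
    ----------
    baseline_window_s, baseline_percentile
        Rolling-baseline window (centered, truncated at edges) and the
        percentile used as the baseline value.
    drift_bin_s, drift_limit
        Bin width for the drift QC medians and the maximum tolerated
        (max/min - 1) ratio; 2.0 means a 200% increase is rejected.
    amp_threshold, sigma_mult
        Responder rule: peak dF/F must exceed ``amp_threshold`` *and*
        ``sigma_mult`` times the pre-event noise SD.
    response_window_s, ligand_window_s, noise_window_s
        Response windows for cutaneous stimuli and bath-applied ligands,
        and the pre-event window used for the noise SD.
    capsaicin_factor, capsaicin_window_s, capsaicin_blind_s
        Capsaicin-responder rule: mean dF/F in the 2-min post window must
        exceed ``capsaicin_factor`` times the 2-min pre window, with a
        blind interval excluded on both sides of the injection.
    per_site_area_mm2
        Skin area represented by one responsive grid site (225 mm^2 region,
        16 sites, ~3.75 mm spacing).
    n_clusters, kmeans_n_init
        K-means configuration for CICADA profiles.
    specificity_weight
        Weight on specificity in the threshold-calibration objective
        (values > 1 favor specificity over sensitivity).
    wdr_ratio
        Intensity-coding ratio for the WDR projection-neuron class: the HT
        peak must be at least this multiple of the best LT-class peak.
    minmax_normalization
        If True, use the conventional (x - min)/(max - min) CICADA
        normalization instead of the default (x - min)/max form.
    drift_reference_first_bin
        Alternative reading of the drift rule: deviation of any binned
        median from the first bin, rather than the max/min ratio.
    """

    baseline_window_s: float = 300.0
    baseline_percentile: float = 30.0
    drift_bin_s: float = 300.0
    drift_limit: float = 2.0
    amp_threshold: float = 1.25
    sigma_mult: float = 6.0
    response_window_s: float = 5.0
    ligand_window_s: float = 120.0
    noise_window_s: float = 30.0
    capsaicin_factor: float = 1.5
    capsaicin_window_s: float = 120.0
    capsaicin_blind_s: float = 30.0
    per_site_area_mm2: float = 3.75
    n_clusters: int = 7
    kmeans_n_init: int = 25
    specificity_weight: float = 1.25
    wdr_ratio: float = 1.2
    minmax_normalization: bool = False
    drift_reference_first_bin: bool = False
    lamina_boundaries_um: tuple[float, ...] = (20.0, 40.0)
    basis_angles: dict[str, float] = field(default_factory=lambda: dict(BASIS_ANGLES_CARDINAL))
    geometry: ImagingGeometry = field(default_factory=ImagingGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "baseline_window_s", "drift_bin_s", "drift_limit", "amp_threshold",
            "sigma_mult", "response_window_s", "ligand_window_s", "noise_window_s",
            "capsaicin_factor", "capsaicin_window_s", "per_site_area_mm2",
            "specificity_weight", "wdr_ratio",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0 < self.baseline_percentile < 100:
            raise ConfigError("baseline_percentile must lie in (0, 100)")
        if self.capsaicin_blind_s < 0:
            raise ConfigError("capsaicin_blind_s must be non-negative")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        angles = sorted(self.basis_angles.values())
        if len(angles) != 3:
            raise ConfigError("basis_angles must contain exactly three modalities")
        gaps = {round((b - a) % 360.0, 9) for a, b in zip(angles, angles[1:] + angles[:1])}
        if gaps != {120.0}:
            raise ConfigError("basis angles must be pairwise 120 degrees apart")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            geo = dict(d["geometry"])
            for key in ("fov_um", "shape_px", "plane_offsets_um"):
                if key in geo and isinstance(geo[key], list):
                    geo[key] = tuple(geo[key])
            d["geometry"] = ImagingGeometry(**geo)
        if "lamina_boundaries_um" in d and isinstance(d["lamina_boundaries_um"], list):
            d["lamina_boundaries_um"] = tuple(d["lamina_boundaries_um"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
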