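"""Synthetic dorsal-horn imaging experiments with known ground truth.

The generator emulates what the downstream stages assume about real
recordings: GCaMP6s-like stimulus-locked transients sampled at 1 Hz,
slow ligand-evoked transients in a TTX block at the end of the protocol,
ongoing spontaneous activity, Gaussian shot noise, multiplicative
photobleaching, somatotopic receptive-field placement on the 4x4 cutaneous
grid, and capsaicin effects (direct responders plus low-threshold gain and
receptive-field expansion in the post block).  Every injected response is
recorded in the returned ground truth so recovery can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import LIGANDS, Event, EventTimeline, RoiTable, TraceSet
from .errors import ConfigError

# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class KernelParams:
    """Fluorescence impulse-response and noise parameters.

    The kernel is a difference of exponentials (GCaMP6s-like at 1 Hz
    sampling); bath-ligand responses use a much slower rise/decay pair to
    mimic GPCR second-messenger kinetics.  Bleach is multiplicative
    exponential on raw F so the rolling baseline has realistic work to do.
    """

    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.5
    ligand_rise_tau_s: float = 8.0
    ligand_decay_tau_s: float = 40.0
    noise_sd: float = 0.05
    bleach_fraction_per_h: float = 0.10
    baseline_F: float = 100.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ConfigError("kernel taus must be > 0")
        if self.rise_tau_s >= self.decay_tau_s:
            raise ConfigError("rise tau must be shorter than decay tau")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.bleach_fraction_per_h < 1:
            raise ConfigError("bleach_fraction_per_h must lie in [0, 1)")


@dataclass
class CellSpec:
    """Generative parameters of one synthetic cell.

    Amplitudes are in dF/F units.  ``rf_radius`` is the radius (in grid
    sites) of the disc around ``rf_center`` within which static filament
    stimulation drives the cell.  Sensitization parameters act in the post
    block only: ``lt_gain`` multiplies static-LT amplitudes and
    ``rf_expansion`` multiplies the receptive-field *area* (the radius
    scales by its square root, so the planted factor equals the expected
    fold-change in responsive-site count).  ``capsaicin_direct`` cells
    double their spontaneous event rate for 5 min after the injection.
    """

    archetype: str = ""
    heat_amp: float = 0.0
    cold_amp: float = 0.0
    brush_amp: float = 0.0
    airpuff_amp: float = 0.0
    lt_amp: float = 0.0
    ht_amp: float = 0.0
    rf_center: tuple[float, float] = (1.5, 1.5)
    rf_radius: float = 1.1
    ligand_amps: np.ndarray = field(default_factory=lambda: np.zeros(len(LIGANDS)))
    depth_um: float = 20.0
    is_spbn: bool = False
    lt_gain: float = 1.0
    rf_expansion: float = 1.0
    capsaicin_direct: bool = False
    capsaicin_activity_factor: float = 2.0
    spontaneous_rate_hz: float = 0.25
    spontaneous_amp: float = 0.2
    spontaneous_regularity: float = 10.0

    def __post_init__(self) -> None:
        self.ligand_amps = np.asarray(self.ligand_amps, dtype=float)
        if self.ligand_amps.size != len(LIGANDS):
            raise ConfigError(f"ligand_amps must have length {len(LIGANDS)}")
        for name in (
            "heat_amp", "cold_amp", "brush_amp", "airpuff_amp", "lt_amp", "ht_amp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.rf_radius < 0:
            raise ConfigError("rf_radius must be >= 0")
        if self.lt_gain < 1 or self.rf_expansion < 1:
            raise ConfigError("sensitization gains must be >= 1")

    def static_amplitude(self, family: str, row: int, col: int, block: str) -> float:
        """Amplitude evoked by a static filament at a grid site (0 if outside RF)."""
        radius = self.rf_radius * (
            math.sqrt(self.rf_expansion) if block == "post" else 1.0
        )
        dist = math.hypot(row - self.rf_center[0], col - self.rf_center[1])
        if dist > radius:
            return 0.0
        if family == "static_LT":
            return self.lt_amp * (self.lt_gain if block == "post" else 1.0)
        return self.ht_amp

    def amplitude_for(self, ev: Event) -> float:
        """Injected dF/F amplitude of this cell's response to an event."""
        if ev.kind == "ligand":
            return float(self.ligand_amps[LIGANDS.index(ev.family)])
        if ev.kind == "injection":
            return 0.0  # handled through the spontaneous-rate increase
        if ev.family == "heat":
            return self.heat_amp
        if ev.family == "cold":
            return self.cold_amp
        if ev.family == "brush":
            return self.brush_amp
        if ev.family == "airpuff":
            return self.airpuff_amp
        if ev.family in ("static_LT", "static_HT"):
            return self.static_amplitude(ev.family, ev.grid_row, ev.grid_col, ev.block)
        raise ConfigError(f"no amplitude rule for family '{ev.family}'")


@dataclass
class ProtocolConfig:
    """Timing of the synthetic stimulation protocol.

    Defaults follow the study schedule: dynamic and thermal stimuli 60 s
    apart (brush/airpuff 3x, thermal ramps 2x), receptive-field mapping at
    15 s per site with 2 passes over the 4x4 grid for each filament, a
    capsaicin injection between blocks, a post block identical to the pre
    block, and an end-of-experiment TTX/ligand series (2 min application,
    5 min wash per ligand).  The post block here starts 5 min after
    injection — a desk-scale stand-in for the repeated post-injection
    testing blocks of a full experiment.
    """

    lead_in_s: float = 60.0
    inter_stim_s: float = 60.0
    n_brush: int = 3
    n_airpuff: int = 3
    n_heat: int = 2
    n_cold: int = 2
    include_dynamic: bool = True
    include_thermal: bool = True
    include_grid: bool = True
    n_grid_trials: int = 2
    grid_site_interval_s: float = 15.0
    include_capsaicin: bool = True
    pre_injection_gap_s: float = 200.0
    post_delay_s: float = 300.0
    include_post_block: bool = True
    include_ligands: bool = True
    ligand_duration_s: float = 120.0
    ligand_wash_s: float = 300.0
    stimulus_duration_s: float = 1.0
    tail_s: float = 120.0
    randomize_ligand_order: bool = True


def build_protocol(
    protocol: ProtocolConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> EventTimeline:
    """Lay out the event timeline for one synthetic experiment.

    Grid sites are visited in deterministic row-major order (row 0 col 0..3,
    row 1 col 0..3, ...), one pass per trial.  All onsets land on integer
    seconds so that 1 Hz frames align with event onsets.
    """
    p = protocol or ProtocolConfig()
    rng = rng or np.random.default_rng(0)
    events: list[Event] = []
    t = p.lead_in_s

    def block_events(block: str, start: float) -> float:
        tt = start
        nonlocal events
        if p.include_dynamic:
            for fam, n in (("brush", p.n_brush), ("airpuff", p.n_airpuff)):
                for trial in range(n):
                    events.append(Event("stimulus", fam, tt, p.stimulus_duration_s,
                                        trial_index=trial, block=block))
                    tt += p.inter_stim_s
        if p.include_thermal:
            for fam, n in (("heat", p.n_heat), ("cold", p.n_cold)):
                for trial in range(n):
                    events.append(Event("stimulus", fam, tt, p.stimulus_duration_s,
                                        trial_index=trial, block=block))
                    tt += p.inter_stim_s
        if p.include_grid:
            for fam in ("static_LT", "static_HT"):
                for trial in range(p.n_grid_trials):
                    for row in range(4):
                        for col in range(4):
                            events.append(
                                Event("stimulus", fam, tt, p.stimulus_duration_s,
                                      grid_row=row, grid_col=col,
                                      trial_index=trial, block=block)
                            )
                            tt += p.grid_site_interval_s
        return tt

    t = block_events("pre", t)
    if p.include_capsaicin:
        t += p.pre_injection_gap_s
        events.append(Event("injection", "capsaicin", t, 300.0, block="pre"))
        t += p.post_delay_s
        if p.include_post_block:
            t = block_events("post", t)
    if p.include_ligands:
        t += p.inter_stim_s
        order = (
            list(rng.permutation(len(LIGANDS))) if p.randomize_ligand_order
            else list(range(len(LIGANDS)))
        )
        for li in order:
            events.append(Event("ligand", LIGANDS[li], t, p.ligand_duration_s, block="post"))
            t += p.ligand_duration_s + p.ligand_wash_s
    timeline = EventTimeline(sorted(events, key=lambda e: e.onset_s))
    # round every onset to the frame grid (integer seconds at 1 Hz)
    timeline = EventTimeline(
        [replace(ev, onset_s=float(round(ev.onset_s))) for ev in timeline]
    )
    return timeline


# ---------------------------------------------------------------------------
# population sampling

_ARCHETYPES: dict[str, dict] = {
    # name: (weight among CICADA+ cells, depth um, principal ligands,
    #        modality amplitudes).  Loosely: a superficial polymodal
    #        NKB/SP population, a noxious-tuned SP population, mid-depth
    #        GRP/NMB and CCK mechano populations, and deeper TRH / muscarinic
    #        / oxytocin populations with weak basal drive.
    "Ex1": dict(weight=0.16, depth=8.0, ligs={"NKB": 2.0, "SP": 1.6},
                amps=dict(heat_amp=2.0, cold_amp=1.8, brush_amp=1.8,
                          airpuff_amp=1.6, lt_amp=1.8, ht_amp=2.2),
                rf_radius=1.4, capsaicin_p=0.44),
    "Ex2": dict(weight=0.16, depth=13.0, ligs={"SP": 2.0},
                amps=dict(heat_amp=2.2, cold_amp=0.8, brush_amp=0.6,
                          airpuff_amp=0.4, lt_amp=0.9, ht_amp=2.2),
                rf_radius=1.1, capsaicin_p=0.08),
    "Ex3": dict(weight=0.16, depth=20.0, ligs={"GRP": 2.0, "NMB": 1.8},
                amps=dict(heat_amp=1.8, cold_amp=0.0, brush_amp=1.6,
                          airpuff_amp=1.4, lt_amp=1.6, ht_amp=1.8),
                rf_radius=1.1, capsaicin_p=0.08),
    "Ex4": dict(weight=0.05, depth=26.0, ligs={"CCK": 2.0},
                amps=dict(heat_amp=0.0, cold_amp=0.0, brush_amp=1.4,
                          airpuff_amp=1.2, lt_amp=1.6, ht_amp=2.0),
                rf_radius=1.0, capsaicin_p=0.08),
    "Ex5": dict(weight=0.16, depth=32.0, ligs={"taltirelin": 2.0},
                amps=dict(heat_amp=1.5, cold_amp=0.0, brush_amp=0.7,
                          airpuff_amp=0.5, lt_amp=0.9, ht_amp=1.6),
                rf_radius=1.0, capsaicin_p=0.08),
    "Ex6": dict(weight=0.16, depth=40.0, ligs={"Oxo": 2.0},
                amps=dict(heat_amp=0.9, cold_amp=0.8, brush_amp=0.8,
                          airpuff_amp=0.6, lt_amp=0.9, ht_amp=1.0),
                rf_radius=0.9, capsaicin_p=0.08),
    "Ex7": dict(weight=0.15, depth=48.0, ligs={"OXT": 2.0},
                amps=dict(heat_amp=0.0, cold_amp=1.6, brush_amp=1.5,
                          airpuff_amp=1.3, lt_amp=1.6, ht_amp=1.8),
                rf_radius=1.0, capsaicin_p=0.08),
}


@dataclass
class PopulationConfig:
    """How the synthetic cell population is drawn.

    ``cicada_fraction`` of cells belong to a ligand-responsive archetype
    (~25% of excitatory cells respond to at least one CICADA ligand); the
    rest are unlabeled cells with similar cutaneous drive but no GPCR
    responses.  ``lt_gain`` / ``rf_expansion`` overrides plant
    sensitization effects into specific archetypes for recovery studies.
    """

    cicada_fraction: float = 0.25
    spbn_fraction: float = 0.03
    amp_jitter: float = 0.10
    depth_sd_um: float = 4.0
    lt_gain: dict[str, float] = field(
        default_factory=lambda: {"Ex2": 2.5, "Ex5": 2.5, "Ex6": 2.5}
    )
    rf_expansion: dict[str, float] = field(
        default_factory=lambda: {"Ex2": 2.0, "Ex6": 3.9}
    )
    archetype_weights: Optional[dict[str, float]] = None


def sample_population(
    n_cells: int,
    rng: np.random.Generator,
    config: PopulationConfig | None = None,
) -> list[CellSpec]:
    """Draw a mixed population of CICADA archetypes and unlabeled cells."""
    cfg = config or PopulationConfig()
    names = list(_ARCHETYPES)
    weights = np.array(
        [
            (cfg.archetype_weights or {}).get(n, _ARCHETYPES[n]["weight"])
            for n in names
        ]
    )
    weights = weights / weights.sum()
    cells = []
    for _ in range(n_cells):
        if rng.random() < cfg.cicada_fraction:
            name = names[rng.choice(len(names), p=weights)]
        else:
            name = ""
        cells.append(_sample_cell(name, rng, cfg))
    return cells


def _sample_cell(name: str, rng: np.random.Generator, cfg: PopulationConfig) -> CellSpec:
    if name:
        arch = _ARCHETYPES[name]
        base_amps = arch["amps"]
        depth = float(np.clip(rng.normal(arch["depth"], cfg.depth_sd_um), 0.0, 60.0))
        rf_radius = arch["rf_radius"]
        ligs = np.zeros(len(LIGANDS))
        for lig, amp in arch["ligs"].items():
            ligs[LIGANDS.index(lig)] = amp * (1 + cfg.amp_jitter * rng.standard_normal())
        caps = bool(rng.random() < arch["capsaicin_p"])
        lt_gain = cfg.lt_gain.get(name, 1.0)
        rf_exp = cfg.rf_expansion.get(name, 1.0)
    else:
        base_amps = dict(heat_amp=1.6, cold_amp=0.9, brush_amp=1.4,
                         airpuff_amp=1.2, lt_amp=1.5, ht_amp=1.8)
        depth = float(np.clip(rng.uniform(0, 60), 0.0, 60.0))
        rf_radius = 1.1
        ligs = np.zeros(len(LIGANDS))
        caps = bool(rng.random() < 0.08)
        lt_gain = 1.0
        rf_exp = 1.0
    amps = {
        k: max(0.0, v * (1 + cfg.amp_jitter * rng.standard_normal())) if v else 0.0
        for k, v in base_amps.items()
    }
    return CellSpec(
        archetype=name,
        rf_center=(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5)),
        rf_radius=rf_radius,
        ligand_amps=np.clip(ligs, 0.0, None),
        depth_um=depth,
        is_spbn=bool(rng.random() < cfg.spbn_fraction),
        lt_gain=max(1.0, lt_gain),
        rf_expansion=max(1.0, rf_exp),
        capsaicin_direct=caps,
        **amps,
    )


# ---------------------------------------------------------------------------
# trace synthesis


@dataclass
class GroundTruth:
    """Everything the generator injected, for exact recovery tests."""

    cells: list[CellSpec]
    cell_ids: list[str]
    responses: pd.DataFrame  # one row per injected (cell, event) response
    dff_true: Optional[np.ndarray] = None

    def is_responder(self, cell_id: str, event_index: int) -> bool:
        sel = self.responses
        return bool(
            ((sel["cell_id"] == cell_id) & (sel["event_index"] == event_index)).any()
        )

    def responder_pairs(self) -> set[tuple[str, int]]:
        return set(zip(self.responses["cell_id"], self.responses["event_index"]))

    def cell(self, cell_id: str) -> CellSpec:
        return self.cells[self.cell_ids.index(cell_id)]


def _renewal_onsets(
    rng: np.random.Generator, rate_hz: float, duration_s: float, shape: float
) -> np.ndarray:
    """Event onsets of a gamma-renewal process on [0, duration).

    ``shape`` controls regularity: 1 recovers a Poisson train, larger
    values give quasi-periodic events with interval CV = 1/sqrt(shape).
    """
    if rate_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    n_guess = int(rate_hz * duration_s * 1.5) + 10
    onsets: list[float] = []
    t = float(rng.uniform(0.0, 1.0 / rate_hz))
    while t < duration_s:
        onsets.append(t)
        t += float(rng.gamma(shape, 1.0 / (rate_hz * shape)))
        if len(onsets) > 10 * n_guess:  # safety against bad parameters
            break
    return np.asarray(onsets)


def _kernel_norm(rise_tau: float, decay_tau: float, frame_rate_hz: float) -> float:
    """Peak of the difference-of-exponentials kernel on the frame grid.

    Used to normalize the kernel so a frame-aligned event of amplitude A
    has a discrete peak of exactly A (the continuous peak falls between
    samples at 1 Hz).
    """
    n = max(int(math.ceil(8 * decay_tau * frame_rate_hz)), 2)
    t = np.arange(n) / frame_rate_hz
    return float(np.max(np.exp(-t / decay_tau) - np.exp(-t / rise_tau)))


def _add_transient(
    dff: np.ndarray, onset_s: float, amp: float,
    rise_tau: float, decay_tau: float, norm: float, frame_rate_hz: float,
) -> None:
    """Add one kernel response (arbitrary onset phase) in place."""
    n = dff.size
    length = max(int(math.ceil(8 * decay_tau * frame_rate_hz)), 2)
    i0 = int(math.ceil(onset_s * frame_rate_hz - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i0 + length, n)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / frame_rate_hz - onset_s
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    dff[i0:i1] += amp * k / norm


def generate_experiment(
    cells: Sequence[CellSpec] | int,
    protocol: ProtocolConfig | None = None,
    population: PopulationConfig | None = None,
    kernel: KernelParams | None = None,
    seed: int = 0,
    frame_rate_hz: float = 1.0,
    duration_s: Optional[float] = None,
    keep_dff_true: bool = False,
) -> tuple[TraceSet, EventTimeline, RoiTable, GroundTruth]:
    """Simulate a full experiment; returns traces, events, ROIs, truth.

    ``cells`` is either an explicit list of CellSpec or a cell count to be
    drawn from the default population.  Raw fluorescence is
    ``baseline_F * (1 + dff_true) * bleach(t)`` with ``dff_true`` the sum
    of event-locked kernels, spontaneous transients, and Gaussian noise.
    """
    kp = kernel or KernelParams()
    rng = np.random.default_rng(seed)
    timeline = build_protocol(protocol, rng)
    if isinstance(cells, (int, np.integer)):
        cells = sample_population(int(cells), rng, population)
    cells = list(cells)
    if not cells:
        raise ConfigError("at least one cell is required")
    needed = timeline.end_s() + (protocol or ProtocolConfig()).tail_s
    if duration_s is None:
        duration_s = needed
    elif duration_s < needed:
        raise ConfigError(
            f"protocol needs {needed:g}s but only {duration_s:g}s requested"
        )
    n_frames = int(round(duration_s * frame_rate_hz))
    t_s = np.arange(n_frames) / frame_rate_hz

    # normalization constants so aligned peaks equal the injected amplitude
    stim_k = _kernel_norm(kp.rise_tau_s, kp.decay_tau_s, frame_rate_hz)
    lig_k = _kernel_norm(kp.ligand_rise_tau_s, kp.ligand_decay_tau_s, frame_rate_hz)

    bleach_rate = -math.log(1 - kp.bleach_fraction_per_h) / 3600.0 if kp.bleach_fraction_per_h else 0.0
    bleach = np.exp(-bleach_rate * t_s)
    injection = timeline.injection

    cell_ids = [f"c{i:04d}" for i in range(len(cells))]
    F = np.empty((len(cells), n_frames))
    dff_true = np.zeros((len(cells), n_frames)) if keep_dff_true else None
    truth_rows = []
    roi_rows = []

    for ci, (cid, cell) in enumerate(zip(cell_ids, cells)):
        dff = np.zeros(n_frames)
        for ei, ev in enumerate(timeline):
            amp = cell.amplitude_for(ev)
            if amp <= 0:
                continue
            if ev.kind == "ligand":
                _add_transient(dff, ev.onset_s, amp,
                               kp.ligand_rise_tau_s, kp.ligand_decay_tau_s,
                               lig_k, frame_rate_hz)
            else:
                _add_transient(dff, ev.onset_s, amp,
                               kp.rise_tau_s, kp.decay_tau_s, stim_k, frame_rate_hz)
            truth_rows.append(
                {
                    "cell_id": cid, "event_index": ei, "kind": ev.kind,
                    "family": ev.family, "block": ev.block,
                    "trial_index": ev.trial_index, "grid_row": ev.grid_row,
                    "grid_col": ev.grid_col, "onset_s": ev.onset_s,
                    "amplitude": amp,
                }
            )
        # spontaneous transients (ongoing activity, gamma-renewal train)
        if cell.spontaneous_rate_hz > 0:
            onsets = _renewal_onsets(
                rng, cell.spontaneous_rate_hz, duration_s, cell.spontaneous_regularity
            )
            sigma_ln = 0.25
            mu_ln = math.log(max(cell.spontaneous_amp, 1e-9)) - sigma_ln**2 / 2
            amps = rng.lognormal(mu_ln, sigma_ln, size=onsets.size)
            if cell.capsaicin_direct and injection is not None:
                extra_rate = (cell.capsaicin_activity_factor - 1.0) * cell.spontaneous_rate_hz
                extra = injection.onset_s + _renewal_onsets(
                    rng, extra_rate, injection.duration_s, cell.spontaneous_regularity
                )
                onsets = np.concatenate([onsets, extra])
                amps = np.concatenate([amps, rng.lognormal(mu_ln, sigma_ln, extra.size)])
            for onset, amp in zip(onsets, amps):
                _add_transient(dff, onset, amp,
                               kp.rise_tau_s, kp.decay_tau_s, stim_k, frame_rate_hz)
        if kp.noise_sd > 0:
            dff = dff + rng.normal(0.0, kp.noise_sd, size=n_frames)
        if dff_true is not None:
            dff_true[ci] = dff
        F[ci] = np.clip(kp.baseline_F * (1.0 + dff) * bleach, 0.0, None)

        # somatotopy: mediolateral position tracks the RF column
        if cell.lt_amp > 0 or cell.ht_amp > 0:
            x = (cell.rf_center[1] + 0.5) / 4.0 * 512.0 + rng.normal(0.0, 30.0)
        else:
            x = rng.uniform(0, 512)
        roi_rows.append(
            {
                "cell_id": cid,
                "x_px": float(np.clip(x, 0, 511)),
                "y_px": float(rng.uniform(0, 214)),
                "plane_index": int(np.clip(round(cell.depth_um / 14.0), 0, 2)),
                "is_spbn": cell.is_spbn,
                "depth_um": cell.depth_um,
            }
        )

    traces = TraceSet(cell_ids, F, frame_rate_hz)
    rois = RoiTable(pd.DataFrame(roi_rows))
    truth = GroundTruth(
        cells=cells,
        cell_ids=cell_ids,
        responses=pd.DataFrame(
            truth_rows,
            columns=["cell_id", "event_index", "kind", "family", "block",
                     "trial_index", "grid_row", "grid_col", "onset_s", "amplitude"],
        ),
        dff_true=dff_true,
    )
    return traces, timeline, rois, truth


def generate_annotations(
    traces: TraceSet,
    timeline: EventTimeline,
    truth: GroundTruth,
    label_noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy manual-annotation stand-in for threshold calibration.

    One row per (cell, stimulus/ligand event): the ground-truth responder
    label, flipped with probability ``label_noise_rate`` to emulate
    annotator error.
    """
    if not 0 <= label_noise_rate < 1:
        raise ConfigError("label_noise_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    positives = truth.responder_pairs()
    rows = []
    for cid in traces.cell_ids:
        for ei, ev in enumerate(timeline):
            if ev.kind == "injection":
                continue
            true_label = (cid, ei) in positives
            label = true_label
            if label_noise_rate and rng.random() < label_noise_rate:
                label = not label
            rows.append(
                {
                    "cell_id": cid, "event_index": ei, "family": ev.family,
                    "block": ev.block, "true_responder": true_label, "label": label,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structural volume


def generate_structural_volume(
    xy_shape: tuple[int, int] = (64, 64),
    z_range: tuple[float, float] = (0.0, 40.0),
    surface_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | float = 10.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    z_step_um: float = 1.0,
    background: float = 0.05,
    plateau: float = 0.6,
    rise_width_um: float = 1.0,
    n_cell_bodies: int = 40,
    cell_brightness: float = 0.35,
    cell_radius_um: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic KCl structural stack with a known tissue surface.

    Voxel intensity is a low plateau above the surface, a sigmoidal rise of
    width ``rise_width_um`` at the surface, and a bright, speckled interior
    (randomly placed Gaussian cell bodies) below it, plus Gaussian noise.
    Returns ``(volume (nz, ny, nx), true_surface (ny, nx))`` where the true
    surface is ``surface_fn`` evaluated at every pixel, in um from the top
    of the stack.

    Raises
    ------
    ConfigError
        If the surface does not fit inside ``z_range`` with room for the
        background above and the plateau quartile below.
    """
    ny, nx = xy_shape
    z0, z1 = z_range
    nz = int(round((z1 - z0) / z_step_um))
    if nz < 10:
        raise ConfigError("z_range must span at least 10 slices")
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    if callable(surface_fn):
        surf = np.asarray(surface_fn(xx, yy), dtype=float) + np.zeros_like(xx)
    else:
        surf = np.full((ny, nx), float(surface_fn))
    if surf.min() < z0 + 2 * z_step_um or surf.max() > z0 + 0.7 * (z1 - z0):
        raise ConfigError(
            "z_range too thin to contain the surface with background above "
            "and plateau below"
        )
    rng = np.random.default_rng(seed)
    z = z0 + np.arange(nz, dtype=float) * z_step_um
    depth_below = z[:, None, None] - surf[None, :, :]
    vol = background + (plateau - background) / (
        1.0 + np.exp(-depth_below / rise_width_um)
    )
    # speckled bright cell bodies strictly below the surface
    for _ in range(n_cell_bodies):
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        local_surf = surf[int(cy), int(cx)]
        lo = local_surf + 4 * cell_radius_um
        if lo >= z1 - cell_radius_um:
            continue
        cz = rng.uniform(lo, z1 - cell_radius_um)
        r2 = (
            (z[:, None, None] - cz) ** 2
            + ((yy - cy) ** 2 + (xx - cx) ** 2)[None, :, :] * z_step_um**2
        )
        vol += cell_brightness * np.exp(-r2 / (2 * cell_radius_um**2))
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
    return np.clip(vol, 0.0, None), surf - z0
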