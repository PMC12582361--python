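"""Synthetic multi-patient ECoG cohorts with known coupling and propagation structure.

The generator emulates the statistical structure of an intraoperative
stepwise-sevoflurane recording session: a 1/f^2 (Brownian) background, a 3-4 Hz
delta oscillation with random per-channel frequency and phase, 80-300 Hz HFO
bursts (band-limited noise, 50-150 ms) whose amplitude follows the local delta
phase with coupling depth kappa, directed single-hop burst propagation along a
planted edge set, stage-dependent gains, and an epileptogenic channel class
with *higher* PAC coupling and HFO edge transmission but *lower* delta edge
transmission than the normative class (the double dissociation the biomarkers
are meant to detect).

Every draw flows from one root seed through named substreams, so a cohort is
bit-reproducible.  Ground truth (classes, per-stage kappa, edges, gains) is
returned alongside the recordings and can be round-tripped through JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .core_model import (
    ChannelInfo,
    Recording,
    StageSegment,
    SEVO_STAGES,
)
from .preprocess import ArtifactMask

CLASSES = ("normative", "epileptogenic")

# Default per-(stage, class) parameters.  The anaesthetic protocol (5-min
# stages, 1000 Hz, stepwise sevoflurane 2->4 vol% over an isoflurane baseline,
# SWS control in two-stage patients) follows the intended acquisition setup;
# the class/stage gain magnitudes are free parameters of the simulation,
# chosen so that epileptogenic channels show roughly double the coupling and
# HFO transmission of normative ones while stage trends remain monotone.

_DEFAULT_SCHEDULE = [("Iso", 300.0), ("Sev2", 300.0), ("Sev3", 300.0), ("Sev4", 300.0), ("SWS", 300.0)]

_DEFAULT_KAPPA = {
    ("Iso", "normative"): 0.05,
    ("SWS", "normative"): 0.05,
    ("Sev2", "normative"): 0.15,
    ("Sev3", "normative"): 0.25,
    ("Sev4", "normative"): 0.35,
    ("Iso", "epileptogenic"): 0.10,
    ("SWS", "epileptogenic"): 0.10,
    ("Sev2", "epileptogenic"): 0.30,
    ("Sev3", "epileptogenic"): 0.50,
    ("Sev4", "epileptogenic"): 0.70,
}

_DEFAULT_BURST_RATE = {
    ("Iso", "normative"): 0.5,
    ("SWS", "normative"): 0.5,
    ("Sev2", "normative"): 0.8,
    ("Sev3", "normative"): 1.1,
    ("Sev4", "normative"): 1.4,
    ("Iso", "epileptogenic"): 0.7,
    ("SWS", "epileptogenic"): 0.7,
    ("Sev2", "epileptogenic"): 1.2,
    ("Sev3", "epileptogenic"): 1.7,
    ("Sev4", "epileptogenic"): 2.2,
}

_DEFAULT_P_HFO = {
    ("Iso", "normative"): 0.05,
    ("SWS", "normative"): 0.05,
    ("Sev2", "normative"): 0.10,
    ("Sev3", "normative"): 0.15,
    ("Sev4", "normative"): 0.20,
    ("Iso", "epileptogenic"): 0.15,
    ("SWS", "epileptogenic"): 0.15,
    ("Sev2", "epileptogenic"): 0.35,
    ("Sev3", "epileptogenic"): 0.50,
    ("Sev4", "epileptogenic"): 0.65,
}

_DEFAULT_P_DELTA = {
    ("Iso", "normative"): 0.10,
    ("SWS", "normative"): 0.10,
    ("Sev2", "normative"): 0.40,
    ("Sev3", "normative"): 0.70,
    ("Sev4", "normative"): 0.80,
    ("Iso", "epileptogenic"): 0.02,
    ("SWS", "epileptogenic"): 0.02,
    ("Sev2", "epileptogenic"): 0.02,
    ("Sev3", "epileptogenic"): 0.03,
    ("Sev4", "epileptogenic"): 0.04,
}

_DEFAULT_DELTA_GAIN = {"Iso": 1.0, "SWS": 1.0, "Sev2": 1.05, "Sev3": 1.1, "Sev4": 1.15}


@dataclass
class SimConfig:
    """Cohort-level simulation parameters (study-scale defaults)."""

    n_patients: int = 19
    n_channels_per_patient: int = 16
    frac_epileptogenic: float = 0.30
    frac_two_stage: float = 11 / 19  # two-stage patients also get an SWS block
    fs: float = 1000.0
    stage_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: list(_DEFAULT_SCHEDULE)
    )
    delta_freq_range: tuple[float, float] = (3.0, 4.0)
    delta_phase_diffusion: float = 0.2  # rad^2/s of shared Brownian phase wander
    hfo_freq_range: tuple[float, float] = (80.0, 300.0)
    kappa_by_stage_class: dict = field(default_factory=lambda: dict(_DEFAULT_KAPPA))
    burst_rate_by_stage_class: dict = field(default_factory=lambda: dict(_DEFAULT_BURST_RATE))
    p_propagate_hfo: dict = field(default_factory=lambda: dict(_DEFAULT_P_HFO))
    p_propagate_delta: dict = field(default_factory=lambda: dict(_DEFAULT_P_DELTA))
    delta_gain_by_stage: dict = field(default_factory=lambda: dict(_DEFAULT_DELTA_GAIN))
    edge_density: float = 0.10
    edge_density_epi_factor: float = 3.0  # density multiplier for epi->epi pairs (hyperconnected focus)
    forced_edges: list[tuple[int, int]] | None = None  # explicit 0-based (src, dst); overrides edge_density
    noise_sigma: float = 15.0  # microvolts, Brownian background SD
    line_noise_amp: float = 2.0  # microvolts, 60 Hz
    delta_base_amp: float = 30.0  # microvolts
    delta_event_rate: float = 0.1  # slow-wave amplitude excursions per second
    delta_event_rate_epi_factor: float = 0.3  # epileptogenic sites get fewer excursions (less delta inhibition)
    delta_event_dur: float = 2.5  # seconds (several delta cycles; survives wavelet smoothing + run rule)
    delta_event_gain: float = 2.5  # fractional amplitude boost during an excursion
    hfo_burst_amp: float = 20.0  # microvolts, burst envelope peak before PAC modulation
    hfo_floor_amp: float = 1.5  # microvolts, tonic in-band noise floor
    burst_dur_range: tuple[float, float] = (0.05, 0.15)
    hfo_lag_bins: int = 1  # propagation lag, in HFO burst-train bins (6 cycles at 80 Hz)
    delta_lag_bins: int = 1  # propagation lag, in delta burst-train bins (6 cycles at 3 Hz)
    artifact_rate: float = 0.0  # events/min; artifacts are injected separately
    seed: int = 0

    def validate(self) -> None:
        def _check_unit(d: dict, name: str) -> None:
            for k, v in d.items():
                if not 0.0 <= v <= 1.0 or not math.isfinite(v):
                    raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")

        if self.n_patients < 1 or self.n_channels_per_patient < 2:
            raise ValueError("need >= 1 patient and >= 2 channels")
        if not 0.0 <= self.frac_epileptogenic <= 1.0:
            raise ValueError("frac_epileptogenic outside [0, 1]")
        if not self.stage_schedule:
            raise ValueError("empty stage schedule")
        for stage, dur in self.stage_schedule:
            if dur <= 0:
                raise ValueError(f"degenerate schedule: stage {stage} has duration {dur}")
        _check_unit(self.kappa_by_stage_class, "kappa")
        _check_unit(self.p_propagate_hfo, "p_propagate_hfo")
        _check_unit(self.p_propagate_delta, "p_propagate_delta")
        for d, name in [
            (self.burst_rate_by_stage_class, "burst_rate"),
            (self.delta_gain_by_stage, "delta_gain"),
        ]:
            for k, v in d.items():
                if v < 0 or not math.isfinite(v):
                    raise ValueError(f"{name}[{k}] = {v} must be a finite non-negative rate/gain")
        # The double dissociation must be encoded in the class parameters.
        for stage in SEVO_STAGES:
            if self.kappa_by_stage_class[(stage, "epileptogenic")] < self.kappa_by_stage_class[
                (stage, "normative")
            ]:
                raise ValueError(f"epileptogenic kappa below normative at {stage}")
            if self.p_propagate_hfo[(stage, "epileptogenic")] < self.p_propagate_hfo[
                (stage, "normative")
            ]:
                raise ValueError(f"epileptogenic p_propagate_hfo below normative at {stage}")
            if self.p_propagate_delta[(stage, "epileptogenic")] > self.p_propagate_delta[
                (stage, "normative")
            ]:
                raise ValueError(f"epileptogenic p_propagate_delta above normative at {stage}")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, JSON-serializable."""

    seed: int
    classes: dict  # patient -> {label: class}
    kappa: dict  # patient -> {label: {stage: kappa}}
    edges: dict  # patient -> [{"src", "dst", "lag_bins_hfo", "lag_bins_delta"}]
    delta_gain_by_stage: dict  # stage -> gain
    preferred_phase: dict  # patient -> {label: phi0 (radians)}


def _poisson_events(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [t0, t1)."""
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _hfo_kernel(fs: float, band: tuple[float, float]) -> np.ndarray:
    return signal.firwin(101, band, pass_zero=False, fs=fs)


def _stage_of_sample(schedule_samples: list[tuple[str, int, int]], idx: int) -> str:
    for stage, s, e in schedule_samples:
        if s <= idx < e:
            return stage
    return schedule_samples[-1][0]


def _render_patient(
    cfg: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
    two_stage: bool,
    covariates: dict,
) -> tuple[Recording, dict]:
    schedule = [(s, d) for s, d in cfg.stage_schedule if two_stage or s != "SWS"]
    fs = cfg.fs
    n_ch = cfg.n_channels_per_patient

    # Sample-index layout of the schedule.
    schedule_samples: list[tuple[str, int, int]] = []
    cursor = 0
    for stage, dur in schedule:
        n = int(round(dur * fs))
        schedule_samples.append((stage, cursor, cursor + n))
        cursor += n
    n_samples = cursor
    t = np.arange(n_samples) / fs

    # Channel classes: a contiguous epileptogenic block keeps bipolar
    # derivations class-pure except at the block boundary.
    n_epi = int(round(cfg.frac_epileptogenic * n_ch))
    labels = [f"CH{i + 1:02d}" for i in range(n_ch)]
    classes = {lab: ("epileptogenic" if i < n_epi else "normative") for i, lab in enumerate(labels)}

    meta = []
    for i, lab in enumerate(labels):
        epi = classes[lab] == "epileptogenic"
        meta.append(
            ChannelInfo(
                label=lab,
                patient_id=patient_id,
                is_resected=epi,
                is_soz=epi and i < max(1, n_epi // 2),
                is_lesional=epi and covariates["lesional"],
                has_ied=epi,
                surgery_stages=2 if two_stage else 1,
                hemisphere=covariates["hemisphere"],
                age_years=covariates["age_years"],
                sex=covariates["sex"],
                n_asm=covariates["n_asm"],
                daily_seizures=covariates["daily_seizures"],
            )
        )

    # Planted directed edges (shared across bands; per-band transmission
    # probabilities differ by stage and source-channel class).
    if cfg.forced_edges is not None:
        edges = [(int(i), int(j)) for i, j in cfg.forced_edges]
        for i, j in edges:
            if not (0 <= i < n_ch and 0 <= j < n_ch) or i == j:
                raise ValueError(f"forced edge ({i}, {j}) references invalid channels")
    else:
        # epileptogenic-to-epileptogenic pairs are preferentially connected,
        # emulating the hyperconnected pathological sub-network
        edges = []
        for i in range(n_ch):
            for j in range(n_ch):
                if i == j:
                    continue
                dens = cfg.edge_density
                if (
                    classes[labels[i]] == "epileptogenic"
                    and classes[labels[j]] == "epileptogenic"
                ):
                    dens = min(1.0, dens * cfg.edge_density_epi_factor)
                if rng.random() < dens:
                    edges.append((i, j))

    # One delta rhythm per patient (anaesthetic delta is a global
    # thalamocortical rhythm): a common frequency plus common Brownian phase
    # diffusion, with per-channel phase offsets.  Distinct per-channel
    # frequencies or independent drifts would beat in bipolar derivations,
    # flooding the burst binarization with spurious amplitude crossings; a
    # perfectly periodic phase would defeat circular-shift surrogates.
    delta_freqs = np.full(n_ch, rng.uniform(*cfg.delta_freq_range))
    delta_phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    phase_walk = np.cumsum(
        rng.standard_normal(n_samples) * math.sqrt(cfg.delta_phase_diffusion / fs)
    )
    phi0 = rng.uniform(-np.pi, np.pi, size=n_ch)  # preferred coupling phase

    hfo_bin_s = 6.0 / cfg.hfo_freq_range[0]
    delta_bin_s = 6.0 / cfg.delta_freq_range[0]
    hfo_lag_s = cfg.hfo_lag_bins * hfo_bin_s
    delta_lag_s = cfg.delta_lag_bins * delta_bin_s

    kernel = _hfo_kernel(fs, cfg.hfo_freq_range)

    # --- event generation (per channel, per stage), then single-hop propagation
    hfo_events: list[list[tuple[float, float]]] = [[] for _ in range(n_ch)]  # (time, dur)
    delta_events: list[list[float]] = [[] for _ in range(n_ch)]
    for stage, s0, s1 in schedule_samples:
        t0, t1 = s0 / fs, s1 / fs
        for i in range(n_ch):
            cls = classes[labels[i]]
            rate = cfg.burst_rate_by_stage_class[(stage, cls)]
            for ev in _poisson_events(rng, rate, t0, t1):
                hfo_events[i].append((ev, rng.uniform(*cfg.burst_dur_range)))
            d_rate = cfg.delta_event_rate * (
                cfg.delta_event_rate_epi_factor if cls == "epileptogenic" else 1.0
            )
            for ev in _poisson_events(rng, d_rate, t0, t1):
                delta_events[i].append(ev)
        # propagation (single hop: spawned events do not re-propagate); an
        # edge transmits with the geometric mean of its endpoint classes'
        # probabilities, so the class effect shows in both the efferent and
        # afferent summaries of a channel
        for i, j in edges:
            cls_i, cls_j = classes[labels[i]], classes[labels[j]]
            p_h = math.sqrt(
                cfg.p_propagate_hfo[(stage, cls_i)] * cfg.p_propagate_hfo[(stage, cls_j)]
            )
            p_d = math.sqrt(
                cfg.p_propagate_delta[(stage, cls_i)] * cfg.p_propagate_delta[(stage, cls_j)]
            )
            for ev, dur in list(hfo_events[i]):
                if t0 <= ev < t1 and rng.random() < p_h:
                    hfo_events[j].append((ev + hfo_lag_s, rng.uniform(*cfg.burst_dur_range)))
            for ev in list(delta_events[i]):
                if t0 <= ev < t1 and rng.random() < p_d:
                    delta_events[j].append(ev + delta_lag_s)

    # --- rendering
    samples = np.empty((n_ch, n_samples))
    kappa_truth: dict[str, dict[str, float]] = {}
    for i in range(n_ch):
        cls = classes[labels[i]]
        kappa_truth[labels[i]] = {
            stage: cfg.kappa_by_stage_class[(stage, cls)] for stage, _, _ in schedule_samples
        }

        # Brownian background, detrended and scaled to noise_sigma.
        bg = np.cumsum(rng.standard_normal(n_samples))
        bg = signal.detrend(bg)
        sd = bg.std()
        if sd > 0:
            bg *= cfg.noise_sigma / sd

        # Delta oscillation with slow-wave amplitude excursions.
        phase = 2 * np.pi * delta_freqs[i] * t + delta_phases[i] + phase_walk
        delta_env = np.zeros(n_samples)
        ev_len = int(round(cfg.delta_event_dur * fs))
        hann_d = signal.windows.hann(ev_len)
        for ev in delta_events[i]:
            s = int(round(ev * fs))
            e = min(s + ev_len, n_samples)
            if s < n_samples:
                delta_env[s:e] += hann_d[: e - s]
        stage_gain = np.empty(n_samples)
        for stage, s0, s1 in schedule_samples:
            stage_gain[s0:s1] = cfg.delta_gain_by_stage[stage]
        delta_amp = cfg.delta_base_amp * stage_gain * (1.0 + cfg.delta_event_gain * delta_env)
        delta_wave = delta_amp * np.sin(phase)

        # HFO: tonic in-band floor plus phase-coupled bursts.
        floor = signal.fftconvolve(rng.standard_normal(n_samples), kernel, mode="same")
        fsd = floor.std()
        if fsd > 0:
            floor *= cfg.hfo_floor_amp / fsd
        hfo = floor
        for ev, dur in hfo_events[i]:
            s = int(round(ev * fs))
            if s >= n_samples:
                continue
            ln = max(8, int(round(dur * fs)))
            e = min(s + ln, n_samples)
            stage = _stage_of_sample(schedule_samples, s)
            kap = cfg.kappa_by_stage_class[(stage, cls)]
            mid = min(s + ln // 2, n_samples - 1)
            amp = cfg.hfo_burst_amp * (1.0 + kap * np.cos(phase[mid] - phi0[i]))
            burst = signal.fftconvolve(rng.standard_normal(ln), kernel, mode="same")
            bsd = burst.std()
            if bsd > 0:
                burst *= amp / bsd
            burst *= signal.windows.hann(ln)
            hfo[s:e] += burst[: e - s]

        line = cfg.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        samples[i] = bg + delta_wave + hfo + line

    annotations = [StageSegment(stage, s0, s1) for stage, s0, s1 in schedule_samples]
    rec = Recording(samples, fs, meta, annotations, montage_kind="referential")
    truth = {
        "classes": classes,
        "kappa": kappa_truth,
        "edges": [
            {
                "src": labels[i],
                "dst": labels[j],
                "lag_bins_hfo": cfg.hfo_lag_bins,
                "lag_bins_delta": cfg.delta_lag_bins,
            }
            for i, j in edges
        ],
        "preferred_phase": {labels[i]: float(phi0[i]) for i in range(n_ch)},
    }
    return rec, truth


def generate_cohort(cfg: SimConfig) -> tuple[list[Recording], SimTruth]:
    """Generate one Recording per patient plus the cohort's ground truth."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    patient_seeds = root.spawn(cfg.n_patients + 1)
    cohort_rng = np.random.default_rng(patient_seeds[-1])

    n_two_stage = int(round(cfg.frac_two_stage * cfg.n_patients))
    two_stage_ids = set(cohort_rng.choice(cfg.n_patients, size=n_two_stage, replace=False).tolist())

    recordings = []
    truth = SimTruth(
        seed=cfg.seed,
        classes={},
        kappa={},
        edges={},
        delta_gain_by_stage=dict(cfg.delta_gain_by_stage),
        preferred_phase={},
    )
    for p in range(cfg.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        pid = f"P{p + 1:02d}"
        covariates = {
            "age_years": float(rng.integers(4, 19)),
            "sex": "M" if rng.random() < 0.5 else "F",
            "hemisphere": "L" if rng.random() < 0.5 else "R",
            "n_asm": int(rng.integers(0, 4)),
            "daily_seizures": bool(rng.random() < 0.4),
            "lesional": bool(rng.random() < 0.6),
        }
        rec, tr = _render_patient(cfg, rng, pid, p in two_stage_ids, covariates)
        recordings.append(rec)
        truth.classes[pid] = tr["classes"]
        truth.kappa[pid] = tr["kappa"]
        truth.edges[pid] = tr["edges"]
        truth.preferred_phase[pid] = tr["preferred_phase"]
    return recordings, truth


def inject_artifacts(
    rec: Recording, rate: float, seed: int
) -> tuple[Recording, ArtifactMask]:
    """Add high-amplitude transients (>= 10x background SD) plus a 60 Hz sinusoid.

    Returns a new Recording and the ground-truth artifact mask.  ``rate`` is
    events per minute per channel; ``rate = 0`` returns the recording unchanged
    with an empty mask.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    out = rec.samples.copy()
    am = ArtifactMask(n_samples=rec.n_samples)
    if rate == 0:
        for info in rec.channel_meta:
            am.ranges[info.label] = []
        return (
            Recording(out, rec.fs, list(rec.channel_meta), list(rec.stage_annotations), rec.montage_kind),
            am,
        )
    rng = np.random.default_rng(seed)
    dur = int(round(0.2 * rec.fs))
    t_ev = np.arange(dur) / rec.fs
    duration_min = rec.n_samples / rec.fs / 60.0
    for i, info in enumerate(rec.channel_meta):
        sd = rec.samples[i].std()
        amp = max(10.0 * sd, 1.0)
        mask = np.zeros(rec.n_samples, dtype=bool)
        n_events = rng.poisson(rate * duration_min)
        for _ in range(n_events):
            s = int(rng.integers(0, max(1, rec.n_samples - dur)))
            e = min(s + dur, rec.n_samples)
            transient = amp * signal.windows.hann(dur)[: e - s]
            hum = 0.5 * amp * np.sin(2 * np.pi * 60.0 * t_ev[: e - s])
            out[i, s:e] += transient + hum
            mask[s:e] = True
        am.ranges[info.label] = [
            (int(s), int(e)) for s, e in _ranges_from_bool(mask)
        ]
    return (
        Recording(out, rec.fs, list(rec.channel_meta), list(rec.stage_annotations), rec.montage_kind),
        am,
    )


def _ranges_from_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    from .preprocess import _bool_to_ranges

    return _bool_to_ranges(mask)


def simulate_stats_table(
    n_patients: int = 12,
    n_channels: int = 10,
    slope: float = 0.01,
    sd_patient: float = 0.02,
    sd_noise: float = 0.02,
    intercept: float = 0.05,
    biomarker: str = "MI",
    seed: int = 0,
) -> "pd.DataFrame":
    """Table-level cohort simulator: biomarker values linear in the stage code.

    Emulates only the *statistical* structure the mixed models see (patient
    random intercepts + iid noise around a linear stage trend on normative
    channels), with no signal processing, for fast calibration studies of the
    stage-trend model.  One control epoch plus the nine sevoflurane analysis
    minutes per channel.
    """
    import pandas as pd

    from .core_model import make_biomarker_rows

    rng = np.random.default_rng(seed)
    stages = [("Iso", 1)] + [(s, e) for s in SEVO_STAGES for e in (1, 2, 3)]
    codes = {("Iso", 1): 0}
    codes.update({(s, e): SEVO_STAGES.index(s) * 3 + e for s in SEVO_STAGES for e in (1, 2, 3)})
    rows = []
    for p in range(n_patients):
        offset = rng.normal(0, sd_patient)
        info_kw = dict(
            patient_id=f"P{p + 1:02d}",
            surgery_stages=int(1 + (p % 2)),
            hemisphere="L" if rng.random() < 0.5 else "R",
            age_years=float(rng.integers(4, 19)),
            sex="M" if rng.random() < 0.5 else "F",
            n_asm=int(rng.integers(0, 4)),
            daily_seizures=bool(rng.random() < 0.4),
            # no lesional channels: every simulated site stays normative
        )
        for ch in range(n_channels):
            info = ChannelInfo(label=f"CH{ch + 1:02d}", **info_kw)
            for stage, ep in stages:
                value = intercept + offset + slope * codes[(stage, ep)] + rng.normal(0, sd_noise)
                rows.extend(make_biomarker_rows(info, stage, ep, {biomarker: max(value, 0.0)}))
    return pd.DataFrame(rows)


def export_truth(truth: SimTruth, path: str | Path) -> Path:
    """Write ground truth as JSON; refuses non-finite coupling values."""
    for pid, chans in truth.kappa.items():
        for lab, stages in chans.items():
            for stage, k in stages.items():
                if not math.isfinite(k):
                    raise ValueError(f"non-finite kappa for {pid}/{lab}/{stage}")
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    return path


def load_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        obj = json.load(fh)
    return SimTruth(**obj)
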