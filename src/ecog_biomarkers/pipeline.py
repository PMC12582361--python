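"""End-to-end orchestration: simulate/ingest -> preprocess -> biomarkers -> stats -> hotspots.

``run_full`` drives the whole chain from a single RunConfig and writes a
self-describing artifact directory: the long-format biomarker table, per-epoch
EC matrices, mixed-model term tables, per-stage effect sizes, hotspot edge
lists, and a manifest (config, seed, versions) sufficient to reproduce every
output bit-for-bit.  All randomness flows from one root seed through named
substreams, so identical configs give identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_model import (
    CONTROL_STAGES,
    Recording,
    SEVO_STAGES,
    default_bipolar_pairs,
    load_recording,
    make_biomarker_rows,
    save_recording,
    segment_stages,
    to_bipolar,
    validate_biomarker_table,
)
from .connectivity import binarize_bursts, channel_ec, ec_matrix
from .hotspots import export_edges, hotspots_from_table
from .pac import modulation_index
from .preprocess import auto_artifact_mask, bandpass, notch
from .spectral import wavelet_amplitude, zscore_to_control
from .stats import cohens_d_by_stage, fit_epi_glmm, fit_stage_lmm, subtraction_predictor
from .synthetic_data import SimConfig, export_truth, generate_cohort, inject_artifacts

log = logging.getLogger("ecog_biomarkers")

_EC_BIOMARKER = {
    ("hfo", "combined"): "HFO_EC",
    ("hfo", "efferent"): "HFO_EC_EFF",
    ("hfo", "afferent"): "HFO_EC_AFF",
    ("delta", "combined"): "DELTA_EC",
    ("delta", "efferent"): "DELTA_EC_EFF",
    ("delta", "afferent"): "DELTA_EC_AFF",
}


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    out_dir: str = "run_out"
    sim: SimConfig | None = None
    input_paths: list[tuple[str, str, str]] | None = None  # (signal, meta, annot)
    control: str = "Iso"  # Iso | SWS | both
    seed: int = 0
    # preprocessing
    filter_lo: float = 0.016
    filter_hi: float = 300.0
    notch_freq: float = 60.0
    artifact_z_amp: float = 6.0
    artifact_min_gap_s: float = 0.5
    artifact_rate: float = 0.0  # simulate-mode artifact injection, events/min
    # spectral
    n_cycles: float = 7.0
    hfo_grid_step: float = 10.0
    # connectivity
    ec_threshold_z: float = 2.0
    ec_min_cycles: int = 3
    ec_bin_cycles: int = 6
    ec_history_k: int = 1
    ec_min_triplets: int = 50
    ec_min_triplets_delta: int = 25
    ec_exclude_shared_contacts: bool = True
    # epochs
    max_masked_frac: float = 0.2
    # hotspots
    hotspot_k: float = 3.0
    # outputs
    save_signals: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("exactly one of sim / input_paths must be set")
        if self.control not in ("Iso", "SWS", "both"):
            raise ValueError("control must be Iso, SWS or both")
        if self.sim is not None:
            self.sim.validate()
        if self.filter_hi <= self.filter_lo:
            raise ValueError("filter_hi must exceed filter_lo")
        for name in ("ec_threshold_z", "hotspot_k", "n_cycles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _controls_present(rec: Recording) -> list[str]:
    return [s for s in CONTROL_STAGES if rec.segments_for(s)]


def patient_biomarkers(
    rec: Recording, cfg: RunConfig
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Biomarker rows and per-epoch EC matrices for one referential recording.

    Applies the preprocessing chain (band-pass, notch, bipolar derivation,
    robust artifact masking), z-scores band amplitude to each control stage
    present, and computes MI plus HFO/delta EC per channel and analysis epoch.
    EC biomarkers come from the isoflurane-referenced amplitude when both
    controls exist (the SWS-referenced series feeds the SWS-control analyses).
    """
    rec = notch(bandpass(rec, cfg.filter_lo, cfg.filter_hi), cfg.notch_freq)
    rec = to_bipolar(rec, default_bipolar_pairs(rec.labels))
    mask = auto_artifact_mask(rec, cfg.artifact_z_amp, cfg.artifact_min_gap_s)
    union_mask = mask.union_bool()
    epochs = segment_stages(rec, union_mask, cfg.max_masked_frac)

    controls = _controls_present(rec)
    if not controls:
        raise ValueError(f"patient {rec.patient_id}: no control stage annotated")
    primary_control = "Iso" if "Iso" in controls else "SWS"

    hfo_grid = np.arange(80.0, 301.0, cfg.hfo_grid_step)
    amp = {
        "hfo": wavelet_amplitude(rec, "hfo", mask, cfg.n_cycles, hfo_grid),
        "delta": wavelet_amplitude(rec, "delta", mask, cfg.n_cycles),
    }
    amp_z = {}
    for band in ("hfo", "delta"):
        segs = [
            (s.start_sample, s.end_sample) for s in rec.segments_for(primary_control)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            amp_z[band] = zscore_to_control(amp[band], primary_control, segs)

    keep = [i for i, lab in enumerate(rec.labels) if lab not in mask.rejected]
    rows: list[dict] = []
    matrices: list[pd.DataFrame] = []
    use_epochs = [
        e for e in epochs if e.is_analysis or (e.stage in CONTROL_STAGES and e.epoch_index <= 3)
    ]

    def _trains(band: str, sl: slice) -> list:
        return [
            binarize_bursts(
                amp_z[band].values[i, sl],
                rec.fs,
                band,
                cfg.ec_threshold_z,
                cfg.ec_min_cycles,
                cfg.ec_bin_cycles,
                channel_label=rec.labels[i],
            )
            for i in keep
        ]

    def _store(m, band: str, stage: str, epoch_index: int) -> None:
        mf = m.to_frame()
        mf.insert(0, "band", band)
        mf.insert(1, "stage", stage)
        mf.insert(2, "epoch_index", epoch_index)
        mf.insert(3, "patient_id", rec.patient_id)
        matrices.append(mf)

    # Delta-band EC: the 2-s bins (six cycles at 3 Hz) leave only ~30 bins per
    # 1-min epoch, where plug-in bias noise would swamp the estimate, so the
    # burst trains of a stage's analysis epochs are concatenated into one
    # stage-level matrix whose channel summaries are replicated to that
    # stage's epoch rows.
    delta_by_stage: dict[str, dict] = {}
    for stage_name in {e.stage for e in use_epochs}:
        stage_eps = [e for e in use_epochs if e.stage == stage_name]
        series = None
        for ep in stage_eps:
            s = _trains("delta", slice(ep.start_sample, ep.end_sample))
            if series is None:
                series = s
            else:
                for acc, new in zip(series, s):
                    acc.bits = np.concatenate([acc.bits, new.bits])
        m = ec_matrix(
            series,
            k=cfg.ec_history_k,
            min_triplets=cfg.ec_min_triplets_delta,
            exclude_shared_contacts=cfg.ec_exclude_shared_contacts,
            stage=stage_name,
            epoch_index=0,
        )
        _store(m, "delta", stage_name, 0)
        delta_by_stage[stage_name] = {
            mode: channel_ec(m, mode) for mode in ("combined", "efferent", "afferent")
        }

    for ep in use_epochs:
        sl = slice(ep.start_sample, ep.end_sample)
        m_hfo = ec_matrix(
            _trains("hfo", sl),
            k=cfg.ec_history_k,
            min_triplets=cfg.ec_min_triplets,
            exclude_shared_contacts=cfg.ec_exclude_shared_contacts,
            stage=ep.stage,
            epoch_index=ep.epoch_index,
        )
        _store(m_hfo, "hfo", ep.stage, ep.epoch_index)
        per_mode = {("hfo", mode): channel_ec(m_hfo, mode) for mode in ("combined", "efferent", "afferent")}
        per_mode.update(
            {("delta", mode): ser for mode, ser in delta_by_stage[ep.stage].items()}
        )
        for i in keep:
            info = rec.channel_meta[i]
            ch_mask = mask.mask_bool(info.label)[sl]
            values: dict[str, float] = {}
            try:
                values["MI"] = modulation_index(rec.samples[i, sl], rec.fs, mask=ch_mask).mi
            except ValueError:
                values["MI"] = np.nan
            for (band, mode), ser in per_mode.items():
                values[_EC_BIOMARKER[(band, mode)]] = ser[info.label]
            rows.extend(make_biomarker_rows(info, ep.stage, ep.epoch_index, values))
    return pd.DataFrame(rows), matrices


def compute_biomarker_table(
    recordings: list[Recording], cfg: RunConfig
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Biomarker table over a cohort (concatenated per-patient results)."""
    tables, matrices = [], []
    for rec in recordings:
        t, m = patient_biomarkers(rec, cfg)
        tables.append(t)
        matrices.extend(m)
    table = pd.concat(tables, ignore_index=True)
    return validate_biomarker_table(table), matrices


def _fit_models(
    table: pd.DataFrame, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All stage-trend LMMs and per-stage epileptogenicity GLMMs on a table."""
    controls = ["Iso", "SWS"] if cfg.control == "both" else [cfg.control]
    model_rows = []
    qq_rows = []
    stages_present = [s for s in ("Iso", "SWS") + SEVO_STAGES if (table["stage"] == s).any()]
    for biomarker in ("MI", "HFO_EC", "DELTA_EC"):
        for control in controls:
            if not (table["stage"] == control).any():
                continue
            try:
                res = fit_stage_lmm(table, biomarker, control)
            except ValueError as exc:
                log.warning("stage LMM %s/%s failed: %s", biomarker, control, exc)
                continue
            for _, row in res.terms.iterrows():
                model_rows.append(
                    {"model": "stage_lmm", "biomarker": biomarker, "control": control,
                     "stage": "", "converged": res.converged, **row.to_dict()}
                )
            if res.residual_quantiles is not None:
                probs = np.linspace(0, 1, len(res.residual_quantiles))
                qq_rows.extend(
                    {"biomarker": biomarker, "control": control,
                     "prob": p, "residual_quantile": q}
                    for p, q in zip(probs, res.residual_quantiles)
                )
        for stage in stages_present:
            epochs = sorted(table.loc[table["stage"] == stage, "epoch_index"].unique())
            for ep in epochs if stage in SEVO_STAGES else [None]:
                try:
                    res = fit_epi_glmm(table, biomarker, stage, epoch_index=ep)
                except ValueError as exc:
                    log.warning("epi GLMM %s/%s failed: %s", biomarker, stage, exc)
                    continue
                row = res.term("value").to_dict()
                model_rows.append(
                    {"model": "epi_glmm", "biomarker": biomarker, "control": "",
                     "stage": stage if ep is None else f"{stage}_{ep}",
                     "converged": res.converged, **row}
                )
    effect_rows = []
    for biomarker in ("MI", "HFO_EC", "DELTA_EC"):
        d = cohens_d_by_stage(table, biomarker)
        for stage_name, val in d.items():
            effect_rows.append({"biomarker": biomarker, "stage": stage_name, "cohens_d": val})
    return pd.DataFrame(model_rows), pd.DataFrame(effect_rows), pd.DataFrame(qq_rows)


def run_full(cfg: RunConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        log.info("simulating cohort: %d patients", sim_cfg.n_patients)
        recordings, truth = generate_cohort(sim_cfg)
        export_truth(truth, out / "truth.json")
        if cfg.artifact_rate > 0:
            recordings = [
                inject_artifacts(r, cfg.artifact_rate, seed=cfg.seed + 1000 + i)[0]
                for i, r in enumerate(recordings)
            ]
        if cfg.save_signals:
            sig_dir = out / "signals"
            sig_dir.mkdir(exist_ok=True)
            for r in recordings:
                save_recording(r, sig_dir / f"{r.patient_id}.h5")
    else:
        recordings = [load_recording(*paths) for paths in cfg.input_paths]

    log.info("computing biomarkers for %d patients", len(recordings))
    table, matrices = compute_biomarker_table(recordings, cfg)
    table.to_csv(out / "biomarker_table.csv", index=False)
    ec_dir = out / "ec"
    ec_dir.mkdir(exist_ok=True)
    for mf in matrices:
        pid = mf["patient_id"].iloc[0]
        name = f"{pid}_{mf['band'].iloc[0]}_{mf['stage'].iloc[0]}_{mf['epoch_index'].iloc[0]}.csv"
        mf.to_csv(ec_dir / name)

    log.info("fitting mixed models")
    models, effects, qq = _fit_models(table, cfg)
    models.to_csv(out / "model_results.csv", index=False)
    effects.to_csv(out / "cohens_d.csv", index=False)
    qq.to_csv(out / "qq_residuals.csv", index=False)

    # per-patient resection-completeness proxy at each sevoflurane stage
    sub_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for biomarker in ("MI", "HFO_EC", "DELTA_EC"):
            for stage in SEVO_STAGES:
                if not (table["stage"] == stage).any():
                    continue
                try:
                    s = subtraction_predictor(table, biomarker, stage)
                except ValueError:
                    continue
                sub_rows.extend(
                    {"patient_id": pid, "biomarker": biomarker, "stage": stage, "subtraction": v}
                    for pid, v in s.items()
                )
    pd.DataFrame(sub_rows).to_csv(out / "subtraction.csv", index=False)

    reference = "SWS" if (table["stage"] == "SWS").any() else "Iso"
    hs_dir = out / "hotspots"
    hs_dir.mkdir(exist_ok=True)
    for biomarker in ("MI", "HFO_EC", "DELTA_EC"):
        for stage in SEVO_STAGES:
            if not (table["stage"] == stage).any():
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hs = hotspots_from_table(table, biomarker, stage, reference, cfg.hotspot_k)
                    export_edges(hs, hs_dir / f"{biomarker}_{stage}_edges.csv")
            except ValueError as exc:
                log.warning("hotspots %s/%s failed: %s", biomarker, stage, exc)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": _config_to_jsonable(cfg),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _config_to_jsonable(cfg: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(cfg)
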