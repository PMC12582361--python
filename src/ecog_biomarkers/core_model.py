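"""Domain types, file ingest/egress, montage construction and stage segmentation.

The pipeline works on multichannel intracranial recordings sampled at a fixed
rate (1000 Hz in the intended acquisition setup), annotated with anaesthetic
stages (isoflurane baseline, stepwise sevoflurane 2/3/4 vol%, and optionally
anaesthesia-free slow-wave sleep).  Each stage is subdivided into 1-min
epochs; the first three artifact-free minutes of every sevoflurane stage are
the "analysis epochs" that feed the biomarker statistics, while the control
stages contribute their full span as a z-score baseline.

Signals are stored either in EDF (ingest only) or in the package's own HDF5
container, with channel metadata in a CSV sidecar and stage annotations in a
JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: Recognised anaesthetic stages, in pipeline order.
STAGES = ("Iso", "Sev2", "Sev3", "Sev4", "SWS")
#: Stages recorded under stepwise sevoflurane.
SEVO_STAGES = ("Sev2", "Sev3", "Sev4")
#: Control (reference) stages usable as z-score baselines.
CONTROL_STAGES = ("Iso", "SWS")

EPOCH_S = 60.0  # analysis epoch duration (seconds)
N_ANALYSIS_EPOCHS = 3  # analysis epochs retained per sevoflurane stage

#: Biomarker identifiers used in the long-format biomarker table.
BIOMARKERS = (
    "MI",
    "HFO_EC",
    "DELTA_EC",
    "HFO_EC_AFF",
    "HFO_EC_EFF",
    "DELTA_EC_AFF",
    "DELTA_EC_EFF",
)

_META_COLUMNS = [
    "label",
    "patient_id",
    "is_resected",
    "is_soz",
    "is_lesional",
    "has_ied",
    "surgery_stages",
    "hemisphere",
    "age_years",
    "sex",
    "n_asm",
    "daily_seizures",
]


@dataclass
class ChannelInfo:
    """Per-channel metadata: identity, pathology flags, and patient covariates.

    A channel is *normative* when it was retained at surgery, lies outside the
    seizure-onset zone and MRI lesions, and is free of interictal epileptiform
    discharges.  A channel is *epileptogenic* when it was resected (the cohort
    is restricted to patients with seizure-free outcomes, so resection defines
    the epileptogenic zone operationally).
    """

    label: str
    patient_id: str
    is_resected: bool = False
    is_soz: bool = False
    is_lesional: bool = False
    has_ied: bool = False
    surgery_stages: int = 1
    hemisphere: str = "L"
    age_years: float = 12.0
    sex: str = "M"
    n_asm: int = 1
    daily_seizures: bool = False

    @property
    def is_normative(self) -> bool:
        return not (self.is_resected or self.is_soz or self.is_lesional or self.has_ied)

    @property
    def is_epileptogenic(self) -> bool:
        return bool(self.is_resected)


@dataclass
class StageSegment:
    """A contiguous annotated block of one anaesthetic stage (sample indices, half-open)."""

    stage: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError(
                f"invalid segment [{self.start_sample}, {self.end_sample}) for stage {self.stage}"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EpochSpec:
    """One 1-min epoch within a stage. ``epoch_index`` is 1-based within its stage."""

    stage: str
    epoch_index: int
    start_sample: int
    end_sample: int
    is_analysis: bool = False

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class Recording:
    """A referential or bipolar multichannel recording with metadata and stage annotations."""

    samples: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_meta: list[ChannelInfo]
    stage_annotations: list[StageSegment] = field(default_factory=list)
    montage_kind: str = "referential"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_meta) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_meta)} metadata rows for {self.samples.shape[0]} channels"
            )
        for seg in self.stage_annotations:
            if seg.end_sample > self.n_samples:
                raise ValueError(
                    f"stage annotation {seg.stage} ends at sample {seg.end_sample}, "
                    f"beyond recording length {self.n_samples}"
                )
        starts_ends = sorted((s.start_sample, s.end_sample) for s in self.stage_annotations)
        for (s0, e0), (s1, _e1) in zip(starts_ends, starts_ends[1:]):
            if s1 < e0:
                raise ValueError("stage annotations overlap")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channel_meta]

    @property
    def patient_id(self) -> str:
        return self.channel_meta[0].patient_id

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def segments_for(self, stage: str) -> list[StageSegment]:
        return [s for s in self.stage_annotations if s.stage == stage]


# ---------------------------------------------------------------------------
# ingest / egress


def _meta_from_frame(df: pd.DataFrame) -> dict[str, ChannelInfo]:
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"channel metadata is missing columns: {missing}")
    out: dict[str, ChannelInfo] = {}
    for _, row in df.iterrows():
        info = ChannelInfo(
            label=str(row["label"]),
            patient_id=str(row["patient_id"]),
            is_resected=bool(row["is_resected"]),
            is_soz=bool(row["is_soz"]),
            is_lesional=bool(row["is_lesional"]),
            has_ied=bool(row["has_ied"]),
            surgery_stages=int(row["surgery_stages"]),
            hemisphere=str(row["hemisphere"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            n_asm=int(row["n_asm"]),
            daily_seizures=bool(row["daily_seizures"]),
        )
        out[info.label] = info
    return out


def meta_to_frame(meta: Sequence[ChannelInfo]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in meta], columns=_META_COLUMNS)


def _annotations_from_json(obj: list[dict], fs: float) -> list[StageSegment]:
    segs = []
    for item in obj:
        segs.append(
            StageSegment(
                stage=item["stage"],
                start_sample=int(round(float(item["start_s"]) * fs)),
                end_sample=int(round(float(item["end_s"]) * fs)),
            )
        )
    return segs


def annotations_to_json(rec: Recording) -> list[dict]:
    return [
        {
            "stage": s.stage,
            "start_s": s.start_sample / rec.fs,
            "end_s": s.end_sample / rec.fs,
        }
        for s in rec.stage_annotations
    ]


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to the package's HDF5 container (self-contained)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["montage_kind"] = rec.montage_kind
        f.attrs["channel_meta"] = meta_to_frame(rec.channel_meta).to_json(orient="records")
        f.attrs["stage_annotations"] = json.dumps(annotations_to_json(rec))
    return path


def load_recording(
    signal_path: str | Path,
    meta_path: str | Path | None = None,
    annot_path: str | Path | None = None,
) -> Recording:
    """Load a recording from EDF or the HDF5 container, joining sidecar metadata.

    ``meta_path`` (CSV, one row per channel) and ``annot_path`` (JSON list of
    ``{stage, start_s, end_s}``) are required for EDF and optional for the
    container, which embeds both; when given they override the embedded copies.
    Every signal channel must have a metadata row (hard error naming the first
    channel without one); channels present in the metadata but absent from the
    signal file are rejected the same way.
    """
    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(signal_path, preload=True, verbose="error")
        samples = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
        meta_df = annot = None
    else:
        with h5py.File(signal_path, "r") as f:
            samples = f["samples"][...]
            fs = float(f.attrs["fs"])
            montage_kind = str(f.attrs.get("montage_kind", "referential"))
            meta_df = pd.read_json(f.attrs["channel_meta"], orient="records")
            annot = json.loads(f.attrs["stage_annotations"])
        labels = [str(x) for x in meta_df["label"]]

    if meta_path is not None:
        meta_df = pd.read_csv(meta_path)
    if annot_path is not None:
        with open(annot_path) as fh:
            annot = json.load(fh)
    if meta_df is None:
        raise ValueError("EDF ingest requires a channel metadata sidecar (meta_path)")
    if annot is None:
        raise ValueError("EDF ingest requires a stage annotation sidecar (annot_path)")

    meta_by_label = _meta_from_frame(pd.DataFrame(meta_df))
    channel_meta = []
    for lab in labels:
        if lab not in meta_by_label:
            raise ValueError(f"no metadata for channel {lab!r}")
        channel_meta.append(meta_by_label[lab])
    extra = set(meta_by_label) - set(labels)
    if extra:
        raise ValueError(f"metadata references channels absent from the signal file: {sorted(extra)}")

    segs = _annotations_from_json(annot, fs)
    montage = montage_kind if signal_path.suffix.lower() != ".edf" else "referential"
    return Recording(
        samples=samples,
        fs=fs,
        channel_meta=channel_meta,
        stage_annotations=segs,
        montage_kind=montage,
    )


# ---------------------------------------------------------------------------
# montage


def _or_flags(a: ChannelInfo, b: ChannelInfo, label: str) -> ChannelInfo:
    # Conservative flag propagation: a derived channel touching pathological
    # tissue is itself pathological (OR of the member flags).
    return ChannelInfo(
        label=label,
        patient_id=a.patient_id,
        is_resected=a.is_resected or b.is_resected,
        is_soz=a.is_soz or b.is_soz,
        is_lesional=a.is_lesional or b.is_lesional,
        has_ied=a.has_ied or b.has_ied,
        surgery_stages=a.surgery_stages,
        hemisphere=a.hemisphere,
        age_years=a.age_years,
        sex=a.sex,
        n_asm=a.n_asm,
        daily_seizures=a.daily_seizures,
    )


def default_bipolar_pairs(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Chain montage: consecutive channel pairs (label_i, label_{i+1})."""
    return [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]


def to_bipolar(rec: Recording, pairs: Sequence[tuple[str, str]]) -> Recording:
    """Derive a bipolar montage: output channel = anode - cathode, sample-wise.

    Bipolar labels are ``"anode-cathode"``; metadata flags are OR-combined so a
    pair touching e.g. a resected contact is counted as resected.
    """
    if rec.montage_kind == "bipolar":
        raise ValueError("recording is already bipolar")
    n_s = rec.n_samples
    out = np.empty((len(pairs), n_s))
    meta = []
    for i, (anode, cathode) in enumerate(pairs):
        if anode == cathode:
            raise ValueError(f"bipolar pair must reference distinct channels, got {anode!r} twice")
        ia, ic = rec.channel_index(anode), rec.channel_index(cathode)
        out[i] = rec.samples[ia] - rec.samples[ic]
        meta.append(_or_flags(rec.channel_meta[ia], rec.channel_meta[ic], f"{anode}-{cathode}"))
    return Recording(
        samples=out,
        fs=rec.fs,
        channel_meta=meta,
        stage_annotations=list(rec.stage_annotations),
        montage_kind="bipolar",
    )


def bipolar_contacts(label: str) -> tuple[str, str]:
    """Split a bipolar label ``"A1-A2"`` into its electrode contact names."""
    parts = label.split("-")
    if len(parts) != 2:
        raise ValueError(f"{label!r} is not a bipolar pair label")
    return parts[0], parts[1]


def shares_contact(label_a: str, label_b: str) -> bool:
    """True when two bipolar channels share a physical electrode contact."""
    try:
        ca, cb = set(bipolar_contacts(label_a)), set(bipolar_contacts(label_b))
    except ValueError:
        return False
    return bool(ca & cb)


# ---------------------------------------------------------------------------
# stage segmentation


def segment_stages(
    rec: Recording,
    masked_bool: np.ndarray | None = None,
    max_masked_frac: float = 0.2,
    n_analysis: int = N_ANALYSIS_EPOCHS,
) -> list[EpochSpec]:
    """Split stage annotations into 1-min epochs and mark analysis epochs.

    For each sevoflurane stage the first ``n_analysis`` artifact-free epochs
    (masked fraction <= ``max_masked_frac`` under ``masked_bool``, a boolean
    per-sample mask) are marked ``is_analysis``.  Control stages contribute
    their full span (their epochs are enumerated but never marked as
    sevoflurane analysis epochs).  A sevoflurane stage with zero artifact-free
    epochs is dropped with a warning.
    """
    if not rec.stage_annotations:
        raise ValueError("recording has no stage annotations")
    epoch_len = int(round(EPOCH_S * rec.fs))
    epochs: list[EpochSpec] = []
    for stage in STAGES:
        counter = 0
        chosen = 0
        for seg in rec.segments_for(stage):
            start = seg.start_sample
            while start + epoch_len <= seg.end_sample:
                counter += 1
                spec = EpochSpec(stage, counter, start, start + epoch_len)
                clean = True
                if masked_bool is not None:
                    frac = float(np.mean(masked_bool[spec.start_sample : spec.end_sample]))
                    clean = frac <= max_masked_frac
                if stage in SEVO_STAGES and clean and chosen < n_analysis:
                    spec.is_analysis = True
                    chosen += 1
                epochs.append(spec)
                start += epoch_len
        if stage in SEVO_STAGES and counter > 0 and chosen == 0:
            warnings.warn(f"stage {stage}: no artifact-free epochs; stage dropped from analysis")
    return epochs


def stage_code(stage: str, epoch_index: int) -> int:
    """Ordinal anaesthetic-stage covariate: control = 0, Sev2_1..Sev4_3 = 1..9."""
    if stage in CONTROL_STAGES:
        return 0
    if stage not in SEVO_STAGES:
        raise ValueError(f"no stage code for {stage!r}")
    if not 1 <= epoch_index <= N_ANALYSIS_EPOCHS:
        raise ValueError(f"epoch_index {epoch_index} outside the analysis range 1..3")
    return SEVO_STAGES.index(stage) * N_ANALYSIS_EPOCHS + epoch_index


# ---------------------------------------------------------------------------
# biomarker table

_TABLE_KEY = ["patient_id", "channel_label", "stage", "epoch_index", "biomarker"]

_TABLE_COLUMNS = _TABLE_KEY + [
    "value",
    "is_resected",
    "is_soz",
    "is_lesional",
    "has_ied",
    "is_normative",
    "surgery_stages",
    "hemisphere",
    "age_years",
    "sex",
    "n_asm",
    "daily_seizures",
]


def make_biomarker_rows(
    info: ChannelInfo, stage: str, epoch_index: int, values: dict[str, float]
) -> list[dict]:
    """Long-format rows (one per biomarker) for one channel/stage/epoch."""
    rows = []
    for biomarker, value in values.items():
        if biomarker not in BIOMARKERS:
            raise ValueError(f"unknown biomarker {biomarker!r}")
        rows.append(
            {
                "patient_id": info.patient_id,
                "channel_label": info.label,
                "stage": stage,
                "epoch_index": epoch_index,
                "biomarker": biomarker,
                "value": float(value),
                "is_resected": info.is_resected,
                "is_soz": info.is_soz,
                "is_lesional": info.is_lesional,
                "has_ied": info.has_ied,
                "is_normative": info.is_normative,
                "surgery_stages": info.surgery_stages,
                "hemisphere": info.hemisphere,
                "age_years": info.age_years,
                "sex": info.sex,
                "n_asm": info.n_asm,
                "daily_seizures": info.daily_seizures,
            }
        )
    return rows


def validate_biomarker_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format biomarker table invariants; returns the table."""
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"biomarker table missing columns: {missing}")
    if table.duplicated(subset=_TABLE_KEY).any():
        raise ValueError("(patient, channel, stage, epoch, biomarker) key is not unique")
    finite = table["value"].dropna()
    if (finite < 0).any():
        raise ValueError("biomarker values must be non-negative (MI and plug-in TE are >= 0)")
    return table
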