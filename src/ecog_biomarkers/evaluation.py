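"""Reduced-scale evaluation cohorts and property summaries.

The full acquisition protocol (19 patients, ~100 contacts, 5-min stages) is
far beyond desk scale, so verification runs on reduced cohorts that keep the
protocol's structure: an isoflurane baseline long enough for z-score
referencing, the stepwise sevoflurane stages with 1-min analysis epochs, the
bipolar montage, and the generator's class structure.  ``evaluate_cohort``
runs the full signal pipeline on one such cohort and fits the stage-trend and
epileptogenicity models; repeated over seeds it summarizes how reliably the
planted effects are recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pipeline import RunConfig, compute_biomarker_table
from .stats import fit_epi_glmm, fit_stage_lmm
from .synthetic_data import SimConfig, generate_cohort

#: Reduced evaluation schedule: 90-s isoflurane baseline (>= 60 s of z-score
#: reference), one Sev2 analysis minute, and three analysis minutes each at
#: the 3 and 4 vol% stages that carry the epileptogenicity contrast (the
#: delta-band 2-s bins need the longer windows for a usable TE sample).
REDUCED_SCHEDULE = [("Iso", 90.0), ("Sev2", 60.0), ("Sev3", 180.0), ("Sev4", 180.0)]


def reduced_cohort_config(seed: int, n_patients: int = 5, n_channels: int = 8) -> SimConfig:
    """Generator configuration for one reduced evaluation cohort."""
    return SimConfig(
        n_patients=n_patients,
        n_channels_per_patient=n_channels,
        frac_epileptogenic=0.375,
        frac_two_stage=1.0,
        edge_density=0.3,
        stage_schedule=list(REDUCED_SCHEDULE),
        seed=seed,
    )


@dataclass
class CohortEvaluation:
    """Fitted summaries of one reduced cohort."""

    seed: int
    stage_slope: dict  # biomarker -> (estimate, corrected p)
    glmm_coef: dict  # biomarker -> standardized log-odds at Sev3-4


def evaluate_cohort(seed: int, n_patients: int = 5, n_channels: int = 8) -> CohortEvaluation:
    """Run the signal pipeline on one reduced cohort and fit both model families."""
    sim = reduced_cohort_config(seed, n_patients, n_channels)
    recordings, _ = generate_cohort(sim)
    cfg = RunConfig(out_dir="unused", sim=sim, seed=seed, hfo_grid_step=20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = compute_biomarker_table(recordings, cfg)
        slopes = {}
        coefs = {}
        for biomarker in ("MI", "HFO_EC", "DELTA_EC"):
            res = fit_stage_lmm(table, biomarker, "Iso")
            slopes[biomarker] = (
                res.stage_estimate,
                float(res.term("stage_code")["p_corrected"]),
            )
            glmm = fit_epi_glmm(table, biomarker, ("Sev3", "Sev4"))
            coefs[biomarker] = float(glmm.term("value")["estimate"])
    return CohortEvaluation(seed=seed, stage_slope=slopes, glmm_coef=coefs)


def summarize_findings(evals: list[CohortEvaluation]) -> dict:
    """Fractions of cohorts reproducing the three cohort-level findings the generator encodes.

    (a) positive, Bonferroni-significant normative stage slope for MI and HFO
    EC; (b) the double dissociation at sevoflurane 3-4 vol% (positive
    standardized log-odds for MI and HFO EC, negative for delta EC).
    """
    n = len(evals)
    out = {}
    for biomarker in ("MI", "HFO_EC"):
        ok = sum(
            1
            for e in evals
            if e.stage_slope[biomarker][0] > 0 and e.stage_slope[biomarker][1] < 0.05
        )
        out[f"slope_positive_significant_frac_{biomarker}"] = ok / n
    for biomarker, want_positive in (("MI", True), ("HFO_EC", True), ("DELTA_EC", False)):
        ok = sum(
            1
            for e in evals
            if (e.glmm_coef[biomarker] > 0) == want_positive and e.glmm_coef[biomarker] != 0
        )
        out[f"dissociation_frac_{biomarker}"] = ok / n
    return out


def te_null_distribution(n_pairs_min: int = 200, seed: int = 0) -> np.ndarray:
    """TE across ordered channel pairs of edge-free recordings (null sample)."""
    from .connectivity import binarize_bursts, ec_matrix
    from .spectral import wavelet_amplitude, zscore_to_control

    const = {
        (s, c): v
        for v in (1.0,)
        for s in ("Iso", "Sev2", "Sev3", "Sev4", "SWS")
        for c in ("normative", "epileptogenic")
    }
    nulls: list[float] = []
    block = 0
    while len(nulls) < n_pairs_min:
        sim = SimConfig(
            n_patients=1, n_channels_per_patient=10, frac_epileptogenic=0.0,
            frac_two_stage=0.0, edge_density=0.0,
            stage_schedule=[("Iso", 150.0)],
            burst_rate_by_stage_class=dict(const),
            kappa_by_stage_class={k: 0.2 for k in const},
            seed=seed * 1009 + 1000 + block,
        )
        recs, _ = generate_cohort(sim)
        rec = recs[0]
        amp = wavelet_amplitude(rec, "hfo", grid=np.arange(80.0, 301.0, 20.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_to_control(amp, "Iso", [(0, int(60 * rec.fs))])
            sl = slice(int(60 * rec.fs), int(150 * rec.fs))
            series = [
                binarize_bursts(z.values[i, sl], rec.fs, "hfo", channel_label=f"E{i}")
                for i in range(rec.n_channels)
            ]
            m = ec_matrix(series, exclude_shared_contacts=False)
        nulls.extend(m.te[np.isfinite(m.te)].tolist())
        block += 1
    return np.asarray(nulls)


def planted_edge_te(p: float = 0.5, n_seeds: int = 5, seed: int = 0) -> float:
    """Mean TE along a forced src->dst edge at transmission probability ``p``."""
    from .connectivity import binarize_bursts, transfer_entropy
    from .spectral import wavelet_amplitude, zscore_to_control

    keys = [(s, c) for s in ("Iso", "Sev2", "Sev3", "Sev4", "SWS")
            for c in ("normative", "epileptogenic")]
    tes = []
    for k in range(n_seeds):
        sim = SimConfig(
            n_patients=1, n_channels_per_patient=3, frac_epileptogenic=0.0,
            frac_two_stage=0.0, forced_edges=[(0, 2)],
            stage_schedule=[("Iso", 150.0)],
            p_propagate_hfo={key: p for key in keys},
            p_propagate_delta={key: 0.0 for key in keys},
            burst_rate_by_stage_class={key: 1.0 for key in keys},
            kappa_by_stage_class={key: 0.2 for key in keys},
            seed=seed * 1013 + 2000 + k,
        )
        recs, _ = generate_cohort(sim)
        rec = recs[0]
        amp = wavelet_amplitude(rec, "hfo", grid=np.arange(80.0, 301.0, 20.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_to_control(amp, "Iso", [(0, int(60 * rec.fs))])
            sl = slice(int(60 * rec.fs), int(150 * rec.fs))
            src = binarize_bursts(z.values[0, sl], rec.fs, "hfo")
            dst = binarize_bursts(z.values[2, sl], rec.fs, "hfo")
            tes.append(transfer_entropy(src, dst))
    return float(np.mean(tes))


def surrogate_null_within_fraction(
    z_cut: float = 2.0, n_runs: int = 100, seed: int = 0
) -> float:
    """Fraction of uncoupled channels whose surrogate MI |z| stays below ``z_cut``."""
    from .pac import surrogate_mi_z

    keys = [(s, c) for s in ("Iso", "Sev2", "Sev3", "Sev4", "SWS")
            for c in ("normative", "epileptogenic")]
    n_within = 0
    runs = 0
    block = 0
    while runs < n_runs:
        sim = SimConfig(
            n_patients=1, n_channels_per_patient=10, frac_epileptogenic=0.0,
            frac_two_stage=0.0, edge_density=0.0,
            stage_schedule=[("Iso", 60.0)],
            kappa_by_stage_class={k: 0.0 for k in keys},
            burst_rate_by_stage_class={k: 1.0 for k in keys},
            seed=seed * 1019 + 3000 + block,
        )
        recs, _ = generate_cohort(sim)
        for i in range(recs[0].n_channels):
            if runs >= n_runs:
                break
            z = surrogate_mi_z(recs[0].samples[i], recs[0].fs, n_surrogates=100, seed=i)
            runs += 1
            n_within += int(abs(z) < z_cut)
        block += 1
    return n_within / runs


def null_stage_rejection_rate(
    n_replicates: int = 200,
    n_patients: int = 8,
    n_channels: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I rate of the stage-trend model on null (zero-slope) cohorts.

    Fraction of table-level replicates whose Bonferroni-corrected stage p
    falls below ``alpha``; expected well under alpha at nominal calibration.
    """
    from .synthetic_data import simulate_stats_table

    root = np.random.SeedSequence(seed)
    child = root.generate_state(n_replicates)
    rejections = 0
    fitted = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in child:
            table = simulate_stats_table(
                n_patients=n_patients,
                n_channels=n_channels,
                slope=0.0,
                seed=int(rep_seed % (2**31)),
            )
            res = fit_stage_lmm(table, "MI", "Iso")
            p = res.term("stage_code")["p_corrected"]
            if np.isfinite(p):
                fitted += 1
                rejections += int(p < alpha)
    if fitted == 0:
        raise RuntimeError("no null replicate produced a valid p-value")
    return rejections / fitted


def lmm_ci_coverage(
    n_replicates: int = 200,
    slope: float = 0.01,
    n_patients: int = 12,
    n_channels: int = 10,
    seed: int = 0,
) -> float:
    """Coverage of the 95% Wald interval for the stage slope on linear cohorts."""
    from scipy import stats as sps

    from .synthetic_data import simulate_stats_table

    root = np.random.SeedSequence(seed + 1)
    child = root.generate_state(n_replicates)
    covered = 0
    fitted = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in child:
            table = simulate_stats_table(
                n_patients=n_patients,
                n_channels=n_channels,
                slope=slope,
                seed=int(rep_seed % (2**31)),
            )
            res = fit_stage_lmm(table, "MI", "Iso")
            term = res.term("stage_code")
            if not (res.converged and np.isfinite(term["se"]) and term["se"] > 0):
                continue
            half = sps.t.ppf(0.975, term["df"]) * term["se"]
            fitted += 1
            covered += int(abs(term["estimate"] - slope) <= half)
    if fitted < n_replicates * 0.9:
        raise RuntimeError(f"only {fitted}/{n_replicates} replicates converged")
    return covered / fitted


def glmm_recovery_bias(
    n_seeds: int = 20,
    n_patients: int = 12,
    n_channels: int = 125,
    true_coef: float = 2.0,
    seed: int = 0,
) -> float:
    """Relative bias of the logistic mixed model's raw-scale biomarker coefficient.

    Channels get gamma-distributed biomarker values; labels are drawn from a
    logistic model with patient intercepts.  Returns |mean estimate - truth| /
    truth over ``n_seeds`` simulated cohorts of ``n_patients * n_channels``
    channels.
    """
    import pandas as pd

    from .core_model import make_biomarker_rows, ChannelInfo

    estimates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_seeds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
            rows = []
            for p in range(n_patients):
                b_p = rng.normal(0, 0.3)
                info_kw = dict(
                    patient_id=f"P{p:02d}",
                    surgery_stages=1 + p % 2,
                    hemisphere="LR"[p % 2],
                    age_years=float(5 + p),
                    sex="MF"[p % 2],
                    n_asm=p % 4,
                    daily_seizures=bool(p % 3 == 0),
                    is_lesional=bool(p % 2),
                )
                for ch in range(n_channels):
                    v = rng.gamma(2.0, 0.5)
                    eta = -1.0 + true_coef * v + b_p
                    y = rng.random() < 1.0 / (1.0 + np.exp(-eta))
                    info = ChannelInfo(label=f"C{ch:03d}", is_resected=bool(y), **info_kw)
                    rows.extend(make_biomarker_rows(info, "Sev3", 1, {"MI": v}))
            table = pd.DataFrame(rows)
            res = fit_epi_glmm(table, "MI", "Sev3", standardize_value=False)
            estimates.append(float(res.term("value")["estimate"]))
    return abs(float(np.mean(estimates)) - true_coef) / true_coef
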