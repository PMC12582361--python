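"""Stage-trend linear mixed models, epileptogenicity logistic mixed models, and effect sizes.

The biomarker table is analysed exactly as a long-format electrode-level
dataset: every (patient, channel, stage, epoch) biomarker value is one row,
patients enter as a random intercept, and the anaesthetic stage enters as a
single ordinal covariate (control = 0, the nine sevoflurane minutes = 1..9),
so the fitted stage term is the per-minute biomarker slope.  Fixed-effect
covariates are age, sex, hemisphere, MRI lesion, daily seizures, number of
anti-seizure medications, and one- vs two-stage surgery; covariates without
variation in the subset at hand are dropped automatically.

Linear mixed models are fitted by REML (statsmodels MixedLM) with two-sided
Wald tests on residual degrees of freedom (an approximation to the
Satterthwaite correction, documented as such).  Binary logistic mixed models
use the variational-Bayes binomial mixed GLM with a per-patient random
intercept; coefficients are reported as odds ratios.  Bonferroni correction
uses m = 6 for the stage-trend family and m = 40 for the epileptogenicity
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .core_model import SEVO_STAGES, stage_code

M_STAGE_TREND = 6  # 3 control conditions x 2 biomarkers
M_EPI = 40  # 2 controls x 2 biomarkers x 10 stages

_COVARIATES = [
    ("age_years", "age_years"),
    ("C(sex)", "sex"),
    ("C(hemisphere)", "hemisphere"),
    ("is_lesional", "is_lesional"),
    ("daily_seizures", "daily_seizures"),
    ("n_asm", "n_asm"),
    ("C(surgery_stages)", "surgery_stages"),
]


@dataclass
class ModelResult:
    """Term table and diagnostics of one fitted mixed model."""

    terms: pd.DataFrame  # term, estimate, se, stat, df, p, p_corrected [, odds_ratio]
    m_comparisons: int
    converged: bool
    kind: str  # "lmm" | "glmm"
    n_obs: int
    residual_quantiles: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r}; have {list(self.terms['term'])}")
        return hit.iloc[0]

    @property
    def stage_estimate(self) -> float:
        return float(self.term("stage_code")["estimate"])


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def _varying_covariates(df: pd.DataFrame, focal: str) -> list[str]:
    """Covariate terms that vary and keep the fixed-effects design full rank.

    Patient-level covariates are perfectly collinear once their count reaches
    the number of patients; adding such a column makes the GLS normal
    equations singular.  Greedy rank-checked selection keeps the focal term
    (the stage code or the biomarker value) plus every covariate that adds
    full column rank.
    """
    import patsy

    chosen: list[str] = []
    X = np.asarray(patsy.dmatrix("1 + " + focal, df))
    rank = np.linalg.matrix_rank(X)
    for term, col in _COVARIATES:
        if df[col].nunique() < 2:
            continue
        X2 = np.asarray(patsy.dmatrix(" + ".join(["1", focal] + chosen + [term]), df))
        r2 = np.linalg.matrix_rank(X2)
        if r2 == rank + (X2.shape[1] - X.shape[1]):
            chosen.append(term)
            X, rank = X2, r2
    return chosen


def _coerce_model_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("is_lesional", "daily_seizures"):
        df[col] = df[col].astype(int)
    return df


def add_stage_codes(df: pd.DataFrame, control: str) -> pd.DataFrame:
    """Append the ordinal stage covariate; control epochs code as 0."""
    out = df.copy()
    out["stage_code"] = [
        stage_code(s, e) if s in SEVO_STAGES else 0
        for s, e in zip(out["stage"], out["epoch_index"])
    ]
    return out


def fit_stage_lmm(
    table: pd.DataFrame,
    biomarker: str,
    control: str = "Iso",
    m_comparisons: int = M_STAGE_TREND,
    random_stage_slope: bool = False,
) -> ModelResult:
    """Normative stage-trend linear mixed model for one biomarker.

    Restricts to normative channels, the chosen control stage, and the
    sevoflurane analysis epochs.  An SWS control restricts to two-stage
    patients (the only ones with an SWS recording).
    """
    df = table[(table["biomarker"] == biomarker) & table["is_normative"]]
    df = df[df["stage"].isin(list(SEVO_STAGES) + [control])]
    if control == "SWS":
        df = df[df["surgery_stages"] == 2]
    df = add_stage_codes(df, control).dropna(subset=["value"])
    if df["patient_id"].nunique() < 2:
        raise ValueError("stage LMM needs >= 2 patients")
    df = _coerce_model_frame(df)

    rhs = ["stage_code"] + _varying_covariates(df, "stage_code")
    re_formula = "~stage_code" if random_stage_slope else "1"
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        def _fit(formula):
            model = smf.mixedlm(formula, df, groups=df["patient_id"], re_formula=re_formula)
            fit = None
            for method in ("lbfgs", "bfgs", "cg"):
                try:
                    fit = model.fit(reml=True, method=method)
                except np.linalg.LinAlgError:
                    continue
                if getattr(fit, "converged", True):
                    break
            return model, fit

        model, fit = _fit("value ~ " + " + ".join(rhs))
        if fit is None:
            # near-collinear covariates under GLS weighting: refit stage-only
            model, fit = _fit("value ~ stage_code")
            flags.append("covariates dropped (singular weighted design)")
        if fit is None:
            raise ValueError("stage LMM failed to fit under all optimizers")
    converged = bool(getattr(fit, "converged", True))
    if not converged and np.all(np.isfinite(np.asarray(fit.bse_fe))):
        # optimizer reports non-convergence but the final iterate carries
        # finite curvature: report Wald statistics from it, flagged
        flags.append("convergence flag false; Wald statistics from final iterate")
        converged = True

    n, rank = len(df), np.linalg.matrix_rank(model.exog)
    dof = max(n - rank, 1)
    rows = []
    for name in fit.fe_params.index:
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        tval = est / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tval), dof)) if converged and np.isfinite(tval) else np.nan
        rows.append(
            {
                "term": name.replace("Intercept", "intercept"),
                "estimate": est,
                "se": se,
                "stat": tval,
                "df": dof,
                "p": p,
                "p_corrected": bonferroni_adjust(p, m_comparisons) if np.isfinite(p) else np.nan,
            }
        )
    try:
        resid = np.asarray(fit.resid)
    except (ValueError, np.linalg.LinAlgError):
        # zero-variance random effects: fall back to marginal residuals
        resid = np.asarray(model.endog) - model.exog @ np.asarray(fit.fe_params)
    resid = np.sort(resid)
    quantiles = np.quantile(resid, np.linspace(0, 1, 101)) if resid.size else None
    return ModelResult(
        terms=pd.DataFrame(rows),
        m_comparisons=m_comparisons,
        converged=converged,
        kind="lmm",
        n_obs=n,
        residual_quantiles=quantiles,
        flags=flags,
    )


def fit_epi_glmm(
    table: pd.DataFrame,
    biomarker: str,
    stage: str,
    epoch_index: int | None = None,
    label: str = "epileptogenic",
    m_comparisons: int = M_EPI,
    standardize_value: bool = True,
) -> ModelResult:
    """Binary logistic mixed model: does the biomarker characterize pathology?

    Fits ``label ~ covariates + value`` with a per-patient random intercept on
    all channels at one stage (optionally one 1-min epoch).  ``label`` is
    "epileptogenic" (resected, in this seizure-free cohort) or "soz".
    Reported odds ratios are exp(coefficient); an implausibly large |coef|
    marks quasi-complete separation in ``flags``.

    By default the biomarker value is standardized (zero mean, unit SD) before
    fitting, so the odds ratio reads "per SD of the biomarker": raw transfer
    entropies live on a scale of millibits, where a per-unit log-odds would be
    in the hundreds and outside what the variational posterior can represent.
    Set ``standardize_value=False`` to estimate on the raw scale.
    """
    if label == "epileptogenic":
        ycol = "is_resected"
    elif label == "soz":
        ycol = "is_soz"
    else:
        raise ValueError(f"unknown label {label!r}")
    stages = [stage] if isinstance(stage, str) else list(stage)
    df = table[(table["biomarker"] == biomarker) & table["stage"].isin(stages)]
    if epoch_index is not None:
        df = df[df["epoch_index"] == epoch_index]
    df = df.dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError("no rows for the requested biomarker/stage")
    df["y"] = df[ycol].astype(int)
    if df["y"].nunique() < 2:
        raise ValueError(f"both {label} classes must be present")
    df = _coerce_model_frame(df)
    if standardize_value:
        sd = df["value"].std(ddof=0)
        if sd == 0:
            raise ValueError("biomarker value is constant; cannot standardize")
        df["value"] = (df["value"] - df["value"].mean()) / sd

    rhs = _varying_covariates(df, "value") + ["value"]
    formula = "y ~ " + " + ".join(rhs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            formula, {"patient": "0 + C(patient_id)"}, df
        )
        fit = model.fit_vb()

    flags = []
    rows = []
    for name, est, se in zip(model.exog_names, fit.fe_mean, fit.fe_sd):
        z = est / se if se > 0 else np.nan
        p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append(
            {
                "term": name.replace("Intercept", "intercept"),
                "estimate": float(est),
                "se": float(se),
                "stat": z,
                "df": np.nan,
                "p": p,
                "p_corrected": bonferroni_adjust(p, m_comparisons) if np.isfinite(p) else np.nan,
                "odds_ratio": float(np.exp(np.clip(est, -700, 700))),
            }
        )
        if name == "value" and abs(est) > 25:
            flags.append("possible quasi-complete separation")
    return ModelResult(
        terms=pd.DataFrame(rows),
        m_comparisons=m_comparisons,
        converged=True,
        kind="glmm",
        n_obs=len(df),
        flags=flags,
    )


def cohens_d_by_stage(
    table: pd.DataFrame, biomarker: str, label: str = "epileptogenic"
) -> pd.Series:
    """Per-stage effect size between pathological and other sites.

    For each patient and 1-min epoch: |mean(pathological) - mean(others)|
    divided by the sample SD of all that patient-epoch's sites; the stage value
    is the mean over patients and epochs.  Patient-epochs with a single class
    are skipped.
    """
    ycol = "is_resected" if label == "epileptogenic" else "is_soz"
    df = table[table["biomarker"] == biomarker].dropna(subset=["value"])
    out = {}
    for stage_name, stage_df in df.groupby("stage", sort=False):
        ds = []
        for (_pid, _ep), g in stage_df.groupby(["patient_id", "epoch_index"]):
            y = g[ycol].astype(bool)
            if y.nunique() < 2 or len(g) < 3:
                continue
            sd = g["value"].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            d = abs(g.loc[y, "value"].mean() - g.loc[~y, "value"].mean()) / sd
            ds.append(d)
        if ds:
            out[stage_name] = float(np.mean(ds))
    return pd.Series(out, name=f"cohens_d_{biomarker}_{label}")


def subtraction_predictor(
    table: pd.DataFrame, biomarker: str, stage: str, epoch_index: int | None = None
) -> pd.Series:
    """Per-patient resection-completeness proxy: mean(resected) - mean(retained).

    Patients lacking either class at the requested stage are excluded with a
    warning.  When outcome labels are available, the values feed a logistic
    model of postoperative seizure freedom.
    """
    df = table[(table["biomarker"] == biomarker) & (table["stage"] == stage)]
    if epoch_index is not None:
        df = df[df["epoch_index"] == epoch_index]
    df = df.dropna(subset=["value"])
    out = {}
    for pid, g in df.groupby("patient_id"):
        res = g.loc[g["is_resected"], "value"]
        ret = g.loc[~g["is_resected"].astype(bool), "value"]
        if res.empty or ret.empty:
            warnings.warn(f"patient {pid}: missing a resected/retained class; excluded")
            continue
        out[pid] = float(res.mean() - ret.mean())
    return pd.Series(out, name=f"subtraction_{biomarker}_{stage}")


def log_variant(table: pd.DataFrame) -> pd.DataFrame:
    """Log-transform biomarker values (per-biomarker epsilon for exact zeros).

    epsilon is half the smallest positive value of that biomarker and is added
    only when zeros are present; an all-zero biomarker is an error.  The
    transform is strictly monotone, so downstream rank structure is preserved.
    """
    out = table.copy()
    for biomarker, g in table.groupby("biomarker"):
        vals = g["value"].dropna()
        pos = vals[vals > 0]
        if pos.empty:
            raise ValueError(f"biomarker {biomarker}: all values are zero; cannot log-transform")
        eps = float(pos.min()) / 2.0 if (vals == 0).any() else 0.0
        idx = g.index
        out.loc[idx, "value"] = np.log(table.loc[idx, "value"] + eps)
    return out
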