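"""Mixed-effects contrasts between the Wrap and Lace configurations.

Three model forms are supported, all with Lace as the reference level and
fitted by restricted maximum likelihood:

* ``intercept_only``:         Outcome ~ Config + (1 | Subject)
* ``random_slope``:           Outcome ~ Config + (Config | Subject)
* ``random_slope_with_speed``: Outcome ~ Config + Speed + (Config | Subject)

Subjective ratings and per-section average heart rate use the random
intercept form; stride- and step-level biomechanical outcomes use the
random slope forms, which let every subject respond to the shoe change
with their own effect.  Contrasts are differences of estimated marginal
means (model predictions per configuration averaged over the observed
covariates), with percent differences taken relative to the Lace emmean.

Inference on the condition effect uses a t reference with
``df = n_subjects - 1``: with random slopes the effective information
about the effect is the number of subjects, and a normal reference is
anticonservative for small cohorts.  At this study's size (29 subjects)
the two are indistinguishable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

FORMS = ("intercept_only", "random_slope", "random_slope_with_speed")
ALPHA = 0.05


class ConditionLMM:
    """Linear mixed model for a Wrap-vs-Lace outcome comparison.

    Parameters
    ----------
    data : DataFrame with at least the outcome, config and subject columns
        (plus a speed column for the covariate form).
    outcome : name of the numeric outcome column.
    form : one of ``FORMS``.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 form: str = "random_slope",
                 config_col: str = "config", subject_col: str = "subject",
                 speed_col: str = "speed",
                 reference: str = "Lace"):
        if form not in FORMS:
            raise ValueError(f"unknown model form {form!r}")
        cols = [outcome, config_col, subject_col]
        if form == "random_slope_with_speed":
            cols.append(speed_col)
        df = data[cols].dropna().copy()
        if df[config_col].isna().any() or df[subject_col].isna().any():
            raise ValueError("missing Config/Subject values")
        if not np.isfinite(df[outcome].to_numpy(float)).all():
            raise ValueError("non-finite outcome values")
        levels = set(df[config_col].unique())
        if reference not in levels or len(levels) != 2:
            raise ValueError(f"need exactly two config levels incl. {reference}")
        if df[subject_col].nunique() < 2:
            raise ValueError("need at least two subjects")
        self.data = df
        self.outcome = outcome
        self.form = form
        self.config_col = config_col
        self.subject_col = subject_col
        self.speed_col = speed_col
        self.reference = reference
        self.treatment = (levels - {reference}).pop()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       form: str = "random_slope", **kwargs) -> "ConditionLMM":
        return cls(data, outcome, form=form, **kwargs)

    # -- design matrices ------------------------------------------------

    def _design(self, form: str):
        df = self.data
        wrap = (df[self.config_col] == self.treatment).to_numpy(float)
        exog = {"Intercept": np.ones(len(df)), f"Config[{self.treatment}]": wrap}
        if form == "random_slope_with_speed":
            exog["Speed"] = df[self.speed_col].to_numpy(float)
        exog = pd.DataFrame(exog, index=df.index)
        if form == "intercept_only":
            exog_re = exog[["Intercept"]]
        else:
            exog_re = exog[["Intercept", f"Config[{self.treatment}]"]]
        return df[self.outcome].to_numpy(float), exog, exog_re

    # -- fitting ---------------------------------------------------------

    def fit(self, reml: bool = True, maxiter: int = 200) -> "ConditionLMMResults":
        """REML fit; singular random-slope fits fall back to Eq. (1)."""
        endog, exog, exog_re = self._design(self.form)
        groups = self.data[self.subject_col].to_numpy()
        result, singular, messages = self._fit_once(
            endog, exog, exog_re, groups, reml, maxiter)
        form_used = self.form
        if singular and self.form != "intercept_only":
            messages.append("singular random-slope fit; "
                            "fell back to the random-intercept form")
            warnings.warn(messages[-1], stacklevel=2)
            exog_re = exog[["Intercept"]]  # same fixed effects, (1|Subject)
            result, singular, _ = self._fit_once(
                endog, exog, exog_re, groups, reml, maxiter)
            form_used = "intercept_only"
        return ConditionLMMResults(self, result, form_used, messages)

    def _fit_once(self, endog, exog, exog_re, groups, reml, maxiter):
        messages: list[str] = []
        model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        result = None
        last_exc: Exception | None = None
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    result = model.fit(reml=reml, maxiter=maxiter,
                                       method=method)
                    if not np.isfinite(result.llf):
                        raise ValueError("non-finite REML log-likelihood")
                    break
                except (np.linalg.LinAlgError, ValueError) as exc:
                    result = None
                    last_exc = exc
                    continue
        if result is None:
            raise RuntimeError(
                f"mixed-model fit failed for outcome {self.outcome!r} "
                f"({len(endog)} obs): {last_exc}") from last_exc
        messages.extend(str(w.message) for w in caught)
        cov_re = np.atleast_2d(np.asarray(result.cov_re))
        eig = np.linalg.eigvalsh(cov_re)
        singular = (not np.all(np.isfinite(result.bse_fe.to_numpy()))
                    or (cov_re.shape[0] > 1
                        and eig.min() < 1e-8 * max(eig.max(), 1e-12)))
        return result, singular, messages


@dataclass
class ConditionLMMResults:
    """Estimates, uncertainties and marginal-mean contrasts of one fit."""

    model: ConditionLMM
    _result: object
    form_used: str
    messages: list[str] = field(default_factory=list)

    # -- fixed effects ---------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return self._result.fe_params

    @property
    def bse(self) -> pd.Series:
        return self._result.bse_fe

    @property
    def df_inference(self) -> float:
        """Degrees of freedom for the condition-effect t reference.

        The shoe condition varies within subject, so the effect estimate
        carries essentially one piece of information per subject; the t
        reference uses ``n_subjects - 1``, the paired-comparison df.  A
        normal reference is anticonservative for small cohorts (the
        random-slope variance is estimated from few subjects); at this
        study's size (29 subjects) t(28) and z are indistinguishable.
        """
        return float(self.model.data[self.model.subject_col].nunique() - 1)

    @property
    def effect_name(self) -> str:
        return f"Config[{self.model.treatment}]"

    @property
    def effect(self) -> float:
        return float(self.params[self.effect_name])

    @property
    def effect_se(self) -> float:
        return float(self.bse[self.effect_name])

    @property
    def pvalue(self) -> float:
        t = self.effect / self.effect_se
        return float(2.0 * sps.t.sf(abs(t), self.df_inference))

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA

    # -- variance components --------------------------------------------

    @property
    def variance_components(self) -> dict[str, float]:
        res = self._result
        cov = np.atleast_2d(np.asarray(res.cov_re))
        out = {"intercept_sd": float(np.sqrt(max(cov[0, 0], 0.0))),
               "residual_sd": float(np.sqrt(res.scale))}
        if cov.shape[0] > 1:
            out["slope_sd"] = float(np.sqrt(max(cov[1, 1], 0.0)))
            denom = out["intercept_sd"] * out["slope_sd"]
            out["correlation"] = float(cov[0, 1] / denom) if denom > 0 else 0.0
        return out

    @property
    def converged(self) -> bool:
        return bool(getattr(self._result, "converged", True))

    # -- estimated marginal means ---------------------------------------

    @property
    def emmeans(self) -> dict[str, float]:
        """Model-predicted outcome per config at the observed covariates.

        Every observation is predicted under both configurations (other
        covariates held at their observed values) and the predictions are
        averaged; for a linear model this equals prediction at the
        covariate means.
        """
        _, exog, _ = self.model._design(self.model.form)
        beta = self.params
        out = {}
        for level, wrap in ((self.model.treatment, 1.0),
                            (self.model.reference, 0.0)):
            x = exog.copy()
            x[self.effect_name] = wrap
            x = x[list(beta.index)]
            out[level] = float((x.to_numpy() @ beta.to_numpy()).mean())
        return out

    def emm_contrast(self) -> dict[str, float]:
        """Wrap-minus-Lace marginal-mean difference and percent difference.

        The percent difference is relative to the Lace (reference) emmean;
        a negative value means the Wrap reduces the outcome.
        """
        emm = self.emmeans
        diff = emm[self.model.treatment] - emm[self.model.reference]
        ref = emm[self.model.reference]
        pct = float("nan") if ref == 0 else 100.0 * diff / ref
        return {"difference": float(diff), "percent_difference": pct,
                "pvalue": self.pvalue,
                "emmean_wrap": emm[self.model.treatment],
                "emmean_lace": emm[self.model.reference]}

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        emm = self.emmeans
        con = self.emm_contrast()
        vc = self.variance_components
        n_subj = self.model.data[self.model.subject_col].nunique()
        lines = [
            f"ConditionLMM [{self.form_used}]  outcome: {self.model.outcome}",
            f"  n obs: {len(self.model.data)}   "
            f"subjects: {n_subj}   converged: {self.converged}",
            "  fixed effects:",
        ]
        for name in self.params.index:
            lines.append(f"    {name:<22s} {self.params[name]:>10.4f}"
                         f"  (SE {self.bse[name]:.4f})")
        lines.append("  variance components: "
                     + ", ".join(f"{k}={v:.4f}" for k, v in vc.items()))
        lines.append(f"  emmeans: {self.model.treatment}={emm[self.model.treatment]:.4f}"
                     f"  {self.model.reference}={emm[self.model.reference]:.4f}")
        lines.append(f"  contrast: diff={con['difference']:.4f}"
                     f"  ({con['percent_difference']:+.2f}%)"
                     f"  p={con['pvalue']:.4g}"
                     f"  [t({self.df_inference:.1f})]")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# whole-study analysis
# ---------------------------------------------------------------------------

STRIDE_OUTCOME_COLS = ("speed", "peak_acc", "peak_jerk", "ml_range",
                       "peak_eversion_velocity")
STEP_OUTCOME_COLS = ("heel_contact_area", "toe_contact_area",
                     "peak_heel_pressure", "peak_toe_pressure")
SECTIONS = ("uphill", "top", "downhill")


@dataclass
class StudyResults:
    """Per-section fits for every outcome plus the pooled summary table."""

    fits: dict[tuple[str, str], ConditionLMMResults]
    questionnaire_fits: dict[str, ConditionLMMResults]
    retained_subjects: list
    excluded_subjects: list

    def contrast_table(self) -> pd.DataFrame:
        rows = []
        for (outcome, section), res in self.fits.items():
            con = res.emm_contrast()
            rows.append({"outcome": outcome, "section": section,
                         "form": res.form_used, **con,
                         "significant": con["pvalue"] < ALPHA})
        return pd.DataFrame(rows)

    def questionnaire_table(self) -> pd.DataFrame:
        rows = []
        for item, res in self.questionnaire_fits.items():
            con = res.emm_contrast()
            rows.append({"item": item, **con,
                         "significant": con["pvalue"] < ALPHA})
        return pd.DataFrame(rows)

    def section_effect(self, outcome: str) -> dict[str, dict]:
        return {sec: self.fits[(outcome, sec)].emm_contrast()
                for sec in SECTIONS if (outcome, sec) in self.fits}


def summary_table(strides: pd.DataFrame, steps: pd.DataFrame,
                  hr: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-section means +- SD of every outcome."""
    rows = []
    for df, outcomes in ((hr, ("heart_rate",)),
                         (strides, STRIDE_OUTCOME_COLS),
                         (steps, STEP_OUTCOME_COLS)):
        if df is None or len(df) == 0:
            continue
        for outcome in outcomes:
            if outcome not in df.columns:
                continue
            g = df.groupby(["section", "config"])[outcome]
            for (sec, conf), m in g.mean().items():
                rows.append({"outcome": outcome, "section": sec,
                             "config": conf, "mean": float(m),
                             "sd": float(g.std()[(sec, conf)])})
    return pd.DataFrame(rows)


def analyze_study(strides: pd.DataFrame, steps: pd.DataFrame,
                  hr: pd.DataFrame,
                  questionnaire: pd.DataFrame | None = None,
                  retained_subjects: list | None = None,
                  excluded_subjects: list | None = None,
                  speed_covariate: bool = False) -> StudyResults:
    """Fit the whole study: one model per outcome per trail section.

    Biomechanical outcomes (per-stride IMU metrics and per-step pressure
    metrics) use the random-slope form, separately per section; heart rate
    and questionnaire items use the random-intercept form.  Subjects
    failing the lap-time QC must already be excluded from the inputs (or
    passed via ``retained_subjects`` for filtering here).
    """
    if retained_subjects is not None:
        strides = strides[strides["subject"].isin(retained_subjects)]
        steps = steps[steps["subject"].isin(retained_subjects)]
        hr = hr[hr["subject"].isin(retained_subjects)]
        if questionnaire is not None:
            questionnaire = questionnaire[
                questionnaire["subject"].isin(retained_subjects)]
    if strides["subject"].nunique() < 2:
        raise ValueError("fewer than two retained subjects")
    form_imu = "random_slope_with_speed" if speed_covariate else "random_slope"
    fits: dict[tuple[str, str], ConditionLMMResults] = {}
    for sec in SECTIONS:
        s_sec = strides[strides["section"] == sec]
        for outcome in STRIDE_OUTCOME_COLS:
            form = "random_slope" if outcome == "speed" else form_imu
            fits[(outcome, sec)] = ConditionLMM(
                s_sec, outcome, form=form).fit()
        p_sec = steps[steps["section"] == sec]
        for outcome in STEP_OUTCOME_COLS:
            fits[(outcome, sec)] = ConditionLMM(
                p_sec, outcome, form="random_slope").fit()
        h_sec = hr[hr["section"] == sec]
        fits[("heart_rate", sec)] = ConditionLMM(
            h_sec, "heart_rate", form="intercept_only").fit()
    qfits: dict[str, ConditionLMMResults] = {}
    if questionnaire is not None and len(questionnaire):
        for item, df_item in questionnaire.groupby("item"):
            qfits[item] = ConditionLMM(df_item, "rating",
                                       form="intercept_only").fit()
    return StudyResults(fits=fits, questionnaire_fits=qfits,
                        retained_subjects=sorted(strides["subject"].unique()),
                        excluded_subjects=list(excluded_subjects or []))


def simulate_outcome_table(n_subjects: int, n_per_condition: int,
                           effect: float, rng: np.random.Generator,
                           mean: float = 100.0, intercept_sd: float = 10.0,
                           slope_sd: float = 5.0, residual_sd: float = 15.0,
                           ) -> pd.DataFrame:
    """Observation table drawn directly from the random-slope model.

    Used for statistical calibration runs (e.g. Type-I error under the
    null) where the sensor layer is irrelevant.
    """
    rows = []
    for subj in range(n_subjects):
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        for config, wrap in (("Lace", 0.0), ("Wrap", 1.0)):
            mu = mean + b0 + wrap * (effect + b1)
            vals = mu + rng.normal(0.0, residual_sd, n_per_condition)
            rows.append(pd.DataFrame({
                "subject": subj, "config": config, "outcome": vals}))
    return pd.concat(rows, ignore_index=True)
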