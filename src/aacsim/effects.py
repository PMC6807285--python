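"""Group-level condition-effects statistics.

Linear mixed-effects F tests for the 3 (threat) x 6 (potential loss)
within-subject design — optionally crossed with a between-subject group
factor and covariates — with a random subject intercept.  The approach
outcome is analyzed on condition means with a Greenhouse-Geisser
correction for non-sphericity; latency outcomes are analyzed on single
trials with potential loss 0-4.

Denominator degrees of freedom: the default is a residual-df
approximation (``n_obs - rank(X) - (n_subjects - 1)``), flagged in the
output as approximate.  ``df_method="satterthwaite"`` delegates the whole
F table to lmerTest/lme4 through ``Rscript`` when an R installation is
available, which reproduces the Satterthwaite recipe exactly.
"""

from __future__ import annotations

import io
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from .config import THREAT_CODES

OUTCOMES = ("approach_proportion", "approach_latency", "return_latency")


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def gg_epsilon(subject_by_condition: np.ndarray | pd.DataFrame) -> float:
    """Greenhouse-Geisser sphericity epsilon from subject x condition means.

    Computed from the double-centered covariance of the within-subject
    condition means and clipped to ``[1/(k-1), 1]``.  Equals 1 under
    compound symmetry and attains the lower bound when all within-subject
    variance lies in a single contrast.
    """
    y = np.asarray(subject_by_condition, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need an n_subjects x k matrix with n >= 2, k >= 2")
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    denom = (k - 1) * np.sum(sc * sc)
    if denom <= 0:
        return 1.0
    eps = np.trace(sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# Per-subject summary statistics
# ---------------------------------------------------------------------------

def subject_summary(table: pd.DataFrame, statistic: str,
                    value_col: Optional[str] = None) -> pd.DataFrame:
    """Per-subject summary statistic feeding the single-case comparisons.

    ``loss_linear_coefficient``: least-squares slope of the condition-mean
    outcome on potential loss (averaged over threat).
    ``threat_linear_coefficient``: slope on the linear threat code
    (-1, 0, 1).  ``overall_mean``: mean of all included values.
    """
    if value_col is None:
        value_col = ("approach_proportion" if "approach_proportion" in table
                     else "value")
    rows = []
    for subj, g in table.groupby("subject_id", sort=False):
        g = g.dropna(subset=[value_col])
        if statistic == "overall_mean":
            val = float(g[value_col].mean())
        elif statistic == "loss_linear_coefficient":
            means = g.groupby("potential_loss")[value_col].mean()
            val = float(np.polyfit(means.index.to_numpy(dtype=float),
                                   means.to_numpy(), 1)[0])
        elif statistic == "threat_linear_coefficient":
            means = g.groupby("threat_level")[value_col].mean()
            codes = np.array([THREAT_CODES[lv] for lv in means.index])
            val = float(np.polyfit(codes, means.to_numpy(), 1)[0])
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.append({"subject_id": subj, "statistic": statistic, "value": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-effects condition model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMESpec:
    """Specification of one condition-effects mixed model."""

    outcome: str = "approach_proportion"
    include_group: bool = False
    covariates: tuple[str, ...] = ()
    unit: str = "condition_mean"   # or "single_trial"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass
class ConditionEffectsResults:
    """F table and diagnostics from a fitted condition-effects model."""

    table: pd.DataFrame          # effect, F, df1, df2, p (and p_gg, epsilon)
    epsilon: Optional[float]
    df_method: str
    n_subjects: int
    n_obs: int
    converged: bool
    singular: bool
    diagnostics: list[str] = field(default_factory=list)
    mixedlm_result: object = None

    def summary(self) -> str:
        lines = [f"Condition-effects LME ({self.df_method} df; "
                 f"{self.n_subjects} subjects, {self.n_obs} obs)"]
        if self.epsilon is not None:
            lines.append(f"Greenhouse-Geisser epsilon = {self.epsilon:.4f}")
        if self.singular:
            lines.append("WARNING: singular or non-converged fit: "
                         + "; ".join(self.diagnostics))
        with pd.option_context("display.width", 120):
            lines.append(self.table.to_string(index=False,
                                              float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class ConditionEffectsModel:
    """Mixed model for condition effects on a behavioural outcome.

    Parameters
    ----------
    table
        Tidy data: ``subject_id``, ``threat_level``, ``potential_loss``,
        the outcome column, and optionally ``group`` plus covariates.
    spec
        Which outcome, whether to cross with a group factor, covariates.
    """

    def __init__(self, table: pd.DataFrame, spec: LMESpec):
        self.spec = spec
        col = {"approach_proportion": "approach_proportion",
               "approach_latency": "approach_latency_ms",
               "return_latency": "return_latency_ms"}[spec.outcome]
        if col not in table.columns:
            raise ValueError(f"table lacks outcome column {col!r}")
        df = table.dropna(subset=[col]).copy()
        df = df.rename(columns={col: "y"})
        if df["subject_id"].nunique() < 2:
            raise ValueError("condition-effects model requires >= 2 subjects")
        if spec.include_group and "group" not in df.columns:
            raise ValueError("include_group=True but no 'group' column")
        for lab, c in (("threat_level", "threat_level"),
                       ("potential_loss", "potential_loss")):
            if df[c].nunique() < 2:
                raise ValueError(f"fixed-effect factor {lab} has an empty level"
                                 " structure (fewer than 2 observed levels)")
        self.data = df

    @classmethod
    def from_condition_means(cls, means: pd.DataFrame,
                             **spec_kw) -> "ConditionEffectsModel":
        return cls(means, LMESpec(outcome="approach_proportion",
                                  unit="condition_mean", **spec_kw))

    # -- formula assembly --------------------------------------------------

    def _fixed_terms(self) -> list[str]:
        terms = ["C(threat_level, Sum)", "C(potential_loss, Sum)"]
        if self.spec.include_group:
            terms.append("C(group, Sum)")
        return terms

    def _formula(self, interactions: bool = True) -> str:
        joiner = " * " if interactions else " + "
        rhs = joiner.join(self._fixed_terms())
        for cov in self.spec.covariates:
            rhs = f"({rhs}) * {cov}" if rhs else cov
        return f"y ~ {rhs}"

    # -- fitting -----------------------------------------------------------

    def fit(self, df_method: str = "residual",
            apply_gg: Optional[bool] = None) -> ConditionEffectsResults:
        """Fit the mixed model and assemble the F table.

        ``apply_gg`` defaults to True for the approach-proportion outcome
        (condition means), where the Greenhouse-Geisser epsilon is
        estimated from the subject x (threat x loss) cell means and both
        F-test dfs are multiplied by it before recomputing p.
        """
        if apply_gg is None:
            apply_gg = self.spec.outcome == "approach_proportion"
        if df_method == "satterthwaite":
            res = self._fit_lmer_satterthwaite()
        elif df_method == "residual":
            res = self._fit_statsmodels()
        else:
            raise ValueError("df_method must be 'residual' or 'satterthwaite'")

        eps = None
        if apply_gg:
            eps = self._design_epsilon()
            tab = res.table
            tab["epsilon"] = eps
            tab["p_gg"] = [
                float(st.f.sf(row.F, row.df1 * eps, row.df2 * eps))
                if np.isfinite(row.F) else np.nan
                for row in tab.itertuples()]
            res.epsilon = eps
        return res

    def _design_epsilon(self) -> float:
        cells = (self.data.groupby(["subject_id", "threat_level",
                                    "potential_loss"])["y"].mean()
                 .unstack(["threat_level", "potential_loss"]))
        cells = cells.dropna(axis=0, how="any")
        if cells.shape[0] < 2:
            return 1.0
        return gg_epsilon(cells.to_numpy())

    def _fit_statsmodels(self) -> ConditionEffectsResults:
        df = self.data
        diagnostics: list[str] = []
        singular = False
        model = smf.mixedlm(self._formula(), df, groups=df["subject_id"])
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                fit = _robust_mixedlm_fit(model)
            except RuntimeError:
                # empty design cells can leave the factorial rank-deficient;
                # refit without interactions rather than fail silently
                model = smf.mixedlm(self._formula(interactions=False), df,
                                    groups=df["subject_id"])
                fit = _robust_mixedlm_fit(model)
                singular = True
                diagnostics.append(
                    "full factorial design was rank-deficient "
                    "(empty cells); interactions dropped")
        for w in wlist:
            msg = str(w.message)
            if any(k in msg for k in ("singular", "Singular", "converge",
                                      "boundary", "Hessian")):
                singular = True
                diagnostics.append(msg)

        design_info = model.data.design_info
        params = fit.fe_params.to_numpy()
        cov = fit.cov_params().iloc[:len(params), :len(params)].to_numpy()
        n_obs = len(df)
        n_subj = df["subject_id"].nunique()
        rank = np.linalg.matrix_rank(model.exog)
        df2 = max(n_obs - rank - (n_subj - 1), 1)

        rows = []
        for term in design_info.terms:
            name = term.name()
            if name == "Intercept":
                continue
            sl = design_info.term_name_slices[name]
            idx = np.arange(sl.start, sl.stop)
            c = np.zeros((len(idx), len(params)))
            c[np.arange(len(idx)), idx] = 1.0
            f, df1, p = _wald_f(params, cov, c, df2)
            rows.append({"effect": _clean_term(name), "F": f, "df1": df1,
                         "df2": float(df2), "p": p})
        rows.extend(self._linear_contrast_rows(df2_hint=df2))
        table = pd.DataFrame(rows)
        return ConditionEffectsResults(
            table=table, epsilon=None, df_method="residual (approximate)",
            n_subjects=n_subj, n_obs=n_obs, converged=fit.converged,
            singular=singular, diagnostics=diagnostics, mixedlm_result=fit)

    def _linear_contrast_rows(self, df2_hint: float) -> list[dict]:
        """Linear x linear contrast tests from a numeric-coded refit."""
        df = self.data.copy()
        df["threat_lin"] = df["threat_level"].map(THREAT_CODES)
        df["loss_lin"] = df["potential_loss"].astype(float)
        rhs = "threat_lin * loss_lin"
        if self.spec.include_group:
            rhs = f"({rhs}) * C(group, Sum)"
        model = smf.mixedlm(f"y ~ {rhs}", df, groups=df["subject_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _robust_mixedlm_fit(model)
        params = fit.fe_params
        cov = fit.cov_params().iloc[:len(params), :len(params)]
        rows = []
        wanted = [n for n in params.index if n != "Intercept"]
        for name in wanted:
            i = list(params.index).index(name)
            c = np.zeros((1, len(params)))
            c[0, i] = 1.0
            f, df1, p = _wald_f(params.to_numpy(), cov.to_numpy(), c, df2_hint)
            rows.append({"effect": f"linear:{_clean_term(name)}", "F": f,
                         "df1": df1, "df2": float(df2_hint), "p": p,
                         "estimate": float(params.iloc[i])})
        return rows

    # -- R delegation ------------------------------------------------------

    def _fit_lmer_satterthwaite(self) -> ConditionEffectsResults:
        df = self.data.copy()
        # "L0".."L5" so R reads the loss factor as categorical, not numeric
        df["potential_loss"] = "L" + df["potential_loss"].astype(str)
        rhs = "threat_level * potential_loss"
        if self.spec.include_group:
            rhs += " * group"
        for cov in self.spec.covariates:
            rhs = f"({rhs}) * {cov}"
        with tempfile.TemporaryDirectory() as tmp:
            data_csv = Path(tmp) / "data.csv"
            out_csv = Path(tmp) / "anova.csv"
            df.to_csv(data_csv, index=False)
            script = f"""
options(contrasts = c("contr.sum", "contr.poly"))
suppressMessages(library(lmerTest))
d <- read.csv("{data_csv}", stringsAsFactors = TRUE)
m <- lmer(y ~ {rhs} + (1 | subject_id), data = d)
a <- anova(m, type = 3)
out <- data.frame(effect = rownames(a), F = a[["F value"]],
                  df1 = a[["NumDF"]], df2 = a[["DenDF"]],
                  p = a[["Pr(>F)"]])
write.csv(out, "{out_csv}", row.names = FALSE)
"""
            proc = subprocess.run(["Rscript", "-e", script],
                                  capture_output=True, text=True)
            if proc.returncode != 0 or not out_csv.exists():
                raise RuntimeError(
                    "lmerTest delegation failed:\n" + proc.stderr[-2000:])
            table = pd.read_csv(out_csv)
        table["effect"] = table["effect"].str.replace(":", " x ")
        table = pd.concat(
            [table, pd.DataFrame(self._linear_contrast_rows(
                df2_hint=float(table["df2"].min())))],
            ignore_index=True)
        return ConditionEffectsResults(
            table=table, epsilon=None, df_method="satterthwaite (lmerTest)",
            n_subjects=df["subject_id"].nunique(), n_obs=len(df),
            converged=True, singular=False)


def _robust_mixedlm_fit(model):
    """Fit a MixedLM, falling back across optimizers on failure.

    Random-intercept variances near zero can make individual optimizers
    raise on singular working matrices; trying bfgs, then lbfgs, then
    powell recovers essentially all such fits.
    """
    last = None
    for method in ("bfgs", "lbfgs", "powell", "cg"):
        try:
            return model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise RuntimeError(f"mixed-model fit failed with every optimizer: {last}")


def _wald_f(params: np.ndarray, cov: np.ndarray, c: np.ndarray,
            df2: float) -> tuple[float, float, float]:
    cb = c @ params
    middle = c @ cov @ c.T
    try:
        stat = float(cb @ np.linalg.solve(middle, cb))
    except np.linalg.LinAlgError:
        return np.nan, float(len(cb)), np.nan
    q = c.shape[0]
    f = stat / q
    p = float(st.f.sf(f, q, df2))
    return f, float(q), p


def _clean_term(name: str) -> str:
    out = (name.replace("C(threat_level, Sum)", "threat")
               .replace("C(potential_loss, Sum)", "loss")
               .replace("C(group, Sum)", "group")
               .replace("threat_lin", "threat").replace("loss_lin", "loss")
               .replace(":", " x "))
    return out


def fit_condition_lme(table: pd.DataFrame, spec: LMESpec,
                      df_method: str = "residual") -> ConditionEffectsResults:
    """Functional wrapper: build and fit a :class:`ConditionEffectsModel`."""
    return ConditionEffectsModel(table, spec).fit(df_method=df_method)
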