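"""Cohort-level statistics: densities, dichotomization, Cox, FDR, ANOVA, KM.

Survival analyses use a five-year horizon: times are administratively
censored at 60 months (events after the horizon count as censored at the
horizon). Cox models are fit by partial likelihood with Breslow tie handling
(statsmodels ``PHReg``); hazard ratios are reported with Wald 95% CIs.
Families of p-values are adjusted by Benjamini-Hochberg FDR. Kaplan-Meier
curves come from the product-limit estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

HORIZON_MONTHS = 60.0


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------

def densities(cells: pd.DataFrame, cores: pd.DataFrame,
              phenotypes: list[str] | None = None) -> pd.DataFrame:
    """Per-patient cell densities (cells/mm²) by phenotype and compartment.

    Counts per core and compartment are divided by that compartment's area
    and averaged over the patient's valid cores (duplicate cores). A core
    compartment with area <= 0 is skipped (and logged if it contains cells);
    zero cells in a valid compartment is density 0, not missing.
    """
    if phenotypes is None:
        phenotypes = sorted(cells["phenotype"].unique())
    area_cols = {"epithelium": "area_epithelium_mm2",
                 "stroma": "area_stroma_mm2"}
    counts = (cells.groupby(["core_id", "compartment", "phenotype"])
              .size().rename("count").reset_index())
    rows = []
    for _, core in cores.iterrows():
        for comp, acol in area_cols.items():
            area = core[acol]
            sub = counts[(counts["core_id"] == core["core_id"])
                         & (counts["compartment"] == comp)]
            if area <= 0:
                if sub["count"].sum() > 0:
                    log.warning("core %s %s has zero area but %d cells; skipped",
                                core["core_id"], comp, sub["count"].sum())
                continue
            got = dict(zip(sub["phenotype"], sub["count"]))
            for ph in phenotypes:
                rows.append({"patient_id": core["patient_id"],
                             "core_id": core["core_id"],
                             "phenotype": ph, "compartment": comp,
                             "density": got.get(ph, 0) / area})
    per_core = pd.DataFrame(rows)
    if not len(per_core):
        return pd.DataFrame(columns=["patient_id", "phenotype", "compartment",
                                     "density"])
    return (per_core.groupby(["patient_id", "phenotype", "compartment"],
                             as_index=False)["density"].mean())


# --------------------------------------------------------------------------
# dichotomization
# --------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Per-patient group labels from a split rule."""

    labels: pd.Series          # "low"/"high", or "Q1"/"Q4" with NaN middle
    mode: str
    split_value: float | tuple[float, float]
    degenerate: bool = False


def dichotomize(values: pd.Series, mode: str = "median") -> GroupAssignment:
    """Split patients into groups on a per-patient value.

    ``median``/``mean``: high = strictly above the cohort statistic, ties go
    low. ``quartile``: Q1 = values <= first quartile, Q4 = strictly above the
    third quartile, middle half missing. All-identical values are flagged
    degenerate with no split.
    """
    v = values.dropna()
    if len(v) < 2:
        raise ValueError("need at least 2 non-missing values to split")
    if v.nunique() == 1:
        log.warning("all values identical; degenerate split")
        return GroupAssignment(pd.Series(np.nan, index=values.index),
                               mode, float(v.iloc[0]), degenerate=True)
    if mode in ("median", "mean"):
        cut = float(v.median() if mode == "median" else v.mean())
        lab = pd.Series(np.where(values > cut, "high", "low"),
                        index=values.index, dtype=object)
        lab[values.isna()] = np.nan
        return GroupAssignment(lab, mode, cut)
    if mode == "quartile":
        q1, q3 = float(v.quantile(0.25)), float(v.quantile(0.75))
        lab = pd.Series(np.nan, index=values.index, dtype=object)
        lab[values <= q1] = "Q1"
        lab[values > q3] = "Q4"
        return GroupAssignment(lab, mode, (q1, q3))
    raise ValueError(f"unknown split mode {mode!r}")


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    """One Cox contrast."""

    variable: str
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None
    n: int
    n_events: int
    model: str = "univariate"
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in
             ("variable", "endpoint", "hr", "ci_low", "ci_high", "p",
              "p_adj", "n", "n_events", "model")}
        d["flags"] = ";".join(self.flags)
        return d


def truncate_at_horizon(time: pd.Series, event: pd.Series,
                        horizon: float = HORIZON_MONTHS):
    """Administrative censoring: events after the horizon become censored."""
    t = np.minimum(time.to_numpy(dtype=float), horizon)
    e = event.to_numpy(dtype=int) * (time.to_numpy(dtype=float) <= horizon)
    return t, e.astype(int)


def _encode(x: pd.Series) -> pd.Series:
    """Numeric coding for a covariate; binary group labels become 0/1."""
    if x.dtype == object:
        levels = sorted(x.dropna().unique())
        order = {"low": 0, "high": 1, "Q1": 0, "Q4": 1}
        if set(levels) <= set(order):
            return x.map(order)
        if len(levels) != 2:
            raise ValueError(f"cannot encode non-binary labels {levels}")
        return x.map({levels[0]: 0, levels[1]: 1})
    return pd.to_numeric(x)


def cox_univariate(covariate: pd.Series, time: pd.Series, event: pd.Series,
                   endpoint: str = "os", horizon: float = HORIZON_MONTHS,
                   variable: str | None = None) -> SurvivalResult | None:
    """Univariate Cox model at the five-year horizon.

    Returns ``None`` (logged) when no events remain after truncation.
    Monotone-likelihood (separation) fits are flagged ``ci_unreliable``.
    """
    variable = variable or (covariate.name or "x")
    df = pd.DataFrame({"x": _encode(covariate), "t": time, "e": event}).dropna()
    t, e = truncate_at_horizon(df["t"], df["e"], horizon)
    if e.sum() == 0:
        log.warning("no events after truncation for %s/%s", variable, endpoint)
        return None
    x = df["x"].to_numpy(dtype=float)[:, None]
    if np.ptp(x) == 0:
        log.warning("constant covariate %s; no contrast", variable)
        return None
    try:
        res = PHReg(t, x, status=e, ties="breslow").fit()
    except np.linalg.LinAlgError:
        log.warning("Cox fit failed for %s/%s (singular information matrix, "
                    "likely separation); skipped", variable, endpoint)
        return None
    beta = float(res.params[0])
    se = float(res.bse[0])
    flags = ()
    if not np.isfinite(se) or se > 1e3 or abs(beta) > 15:
        flags = ("ci_unreliable",)
        log.warning("possible separation for %s/%s", variable, endpoint)
    zcrit = sps.norm.ppf(0.975)
    z = beta / se if se > 0 else np.inf
    p = float(2 * sps.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    with np.errstate(over="ignore"):        # separated fits give infinite CIs
        return SurvivalResult(
            variable=variable, endpoint=endpoint, hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - zcrit * se)),
            ci_high=float(np.exp(beta + zcrit * se)),
            p=p, p_adj=None, n=len(df), n_events=int(e.sum()), flags=flags)


def cox_multivariate(variables: pd.DataFrame, time: pd.Series,
                     event: pd.Series, endpoint: str = "os",
                     horizon: float = HORIZON_MONTHS,
                     select_adj_p: float | None = 0.05
                     ) -> tuple[list[SurvivalResult], list[SurvivalResult]]:
    """Univariate screen then one joint Cox model.

    Each column of ``variables`` is screened univariately; p-values are
    BH-adjusted across the screen, and variables with adjusted p below
    ``select_adj_p`` enter the joint model (all enter when ``None``).
    Collinear columns are dropped with a warning. Returns
    ``(multivariate results, univariate results)``.
    """
    uni = []
    for col in variables.columns:
        r = cox_univariate(variables[col], time, event, endpoint, horizon,
                           variable=col)
        if r is not None:
            uni.append(r)
    if uni:
        adj = fdr_adjust([r.p for r in uni])
        for r, a in zip(uni, adj):
            r.p_adj = float(a)
    selected = ([r.variable for r in uni] if select_adj_p is None
                else [r.variable for r in uni if r.p_adj < select_adj_p])
    if not selected:
        return [], uni

    df = variables[selected].apply(_encode).copy()
    df["__t"] = time.to_numpy(dtype=float)
    df["__e"] = np.asarray(event, dtype=int)
    df = df.dropna()
    X = df[selected].to_numpy(dtype=float)
    # drop collinear columns (rank-deficient design)
    keep = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial] - X[:, trial].mean(axis=0)) == len(trial):
            keep.append(j)
        else:
            log.warning("dropping collinear covariate %r", selected[j])
    cols = [selected[j] for j in keep]
    X = X[:, keep]
    t, e = truncate_at_horizon(df["__t"], df["__e"], horizon)
    if e.sum() == 0 or not cols:
        return [], uni
    try:
        res = PHReg(t, X, status=e, ties="breslow").fit()
    except np.linalg.LinAlgError:
        log.warning("multivariate Cox fit failed (singular information "
                    "matrix, likely separation at small n); skipped")
        return [], uni
    zcrit = sps.norm.ppf(0.975)
    out = []
    for i, col in enumerate(cols):
        beta, se = float(res.params[i]), float(res.bse[i])
        z = beta / se if se > 0 else np.inf
        p = min(max(float(2 * sps.norm.sf(abs(z))), np.nextafter(0, 1)), 1.0)
        out.append(SurvivalResult(
            variable=col, endpoint=endpoint, hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - zcrit * se)),
            ci_high=float(np.exp(beta + zcrit * se)),
            p=p, p_adj=None, n=len(df), n_events=int(e.sum()),
            model="multivariate"))
    if out:
        adj = fdr_adjust([r.p for r in out])
        for r, a in zip(out, adj):
            r.p_adj = float(a)
    return out, uni


# --------------------------------------------------------------------------
# multiple testing, correlation, ANOVA, KM
# --------------------------------------------------------------------------

def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_matrix(table: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix (unit diagonal).

    Zero-variance variables have missing rows/columns.
    """
    corr = table.corr(method="pearson", min_periods=min_periods)
    std = table.std(ddof=0)
    dead = std.index[(std == 0) | std.isna()]
    corr.loc[dead, :] = np.nan
    corr.loc[:, dead] = np.nan
    np.fill_diagonal(corr.values, np.where(corr.columns.isin(dead), np.nan, 1.0))
    return corr


def anova_oneway(values: pd.Series, groups: pd.Series):
    """One-way ANOVA F and p (between/within mean-square ratio)."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    samples = [grp["v"].to_numpy(dtype=float) for _, grp in df.groupby("g")]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def anova_twoway(values: pd.Series, factor_a: pd.Series, factor_b: pd.Series
                 ) -> pd.DataFrame:
    """Two-way ANOVA (type-II sums of squares) with interaction."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"v": pd.to_numeric(values),
                       "a": factor_a.astype(str),
                       "b": factor_b.astype(str)}).dropna()
    fit = smf.ols("v ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    tab = tab.loc[tab.index != "Residual", ["F", "PR(>F)"]]
    return tab.rename(columns={"PR(>F)": "p"})


def anova_fdr(tests: list[tuple[str, pd.Series, pd.Series]]) -> pd.DataFrame:
    """Family of one-way ANOVAs with BH adjustment across the family.

    ``tests`` is a list of ``(name, values, groups)``. Contrasts with an
    empty or singleton group are missing (logged), not errors.
    """
    rows = []
    for name, values, groups in tests:
        try:
            f, p = anova_oneway(values, groups)
            rows.append({"name": name, "F": f, "p": p})
        except ValueError as exc:
            log.warning("ANOVA %r skipped: %s", name, exc)
            rows.append({"name": name, "F": np.nan, "p": np.nan})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = fdr_adjust(out.loc[ok, "p"])
    return out


def km_curve(time: pd.Series, event: pd.Series, groups: pd.Series,
             horizon: float = HORIZON_MONTHS) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group, truncated at the horizon.

    Returns one DataFrame per group with columns ``time``, ``survival``,
    ``at_risk``.
    """
    df = pd.DataFrame({"t": time, "e": event, "g": groups}).dropna()
    out = {}
    for g, grp in df.groupby("g"):
        t, e = truncate_at_horizon(grp["t"], grp["e"], horizon)
        km = KaplanMeierFitter()
        km.fit(t, e)
        surv = km.survival_function_.iloc[:, 0]
        at_risk = km.event_table["at_risk"].reindex(surv.index)
        out[str(g)] = pd.DataFrame({"time": surv.index.to_numpy(),
                                    "survival": surv.to_numpy(),
                                    "at_risk": at_risk.to_numpy()})
    return out
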