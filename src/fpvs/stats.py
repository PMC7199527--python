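"""Group-level inference on summed baseline-corrected responses.

The core model is a linear mixed-effects model of amplitude with stimulus
type (faces vs. houses) and ROI (MO, LOT, ROT) as within-subject factors,
group (TD vs. ASD) between subjects, and a random intercept per subject;
the two counterbalanced rate-mappings enter as replicates.  Post-hoc
faces−houses contrasts within each group × ROI cell are Tukey-corrected
over the family of all 12 cell means (studentized-range adjustment), which
is what reproduces emmeans-style adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

FIXED_FORMULA = "amplitude_uv ~ C(group, Sum) * C(stimulus, Sum) * C(roi, Sum)"
TERMS = ("group", "stimulus", "roi", "group:stimulus", "group:roi",
         "stimulus:roi", "group:stimulus:roi")


class ContrastError(ValueError):
    pass


@dataclass
class ModelResult:
    """Fixed-effect F table, cell means and variance components."""

    anova: pd.DataFrame          # term, F, df_num, df_den, p
    cell_means: pd.DataFrame     # group, roi, stimulus, mean, n
    sigma2: float                # residual variance
    tau2: float                  # random-intercept variance
    df_den: float
    df_method: str
    n_obs: int
    n_subjects: int
    singular: bool
    data: pd.DataFrame = field(repr=False, default=None)

    def term_p(self, term: str) -> float:
        return float(self.anova.set_index("term").loc[term, "p"])

    def term_f(self, term: str) -> float:
        return float(self.anova.set_index("term").loc[term, "F"])


def _term_of_column(name: str) -> str | None:
    """Map a patsy column name to its model term ('group:roi', ...)."""
    if name == "Intercept":
        return None
    parts = name.split(":")
    factors = []
    for p in parts:
        for f in ("group", "stimulus", "roi"):
            if f"C({f}" in p:
                factors.append(f)
    return ":".join(factors) if factors else None


def fit_lmem(tbl: pd.DataFrame, formula: str = FIXED_FORMULA,
             df_method: str = "pooled") -> ModelResult:
    """Fit the stimulus × ROI × group mixed model with random intercepts.

    F statistics are Wald tests of each term's (sum-coded) coefficients
    against the REML fixed-effect covariance; the denominator df is, by
    default, the pooled residual df
    ``n_obs − rank(X) − (n_subjects − 1)`` (equivalent to Satterthwaite
    and Kenward-Roger for within-subject terms on this balanced design),
    or plain ``n_obs − rank(X)`` with ``df_method='residual'``.
    """
    import statsmodels.formula.api as smf

    tbl = tbl.copy()
    for col in ("subject", "group", "stimulus", "roi"):
        if col not in tbl.columns:
            raise ValueError(f"response table lacks column {col!r}")
    for g in ("TD", "ASD"):
        if tbl.loc[tbl.group == g, "subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {g}")

    n_obs = len(tbl)
    n_subj = tbl["subject"].nunique()
    if float(tbl["amplitude_uv"].std()) < 1e-12:
        # degenerate: no variance at all -> every effect is exactly zero
        cells = (tbl.groupby(["group", "roi", "stimulus"], observed=True)
                 ["amplitude_uv"].agg(["mean", "count"]).reset_index()
                 .rename(columns={"count": "n"}))
        anova = pd.DataFrame([dict(term=t, F=0.0, df_num=1, df_den=np.nan,
                                   p=1.0) for t in TERMS])
        return ModelResult(anova=anova, cell_means=cells, sigma2=0.0,
                           tau2=0.0, df_den=np.nan, df_method=df_method,
                           n_obs=n_obs, n_subjects=n_subj, singular=True,
                           data=tbl)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, tbl, groups=tbl["subject"])
        res = md.fit(reml=True)

    k = md.exog.shape[1]
    beta = res.fe_params.to_numpy()
    V = np.asarray(res.cov_params())[:k, :k]
    names = list(res.fe_params.index)
    rank = np.linalg.matrix_rank(md.exog)
    if df_method == "pooled":
        df_den = n_obs - rank - (n_subj - 1)
    elif df_method == "residual":
        df_den = n_obs - rank
    else:
        raise ValueError(f"unknown df_method {df_method!r}")

    rows = []
    for term in TERMS:
        idx = [i for i, nm in enumerate(names) if _term_of_column(nm) == term]
        if not idx:
            continue
        L = np.zeros((len(idx), k))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        lb = L @ beta
        F = float(lb @ np.linalg.pinv(L @ V @ L.T) @ lb / len(idx))
        p = float(sps.f.sf(F, len(idx), df_den))
        rows.append(dict(term=term, F=F, df_num=len(idx), df_den=df_den, p=p))
    anova = pd.DataFrame(rows)

    cells = (tbl.groupby(["group", "roi", "stimulus"], observed=True)
             ["amplitude_uv"].agg(["mean", "count"]).reset_index()
             .rename(columns={"count": "n"}))
    tau2 = float(np.asarray(res.cov_re).ravel()[0])
    singular = tau2 <= 1e-10 or not res.converged
    return ModelResult(anova=anova, cell_means=cells, sigma2=float(res.scale),
                       tau2=tau2, df_den=float(df_den), df_method=df_method,
                       n_obs=n_obs, n_subjects=n_subj, singular=singular,
                       data=tbl)


@dataclass
class ContrastResult:
    label: str
    group: str
    roi: str
    estimate_uv: float  # faces − houses
    se: float
    t: float
    df: float
    p_tukey: float

    @property
    def significant(self) -> bool:
        return self.p_tukey < 0.05


def posthoc_contrasts(model: ModelResult, k_family: int | None = None
                      ) -> list[ContrastResult]:
    """faces − houses within each group × ROI cell, Tukey-adjusted.

    Under the saturated fixed structure the estimate is the difference of
    observed cell means; its SE uses the residual variance only because the
    random intercept cancels in a within-subject contrast.  The adjustment
    treats the contrasts as members of the all-pairwise family over the
    ``k_family`` (default: all 12) cell means.
    """
    cells = model.cell_means.set_index(["group", "roi", "stimulus"])
    if k_family is None:
        k_family = len(model.cell_means)
    out = []
    for group in model.cell_means["group"].unique():
        for roi in model.cell_means["roi"].unique():
            try:
                mf = cells.loc[(group, roi, "faces")]
                mh = cells.loc[(group, roi, "houses")]
            except KeyError as err:
                raise ContrastError(f"missing cell {group}/{roi}") from err
            est = float(mf["mean"] - mh["mean"])
            se = float(np.sqrt(model.sigma2 * (1.0 / mf["n"] + 1.0 / mh["n"])))
            t = est / se
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0),
                                               k_family, model.df_den))
            out.append(ContrastResult(
                label=f"faces-houses | {group} {roi}", group=group, roi=roi,
                estimate_uv=est, se=se, t=t, df=model.df_den, p_tukey=p))
    return out


def contrast_table(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contrasts])


# ---------------------------------------------------------------------------
# time course


@dataclass
class TimeCourseResult:
    lengths: tuple[float, ...]
    tables: dict            # length -> ResponseTable (OT rows)
    interaction: pd.DataFrame  # length, F, df_num, df_den, p


OT_FORMULA = "amplitude_uv ~ C(group, Sum) * C(stimulus, Sum) * C(roi, Sum)"
OT_POOLED_FORMULA = "amplitude_uv ~ C(group, Sum) * C(stimulus, Sum)"


def time_course(quantify_at_length, lengths=tuple(range(5, 65, 5)),
                pool_hemispheres: bool = False) -> TimeCourseResult:
    """Group × stimulus interaction over occipito-temporal channels as a
    function of analyzed duration.

    ``quantify_at_length(L)`` must return the response table obtained by
    re-running cropping → FFT → quantification on the first L seconds
    after fade-in (the caller owns the data; see
    ``pipeline.cohort_time_course``).  By default the model keeps LOT/ROT
    as a hemisphere factor (which is what reproduces the reported
    denominator df); ``pool_hemispheres`` averages them instead.
    """
    tables, rows = {}, []
    for L in lengths:
        tbl = quantify_at_length(L)
        ot = tbl[tbl.roi.isin(["LOT", "ROT"])].copy()
        if pool_hemispheres:
            ot = (ot.groupby(["subject", "group", "stimulus", "rate"],
                             observed=True)["amplitude_uv"]
                  .mean().reset_index())
            ot["roi"] = "OT"
            res = fit_lmem(ot, formula=OT_POOLED_FORMULA)
        else:
            res = fit_lmem(ot, formula=OT_FORMULA)
        tables[L] = ot
        row = res.anova.set_index("term").loc["group:stimulus"]
        rows.append(dict(length=L, F=float(row["F"]),
                         df_num=int(row["df_num"]),
                         df_den=float(row["df_den"]), p=float(row["p"])))
    return TimeCourseResult(lengths=tuple(lengths), tables=tables,
                            interaction=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# behavior and brain-behavior correlation


def behavior_summary(tbl: pd.DataFrame, welch: bool = True) -> pd.DataFrame:
    """Per-group accuracy/RT means and SDs with two-sided t-tests.

    Welch's unequal-variance t is the default; ``welch=False`` pools.
    Emits one row per measure with the group descriptives, t, df and p.
    """
    rows = []
    for measure in ("accuracy", "mean_rt"):
        groups = {}
        for g in ("ASD", "TD"):
            v = tbl.loc[tbl.group == g, measure].dropna().to_numpy()
            if v.size < 2:
                raise ValueError(f"need >= 2 subjects in group {g}")
            groups[g] = v
        t, p = sps.ttest_ind(groups["ASD"], groups["TD"],
                             equal_var=not welch)
        if welch:
            n1, n2 = groups["ASD"].size, groups["TD"].size
            v1, v2 = groups["ASD"].var(ddof=1), groups["TD"].var(ddof=1)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = groups["ASD"].size + groups["TD"].size - 2
        rows.append(dict(measure=measure,
                         asd_mean=groups["ASD"].mean(),
                         asd_sd=groups["ASD"].std(ddof=1),
                         td_mean=groups["TD"].mean(),
                         td_sd=groups["TD"].std(ddof=1),
                         t=float(t), df=float(df), p=float(p)))
    return pd.DataFrame(rows)


def correlate_srs(resp: pd.DataFrame, srs: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between neural measures and SRS T-scores.

    Measures per subject and ROI: faces amplitude, houses amplitude, and
    their difference (each averaged over the two rate replicates);
    computed within each group and pooled across groups.  No correction
    beyond the per-test p is applied (metadata column says so).
    """
    wide = (resp.groupby(["subject", "group", "roi", "stimulus"],
                         observed=True)["amplitude_uv"]
            .mean().unstack("stimulus").reset_index())
    wide["difference"] = wide["faces"] - wide["houses"]
    merged = wide.merge(srs[["subject", "srs_t"]], on="subject")
    rows = []
    for scope in ("TD", "ASD", "all"):
        sub = merged if scope == "all" else merged[merged.group == scope]
        for roi in sub["roi"].unique():
            at = sub[sub.roi == roi]
            for measure in ("faces", "houses", "difference"):
                x = at[measure].to_numpy()
                y = at["srs_t"].to_numpy()
                if np.unique(x).size < 2 or np.unique(y).size < 2:
                    raise ValueError("constant input: Spearman undefined")
                rho, p = sps.spearmanr(x, y)
                rows.append(dict(scope=scope, roi=roi, measure=measure,
                                 rho=float(rho), p=float(p), n=len(at),
                                 multiple_testing="none"))
    return pd.DataFrame(rows)
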