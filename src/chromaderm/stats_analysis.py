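"""Repeated-measures linear mixed models, LS-means, and pairwise contrasts.

The longitudinal responses (color proportions, chromatic and achromatic
contrast) are analyzed with a linear mixed model: fixed factors such as
treatment, time, and their interaction; a random intercept per individual
for the repeated measures. Fitting is REML via statsmodels MixedLM.

Outputs per fit: an F-table for the fixed terms (Wald statistics divided
by their numerator df, referred to an F distribution), least-squares means
per treatment-by-time cell with standard errors, and all pairwise
time-within-treatment contrasts with Bonferroni adjustment (raw p-values
reported alongside).

Denominator degrees of freedom use a containment-style rule,
df = n_obs - rank(X) - (n_groups - 1), which reproduces the df of classic
mixed-model ANOVA on balanced longitudinal designs. The convention is
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "fit_lmm",
    "lsmeans_table",
    "change_in_achromatic_contrast",
]


@dataclass
class ModelResult:
    """Fixed-effect F-table, LS-means, and pairwise contrasts of one fit."""

    anova: pd.DataFrame          # term, F, df_num, df_den, p
    lsmeans: pd.DataFrame        # one row per factor cell: estimate, se
    contrasts: pd.DataFrame      # pair, estimate, se, t, df, p_raw, p_adjusted
    converged: bool
    df_method: str = "containment"
    variance_components: dict = field(default_factory=dict)
    log_response: bool = False
    formula: str = ""


def _term_formula(fixed: list[str]) -> str:
    parts = []
    for term in fixed:
        if ":" in term:
            parts.append(":".join(f"C({f.strip()})" for f in term.split(":")))
        else:
            parts.append(f"C({term})")
    return " + ".join(parts)


def _cells(table: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Reference grid: the cross of observed factor levels, in sorted order."""
    levels = [np.sort(table[f].unique()) for f in factors]
    grid = pd.MultiIndex.from_product(levels, names=factors).to_frame(index=False)
    return grid


def fit_lmm(table: pd.DataFrame, response: str = "response",
            fixed: list[str] | None = None, random_intercept: str = "id",
            adjust: str = "bonferroni", log_response: bool = False,
            contrast_within: str | None = "treatment",
            contrast_over: str | None = "time") -> ModelResult:
    """Fit a random-intercept linear mixed model and summarize it.

    Parameters
    ----------
    table : tidy DataFrame with one row per observation.
    fixed : fixed-effect terms, ``":"`` marking interactions
        (default ``["treatment", "time", "treatment:time"]``).
    random_intercept : grouping column for the per-individual intercept.
    log_response : natural-log the response before fitting (used for
        achromatic contrast); LS-means are then on the log scale.
    contrast_within / contrast_over : pairwise contrasts compare levels of
        ``contrast_over`` within each level of ``contrast_within``.

    Degenerate noiseless data (zero residual variance) are detected and
    fitted by ordinary least squares, where the mixed model is singular
    but its fixed-effect solution (the cell means, for a saturated
    balanced design) is still well defined.
    """
    if fixed is None:
        fixed = ["treatment", "time", "treatment:time"]
    data = table.copy()
    for col in (response, random_intercept):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from table")
    factors = sorted({f.strip() for term in fixed for f in term.split(":")})
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} needs >= 2 levels")
    counts = data.groupby(random_intercept, observed=True).size()
    if (counts < 2).any():
        raise ValueError("every individual needs >= 2 observations")

    yname = "_y"
    if log_response:
        if (data[response] <= 0).any():
            raise ValueError("log transform requires strictly positive responses")
        data[yname] = np.log(data[response].astype(float))
    else:
        data[yname] = data[response].astype(float)

    rhs = _term_formula(fixed)
    formula = f"{yname} ~ {rhs}"
    n_groups = data[random_intercept].nunique()

    ols_res = smf.ols(formula, data=data).fit()
    rank_x = int(np.linalg.matrix_rank(ols_res.model.exog))
    if rank_x < ols_res.model.exog.shape[1]:
        raise ValueError("singular fixed-effect design: some factor cells are "
                         "empty or aliased")
    df_den = len(data) - rank_x - (n_groups - 1)
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom under the containment rule")

    degenerate = ols_res.ssr < max(1e-10 * max(ols_res.centered_tss, 1.0), 1e-300)
    converged = True
    if degenerate:
        res = ols_res
        vc = {"id_var": 0.0, "residual_var": 0.0}
    else:
        model = smf.mixedlm(formula, data=data, groups=data[random_intercept])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        converged = bool(getattr(res, "converged", True))
        if not converged:
            warnings.warn("mixed-model variance components did not converge; "
                          "results flagged", stacklevel=2)
        vc = {"id_var": float(res.cov_re.iloc[0, 0]),
              "residual_var": float(res.scale)}

    # --- F-table from Wald statistics per fixed term
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test_terms(scalar=True)
    for term, stat_row in wt.table.iterrows():
        if term == "Intercept":
            continue
        q = int(stat_row["df_constraint"])
        chi2 = float(stat_row["statistic"])
        if degenerate:
            # OLS wald_test_terms reports F directly
            fstat = chi2
        else:
            fstat = chi2 / q
        pval = float(sps.f.sf(fstat, q, df_den))
        clean = term.replace("C(", "").replace(")", "")
        rows.append({"term": clean, "F": fstat, "df_num": q,
                     "df_den": df_den, "p": pval})
    anova = pd.DataFrame(rows)

    # --- LS-means over the cross of all fixed factors
    grid = _cells(data, factors)
    design_info = ols_res.model.data.design_info
    (lmat,) = patsy.build_design_matrices([design_info], grid)
    lmat = np.asarray(lmat)
    params = np.asarray(res.params)[:lmat.shape[1]]
    cov = np.asarray(res.cov_params())[:lmat.shape[1], :lmat.shape[1]]
    est = lmat @ params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", lmat, cov, lmat), 0.0))
    if degenerate:
        se = np.zeros_like(se)
    lsmeans = grid.copy()
    lsmeans["estimate"] = est
    lsmeans["se"] = se

    # --- pairwise contrasts of `contrast_over` within `contrast_within`
    contrasts = pd.DataFrame(
        columns=["within", "pair", "estimate", "se", "t", "df",
                 "p_raw", "p_adjusted"])
    if (contrast_within in factors and contrast_over in factors
            and contrast_within != contrast_over):
        crows = []
        for wlev in np.sort(data[contrast_within].unique()):
            sub = lsmeans[lsmeans[contrast_within] == wlev]
            levs = list(sub[contrast_over])
            for i in range(len(levs)):
                for j in range(i + 1, len(levs)):
                    ri = grid.index[(grid[contrast_within] == wlev)
                                    & (grid[contrast_over] == levs[i])][0]
                    rj = grid.index[(grid[contrast_within] == wlev)
                                    & (grid[contrast_over] == levs[j])][0]
                    lvec = lmat[ri] - lmat[rj]
                    diff = float(lvec @ params)
                    var = float(lvec @ cov @ lvec)
                    cse = float(np.sqrt(max(var, 0.0)))
                    if degenerate or cse == 0.0:
                        tstat = np.inf if diff != 0 else 0.0
                        p_raw = 0.0 if diff != 0 else 1.0
                    else:
                        tstat = diff / cse
                        p_raw = float(2 * sps.t.sf(abs(tstat), df_den))
                    crows.append({
                        "within": wlev,
                        "pair": f"{levs[i]} - {levs[j]}",
                        "estimate": diff, "se": cse, "t": tstat,
                        "df": df_den, "p_raw": p_raw,
                    })
        contrasts = pd.DataFrame(crows)
        m = len(contrasts)
        if adjust == "bonferroni":
            contrasts["p_adjusted"] = np.minimum(contrasts["p_raw"] * m, 1.0)
        elif adjust in (None, "none"):
            contrasts["p_adjusted"] = contrasts["p_raw"]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")

    return ModelResult(anova=anova, lsmeans=lsmeans, contrasts=contrasts,
                       converged=converged, variance_components=vc,
                       log_response=log_response, formula=formula)


def lsmeans_table(result: ModelResult) -> pd.DataFrame:
    """Tidy LS-means: one row per factor cell with estimate and SE.

    When the model was fitted on the log scale, back-transformed
    (geometric-scale) estimates are appended as ``estimate_geometric``.
    """
    out = result.lsmeans.copy()
    if result.log_response:
        out["estimate_geometric"] = np.exp(out["estimate"])
    return out


def change_in_achromatic_contrast(lsmeans: pd.DataFrame, group: str,
                                  from_time: str = "pre",
                                  to_time: str = "week4",
                                  group_col: str = "treatment",
                                  time_col: str = "time") -> tuple[float, int]:
    """LS-mean(from) - LS-mean(to) for one treatment group, plus nearest-integer JND.

    This is the headline summary of a treatment-induced change: how many
    just-noticeable differences the group moved between two timepoints.
    """
    def _cell(t):
        sel = lsmeans[(lsmeans[group_col] == group) & (lsmeans[time_col] == t)]
        if len(sel) != 1:
            raise ValueError(f"cell ({group}, {t}) missing or duplicated")
        return float(sel["estimate"].iloc[0])

    change = _cell(from_time) - _cell(to_time)
    return change, int(round(change))
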