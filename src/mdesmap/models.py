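"""Statistical scaffolding: mixed models, bin-wise ANOVAs, comprehension model, FDR.

Random-intercept linear mixed models (participant as the grouping factor)
relate thought-pattern scores to movies and to gradient coordinates; ordinary
regressions on the sampling-bin index describe within-movie temporal trends;
the comprehension model crosses movies with thought patterns and follows
significant interactions with simple slopes.  Families of tests are corrected
with Benjamini-Hochberg FDR; pairwise least-squares-means contrasts use the
Tukey (studentized range) adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import dmatrix
from scipy.stats import studentized_range, t as t_dist
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelResult",
    "fdr_bh",
    "partial_eta_sq",
    "lmm_thought_by_movie",
    "anova_across_bins",
    "lmm_comprehension",
    "lmm_gradient_thought",
]


@dataclass
class ModelResult:
    """Fixed-effect terms, least-squares means and pairwise contrasts of one model."""

    formula_text: str
    terms: dict = field(default_factory=dict)
    lsmeans: dict = field(default_factory=dict)
    pairwise: list = field(default_factory=list)
    random_intercept: bool = True
    notes: list = field(default_factory=list)
    simple_slopes: dict = field(default_factory=dict)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (reject flags, adjusted p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def partial_eta_sq(f_stat: float, df1: float, df2: float) -> float:
    """Partial eta-squared recovered from an F statistic and its dfs."""
    if not np.isfinite(f_stat):
        return 1.0
    return float(f_stat * df1 / (f_stat * df1 + df2))


def _fit_random_intercept(formula: str, data: pd.DataFrame, groups: str):
    """MixedLM with participant random intercept; singular fits fall back to OLS."""
    notes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = smf.mixedlm(formula, data, groups=data[groups]).fit(reml=True)
            singular = (not np.isfinite(res.cov_re.to_numpy()).all()) or np.any(
                np.diag(res.cov_re) < 0
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"mixed model failed ({exc}); fixed-intercept fallback")
            singular = True
            res = None
    if res is None or singular:
        if res is not None:
            notes.append("singular random-effects fit; fixed-intercept fallback")
        res = smf.ols(formula, data).fit()
        return res, False, notes
    return res, True, notes


def _fixed_params(res, mixed: bool):
    """Fixed-effect names/estimates/cov, excluding the variance component row."""
    params = res.params
    if mixed:
        k = res.model.k_fe
        names = list(res.model.exog_names)[:k]
        beta = params.to_numpy()[:k]
        cov = np.asarray(res.cov_params())[:k, :k]
    else:
        names = list(params.index)
        beta = params.to_numpy()
        cov = np.asarray(res.cov_params())
    return names, beta, cov


def _resid_df(res, mixed: bool, data: pd.DataFrame, groups: str | None) -> float:
    n = len(data)
    k = res.model.k_fe if mixed else len(res.params)
    if mixed and groups is not None:
        return max(n - k - data[groups].nunique() + 1, 1)
    return max(n - k, 1)


def _wald_f(res, names, beta, cov, df2, which: list[str]):
    """Joint Wald F for a subset of fixed-effect coefficients."""
    idx = [names.index(w) for w in which]
    b = beta[idx]
    V = cov[np.ix_(idx, idx)]
    df1 = len(idx)
    F = float(b @ np.linalg.solve(V, b) / df1)
    from scipy.stats import f as f_dist

    p = float(f_dist.sf(F, df1, df2))
    return F, df1, p


def _lsmeans_and_tukey(res, mixed, data, cat_col, df2, covariate_means=None):
    """Model-adjusted means per level of ``cat_col`` and Tukey-corrected pairwise contrasts."""
    names, beta, cov = _fixed_params(res, mixed)
    design_info = res.model.data.design_info
    levels = sorted(data[cat_col].unique())
    rows = {}
    base = {c: data[c].mean() for c in data.columns
            if np.issubdtype(data[c].dtype, np.number)}
    if covariate_means:
        base.update(covariate_means)
    for lev in levels:
        newdata = pd.DataFrame([{**base, cat_col: lev}])
        rows[lev] = np.asarray(dmatrix(design_info, newdata))[0]
    lsmeans = {}
    for lev, row in rows.items():
        m = float(row @ beta)
        se = float(np.sqrt(row @ cov @ row))
        lsmeans[lev] = {"M": m, "SE": se}
    pairwise = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            c = rows[levels[i]] - rows[levels[j]]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t_val = est / se
            p_tuk = float(studentized_range.sf(abs(t_val) * np.sqrt(2), k, df2))
            pairwise.append(
                {"a": levels[i], "b": levels[j], "estimate": est, "t": t_val,
                 "df": df2, "p_adjusted": min(1.0, p_tuk), "method": "tukey"}
            )
    return lsmeans, pairwise


def lmm_thought_by_movie(
    scores: pd.DataFrame,
    components: list[str],
    movie_col: str = "movie_id",
    participant_col: str = "participant_id",
    q_fdr: float = 0.05,
) -> dict[str, ModelResult]:
    """Per component: random-intercept model of score on movie, omnibus F,
    Tukey pairwise lsmeans contrasts, and FDR of the omnibus p across components."""
    movies = scores[movie_col].unique()
    if len(movies) < 2 or scores[participant_col].nunique() < 2:
        raise ValueError("need >= 2 movies and >= 2 participants")
    results: dict[str, ModelResult] = {}
    omnibus_p = []
    for comp in components:
        df = scores[[participant_col, movie_col, comp]].rename(columns={comp: "score"})
        formula = f"score ~ C({movie_col})"
        res, mixed, notes = _fit_random_intercept(formula, df, participant_col)
        names, beta, cov = _fixed_params(res, mixed)
        movie_terms = [n for n in names if n.startswith(f"C({movie_col})")]
        df2 = _resid_df(res, mixed, df, participant_col)
        F, df1, p = _wald_f(res, names, beta, cov, df2, movie_terms)
        lsm, pw = _lsmeans_and_tukey(res, mixed, df, movie_col, df2)
        mr = ModelResult(formula_text=formula, random_intercept=mixed, notes=notes)
        mr.terms[movie_col] = {
            "estimate": None, "SE": None, "df": (df1, df2), "statistic": F,
            "p": p, "eta_sq": partial_eta_sq(F, df1, df2),
        }
        mr.lsmeans = lsm
        mr.pairwise = pw
        results[comp] = mr
        omnibus_p.append(p)
    reject, p_adj = fdr_bh(omnibus_p, q=q_fdr)
    for comp, rej, pa in zip(components, reject, p_adj):
        results[comp].terms[movie_col]["p_fdr"] = float(pa)
        results[comp].terms[movie_col]["significant_fdr"] = bool(rej)
    return results


def anova_across_bins(
    scores: pd.DataFrame,
    component: str,
    bin_col: str = "bin_index",
    movie: str | None = None,
    movie_col: str = "movie_id",
) -> ModelResult:
    """Single-df regression of a component score on the (numeric) sampling-bin index."""
    df = scores if movie is None else scores[scores[movie_col] == movie]
    if df[bin_col].nunique() < 2:
        raise ValueError("need more than one sampling bin")
    y = df[component].to_numpy(dtype=float)
    x = df[bin_col].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_reg = float(((fitted - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    df1, df2 = 1, n - 2
    ms_reg = ss_reg / df1
    ms_res = ss_res / df2
    if ms_res <= 1e-12 * max(ms_reg, 1.0):  # exact fit up to float round-off
        F, p = np.inf, 0.0
    else:
        from scipy.stats import f as f_dist

        F = ms_reg / ms_res
        p = float(f_dist.sf(F, df1, df2))
    mr = ModelResult(formula_text=f"{component} ~ {bin_col}", random_intercept=False)
    mr.terms[bin_col] = {
        "estimate": float(coef[1]), "Df": df1, "SumSq": ss_reg, "MeanSq": ms_reg,
        "statistic": F, "p": p, "eta_sq": partial_eta_sq(F, df1, df2),
    }
    mr.terms["Residuals"] = {"Df": df2, "SumSq": ss_res, "MeanSq": ms_res}
    return mr


def lmm_comprehension(
    comprehension: pd.DataFrame,
    pattern_means: pd.DataFrame,
    components: list[str],
    movie_col: str = "movie_id",
    participant_col: str = "participant_id",
    score_col: str = "score",
    q_fdr: float = 0.05,
) -> ModelResult:
    """Comprehension ~ movie * (four thought patterns) with participant random intercept.

    The FDR family comprises the nine fixed-effect terms (movie, four pattern
    main effects, four movie x pattern interactions); significant interactions
    are followed by per-movie simple slopes, themselves FDR-corrected.
    """
    data = comprehension.merge(pattern_means, on=[participant_col, movie_col],
                               how="inner", validate="one_to_one")
    missing = set(zip(comprehension[participant_col], comprehension[movie_col])) - set(
        zip(data[participant_col], data[movie_col])
    )
    if missing:
        raise ValueError(f"missing pattern scores for keys: {sorted(missing)[:5]}")
    rhs = " + ".join(components)
    # sum-coded movie factor: pattern main effects are average slopes across
    # movies, interactions are per-movie deviations
    mterm = f"C({movie_col}, Sum)"
    formula = f"{score_col} ~ {mterm} * ({rhs})"
    res, mixed, notes = _fit_random_intercept(formula, data, participant_col)
    names, beta, cov = _fixed_params(res, mixed)
    df2 = _resid_df(res, mixed, data, participant_col)

    families: dict[str, list[str]] = {movie_col: [n for n in names
                                                  if n.startswith(mterm) and ":" not in n]}
    for comp in components:
        families[comp] = [comp]
        families[f"{movie_col}:{comp}"] = [n for n in names if ":" in n and n.endswith(f":{comp}")]

    mr = ModelResult(formula_text=formula, random_intercept=mixed, notes=notes)
    fam_names, fam_p = [], []
    for fam, terms in families.items():
        F, df1, p = _wald_f(res, names, beta, cov, df2, terms)
        entry = {"df": (df1, df2), "statistic": F, "p": p,
                 "eta_sq": partial_eta_sq(F, df1, df2)}
        if len(terms) == 1:
            i = names.index(terms[0])
            entry["estimate"] = float(beta[i])
            entry["SE"] = float(np.sqrt(cov[i, i]))
        mr.terms[fam] = entry
        fam_names.append(fam)
        fam_p.append(p)
    reject, p_adj = fdr_bh(fam_p, q=q_fdr)
    for fam, rej, pa in zip(fam_names, reject, p_adj):
        mr.terms[fam]["p_fdr"] = float(pa)
        mr.terms[fam]["significant_fdr"] = bool(rej)

    mr.lsmeans, mr.pairwise = _lsmeans_and_tukey(res, mixed, data, movie_col, df2)

    # simple slopes per movie for FDR-significant interactions; under sum
    # coding the omitted level's interaction coefficient is minus the sum of
    # the displayed ones
    movies = sorted(data[movie_col].unique())
    mr.simple_slopes = {}
    for comp in components:
        fam = f"{movie_col}:{comp}"
        if not mr.terms[fam]["significant_fdr"]:
            continue
        inter_terms = families[fam]
        level_of = {n: n.split("[S.", 1)[1].split("]", 1)[0] for n in inter_terms}
        slopes = {}
        raw_p = []
        for m in movies:
            c = np.zeros(len(beta))
            c[names.index(comp)] = 1.0
            shown = [n for n, lev in level_of.items() if lev == str(m)]
            if shown:
                c[names.index(shown[0])] = 1.0
            else:  # omitted level
                for n in inter_terms:
                    c[names.index(n)] = -1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t_val = est / se
            p = float(2 * t_dist.sf(abs(t_val), df2))
            slopes[m] = {"b": est, "SE": se, "t": t_val, "p": p}
            raw_p.append(p)
        rej, pa = fdr_bh(raw_p, q=q_fdr)
        for m, r_, pa_ in zip(movies, rej, pa):
            slopes[m]["p_fdr"] = float(pa_)
            slopes[m]["significant_fdr"] = bool(r_)
        mr.simple_slopes[comp] = slopes
    return mr


def lmm_gradient_thought(
    probe_data: pd.DataFrame,
    components: list[str],
    gradient_cols: list[str] = ("g1", "g2", "g3", "g4", "g5"),
    participant_col: str = "participant_id",
    q_fdr: float = 0.05,
) -> dict[str, ModelResult]:
    """Per component: mixed model of score on the five gradient coordinates,
    participant random intercept, FDR across the five gradient terms."""
    gradient_cols = list(gradient_cols)
    G = probe_data[gradient_cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(G)), G])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("gradient predictors are rank deficient")
    results: dict[str, ModelResult] = {}
    for comp in components:
        cols = [participant_col, comp] + gradient_cols
        df = probe_data[cols].rename(columns={comp: "score"})
        formula = "score ~ " + " + ".join(gradient_cols)
        res, mixed, notes = _fit_random_intercept(formula, df, participant_col)
        names, beta, cov = _fixed_params(res, mixed)
        df2 = _resid_df(res, mixed, df, participant_col)
        mr = ModelResult(formula_text=formula, random_intercept=mixed, notes=notes)
        raw_p = []
        for g in gradient_cols:
            i = names.index(g)
            est = float(beta[i])
            se = float(np.sqrt(cov[i, i]))
            t_val = est / se
            p = float(2 * t_dist.sf(abs(t_val), df2))
            F = t_val**2
            mr.terms[g] = {
                "estimate": est, "SE": se, "df": df2, "statistic": t_val,
                "p": p, "eta_sq": partial_eta_sq(F, 1, df2),
            }
            raw_p.append(p)
        reject, p_adj = fdr_bh(raw_p, q=q_fdr)
        for g, rej, pa in zip(gradient_cols, reject, p_adj):
            mr.terms[g]["p_fdr"] = float(pa)
            mr.terms[g]["significant_fdr"] = bool(rej)
        results[comp] = mr
    return results
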