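"""The statistical layer on top of the pair metrics.

Mirrors the study design: five-level pair-category OLS regressions of %REC
and %DET; linear mixed models (random intercept per pair, REML) contrasting
true against surrogate data; node-distance regressions on the proximity
network; a one-sample t-test on imam lead lags; a Mann-Whitney comparison of
nearest-neighbour spacing between the two spaces; and questionnaire
summaries. Mixed-model p-values use the normal approximation on the z
statistic; a non-converging mixed model falls back to OLS with
cluster-robust standard errors and is flagged as such in the returned table.

Model tables are tidy DataFrames with columns
``term, estimate, std_error, p_value, stars, model_id``. Pairs with an
undefined %DET (no recurrent points) are dropped listwise per model and the
drop count logged. No multiple-testing correction is applied by default
(per-model stars only); :func:`holm_adjust` is available for callers who
want one.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf

from .network import REFERENCE_CATEGORY

logger = logging.getLogger(__name__)

def _category_term(data: pd.DataFrame) -> str:
    """Treatment coding with separated pairs as reference; if listwise drops
    removed every separated row, fall back to the first category present."""
    present = set(data["category"])
    ref = REFERENCE_CATEGORY
    if ref not in present:
        ref = sorted(present)[0]
        logger.warning(
            "reference category %r absent after drops; using %r instead",
            REFERENCE_CATEGORY, ref,
        )
    return f"C(category, Treatment(reference='{ref}'))"


@dataclass
class LagTestResult:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    degenerate: bool = False


@dataclass
class QuestionnaireSummary:
    question: str
    n_yes: int
    n_total: int
    pct_yes: float


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _clean_term(term: str) -> str:
    term = re.sub(r"C\(category, Treatment\(reference='[^']*'\)\)\[T\.([^\]]+)\]", r"\1", term)
    term = term.replace("Intercept", "(intercept)")
    return term.replace(":", " x ")


def _tidy(params, bse, pvalues, model_id: str, note: str = "") -> pd.DataFrame:
    rows = []
    for term in params.index:
        p = float(pvalues[term])
        rows.append(
            {
                "term": _clean_term(term),
                "estimate": float(params[term]),
                "std_error": float(bse[term]),
                "p_value": p,
                "stars": significance_stars(p),
                "model_id": model_id,
            }
        )
    table = pd.DataFrame(rows)
    if note:
        table.attrs["note"] = note
    return table


def _outcome_column(outcome: str) -> str:
    col = {"rec": "rec_pct", "det": "det_pct"}.get(outcome, outcome)
    if col not in ("rec_pct", "det_pct"):
        raise ValueError(f"unknown outcome {outcome!r} (use 'rec' or 'det')")
    return col


def _prepare(df: pd.DataFrame, outcome: str, signal: str, types=("true",)) -> pd.DataFrame:
    col = _outcome_column(outcome)
    data = df[(df["signal"] == signal) & (df["type"].isin(types))].copy()
    n_undef = int(data[col].isna().sum())
    if n_undef:
        logger.info("dropping %d rows with undefined %s (%s/%s)", n_undef, col, outcome, signal)
        data = data.dropna(subset=[col])
    data = data.rename(columns={col: "y"})
    return data


def fit_category_model(pair_metrics: pd.DataFrame, outcome: str, signal: str) -> pd.DataFrame:
    """Five-level pair-category OLS on true-data metrics (separated = reference)."""
    data = _prepare(pair_metrics, outcome, signal)
    present = data["category"].unique()
    if len(present) < 2:
        raise ValueError("need at least two pair categories to fit the model")
    if len(present) < 5:
        logger.warning("only %d of 5 categories present; absent ones dropped", len(present))
    model = smf.ols(f"y ~ {_category_term(data)}", data=data).fit()
    return _tidy(model.params, model.bse, model.pvalues, f"category:{signal}:{outcome}")


def fit_surrogate_contrast_model(
    pair_metrics: pd.DataFrame, outcome: str, signal: str
) -> pd.DataFrame:
    """Mixed model of true-vs-surrogate metrics: category * type, pair random intercept.

    ``is_true`` codes data type with surrogate as the reference level, so the
    ``type`` row is the chance-level-to-true shift for the reference category.
    """
    data = _prepare(pair_metrics, outcome, signal, types=("true", "surrogate"))
    data["is_true"] = (data["type"] == "true").astype(float)
    formula = f"y ~ {_category_term(data)} * is_true"
    model_id = f"surrogate_contrast:{signal}:{outcome}"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=data, groups=data["pair_id"]).fit(reml=True)
        if not fit.converged:
            raise RuntimeError("mixed model did not converge")
        fe = fit.fe_params
        table = _tidy(fe, fit.bse.loc[fe.index], fit.pvalues.loc[fe.index], model_id)
        table["term"] = table["term"].str.replace("is_true", "type", regex=False)
        return table
    except Exception as exc:  # non-convergence or singular fit
        logger.warning("%s: mixed model failed (%s); falling back to cluster-robust OLS", model_id, exc)
        ols = smf.ols(formula, data=data).fit(
            cov_type="cluster", cov_kwds={"groups": data["pair_id"]}
        )
        table = _tidy(ols.params, ols.bse, ols.pvalues, model_id, note="ols_cluster_fallback")
        table["term"] = table["term"].str.replace("is_true", "type", regex=False)
        table["model_id"] = model_id + ":ols_fallback"
        return table


def fit_network_model(
    pair_metrics: pd.DataFrame, outcome: str, signal: str, with_random_pair: bool = False
) -> pd.DataFrame:
    """Node-distance regression: outcome ~ nodes, finite path lengths only.

    With ``with_random_pair`` the model includes the true-vs-surrogate type
    and its interaction with node distance under a pair random intercept.
    """
    types = ("true", "surrogate") if with_random_pair else ("true",)
    data = _prepare(pair_metrics, outcome, signal, types=types)
    data = data[np.isfinite(data["node_distance"])].copy()
    data = data.rename(columns={"node_distance": "nodes"})
    if data["nodes"].nunique() < 2:
        raise ValueError("node distances take a single value; slope inestimable")
    if not with_random_pair:
        model = smf.ols("y ~ nodes", data=data).fit()
        return _tidy(model.params, model.bse, model.pvalues, f"network:{signal}:{outcome}")
    data["is_true"] = (data["type"] == "true").astype(float)
    model_id = f"network_mixed:{signal}:{outcome}"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("y ~ nodes * is_true", data=data, groups=data["pair_id"]).fit(reml=True)
        if not fit.converged:
            raise RuntimeError("mixed model did not converge")
        fe = fit.fe_params
        table = _tidy(fe, fit.bse.loc[fe.index], fit.pvalues.loc[fe.index], model_id)
    except Exception as exc:
        logger.warning("%s: mixed model failed (%s); falling back to cluster-robust OLS", model_id, exc)
        ols = smf.ols("y ~ nodes * is_true", data=data).fit(
            cov_type="cluster", cov_kwds={"groups": data["pair_id"]}
        )
        table = _tidy(ols.params, ols.bse, ols.pvalues, model_id + ":ols_fallback")
    table["term"] = table["term"].str.replace("is_true", "type", regex=False)
    return table


def lag_t_test(peak_lags) -> LagTestResult:
    """One-sample t-test of per-pair DCRP peak lags against zero."""
    lags = np.asarray(list(peak_lags), dtype=float)
    if lags.size < 2:
        raise ValueError("need at least two lags for a t-test")
    mean = float(lags.mean())
    sd = float(lags.std(ddof=1))
    if sd == 0:
        return LagTestResult(t=np.nan, df=lags.size - 1, p=np.nan, mean=mean, sd=0.0, degenerate=True)
    t, p = sps.ttest_1samp(lags, 0.0)
    return LagTestResult(t=float(t), df=lags.size - 1, p=float(p), mean=mean, sd=sd)


def spacing_comparison(nn_distances_a, nn_distances_b) -> tuple:
    """Two-sided Mann-Whitney U (midrank ties) on nearest-neighbour spacings."""
    a = np.asarray(list(nn_distances_a), dtype=float)
    b = np.asarray(list(nn_distances_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both spacing samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def summarize_questionnaire(responses: pd.DataFrame) -> list:
    """Per-question yes-counts and percentages from a binary response table.

    ``responses``: rows = participants, columns = questions, values yes/no
    (also accepts True/False or 1/0). Percentages are rounded to one decimal.
    """
    yes = {"yes", "y", "true", "1", "1.0"}
    no = {"no", "n", "false", "0", "0.0"}
    out = []
    for question in responses.columns:
        col = responses[question]
        if col.isna().any():
            raise ValueError(f"question {question!r} has missing responses")
        coded = []
        for v in col:
            s = str(v).strip().lower()
            if s in yes:
                coded.append(1)
            elif s in no:
                coded.append(0)
            else:
                raise ValueError(f"non-binary response {v!r} for question {question!r}")
        n_yes, n_total = int(sum(coded)), len(coded)
        out.append(
            QuestionnaireSummary(
                question=str(question),
                n_yes=n_yes,
                n_total=n_total,
                pct_yes=round(100.0 * n_yes / n_total, 1),
            )
        )
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default everywhere)."""
    p = np.asarray(list(p_values), dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
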