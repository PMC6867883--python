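"""Statistical layer: Fisher-z correlation inference, power arithmetic,
domain x anxiety interaction regression, binomial regression of choice
counts, and test-retest reliability.

The interaction model approximates a mixed model with categorical random
intercepts by a fixed-stratum normal maximum-likelihood regression: with
categorical strata as the only grouping, fixed intercepts reproduce the
mean structure that the coefficients test.  Independent variables are not
transformed, all p-values are two-sided, and no multiplicity correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidArgumentError,
    RankDeficiencyError,
    SeparationError,
    UndefinedMeasureError,
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass
class RegressionResult:
    table: pd.DataFrame  # columns: name, beta, ci_low, ci_high, se, t, p
    df: int
    adjusted_r2: float

    def coef(self, name: str) -> pd.Series:
        hit = self.table[self.table["name"] == name]
        if len(hit) != 1:
            raise KeyError(f"coefficient {name!r} not found; have {list(self.table['name'])}")
        return hit.iloc[0]


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)); two-sided p from
    the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise InvalidArgumentError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMeasureError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    z_crit = stats.norm.ppf(1 - alpha / 2)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = z_crit / np.sqrt(n - 3)
    ci_low, ci_high = float(np.tanh(zr - half)), float(np.tanh(zr + half))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, ci_low=ci_low, ci_high=ci_high, p=p)


def fisher_null_halfwidth(n: int, alpha: float = 0.05) -> float:
    """Half-width (on the r scale) of the null sampling band at size n."""
    return float(np.tanh(stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)))


def sample_size_for_r(rho: float, power: float, alpha: float = 0.05) -> int:
    """Sample size to detect a correlation rho at given power (two-sided alpha).

    n = round(((z_{1-alpha/2} + z_power) / atanh(rho))^2 + 3), floored at 4.
    """
    if not 0 < abs(rho) < 1:
        raise InvalidArgumentError("rho must satisfy 0 < |rho| < 1")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise InvalidArgumentError("power and alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = round(((z_a + z_b) / np.arctanh(rho)) ** 2 + 3)
    return max(int(n), 4)


def _check_rank(exog: pd.DataFrame) -> None:
    X = np.asarray(exog, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # identify offending columns by greedy QR-style scan
    bad, kept = [], []
    for j, name in enumerate(exog.columns):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(name)
    raise RankDeficiencyError(bad)


def _ols_result(model_fit, n: int, alpha: float = 0.05) -> RegressionResult:
    ci = model_fit.conf_int(alpha)
    table = pd.DataFrame(
        {
            "name": model_fit.params.index,
            "beta": model_fit.params.values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
            "se": model_fit.bse.values,
            "t": model_fit.tvalues.values,
            "p": model_fit.pvalues.values,
        }
    ).reset_index(drop=True)
    return RegressionResult(table=table, df=int(model_fit.df_resid), adjusted_r2=float(model_fit.rsquared_adj))


def interaction_model(
    long_table: pd.DataFrame,
    covariates: tuple = (),
    strata: tuple = (),
    alpha: float = 0.05,
) -> RegressionResult:
    """Fit HCP ~ domain * math_anxiety (+ covariates + stratum intercepts).

    ``long_table`` holds two rows per participant (one per domain) with
    columns ``participant_id``, ``domain`` ('math'/'word'), ``hcp``,
    ``math_anxiety``, plus any covariate/stratum columns.  Math is the
    reference domain, so the anxiety main effect is the math-domain slope
    and the interaction is the word-minus-math slope difference.
    """
    import statsmodels.formula.api as smf

    required = {"participant_id", "domain", "hcp", "math_anxiety"}
    missing = required - set(long_table.columns)
    if missing:
        raise InvalidArgumentError(f"long table missing columns {sorted(missing)}")
    df = long_table.dropna(subset=["hcp", "math_anxiety", *covariates]).copy()
    terms = ["C(domain, Treatment('math')) * math_anxiety"]
    terms += [f"Q('{c}')" for c in covariates]
    terms += [f"C(Q('{s}'))" for s in strata]
    formula = "hcp ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    exog = pd.DataFrame(model.exog, columns=model.exog_names)
    _check_rank(exog)
    fit = model.fit()
    res = _ols_result(fit, len(df), alpha)
    res.table["name"] = res.table["name"].str.replace(
        "C(domain, Treatment('math'))[T.word]", "domain[word]", regex=False
    )
    return res


INTERACTION_TERM = "domain[word]:math_anxiety"


def binomial_hcp_model(counts_table: pd.DataFrame, covariates: tuple = ("math_anxiety",), alpha: float = 0.05) -> RegressionResult:
    """Logistic regression of hard-choice counts k out of m on covariates.

    ``counts_table`` needs columns ``k`` and ``m`` plus the covariates.
    Coefficients are on the log-odds scale.
    """
    import statsmodels.api as sm

    k = np.asarray(counts_table["k"], dtype=float)
    m = np.asarray(counts_table["m"], dtype=float)
    if (k < 0).any() or (k > m).any():
        raise InvalidArgumentError("need 0 <= k <= m")
    if (k == m).all() or (k == 0).all():
        raise SeparationError("degenerate outcome: every count at the same boundary")
    X = sm.add_constant(counts_table[list(covariates)].astype(float))
    _check_rank(X)
    model = sm.GLM(np.column_stack([k, m - k]), X, family=sm.families.Binomial())
    try:
        fit = model.fit()
    except Exception as exc:  # perfect separation raises inside IRLS
        raise SeparationError(f"binomial fit failed: {exc}") from exc
    if not np.isfinite(fit.bse).all() or (np.abs(fit.params) > 30).any():
        offender = fit.params.abs().idxmax()
        raise SeparationError(f"separation suspected; runaway coefficient for {offender!r}")
    ci = fit.conf_int(alpha)
    table = pd.DataFrame(
        {
            "name": fit.params.index,
            "beta": fit.params.values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
            "se": fit.bse.values,
            "t": fit.tvalues.values,
            "p": fit.pvalues.values,
        }
    ).reset_index(drop=True)
    return RegressionResult(table=table, df=int(fit.df_resid), adjusted_r2=float("nan"))


def test_retest(
    session1: pd.DataFrame,
    session2: pd.DataFrame,
    measures: tuple = ("hcp_math", "hcp_word", "adl_math", "adl_word"),
    alpha: float = 0.05,
) -> dict[str, CorrelationResult]:
    """Pearson test-retest correlation per measure over matched participants."""
    merged = session1.merge(session2, on="participant_id", suffixes=("_s1", "_s2"))
    if len(merged) == 0:
        raise InvalidArgumentError("no overlapping participant ids between sessions")
    out = {}
    for m in measures:
        sub = merged[[f"{m}_s1", f"{m}_s2"]].dropna()
        out[m] = pearson_ci(sub[f"{m}_s1"], sub[f"{m}_s2"], alpha)
    return out


def summaries_to_long(summaries: pd.DataFrame, covariate_stems: tuple = ("easy_accuracy", "hard_accuracy", "easy_rt", "hard_rt", "adl"), strata: tuple = ()) -> pd.DataFrame:
    """Stack a per-participant summary frame into the two-row-per-participant
    layout expected by :func:`interaction_model` (per-domain covariates)."""
    rows = []
    for _, r in summaries.iterrows():
        for domain in ("math", "word"):
            row = {
                "participant_id": r["participant_id"],
                "domain": domain,
                "hcp": r[f"hcp_{domain}"],
                "math_anxiety": r["math_anxiety"],
            }
            for stem in covariate_stems:
                row[stem] = r[f"{stem}_{domain}"]
            for s in strata:
                row[s] = r[s]
            rows.append(row)
    return pd.DataFrame(rows)
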