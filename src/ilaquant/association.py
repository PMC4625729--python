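"""Association models linking HAA% to visual ILA, lung volume and genotype.

All fits are ordinary GLMs via statsmodels: logistic regression for the
odds of visual ILA per 1 % HAA (with the indeterminate-handling policy
made explicit), linear regression for CT lung volume (TLC, ml) per 1 %
HAA, stratified fits with a pooled interaction test for effect
modification, and single-variant additive genetic models (genotype coded
0/1/2 entered as one numeric term).  Confidence intervals are Wald on the
link scale, exponentiated for odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_ADJUSTMENT = (
    "age",
    "sex",
    "race",
    "bmi",
    "pack_years",
    "current_smoker",
    "emph_pct",
)

#: Adjustment used for genetic models (no race/emphysema term, mirroring
#: an age/sex/BMI/smoking-adjusted single-variant analysis).
GENETIC_ADJUSTMENT = ("age", "sex", "bmi", "pack_years", "current_smoker")

STRATIFIERS = {"emph_pct@5": ("emph_pct", 5.0), "bmi@30": ("bmi", 30.0)}


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


class StratumError(ValueError):
    """Raised when a requested stratum or subset is empty."""


@dataclass
class AssociationResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjustment_set: tuple[str, ...]
    scale: str = ""  # "odds_ratio" or "ml_per_pct" etc.
    stratum_label: str | None = None

    def __str__(self) -> str:  # compact report line
        lab = f" [{self.stratum_label}]" if self.stratum_label else ""
        return (
            f"{self.scale}{lab}: {self.estimate:.3g} "
            f"(95% CI {self.ci_low:.3g}-{self.ci_high:.3g}, p={self.p_value:.3g}, "
            f"n={self.n_used})"
        )


def _encode(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric design columns for the given cohort variables."""
    out = {}
    for col in columns:
        if col == "sex":
            out["female"] = (df["sex"] == "female").astype(float)
        elif col == "race":
            out["african_american"] = (df["race"] == "african_american").astype(float)
        elif col == "current_smoker":
            out["current_smoker"] = df["current_smoker"].astype(float)
        else:
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def _design(df: pd.DataFrame, exposure: str, adjustment_set) -> pd.DataFrame:
    X = _encode(df, (exposure, *adjustment_set))
    return sm.add_constant(X, has_constant="add")


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    if y.min() == y.max():
        raise SeparationError("outcome has a single class; logistic fit impossible")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.isfinite(res.params).all() or np.abs(res.params.iloc[1:]).max() > 15:
        raise SeparationError(
            "logistic fit shows separation (diverging coefficients); "
            "refusing to report an unbounded odds ratio"
        )
    return res


def _wald_result(res, term: str, n: int, adjustment_set, scale: str,
                 exp: bool, stratum_label: str | None = None) -> AssociationResult:
    est = res.params[term]
    lo, hi = res.conf_int().loc[term]
    p = res.pvalues[term]
    if exp:
        est, lo, hi = np.exp([est, lo, hi])
    return AssociationResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        n_used=n,
        adjustment_set=tuple(adjustment_set),
        scale=scale,
        stratum_label=stratum_label,
    )


def _apply_policy(cohort: pd.DataFrame, indeterminate_policy: str) -> pd.DataFrame:
    if indeterminate_policy == "exclude":
        return cohort[cohort["visual_status"] != "indeterminate"]
    if indeterminate_policy == "as_control":
        return cohort
    raise ValueError(f"unknown indeterminate_policy {indeterminate_policy!r}")


def fit_ila_logistic(
    cohort: pd.DataFrame,
    adjustment_set=DEFAULT_ADJUSTMENT,
    indeterminate_policy: str = "exclude",
) -> AssociationResult:
    """Adjusted odds ratio of visual ILA per 1 % increase in HAA.

    With ``indeterminate_policy='exclude'`` indeterminate reads are
    dropped (the primary analysis); with ``'as_control'`` they are pooled
    with the unaffected controls.
    """
    sub = _apply_policy(cohort, indeterminate_policy)
    y = (sub["visual_status"] == "ila").to_numpy().astype(float)
    X = _design(sub, "haa_pct", adjustment_set)
    res = _fit_logit(y, X)
    return _wald_result(res, "haa_pct", len(sub), adjustment_set, "odds_ratio", exp=True)


def fit_tlc_linear(
    cohort: pd.DataFrame,
    adjustment_set=("age", "sex", "bmi"),
    subset: str = "all",
) -> AssociationResult:
    """Adjusted change in CT lung volume (ml) per 1 % increase in HAA.

    ``subset='ila_only'`` restricts to subjects with a visual ILA read.
    """
    if subset == "all":
        sub = cohort
    elif subset == "ila_only":
        sub = cohort[cohort["visual_status"] == "ila"]
        if len(sub) == 0:
            raise StratumError("no subjects with visual ILA; subset is empty")
    else:
        raise ValueError(f"subset must be 'all' or 'ila_only', got {subset!r}")
    y = sub["tlc_ml"].to_numpy(dtype=float)
    X = _design(sub, "haa_pct", adjustment_set)
    res = sm.OLS(y, X).fit()
    return _wald_result(res, "haa_pct", len(sub), adjustment_set, "ml_per_pct", exp=False)


def stratified_effects(
    cohort: pd.DataFrame,
    stratifier: str = "emph_pct@5",
    adjustment_set=DEFAULT_ADJUSTMENT,
    indeterminate_policy: str = "exclude",
) -> tuple[list[AssociationResult], float]:
    """Per-stratum odds ratios of ILA per 1 % HAA plus an interaction p.

    ``stratifier`` is ``'variable@cutoff'`` (``emph_pct@5`` or ``bmi@30``).
    Returns ([below-cut result, at/above-cut result], interaction p-value
    from the pooled model's HAA-by-stratum Wald test).
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"stratifier must be one of {sorted(STRATIFIERS)}")
    var, cut = STRATIFIERS[stratifier]
    sub = _apply_policy(cohort, indeterminate_policy)
    upper = (sub[var] >= cut).to_numpy()
    strata_masks = ((f"{var}<{cut:g}", ~upper), (f"{var}>={cut:g}", upper))
    for label, mask in strata_masks:
        if mask.sum() == 0:
            raise StratumError(f"stratum {label} is empty")
    results = []
    for label, mask in strata_masks:
        stratum = sub.loc[mask]
        y = (stratum["visual_status"] == "ila").to_numpy().astype(float)
        X = _design(stratum, "haa_pct", adjustment_set)
        res = _fit_logit(y, X)
        results.append(
            _wald_result(
                res, "haa_pct", int(mask.sum()), adjustment_set,
                "odds_ratio", exp=True, stratum_label=label,
            )
        )
    # pooled interaction test
    y = (sub["visual_status"] == "ila").to_numpy().astype(float)
    X = _design(sub, "haa_pct", adjustment_set)
    X["stratum_upper"] = upper.astype(float)
    X["haa_x_stratum"] = X["haa_pct"] * X["stratum_upper"]
    res = _fit_logit(y, X)
    return results, float(res.pvalues["haa_x_stratum"])


def genotype_association(
    cohort: pd.DataFrame,
    outcome: str = "haa_continuous",
    adjustment_set=GENETIC_ADJUSTMENT,
    threshold_pct: float = 10.0,
) -> AssociationResult:
    """Additive genetic model of HAA on genotype (0/1/2 risk alleles).

    ``outcome='haa_continuous'`` fits a linear model of HAA% on allele
    count; ``'haa_ge_threshold'`` fits a logistic model of exceeding the
    given HAA threshold, returning an odds ratio per allele.
    """
    g = cohort["genotype"]
    if g.nunique() < 2:
        raise ValueError("monomorphic genotype: association model is unidentified")
    X = _design(cohort, "genotype", adjustment_set)
    if outcome == "haa_continuous":
        y = cohort["haa_pct"].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        return _wald_result(
            res, "genotype", len(cohort), adjustment_set, "pct_haa_per_allele", exp=False
        )
    if outcome == "haa_ge_threshold":
        y = (cohort["haa_pct"] >= threshold_pct).to_numpy().astype(float)
        res = _fit_logit(y, X)
        return _wald_result(
            res, "genotype", len(cohort), adjustment_set, "odds_ratio", exp=True
        )
    raise ValueError(
        f"outcome must be 'haa_continuous' or 'haa_ge_threshold', got {outcome!r}"
    )


def association_table(results) -> pd.DataFrame:
    """Collect AssociationResults into a report table."""
    rows = []
    for name, r in results:
        rows.append(
            {
                "model": name,
                "stratum": r.stratum_label or "",
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "n": r.n_used,
                "scale": r.scale,
            }
        )
    return pd.DataFrame(rows)
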