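"""Agreement between threshold-based and visual ILA classification.

A subject is HAA-positive when the percentage of lung in the high
attenuation window meets a threshold (boundary inclusive: ``>=``).
Against the visual read this yields a 2x2 contingency table, from which
Cohen's kappa (chance-corrected agreement), a diagnostic accuracy panel
(sensitivity, specificity, PPV, NPV) and a rank-based c-statistic are
computed.  Subjects with an *indeterminate* visual read can either be
excluded or counted as controls; both policies are first-class because
they answer different questions and the attenuation between them is
itself informative.

Kappa's p-value tests H0: kappa = 0 with the asymptotic z statistic and
the large-sample null variance

    var0 = [p_e + p_e^2 - sum_i p_i. p_.i (p_i. + p_.i)] / [n (1 - p_e)^2]

where p_i. and p_.i are the row and column marginal proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INDETERMINATE_POLICIES = ("exclude", "as_control")


class DegenerateTableError(ValueError):
    """Raised when a statistic is undefined for the given table."""


@dataclass
class ContingencyTable2x2:
    """Counts of visual ILA status against HAA-threshold classification.

    a: visual-ILA & HAA-positive,  b: visual-ILA & HAA-negative,
    c: no-ILA & HAA-positive,      d: no-ILA & HAA-negative.
    """

    a: int
    b: int
    c: int
    d: int
    indeterminate_policy: str = "exclude"
    n_indeterminate_absorbed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")
        if self.total == 0:
            raise DegenerateTableError("contingency table has zero total")
        if self.indeterminate_policy not in INDETERMINATE_POLICIES:
            raise ValueError(
                f"indeterminate_policy must be one of {INDETERMINATE_POLICIES}"
            )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AgreementStats:
    """Agreement panel; rates with an undefined denominator are None."""

    kappa: float | None = None
    kappa_p: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    threshold_used: float | None = None
    c_statistic: float | None = None


def classify_by_haa(haa_pct, threshold_pct: float):
    """HAA-positive iff haa_pct >= threshold (boundary counts as positive)."""
    if not (0.0 < threshold_pct < 100.0):
        raise ValueError(f"threshold must lie in (0, 100), got {threshold_pct}")
    arr = np.asarray(haa_pct, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ValueError("haa_pct values must lie in [0, 100]")
    pos = arr >= threshold_pct
    return bool(pos) if np.isscalar(haa_pct) else pos


def percentile_threshold(haa_values, q: float = 95.0) -> float:
    """Linear-interpolation sample percentile of HAA%, used to derive a
    cohort-specific positivity threshold (the 95th percentile by default)."""
    arr = np.asarray(haa_values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_threshold requires at least one value")
    if arr.size < 20:
        import warnings

        warnings.warn(
            f"percentile threshold from only {arr.size} values is unstable",
            stacklevel=2,
        )
    return float(np.percentile(arr, q, method="linear"))


def build_contingency(
    cohort: pd.DataFrame,
    threshold_pct: float,
    indeterminate_policy: str = "exclude",
) -> ContingencyTable2x2:
    """Cross-classify visual status against the HAA threshold rule."""
    if indeterminate_policy not in INDETERMINATE_POLICIES:
        raise ValueError(
            f"indeterminate_policy must be one of {INDETERMINATE_POLICIES}"
        )
    status = cohort["visual_status"]
    indet = status == "indeterminate"
    if indeterminate_policy == "exclude":
        sub = cohort.loc[~indet]
        absorbed = 0
    else:
        sub = cohort
        absorbed = int(indet.sum())
    if len(sub) == 0:
        raise DegenerateTableError("no subjects left after indeterminate policy")
    pos = classify_by_haa(sub["haa_pct"].to_numpy(), threshold_pct)
    ila = (sub["visual_status"] == "ila").to_numpy()
    return ContingencyTable2x2(
        a=int((ila & pos).sum()),
        b=int((ila & ~pos).sum()),
        c=int((~ila & pos).sum()),
        d=int((~ila & ~pos).sum()),
        indeterminate_policy=indeterminate_policy,
        n_indeterminate_absorbed=absorbed,
    )


def cohen_kappa(t: ContingencyTable2x2) -> tuple[float, float | None]:
    """Cohen's kappa and its two-sided asymptotic p-value against kappa=0.

    The p-value uses the large-sample null variance and requires all four
    marginals to be positive; with any zero marginal it is returned as
    None.  Degenerate tables with expected agreement 1 have no defined
    kappa and raise.
    """
    n = t.total
    p_o = (t.a + t.d) / n
    row1, row2 = (t.a + t.b) / n, (t.c + t.d) / n
    col1, col2 = (t.a + t.c) / n, (t.b + t.d) / n
    p_e = row1 * col1 + row2 * col2
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError(
            "kappa undefined: expected agreement is 1 (degenerate marginals)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    if min(row1, row2, col1, col2) == 0:
        return kappa, None
    s = row1 * col1 * (row1 + col1) + row2 * col2 * (row2 + col2)
    var0 = (p_e + p_e**2 - s) / (n * (1.0 - p_e) ** 2)
    if var0 <= 0:  # pragma: no cover - defensive
        return kappa, None
    z = kappa / np.sqrt(var0)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(p)


def diagnostic_panel(
    t: ContingencyTable2x2, threshold_used: float | None = None
) -> AgreementStats:
    """Sensitivity, specificity, PPV, NPV and kappa for one table.

    Statistics with a zero denominator are reported as None (missing),
    never as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    try:
        kappa, kappa_p = cohen_kappa(t)
    except DegenerateTableError:
        kappa, kappa_p = None, None
    return AgreementStats(
        kappa=kappa,
        kappa_p=kappa_p,
        sensitivity=ratio(t.a, t.a + t.b),
        specificity=ratio(t.d, t.c + t.d),
        ppv=ratio(t.a, t.a + t.c),
        npv=ratio(t.d, t.b + t.d),
        threshold_used=threshold_used,
    )


def c_statistic(haa_values, ila_labels) -> float:
    """Rank-based AUC: probability a random case out-ranks a random control,
    ties counted one half (equivalently Mann-Whitney U / (n1*n0))."""
    x = np.asarray(haa_values, dtype=float)
    y = np.asarray(ila_labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic requires both cases and controls")
    ranks = stats.rankdata(x)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def threshold_sweep(
    cohort: pd.DataFrame,
    grid,
    indeterminate_policy: str = "exclude",
) -> pd.DataFrame:
    """Agreement panel across a grid of thresholds, one row per threshold,
    with Youden's J (sensitivity + specificity - 1) for threshold choice."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    rows = []
    for thr in grid:
        t = build_contingency(cohort, float(thr), indeterminate_policy)
        s = diagnostic_panel(t, threshold_used=float(thr))
        youden = (
            s.sensitivity + s.specificity - 1.0
            if s.sensitivity is not None and s.specificity is not None
            else np.nan
        )
        rows.append(
            {
                "threshold": float(thr),
                "kappa": s.kappa,
                "kappa_p": s.kappa_p,
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "ppv": s.ppv,
                "npv": s.npv,
                "youden": youden,
            }
        )
    return pd.DataFrame(rows)


def best_threshold(sweep: pd.DataFrame, rule: str = "youden") -> float:
    """Select the best threshold from a sweep (max Youden's J by default;
    ties resolved toward the lowest threshold)."""
    if rule != "youden":
        raise ValueError(f"unknown selection rule {rule!r}")
    valid = sweep.dropna(subset=["youden"])
    if valid.empty:
        raise ValueError("no threshold with a defined Youden index")
    best = valid.loc[valid["youden"].idxmax()]
    ties = valid[np.isclose(valid["youden"], best["youden"])]
    return float(ties["threshold"].min())
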