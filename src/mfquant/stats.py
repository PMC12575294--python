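"""Group comparisons: rank / distribution tests, two-way ANOVA, behavior.

Pooled cluster-size distributions are compared with a two-sided
Mann-Whitney U test (exact for small samples, tie-corrected normal
approximation otherwise) and a two-sample Kolmogorov-Smirnov test.
Per-mouse metrics are compared with a two-way Group x Sex ANOVA using Type
III sums of squares under sum-to-zero contrasts (appropriate for the
unbalanced cells of small cohorts). Behavioral memory performance is a
discrimination ratio of novel-to-familiar exploration times.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import ParameterError

logger = logging.getLogger("mfquant")

#: per-sample size at or below which the Mann-Whitney p is computed exactly
EXACT_MW_CUTOFF = 20


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "details": self.details,
        }


def _validate_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    return a, b


def mann_whitney(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For samples of at most 20 each, the p-value is exact (full enumeration
    of the permutation distribution of U, valid with ties); larger samples
    use the tie-corrected normal approximation with continuity correction.
    """
    a, b = _validate_samples(sample_a, sample_b)
    small = max(a.size, b.size) <= EXACT_MW_CUTOFF
    if small:
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        if ties:
            # scipy's 'exact' method assumes no ties; enumerate instead
            method = sps.PermutationMethod(n_resamples=np.inf)
            method_label = "exact (permutation enumeration, ties)"
        else:
            method = "exact"
            method_label = "exact"
    else:
        method = "asymptotic"
        method_label = "asymptotic (tie-corrected normal)"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        details={"method": method_label},
    )


def ks_two_sample(sample_a, sample_b) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p."""
    a, b = _validate_samples(sample_a, sample_b)
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(
        test_name="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        details={"method": "asymptotic"},
    )


def anova_two_way(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    sex: str = "sex",
) -> TestResult:
    """Two-way Group x Sex ANOVA with Type III sums of squares.

    Uses sum-to-zero contrasts so main effects are interpretable in
    unbalanced designs. If some Group x Sex cell is empty, the interaction
    is dropped with a warning. Returns the Group term as the headline
    result; the full ANOVA table (SS, df, F, p per term) is in
    ``details["anova_table"]``. With constant data (zero residual
    variance) F is reported as 0 and p as 1.
    """
    df = data[[value, group, sex]].dropna().copy()
    groups = df[group].unique()
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    degenerate = np.ptp(df[value].to_numpy()) == 0  # constant response
    cells = df.groupby([group, sex], observed=True).size()
    n_sex = df[sex].nunique()
    full_cells = len(groups) * n_sex
    with_interaction = len(cells) == full_cells and n_sex > 1
    if not with_interaction:
        warnings.warn(
            "empty Group x Sex cell: interaction term dropped", stacklevel=2
        )
    elif len(df) <= full_cells:
        # one observation per cell saturates the model; fall back to the
        # additive design so a residual remains
        warnings.warn(
            "no residual df for the interaction: term dropped", stacklevel=2
        )
        with_interaction = False
    n_additive_params = 1 + (len(groups) - 1) + (n_sex - 1)
    if len(df) <= n_additive_params:
        raise ParameterError("too few observations for a two-way ANOVA")
    rhs = f"C({group}, Sum) * C({sex}, Sum)" if with_interaction else (
        f"C({group}, Sum) + C({sex}, Sum)" if df[sex].nunique() > 1
        else f"C({group}, Sum)"
    )
    fit = smf.ols(f"{value} ~ {rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels divide-by-zero on df=0
        table = anova_lm(fit, typ=3)
    table = table.rename(
        index=lambda s: s.replace(f"C({group}, Sum)", "group").replace(
            f"C({sex}, Sum)", "sex"
        ).replace(":", " x ")
    )
    resid_df = float(table.loc["Residual", "df"])
    resid_ss = float(table.loc["Residual", "sum_sq"])

    def _term(name: str) -> dict:
        row = table.loc[name]
        f_val, p_val = float(row["F"]), float(row["PR(>F)"])
        if degenerate or not math.isfinite(f_val):
            # constant response: every SS is 0, F is 0/0; report F=0, p=1
            f_val, p_val = 0.0, 1.0
        return {
            "sum_sq": float(row["sum_sq"]),
            "df": float(row["df"]),
            "F": f_val,
            "p": p_val,
        }

    terms = {
        name: _term(name) for name in table.index if name not in ("Intercept", "Residual")
    }
    g = terms["group"]
    n_per_group = df.groupby(group, observed=True).size()
    return TestResult(
        test_name="two_way_anova_type3",
        statistic=g["F"],
        p_value=g["p"],
        n_a=int(n_per_group.iloc[0]),
        n_b=int(n_per_group.iloc[1]) if len(n_per_group) > 1 else 0,
        details={
            "terms": terms,
            "residual_df": resid_df,
            "residual_ss": resid_ss,
            "contrasts": "sum-to-zero",
            "ss_type": 3,
            "interaction_included": with_interaction,
        },
    )


@dataclass(frozen=True)
class BehaviorRecord:
    """Scored exploration times for one mouse in one task."""

    mouse_id: str
    condition: str
    time_novel: float
    time_familiar: float

    def __post_init__(self) -> None:
        if self.time_novel < 0 or self.time_familiar < 0:
            raise ParameterError("exploration times must be >= 0")


def discrimination_ratio(record: BehaviorRecord | None = None, *,
                         time_novel: float | None = None,
                         time_familiar: float | None = None) -> float:
    """Discrimination ratio: time near the novel condition divided by time
    near the familiar one. 1 means equal exploration of both."""
    if record is not None:
        time_novel, time_familiar = record.time_novel, record.time_familiar
    if time_novel is None or time_familiar is None:
        raise ParameterError("provide a record or both times")
    if time_familiar <= 0:
        raise ParameterError(
            "discrimination ratio undefined: familiar time must be > 0"
        )
    return float(time_novel) / float(time_familiar)
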