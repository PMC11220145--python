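"""Cohort statistics: allele-category assignment, per-category OLS of the
expansion ratio on inherited CAG length and age at sampling, a per-CAG
age-effect scan, and the covariate-adjusted group comparison (ANCOVA).

Conventions: covariates enter raw (uncentred); main effects are reported
from the no-interaction model and the CAG x age interaction p-value from a
second, augmented fit; two-sided tests at alpha = 0.05; no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CagMosaicError, CollinearDesignError, SchemaError

CATEGORY_ORDER = ("normal", "intermediate", "reduced_penetrance", "full_penetrance")

#: CAG windows used when reproducing the tabulated category fits.  In
#: ``table1`` mode full-penetrance is restricted to 40-50 CAG; in
#: ``results_text`` mode all >=40 CAG records are used.
CATEGORY_CAG_WINDOWS = {
    "table1": {
        "normal": (10, 26),
        "intermediate": (27, 35),
        "reduced_penetrance": (36, 39),
        "full_penetrance": (40, 50),
    },
    "results_text": {
        "normal": (10, 26),
        "intermediate": (27, 35),
        "reduced_penetrance": (36, 39),
        "full_penetrance": (40, 10**6),
    },
}

REQUIRED_COLUMNS = ("sample_id", "inherited_cag", "age_at_sampling", "group", "ratio")


def assign_category(inherited_cag: int) -> str:
    """Clinical allele category from inherited CAG length.

    <=26 normal; 27-35 intermediate; 36-39 reduced penetrance; >=40 full
    penetrance.  27 belongs to the intermediate category.
    """
    if inherited_cag < 1:
        raise ValueError("inherited_cag must be >= 1")
    if inherited_cag <= 26:
        return "normal"
    if inherited_cag <= 35:
        return "intermediate"
    if inherited_cag <= 39:
        return "reduced_penetrance"
    return "full_penetrance"


@dataclass(frozen=True)
class RegressionResult:
    """Per-category OLS result: main effects, Wald 95% CIs, R^2, and the
    interaction p from the augmented model."""

    category: str
    n: int
    beta_cag: float
    beta_age: float
    ci95_cag: tuple[float, float]
    ci95_age: tuple[float, float]
    p_cag: float
    p_age: float
    r2: float
    interaction_p: float | None
    intercept: float

    def __post_init__(self) -> None:
        if not (self.ci95_cag[0] <= self.beta_cag <= self.ci95_cag[1]):
            raise ValueError("CAG CI must contain its point estimate")
        if not (self.ci95_age[0] <= self.beta_age <= self.ci95_age[1]):
            raise ValueError("age CI must contain its point estimate")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("R^2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95_cag"] = list(self.ci95_cag)
        d["ci95_age"] = list(self.ci95_age)
        return d


def validate_cohort_table(records: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a cohort table; returns the table with a category
    column derived from inherited CAG."""
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    bad = records.index[records[["inherited_cag", "age_at_sampling", "ratio"]]
                        .isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"missing covariate(s) in row(s) {list(bad[:5])}")
    if (records["ratio"] < 0).any():
        raise SchemaError("ratio must be >= 0")
    if (records["age_at_sampling"] < 0).any():
        raise SchemaError("age_at_sampling must be >= 0")
    out = records.copy()
    out["category"] = out["inherited_cag"].astype(int).map(assign_category)
    return out


def _check_design(X: pd.DataFrame) -> None:
    for col in X.columns:
        if col == "const":
            continue
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise CollinearDesignError(col)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise CollinearDesignError("design")


def fit_category_regression(
    records: pd.DataFrame,
    category: str,
    with_interaction: bool = True,
    mode: str = "table1",
    min_records: int = 10,
) -> RegressionResult:
    """OLS of ratio on inherited CAG and age for one allele category.

    Records are restricted to the category's CAG window for the chosen
    reporting ``mode``.  Main effects come from the no-interaction model;
    ``interaction_p`` (if requested) from a second fit adding CAG x age.
    """
    if mode not in CATEGORY_CAG_WINDOWS:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = CATEGORY_CAG_WINDOWS[mode][category]
    sub = validate_cohort_table(records)
    sub = sub[(sub["category"] == category)
              & sub["inherited_cag"].between(lo, hi)].copy()
    if len(sub) < min_records:
        raise CagMosaicError(
            f"{len(sub)} records in category {category!r} < {min_records}")
    X = sm.add_constant(sub[["inherited_cag", "age_at_sampling"]].astype(float))
    _check_design(X)
    fit = sm.OLS(sub["ratio"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    interaction_p = None
    if with_interaction:
        Xi = X.copy()
        Xi["cag_x_age"] = Xi["inherited_cag"] * Xi["age_at_sampling"]
        _check_design(Xi)
        fit_i = sm.OLS(sub["ratio"].to_numpy(dtype=float), Xi).fit()
        interaction_p = float(fit_i.pvalues["cag_x_age"])
    return RegressionResult(
        category=category,
        n=int(len(sub)),
        beta_cag=float(fit.params["inherited_cag"]),
        beta_age=float(fit.params["age_at_sampling"]),
        ci95_cag=(float(ci.loc["inherited_cag", 0]), float(ci.loc["inherited_cag", 1])),
        ci95_age=(float(ci.loc["age_at_sampling", 0]), float(ci.loc["age_at_sampling", 1])),
        p_cag=float(fit.pvalues["inherited_cag"]),
        p_age=float(fit.pvalues["age_at_sampling"]),
        r2=float(fit.rsquared),
        interaction_p=interaction_p,
        intercept=float(fit.params["const"]),
    )


def fit_all_categories(
    records: pd.DataFrame,
    with_interaction: bool = True,
    mode: str = "table1",
    min_records: int = 10,
) -> dict[str, RegressionResult]:
    """Fit every category with enough records; skips sparse categories."""
    out = {}
    table = validate_cohort_table(records)
    for category in CATEGORY_ORDER:
        try:
            out[category] = fit_category_regression(
                table, category, with_interaction=with_interaction,
                mode=mode, min_records=min_records)
        except CagMosaicError:
            continue
    return out


def age_effect_scan(
    records: pd.DataFrame,
    min_cag: int,
    max_cag: int,
    cumulative: bool = False,
    min_records: int = 3,
) -> pd.DataFrame:
    """Per-CAG-length OLS of ratio on age alone.

    With ``cumulative=True`` each row pools all records with at least that
    many CAG (>=CAG strata) instead of the exact length.  Rows with fewer
    than ``min_records`` records are marked not estimable.
    """
    table = validate_cohort_table(records)
    rows = []
    for cag in range(min_cag, max_cag + 1):
        if cumulative:
            sub = table[table["inherited_cag"] >= cag]
        else:
            sub = table[table["inherited_cag"] == cag]
        row = {"cag": cag, "mode": "cumulative" if cumulative else "exact",
               "n": int(len(sub)), "beta_age": np.nan, "p_age": np.nan,
               "estimable": False}
        if len(sub) >= min_records and np.ptp(sub["age_at_sampling"].to_numpy()) > 0:
            X = sm.add_constant(sub[["age_at_sampling"]].astype(float))
            fit = sm.OLS(sub["ratio"].to_numpy(dtype=float), X).fit()
            row.update(beta_age=float(fit.params["age_at_sampling"]),
                       p_age=float(fit.pvalues["age_at_sampling"]),
                       estimable=True)
        rows.append(row)
    return pd.DataFrame(rows)


def adjusted_group_comparison(records: pd.DataFrame) -> dict:
    """ANCOVA of ratio on group + CAG + age for the two groups present.

    Adjusted group means are the model predictions at the covariate grand
    means; the p-value is the two-sided Wald p of the group indicator.
    """
    table = validate_cohort_table(records)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise CagMosaicError(f"exactly two groups required, found {groups}")
    sizes = table["group"].value_counts()
    if (sizes < 2).any():
        raise CagMosaicError(f"each group needs >= 2 records, found {sizes.to_dict()}")
    indicator = (table["group"] == groups[1]).astype(float)
    X = sm.add_constant(pd.DataFrame({
        "group": indicator,
        "inherited_cag": table["inherited_cag"].astype(float),
        "age_at_sampling": table["age_at_sampling"].astype(float),
    }))
    _check_design(X)
    fit = sm.OLS(table["ratio"].to_numpy(dtype=float), X).fit()
    grand = {
        "inherited_cag": float(table["inherited_cag"].mean()),
        "age_at_sampling": float(table["age_at_sampling"].mean()),
    }
    base = (fit.params["const"]
            + fit.params["inherited_cag"] * grand["inherited_cag"]
            + fit.params["age_at_sampling"] * grand["age_at_sampling"])
    adjusted_means = {
        groups[0]: float(base),
        groups[1]: float(base + fit.params["group"]),
    }
    return {
        "groups": groups,
        "n": {g: int(sizes[g]) for g in groups},
        "adjusted_means": adjusted_means,
        "difference": float(fit.params["group"]),
        "p_value": float(fit.pvalues["group"]),
        "covariate_grand_means": grand,
    }
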