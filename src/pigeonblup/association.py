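"""Carrier-group association with deviated breeding values.

For each race trait, the deviated EBV (DEBV) of genotyped birds is
regressed on carrier group (S+ vs S-) with an ordinary-least-squares
fixed-effects model and the group term is tested by an F-test.  With two
groups and no covariates this is exactly the pooled-variance two-sample
t-test (F = t^2, identical p).  Sex can be added as an optional covariate;
no relatedness correction is applied — the genotyped birds' DEBV are
regressed directly, as in the original analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    trait: str
    group_labels: tuple[str, str]        # (carrier+, carrier-)
    n: tuple[int, int]
    mean_debv: tuple[float, float]
    sd_debv: tuple[float, float]
    effect: float                        # carrier+ minus carrier-
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    bonferroni_p: Optional[float] = None  # supplementary, not the original procedure

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "n_plus": self.n[0],
            "n_minus": self.n[1],
            "mean_debv_plus": self.mean_debv[0],
            "mean_debv_minus": self.mean_debv[1],
            "sd_debv_plus": self.sd_debv[0],
            "sd_debv_minus": self.sd_debv[1],
            "effect": self.effect,
            "F": self.f_statistic,
            "df1": self.df[0],
            "df2": self.df[1],
            "p": self.p_value,
            "bonferroni_p": self.bonferroni_p,
        }


def associate(
    debv: np.ndarray,
    carrier: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    trait: str = "",
) -> AssociationResult:
    """OLS of DEBV on carrier group (+ optional categorical covariates).

    ``carrier`` is boolean (True = carries the target allele).  The F-test
    is on the single group contrast; the effect is the carrier+ minus
    carrier- adjusted difference.

    Raises
    ------
    ValueError
        If either group is empty or residual degrees of freedom are zero.
    """
    debv = np.asarray(debv, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    if debv.shape != carrier.shape:
        raise ValueError("debv and carrier must have equal length")
    n_plus, n_minus = int(carrier.sum()), int((~carrier).sum())
    if n_plus == 0 or n_minus == 0:
        raise ValueError("both carrier groups must be non-empty")

    cols = {"const": np.ones(len(debv)), "carrier": carrier.astype(float)}
    if covariates is not None:
        dummies = pd.get_dummies(covariates.astype("category"), drop_first=True)
        for name in dummies.columns:
            cols[str(name)] = dummies[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if len(debv) - X.shape[1] <= 0:
        raise ValueError("zero residual degrees of freedom")
    fit = sm.OLS(debv, X).fit()
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    ftest = fit.f_test(contrast)
    f_stat = float(np.squeeze(ftest.fvalue))
    p = float(np.squeeze(ftest.pvalue))
    plus, minus = debv[carrier], debv[~carrier]
    effect = float(fit.params.iloc[1])
    if plus.std(ddof=0) == 0 and minus.std(ddof=0) == 0 and plus.mean() == minus.mean():
        # Degenerate identical-values case: no effect, p = 1 by convention.
        f_stat, p, effect = 0.0, 1.0, 0.0
    return AssociationResult(
        trait=trait,
        group_labels=("+", "-"),
        n=(n_plus, n_minus),
        mean_debv=(float(plus.mean()), float(minus.mean())),
        sd_debv=(
            float(plus.std(ddof=1)) if n_plus > 1 else float("nan"),
            float(minus.std(ddof=1)) if n_minus > 1 else float("nan"),
        ),
        effect=effect,
        f_statistic=f_stat,
        df=(1, int(fit.df_resid)),
        p_value=p,
    )


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (statistic, p); oracle companion."""
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def associate_all_traits(
    ebv_table: pd.DataFrame,
    carriers: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Run the association per trait over the genotyped subset.

    ``ebv_table`` is long-format with columns animal_id/trait/debv (as from
    :func:`pigeonblup.ebv.ebv_table`); ``carriers`` is a boolean Series
    indexed by animal_id for genotyped birds.  Genotyped animals without an
    EBV are dropped with a warning.  A Bonferroni-adjusted column is
    appended as supplementary output (the original analysis reported raw
    per-trait p-values).
    """
    traits = list(dict.fromkeys(ebv_table["trait"]))
    if not traits:
        raise ValueError("ebv_table contains no traits")
    genotyped = set(carriers.index)
    with_ebv = set(ebv_table["animal_id"])
    dropped = genotyped - with_ebv
    if dropped:
        logger.warning("%d genotyped animals lack an EBV and are dropped", len(dropped))
    usable = genotyped & with_ebv
    if not usable:
        raise ValueError("no genotyped animal has an EBV")
    rows = []
    for trait in traits:
        sub = ebv_table[(ebv_table["trait"] == trait) & ebv_table["animal_id"].isin(usable)]
        sub = sub.set_index("animal_id")
        ids = sub.index.to_list()
        cov = covariates.loc[ids] if covariates is not None else None
        res = associate(
            sub["debv"].to_numpy(),
            carriers.loc[ids].to_numpy(dtype=bool),
            covariates=cov,
            trait=trait,
        )
        rows.append(res.to_row())
    report = pd.DataFrame(rows)
    if bonferroni:
        report["bonferroni_p"] = np.minimum(report["p"] * len(traits), 1.0)
    else:
        report = report.drop(columns=["bonferroni_p"])
    return report


def group_distribution_summary(
    ebv_table: pd.DataFrame, carriers: pd.Series
) -> pd.DataFrame:
    """Per-trait, per-group DEBV distribution summaries (for box plots)."""
    merged = ebv_table[ebv_table["animal_id"].isin(carriers.index)].copy()
    merged["group"] = merged["animal_id"].map(
        lambda a: "+" if bool(carriers.loc[a]) else "-"
    )
    return (
        merged.groupby(["trait", "group"])["debv"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )
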