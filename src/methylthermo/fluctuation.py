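"""Boltzmann-factor fluctuation analysis of methylome entropy.

In healthy differentiated tissue the dimensionless entropy magnitude
|S|/c (c = k_B or R) and the mean divergence ν = ⟨χ⟩ of each chromosome
obey, up to experimental error, the feedback-control relation

    e^{−|S|/c} = η · (1 − e^{−ν})

whose single constant η measures the efficacy of the non-equilibrium
feedback exerted by the methylation machinery.  Equivalent diagnostics
are the linearization e^{−|S|/c} ≅ η·ν + c₀ and the near-constancy of
the sum of Boltzmann factors ⟨e^{−|S|/c} + e^{−ν}⟩ = η ≈ 1.  Departures
— a positive slope of e^{−|S|/c} against e^{−ν}, or a sum drifting away
from the healthy band — flag dysfunctional states (e.g. loss of the
maintenance methyltransferase, cancer, undifferentiated stem cells).

This module builds the factors from thermodynamic states, fits the
feedback models, tests sum-of-factors equality between groups, clusters
chromosomes on the ν axis, and compares entropy between groups with a
chromosome-random-intercept mixed model or a paired Wilcoxon test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import DegenerateDataError, SampleSizeError, UnitMismatchError
from .thermo import ThermoState

ModelForm = Literal["exp_exp", "linear_nu", "sum_mean"]


@dataclass
class FluctuationPoint:
    """One (sample, chromosome) point of the fluctuation analysis."""

    sample_id: str
    chromosome: str
    s_abs: float        # dimensionless |S|/c
    nu_mean: float      # mean divergence ⟨χ⟩
    factor_S: float     # e^{−|S|/c}
    factor_nu: float    # e^{−ν}
    group_label: str = ""

    @property
    def factor_sum(self) -> float:
        return self.factor_S + self.factor_nu


@dataclass
class FeedbackFit:
    """Fitted feedback-efficacy model."""

    eta: float
    intercept_c: float
    eta_stderr: float
    intercept_stderr: float
    r_squared: float
    model_form: ModelForm
    n_points: int
    slope_sign: int = 0          # sign of the slope of y against the regressor
    eta_unconstrained: float = float("nan")       # exp_exp diagnostic slope
    intercept_unconstrained: float = float("nan")


def boltzmann_factors(
    states: Sequence[ThermoState],
    constants=None,
) -> list[FluctuationPoint]:
    """Build fluctuation points e^{−|S|/c}, e^{−ν} from thermo states.

    The dimensionless entropy uses |S|/R in molar mode, |S|/k_B per
    molecule, and |S| directly for dimensionless states.  Rows lacking a
    mean divergence are skipped with a warning.
    """
    from .thermo import DEFAULT_CONSTANTS

    constants = constants or DEFAULT_CONSTANTS
    points: list[FluctuationPoint] = []
    skipped = 0
    for st in states:
        if not np.isfinite(st.mean_chi):
            skipped += 1
            continue
        c = constants.scale(st.constant_mode)
        s_abs = abs(st.S) / c
        points.append(
            FluctuationPoint(
                sample_id=st.sample_id,
                chromosome=st.chromosome,
                s_abs=s_abs,
                nu_mean=st.mean_chi,
                factor_S=math.exp(-s_abs),
                factor_nu=math.exp(-st.mean_chi),
                group_label=st.group_label,
            )
        )
    if skipped:
        warnings.warn(
            f"boltzmann_factors: skipped {skipped} state(s) without mean_chi",
            stacklevel=2,
        )
    return points


def points_to_frame(points: Sequence[FluctuationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [p.sample_id for p in points],
            "group": [p.group_label for p in points],
            "chromosome": [p.chromosome for p in points],
            "s_abs": [p.s_abs for p in points],
            "nu_mean": [p.nu_mean for p in points],
            "factor_S": [p.factor_S for p in points],
            "factor_nu": [p.factor_nu for p in points],
            "factor_sum": [p.factor_sum for p in points],
        }
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Slope, intercept, their standard errors and R² of simple OLS."""
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.stderr, res.intercept_stderr, res.rvalue**2


def fit_feedback_model(
    points: Sequence[FluctuationPoint],
    form: ModelForm = "exp_exp",
) -> FeedbackFit:
    """Estimate the feedback-efficacy constant η.

    * ``exp_exp``: y = e^{−|S|/c} against x = e^{−ν}, constrained to the
      single-constant form y = η(1 − x); the unconstrained two-parameter
      line is reported as a diagnostic, and its slope sign flags
      dysfunction when positive.
    * ``linear_nu``: y ≅ η·ν + c₀ (small-ν linearization).
    * ``sum_mean``: η = ⟨e^{−|S|/c} + e^{−ν}⟩; its standard error is the
      standard error of that mean.
    """
    n = len(points)
    if n < 3:
        raise SampleSizeError(f"need at least 3 points, got {n}")
    y = np.array([p.factor_S for p in points])
    if form == "exp_exp":
        x = np.array([p.factor_nu for p in points])
        regressor = 1.0 - x
        if np.ptp(regressor) <= 0:
            raise DegenerateDataError("zero variance in e^{-nu} regressor")
        # least squares through the origin on (1 - x)
        sxx = float(np.sum(regressor**2))
        eta = float(np.sum(y * regressor) / sxx)
        resid = y - eta * regressor
        dof = max(n - 1, 1)
        eta_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan
        slope_u, icpt_u, _, _, _ = _ols(x, y)
        return FeedbackFit(
            eta=eta, intercept_c=0.0, eta_stderr=eta_se, intercept_stderr=0.0,
            r_squared=r2, model_form=form, n_points=n,
            slope_sign=int(np.sign(slope_u)),
            eta_unconstrained=-slope_u, intercept_unconstrained=icpt_u,
        )
    if form == "linear_nu":
        x = np.array([p.nu_mean for p in points])
        if np.ptp(x) <= 0:
            raise DegenerateDataError("zero variance in nu regressor")
        slope, icpt, slope_se, icpt_se, r2 = _ols(x, y)
        return FeedbackFit(
            eta=slope, intercept_c=icpt, eta_stderr=slope_se,
            intercept_stderr=icpt_se, r_squared=r2, model_form=form,
            n_points=n, slope_sign=int(np.sign(slope)),
        )
    if form == "sum_mean":
        s = np.array([p.factor_sum for p in points])
        eta = float(s.mean())
        se = float(s.std(ddof=1) / math.sqrt(n))
        return FeedbackFit(
            eta=eta, intercept_c=0.0, eta_stderr=se, intercept_stderr=0.0,
            r_squared=float("nan"), model_form=form, n_points=n,
        )
    raise ValueError(f"unknown model form {form!r}")


def sum_factor_summary(
    points: Sequence[FluctuationPoint],
    groups: Sequence[str] | None = None,
    band_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-group mean/sd of the Boltzmann-factor sum, with a rank test.

    For exactly two groups a Mann–Whitney rank test of equality is run
    and its p-value attached to every row.  Groups whose mean leaves the
    pooled band (pooled mean ± band_sd · pooled sd) are flagged as
    departing — the signature of dysfunctional states.
    """
    df = points_to_frame(points)
    if groups is not None:
        df = df[df["group"].isin(list(groups))]
    if df.empty:
        raise ValueError("no points in the requested groups")
    counts = df.groupby("group")["factor_sum"].count()
    if (counts < 2).any():
        raise SampleSizeError(
            f"need >= 2 points per group for dispersion, got {counts.to_dict()}"
        )
    summary = (
        df.groupby("group")["factor_sum"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    pooled_mean = df["factor_sum"].mean()
    pooled_sd = df["factor_sum"].std(ddof=1)
    summary["departs"] = (
        (summary["mean"] - pooled_mean).abs() > band_sd * pooled_sd
    )
    labels = summary["group"].tolist()
    if len(labels) == 2:
        a = df.loc[df["group"] == labels[0], "factor_sum"]
        b = df.loc[df["group"] == labels[1], "factor_sum"]
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        summary["rank_test_p"] = p
    return summary


def cluster_chromosomes(
    points: Sequence[FluctuationPoint],
    k: int = 2,
    seed: int = 1,
    features: Literal["nu", "nu_factor"] = "nu",
    n_init: int = 25,
) -> tuple[np.ndarray, float]:
    """K-means split of chromosomes, 1-D on ν by default.

    Returns (labels, cutpoint); the cutpoint is the midpoint on the ν
    axis between the adjacent clusters (the vertical line separating the
    two regimes).  With ``features='nu_factor'`` clustering is 2-D on
    (ν, e^{−|S|/c}) and the cutpoint is still reported on ν.
    """
    n = len(points)
    if n < k:
        raise SampleSizeError(f"need at least k={k} points, got {n}")
    nu = np.array([p.nu_mean for p in points])
    if features == "nu":
        X = nu[:, None]
    elif features == "nu_factor":
        X = np.column_stack([nu, [p.factor_S for p in points]])
    else:
        raise ValueError(f"unknown feature space {features!r}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    # cutpoint between the two clusters with adjacent nu ranges
    order = np.argsort([nu[labels == j].mean() for j in range(k)])
    low, high = order[0], order[1] if k > 1 else order[0]
    if k > 1:
        cut = 0.5 * (nu[labels == low].max() + nu[labels == high].min())
    else:
        cut = float(nu.mean())
    return labels, float(cut)


def compare_entropy_groups(
    table: pd.DataFrame,
    method: Literal["mixed_model", "wilcoxon_paired"] = "mixed_model",
    entropy_col: str = "S",
    group_col: str = "group",
    chromosome_col: str = "chromosome",
) -> tuple[float, float]:
    """Compare entropy between two groups; returns (statistic, p-value).

    ``mixed_model`` fits entropy = group + (1 | chromosome) — a fixed
    group effect with a chromosome random intercept — and reports the
    Wald z statistic and p-value of the group effect.  ``wilcoxon_paired``
    runs a signed-rank test on chromosome-paired group means and requires
    the chromosome sets to match.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if method == "mixed_model":
        import statsmodels.formula.api as smf

        df = table.rename(
            columns={entropy_col: "entropy", group_col: "grp", chromosome_col: "chrom"}
        )[["entropy", "grp", "chrom"]].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("entropy ~ grp", df, groups=df["chrom"])
            fit = model.fit(reml=True)
        term = [t for t in fit.params.index if t.startswith("grp")][0]
        z = float(fit.tvalues[term])
        p = float(fit.pvalues[term])
        return z, p
    if method == "wilcoxon_paired":
        means = (
            table.groupby([group_col, chromosome_col])[entropy_col]
            .mean()
            .unstack(group_col)
        )
        if means.isna().any().any():
            raise UnitMismatchError(
                "chromosomes are not matched across groups for the paired test"
            )
        res = stats.wilcoxon(means[groups[0]], means[groups[1]])
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
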