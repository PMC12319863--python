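"""Classical statistics used throughout the analysis.

Thin, explicit wrappers with pinned conventions: Welch's t-test (summary
or raw data), pooled-SD Cohen's d, 2x2 chi-square with Cramer's V, two-way
ANOVA (fully between-subjects or mixed with one within factor), Fisher's
Z, Spearman correlation with Bonferroni correction, framewise
displacement, and the one-sample t-test. Every function returns a
:class:`StatResult` so downstream tables are uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


@dataclass
class StatResult:
    """A single test statistic with df, p, and effect sizes."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, table-friendly
        es = ", ".join(f"{k}={v:.3f}" for k, v in self.effect_sizes.items())
        return (
            f"StatResult({self.name}: stat={self.statistic:.3f}, "
            f"df={self.df}, p={self.p:.4g}{', ' + es if es else ''})"
        )


# ---------------------------------------------------------------------------
# t-tests and effect sizes


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """Welch's two-sample t-test from summary statistics.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2) with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("welch_t undefined when both SDs are zero")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    d = cohens_d(mean1, sd1, n1, mean2, sd2, n2)
    return StatResult("welch_t", float(t), float(df), float(p), {"cohens_d": d})


def welch_t_raw(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Welch's t-test from raw samples (delegates to :func:`welch_t`)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with the pooled standard deviation.

    For equal n the pooled SD reduces to sqrt((sd1^2 + sd2^2)/2); in
    general the (n-1)-weighted pooled formula is used.
    """
    pooled = math.sqrt(
        ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("cohens_d undefined for zero pooled SD")
    return (mean1 - mean2) / pooled


def one_sample_t(values: np.ndarray, mu0: float) -> StatResult:
    """One-sample t-test of mean(values) against mu0, two-sided.

    Cohen's d = (mean - mu0) / sd.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("one_sample_t requires n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("one_sample_t undefined for zero variance")
    t, p = sps.ttest_1samp(values, mu0)
    d = (values.mean() - mu0) / sd
    return StatResult("one_sample_t", float(t), n - 1, float(p), {"cohens_d": d})


# ---------------------------------------------------------------------------
# categorical


def chi_square_2x2(
    successes1: int, n1: int, successes2: int, n2: int, correction: bool = False
) -> StatResult:
    """Pearson chi-square on a 2x2 table of success counts, with Cramer's V.

    Continuity correction off by default. V = sqrt(chi2 / N).
    """
    table = np.array(
        [
            [successes1, n1 - successes1],
            [successes2, n2 - successes2],
        ]
    )
    if (table < 0).any():
        raise ValueError("counts must be nonnegative and successes <= n")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for empty table margins")
    # chi2_contingency errors on a zero expected count only when a margin
    # is empty, which is excluded above.
    chi2, p, df, _ = sps.chi2_contingency(table, correction=correction)
    v = math.sqrt(chi2 / table.sum())
    return StatResult("chi_square", float(chi2), float(df), float(p), {"cramers_v": v})


# ---------------------------------------------------------------------------
# ANOVA


def two_way_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    design: str = "between",
    subject: np.ndarray | None = None,
) -> dict[str, StatResult]:
    """Two-way ANOVA with both partial and generalized eta squared.

    Parameters
    ----------
    values, factor_a, factor_b
        Response and the two factors, one entry per observation.
    design
        ``"between"`` — both factors between-subjects (type-II SS);
        ``"mixed"`` — ``factor_a`` within-subjects, ``factor_b``
        between-subjects; requires ``subject`` ids.

    Returns a dict keyed by ``"factor_a"``, ``"factor_b"``,
    ``"interaction"``.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a),
            "b": np.asarray(factor_b),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")

    if design == "between":
        model = ols("value ~ C(a) * C(b)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        ss_err = float(table.loc["Residual", "sum_sq"])
        out: dict[str, StatResult] = {}
        for key, row_name in [
            ("factor_a", "C(a)"),
            ("factor_b", "C(b)"),
            ("interaction", "C(a):C(b)"),
        ]:
            ss = float(table.loc[row_name, "sum_sq"])
            df1 = float(table.loc[row_name, "df"])
            df2 = float(table.loc["Residual", "df"])
            f = float(table.loc[row_name, "F"])
            p = float(table.loc[row_name, "PR(>F)"])
            out[key] = StatResult(
                f"anova_{key}",
                f,
                (df1, df2),
                p,
                {
                    "partial_eta_sq": ss / (ss + ss_err),
                    "generalized_eta_sq": ss / (ss + ss_err),
                },
            )
        return out

    if design == "mixed":
        if subject is None:
            raise ValueError("mixed design requires subject ids")
        df["subject"] = np.asarray(subject)
        table = pg.mixed_anova(
            data=df, dv="value", within="a", between="b", subject="subject"
        ).set_index("Source")
        # error SS per stratum, reconstructed from MS_effect / F
        ss_err = {}
        for src in table.index:
            row = table.loc[src]
            ms_eff = row["SS"] / row["DF1"]
            ms_err = ms_eff / row["F"]
            ss_err[src] = ms_err * row["DF2"]
        ss_err_total = ss_err["b"] + ss_err["a"]  # between + within strata
        out = {}
        for key, src in [
            ("factor_a", "a"),
            ("factor_b", "b"),
            ("interaction", "Interaction"),
        ]:
            row = table.loc[src]
            ss = float(row["SS"])
            out[key] = StatResult(
                f"anova_{key}",
                float(row["F"]),
                (float(row["DF1"]), float(row["DF2"])),
                float(row["p_unc"]),
                {
                    "partial_eta_sq": ss / (ss + ss_err["a" if src != "b" else "b"]),
                    "generalized_eta_sq": ss / (ss + ss_err_total),
                },
            )
        return out

    raise ValueError(f"unknown design {design!r}")


def pairwise_bonferroni(
    values: np.ndarray, levels: np.ndarray, paired_by: np.ndarray | None = None
) -> pd.DataFrame:
    """Post-hoc pairwise t-tests between factor levels, Bonferroni-corrected.

    If ``paired_by`` (subject ids) is given, paired t-tests are used.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    uniq = list(pd.unique(levels))
    rows = []
    n_pairs = len(uniq) * (len(uniq) - 1) // 2
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            xi = values[levels == uniq[i]]
            xj = values[levels == uniq[j]]
            if paired_by is not None:
                si = paired_by[levels == uniq[i]]
                sj = paired_by[levels == uniq[j]]
                order_i = np.argsort(si)
                order_j = np.argsort(sj)
                t, p = sps.ttest_rel(xi[order_i], xj[order_j])
            else:
                t, p = sps.ttest_ind(xi, xj)
            rows.append(
                {
                    "level_1": uniq[i],
                    "level_2": uniq[j],
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonferroni": min(1.0, float(p) * n_pairs),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing Z transform, Z = atanh(r)."""
    if abs(r) >= 1:
        raise ValueError("fisher_z requires |r| < 1")
    return math.atanh(r)


def spearman_bonferroni(
    x: np.ndarray, y: np.ndarray, family: int = 1
) -> StatResult:
    """Spearman's rho with Bonferroni-corrected p for a stated family size.

    Returns NaN statistic/p when an input is constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman requires paired data with n >= 3")
    if family < 1:
        raise ValueError("family size must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            "spearman", float("nan"), len(x) - 2, float("nan"), {"family": family}
        )
    rho, p = sps.spearmanr(x, y)
    return StatResult(
        "spearman",
        float(rho),
        len(x) - 2,
        float(p),
        {"p_bonferroni": min(1.0, float(p) * family), "family": family},
    )


# ---------------------------------------------------------------------------
# motion quality control


def framewise_displacement(
    motion: np.ndarray, head_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Per-volume framewise displacement and its mean.

    FD_t = sum |Delta translation| + head_radius * sum |Delta rotation|,
    translations in mm, rotations in radians projected onto a sphere of
    ``head_radius`` mm. The first volume has FD = 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6): 3 translations + 3 rotations")
    if motion.shape[0] < 2:
        raise ValueError("framewise displacement needs >= 2 volumes")
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + head_radius * delta[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return fd, float(fd.mean())
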