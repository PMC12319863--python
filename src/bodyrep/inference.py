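"""Inference on representational geometry.

ANOSIM with an exhaustive null over all 420 labeled 4/2/2 partitions of
the 8 body parts, the Mantel matrix-correlation test with complete 8!
enumeration, within/between-group RDM similarity with a mixed two-way
ANOVA on Fisher-Z correlations, and Spearman trait correlations with
Bonferroni correction.

A note on the 420-model null: the two size-2 categories (face,
non-effector) are interchangeable labels as far as the rank-based ANOSIM
R is concerned, so the 420 labeled models comprise 210 structurally
distinct partitions, each contributing its R value exactly twice. The
exhaustive p-value therefore has a floor of 2/420 ~ 0.005 for any matrix
whose hypothesized partition strictly beats every distinct alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import stats
from .conditions import BODY_PARTS, CATEGORY_LABELS, HYPOTHESIZED_CATEGORIES
from .rsa import DissimilarityMatrix, aggregate_rdms


@dataclass(frozen=True)
class PartitionModel:
    """Assignment of conditions to the three labeled categories (sizes 4/2/2)."""

    assignment: tuple[str, ...]  # category label per condition, canonical order
    conditions: tuple[str, ...] = BODY_PARTS
    sizes: tuple[int, ...] = (4, 2, 2)
    labels: tuple[str, ...] = CATEGORY_LABELS

    def __post_init__(self) -> None:
        if len(self.assignment) != len(self.conditions):
            raise ValueError("one category per condition required")
        counts = tuple(self.assignment.count(lab) for lab in self.labels)
        if counts != self.sizes:
            raise ValueError(f"category sizes {counts} != required {self.sizes}")

    def category_of(self, condition: str) -> str:
        return self.assignment[self.conditions.index(condition)]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.conditions, self.assignment))

    def within_mask(self) -> np.ndarray:
        """Boolean upper-triangle vector: True where a pair shares a category."""
        a = np.asarray(self.assignment)
        iu = np.triu_indices(len(a), k=1)
        return a[iu[0]] == a[iu[1]]


def hypothesized_partition() -> PartitionModel:
    """Effector = {hand, foot, arm, leg}; face = {UF, LF}; non-effector = {chest, waist}."""
    return PartitionModel(
        assignment=tuple(HYPOTHESIZED_CATEGORIES[c] for c in BODY_PARTS)
    )


def enumerate_partitions(
    conditions: tuple[str, ...] = BODY_PARTS,
    sizes: tuple[int, ...] = (4, 2, 2),
    labels: tuple[str, ...] = CATEGORY_LABELS,
) -> list[PartitionModel]:
    """All labeled assignments of conditions to categories of the given sizes.

    For 8 conditions and sizes (4, 2, 2) this yields 8!/(4! 2! 2!) = 420
    models, in a deterministic order with the hypothesized model first
    (when enumerating the canonical body parts).
    """
    if sum(sizes) != len(conditions):
        raise ValueError("sizes must sum to the condition count")
    n = len(conditions)
    models: list[PartitionModel] = []
    idx = list(range(n))
    for first in itertools.combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in first]
        for second in itertools.combinations(rest1, sizes[1]):
            assign = [labels[2]] * n
            for i in first:
                assign[i] = labels[0]
            for i in second:
                assign[i] = labels[1]
            models.append(
                PartitionModel(
                    assignment=tuple(assign),
                    conditions=conditions,
                    sizes=sizes,
                    labels=labels,
                )
            )
    if conditions == BODY_PARTS and sizes == (4, 2, 2) and labels == CATEGORY_LABELS:
        hyp = hypothesized_partition()
        pos = models.index(hyp)
        models.insert(0, models.pop(pos))
    return models


@dataclass
class AnosimResult:
    """ANOSIM R with its exhaustive partition-permutation null."""

    r: float
    p: float
    null_distribution: np.ndarray  # one R per enumerated model
    model: PartitionModel


@dataclass
class MantelResult:
    r: float
    p: float
    scheme: str
    n_permutations: int


@dataclass
class GroupSimilarityResult:
    """Fisher-Z within/between-group RDM correlations and their mixed ANOVA."""

    z_table: pd.DataFrame  # columns: subject, group, type, r, z
    anova: dict[str, stats.StatResult]


def anosim_r(D: DissimilarityMatrix, model: PartitionModel) -> float:
    """Rank-based ANOSIM statistic R = (rbar_between - rbar_within) / (M/2).

    The M = n(n-1)/2 off-diagonal dissimilarities are ranked with average
    ranks for ties; rbar_between and rbar_within are the mean ranks of
    pairs spanning and sharing a category. R is in [-1, 1]; values near 1
    indicate strong category separation.
    """
    vec = D.offdiag()
    ranks = sps.rankdata(vec)
    within = model.within_mask()
    m = len(vec)
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim_test(
    D: DissimilarityMatrix, hypothesized: PartitionModel | None = None
) -> AnosimResult:
    """Exhaustive permutation test of the hypothesized partition.

    R is computed for every enumerated model (420 for 8 conditions,
    4/2/2); p is the fraction of models with R >= the hypothesized R, the
    hypothesized model included, giving a minimum possible p of 1/420.
    """
    if hypothesized is None:
        hypothesized = hypothesized_partition()
    models = enumerate_partitions(
        hypothesized.conditions, hypothesized.sizes, hypothesized.labels
    )
    vec = D.offdiag()
    ranks = sps.rankdata(vec)
    m = len(vec)
    null = np.empty(len(models))
    for k, model in enumerate(models):
        within = model.within_mask()
        null[k] = (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)
    r_obs = anosim_r(D, hypothesized)
    p = float((null >= r_obs - 1e-12).sum()) / len(models)
    return AnosimResult(r=r_obs, p=p, null_distribution=null, model=hypothesized)


def mantel_test(
    D1: DissimilarityMatrix,
    D2: DissimilarityMatrix,
    scheme: str = "complete",
    n_permutations: int = 10000,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson r between off-diagonal dissimilarities.

    The null permutes the condition labels of the second matrix: complete
    enumeration of all n! relabelings (feasible at n = 8: 40,320) or
    Monte-Carlo sampling. One-sided: p = fraction of permuted r >= the
    observed r, identity included.
    """
    if D1.conditions != D2.conditions:
        raise ValueError("matrices must share the condition order")
    n = D1.n
    v1 = D1.offdiag()
    if np.ptp(v1) == 0 or np.ptp(D2.offdiag()) == 0:
        raise ValueError("Mantel r undefined for constant off-diagonal values")
    iu = np.triu_indices(n, k=1)
    if scheme == "complete":
        perms = np.array(list(itertools.permutations(range(n))))
    elif scheme == "monte_carlo":
        rng = np.random.default_rng([seed, 49979687])
        perms = np.vstack(
            [np.arange(n)] + [rng.permutation(n) for _ in range(n_permutations - 1)]
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # permuted off-diagonal vectors of D2, all at once
    vals = D2.values[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perms, m)
    z1 = (v1 - v1.mean()) / v1.std()
    vz = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    rs = vz @ z1 / len(v1)
    r_obs = float(rs[0]) if scheme == "monte_carlo" else float(
        np.corrcoef(v1, D2.offdiag())[0, 1]
    )
    p = float((rs >= r_obs - 1e-12).sum()) / len(rs)
    return MantelResult(r=r_obs, p=p, scheme=scheme, n_permutations=len(rs))


def within_between_similarity(
    rdms: list[DissimilarityMatrix],
) -> GroupSimilarityResult:
    """Within- vs between-group RDM similarity on Fisher-Z correlations.

    For each subject: Pearson r between the subject's off-diagonal vector
    and (i) the leave-one-out mean RDM of the subject's own group, (ii)
    the full mean RDM of the other group. Z = atanh(r). A mixed two-way
    ANOVA (correlation type within-subject, group between-subject) tests
    for geometry differences.
    """
    groups = sorted({m.group for m in rdms})
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    by_group = {g: [m for m in rdms if m.group == g] for g in groups}
    if min(len(v) for v in by_group.values()) < 2:
        raise ValueError(">= 2 subjects per group required")
    full_mean = {g: aggregate_rdms(by_group[g]).offdiag() for g in groups}
    rows = []
    for g in groups:
        other = groups[1] if g == groups[0] else groups[0]
        for m in by_group[g]:
            own = aggregate_rdms(by_group[g], leave_out=m.subject).offdiag()
            v = m.offdiag()
            if np.ptp(v) == 0:
                raise ValueError(f"degenerate (constant) RDM for {m.subject}")
            for kind, ref in (("within", own), ("between", full_mean[other])):
                r = float(np.corrcoef(v, ref)[0, 1])
                rows.append(
                    {
                        "subject": m.subject,
                        "group": g,
                        "type": kind,
                        "r": r,
                        "z": stats.fisher_z(r),
                    }
                )
    table = pd.DataFrame(rows)
    anova = stats.two_way_anova(
        table["z"].to_numpy(),
        table["type"].to_numpy(),
        table["group"].to_numpy(),
        design="mixed",
        subject=table["subject"].to_numpy(),
    )
    return GroupSimilarityResult(z_table=table, anova=anova)


def subject_anosim_r(
    rdms: list[DissimilarityMatrix], model: PartitionModel | None = None
) -> pd.DataFrame:
    """Per-subject ANOSIM R values (columns: subject, group, anosim_r)."""
    if model is None:
        model = hypothesized_partition()
    return pd.DataFrame(
        {
            "subject": [m.subject for m in rdms],
            "group": [m.group for m in rdms],
            "anosim_r": [anosim_r(m, model) for m in rdms],
        }
    )


def trait_correlations(
    subject_r: pd.DataFrame,
    traits: pd.DataFrame,
    trait_columns: list[str] | None = None,
    family: int = 16,
) -> pd.DataFrame:
    """Spearman rho between per-subject ANOSIM R and each trait score.

    ``family`` is the Bonferroni family size (default 16: 8 traits x 2
    hemispheres, the full analysis family). Constant traits yield NaN rho,
    reported as missing rather than dropped.
    """
    merged = subject_r.merge(traits, on="subject", suffixes=("", "_trait"))
    if len(merged) != len(subject_r):
        raise ValueError("subjects in R table and trait table do not align")
    if trait_columns is None:
        trait_columns = [
            c
            for c in traits.columns
            if c not in ("subject", "group") and pd.api.types.is_numeric_dtype(traits[c])
        ]
    rows = []
    for col in trait_columns:
        res = stats.spearman_bonferroni(
            merged["anosim_r"].to_numpy(), merged[col].to_numpy(), family=family
        )
        rows.append(
            {
                "trait": col,
                "rho": res.statistic,
                "p_raw": res.p,
                "p_bonferroni": res.effect_sizes.get("p_bonferroni", float("nan"))
                if not math.isnan(res.statistic)
                else float("nan"),
                "n": len(merged),
            }
        )
    return pd.DataFrame(rows)
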