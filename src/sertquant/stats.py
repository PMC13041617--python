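"""Group-comparison and diagnostic-performance statistics.

Nonparametric two-group comparison (Mann-Whitney U), Fisher's exact test
for sex distributions, age-adjusted ANCOVA by ordinary least squares, and
empirical ROC analysis with the Youden-index optimal cutoff.  Significance
is two-sided at alpha = 0.05 throughout; p values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupSamples",
    "MannWhitneyResult",
    "AncovaResult",
    "RocResult",
    "mann_whitney",
    "fisher_exact",
    "ancova_group_effect",
    "roc_analysis",
]


@dataclass(frozen=True)
class GroupSamples:
    """Observations for two groups, optionally with per-subject ages."""

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple[str, str] = ("MSA-P", "HC")
    ages_a: np.ndarray | None = None
    ages_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be nonempty")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        for name in ("ages_a", "ages_b"):
            ages = getattr(self, name)
            if ages is not None:
                ages = np.asarray(ages, dtype=float)
                vals = a if name == "ages_a" else b
                if ages.size != vals.size:
                    raise ValueError(f"{name} length does not match values")
                object.__setattr__(self, name, ages)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of group A
    p: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class AncovaResult:
    group_coef: float  # effect of group A relative to group B
    group_se: float
    group_p: float
    age_coef: float
    age_p: float


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary.

    ``direction`` states the positive decision rule ("<=" when the positive
    group takes lower metric values, ">=" otherwise), chosen automatically
    so that AUC >= 0.5.  ``cutoff`` is the observed metric value maximizing
    Youden's J = sensitivity + specificity - 1; J-ties are broken toward
    higher specificity.
    """

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    positive_label: str
    youden_j: float


def mann_whitney(samples: GroupSamples) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (U reported for group A).

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with
    tie and continuity corrections.
    """
    a, b = samples.values_a, samples.values_b
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (pooled.size <= 20) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(
        float(res.statistic), float(res.pvalue), "exact" if exact else "asymptotic"
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables at most as probable as
    the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def ancova_group_effect(samples: GroupSamples) -> AncovaResult:
    """Age-adjusted group comparison: OLS fit of outcome ~ group + age.

    The group indicator is 1 for group A, so ``group_coef`` is the adjusted
    mean difference A - B; p values are two-sided t tests.
    """
    if samples.ages_a is None or samples.ages_b is None:
        raise ValueError("ANCOVA requires ages for both groups")
    y = np.concatenate([samples.values_a, samples.values_b])
    if y.size < 4:
        raise ValueError("ANCOVA requires a combined sample size of at least 4")
    group = np.concatenate(
        [np.ones(samples.values_a.size), np.zeros(samples.values_b.size)]
    )
    age = np.concatenate([samples.ages_a, samples.ages_b])
    X = sm.add_constant(np.column_stack([group, age]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (group and age collinear)")
    fit = sm.OLS(y, X).fit()
    return AncovaResult(
        group_coef=float(fit.params[1]),
        group_se=float(fit.bse[1]),
        group_p=float(fit.pvalues[1]),
        age_coef=float(fit.params[2]),
        age_p=float(fit.pvalues[2]),
    )


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos = neg) via midranks (ties counted half)."""
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    n1, n2 = pos.size, neg.size
    u_pos = r_pos - n1 * (n1 + 1) / 2.0
    return u_pos / (n1 * n2)


def roc_analysis(samples: GroupSamples, positive_label: str | None = None) -> RocResult:
    """Empirical ROC with trapezoidal AUC and Youden-optimal cutoff.

    The decision direction is detected automatically: if the positive
    group's values tend to be lower, positivity is declared for metric <=
    cutoff (the midbrain-to-pons ratio case), otherwise for metric >=
    cutoff.  The reported cutoff is an observed metric value.
    """
    if positive_label is None:
        positive_label = samples.labels[0]
    if positive_label == samples.labels[0]:
        pos, neg = samples.values_a, samples.values_b
    elif positive_label == samples.labels[1]:
        pos, neg = samples.values_b, samples.values_a
    else:
        raise ValueError(f"unknown positive label {positive_label!r}")

    auc_ge = _auc_rank(pos, neg)  # AUC for the "higher value = positive" rule
    if auc_ge >= 0.5:
        direction, auc = ">=", auc_ge
        score_pos, score_neg = pos, neg
    else:
        direction, auc = "<=", 1.0 - auc_ge
        score_pos, score_neg = -pos, -neg

    best = None
    for c in np.unique(np.concatenate([score_pos, score_neg])):
        sens = float((score_pos >= c).mean())
        spec = float((score_neg < c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, c)
    j, sens, spec, c = best
    cutoff = float(c if direction == ">=" else -c)
    return RocResult(
        auc=float(auc),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        positive_label=positive_label,
        youden_j=float(j),
    )
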