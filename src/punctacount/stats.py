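"""Group statistics for per-cell counts, cells per field and densitometry.

The workflow: Shapiro–Wilk normality screening; one-way ANOVA with Tukey's
HSD for approximately normal data (densitometry, cells per field); the
Kruskal–Wallis rank test with Dunn's post-hoc z tests and Bonferroni
adjustment for the heavily tied, skewed per-cell puncta counts.  Box
summaries report mean, median and the 10th/90th percentiles (linear
interpolation between closest ranks).

The Kruskal–Wallis H and the Dunn variance both carry the tie correction
Σ(t³−t); per-cell counts are small integers, so ties dominate and the
correction is essential.  The Shapiro–Wilk gate is advisory: callers get
both parametric and nonparametric results plus a flag saying which one the
normality rule selects.

A ``power_check`` utility calibrates the whole decision chain against the
synthetic generator's negative-binomial count model: it estimates the
rejection rate of the Dunn contrast under a configured effect (or under the
null, where the rate should sit near the nominal α).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import sample_puncta_counts

__all__ = [
    "GroupSample",
    "TestResult",
    "normality_check",
    "anova_tukey",
    "kruskal_dunn",
    "summarize_box",
    "analyze_groups",
    "power_check",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSample:
    """A named sample of values (counts, cells/field, or % of control)."""

    group: str
    values: tuple[float, ...]
    baf_pretreated: bool = False

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"group {self.group!r} has no values")


@dataclass(frozen=True)
class TestResult:
    """Omnibus statistic with an optional pairwise post-hoc table."""

    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def normality_check(sample: GroupSample) -> TestResult:
    """Shapiro–Wilk test of normality; requires n ≥ 3."""
    values = np.asarray(sample.values, dtype=float)
    if values.size < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got n={values.size}")
    if np.ptp(values) == 0:
        # degenerate constant sample: W undefined, report non-normal
        return TestResult("shapiro_wilk", float("nan"), 0.0)
    stat, p = sps.shapiro(values)
    return TestResult("shapiro_wilk", float(stat), float(min(max(p, 0.0), 1.0)))


def anova_tukey(groups: list[GroupSample]) -> TestResult:
    """One-way ANOVA with Tukey's HSD pairwise table.

    Groups whose means are all equal give F = 0 with p = 1 (including the
    fully degenerate all-constant case where the F ratio is 0/0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    if ss_between == 0:
        posthoc = pd.DataFrame(
            [
                {"group1": groups[i].group, "group2": groups[j].group,
                 "statistic": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                for i, j in pairs
            ]
        )
        return TestResult("anova_tukey", 0.0, 1.0, posthoc)

    f_stat, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in pairs:
        p_adj = float(tukey.pvalue[i, j])
        rows.append(
            {"group1": groups[i].group, "group2": groups[j].group,
             "statistic": float(tukey.statistic[i, j]),
             "p_raw": p_adj,  # Tukey p-values are family-wise by construction
             "p_adj": p_adj}
        )
    return TestResult("anova_tukey", float(f_stat), float(p), pd.DataFrame(rows))


def _dunn_table(groups: list[GroupSample]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks, tie-corrected, Bonferroni."""
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_factor = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance_factor -= tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se2 = variance_factor * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if se2 <= 0:  # all values tied: no evidence of any difference
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        rows.append(
            {"group1": groups[i].group, "group2": groups[j].group,
             "statistic": float(z), "p_raw": p_raw,
             "p_adj": float(min(1.0, p_raw * m))}
        )
    return pd.DataFrame(rows)


def kruskal_dunn(groups: list[GroupSample]) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn/Bonferroni post-hoc table.

    Identical constant groups (all observations tied) give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    if sum(a.size for a in arrays) < 5:
        raise ValueError("Kruskal–Wallis needs total n >= 5")
    try:
        with np.errstate(invalid="ignore"):
            h_stat, p = sps.kruskal(*arrays)
        h_stat, p = float(h_stat), float(p)
    except ValueError:
        h_stat, p = float("nan"), float("nan")
    if not (np.isfinite(h_stat) and np.isfinite(p)):
        # every observation identical: the tie correction divides 0 by 0,
        # but a fully tied pooled sample carries no evidence, so H = 0
        h_stat, p = 0.0, 1.0
    return TestResult("kruskal_dunn", h_stat, min(max(p, 0.0), 1.0),
                      _dunn_table(groups))


def summarize_box(sample: GroupSample) -> dict[str, float]:
    """Mean, median and 10th/90th percentiles (linear interpolation)."""
    values = np.asarray(sample.values, dtype=float)
    if values.size < 1:
        raise ValueError("need n >= 1")
    return {
        "group": sample.group,
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "p10": float(np.percentile(values, 10)),
        "p90": float(np.percentile(values, 90)),
    }


@dataclass(frozen=True)
class GroupAnalysis:
    """Both test tracks plus the advisory normality-based selection."""

    shapiro: list[TestResult]
    parametric: TestResult
    nonparametric: TestResult
    selected: str  # "parametric" | "nonparametric"


def analyze_groups(groups: list[GroupSample], alpha: float = ALPHA) -> GroupAnalysis:
    """Run both tracks; flag which one the Shapiro–Wilk rule selects.

    The rule: if every group with n ≥ 3 passes Shapiro–Wilk at ``alpha``,
    the parametric track (ANOVA/Tukey) is flagged, otherwise the
    nonparametric one (Kruskal–Wallis/Dunn).  Both results are returned
    either way.
    """
    shapiro = [normality_check(g) for g in groups if len(g.values) >= 3]
    all_normal = bool(shapiro) and all(r.p_value > alpha for r in shapiro)
    return GroupAnalysis(
        shapiro=shapiro,
        parametric=anova_tukey(groups),
        nonparametric=kruskal_dunn(groups),
        selected="parametric" if all_normal else "nonparametric",
    )


@dataclass(frozen=True)
class EffectConfig:
    """Count-model effect layout for power/type-I simulation: group name →
    multiplier on the baseline negative-binomial mean."""

    multipliers: dict[str, float] = field(default_factory=lambda: {"control": 1.0,
                                                                   "treated": 1.0})
    base_mean: float = 8.0
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if len(self.multipliers) < 2:
            raise ValueError("need at least 2 groups")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be > 0")

    @property
    def contrast(self) -> tuple[str, str]:
        """Reference group vs the first group with multiplier ≠ 1 (or the
        last group under a pure null)."""
        names = list(self.multipliers)
        affected = next((g for g in names[1:] if self.multipliers[g] != 1.0),
                        names[-1])
        return names[0], affected


def power_check(
    effect_config: EffectConfig,
    n_per_group: int = 100,
    n_sims: int = 500,
    seed: int = 0,
    alpha: float = ALPHA,
) -> float:
    """Rejection rate of the Dunn contrast over simulated count studies.

    Each simulation draws negative-binomial per-cell counts for every group,
    runs ``kruskal_dunn`` and checks whether the Bonferroni-adjusted p of
    the affected contrast is below ``alpha``.  Under a null configuration
    (all multipliers 1) the returned rate estimates the type-I error.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ref, affected = effect_config.contrast
    rejections = 0
    for _ in range(n_sims):
        groups = [
            GroupSample(
                group=name,
                values=tuple(
                    sample_puncta_counts(
                        rng, effect_config.base_mean * mult,
                        effect_config.dispersion, n_per_group
                    ).tolist()
                ),
            )
            for name, mult in effect_config.multipliers.items()
        ]
        table = kruskal_dunn(groups).posthoc
        row = table[
            ((table.group1 == ref) & (table.group2 == affected))
            | ((table.group1 == affected) & (table.group2 == ref))
        ]
        if float(row.iloc[0].p_adj) < alpha:
            rejections += 1
    return rejections / n_sims
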