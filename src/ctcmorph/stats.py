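"""Cohort summaries and nonparametric group comparisons.

Per cohort the size analysis reports the median area (μm²), the IQR as the
single width Q3 − Q1 (linear-interpolation quantiles), the computed
diameter of the median area, and — when nucleus data exist — the median
nucleus area and the NCR (median of per-event ratios; the ratio of medians
is reported alongside). Group differences are tested with the
Kruskal–Wallis test, pairwise two-sided Mann–Whitney U tests, and the
independent-samples median test, without multiplicity correction unless
requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .morphometry import equivalent_diameter

__all__ = [
    "GroupSummary",
    "TestResult",
    "ComparisonPlan",
    "summarize_group",
    "kruskal_wallis",
    "mann_whitney_u",
    "median_test",
    "run_comparisons",
    "bonferroni_adjust",
    "format_p",
]


@dataclass
class GroupSummary:
    """Size (and optionally nucleus) summary of one cohort."""

    group: str
    material: str = "blood"
    n: int = 0
    median_area: float | None = None
    iqr_area: float | None = None
    cd: float | None = None
    median_dapi_area: float | None = None
    ncr: float | None = None
    ncr_of_medians: float | None = None


@dataclass
class TestResult:
    """Outcome of one nonparametric comparison."""

    test: str
    groups: tuple[str, ...]
    statistic: float | None
    p_value: float | None
    n_per_group: tuple[int, ...]
    quantity: str = "ck_area"


def summarize_group(
    values: Sequence[float],
    group: str,
    material: str = "blood",
    *,
    dapi_values: Sequence[float] | None = None,
    ncr_values: Sequence[float] | None = None,
) -> GroupSummary:
    """Summarize one cohort's area distribution (median, IQR width, CD).

    An empty cohort yields ``n = 0`` with undefined statistics rather than
    an error.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("areas must be nonnegative")
    out = GroupSummary(group=group, material=material, n=len(values))
    if len(values) == 0:
        return out
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    out.median_area = float(med)
    out.iqr_area = float(q3 - q1)
    out.cd = equivalent_diameter(float(med))
    if dapi_values is not None and len(dapi_values):
        out.median_dapi_area = float(np.median(dapi_values))
        if out.median_area:
            out.ncr_of_medians = out.median_dapi_area / out.median_area
    if ncr_values is not None and len(ncr_values):
        out.ncr = float(np.median(ncr_values))
    return out


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None, *, quantity: str = "ck_area"
) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square p with k−1 df)."""
    if len(groups) < 2:
        raise ValueError(f"Kruskal-Wallis needs at least 2 groups, got {len(groups)}")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    labels = tuple(labels) if labels is not None else tuple(f"group{i}" for i in range(len(groups)))
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*groups)
    return TestResult(
        test="kruskal_wallis",
        groups=labels,
        statistic=float(stat),
        p_value=float(p),
        n_per_group=tuple(len(g) for g in groups),
        quantity=quantity,
    )


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    *,
    quantity: str = "ck_area",
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        test="mann_whitney_u",
        groups=labels,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(len(a), len(b)),
        quantity=quantity,
    )


def median_test(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None, *, quantity: str = "ck_area"
) -> TestResult:
    """Independent-samples median test.

    Each value is classified as above vs at-or-below the pooled median and
    the resulting contingency table tested with chi-square. When the
    classification is degenerate (e.g. all values equal) the result is
    reported as undefined rather than raising.
    """
    if len(groups) < 2:
        raise ValueError(f"median test needs at least 2 groups, got {len(groups)}")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    labels = tuple(labels) if labels is not None else tuple(f"group{i}" for i in range(len(groups)))
    n_per_group = tuple(len(g) for g in groups)
    try:
        res = sps.median_test(*groups, ties="below")
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:
        stat, p = None, None
    return TestResult(
        test="median_test",
        groups=labels,
        statistic=stat,
        p_value=p,
        n_per_group=n_per_group,
        quantity=quantity,
    )


def median_test_table(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """2×k contingency table (above / at-or-below the pooled median)."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = np.median(pooled)
    above = [int(np.sum(np.asarray(g) > grand)) for g in groups]
    below = [len(g) - a for g, a in zip(groups, above)]
    return np.array([above, below])


@dataclass
class ComparisonPlan:
    """The published comparison plan expressed over cohort names.

    ``tumor_cohorts`` are compared jointly (KW + median test) and pairwise
    (MWU). ``liquor_pairs`` compares fluids within a tumor type (skipped
    with a warning when the liquor cohort is absent). ``cell_line_pairs``
    compares patient CTCs with the matching cultured cells, and every
    tumor cohort is compared against ``leukocyte_cohort``.
    """

    tumor_cohorts: tuple[str, ...] = (
        "breast_blood",
        "prostate_blood",
        "colorectal_blood",
        "bladder_blood",
    )
    liquor_pairs: tuple[tuple[str, str], ...] = (("breast_blood", "breast_liquor"),)
    cell_line_pairs: tuple[tuple[str, str], ...] = (
        ("breast_blood", "breast_cell_line_blood"),
        ("prostate_blood", "prostate_cell_line_blood"),
    )
    leukocyte_cohort: str | None = "leukocyte_blood"
    include_median_test: bool = True


def run_comparisons(
    samples: Mapping[str, Sequence[float]],
    plan: ComparisonPlan | None = None,
    *,
    quantity: str = "ck_area",
    bonferroni: bool = False,
) -> list[TestResult]:
    """Execute the comparison plan on per-cohort value arrays.

    Required cohorts (tumor types) missing from ``samples`` raise a
    validation error listing them; optional cohorts (liquor, cell lines,
    leukocytes) are skipped with a warning.
    """
    plan = plan or ComparisonPlan()
    missing = [name for name in plan.tumor_cohorts if name not in samples or len(samples[name]) == 0]
    if missing:
        raise ValueError(f"cohorts required by the comparison plan are missing or empty: {missing}")

    def has(name: str | None) -> bool:
        return name is not None and name in samples and len(samples[name]) > 0

    results: list[TestResult] = []
    tumor = list(plan.tumor_cohorts)
    results.append(kruskal_wallis([samples[t] for t in tumor], tumor, quantity=quantity))
    if plan.include_median_test:
        results.append(median_test([samples[t] for t in tumor], tumor, quantity=quantity))
    for i in range(len(tumor)):
        for j in range(i + 1, len(tumor)):
            results.append(
                mann_whitney_u(
                    samples[tumor[i]], samples[tumor[j]], (tumor[i], tumor[j]), quantity=quantity
                )
            )
    for blood, liquor in plan.liquor_pairs:
        if not has(liquor):
            warnings.warn(f"cohort {liquor!r} absent; fluid comparison skipped")
            continue
        results.append(mann_whitney_u(samples[blood], samples[liquor], (blood, liquor), quantity=quantity))
    for patient, cel in plan.cell_line_pairs:
        if not has(cel):
            warnings.warn(f"cohort {cel!r} absent; cell-line comparison skipped")
            continue
        results.append(mann_whitney_u(samples[patient], samples[cel], (patient, cel), quantity=quantity))
    if plan.leukocyte_cohort is not None:
        if not has(plan.leukocyte_cohort):
            warnings.warn(f"cohort {plan.leukocyte_cohort!r} absent; leukocyte comparisons skipped")
        else:
            for t in tumor:
                results.append(
                    mann_whitney_u(
                        samples[plan.leukocyte_cohort],
                        samples[t],
                        (plan.leukocyte_cohort, t),
                        quantity=quantity,
                    )
                )
    if bonferroni:
        results = bonferroni_adjust(results)
    return results


def bonferroni_adjust(results: Sequence[TestResult]) -> list[TestResult]:
    """Bonferroni-correct the p-values of a batch of results."""
    m = len(results)
    return [
        replace(r, p_value=min(1.0, r.p_value * m)) if r.p_value is not None else replace(r)
        for r in results
    ]


def format_p(p: float | None) -> str:
    """Render a p-value the way the report presents it (3 decimals, '< 0.001')."""
    if p is None:
        return "undefined"
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"
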