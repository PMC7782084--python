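"""End-to-end analysis: gallery (or feature table) → measurements →
selection cascade → morphometry → cohort summaries → comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import P2ABins, apply_selection_cascade, compare_to_expert_counts, tabulate_counts
from .config import AnalysisConfig
from .features import EventRecord, measure_event
from .io import CohortManifest, read_feature_table, read_gallery
from .morphometry import morphometry_frame, morphometry_table
from .stats import ComparisonPlan, GroupSummary, TestResult, run_comparisons, summarize_group

__all__ = ["PipelineResult", "analyze_records", "run_gallery_analysis", "run_feature_table_analysis"]


def cohort_key(group: str, material: str) -> str:
    return f"{group}_{material}"


@dataclass
class PipelineResult:
    """Everything the analysis produces for one set of cartridges."""

    records: list[EventRecord]
    counts: pd.DataFrame
    morphometry: pd.DataFrame
    summaries: list[GroupSummary]
    comparisons: list[TestResult] = field(default_factory=list)
    expert_comparison: pd.DataFrame | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": s.group,
                    "material": s.material,
                    "n": s.n,
                    "median_area_um2": s.median_area,
                    "iqr_area_um2": s.iqr_area,
                    "cd_um": s.cd,
                    "median_dapi_area_um2": s.median_dapi_area,
                    "ncr": s.ncr,
                    "ncr_of_medians": s.ncr_of_medians,
                }
                for s in self.summaries
            ]
        )

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "test": t.test,
                    "quantity": t.quantity,
                    "groups": " vs ".join(t.groups),
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "n_per_group": "/".join(str(n) for n in t.n_per_group),
                }
                for t in self.comparisons
            ]
        )


def _size_samples(records: list[EventRecord]) -> dict[str, list[float]]:
    """Per-cohort size samples: CK area of size-eligible CTCs, CD45 area of leukocytes."""
    samples: dict[str, list[float]] = {}
    for r in records:
        if "leukocyte" in r.flags:
            samples.setdefault(cohort_key(r.group, r.material), []).append(r.cd45.area)
        elif "size_eligible" in r.flags:
            samples.setdefault(cohort_key(r.group, r.material), []).append(r.ck.area)
    return samples


def analyze_records(
    records: list[EventRecord],
    config: AnalysisConfig | None = None,
    *,
    manifest: CohortManifest | None = None,
    plan: ComparisonPlan | None = None,
) -> PipelineResult:
    """Classify measured records and produce counts, morphometry, summaries
    and (when the planned cohorts are present) the comparison battery."""
    config = config or AnalysisConfig()
    bins = P2ABins.from_edges(config.p2a_edges)
    records = apply_selection_cascade(records, bins)
    counts = tabulate_counts(records)
    morpho_rows = morphometry_table(records, convention=config.ncr_convention)
    morpho = morphometry_frame(morpho_rows)

    summaries = []
    for (group, material), sub in morpho.groupby(["group", "material"], sort=True):
        with_ncr = sub.dropna(subset=["ncr"])
        summaries.append(
            summarize_group(
                sub["ck_area_um2"].to_numpy(),
                group,
                material,
                dapi_values=with_ncr["dapi_area_um2"].to_numpy(),
                ncr_values=with_ncr["ncr"].to_numpy(),
            )
        )
    # leukocyte cohorts: size lives in the CD45 channel
    leuko = [r for r in records if "leukocyte" in r.flags]
    for (group, material) in sorted({(r.group, r.material) for r in leuko}):
        values = [r.cd45.area for r in leuko if (r.group, r.material) == (group, material)]
        summaries.append(summarize_group(values, group, material))

    samples = _size_samples(records)
    comparisons: list[TestResult] = []
    plan = plan or ComparisonPlan()
    required_present = all(samples.get(name) for name in plan.tumor_cohorts)
    if required_present:
        comparisons = run_comparisons(samples, plan, bonferroni=config.bonferroni)
        ncr_samples = {
            cohort_key(g, m): sub["ncr"].to_numpy()
            for (g, m), sub in morpho.dropna(subset=["ncr"]).groupby(["group", "material"])
        }
        nucleus_plan = ComparisonPlan(
            tumor_cohorts=plan.tumor_cohorts,
            liquor_pairs=plan.liquor_pairs,
            cell_line_pairs=plan.cell_line_pairs,
            leukocyte_cohort=None,
            include_median_test=plan.include_median_test,
        )
        if all(len(ncr_samples.get(name, ())) > 0 for name in plan.tumor_cohorts):
            dapi_samples = {
                cohort_key(g, m): sub["dapi_area_um2"].to_numpy()
                for (g, m), sub in morpho.dropna(subset=["dapi_area_um2"]).groupby(["group", "material"])
            }
            comparisons += run_comparisons(
                dapi_samples, nucleus_plan, quantity="dapi_area", bonferroni=config.bonferroni
            )
            comparisons += run_comparisons(
                ncr_samples, nucleus_plan, quantity="ncr", bonferroni=config.bonferroni
            )

    expert = compare_to_expert_counts(records, manifest) if manifest is not None else None
    return PipelineResult(
        records=records,
        counts=counts,
        morphometry=morpho,
        summaries=summaries,
        comparisons=comparisons,
        expert_comparison=expert,
    )


def run_gallery_analysis(
    gallery_dir: str | Path,
    manifest: CohortManifest,
    config: AnalysisConfig | None = None,
    *,
    plan: ComparisonPlan | None = None,
) -> PipelineResult:
    """Measure and analyze every event of an on-disk gallery."""
    config = config or AnalysisConfig()
    events = read_gallery(gallery_dir, manifest, default_pixel_size=config.pixel_size_um)
    records = [
        measure_event(
            ev,
            min_component_area_um2=config.min_component_area_um2,
            merge_distance_um=config.merge_distance_um,
            median_filter_size=config.median_filter_size,
        )
        for ev in events
    ]
    return analyze_records(records, config, manifest=manifest, plan=plan)


def run_feature_table_analysis(
    path: str | Path,
    config: AnalysisConfig | None = None,
    *,
    manifest: CohortManifest | None = None,
    plan: ComparisonPlan | None = None,
) -> PipelineResult:
    """Analyze pre-measured per-event features from a delimited table."""
    return analyze_records(read_feature_table(path), config, manifest=manifest, plan=plan)
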