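"""P2A binning, the selection cascade and cohort tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcmorph.classify import (
    P2ABins,
    apply_selection_cascade,
    classify_singularity,
    compare_to_expert_counts,
    counts_with_total,
    select_ctc_events,
    select_leukocytes,
    select_nucleus_evaluable,
    tabulate_counts,
)
from ctcmorph.io import CohortManifest, ManifestEntry

from conftest import make_record

BINS = P2ABins()


@pytest.mark.parametrize(
    "p2a,label",
    [
        (1.0, "single"),       # a round single cell
        (1.5, "doublet"),      # lower edge belongs to the doublet bin
        (2.49, "doublet"),
        (2.5, "small_cluster"),
        (4.0, "large_cluster"),  # upper edge closed for large clusters
        (0.0, "single"),
        (None, "undefined"),
    ],
)
def test_singularity_bins(p2a, label):
    assert classify_singularity(p2a, BINS) == label


def test_negative_p2a_rejected():
    with pytest.raises(ValueError):
        classify_singularity(-0.1, BINS)


def test_bin_edges_validated():
    with pytest.raises(ValueError):
        P2ABins(2.5, 1.5, 4.0)


@settings(max_examples=200, deadline=None)
@given(p2a=st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
def test_bins_partition_nonnegative_reals(p2a):
    labels = [classify_singularity(p2a, BINS)]
    assert labels[0] in ("single", "doublet", "small_cluster", "large_cluster")


# ---------------------------------------------------------------------------
# cascade


def test_ck_negative_event_not_size_eligible():
    (rec,) = select_ctc_events([make_record(ck=None, dapi=(50, 1.0))])
    assert "size_eligible" not in rec.flags
    assert rec.singularity_class == "undefined"


@pytest.mark.parametrize("p2a,eligible", [(1.2, True), (2.7, False)])
def test_ck_positive_eligibility_follows_bin(p2a, eligible):
    (rec,) = select_ctc_events([make_record(ck=(120, p2a))])
    assert ("size_eligible" in rec.flags) == eligible


@pytest.mark.parametrize(
    "dapi,ck,expected",
    [
        (None, (120, 1.1), False),          # DAPI size 0: not evaluable
        ((130, 1.1), (120, 1.1), False),    # nucleus not smaller than cytoplasm
        ((50, 1.1), (120, 1.1), True),
        ((50, 1.9), (120, 1.1), False),     # double nucleus: evaluable but not NCR-eligible
    ],
)
def test_nucleus_evaluability_rules(dapi, ck, expected):
    recs = select_ctc_events([make_record(ck=ck, dapi=dapi)])
    (rec,) = select_nucleus_evaluable(recs)
    assert ("ncr_eligible" in rec.flags) == expected


def test_double_nucleus_counts_as_evaluable_but_not_single():
    recs = select_ctc_events([make_record(ck=(120, 1.1), dapi=(50, 1.9))])
    (rec,) = select_nucleus_evaluable(recs)
    assert "dapi_evaluable" in rec.flags and "ncr_eligible" not in rec.flags
    assert rec.dapi_singularity_class == "double"


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(cd45=(60, 1.1), dapi=(40, 1.0)), True),
        (dict(cd45=(60, 1.1), dapi=(40, 1.0), ck=(50, 1.0)), False),  # CK+ events are not leukocytes
        (dict(cd45=(60, 1.8), dapi=(40, 1.0)), False),  # CD45 doublet fails the singularity rule
        (dict(cd45=(60, 1.1)), False),  # DAPI-negative
    ],
)
def test_leukocyte_selection(kwargs, expected):
    (rec,) = select_leukocytes([make_record(**kwargs)])
    assert ("leukocyte" in rec.flags) == expected


def _random_records(rng, n=200):
    recs = []
    for i in range(n):
        ck = None if rng.random() < 0.15 else (float(rng.lognormal(4.5, 0.6)), float(rng.uniform(0.9, 6)))
        dapi = None if rng.random() < 0.3 else (float(rng.lognormal(3.8, 0.6)), float(rng.uniform(0.9, 3)))
        cd45 = None if rng.random() < 0.7 else (float(rng.lognormal(4.0, 0.4)), float(rng.uniform(0.9, 3)))
        recs.append(
            make_record(
                event_id=f"e{i}",
                group=rng.choice(["breast", "prostate"]),
                material=rng.choice(["blood", "liquor"]),
                ck=ck,
                dapi=dapi,
                cd45=cd45,
            )
        )
    return recs


def test_cascade_monotonicity_on_random_cohort(rng):
    recs = apply_selection_cascade(_random_records(rng))
    detected = set(r.event_id for r in recs)
    ck_pos = {r.event_id for r in recs if r.ck.positive}
    size = {r.event_id for r in recs if "size_eligible" in r.flags}
    evaluable = {r.event_id for r in recs if "dapi_evaluable" in r.flags}
    ncr = {r.event_id for r in recs if "ncr_eligible" in r.flags}
    assert ncr <= evaluable <= size <= ck_pos <= detected


def test_tabulation_conservation_on_random_cohort(rng):
    recs = apply_selection_cascade(_random_records(rng))
    counts = tabulate_counts(recs)
    classes = counts[["single", "doublet", "small_cluster", "large_cluster"]].sum(axis=1)
    assert (classes == counts["ck_positive"]).all()
    dapi = counts[["dapi_single", "dapi_double", "dapi_clustered"]].sum(axis=1)
    assert (dapi == counts["dapi_evaluable"]).all()
    assert (counts["dapi_evaluable"] <= counts["single"]).all()
    total = counts_with_total(counts)
    assert (total.loc[("total", "")] == counts.sum(axis=0)).all()


def test_tabulate_known_composition():
    recs = [make_record(event_id=f"s{i}", ck=(100, 1.0)) for i in range(10)]
    recs += [make_record(event_id=f"d{i}", ck=(100, 2.0)) for i in range(2)]
    counts = tabulate_counts(apply_selection_cascade(recs))
    row = counts.loc[("g", "blood")]
    assert row["ck_positive"] == 12 and row["single"] == 10 and row["doublet"] == 2


# ---------------------------------------------------------------------------
# expert-count comparison


def test_expert_ratios():
    recs = [make_record(event_id=f"e{i}", cartridge_id="c1", ck=(100, 1.0)) for i in range(9)]
    manifest = CohortManifest(
        [ManifestEntry("c1", "g", "blood", 10), ManifestEntry("c2", "g", "blood", 0)]
    )
    table = compare_to_expert_counts(recs, manifest).set_index("cartridge_id")
    assert table.loc["c1", "ratio"] == pytest.approx(0.9)
    assert np.isnan(table.loc["c2", "ratio"]) and table.loc["c2", "detected"] == 0


def test_equal_counts_give_unit_ratio():
    recs = [make_record(event_id=f"e{i}", cartridge_id="c1") for i in range(5)]
    manifest = CohortManifest([ManifestEntry("c1", "g", "blood", 5)])
    assert compare_to_expert_counts(recs, manifest)["ratio"].iloc[0] == pytest.approx(1.0)


def test_unknown_cartridge_raises():
    recs = [make_record(cartridge_id="mystery")]
    manifest = CohortManifest([ManifestEntry("c1", "g")])
    with pytest.raises(ValueError, match="mystery"):
        compare_to_expert_counts(recs, manifest)
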