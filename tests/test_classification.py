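"""Pathogenicity rule cascade: MAF gating, LOF and in-silico rules,
ClinVar override, exclusions, census percentages, and global properties."""

import pytest
from hypothesis import given, settings, strategies as st

from rarecarrier.classification import (
    ClassificationPolicy,
    PathogenicCall,
    census,
    classify_cohort,
    classify_variant,
    group_af,
    is_rare,
)
from rarecarrier.io import ClinVar, Consequence, GroupCounts, PolyPhen, Sift
from rarecarrier.simulate import CohortSimConfig, simulate_cohort

from conftest import make_variant


def test_group_af_direct_quotient(small_panel):
    v = make_variant(small_panel, counts={"afr": (2, 0)})
    afs = group_af(v, small_panel)
    assert afs["afr"] == pytest.approx(2 / 16256)
    assert afs["asj"] == 0.0
    assert "oth" not in afs  # excluded group never analysed


def test_group_af_zero_denominator(small_panel):
    v = make_variant(
        small_panel,
        counts={"afr": GroupCounts(ac=0, an=0, nhomalt=0,
                                   ac_male=0, ac_female=0)},
    )
    assert group_af(v, small_panel)["afr"] == 0.0


def test_is_rare_requires_every_group(small_panel):
    policy = ClassificationPolicy()
    # 0.5% in one group, absent elsewhere: rare
    v = make_variant(small_panel, counts={"afr": (81, 0)})
    assert is_rare(v, small_panel, policy)
    # 2% in one group is enough to fail, regardless of the others
    v = make_variant(small_panel, counts={"afr": (326, 0), "asj": (1, 0)})
    assert not is_rare(v, small_panel, policy)


def test_is_rare_strict_at_threshold(small_panel):
    # exactly 1.0% in asj (ac = 0.01 * 10080): not rare (strict inequality)
    v = make_variant(small_panel, counts={"asj": (100, 0)})
    assert 100 / 10080 < 0.01
    v2 = make_variant(small_panel, counts={"asj": (101, 0)})
    assert not is_rare(v2, small_panel, ClassificationPolicy(maf_threshold=101 / 10080))


def test_lof_called_pathogenic_without_annotations(small_panel):
    v = make_variant(
        small_panel, consequence=Consequence.STOP_GAINED,
        counts={"afr": (3, 0)},
    )
    call = classify_variant(v, small_panel)
    assert call.status == "pathogenic"
    assert call.reasons == ("lof_class",)


@pytest.mark.parametrize(
    "cons",
    [
        Consequence.STOP_GAINED,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.FRAMESHIFT,
    ],
)
def test_all_lof_classes(small_panel, cons):
    v = make_variant(small_panel, consequence=cons, counts={"afr": (1, 0)})
    assert classify_variant(v, small_panel).status == "pathogenic"


def test_clinvar_rescues_benign_in_silico(small_panel):
    v = make_variant(
        small_panel,
        counts={"afr": (2, 0)},
        sift=Sift.TOLERATED,
        polyphen=PolyPhen.BENIGN,
        clinvar=ClinVar.PATHOGENIC,
    )
    call = classify_variant(v, small_panel)
    assert call.status == "pathogenic"
    assert call.reasons == ("clinvar_pathogenic",)


def test_clinvar_conflicting_never_rescues(small_panel):
    v = make_variant(
        small_panel,
        counts={"afr": (2, 0)},
        sift=Sift.TOLERATED,
        polyphen=PolyPhen.BENIGN,
        clinvar=ClinVar.CONFLICTING,
    )
    assert classify_variant(v, small_panel).status == "non_pathogenic"


def test_synonymous_never_pathogenic(small_panel):
    v = make_variant(
        small_panel, consequence=Consequence.SYNONYMOUS,
        counts={"afr": (2, 0)}, protein_change="G149G",
        sift=Sift.DELETERIOUS, polyphen=PolyPhen.PROBABLY_DAMAGING,
    )
    call = classify_variant(v, small_panel)
    assert call.status == "non_pathogenic"
    assert call.reasons == ("synonymous",)


def test_exclusion_cascade_order(small_panel):
    # QC flag wins over everything else
    v = make_variant(
        small_panel, counts={"afr": (400, 0)}, qc_flag=True, isoform="2",
    )
    assert classify_variant(v, small_panel).reasons == ("qc_flagged",)
    # then common allele, before isoform
    v = make_variant(small_panel, counts={"afr": (400, 0)}, isoform="2")
    assert classify_variant(v, small_panel).reasons == ("common_allele",)
    # then noncanonical isoform
    v = make_variant(small_panel, counts={"afr": (2, 0)}, isoform="2")
    assert classify_variant(v, small_panel).reasons == ("noncanonical_isoform",)
    # carriers only in the excluded catch-all group
    v = make_variant(small_panel, counts={"oth": (2, 0)})
    assert classify_variant(v, small_panel).reasons == ("other_group_only",)
    # in-frame indels excluded
    v = make_variant(
        small_panel, consequence=Consequence.INFRAME_INDEL,
        counts={"afr": (2, 0)}, ref="ATTT", alt="A",
    )
    call = classify_variant(v, small_panel)
    assert (call.status, call.reasons) == ("excluded", ("inframe_indel",))


def test_unscorable_missense_never_crashes(small_panel):
    v = make_variant(small_panel, counts={"afr": (2, 0)})
    call = classify_variant(v, small_panel)
    assert call.status == "non_pathogenic"
    assert "unscorable" in call.reasons


@pytest.mark.parametrize(
    "rule,sift,polyphen,expected",
    [
        ("both_damaging", Sift.DELETERIOUS, PolyPhen.POSSIBLY_DAMAGING, True),
        ("both_damaging", Sift.DELETERIOUS, PolyPhen.BENIGN, False),
        ("either_damaging", Sift.DELETERIOUS, PolyPhen.BENIGN, True),
        ("either_damaging", Sift.TOLERATED, PolyPhen.PROBABLY_DAMAGING, True),
        ("sift_only", Sift.DELETERIOUS, PolyPhen.BENIGN, True),
        ("polyphen_only", Sift.DELETERIOUS, PolyPhen.BENIGN, False),
    ],
)
def test_in_silico_rules(small_panel, rule, sift, polyphen, expected):
    v = make_variant(
        small_panel, counts={"afr": (2, 0)}, sift=sift, polyphen=polyphen
    )
    policy = ClassificationPolicy(in_silico_rule=rule)
    call = classify_variant(v, small_panel, policy)
    assert (call.status == "pathogenic") is expected


def test_pathogenic_call_requires_reason():
    with pytest.raises(ValueError):
        PathogenicCall("x", "pathogenic", ())
    with pytest.raises(ValueError):
        PathogenicCall("x", "pathogenic", ("synonymous",))


def test_census_percentages(small_panel):
    variants = []
    pos = 1
    for cons, n in [
        (Consequence.FRAMESHIFT, 34),
        (Consequence.SPLICE_ACCEPTOR, 6),
        (Consequence.SPLICE_DONOR, 6),
        (Consequence.STOP_GAINED, 13),
        (Consequence.MISSENSE, 355),
    ]:
        for _ in range(n):
            variants.append(
                make_variant(
                    small_panel, pos=pos, counts={"afr": (1, 0)},
                    consequence=cons,
                    sift=Sift.DELETERIOUS,
                    polyphen=PolyPhen.PROBABLY_DAMAGING,
                )
            )
            pos += 1
    calls = classify_cohort(variants, small_panel)
    table = census(calls, variants).set_index("consequence")
    assert table.loc["missense", "n_mutations"] == 355
    assert table.loc["missense", "pct_of_pathogenic"] == pytest.approx(
        85.7, abs=0.05
    )
    assert table.loc["frameshift", "pct_of_pathogenic"] == pytest.approx(
        8.2, abs=0.05
    )
    assert table["pct_of_pathogenic"].sum() == pytest.approx(100.0)


def test_census_single_variant(small_panel):
    v = make_variant(
        small_panel, counts={"afr": (1, 0)},
        sift=Sift.DELETERIOUS, polyphen=PolyPhen.PROBABLY_DAMAGING,
    )
    calls = classify_cohort([v], small_panel)
    table = census(calls, [v])
    assert table["pct_of_pathogenic"].tolist() == [100.0]


def test_partition_and_idempotence(full_panel):
    records, _ = simulate_cohort(CohortSimConfig(panel=full_panel, seed=3))
    calls1 = classify_cohort(records, full_panel)
    calls2 = classify_cohort(list(reversed(records)), full_panel)
    assert {c.variant_id: c for c in calls1} == {
        c.variant_id: c for c in calls2
    }  # order-independent
    statuses = [c.status for c in calls1]
    assert len(statuses) == len(records)  # exactly one status per variant
    assert set(statuses) <= {"pathogenic", "non_pathogenic", "excluded"}


def test_maf_monotonicity(full_panel):
    """Tightening the MAF threshold never adds pathogenic calls."""
    records, _ = simulate_cohort(CohortSimConfig(panel=full_panel, seed=4))
    loose = {
        c.variant_id
        for c in classify_cohort(
            records, full_panel, ClassificationPolicy(maf_threshold=0.01)
        )
        if c.status == "pathogenic"
    }
    tight = {
        c.variant_id
        for c in classify_cohort(
            records, full_panel, ClassificationPolicy(maf_threshold=0.001)
        )
        if c.status == "pathogenic"
    }
    assert tight <= loose


@settings(max_examples=30, derandomize=True)
@given(ac=st.integers(0, 100), nhom_frac=st.floats(0, 0.5))
def test_rare_single_group_variants_classified_consistently(ac, nhom_frac):
    """Classification is a pure function of the record: repeated calls agree,
    and the status partition is total for any in-range counts."""
    from rarecarrier.io import PopulationGroup, PopulationPanel

    panel = PopulationPanel(
        groups=(PopulationGroup("g", 10000, 5000, 5000),), other_label=None
    )
    nhom = int(ac * nhom_frac / 2)
    v = make_variant(
        panel, counts={"g": (ac, nhom)},
        sift=Sift.DELETERIOUS, polyphen=PolyPhen.PROBABLY_DAMAGING,
    )
    c1 = classify_variant(v, panel)
    c2 = classify_variant(v, panel)
    assert c1 == c2
    assert c1.status in {"pathogenic", "non_pathogenic", "excluded"}
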