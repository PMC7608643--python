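"""Pathogenicity classification of single-gene variants.

A deterministic rule cascade assigns every variant exactly one status —
``pathogenic``, ``non_pathogenic`` or ``excluded`` — with machine-readable
reason codes.  The rules mirror a common gnomAD-based screening design:

* variants flagged for dubious annotation or quality are excluded;
* only rare variants are considered (alt-allele frequency strictly below a
  threshold, default 1%, in *every* analysed ancestry group);
* variants whose protein consequence is not on the canonical isoform, or
  whose carriers all fall in the excluded catch-all ancestry group, are
  excluded;
* nonsense (stop gained), essential splice-site and frameshift alleles are
  loss-of-function and called pathogenic outright;
* missense alleles are called pathogenic when damaging in silico
  (SIFT/PolyPhen-2) or, overriding a benign in-silico verdict, when ClinVar
  asserts pathogenic/likely pathogenic;
* synonymous variants are never pathogenic; in-frame indels and other
  unscored consequence classes are excluded from study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .io import (
    ClinVar,
    Consequence,
    PolyPhen,
    PopulationPanel,
    Sift,
    VariantRecord,
)

DEFAULT_LOF_CLASSES = frozenset(
    {
        Consequence.STOP_GAINED,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.FRAMESHIFT,
    }
)
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {
        Consequence.SYNONYMOUS,
        Consequence.INFRAME_INDEL,
        Consequence.OTHER,
        Consequence.STOP_LOST,
        Consequence.START_LOST,
    }
)

IN_SILICO_RULES = ("both_damaging", "either_damaging", "sift_only", "polyphen_only")


@dataclass(frozen=True)
class ClassificationPolicy:
    maf_threshold: float = 0.01
    lof_classes: frozenset = DEFAULT_LOF_CLASSES
    in_silico_rule: str = "both_damaging"
    polyphen_damaging: frozenset = frozenset(
        {PolyPhen.PROBABLY_DAMAGING, PolyPhen.POSSIBLY_DAMAGING}
    )
    clinvar_override: bool = True
    canonical_isoform: str = "1"
    excluded_classes: frozenset = DEFAULT_EXCLUDED_CLASSES

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must be in (0, 0.5]")
        if self.lof_classes & self.excluded_classes:
            raise ValueError("lof_classes and excluded_classes must be disjoint")
        if self.in_silico_rule not in IN_SILICO_RULES:
            raise ValueError(f"in_silico_rule must be one of {IN_SILICO_RULES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationPolicy":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        if "maf_threshold" in doc:
            kwargs["maf_threshold"] = float(doc["maf_threshold"])
        if "lof_classes" in doc:
            kwargs["lof_classes"] = frozenset(
                Consequence(c) for c in doc["lof_classes"]
            )
        if "excluded_classes" in doc:
            kwargs["excluded_classes"] = frozenset(
                Consequence(c) for c in doc["excluded_classes"]
            )
        if "in_silico_rule" in doc:
            kwargs["in_silico_rule"] = doc["in_silico_rule"]
        if "polyphen_damaging" in doc:
            kwargs["polyphen_damaging"] = frozenset(
                PolyPhen(p) for p in doc["polyphen_damaging"]
            )
        if "clinvar_override" in doc:
            kwargs["clinvar_override"] = bool(doc["clinvar_override"])
        if "canonical_isoform" in doc:
            kwargs["canonical_isoform"] = str(doc["canonical_isoform"])
        return cls(**kwargs)


# Reason codes carried by PathogenicCall.
REASONS = (
    "lof_class",
    "insilico_damaging",
    "clinvar_pathogenic",
    "common_allele",
    "synonymous",
    "inframe_indel",
    "excluded_class",
    "qc_flagged",
    "other_group_only",
    "noncanonical_isoform",
    "insilico_benign",
    "unscorable",
)

PATHOGENIC_REASONS = frozenset(
    {"lof_class", "insilico_damaging", "clinvar_pathogenic"}
)


@dataclass(frozen=True)
class PathogenicCall:
    variant_id: str
    status: str  # pathogenic | non_pathogenic | excluded
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("every call carries at least one reason")
        if self.status == "pathogenic" and not (
            set(self.reasons) & PATHOGENIC_REASONS
        ):
            raise ValueError("pathogenic call without a pathogenic reason")


def group_af(variant: VariantRecord, panel: PopulationPanel) -> dict[str, float]:
    """Per-analysed-group alt-allele frequency ac/an ('other' excluded).

    Groups with an = 0 report 0.0; see :func:`zero_denominator_groups`.
    """
    afs = {}
    for g in panel.analysed:
        if g.label not in variant.counts:
            raise KeyError(
                f"{variant.variant_id}: panel group {g.label!r} absent from "
                f"variant counts"
            )
        c = variant.counts[g.label]
        afs[g.label] = c.ac / c.an if c.an > 0 else 0.0
    return afs


def zero_denominator_groups(
    variant: VariantRecord, panel: PopulationPanel
) -> set[str]:
    return {
        g.label
        for g in panel.analysed
        if variant.counts[g.label].an == 0
    }


def is_rare(
    variant: VariantRecord,
    panel: PopulationPanel,
    policy: ClassificationPolicy,
) -> bool:
    """True iff the alt-allele frequency is strictly below the threshold in
    every analysed group (a tie at exactly the threshold is not rare)."""
    return all(
        af < policy.maf_threshold for af in group_af(variant, panel).values()
    )


def _in_silico_damaging(
    variant: VariantRecord, policy: ClassificationPolicy
) -> bool:
    sift_dam = variant.sift == Sift.DELETERIOUS
    poly_dam = variant.polyphen in policy.polyphen_damaging
    rule = policy.in_silico_rule
    if rule == "both_damaging":
        return sift_dam and poly_dam
    if rule == "either_damaging":
        return sift_dam or poly_dam
    if rule == "sift_only":
        return sift_dam
    return poly_dam


def classify_variant(
    variant: VariantRecord,
    panel: PopulationPanel,
    policy: ClassificationPolicy | None = None,
) -> PathogenicCall:
    """Apply the rule cascade to one variant (order fixed; see module doc)."""
    policy = policy or ClassificationPolicy()
    vid = variant.variant_id

    if variant.qc_flag:
        return PathogenicCall(vid, "excluded", ("qc_flagged",))
    if not is_rare(variant, panel, policy):
        return PathogenicCall(vid, "excluded", ("common_allele",))
    if variant.isoform != policy.canonical_isoform:
        return PathogenicCall(vid, "excluded", ("noncanonical_isoform",))
    analysed_ac = variant.total_ac(panel.analysed_labels)
    other_ac = (
        variant.counts[panel.other_label].ac
        if panel.other_label and panel.other_label in variant.counts
        else 0
    )
    if analysed_ac == 0 and other_ac > 0:
        return PathogenicCall(vid, "excluded", ("other_group_only",))
    if variant.consequence in policy.excluded_classes:
        if variant.consequence == Consequence.SYNONYMOUS:
            return PathogenicCall(vid, "non_pathogenic", ("synonymous",))
        if variant.consequence == Consequence.INFRAME_INDEL:
            return PathogenicCall(vid, "excluded", ("inframe_indel",))
        return PathogenicCall(vid, "excluded", ("excluded_class",))
    if variant.consequence in policy.lof_classes:
        return PathogenicCall(vid, "pathogenic", ("lof_class",))
    # Remaining class: missense (or any class neither LOF nor excluded).
    if policy.clinvar_override and variant.clinvar in (
        ClinVar.PATHOGENIC,
        ClinVar.LIKELY_PATHOGENIC,
    ):
        return PathogenicCall(vid, "pathogenic", ("clinvar_pathogenic",))
    if (
        variant.sift == Sift.MISSING
        and variant.polyphen == PolyPhen.MISSING
        and variant.clinvar == ClinVar.ABSENT
    ):
        return PathogenicCall(vid, "non_pathogenic", ("unscorable",))
    if _in_silico_damaging(variant, policy):
        return PathogenicCall(vid, "pathogenic", ("insilico_damaging",))
    return PathogenicCall(vid, "non_pathogenic", ("insilico_benign",))


def classify_cohort(
    variants: list[VariantRecord],
    panel: PopulationPanel,
    policy: ClassificationPolicy | None = None,
) -> list[PathogenicCall]:
    policy = policy or ClassificationPolicy()
    return [classify_variant(v, panel, policy) for v in variants]


def pathogenic_variants(
    variants: list[VariantRecord], calls: list[PathogenicCall]
) -> list[VariantRecord]:
    status = {c.variant_id: c.status for c in calls}
    return [v for v in variants if status[v.variant_id] == "pathogenic"]


def census(
    calls: list[PathogenicCall], variants: list[VariantRecord]
) -> pd.DataFrame:
    """Consequence-class census of distinct pathogenic variants.

    Returns one row per consequence class with the distinct-variant count and
    its percentage of the pathogenic total (percentages at full precision).
    """
    cons = {v.variant_id: v.consequence for v in variants}
    path_ids = [c.variant_id for c in calls if c.status == "pathogenic"]
    counts: dict[str, int] = {}
    for vid in path_ids:
        key = str(cons[vid])
        counts[key] = counts.get(key, 0) + 1
    total = len(path_ids)
    rows = [
        {
            "consequence": k,
            "n_mutations": n,
            "pct_of_pathogenic": 100.0 * n / total if total else 0.0,
        }
        for k, n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    df = pd.DataFrame(
        rows, columns=["consequence", "n_mutations", "pct_of_pathogenic"]
    )
    return df


def calls_table(
    calls: list[PathogenicCall],
    variants: list[VariantRecord],
    panel: PopulationPanel,
) -> pd.DataFrame:
    """Flat TSV-ready view: variant_id, status, reasons, per-group AF."""
    by_id = {v.variant_id: v for v in variants}
    rows = []
    for c in calls:
        v = by_id[c.variant_id]
        row = {
            "variant_id": c.variant_id,
            "status": c.status,
            "reasons": ";".join(c.reasons),
        }
        for lab, af in group_af(v, panel).items():
            row[f"af_{lab}"] = af
        rows.append(row)
    return pd.DataFrame(rows)
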