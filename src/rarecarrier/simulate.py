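"""Synthetic gnomAD-like cohorts and gene-constraint tables with known truth.

The cohort generator emulates the per-population allele-count structure of a
large exome aggregation database for a single gene: six analysed ancestry
groups plus an excluded catch-all, rare variants with a heavy-tailed
(zipf-like) allele-count spectrum, Hardy-Weinberg homozygote realisation,
binomial sex splits, and SIFT/PolyPhen-2/ClinVar annotation fields with
configurable noise.  Every generated record carries a truth label so that
downstream classification, prevalence, and domain statistics can be checked
exactly.

A single integer seed drives one ``SeedSequence``; per-variant substreams
are spawned by variant index, so enlarging a cohort never perturbs the
variants already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constraint import DEFAULT_FACTORS, GeneCounts
from .io import (
    ClinVar,
    Consequence,
    GroupCounts,
    PolyPhen,
    PopulationGroup,
    PopulationPanel,
    ProteinChange,
    Sift,
    VariantRecord,
)

#: Default panel: six analysed ancestry groups at gnomAD v2 exome sizes plus
#: an 'oth' catch-all to exercise the exclusion path.
def default_panel() -> PopulationPanel:
    return PopulationPanel(
        groups=(
            PopulationGroup("nfe", 67709, 37442, 30267),
            PopulationGroup("amr", 17296, 7161, 10135),
            PopulationGroup("sas", 15308, 11536, 3772),
            PopulationGroup("eas", 9197, 4533, 4664),
            PopulationGroup("afr", 8128, 3093, 5035),
            PopulationGroup("asj", 5040, 2590, 2450),
            PopulationGroup("oth", 3070, 1535, 1535),
        ),
        other_label="oth",
    )


#: Default per-class variant counts, mirroring the observed single-gene
#: census: LOF classes at their published counts, missense split into
#: pathogenic-like and benign-like fractions, plus synonymous alleles.
DEFAULT_CLASS_COUNTS = {
    Consequence.FRAMESHIFT: 34,
    Consequence.SPLICE_ACCEPTOR: 6,
    Consequence.SPLICE_DONOR: 6,
    Consequence.STOP_GAINED: 13,
    Consequence.MISSENSE: 647,
    Consequence.SYNONYMOUS: 150,
    Consequence.INFRAME_INDEL: 5,
}

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CohortSimConfig:
    panel: PopulationPanel = field(default_factory=default_panel)
    class_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    pathogenic_missense_fraction: float = 355 / 647
    ethnic_specific_fraction: float = 0.82
    common_negative_fraction: float = 0.10  # benign variants made common
    zipf_a: float = 1.5  # allele-copy spectrum exponent over 1..max_copies
    max_copies: int = 30
    hom_rule: str = "hwe"  # 'hwe' or 'explicit' (no homozygotes drawn)
    annotation_noise: float = 0.0
    clinvar_rescue_rate: float = 2 / 355
    qc_flag_rate: float = 0.01
    noncanonical_rate: float = 0.01
    other_only_rate: float = 0.006
    protein_length: int = 1278
    gene: str = "GENE1"
    chrom: str = "18"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pathogenic_missense_fraction",
            "ethnic_specific_fraction",
            "common_negative_fraction",
            "annotation_noise",
            "clinvar_rescue_rate",
            "qc_flag_rate",
            "noncanonical_rate",
            "other_only_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hom_rule not in ("hwe", "explicit"):
            raise ValueError("hom_rule must be 'hwe' or 'explicit'")


def _zipf_copies(rng: np.random.Generator, a: float, max_copies: int) -> int:
    """Heavy-tailed total alt-copy count on {1..max_copies}."""
    support = np.arange(1, max_copies + 1)
    weights = support.astype(float) ** -a
    weights /= weights.sum()
    return int(rng.choice(support, p=weights))


def draw_homozygotes(rng: np.random.Generator, n: int, q: float) -> int:
    """Hardy-Weinberg homozygote count: Binomial(n, q^2)."""
    return int(rng.binomial(n, q * q))


def _split_sex(
    rng: np.random.Generator, k: int, p_male: float
) -> tuple[int, int]:
    m = int(rng.binomial(k, p_male))
    return m, k - m


def _simulate_variant(
    idx: int, cons: Consequence, config: CohortSimConfig, ss: np.random.SeedSequence
) -> tuple[VariantRecord, dict]:
    rng = np.random.default_rng(ss)
    panel = config.panel
    analysed = panel.analysed
    sizes = np.array([g.n_individuals for g in analysed], dtype=float)

    # --- truth status -----------------------------------------------------
    if cons in (
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.STOP_GAINED,
    ):
        truth = "pathogenic"
    elif cons == Consequence.MISSENSE:
        truth = (
            "pathogenic"
            if rng.random() < config.pathogenic_missense_fraction
            else "non_pathogenic"
        )
    elif cons == Consequence.SYNONYMOUS:
        truth = "non_pathogenic"
    else:
        truth = "excluded"
    truth_reason = ""

    qc_flag = rng.random() < config.qc_flag_rate
    isoform = "1"
    other_only = False
    if not qc_flag:
        if rng.random() < config.noncanonical_rate:
            isoform = "2"
        elif rng.random() < config.other_only_rate:
            other_only = True
    if qc_flag:
        truth, truth_reason = "excluded", "qc_flagged"
    elif isoform != "1":
        truth, truth_reason = "excluded", "noncanonical_isoform"
    elif other_only:
        truth, truth_reason = "excluded", "other_group_only"

    common = False
    if truth == "non_pathogenic" and not qc_flag and isoform == "1":
        common = rng.random() < config.common_negative_fraction
        if common:
            truth, truth_reason = "excluded", "common_allele"

    # --- group membership and allele counts -------------------------------
    if other_only:
        chosen = [panel.group(panel.other_label)]
    else:
        specific = rng.random() < config.ethnic_specific_fraction
        k = 1 if specific else int(rng.integers(2, min(4, len(analysed)) + 1))
        pick = rng.choice(
            len(analysed), size=k, replace=False, p=sizes / sizes.sum()
        )
        chosen = [analysed[i] for i in sorted(pick)]

    counts: dict[str, GroupCounts] = {}
    truth_group_het: dict[str, int] = {}
    truth_group_hom: dict[str, int] = {}
    chosen_labels = {g.label for g in chosen}
    for g in panel.groups:
        an = g.n_alleles
        if g.label not in chosen_labels:
            counts[g.label] = GroupCounts(0, an, 0, 0, 0, 0, 0)
            continue
        if common:
            af = rng.uniform(0.015, 0.05)
            ac = max(1, int(rng.binomial(an, af)))
        else:
            ac = _zipf_copies(rng, config.zipf_a, config.max_copies)
            ac = min(ac, an)
        if config.hom_rule == "hwe":
            q = ac / an
            nhom = min(draw_homozygotes(rng, g.n_individuals, q), ac // 2)
        else:
            nhom = 0
        p_male = g.n_male / g.n_individuals
        nhom_m, nhom_f = _split_sex(rng, nhom, p_male)
        het = ac - 2 * nhom
        het_m, het_f = _split_sex(rng, het, p_male)
        ac_m = 2 * nhom_m + het_m
        ac_f = 2 * nhom_f + het_f
        counts[g.label] = GroupCounts(
            ac=ac,
            an=an,
            nhomalt=nhom,
            ac_male=ac_m,
            ac_female=ac_f,
            nhomalt_male=nhom_m,
            nhomalt_female=nhom_f,
        )
        truth_group_het[g.label] = het
        truth_group_hom[g.label] = nhom

    # --- annotations -------------------------------------------------------
    sift, polyphen, clinvar = Sift.MISSING, PolyPhen.MISSING, ClinVar.ABSENT
    protein_change = None
    if cons in (Consequence.MISSENSE, Consequence.SYNONYMOUS):
        residue = int(rng.integers(1, config.protein_length + 1))
        ref_aa = AA[rng.integers(len(AA))]
        alt_aa = ref_aa if cons == Consequence.SYNONYMOUS else AA[
            rng.integers(len(AA))
        ]
        protein_change = ProteinChange(ref_aa, residue, alt_aa)
    if cons == Consequence.MISSENSE:
        damaging = truth == "pathogenic" or (
            truth_reason in ("qc_flagged", "noncanonical_isoform",
                             "other_group_only")
            and rng.random() < config.pathogenic_missense_fraction
        )
        rescued = damaging and rng.random() < config.clinvar_rescue_rate
        if rescued:
            sift, polyphen = Sift.TOLERATED, PolyPhen.BENIGN
            clinvar = ClinVar.PATHOGENIC
        elif damaging:
            sift = Sift.DELETERIOUS
            polyphen = (
                PolyPhen.PROBABLY_DAMAGING
                if rng.random() < 0.7
                else PolyPhen.POSSIBLY_DAMAGING
            )
        else:
            sift, polyphen = Sift.TOLERATED, PolyPhen.BENIGN
        if config.annotation_noise > 0 and rng.random() < config.annotation_noise:
            # contradict the truth-aligned verdicts
            if sift == Sift.DELETERIOUS:
                sift, polyphen = Sift.TOLERATED, PolyPhen.BENIGN
            else:
                sift, polyphen = Sift.DELETERIOUS, PolyPhen.PROBABLY_DAMAGING

    pos = 21_100_000 + idx * 10
    ref, alt = "A", "G"
    if cons == Consequence.FRAMESHIFT:
        ref, alt = "AT", "A"
    elif cons == Consequence.INFRAME_INDEL:
        ref, alt = "ATTT", "A"

    record = VariantRecord(
        chrom=config.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=config.gene,
        consequence=cons,
        protein_change=protein_change,
        isoform=isoform,
        counts=counts,
        sift=sift,
        polyphen=polyphen,
        clinvar=clinvar,
        qc_flag=qc_flag,
    )
    analysed_present = [
        g.label for g in analysed if counts[g.label].ac > 0
    ]
    truth_row = {
        "variant_id": record.variant_id,
        "consequence": str(cons),
        "truth_status": truth,
        "truth_reason": truth_reason
        or (
            "lof_class"
            if truth == "pathogenic"
            and cons != Consequence.MISSENSE
            else (
                "clinvar_pathogenic"
                if cons == Consequence.MISSENSE and clinvar == ClinVar.PATHOGENIC
                else (
                    "insilico_damaging"
                    if truth == "pathogenic"
                    else (
                        "synonymous"
                        if cons == Consequence.SYNONYMOUS
                        else (
                            "inframe_indel"
                            if cons == Consequence.INFRAME_INDEL
                            else "insilico_benign"
                        )
                    )
                )
            )
        ),
        "specific_group": (
            analysed_present[0] if len(analysed_present) == 1 else
            ("unobserved" if not analysed_present else "overlap")
        ),
        "total_ac": sum(
            counts[g.label].ac for g in analysed
        ),
        "het_carriers": sum(truth_group_het.get(g.label, 0) for g in analysed),
        "hom_carriers": sum(truth_group_hom.get(g.label, 0) for g in analysed),
    }
    return record, truth_row


def simulate_cohort(
    config: CohortSimConfig | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Generate a cohort and its truth table (deterministic under the seed)."""
    config = config or CohortSimConfig()
    order: list[Consequence] = []
    for cons, n in config.class_counts.items():
        order.extend([Consequence(cons)] * int(n))
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(order))
    records, truth_rows = [], []
    for idx, (cons, ss) in enumerate(zip(order, streams)):
        rec, truth = _simulate_variant(idx, cons, config, ss)
        records.append(rec)
        truth_rows.append(truth)
    truth_df = pd.DataFrame(truth_rows)
    return records, truth_df


def simulate_constraint_genes(
    n_genes: int,
    priors: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    exp_meanlog: float = 3.0,
    exp_sdlog: float = 1.0,
    factors: Sequence[float] = DEFAULT_FACTORS,
    seed: int = 0,
) -> tuple[list[GeneCounts], np.ndarray]:
    """Simulate per-gene observed/expected counts under the 3-class mixture.

    Expected LOF counts are lognormal; each gene's class is drawn from the
    priors and its observed LOF count from Poisson(factor_class * expected).
    Synonymous and missense counts are generated as unconstrained
    (factor 1) classes.  Returns the gene table and the true class indices
    (0 = null, 1 = recessive, 2 = haploinsufficient).
    """
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    factors = np.asarray(factors, dtype=float)
    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=n_genes, p=priors)
    exp_lof = rng.lognormal(exp_meanlog, exp_sdlog, size=n_genes)
    obs_lof = rng.poisson(factors[classes] * exp_lof)
    exp_syn = rng.lognormal(exp_meanlog + 1.0, exp_sdlog, size=n_genes)
    obs_syn = rng.poisson(exp_syn)
    exp_mis = rng.lognormal(exp_meanlog + 1.5, exp_sdlog, size=n_genes)
    obs_mis = rng.poisson(exp_mis)
    genes = [
        GeneCounts(
            gene=f"G{i:05d}",
            obs_syn=int(obs_syn[i]),
            exp_syn=float(exp_syn[i]),
            obs_mis=int(obs_mis[i]),
            exp_mis=float(exp_mis[i]),
            obs_lof=int(obs_lof[i]),
            exp_lof=float(exp_lof[i]),
        )
        for i in range(n_genes)
    ]
    return genes, classes
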