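"""Carrier prevalence by ancestry group: counts, frequencies, ethnic-specific
partition, sex stratification, fold differences, and chi-square heterogeneity
tests.

Carrier counts are allele-derived, because aggregate databases expose per-
variant allele counts rather than individual genotypes: per variant and
group, homozygous carriers are ``nhomalt`` and heterozygous carriers are
``ac - 2*nhomalt``.  An individual compound-heterozygous for two different
variants is therefore counted once per variant — a known limitation of
allele-count data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from scipy.stats.contingency import expected_freq

from .io import PopulationPanel, VariantRecord

GLOBAL = "global"

COUNT_FIELDS = [
    "n_individuals",
    "n_male",
    "n_female",
    "total_alleles",
    "mutated_alleles",
    "het_carriers",
    "hom_carriers",
    "het_male",
    "het_female",
    "hom_male",
    "hom_female",
    "ethnic_specific_mutations",
    "ethnic_specific_mutated_alleles",
    "ethnic_specific_het",
    "ethnic_specific_hom",
]


def _attribute_hom_sex(ac_male: int, ac_female: int, nhomalt: int,
                       nhomalt_male, nhomalt_female) -> tuple[int, int]:
    """Split homozygotes by sex.

    Uses the dedicated per-variant fields when present; otherwise attributes
    homozygotes to the sex with sufficient allele count, ties broken toward
    male (male-first fill).
    """
    if nhomalt_male is not None and nhomalt_female is not None:
        return int(nhomalt_male), int(nhomalt_female)
    hom_m = min(nhomalt, ac_male // 2)
    hom_f = nhomalt - hom_m
    if 2 * hom_f > ac_female:  # pragma: no cover - impossible post-validation
        raise ValueError("homozygote alleles exceed female allele count")
    return hom_m, hom_f


def ethnic_specific_partition(
    variants: list[VariantRecord], panel: PopulationPanel
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Partition variants into per-group specific sets, an overlap set, and
    an unobserved bin (ac = 0 in every analysed group)."""
    labels = panel.analysed_labels
    specific: dict[str, set[str]] = {lab: set() for lab in labels}
    overlap: set[str] = set()
    unobserved: set[str] = set()
    for v in variants:
        present = [lab for lab in labels if v.counts[lab].ac > 0]
        if len(present) == 0:
            unobserved.add(v.variant_id)
        elif len(present) == 1:
            specific[present[0]].add(v.variant_id)
        else:
            overlap.add(v.variant_id)
    return specific, overlap, unobserved


def carrier_counts(
    variants: list[VariantRecord], panel: PopulationPanel
) -> pd.DataFrame:
    """Build the per-group carrier table (plus a summed ``global`` row).

    All inputs should already be classified pathogenic; the table sums allele
    counts over variants within each analysed group.
    """
    labels = panel.analysed_labels
    specific, _overlap, _unobs = ethnic_specific_partition(variants, panel)
    rows = {}
    for g in panel.analysed:
        lab = g.label
        mut = het = hom = het_m = het_f = hom_m = hom_f = 0
        es_mut_alleles = es_het = es_hom = 0
        for v in variants:
            c = v.counts[lab]
            mut += c.ac
            hom += c.nhomalt
            het += c.ac - 2 * c.nhomalt
            h_m, h_f = _attribute_hom_sex(
                c.ac_male, c.ac_female, c.nhomalt,
                c.nhomalt_male, c.nhomalt_female,
            )
            hom_m += h_m
            hom_f += h_f
            het_m += c.ac_male - 2 * h_m
            het_f += c.ac_female - 2 * h_f
            if v.variant_id in specific[lab]:
                es_mut_alleles += c.ac
                es_het += c.ac - 2 * c.nhomalt
                es_hom += c.nhomalt
        rows[lab] = {
            "n_individuals": g.n_individuals,
            "n_male": g.n_male,
            "n_female": g.n_female,
            "total_alleles": g.n_alleles,
            "mutated_alleles": mut,
            "het_carriers": het,
            "hom_carriers": hom,
            "het_male": het_m,
            "het_female": het_f,
            "hom_male": hom_m,
            "hom_female": hom_f,
            "ethnic_specific_mutations": len(specific[lab]),
            "ethnic_specific_mutated_alleles": es_mut_alleles,
            "ethnic_specific_het": es_het,
            "ethnic_specific_hom": es_hom,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[labels]
    df.loc[GLOBAL] = df.sum(axis=0)
    df.index.name = "group"
    return df.astype(int)


def frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Populate frequency fields (stored as fractions at full precision;
    percentage display belongs to the report layer)."""
    df = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["allele_frequency"] = np.where(
            df["total_alleles"] > 0,
            df["mutated_alleles"] / df["total_alleles"],
            0.0,
        )
        df["het_frequency"] = np.where(
            df["n_individuals"] > 0,
            df["het_carriers"] / df["n_individuals"],
            0.0,
        )
        df["hom_frequency"] = np.where(
            df["n_individuals"] > 0,
            df["hom_carriers"] / df["n_individuals"],
            0.0,
        )
        df["ethnic_specific_allele_frequency"] = np.where(
            df["total_alleles"] > 0,
            df["ethnic_specific_mutated_alleles"] / df["total_alleles"],
            0.0,
        )
    df["zero_denominator"] = df["n_individuals"] == 0
    return df


def carrier_table(
    variants: list[VariantRecord], panel: PopulationPanel
) -> pd.DataFrame:
    return frequencies(carrier_counts(variants, panel))


@dataclass(frozen=True)
class FoldDifference:
    """Max/min ratio of a per-group frequency.

    ``rounded`` follows the display convention (frequencies rounded to two
    decimal percentage points before the quotient); ``unrounded`` is the
    full-precision quotient.  Both are reported.
    """

    field: str
    rounded: float | None
    unrounded: float | None
    min_group: str
    max_group: str
    undefined: bool = False


def fold_difference(
    table: pd.DataFrame, field: str = "het_frequency"
) -> FoldDifference:
    groups = table.drop(index=GLOBAL, errors="ignore")
    freqs = groups[field]
    if (freqs > 0).sum() < len(freqs) or len(freqs) < 2:
        lo = freqs.idxmin() if len(freqs) else ""
        hi = freqs.idxmax() if len(freqs) else ""
        return FoldDifference(field, None, None, lo, hi, undefined=True)
    lo, hi = freqs.idxmin(), freqs.idxmax()
    pct = (100.0 * freqs).round(2)
    return FoldDifference(
        field,
        rounded=float(pct.max() / pct.min()),
        unrounded=float(freqs.max() / freqs.min()),
        min_group=str(lo),
        max_group=str(hi),
    )


@dataclass(frozen=True)
class HeterogeneityTest:
    table_kind: str
    statistic: float
    df: int
    p_value: float
    p_display: str
    low_expected: bool = False  # some expected cell < 5
    scope: str = GLOBAL  # 'global' or a group label for per-group tests
    skipped: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not self.skipped:
            assert self.statistic >= 0 and 0.0 <= self.p_value <= 1.0


def chi_square(
    contingency,
    table_kind: str = "allele_frequency",
    scope: str = GLOBAL,
    correction: bool = False,
) -> HeterogeneityTest:
    """Pearson chi-square test of homogeneity on an r x k count table.

    Expected counts come from the row/column marginals; the p-value is the
    upper-tail chi-square probability (the two-sided test for this
    statistic).  No continuity correction by default.  A p-value that
    underflows double precision is displayed as ``< 2.2e-308``, never as 0.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    exp = expected_freq(obs)
    if (exp == 0).any():
        raise ValueError("zero expected cell (a marginal is zero)")
    stat, p, dof, exp = chi2_contingency(obs, correction=correction)
    p_display = "< 2.2e-308" if (p == 0.0 and stat > 0) else repr(float(p))
    return HeterogeneityTest(
        table_kind=table_kind,
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        p_display=p_display,
        low_expected=bool((exp < 5).any()),
        scope=scope,
    )


def allele_frequency_test(
    table: pd.DataFrame, ethnic_specific: bool = False
) -> HeterogeneityTest:
    """Heterogeneity of mutated-allele frequency across groups:
    2 x k table of (mutated, non-mutated) alleles."""
    groups = table.drop(index=GLOBAL, errors="ignore")
    col = (
        "ethnic_specific_mutated_alleles" if ethnic_specific else "mutated_alleles"
    )
    mutated = groups[col].to_numpy()
    other = groups["total_alleles"].to_numpy() - mutated
    kind = "ethnic_specific" if ethnic_specific else "allele_frequency"
    return chi_square(np.vstack([mutated, other]), table_kind=kind)


def sex_comparison(table: pd.DataFrame) -> list[HeterogeneityTest]:
    """2x2 carrier-vs-noncarrier by sex tests, globally and per group.

    Carriers pool heterozygous and homozygous individuals.  Groups with zero
    individuals of one sex are skipped with a flag.
    """
    tests = []
    for label, row in table.iterrows():
        scope = str(label)
        if row["n_male"] == 0 or row["n_female"] == 0:
            tests.append(
                HeterogeneityTest(
                    table_kind="sex",
                    statistic=float("nan"),
                    df=0,
                    p_value=float("nan"),
                    p_display=".",
                    scope=scope,
                    skipped=True,
                    note="no individuals of one sex",
                )
            )
            continue
        car_m = int(row["het_male"] + row["hom_male"])
        car_f = int(row["het_female"] + row["hom_female"])
        tab = [
            [car_m, int(row["n_male"]) - car_m],
            [car_f, int(row["n_female"]) - car_f],
        ]
        try:
            tests.append(chi_square(tab, table_kind="sex", scope=scope))
        except ValueError as exc:  # e.g. no carriers at all in the group
            tests.append(
                HeterogeneityTest(
                    table_kind="sex",
                    statistic=float("nan"),
                    df=0,
                    p_value=float("nan"),
                    p_display=".",
                    scope=scope,
                    skipped=True,
                    note=str(exc),
                )
            )
    return tests


def heterogeneity_tests(table: pd.DataFrame) -> list[HeterogeneityTest]:
    """All standard tests: allele-frequency and ethnic-specific heterogeneity
    across groups, plus the sex comparisons (global row last in the input)."""
    out = [allele_frequency_test(table, ethnic_specific=False),
           allele_frequency_test(table, ethnic_specific=True)]
    # per-group sex tests with the global row reported under scope 'global'
    out.extend(sex_comparison(table))
    return out


def tests_table(tests: list[HeterogeneityTest]) -> pd.DataFrame:
    rows = [
        {
            "table_kind": t.table_kind,
            "scope": t.scope,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "p_display": t.p_display,
            "significant_0.05": (not t.skipped) and t.p_value < 0.05,
            "low_expected": t.low_expected,
            "skipped": t.skipped,
        }
        for t in tests
    ]
    return pd.DataFrame(rows)


def cumulative_frequency_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group cumulative pathogenic allele frequency split into
    ethnic-specific vs overlapping contributions (a plot-ready analogue of a
    stacked-bar figure)."""
    df = table.copy()
    out = pd.DataFrame(index=df.index)
    out["allele_frequency"] = df["allele_frequency"]
    out["ethnic_specific_allele_frequency"] = df[
        "ethnic_specific_allele_frequency"
    ]
    out["overlapping_allele_frequency"] = (
        df["allele_frequency"] - df["ethnic_specific_allele_frequency"]
    )
    out.index.name = "group"
    return out
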