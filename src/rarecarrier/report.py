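"""Display-layer rounding and summary tables.

All upstream modules keep values at full precision; the printed convention —
two-decimal percentages, one-decimal fold changes, two-decimal o/e and pLI —
lives here and only here.
"""

from __future__ import annotations

import pandas as pd

from .constraint import ConstraintResult
from .prevalence import GLOBAL, FoldDifference


def pct(fraction: float, decimals: int = 2) -> float:
    """A fraction as a percentage rounded for display."""
    return round(100.0 * fraction, decimals)


def carrier_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Printable per-group prevalence summary (percentages at 2 dp, the
    homozygote frequency at 4 dp to keep sub-0.01% values visible)."""
    out = pd.DataFrame(index=table.index)
    out["N"] = table["n_individuals"]
    out["total_alleles"] = table["total_alleles"]
    out["mutated_alleles"] = table["mutated_alleles"]
    out["allele_frequency_pct"] = (100.0 * table["allele_frequency"]).round(2)
    out["het_carriers"] = table["het_carriers"]
    out["het_frequency_pct"] = (100.0 * table["het_frequency"]).round(2)
    out["hom_carriers"] = table["hom_carriers"]
    out["hom_frequency_pct"] = (100.0 * table["hom_frequency"]).round(4)
    out["het_MF"] = (
        table["het_male"].astype(str) + "/" + table["het_female"].astype(str)
    )
    out["hom_MF"] = (
        table["hom_male"].astype(str) + "/" + table["hom_female"].astype(str)
    )
    out["ethnic_specific_mutations"] = table["ethnic_specific_mutations"]
    out["ethnic_specific_mutated_alleles"] = table[
        "ethnic_specific_mutated_alleles"
    ]
    out.index.name = "group"
    return out


def fold_summary(fold: FoldDifference) -> dict:
    return {
        "field": fold.field,
        "fold_rounded_display": (
            None if fold.rounded is None else round(fold.rounded, 1)
        ),
        "fold_unrounded": (
            None if fold.unrounded is None else round(fold.unrounded, 2)
        ),
        "min_group": fold.min_group,
        "max_group": fold.max_group,
        "undefined": fold.undefined,
    }


def constraint_summary(result: ConstraintResult) -> pd.DataFrame:
    """Per-class constraint metrics at printed precision."""
    rows = []
    for cls in ("syn", "mis", "lof"):
        lo, hi = result.oe_ci90[cls]
        rows.append(
            {
                "class": cls,
                "oe": round(result.oe[cls], 2),
                "oe_ci90_low": round(lo, 2),
                "oe_ci90_high": round(hi, 2),
                "z": round(result.z[cls], 2),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["pLI"] = round(result.pLI, 2)
    df.attrs["labels"] = list(result.labels)
    return df


def census_summary(census: pd.DataFrame) -> pd.DataFrame:
    out = census.copy()
    out["pct_of_pathogenic"] = out["pct_of_pathogenic"].round(1)
    return out


def domain_summary(stats: pd.DataFrame) -> pd.DataFrame:
    out = stats.copy()
    out["pct_mutant_aa"] = out["pct_mutant_aa"].round(2)
    out["pct_individuals"] = out["pct_individuals"].round(2)
    return out
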