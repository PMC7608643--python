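"""Protein-domain burden of pathogenic missense mutations.

Each pathogenic missense variant is placed at its mutated residue on a
non-overlapping domain model; residues outside every domain fall in an
inter-domain ``linker`` bin.  Per domain the module reports the number of
distinct mutations, distinct mutated residues, carrier-individuals
(allele-derived het + hom per variant), and two length-normalised
percentages:

* ``pct_mutant_aa`` = 100 * distinct mutated residues / domain length
  (bounded by 100);
* ``pct_individuals`` = 100 * carrier-individuals / domain length, which may
  exceed 100 when a short domain harbours frequently carried mutations.

Truncating alleles (nonsense, frameshift, splice) affect every downstream
domain and are not placed; they are reported only as a count.
"""

from __future__ import annotations

import pandas as pd

from .io import Consequence, DomainModel, PopulationPanel, VariantRecord

LINKER = "linker"
SSD = "SSD"


def assign_domain(residue: int, model: DomainModel) -> str | None:
    """Name of the unique domain containing a 1-based residue, else None."""
    if not (1 <= residue <= model.protein_length):
        raise ValueError(
            f"residue {residue} outside protein 1..{model.protein_length}"
        )
    for d in model.domains:
        if d.start <= residue <= d.end:
            return d.name
    return None


def carriers_per_variant(
    variant: VariantRecord, panel: PopulationPanel
) -> int:
    """Allele-derived carrier-individuals: het + hom summed over groups."""
    total = 0
    for lab in panel.analysed_labels:
        c = variant.counts[lab]
        total += (c.ac - 2 * c.nhomalt) + c.nhomalt
    return total


def domain_stats(
    variants: list[VariantRecord],
    model: DomainModel,
    panel: PopulationPanel,
) -> tuple[pd.DataFrame, int]:
    """Per-domain burden table for pathogenic missense variants.

    Returns ``(table, n_skipped)`` where the table holds one row per domain
    (in sequence order) plus the linker bin and an SSD aggregate row summing
    the sterol-sensing-domain members, and ``n_skipped`` counts variants
    lacking a protein change (warned about, never fatal).
    """
    placements: dict[str, list[tuple[int, str, int]]] = {
        d.name: [] for d in model.domains
    }
    placements[LINKER] = []
    n_skipped = 0
    for v in variants:
        if v.consequence != Consequence.MISSENSE:
            continue
        if v.protein_change is None:
            n_skipped += 1
            continue
        res = v.protein_change.residue
        name = assign_domain(res, model) or LINKER
        placements[name].append((res, v.variant_id, carriers_per_variant(v, panel)))

    lengths = {d.name: d.length for d in model.domains}
    linker_len = model.protein_length - sum(lengths.values())
    lengths[LINKER] = linker_len

    rows = []
    for name in [d.name for d in model.domains] + [LINKER]:
        hits = placements[name]
        n_mut = len(hits)
        n_pos = len({res for res, _, _ in hits})
        n_ind = sum(carriers for _, _, carriers in hits)
        length = lengths[name]
        rows.append(
            {
                "domain": name,
                "length": length,
                "n_mutations": n_mut,
                "n_positions": n_pos,
                "n_individuals": n_ind,
                "pct_mutant_aa": 100.0 * n_pos / length if length else 0.0,
                "pct_individuals": 100.0 * n_ind / length if length else 0.0,
            }
        )
    # SSD aggregate over flagged member domains
    ssd_names = [d.name for d in model.domains if d.in_ssd]
    ssd_hits = [h for n in ssd_names for h in placements[n]]
    ssd_len = sum(lengths[n] for n in ssd_names)
    rows.append(
        {
            "domain": SSD,
            "length": ssd_len,
            "n_mutations": len(ssd_hits),
            "n_positions": len({res for res, _, _ in ssd_hits}),
            "n_individuals": sum(c for _, _, c in ssd_hits),
            "pct_mutant_aa": (
                100.0 * len({res for res, _, _ in ssd_hits}) / ssd_len
                if ssd_len
                else 0.0
            ),
            "pct_individuals": (
                100.0 * sum(c for _, _, c in ssd_hits) / ssd_len
                if ssd_len
                else 0.0
            ),
        }
    )
    df = pd.DataFrame(rows)
    return df, n_skipped


def truncating_count(variants: list[VariantRecord]) -> int:
    """Count of pathogenic truncating (non-missense) alleles, reported
    separately because they are not placed on the domain model."""
    return sum(1 for v in variants if v.consequence != Consequence.MISSENSE)
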