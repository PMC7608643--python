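import pytest

from rarecarrier.io import (
    Consequence,
    GroupCounts,
    PopulationGroup,
    PopulationPanel,
    ProteinChange,
    VariantRecord,
)


@pytest.fixture(scope="session")
def small_panel() -> PopulationPanel:
    """Two analysed groups plus an excluded catch-all."""
    return PopulationPanel(
        groups=(
            PopulationGroup("afr", 8128, 3093, 5035),
            PopulationGroup("asj", 5040, 2590, 2450),
            PopulationGroup("oth", 3070, 1535, 1535),
        ),
        other_label="oth",
    )


@pytest.fixture(scope="session")
def full_panel() -> PopulationPanel:
    from rarecarrier.simulate import default_panel

    return default_panel()


def make_variant(
    panel: PopulationPanel,
    pos: int = 1000,
    consequence: Consequence = Consequence.MISSENSE,
    counts: dict | None = None,
    protein_change: str | None = "G149R",
    **kwargs,
) -> VariantRecord:
    """Build a record with zero counts everywhere except ``counts``, which
    maps group label -> (ac, nhomalt) or a full GroupCounts."""
    counts = counts or {}
    full = {}
    for g in panel.groups:
        spec = counts.get(g.label, (0, 0))
        if isinstance(spec, GroupCounts):
            full[g.label] = spec
            continue
        ac, nhom = spec
        # attribute alleles male-first for reproducibility in fixtures
        hom_m = min(nhom, g.n_male)
        het = ac - 2 * nhom
        full[g.label] = GroupCounts(
            ac=ac,
            an=g.n_alleles,
            nhomalt=nhom,
            ac_male=2 * hom_m + het,
            ac_female=2 * (nhom - hom_m),
            nhomalt_male=hom_m,
            nhomalt_female=nhom - hom_m,
        )
    needs_pch = consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS)
    return VariantRecord(
        chrom="18",
        pos=pos,
        ref=kwargs.pop("ref", "A"),
        alt=kwargs.pop("alt", "G"),
        gene="GENE1",
        consequence=consequence,
        protein_change=(
            ProteinChange.parse(protein_change)
            if (protein_change and needs_pch)
            else None
        ),
        isoform=kwargs.pop("isoform", "1"),
        counts=full,
        **kwargs,
    )
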