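"""Data model and I/O for variant tables, domain models, and population panels.

The variant table follows the gnomAD v2 export convention: per-population
allele counts are carried as ``AC_<pop>``, ``AN_<pop>``, ``nhomalt_<pop>``
with sex-split counts ``AC_<pop>_male`` / ``AC_<pop>_female`` (and optional
``nhomalt_<pop>_male`` / ``nhomalt_<pop>_female``).  Two dialects of the same
schema are supported: VCF 4.2 with those keys as INFO fields plus a
CSQ-style ``ANN`` field, and a flat TSV with one variant per row using the
same names as columns and ``.`` for missing values.  Both dialects of the
same cohort load to identical record lists.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml


class LoadError(Exception):
    """A required field or file-level structure is missing or malformed."""


class ValidationError(Exception):
    """A loaded record violates a data-model invariant."""


class Consequence(enum.StrEnum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    FRAMESHIFT = "frameshift"
    START_LOST = "start_lost"
    STOP_LOST = "stop_lost"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class Sift(enum.StrEnum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class PolyPhen(enum.StrEnum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class ClinVar(enum.StrEnum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


@dataclass(frozen=True)
class PopulationGroup:
    label: str
    n_individuals: int
    n_male: int
    n_female: int

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_individuals:
            raise ValidationError(
                f"group {self.label!r}: n_male + n_female "
                f"({self.n_male} + {self.n_female}) != n_individuals "
                f"({self.n_individuals})"
            )

    @property
    def n_alleles(self) -> int:
        """Total autosomal alleles: two per sequenced individual."""
        return 2 * self.n_individuals


@dataclass(frozen=True)
class PopulationPanel:
    """Ancestry groups of a cohort.

    The group named by ``other_label`` (a catch-all of unassigned ancestries)
    is kept in the file model but excluded from every analysis.
    """

    groups: tuple[PopulationGroup, ...]
    other_label: str | None = None

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate group labels in panel")
        if self.other_label is not None and self.other_label not in labels:
            raise ValidationError(
                f"other_label {self.other_label!r} names no panel group"
            )

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def analysed(self) -> list[PopulationGroup]:
        """All groups except the excluded catch-all."""
        return [g for g in self.groups if g.label != self.other_label]

    @property
    def analysed_labels(self) -> list[str]:
        return [g.label for g in self.analysed]

    def group(self, label: str) -> PopulationGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            groups = tuple(
                PopulationGroup(
                    label=str(g["label"]),
                    n_individuals=int(g["n"]),
                    n_male=int(g["n_male"]),
                    n_female=int(g["n_female"]),
                )
                for g in doc["groups"]
            )
        except KeyError as exc:
            raise LoadError(f"panel file {path}: missing key {exc}") from exc
        return cls(groups=groups, other_label=doc.get("other_label"))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "groups": [
                {
                    "label": g.label,
                    "n": g.n_individuals,
                    "n_male": g.n_male,
                    "n_female": g.n_female,
                }
                for g in self.groups
            ],
            "other_label": self.other_label,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


_PCHANGE_RE = re.compile(r"^(?:p\.)?([A-Z*])(\d+)([A-Z*]|fs)$")


@dataclass(frozen=True)
class ProteinChange:
    """Amino-acid consequence on the canonical isoform, 1-based residue.

    ``alt_aa`` is a one-letter code, ``*`` for a gained stop, or ``fs`` for a
    frameshift marker.
    """

    ref_aa: str
    residue: int
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"

    @classmethod
    def parse(cls, text: str) -> "ProteinChange":
        m = _PCHANGE_RE.match(text)
        if not m:
            raise LoadError(f"unparseable protein change {text!r}")
        return cls(ref_aa=m.group(1), residue=int(m.group(2)), alt_aa=m.group(3))


@dataclass(frozen=True)
class GroupCounts:
    """Allele counts of one variant within one ancestry group."""

    ac: int
    an: int
    nhomalt: int
    ac_male: int
    ac_female: int
    nhomalt_male: int | None = None
    nhomalt_female: int | None = None


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    protein_change: ProteinChange | None
    isoform: str
    counts: dict[str, GroupCounts]
    sift: Sift = Sift.MISSING
    polyphen: PolyPhen = PolyPhen.MISSING
    clinvar: ClinVar = ClinVar.ABSENT
    qc_flag: bool = False

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    def total_ac(self, labels: Iterable[str]) -> int:
        return sum(self.counts[lab].ac for lab in labels)


def validate_record(record: VariantRecord, panel: PopulationPanel) -> None:
    """Check every count invariant of one record against the panel."""
    for g in panel.groups:
        if g.label not in record.counts:
            raise ValidationError(
                f"{record.variant_id}: no counts for panel group {g.label!r}"
            )
        c = record.counts[g.label]
        if not (0 <= 2 * c.nhomalt <= c.ac <= c.an <= g.n_alleles):
            raise ValidationError(
                f"{record.variant_id} [{g.label}]: require "
                f"0 <= 2*nhomalt ({2 * c.nhomalt}) <= ac ({c.ac}) "
                f"<= an ({c.an}) <= 2*n ({g.n_alleles})"
            )
        if c.ac_male + c.ac_female != c.ac:
            raise ValidationError(
                f"{record.variant_id} [{g.label}]: ac_male + ac_female "
                f"({c.ac_male} + {c.ac_female}) != ac ({c.ac})"
            )
        if c.nhomalt_male is not None and c.nhomalt_female is not None:
            if c.nhomalt_male + c.nhomalt_female != c.nhomalt:
                raise ValidationError(
                    f"{record.variant_id} [{g.label}]: homozygote sex split "
                    f"does not sum to nhomalt"
                )
    if (
        record.consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS)
        and record.protein_change is None
    ):
        raise ValidationError(
            f"{record.variant_id}: {record.consequence} without protein_change"
        )


# ---------------------------------------------------------------------------
# TSV dialect

_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "protein_change",
    "isoform",
    "sift",
    "polyphen",
    "clinvar",
    "qc_flag",
]


def _count_columns(label: str) -> list[str]:
    return [
        f"AC_{label}",
        f"AN_{label}",
        f"nhomalt_{label}",
        f"AC_{label}_male",
        f"AC_{label}_female",
    ]


def _record_from_row(row: dict, labels: Sequence[str], where: str) -> VariantRecord:
    counts: dict[str, GroupCounts] = {}
    for lab in labels:
        try:
            nh_m = row.get(f"nhomalt_{lab}_male")
            nh_f = row.get(f"nhomalt_{lab}_female")
            counts[lab] = GroupCounts(
                ac=int(row[f"AC_{lab}"]),
                an=int(row[f"AN_{lab}"]),
                nhomalt=int(row[f"nhomalt_{lab}"]),
                ac_male=int(row[f"AC_{lab}_male"]),
                ac_female=int(row[f"AC_{lab}_female"]),
                nhomalt_male=None if nh_m in (None, ".", "") else int(nh_m),
                nhomalt_female=None if nh_f in (None, ".", "") else int(nh_f),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LoadError(f"{where}: bad or missing count field for "
                            f"group {lab!r}: {exc}") from exc
    pch = row.get("protein_change")
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row["gene"]),
        consequence=Consequence(row["consequence"]),
        protein_change=None if pch in (None, ".", "") else ProteinChange.parse(pch),
        isoform=str(row["isoform"]),
        counts=counts,
        sift=Sift(row.get("sift") or "missing"),
        polyphen=PolyPhen(row.get("polyphen") or "missing"),
        clinvar=ClinVar(row.get("clinvar") or "absent"),
        qc_flag=str(row.get("qc_flag", "false")).lower() in ("true", "1", "yes"),
    )


def _tsv_labels(columns: Iterable[str]) -> list[str]:
    labels = []
    for col in columns:
        if col.startswith("AC_") and not col.endswith(("_male", "_female")):
            labels.append(col[3:])
    return labels


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    labels = _tsv_labels(df.columns)
    if not labels:
        raise LoadError(f"{path}: no per-population AC_<pop> columns found")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        clean = {k: (None if v == "." else v) for k, v in row.items()}
        records.append(_record_from_row(clean, labels, f"{path} line {i + 2}"))
    return records


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    labels = list(records[0].counts) if records else []
    has_hom_sex = any(
        c.nhomalt_male is not None for r in records for c in r.counts.values()
    )
    cols = list(_FIXED_COLUMNS)
    for lab in labels:
        cols += _count_columns(lab)
        if has_hom_sex:
            cols += [f"nhomalt_{lab}_male", f"nhomalt_{lab}_female"]
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "consequence": str(r.consequence),
            "protein_change": str(r.protein_change) if r.protein_change else ".",
            "isoform": r.isoform,
            "sift": str(r.sift),
            "polyphen": str(r.polyphen),
            "clinvar": str(r.clinvar),
            "qc_flag": str(r.qc_flag).lower(),
        }
        for lab in labels:
            c = r.counts[lab]
            row[f"AC_{lab}"] = c.ac
            row[f"AN_{lab}"] = c.an
            row[f"nhomalt_{lab}"] = c.nhomalt
            row[f"AC_{lab}_male"] = c.ac_male
            row[f"AC_{lab}_female"] = c.ac_female
            if has_hom_sex:
                row[f"nhomalt_{lab}_male"] = (
                    "." if c.nhomalt_male is None else c.nhomalt_male
                )
                row[f"nhomalt_{lab}_female"] = (
                    "." if c.nhomalt_female is None else c.nhomalt_female
                )
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect

_ANN_FIELDS = "consequence|protein_change|isoform|sift|polyphen|clinvar|flag"


def _vcf_header(labels: Sequence[str], has_hom_sex: bool):
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add("1", length=249250621)
    header.contigs.add("18", length=78077248)
    for lab in labels:
        header.info.add(f"AC_{lab}", "A", "Integer", f"Alt allele count, {lab}")
        header.info.add(f"AN_{lab}", 1, "Integer", f"Total alleles, {lab}")
        header.info.add(f"nhomalt_{lab}", "A", "Integer",
                        f"Homozygous-alt individuals, {lab}")
        header.info.add(f"AC_{lab}_male", "A", "Integer",
                        f"Alt allele count in males, {lab}")
        header.info.add(f"AC_{lab}_female", "A", "Integer",
                        f"Alt allele count in females, {lab}")
        if has_hom_sex:
            header.info.add(f"nhomalt_{lab}_male", "A", "Integer",
                            f"Homozygous-alt males, {lab}")
            header.info.add(f"nhomalt_{lab}_female", "A", "Integer",
                            f"Homozygous-alt females, {lab}")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("ANN", "A", "String", f"Annotation: {_ANN_FIELDS}")
    return header


def write_variant_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write one VCF line per record (sites stay biallelic on output)."""
    import pysam

    labels = list(records[0].counts) if records else []
    has_hom_sex = any(
        c.nhomalt_male is not None for r in records for c in r.counts.values()
    )
    header = _vcf_header(labels, has_hom_sex)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            for lab in labels:
                c = r.counts[lab]
                rec.info[f"AC_{lab}"] = (c.ac,)
                rec.info[f"AN_{lab}"] = c.an
                rec.info[f"nhomalt_{lab}"] = (c.nhomalt,)
                rec.info[f"AC_{lab}_male"] = (c.ac_male,)
                rec.info[f"AC_{lab}_female"] = (c.ac_female,)
                if has_hom_sex and c.nhomalt_male is not None:
                    rec.info[f"nhomalt_{lab}_male"] = (c.nhomalt_male,)
                    rec.info[f"nhomalt_{lab}_female"] = (c.nhomalt_female,)
            rec.info["GENE"] = r.gene
            ann = "|".join(
                [
                    str(r.consequence),
                    str(r.protein_change) if r.protein_change else "",
                    r.isoform,
                    str(r.sift),
                    str(r.polyphen),
                    str(r.clinvar),
                    "flagged" if r.qc_flag else "ok",
                ]
            )
            rec.info["ANN"] = (ann,)
            vcf.write(rec)


def _info_alt(value, i: int):
    """INFO values declared Number=A arrive as tuples; pick the i-th alt."""
    if isinstance(value, tuple):
        return value[i]
    return value


def read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the VCF dialect; multi-allelic sites are decomposed per alt.

    AN is site-level and is duplicated across the decomposed records.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        labels = [
            key[3:]
            for key in vcf.header.info
            if key.startswith("AC_") and not key.endswith(("_male", "_female"))
        ]
        if not labels:
            raise LoadError(f"{path}: no AC_<pop> INFO keys declared")
        for site in vcf:
            alts = site.alts or ()
            for i, alt in enumerate(alts):
                info = site.info
                try:
                    anns = info["ANN"]
                except KeyError as exc:
                    raise LoadError(
                        f"{path} pos {site.pos}: missing ANN field"
                    ) from exc
                parts = _info_alt(anns, i).split("|")
                if len(parts) != 7:
                    raise LoadError(
                        f"{path} pos {site.pos}: ANN needs 7 fields "
                        f"({_ANN_FIELDS})"
                    )
                cons, pch, isoform, sift, poly, clin, flag = parts
                counts = {}
                for lab in labels:
                    try:
                        nh_m = (
                            _info_alt(info[f"nhomalt_{lab}_male"], i)
                            if f"nhomalt_{lab}_male" in info
                            else None
                        )
                        nh_f = (
                            _info_alt(info[f"nhomalt_{lab}_female"], i)
                            if f"nhomalt_{lab}_female" in info
                            else None
                        )
                        counts[lab] = GroupCounts(
                            ac=_info_alt(info[f"AC_{lab}"], i),
                            an=info[f"AN_{lab}"],
                            nhomalt=_info_alt(info[f"nhomalt_{lab}"], i),
                            ac_male=_info_alt(info[f"AC_{lab}_male"], i),
                            ac_female=_info_alt(info[f"AC_{lab}_female"], i),
                            nhomalt_male=nh_m,
                            nhomalt_female=nh_f,
                        )
                    except KeyError as exc:
                        raise LoadError(
                            f"{path} pos {site.pos}: missing INFO key {exc} "
                            f"for group {lab!r}"
                        ) from exc
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        gene=info.get("GENE", ""),
                        consequence=Consequence(cons),
                        protein_change=(
                            ProteinChange.parse(pch) if pch else None
                        ),
                        isoform=isoform,
                        counts=counts,
                        sift=Sift(sift),
                        polyphen=PolyPhen(poly),
                        clinvar=ClinVar(clin),
                        qc_flag=flag == "flagged",
                    )
                )
    return records


def read_variant_table(
    path: str | Path,
    dialect: str = "auto",
    panel: PopulationPanel | None = None,
    collect_errors: bool = False,
):
    """Load a variant table in either dialect.

    With a panel, every record is validated; ``collect_errors=True`` returns
    ``(records, rejections)`` where rejections are ``(variant_id, message)``
    pairs instead of raising — no row is ever silently dropped.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix in (".vcf", ".bcf", ".gz") else "tsv"
    if dialect == "vcf":
        records = read_variant_vcf(path)
    elif dialect == "tsv":
        records = read_variant_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if panel is not None:
        kept, rejections = [], []
        for rec in records:
            try:
                validate_record(rec, panel)
            except ValidationError as exc:
                if not collect_errors:
                    raise
                rejections.append((rec.variant_id, str(exc)))
            else:
                kept.append(rec)
        if collect_errors:
            return kept, rejections
        return kept
    if collect_errors:
        return records, []
    return records


# ---------------------------------------------------------------------------
# Domain model

class DomainCategory(enum.StrEnum):
    LUMINAL = "luminal"
    CYTOPLASMIC = "cytoplasmic"
    TRANSMEMBRANE = "transmembrane"


@dataclass(frozen=True)
class Domain:
    name: str
    category: DomainCategory
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    in_ssd: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainModel:
    """Non-overlapping protein-domain intervals; residues between domains
    fall in an implicit inter-domain linker bin."""

    protein_length: int
    domains: tuple[Domain, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate domain names")
        for d in self.domains:
            if not (1 <= d.start <= d.end <= self.protein_length):
                raise ValidationError(
                    f"domain {d.name}: interval [{d.start},{d.end}] outside "
                    f"1..{self.protein_length} or end < start"
                )
        by_start = sorted(self.domains, key=lambda d: d.start)
        for a, b in zip(by_start, by_start[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"domains {a.name} and {b.name} overlap "
                    f"([{a.start},{a.end}] vs [{b.start},{b.end}])"
                )
        object.__setattr__(self, "domains", tuple(by_start))


def read_domain_model(path: str | Path) -> DomainModel:
    """Read a domain TSV (name, category, start, end, in_ssd).

    Protein length is carried in a ``# protein_length=<n>`` comment line.
    """
    protein_length = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.search(r"protein_length\s*=\s*(\d+)", line)
                if m:
                    protein_length = int(m.group(1))
    if protein_length is None:
        raise LoadError(f"{path}: no '# protein_length=<n>' comment line")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["name", "category", "start", "end", "in_ssd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing domain columns {missing}")
    domains = tuple(
        Domain(
            name=str(r["name"]),
            category=DomainCategory(r["category"]),
            start=int(r["start"]),
            end=int(r["end"]),
            in_ssd=bool(r["in_ssd"]) if isinstance(r["in_ssd"], (bool,)) else
            str(r["in_ssd"]).lower() in ("true", "1", "yes"),
        )
        for r in df.to_dict("records")
    )
    return DomainModel(protein_length=protein_length, domains=domains)


# ---------------------------------------------------------------------------
# Generic result-table I/O

def write_table(rows, path: str | Path, format: str = "tsv") -> None:
    """Serialize a result table (DataFrame, dataclass, or list of dataclasses).

    Numbers are written at full precision; display rounding belongs to the
    report layer.  ``read_table`` round-trips what this writes.
    """
    if rows is None:
        raise ValueError("rows is None")
    if dataclasses.is_dataclass(rows) and not isinstance(rows, type):
        obj = dataclasses.asdict(rows)
        if format == "json":
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=str)
            return
        rows = pd.DataFrame([obj])
    elif isinstance(rows, list):
        rows = pd.DataFrame(
            [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
             for r in rows]
        )
    if not isinstance(rows, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(rows)}")
    if format == "tsv":
        index = rows.index.name is not None
        rows.to_csv(path, sep="\t", index=index)
    elif format == "json":
        # json.dump writes shortest round-trip float reprs (bit-exact on
        # re-read), unlike DataFrame.to_json which caps the precision
        payload = {
            "index_name": rows.index.name,
            "columns": [str(c) for c in rows.columns],
            "index": rows.index.tolist(),
            "data": rows.astype(object).to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=lambda o: o.item())
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["data"], columns=payload["columns"])
        df.index = pd.Index(payload["index"], name=payload["index_name"])
        return df
    raise ValueError(f"unknown format {format!r}")
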