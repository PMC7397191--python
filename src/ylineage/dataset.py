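"""Sample records, population datasets, tab-delimited I/O and variant filtering.

The on-disk format is a UTF-8 tab-separated table: ``SampleID``,
``Population``, one column per Y-STR locus (alleles as decimal repeat
counts, ``null``, or ``-``-joined multisets; DYS389II post-adjustment),
one column per Y-SNP (``A``/``D``/``N`` for ancestral/derived/missing)
and a ``Haplogroup`` column (``-`` when unassigned).  Round-tripping a
dataset through write/read is lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .haplotype import Haplotype, LocusCall, parse_allele
from .loci import PANEL_27, LocusDef

ANCESTRAL = "A"
DERIVED = "D"
MISSING = "N"

_SNP_STATES = {ANCESTRAL, DERIVED, MISSING}


@dataclass
class SampleRecord:
    """One genotyped male: Y-STR haplotype, Y-SNP profile, labels."""

    sample_id: str
    population: str
    haplotype: Haplotype
    snp_profile: dict[str, str] = field(default_factory=dict)
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        bad = {s for s in self.snp_profile.values()} - _SNP_STATES
        if bad:
            raise ValueError(f"{self.sample_id}: invalid SNP states {sorted(bad)}")


@dataclass
class PopulationDataset:
    """An ordered collection of samples sharing a locus panel and SNP panel."""

    samples: list[SampleRecord]
    panel: tuple[LocusDef, ...] = PANEL_27
    snp_panel: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def populations(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.samples:
            if s.population not in out:
                out.append(s.population)
        return tuple(out)

    def subset(self, keep) -> "PopulationDataset":
        """New dataset with the samples for which ``keep(sample)`` is true."""
        return PopulationDataset(
            [s for s in self.samples if keep(s)], self.panel, self.snp_panel
        )

    def by_population(self, name: str) -> "PopulationDataset":
        return self.subset(lambda s: s.population == name)


@dataclass(frozen=True)
class VariantReport:
    """Null/intermediate/CNV annotations for every sample in a dataset.

    ``records`` has one row per (sample, locus, class) with the allele
    string; ``by_class``/``by_locus`` aggregate allele-level counts.
    """

    records: pd.DataFrame  # sample_id, population, locus, class, alleles
    by_class: dict[str, int]
    by_locus: dict[str, int]
    carriers: frozenset[str]

    def loci_for_sample(self, sample_id: str) -> dict[str, list[str]]:
        sub = self.records[self.records["sample_id"] == sample_id]
        out: dict[str, list[str]] = {}
        for _, row in sub.iterrows():
            out.setdefault(row["locus"], []).append(row["class"])
        return out


def classify_variants(dataset: PopulationDataset) -> VariantReport:
    """Annotate every sample with its null, intermediate and CNV loci.

    A sample may carry several classes, and one locus call may belong to
    more than one class (e.g. a micro-variant allele inside a triallelic
    pattern counts as both intermediate and CNV).
    """
    rows = []
    by_class = {"null": 0, "intermediate": 0, "cnv": 0}
    by_locus: dict[str, int] = {}
    carriers: set[str] = set()
    for s in dataset:
        for locus_name, classes in s.haplotype.variant_loci.items():
            carriers.add(s.sample_id)
            call = s.haplotype.calls[locus_name]
            for cls in classes:
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "population": s.population,
                        "locus": locus_name,
                        "class": cls,
                        "alleles": str(call),
                    }
                )
                by_class[cls] += 1
                by_locus[locus_name] = by_locus.get(locus_name, 0) + 1
    records = pd.DataFrame(
        rows, columns=["sample_id", "population", "locus", "class", "alleles"]
    )
    return VariantReport(records, by_class, by_locus, frozenset(carriers))


def filter_for_distance(dataset: PopulationDataset) -> PopulationDataset:
    """Drop haplotypes carrying null, intermediate or CNV calls.

    Distance-based analyses (RST/AMOVA, individual d-values, networks of
    integer-step haplotypes) require complete single-valued repeat counts,
    so variant carriers are removed; the input dataset is unmodified.
    """
    kept = dataset.subset(lambda s: s.haplotype.is_variant_free)
    if len(kept) == 0 and len(dataset) > 0:
        warnings.warn(
            "all samples carry variant alleles; filtered dataset is empty",
            stacklevel=2,
        )
    return kept


class UnknownColumnError(ValueError):
    """The table header names loci absent from the declared panel."""


def write_table(dataset: PopulationDataset, path: str | Path) -> None:
    """Serialise a dataset to the canonical tab-separated layout."""
    cols = ["SampleID", "Population"]
    cols += [l.name for l in dataset.panel]
    cols += list(dataset.snp_panel)
    cols += ["Haplogroup"]
    rows = []
    for s in dataset:
        row = [s.sample_id, s.population]
        row += [str(s.haplotype.calls[l.name]) for l in dataset.panel]
        row += [s.snp_profile.get(snp, MISSING) for snp in dataset.snp_panel]
        row += [s.haplogroup if s.haplogroup is not None else "-"]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_table(
    path: str | Path,
    panel: tuple[LocusDef, ...] = PANEL_27,
    delimiters: str = "-/",
) -> PopulationDataset:
    """Read a tab-separated haplotype table.

    Columns other than ``SampleID``/``Population``/``Haplogroup`` and the
    panel's loci are taken to be Y-SNP columns when their values are all
    A/D/N; anything else raises :class:`UnknownColumnError`.
    """
    # keep_default_na=False: "null" is an allele token, not a missing value
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"SampleID", "Population"}
    if not required.issubset(df.columns):
        raise UnknownColumnError(f"missing required columns {required - set(df.columns)}")
    locus_names = {l.name for l in panel}
    snp_cols: list[str] = []
    unknown: list[str] = []
    for col in df.columns:
        if col in required or col == "Haplogroup" or col in locus_names:
            continue
        values = set(df[col].astype(str)) - {""}
        if values <= _SNP_STATES:
            snp_cols.append(col)
        else:
            unknown.append(col)
    if unknown:
        raise UnknownColumnError(f"unknown locus columns: {unknown}")
    missing_loci = [l.name for l in panel if l.name not in df.columns]
    if missing_loci:
        raise UnknownColumnError(f"panel loci absent from table: {missing_loci}")

    samples = []
    for _, row in df.iterrows():
        calls = {}
        for locus in panel:
            alleles = parse_allele(row[locus.name], delimiters=delimiters)
            calls[locus.name] = LocusCall(locus, alleles)
        profile = {snp: (row[snp] or MISSING) for snp in snp_cols}
        hap_label = row.get("Haplogroup", "-")
        samples.append(
            SampleRecord(
                sample_id=row["SampleID"],
                population=row["Population"],
                haplotype=Haplotype(calls),
                snp_profile=profile,
                haplogroup=None if hap_label in ("-", "") else hap_label,
            )
        )
    return PopulationDataset(samples, panel, tuple(snp_cols))


def write_variant_report(report: VariantReport, path: str | Path) -> None:
    report.records.to_csv(path, sep="\t", index=False)
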