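"""Forensic haplotype statistics: HD, MP, DC and per-locus gene diversity.

For a sample of n haplotypes with haplotype frequencies p_i:

    HD = n (1 - sum p_i^2) / (n - 1)        haplotype diversity
    MP = sum p_i^2                          match probability
    DC = N_d / N_t                          discrimination capacity

where N_d is the number of distinct haplotypes and N_t the sample size.
Gene diversity (GD) per locus is the same unbiased estimator applied to
allele frequencies, with n the allele-pool size (multi-copy loci pour
each allele of the multiset into the pool, and null alleles count as a
distinct allele class).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .dataset import PopulationDataset
from .haplogroups import HaplogroupTree
from .loci import LocusDef, get_panel


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Occurrence-count multiset of the haplotypes in a sample."""

    n_total: int
    multiplicities: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.multiplicities) != self.n_total:
            raise ValueError("multiplicities must sum to n_total")

    @property
    def n_distinct(self) -> int:
        return len(self.multiplicities)


@dataclass(frozen=True)
class ForensicParams:
    hd: float
    mp: float
    dc: float
    n: int
    n_distinct: int

    def rounded(self, places: int = 5) -> "ForensicParams":
        """Half-up rounding to the precision used in published tables."""

        def r(x: float) -> float:
            q = Decimal(1).scaleb(-places)
            return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

        return ForensicParams(r(self.hd), r(self.mp), r(self.dc), self.n, self.n_distinct)


def spectrum(
    dataset: PopulationDataset, panel: tuple[LocusDef, ...] | int | None = None
) -> HaplotypeSpectrum:
    """Haplotype occurrence spectrum over a locus panel.

    Haplotype identity is exact equality of every locus call, with
    multi-copy allele multisets compared as multisets.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset slice")
    if panel is None:
        panel = dataset.panel
    elif isinstance(panel, int):
        panel = get_panel(panel)
    counts = Counter(s.haplotype.restrict(panel).key() for s in dataset)
    return HaplotypeSpectrum(len(dataset), tuple(sorted(counts.values(), reverse=True)))


def forensic_params(s: HaplotypeSpectrum) -> ForensicParams:
    """HD, MP and DC from a haplotype spectrum (requires n >= 2)."""
    n = s.n_total
    if n < 2:
        raise ValueError("HD is undefined for fewer than 2 haplotypes")
    mp = sum((m / n) ** 2 for m in s.multiplicities)
    hd = n * (1.0 - mp) / (n - 1)
    dc = s.n_distinct / n
    return ForensicParams(hd=hd, mp=mp, dc=dc, n=n, n_distinct=s.n_distinct)


def gene_diversity(dataset: PopulationDataset, locus_name: str) -> float:
    """Unbiased gene diversity of one locus: GD = n(1 - sum p_i^2)/(n-1).

    n is the allele-pool size (every allele of every multiset); null
    alleles form their own allele class.
    """
    pool: Counter = Counter()
    for s in dataset:
        call = s.haplotype.calls[locus_name]
        for a in call.alleles:
            pool[a.tenths] += 1  # None groups the null class
    n = sum(pool.values())
    if n < 2:
        raise ValueError(f"{locus_name}: allele pool smaller than 2")
    sq = sum((c / n) ** 2 for c in pool.values())
    return n * (1.0 - sq) / (n - 1)


def gene_diversity_table(
    dataset: PopulationDataset, strata: dict[str, PopulationDataset] | None = None
) -> pd.DataFrame:
    """Per-locus GD for the whole dataset and any named sample strata."""
    strata = {"total": dataset, **(strata or {})}
    rows = []
    for name, sub in strata.items():
        for locus in dataset.panel:
            rows.append(
                {
                    "stratum": name,
                    "locus": locus.name,
                    "gd": gene_diversity(sub, locus.name),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def haplogroup_stratum(
    dataset: PopulationDataset, node_label: str, tree: HaplogroupTree
) -> PopulationDataset:
    """Samples whose haplogroup path passes through ``node_label``.

    Strata are closed under descent: a sample called O2a2b1a1 belongs to
    the K, O2, O2a2 and O2a2b strata as well.
    """
    return dataset.subset(
        lambda s: s.haplogroup is not None
        and tree.descends_from(s.haplogroup, node_label)
    )


def table_report(
    dataset: PopulationDataset,
    haplogroup_nodes: tuple[str, ...] = ("K", "O2", "O2a2", "O2a2b", "O2a2b1a1"),
    panels: tuple[int, ...] = (17, 27),
    tree: HaplogroupTree | None = None,
    round_places: int = 5,
) -> pd.DataFrame:
    """Forensic-parameter grid: population x panel x haplogroup stratum.

    Mirrors the layout of published per-population tables (HD, DC, MP,
    distinct haplotypes, sample size), with a ``Total`` stratum and one
    stratum per requested haplogroup node.  Strata with n < 2 are
    reported with NaN parameters rather than raising.
    """
    tree = tree or HaplogroupTree.default()
    rows = []
    for pop in dataset.populations:
        pop_ds = dataset.by_population(pop)
        strata: list[tuple[str, PopulationDataset]] = [("Total", pop_ds)]
        strata += [
            (node, haplogroup_stratum(pop_ds, node, tree))
            for node in haplogroup_nodes
        ]
        for stratum_name, sub in strata:
            for n_loci in panels:
                row = {
                    "population": pop,
                    "stratum": stratum_name,
                    "panel": n_loci,
                    "hd": float("nan"),
                    "dc": float("nan"),
                    "mp": float("nan"),
                    "n_distinct": None,
                    "n": len(sub),
                }
                if len(sub) >= 2:
                    fp = forensic_params(spectrum(sub, n_loci)).rounded(round_places)
                    row.update(
                        hd=fp.hd, dc=fp.dc, mp=fp.mp, n_distinct=fp.n_distinct
                    )
                rows.append(row)
    return pd.DataFrame(rows)
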