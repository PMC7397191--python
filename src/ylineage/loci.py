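"""Y-STR locus definitions: panels, copy numbers and mutation rates.

The 27-locus panel corresponds to the Yfiler Plus marker set; the nested
17-locus panel is the classic Yfiler set.  DYS385a/b and DYF387S1a/b are
multi-copy loci typed as unordered allele pairs.  Per-locus mutation rates
are per-generation point estimates drawn from the published pedigree
literature; they parameterise the stepwise-mutation simulator, the
mutation-rate weighting of the individual d-value distance, and the
median-joining network locus weights.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LocusDef:
    """A Y-STR locus.

    Attributes
    ----------
    name:
        Marker identifier, e.g. ``"DYS518"``.
    copy_number:
        Expected number of alleles per male (2 for DYS385a/b and
        DYF387S1a/b, otherwise 1).
    mutation_rate:
        Per-generation mutation rate (mutations/generation), > 0.
    in_panel17:
        Whether the locus belongs to the 17-locus subset.
    """

    name: str
    copy_number: int
    mutation_rate: float
    in_panel17: bool

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError(f"{self.name}: mutation_rate must be > 0")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")


# name, copy_number, mutation rate (per generation), member of 17-locus panel
_LOCUS_TABLE: list[tuple[str, int, float, bool]] = [
    ("DYS438",    1, 3.78e-4, True),
    ("DYS392",    1, 1.04e-3, True),
    ("DYS393",    1, 1.07e-3, True),
    ("DYS437",    1, 1.12e-3, True),
    ("DYS448",    1, 1.35e-3, True),
    ("DYS390",    1, 2.12e-3, True),
    ("DYS19",     1, 2.29e-3, True),
    ("DYS385ab",  2, 2.33e-3, True),
    ("DYS391",    1, 2.61e-3, True),
    ("DYS389I",   1, 2.46e-3, True),
    ("YGATAH4",   1, 2.83e-3, True),
    ("DYS533",    1, 4.10e-3, False),
    ("DYS635",    1, 3.52e-3, True),
    ("DYS389II",  1, 3.60e-3, True),
    ("DYS456",    1, 4.22e-3, True),
    ("DYS481",    1, 4.96e-3, False),
    ("DYS439",    1, 5.02e-3, True),
    ("DYS460",    1, 5.67e-3, False),
    ("DYS458",    1, 6.44e-3, True),
    ("DYS449",    1, 1.22e-2, False),
    ("DYS570",    1, 1.24e-2, False),
    ("DYS576",    1, 1.43e-2, False),
    ("DYF387S1ab", 2, 1.59e-2, False),
    ("DYS627",    1, 1.23e-2, False),
    ("DYS518",    1, 1.84e-2, False),
]

#: All 27 loci (multi-copy loci count twice toward the panel size).
PANEL_27: tuple[LocusDef, ...] = tuple(
    LocusDef(name, cn, mu, p17) for name, cn, mu, p17 in _LOCUS_TABLE
)

#: The nested 17-locus subset.
PANEL_17: tuple[LocusDef, ...] = tuple(l for l in PANEL_27 if l.in_panel17)

LOCUS_BY_NAME: dict[str, LocusDef] = {l.name: l for l in PANEL_27}

#: Default per-locus mutation-rate table (locus name -> rate/generation).
DEFAULT_MUTATION_RATES: dict[str, float] = {
    l.name: l.mutation_rate for l in PANEL_27
}


def panel_size(panel: tuple[LocusDef, ...]) -> int:
    """Number of allele slots in a panel (multi-copy loci count copy_number)."""
    return sum(l.copy_number for l in panel)


def get_panel(n_loci: int) -> tuple[LocusDef, ...]:
    """Return the 17- or 27-locus panel by its conventional size."""
    if n_loci == 17:
        return PANEL_17
    if n_loci == 27:
        return PANEL_27
    raise ValueError(f"unknown panel size {n_loci}; expected 17 or 27")
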