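"""Exact-decimal Y-STR allele model: alleles, locus calls, haplotypes.

Alleles are stored as scaled integers in tenths of a repeat unit so that
micro-variants compare exactly (37.2 is ``372`` tenths, never a binary
float).  A null allele (locus dropout) is a distinct sentinel, not a
number.  Multi-copy loci hold an unordered multiset of alleles,
serialised sorted ascending.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

from .loci import LOCUS_BY_NAME, LocusDef

_ALLELE_RE = re.compile(r"^\d+(\.\d)?$")

#: Fractional tenths classes observed at Y-STR loci (.1/.2/.3 micro-variants).
ALLOWED_TENTHS = (0, 1, 2, 3)


@total_ordering
@dataclass(frozen=True)
class Allele:
    """A single STR allele as tenths of a repeat, or the NULL sentinel.

    ``Allele(372)`` is allele 37.2; ``Allele(None)`` is a null allele.
    """

    tenths: int | None

    def __post_init__(self) -> None:
        if self.tenths is not None:
            if self.tenths < 0:
                raise ValueError("allele repeat count must be non-negative")
            if self.tenths % 10 not in ALLOWED_TENTHS:
                raise ValueError(
                    f"unsupported micro-variant fraction .{self.tenths % 10}"
                )

    @property
    def is_null(self) -> bool:
        return self.tenths is None

    @property
    def is_intermediate(self) -> bool:
        """True for micro-variant alleles with an incomplete repeat (.1/.2/.3)."""
        return self.tenths is not None and self.tenths % 10 != 0

    @classmethod
    def from_text(cls, token: str) -> "Allele":
        token = token.strip()
        if token.lower() == "null":
            return cls(None)
        if not _ALLELE_RE.match(token):
            raise AlleleParseError(f"malformed allele token: {token!r}")
        if "." in token:
            whole, frac = token.split(".")
            return cls(int(whole) * 10 + int(frac))
        return cls(int(token) * 10)

    def __str__(self) -> str:
        if self.tenths is None:
            return "null"
        whole, frac = divmod(self.tenths, 10)
        return f"{whole}.{frac}" if frac else str(whole)

    def __lt__(self, other: "Allele") -> bool:
        # nulls sort first so serialisation order is total and stable
        a = -1 if self.tenths is None else self.tenths
        b = -1 if other.tenths is None else other.tenths
        return a < b

    def __float__(self) -> float:
        if self.tenths is None:
            raise ValueError("null allele has no numeric value")
        return self.tenths / 10.0


NULL = Allele(None)


class AlleleParseError(ValueError):
    """A token could not be interpreted as an allele."""


def parse_allele(text: str, delimiters: str = "-/") -> tuple[Allele, ...]:
    """Parse an allele-string cell into a sorted allele multiset.

    Multi-allele strings use ``-`` or ``/`` between tokens (``"13-19-20"``).
    ``"null"`` (case-insensitive) is the dropout sentinel.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele string")
    tokens = re.split("[" + re.escape(delimiters) + "]", text.strip())
    return tuple(sorted(Allele.from_text(t) for t in tokens))


def adjust_dys389(raw_ii: Allele, raw_i: Allele) -> Allele:
    """DYS389II repeat count with the embedded DYS389I repeats subtracted.

    The DYS389 amplicon structure nests locus I inside locus II, so the raw
    II count double-counts the I repeats; all analyses use II − I.
    """
    if raw_ii.is_null or raw_i.is_null:
        raise NullAdjustmentError(
            "DYS389 adjustment undefined for null alleles; record DYS389II as null"
        )
    diff = raw_ii.tenths - raw_i.tenths
    if diff < 0:
        raise ValueError(
            f"DYS389II ({raw_ii}) smaller than DYS389I ({raw_i})"
        )
    return Allele(diff)


class NullAdjustmentError(ValueError):
    """DYS389II adjustment attempted on a null input."""


@dataclass(frozen=True)
class LocusCall:
    """Observed allele multiset at one locus for one sample."""

    locus: LocusDef
    alleles: tuple[Allele, ...]  # sorted ascending

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"{self.locus.name}: empty locus call")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_null(self) -> bool:
        return any(a.is_null for a in self.alleles)

    @property
    def is_intermediate(self) -> bool:
        return any(a.is_intermediate for a in self.alleles)

    @property
    def is_cnv(self) -> bool:
        """More alleles than the locus's expected copy number (e.g. triallelic)."""
        return len(self.alleles) > self.locus.copy_number

    @property
    def is_copy_anomaly(self) -> bool:
        """Any departure from the expected allele count (gain or loss)."""
        return len(self.alleles) != self.locus.copy_number

    @property
    def variant_classes(self) -> tuple[str, ...]:
        classes = []
        if self.is_null:
            classes.append("null")
        if self.is_intermediate:
            classes.append("intermediate")
        if self.is_cnv:
            classes.append("cnv")
        return tuple(classes)

    def __str__(self) -> str:
        return "-".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class Haplotype:
    """Complete Y-STR profile of one male over a declared panel.

    DYS389II is stored post-adjustment (DYS389I subtracted).
    """

    calls: dict[str, LocusCall] = field(hash=False)

    def __post_init__(self) -> None:
        for name, call in self.calls.items():
            if call.locus.name != name:
                raise ValueError(f"call keyed {name} refers to {call.locus.name}")

    def restrict(self, panel: tuple[LocusDef, ...]) -> "Haplotype":
        """Project onto a sub-panel (e.g. 27 -> 17 loci)."""
        missing = [l.name for l in panel if l.name not in self.calls]
        if missing:
            raise KeyError(f"haplotype lacks panel loci: {missing}")
        return Haplotype({l.name: self.calls[l.name] for l in panel})

    def key(self) -> tuple:
        """Hashable identity: exact equality of every locus call (multisets)."""
        return tuple(
            (name, tuple(a.tenths for a in self.calls[name].alleles))
            for name in sorted(self.calls)
        )

    @property
    def variant_loci(self) -> dict[str, tuple[str, ...]]:
        """Loci with null/intermediate/CNV calls, with their classes."""
        return {
            name: call.variant_classes
            for name, call in self.calls.items()
            if call.variant_classes
        }

    @property
    def is_variant_free(self) -> bool:
        return not self.variant_loci


def make_call(locus_name: str, alleles: str | tuple[Allele, ...]) -> LocusCall:
    """Convenience constructor: ``make_call("DYS518", "37.2")``."""
    locus = LOCUS_BY_NAME[locus_name]
    if isinstance(alleles, str):
        alleles = parse_allele(alleles)
    return LocusCall(locus, tuple(alleles))
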