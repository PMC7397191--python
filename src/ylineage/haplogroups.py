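"""Hierarchical Y-SNP panel: haplogroup assignment and frequency comparison.

The shipped panel is a 24-marker pedigree-tagging set resolving the major
East Asian paternal lineages (C2, D, N1a1, QR and the O sublineages down
to O2a2b1a1-M117).  The tree topology follows ISOGG/YCC nomenclature and
lives in an editable edge-list config (``data/haplogroup_tree.tsv``,
rows ``child<TAB>parent<TAB>label``); with no marker for the GHIJK level
in the panel, G-M201 attaches directly to the root.

A sample's haplogroup is the deepest marker whose entire root path is in
the derived state.  Missing states are treated as non-derived when walking
(conservative assignment) but never reported as conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.stats import chi2_contingency

from .dataset import ANCESTRAL, DERIVED, MISSING, PopulationDataset

ROOT = "ROOT"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class SNPDef:
    name: str
    parent: str  # marker name or ROOT


@dataclass(frozen=True)
class HaplogroupCall:
    """Result of walking one SNP profile down the tree."""

    label: str
    path: tuple[str, ...]  # derived markers, root -> assigned node
    conflicts: tuple[str, ...]  # derived markers off the chosen path

    @property
    def is_clean(self) -> bool:
        return not self.conflicts


class HaplogroupTree:
    """Rooted tree of binary markers with haplogroup labels per node."""

    def __init__(self, nodes: list[SNPDef], labels: dict[str, str]):
        self.nodes = {n.name: n for n in nodes}
        self.labels = dict(labels)
        self._validate()
        self._children: dict[str, list[str]] = {}
        for n in nodes:
            self._children.setdefault(n.parent, []).append(n.name)
        # precomputed root paths, each ordered root -> node
        self._paths: dict[str, tuple[str, ...]] = {}
        for name in self.nodes:
            path = []
            cur = name
            while cur != ROOT:
                path.append(cur)
                cur = self.nodes[cur].parent
            self._paths[name] = tuple(reversed(path))

    def _validate(self) -> None:
        for n in self.nodes.values():
            if n.parent != ROOT and n.parent not in self.nodes:
                raise ValueError(f"{n.name}: unknown parent {n.parent}")
        # cycle check: every node must reach ROOT
        for name in self.nodes:
            seen = set()
            cur = name
            while cur != ROOT:
                if cur in seen:
                    raise ValueError(f"cycle through {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent
        missing = set(self.nodes) - set(self.labels)
        if missing:
            raise ValueError(f"nodes without labels: {sorted(missing)}")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    def root_path(self, marker: str) -> tuple[str, ...]:
        return self._paths[marker]

    def children(self, marker: str) -> tuple[str, ...]:
        return tuple(self._children.get(marker, ()))

    def label_of(self, marker: str) -> str:
        return self.labels[marker]

    def marker_of_label(self, label: str) -> str:
        for m, lab in self.labels.items():
            if lab == label:
                return m
        raise KeyError(label)

    def descends_from(self, label: str, ancestor_label: str) -> bool:
        """True if ``label``'s node lies on or below ``ancestor_label``'s node."""
        if label == UNRESOLVED:
            return False
        anc = self.marker_of_label(ancestor_label)
        return anc in self.root_path(self.marker_of_label(label))

    @classmethod
    def from_config(cls, path: str | Path) -> "HaplogroupTree":
        df = pd.read_csv(
            path, sep="\t", names=["child", "parent", "label"], dtype=str
        )
        nodes = [SNPDef(r.child, r.parent) for r in df.itertuples()]
        labels = {r.child: r.label for r in df.itertuples()}
        return cls(nodes, labels)

    @classmethod
    def default(cls) -> "HaplogroupTree":
        ref = resources.files("ylineage.data").joinpath("haplogroup_tree.tsv")
        with resources.as_file(ref) as p:
            return cls.from_config(p)


def assign_haplogroup(
    profile: dict[str, str], tree: HaplogroupTree
) -> HaplogroupCall:
    """Most-derived consistent haplogroup for a Y-SNP state profile.

    The assigned node is the deepest marker whose entire root path is
    derived; among equally deep candidates the lexicographically smallest
    marker wins (a tie indicates conflicting derived states, which are
    reported).  An all-ancestral profile yields the ``unresolved`` label.
    """
    unknown = set(profile) - set(tree.markers)
    if unknown:
        raise KeyError(f"profile names unknown markers: {sorted(unknown)}")

    def state(m: str) -> str:
        return profile.get(m, MISSING)

    candidates = [
        m
        for m in tree.markers
        if all(state(p) == DERIVED for p in tree.root_path(m))
    ]
    derived_all = {m for m in tree.markers if state(m) == DERIVED}
    if not candidates:
        return HaplogroupCall(UNRESOLVED, (), tuple(sorted(derived_all)))
    best = min(candidates, key=lambda m: (-len(tree.root_path(m)), m))
    path = tree.root_path(best)
    conflicts = tuple(sorted(derived_all - set(path)))
    return HaplogroupCall(tree.label_of(best), path, conflicts)


def assign_all(
    dataset: PopulationDataset, tree: HaplogroupTree | None = None
) -> PopulationDataset:
    """Assign haplogroups in place for every sample; returns the dataset."""
    tree = tree or HaplogroupTree.default()
    for s in dataset:
        s.haplogroup = assign_haplogroup(s.snp_profile, tree).label
    return dataset


def haplogroup_frequencies(dataset: PopulationDataset) -> pd.DataFrame:
    """Per-population haplogroup counts and frequencies (long format).

    Frequencies within each population sum to 1 over assigned labels.
    """
    rows = []
    for pop in dataset.populations:
        sub = dataset.by_population(pop)
        counts: dict[str, int] = {}
        for s in sub:
            if s.haplogroup is None:
                raise ValueError(f"{s.sample_id}: haplogroup not assigned")
            counts[s.haplogroup] = counts.get(s.haplogroup, 0) + 1
        n = len(sub)
        for label in sorted(counts):
            rows.append(
                {
                    "population": pop,
                    "haplogroup": label,
                    "count": counts[label],
                    "frequency": counts[label] / n,
                }
            )
    return pd.DataFrame(rows, columns=["population", "haplogroup", "count", "frequency"])


def compare_snp_frequencies(
    dataset: PopulationDataset,
    correction_m: int | None = None,
    continuity: bool = True,
) -> pd.DataFrame:
    """Two-population 2x2 chi-square test per Y-SNP marker.

    Markers with no derived allele in either population are reported
    ``testable=False`` (no test possible).  ``correction_m`` defaults to
    the number of testable markers; the Bonferroni threshold is
    ``0.05 / correction_m``.  The continuity-corrected statistic is the
    default, matching the R ``chisq.test`` behaviour for 2x2 tables.
    """
    pops = dataset.populations
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {len(pops)}")
    markers = dataset.snp_panel
    counts = {}
    for marker in markers:
        table = []
        for pop in pops:
            sub = dataset.by_population(pop)
            d = sum(1 for s in sub if s.snp_profile.get(marker) == DERIVED)
            a = sum(1 for s in sub if s.snp_profile.get(marker) == ANCESTRAL)
            table.append((d, a))
        counts[marker] = table
    testable = [m for m in markers if sum(t[0] for t in counts[m]) > 0]
    m_corr = correction_m if correction_m is not None else len(testable)
    threshold = 0.05 / m_corr if m_corr else float("nan")
    rows = []
    for marker in markers:
        (d1, a1), (d2, a2) = counts[marker]
        row = {
            "snp": marker,
            f"derived_{pops[0]}": d1,
            f"derived_{pops[1]}": d2,
            f"ancestral_{pops[0]}": a1,
            f"ancestral_{pops[1]}": a2,
            "testable": marker in testable,
            "statistic": float("nan"),
            "p_value": float("nan"),
            "significant": False,
            "threshold": threshold,
        }
        if marker in testable:
            stat, p, _, _ = chi2_contingency(
                [[d1, a1], [d2, a2]], correction=continuity
            )
            row.update(statistic=stat, p_value=p, significant=bool(p < threshold))
        rows.append(row)
    return pd.DataFrame(rows)


def haplogroup_distribution_test(
    dataset: PopulationDataset, min_expected: float = 1.0
) -> dict:
    """Label-by-population chi-square over the full haplogroup table.

    Haplogroup categories whose total expected count falls below
    ``min_expected`` in any population are pooled into an ``other``
    category before testing.
    """
    freq = haplogroup_frequencies(dataset)
    table = freq.pivot_table(
        index="haplogroup", columns="population", values="count", fill_value=0
    )
    n_by_pop = table.sum(axis=0)
    grand = n_by_pop.sum()
    row_tot = table.sum(axis=1)
    expected = pd.DataFrame(
        {p: row_tot * n_by_pop[p] / grand for p in table.columns}
    )
    small = expected.min(axis=1) < min_expected
    if small.any():
        pooled = table.loc[small].sum(axis=0)
        table = table.loc[~small]
        table.loc["other"] = pooled
    stat, p, dof, _ = chi2_contingency(table.values)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "dof": int(dof),
        "n_categories": int(table.shape[0]),
    }
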