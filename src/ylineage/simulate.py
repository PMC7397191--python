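"""Seeded two-population Y-STR/Y-SNP simulator with truth logs.

The generator emulates the sampling design the analyses assume: two
populations with distinct haplogroup frequency vectors; within each
(population, haplogroup) cell, haplotypes evolve from a haplogroup
founder along a random-merge (Kingman-like) genealogy under a
single-step symmetric stepwise mutation model (each locus copy mutates
+-1 repeat with probability m_i per generation).  Population structure
arises because the two populations' per-haplogroup founders diverge from
a common founder for a configurable number of generations.  Y-SNP states
are set exactly consistent with the sample's true haplogroup.

Null alleles, ".2" micro-variants at DYS518 (optionally conditional on
the QR haplogroup) and copy-number variants are injected on top and
logged, so the variant classifier and the distance filter can be tested
against the injector's own record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ANCESTRAL, DERIVED, PopulationDataset, SampleRecord
from .haplogroups import HaplogroupTree
from .haplotype import NULL, Allele, Haplotype, LocusCall
from .loci import DEFAULT_MUTATION_RATES, PANEL_27, LocusDef

#: Modal founder allele (repeat units) per locus, in plausible Yfiler ranges.
DEFAULT_FOUNDER_ALLELES: dict[str, int] = {
    "DYS438": 10, "DYS392": 13, "DYS393": 12, "DYS437": 14, "DYS448": 19,
    "DYS390": 23, "DYS19": 15, "DYS385ab": 13, "DYS391": 10, "DYS389I": 12,
    "YGATAH4": 12, "DYS533": 11, "DYS635": 21, "DYS389II": 17, "DYS456": 15,
    "DYS481": 23, "DYS439": 12, "DYS460": 10, "DYS458": 16, "DYS449": 30,
    "DYS570": 17, "DYS576": 18, "DYF387S1ab": 36, "DYS627": 21, "DYS518": 38,
}

#: Haplogroup frequency vectors anchored on the two studied populations
#: (southern-like anchors O1a 16.3%, O1b 14.9%; northern-like anchors
#: O2a2b 23.3%, O2a1 18.4%; remaining mass spread over the minor clades).
YUNNAN_LIKE_FREQS: dict[str, float] = {
    "O1a": 0.163, "O1b": 0.149, "O2a2b1a1": 0.149, "O2a1": 0.127,
    "O2a2b": 0.115, "C2": 0.081, "O2": 0.030, "O2a2": 0.030,
    "O2a2a1a2": 0.020, "O1b2": 0.025, "N1a1": 0.020, "N": 0.010,
    "QR": 0.032, "D": 0.010, "D1a1a1": 0.015, "C": 0.008,
    "IJ": 0.006, "K": 0.010,
}
SHANDONG_LIKE_FREQS: dict[str, float] = {
    "O2a2b": 0.233, "O2a1": 0.184, "O2a2b1a1": 0.141, "C2": 0.128,
    "O1b": 0.066, "O1a": 0.040, "O2": 0.030, "O2a2": 0.025,
    "O2a2a1a2": 0.015, "O1b2": 0.010, "N1a1": 0.020, "N": 0.010,
    "QR": 0.060, "D": 0.005, "D1a1a1": 0.005, "C": 0.005,
    "IJ": 0.003, "K": 0.020,
}

#: Loci at which dropout (null) alleles are injected, mirroring the locus
#: spread reported for observed null alleles.
DEFAULT_NULL_LOCI = (
    "DYS448", "DYS390", "DYS391", "DYS456", "DYS481", "DYS460", "DYS458",
    "DYS449", "DYS570", "DYS576", "DYS627", "DYS518", "DYF387S1ab",
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n: int
    haplogroup_freqs: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        total = sum(self.haplogroup_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: frequencies sum to {total}, not 1")
        if any(not 0 <= f <= 1 for f in self.haplogroup_freqs.values()):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("Yunnan", 565, YUNNAN_LIKE_FREQS),
        PopulationSpec("Shandong", 305, SHANDONG_LIKE_FREQS),
    )
    mutation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    founder_alleles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FOUNDER_ALLELES)
    )
    #: generations separating each population's haplogroup founder from the
    #: shared founder (between-population divergence)
    divergence_generations: int = 40
    #: depth of the within-(population, haplogroup) genealogy
    within_generations: int = 100
    #: generations separating each haplogroup founder from the panel-wide
    #: modal haplotype (between-haplogroup differentiation)
    haplogroup_depth: int = 300
    null_prob: float = 0.0
    null_loci: tuple[str, ...] = DEFAULT_NULL_LOCI
    dot2_prob_qr: float = 0.0  # P(".2" at DYS518 | haplogroup under QR)
    cnv_prob: float = 0.0
    panel: tuple[LocusDef, ...] = PANEL_27

    def __post_init__(self) -> None:
        for p in (self.null_prob, self.dot2_prob_qr, self.cnv_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("injection probabilities must lie in [0, 1]")
        for g in (
            self.divergence_generations,
            self.within_generations,
            self.haplogroup_depth,
        ):
            if g < 0:
                raise ValueError("generation counts must be non-negative")


@dataclass
class SimTruth:
    """Oracle side-channel: what the generator actually did."""

    true_haplogroup: dict[str, str]
    #: one row per genealogy node (tips and internal): node, sample_id
    #: (tips only), population, haplogroup, parent node, branch length
    genealogy: pd.DataFrame
    mutation_log: pd.DataFrame  # population, haplogroup, locus, n_events, total_generations
    injection_log: pd.DataFrame  # sample_id, locus, class, detail
    locus_exposure: dict[str, float]  # locus -> total (generations x copies) simulated

    @property
    def variant_carriers(self) -> frozenset[str]:
        if self.injection_log.empty:
            return frozenset()
        return frozenset(self.injection_log["sample_id"])

    def clade_descendants(self, node: str) -> list[str]:
        """Sample ids of all tips below a genealogy node."""
        children: dict[str, list[str]] = {}
        for r in self.genealogy.itertuples():
            children.setdefault(r.parent, []).append(r.node)
        tips = dict(zip(self.genealogy["node"], self.genealogy["sample_id"]))
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            if tips.get(cur):
                out.append(tips[cur])
            stack.extend(children.get(cur, []))
        return sorted(out)


def _mutate(
    vec: dict[str, list[int]],
    gens: int,
    rates: dict[str, float],
    rng: np.random.Generator,
    events_out: dict[str, int] | None = None,
) -> dict[str, list[int]]:
    """Apply the single-step symmetric SMM for ``gens`` generations."""
    out = {k: list(v) for k, v in vec.items()}
    if gens <= 0:
        return out
    for name, copies in out.items():
        m = rates[name]
        for c in range(len(copies)):
            k = int(rng.binomial(gens, m))
            if k:
                step = int(rng.choice([-1, 1], size=k).sum())
                copies[c] = max(10, copies[c] + step * 10)  # floor at 1 repeat
                if events_out is not None:
                    events_out[name] = events_out.get(name, 0) + k
    return out


def _evolve_genealogy(
    founder: dict[str, list[int]],
    n: int,
    depth: int,
    rates: dict[str, float],
    rng: np.random.Generator,
    events: dict[str, int],
) -> tuple[list[dict[str, list[int]]], list[tuple[int, int, int]], float]:
    """Evolve ``n`` tips from the founder along a random-merge genealogy.

    Returns tip haplotypes (tips are node ids 0..n-1), the branch list
    (child, parent, generations; founder = -1), and the summed branch
    length in generations.
    """
    if n == 1:
        haps = _mutate(founder, depth, rates, rng, events)
        return [haps], [(0, -1, depth)], float(depth)
    merge_ages = sorted(int(round(a)) for a in rng.uniform(0, depth, size=n - 1))
    next_id = n
    lineages = [(i, 0) for i in range(n)]  # (node, age at which lineage starts)
    parent: dict[int, tuple[int, int]] = {}
    for age in merge_ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ta), (b, tb) = lineages[i], lineages[j]
        anc = next_id
        next_id += 1
        parent[a] = (anc, max(0, age - ta))
        parent[b] = (anc, max(0, age - tb))
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append((anc, age))
    for node, t in lineages:
        parent[node] = (-1, max(0, depth - t))

    children: dict[int, list[tuple[int, int]]] = {}
    for child, (anc, bl) in parent.items():
        children.setdefault(anc, []).append((child, bl))
    haps: dict[int, dict[str, list[int]]] = {-1: founder}
    stack = [-1]
    while stack:
        node = stack.pop()
        for child, bl in sorted(children.get(node, [])):
            haps[child] = _mutate(haps[node], bl, rates, rng, events)
            stack.append(child)
    branches = [(c, p, bl) for c, (p, bl) in sorted(parent.items())]
    total = float(sum(bl for _, _, bl in branches))
    return [haps[i] for i in range(n)], branches, total


def simulate(config: SimConfig) -> tuple[PopulationDataset, SimTruth]:
    """Generate a multi-population dataset and its truth log (seeded)."""
    rng = np.random.default_rng(config.seed)
    tree = HaplogroupTree.default()
    rates = config.mutation_rates
    panel = config.panel
    panel_by_name = {l.name: l for l in panel}

    all_labels = sorted(
        {lab for p in config.populations for lab in p.haplogroup_freqs}
    )
    for lab in all_labels:
        tree.marker_of_label(lab)  # validates the label exists

    base = {
        l.name: [config.founder_alleles[l.name] * 10] * l.copy_number
        for l in panel
    }
    hg_founder = {
        lab: _mutate(base, config.haplogroup_depth, rates, rng)
        for lab in all_labels
    }

    samples: list[SampleRecord] = []
    true_hg: dict[str, str] = {}
    geno_rows: list[dict] = []
    mut_rows: list[dict] = []
    exposure: dict[str, float] = {l.name: 0.0 for l in panel}

    for spec in config.populations:
        labels = sorted(spec.haplogroup_freqs)
        probs = np.array([spec.haplogroup_freqs[lab] for lab in labels])
        counts = rng.multinomial(spec.n, probs / probs.sum())
        pop_founders = {
            lab: _mutate(hg_founder[lab], config.divergence_generations, rates, rng)
            for lab in labels
        }
        serial = 0
        for lab, c in zip(labels, counts):
            if c == 0:
                continue
            ev: dict[str, int] = {}
            tips, branches, total_gens = _evolve_genealogy(
                pop_founders[lab], int(c), config.within_generations, rates, rng, ev
            )
            for l in panel:
                exposure[l.name] += total_gens * l.copy_number
            for locus_name in sorted(ev):
                mut_rows.append(
                    {
                        "population": spec.name,
                        "haplogroup": lab,
                        "locus": locus_name,
                        "n_events": ev[locus_name],
                        "total_generations": total_gens,
                    }
                )
            marker = tree.marker_of_label(lab)
            on_path = set(tree.root_path(marker))
            profile = {
                m: (DERIVED if m in on_path else ANCESTRAL) for m in tree.markers
            }
            clade = f"{spec.name}/{lab}"
            tip_sid = {
                t: f"{spec.name}-{lab}-{serial + t:04d}" for t in range(int(c))
            }
            for child, par, bl in branches:
                geno_rows.append(
                    {
                        "node": f"{clade}/{child}",
                        "sample_id": tip_sid.get(child, ""),
                        "population": spec.name,
                        "haplogroup": lab,
                        "parent": f"{clade}/founder" if par == -1 else f"{clade}/{par}",
                        "branch_generations": bl,
                    }
                )
            for t_idx, tip in enumerate(tips):
                sid = tip_sid[t_idx]
                calls = {
                    name: LocusCall(
                        panel_by_name[name], tuple(Allele(x) for x in copies)
                    )
                    for name, copies in tip.items()
                }
                samples.append(
                    SampleRecord(sid, spec.name, Haplotype(calls), dict(profile))
                )
                true_hg[sid] = lab
            serial += int(c)

    inj_rows = _inject_variants(samples, true_hg, config, tree, rng)

    dataset = PopulationDataset(samples, panel, tuple(tree.markers))
    truth = SimTruth(
        true_haplogroup=true_hg,
        genealogy=pd.DataFrame(
            geno_rows,
            columns=[
                "node", "sample_id", "population", "haplogroup",
                "parent", "branch_generations",
            ],
        ),
        mutation_log=pd.DataFrame(
            mut_rows,
            columns=["population", "haplogroup", "locus", "n_events", "total_generations"],
        ),
        injection_log=pd.DataFrame(
            inj_rows, columns=["sample_id", "locus", "class", "detail"]
        ),
        locus_exposure=exposure,
    )
    return dataset, truth


def _inject_variants(
    samples: list[SampleRecord],
    true_hg: dict[str, str],
    config: SimConfig,
    tree: HaplogroupTree,
    rng: np.random.Generator,
) -> list[dict]:
    rows: list[dict] = []
    panel_by_name = {l.name: l for l in config.panel}
    single_copy = [l.name for l in config.panel if l.copy_number == 1]
    for s in samples:
        calls = dict(s.haplotype.calls)
        touched: set[str] = set()

        if config.dot2_prob_qr > 0 and tree.descends_from(true_hg[s.sample_id], "QR"):
            if rng.random() < config.dot2_prob_qr:
                old = calls["DYS518"].alleles[0]
                new = Allele(old.tenths + 2)
                calls["DYS518"] = LocusCall(panel_by_name["DYS518"], (new,))
                touched.add("DYS518")
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "locus": "DYS518",
                        "class": "intermediate",
                        "detail": f"{old}->{new}",
                    }
                )

        if config.null_prob > 0:
            for locus_name in config.null_loci:
                if locus_name in touched:
                    continue
                if rng.random() < config.null_prob:
                    calls[locus_name] = LocusCall(panel_by_name[locus_name], (NULL,))
                    touched.add(locus_name)
                    rows.append(
                        {
                            "sample_id": s.sample_id,
                            "locus": locus_name,
                            "class": "null",
                            "detail": "dropout",
                        }
                    )

        if config.cnv_prob > 0 and rng.random() < config.cnv_prob:
            free = [l for l in single_copy if l not in touched]
            locus_name = free[int(rng.integers(len(free)))]
            old = calls[locus_name].alleles[0]
            extra = Allele(old.tenths + 10)
            calls[locus_name] = LocusCall(
                panel_by_name[locus_name], tuple(sorted((old, extra)))
            )
            touched.add(locus_name)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "locus": locus_name,
                    "class": "cnv",
                    "detail": f"{old}/{extra}",
                }
            )

        if touched:
            s.haplotype = Haplotype(calls)
    return rows


def make_fixture(name: str) -> tuple[PopulationDataset, SimTruth]:
    """Deterministic packaged datasets for tests and worked examples.

    Presets: ``tiny`` (10 samples), ``table1-like`` (870 samples split
    565/305 across the two population profiles, with variant injection),
    ``qr-network`` (a QR-only clade in which one DYS518 ".2" mutation
    arises on a single internal branch of the genealogy).
    """
    if name == "tiny":
        cfg = SimConfig(
            seed=101,
            populations=(
                PopulationSpec("Yunnan", 6, YUNNAN_LIKE_FREQS),
                PopulationSpec("Shandong", 4, SHANDONG_LIKE_FREQS),
            ),
        )
    elif name == "table1-like":
        cfg = SimConfig(
            seed=202,
            null_prob=0.0025,
            dot2_prob_qr=0.644,
            cnv_prob=0.012,
        )
    elif name == "qr-network":
        # the carrier clade is simulated as its own founder lineage with a
        # long stem (the ".2" mutation arises once, on that stem) inside a
        # QR-only background clade
        cfg = SimConfig(
            seed=303,
            populations=(
                PopulationSpec("QRbg", 33, {"QR": 1.0}),
                PopulationSpec("QRcar", 12, {"QR": 1.0}),
            ),
            divergence_generations=60,
            within_generations=20,
        )
        ds, truth = simulate(cfg)
        _add_dot2(ds, truth, [s.sample_id for s in ds if s.population == "QRcar"])
        return ds, truth
    else:
        raise KeyError(f"unknown preset {name!r}")
    return simulate(cfg)


def _add_dot2(
    ds: PopulationDataset, truth: SimTruth, carriers: list[str]
) -> None:
    """Give the named samples a DYS518 ".2" allele and log the injection."""
    carrier_set = set(carriers)
    rows = []
    lookup = {l.name: l for l in ds.panel}
    for s in ds:
        if s.sample_id in carrier_set:
            old = s.haplotype.calls["DYS518"].alleles[0]
            new = Allele(old.tenths + 2)
            calls = dict(s.haplotype.calls)
            calls["DYS518"] = LocusCall(lookup["DYS518"], (new,))
            s.haplotype = Haplotype(calls)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "locus": "DYS518",
                    "class": "intermediate",
                    "detail": f"{old}->{new}",
                }
            )
    truth.injection_log = pd.DataFrame(
        rows, columns=["sample_id", "locus", "class", "detail"]
    )
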