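"""Genetic distances: individual d/D values and population AMOVA with RST.

Individual level
----------------
The Y-STR distance between two variant-free haplotypes a, b over an
n-locus panel weights each locus by its mutation rate m_i:

    d(a, b) = (1/n) * sum_i (a_i - b_i)^2 / (2 m_i)

so slow loci (small m_i) contribute more per repeat difference.  The
Y-SNP distance is the normalised Hamming distance over L binary markers:

    D(a, b) = (#discordant markers) / L

Population level
----------------
RST is the microsatellite fixation index estimated from a two-level
AMOVA on squared allele-size differences: with among-group and
within-group variance components sigma2_a and sigma2_w,

    RST = sigma2_a / (sigma2_a + sigma2_w)

and its significance is evaluated by permuting individuals across groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .dataset import DERIVED, MISSING, PopulationDataset, filter_for_distance
from .haplotype import Haplotype
from .loci import DEFAULT_MUTATION_RATES


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with method metadata."""

    ids: tuple[str, ...]
    values: np.ndarray
    method: str  # "str_d" | "snp_D" | "rst"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def has_negative(self) -> bool:
        """RST estimates can dip below zero; flagged rather than clamped."""
        return bool((self.values < -1e-12).any())

    def floored(self) -> "DistanceMatrix":
        """Copy with negative entries floored at 0 (for ordination input)."""
        return DistanceMatrix(self.ids, np.maximum(self.values, 0.0), self.method)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in self.values[i]) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                fh.write(
                    f"{name[:10]:<10}" + " ".join(f"{x:.6f}" for x in self.values[i]) + "\n"
                )


class VariantAlleleError(ValueError):
    """A distance was requested on a haplotype still carrying variants."""


def _locus_values(hap: Haplotype, locus_name: str) -> tuple[float, ...]:
    call = hap.calls[locus_name]
    if call.variant_classes or call.is_copy_anomaly:
        raise VariantAlleleError(
            f"{locus_name}: variant or anomalous call {call}; "
            "apply filter_for_distance first"
        )
    return tuple(a.tenths / 10.0 for a in call.alleles)


def str_pair_distance(
    a: Haplotype,
    b: Haplotype,
    rates: dict[str, float] | None = None,
) -> float:
    """Mutation-rate-weighted squared-difference distance between haplotypes.

    Multi-copy loci pair their sorted allele multisets order-for-order
    (the minimum-cost pairing under squared differences) and each copy
    counts toward the locus total n.
    """
    rates = rates if rates is not None else DEFAULT_MUTATION_RATES
    if set(a.calls) != set(b.calls):
        raise ValueError("haplotypes are on different panels")
    total = 0.0
    n = 0
    for name in a.calls:
        if name not in rates:
            raise KeyError(f"no mutation rate for locus {name}")
        m = rates[name]
        va = _locus_values(a, name)
        vb = _locus_values(b, name)
        # sorted-order pairing minimises the sum of squared differences
        for x, y in zip(va, vb):
            total += (x - y) ** 2 / (2.0 * m)
            n += 1
    return total / n


def snp_pair_distance(
    a: dict[str, str],
    b: dict[str, str],
    markers: tuple[str, ...] | None = None,
    pairwise_complete: bool = False,
) -> float:
    """Normalised Hamming distance between two Y-SNP state profiles."""
    if markers is None:
        markers = tuple(sorted(set(a) | set(b)))
    use = []
    for m in markers:
        sa, sb = a.get(m, MISSING), b.get(m, MISSING)
        if MISSING in (sa, sb):
            if pairwise_complete:
                continue
            raise ValueError(f"missing state at {m}; set pairwise_complete=True to skip")
        use.append((sa, sb))
    if not use:
        raise ValueError("no jointly typed markers")
    return sum(sa != sb for sa, sb in use) / len(use)


def individual_distance_matrix(
    dataset: PopulationDataset,
    method: str = "str_d",
    rates: dict[str, float] | None = None,
) -> DistanceMatrix:
    """Full symmetric matrix of pairwise individual distances."""
    ids = tuple(s.sample_id for s in dataset)
    n = len(ids)
    mat = np.zeros((n, n))
    samples = list(dataset)
    for i, j in combinations(range(n), 2):
        if method == "str_d":
            d = str_pair_distance(samples[i].haplotype, samples[j].haplotype, rates)
        elif method == "snp_D":
            d = snp_pair_distance(
                samples[i].snp_profile, samples[j].snp_profile, dataset.snp_panel
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat, method)


# ---------------------------------------------------------------------------
# AMOVA / RST


@dataclass(frozen=True)
class AMOVAResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    rst: float
    p_value: float | None
    n_perm: int
    degenerate: bool = False


def allele_size_matrix(
    dataset: PopulationDataset, include_multicopy: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Samples-by-loci matrix of allele sizes (repeat units) for RST.

    Single-copy loci only by default; with ``include_multicopy`` the
    sorted slots of multi-copy loci enter as separate columns.
    """
    cols: list[tuple[str, int]] = []
    for locus in dataset.panel:
        n_slots = locus.copy_number if include_multicopy else 1
        if locus.copy_number > 1 and not include_multicopy:
            continue
        for slot in range(n_slots):
            cols.append((locus.name, slot))
    rows = []
    for s in dataset:
        row = []
        for name, slot in cols:
            vals = _locus_values(s.haplotype, name)
            row.append(vals[slot])
        rows.append(row)
    return np.asarray(rows, dtype=float), [f"{n}.{s}" if s else n for n, s in cols]


def _squared_distance_matrix(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return (diff**2).sum(axis=2)


def _ss_within(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_idx:
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _rst_from_d2(
    d2: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[float, float, float, float, float, bool]:
    n_tot = sum(len(idx) for idx in group_idx)
    k = len(group_idx)
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_within = _ss_within(d2, group_idx)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n_tot - k
    sigma2_w = ss_within / df_within
    n_prime = (n_tot - sum(len(i) ** 2 for i in group_idx) / n_tot) / df_among
    sigma2_a = (ss_among / df_among - sigma2_w) / n_prime
    denom = sigma2_a + sigma2_w
    if denom <= 0:
        return ss_among, ss_within, sigma2_a, sigma2_w, 0.0, True
    return ss_among, ss_within, sigma2_a, sigma2_w, sigma2_a / denom, False


def amova_rst(
    dataset: PopulationDataset,
    grouping: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    include_multicopy: bool = False,
    require_variant_free: bool = True,
) -> AMOVAResult:
    """Two-level AMOVA on squared allele-size differences with RST.

    Permutation significance shuffles individuals across groups (group
    sizes fixed); p = (#{permuted RST >= observed} + 1) / (n_perm + 1).
    """
    if require_variant_free:
        dataset = filter_for_distance(dataset)
    labels = grouping if grouping is not None else [s.population for s in dataset]
    if len(labels) != len(dataset):
        raise ValueError("grouping length does not match dataset")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("AMOVA requires at least two groups")
    group_idx = [np.flatnonzero(np.asarray(labels) == g) for g in uniq]
    for g, idx in zip(uniq, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    x, _ = allele_size_matrix(dataset, include_multicopy)
    d2 = _squared_distance_matrix(x)
    ss_a, ss_w, s2a, s2w, rst, degen = _rst_from_d2(d2, group_idx)
    k, n_tot = len(uniq), len(dataset)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = [len(i) for i in group_idx]
        bounds = np.cumsum(sizes)[:-1]
        hits = 0
        order = np.arange(n_tot)
        for _ in range(n_perm):
            rng.shuffle(order)
            perm_idx = np.split(order.copy(), bounds)
            _, _, _, _, rst_p, _ = _rst_from_d2(d2, perm_idx)
            if rst_p >= rst - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)

    return AMOVAResult(
        ss_among=ss_a,
        ss_within=ss_w,
        df_among=k - 1,
        df_within=n_tot - k,
        sigma2_among=s2a,
        sigma2_within=s2w,
        rst=rst,
        p_value=p_value,
        n_perm=n_perm,
        degenerate=degen,
    )


def pairwise_rst(
    dataset: PopulationDataset,
    populations: tuple[str, ...] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    include_multicopy: bool = False,
) -> tuple[DistanceMatrix, np.ndarray, float]:
    """RST and permutation p for every unordered population pair.

    Returns (RST matrix, p-value matrix, Bonferroni threshold
    alpha / C(k, 2)).
    """
    pops = populations if populations is not None else dataset.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    n_pairs = k * (k - 1) // 2
    threshold = alpha / n_pairs
    rst = np.zeros((k, k))
    pmat = np.ones((k, k))
    ss = np.random.SeedSequence(seed).spawn(n_pairs)
    for idx, (i, j) in enumerate(combinations(range(k), 2)):
        pair_ds = dataset.subset(lambda s: s.population in (pops[i], pops[j]))
        res = amova_rst(
            pair_ds,
            n_perm=n_perm,
            seed=ss[idx],
            include_multicopy=include_multicopy,
        )
        rst[i, j] = rst[j, i] = res.rst
        if res.p_value is not None:
            pmat[i, j] = pmat[j, i] = res.p_value
    return DistanceMatrix(tuple(pops), rst, "rst"), pmat, threshold
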