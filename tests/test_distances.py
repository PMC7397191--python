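"""Individual d/D distances and AMOVA-RST against independent oracles."""

import numpy as np
import pytest

from ylineage.dataset import PopulationDataset, SampleRecord
from ylineage.distances import (
    DistanceMatrix,
    VariantAlleleError,
    amova_rst,
    individual_distance_matrix,
    pairwise_rst,
    snp_pair_distance,
    str_pair_distance,
)
from ylineage.haplotype import Haplotype, make_call
from ylineage.loci import DEFAULT_MUTATION_RATES, PANEL_27
from ylineage.simulate import SimConfig, PopulationSpec, simulate


def hap_from_alleles(alleles: dict[str, str]) -> Haplotype:
    return Haplotype({k: make_call(k, v) for k, v in alleles.items()})


def toy_haplotypes(diffs: dict[str, int]):
    """Pair of 27-locus haplotypes differing by diffs[locus] repeats."""
    base = {}
    other = {}
    for locus in PANEL_27:
        a = "14-15" if locus.copy_number == 2 else "14"
        base[locus.name] = a
        d = diffs.get(locus.name, 0)
        if locus.copy_number == 2:
            other[locus.name] = f"{14 + d}-15"
        else:
            other[locus.name] = str(14 + d)
    return hap_from_alleles(base), hap_from_alleles(other)


class TestStrPairDistance:
    def test_identical_is_zero(self):
        a, b = toy_haplotypes({})
        assert str_pair_distance(a, b) == 0.0

    def test_single_locus_closed_form(self):
        a, b = toy_haplotypes({"DYS19": 1})
        m = DEFAULT_MUTATION_RATES["DYS19"]
        assert str_pair_distance(a, b) == pytest.approx(1 / (2 * m * 27))

    def test_three_locus_toy_hand_oracle(self):
        # rates 0.001 / 0.002 / 0.004, repeat differences 1 / 0 / 2:
        # (1/3) * (1/0.002 + 0 + 4/0.008) = 333.33...
        rates = {"DYS19": 0.001, "DYS390": 0.002, "DYS391": 0.004}
        a = hap_from_alleles({"DYS19": "14", "DYS390": "22", "DYS391": "10"})
        b = hap_from_alleles({"DYS19": "15", "DYS390": "22", "DYS391": "12"})
        assert str_pair_distance(a, b, rates) == pytest.approx(1000 / 3)

    def test_symmetry_and_rate_scaling(self):
        a, b = toy_haplotypes({"DYS19": 2, "DYS518": -1, "DYS385ab": 1})
        d1 = str_pair_distance(a, b)
        assert d1 == str_pair_distance(b, a)
        scaled = {k: 3 * v for k, v in DEFAULT_MUTATION_RATES.items()}
        assert str_pair_distance(a, b, scaled) == pytest.approx(d1 / 3)

    def test_intermediate_allele_directed_to_filter(self):
        # micro-variant carriers are excluded upstream of the d-value
        rates = {"DYS518": 0.01}
        a = hap_from_alleles({"DYS518": "37"})
        b = hap_from_alleles({"DYS518": "37.2"})
        with pytest.raises(VariantAlleleError, match="filter"):
            str_pair_distance(a, b, rates)

    def test_multicopy_minimum_pairing(self):
        rates = {"DYS385ab": 0.002}
        a = hap_from_alleles({"DYS385ab": "13-19"})
        b = hap_from_alleles({"DYS385ab": "14-18"})
        # sorted pairing (13-14, 19-18): (1 + 1) / (2 * 0.002) / 2 copies
        assert str_pair_distance(a, b, rates) == pytest.approx(
            (1 + 1) / (2 * 0.002) / 2
        )

    def test_variant_carrier_rejected(self):
        a, _ = toy_haplotypes({})
        bad = Haplotype({**a.calls, "DYS448": make_call("DYS448", "null")})
        with pytest.raises(VariantAlleleError):
            str_pair_distance(a, bad)

    def test_missing_rate_rejected(self):
        a, b = toy_haplotypes({})
        with pytest.raises(KeyError):
            str_pair_distance(a, b, {"DYS19": 0.001})


class TestSnpPairDistance:
    def test_identical_and_opposite(self):
        a = {f"S{i}": "A" for i in range(24)}
        b = {f"S{i}": "D" for i in range(24)}
        assert snp_pair_distance(a, a) == 0.0
        assert snp_pair_distance(a, b) == 1.0

    def test_quarter_discordant(self):
        a = {f"S{i}": "A" for i in range(24)}
        b = dict(a, **{f"S{i}": "D" for i in range(6)})
        assert snp_pair_distance(a, b) == pytest.approx(0.25)

    def test_missing_state_policy(self):
        a = {"S0": "A", "S1": "N"}
        b = {"S0": "D", "S1": "A"}
        with pytest.raises(ValueError, match="missing"):
            snp_pair_distance(a, b)
        assert snp_pair_distance(a, b, pairwise_complete=True) == 1.0

    def test_triangle_inequality_exhaustive_small(self):
        rng = np.random.default_rng(0)
        markers = tuple(f"S{i}" for i in range(8))
        profiles = [
            {m: ("A", "D")[bit] for m, bit in zip(markers, rng.integers(0, 2, 8))}
            for _ in range(12)
        ]
        for x in profiles:
            for y in profiles:
                for z in profiles:
                    dxy = snp_pair_distance(x, y, markers)
                    dyz = snp_pair_distance(y, z, markers)
                    dxz = snp_pair_distance(x, z, markers)
                    assert dxz <= dxy + dyz + 1e-12


class TestIndividualMatrix:
    def test_matrix_matches_pair_computation(self, tiny):
        ds, _ = tiny
        dm = individual_distance_matrix(ds, "str_d")
        samples = list(ds)
        for i in range(len(samples)):
            for j in range(len(samples)):
                expect = (
                    0.0
                    if i == j
                    else str_pair_distance(samples[i].haplotype, samples[j].haplotype)
                )
                assert dm.values[i, j] == pytest.approx(expect)

    def test_single_sample_zero_matrix(self, tiny):
        ds, _ = tiny
        one = PopulationDataset(ds.samples[:1], ds.panel, ds.snp_panel)
        dm = individual_distance_matrix(one, "snp_D")
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0.0


# ---------------------------------------------------------------------------
# AMOVA oracle: per-locus ANOVA sums of squares, computed with plain loops
# from allele values (an algebraically different route than the pairwise
# squared-distance form used by the implementation).


def amova_oracle(x: np.ndarray, labels: list[str]):
    groups = sorted(set(labels))
    k = len(groups)
    n = len(labels)
    members = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    ss_total = 0.0
    ss_within = 0.0
    for l in range(x.shape[1]):
        grand = sum(x[i, l] for i in range(n)) / n
        for i in range(n):
            ss_total += (x[i, l] - grand) ** 2
        for g in groups:
            gm = sum(x[i, l] for i in members[g]) / len(members[g])
            for i in members[g]:
                ss_within += (x[i, l] - gm) ** 2
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    s2w = ss_within / df_within
    n_prime = (n - sum(len(members[g]) ** 2 for g in groups) / n) / df_among
    s2a = (ss_among / df_among - s2w) / n_prime
    denom = s2a + s2w
    rst = 0.0 if denom <= 0 else s2a / denom
    return ss_among, ss_within, s2a, s2w, rst


def random_instance(rng):
    n_groups = rng.integers(2, 4)
    sizes = [int(rng.integers(2, 4)) for _ in range(n_groups)]
    while sum(sizes) > 8:
        sizes[np.argmax(sizes)] -= 1
        sizes = [max(2, s) for s in sizes]
    n_loci = int(rng.integers(1, 4))
    labels = [f"g{gi}" for gi, s in enumerate(sizes) for _ in range(s)]
    x = rng.integers(8, 18, size=(sum(sizes), n_loci)).astype(float)
    return x, labels


def dataset_from_matrix(x: np.ndarray, labels: list[str]) -> PopulationDataset:
    loci = [l for l in PANEL_27 if l.copy_number == 1][: x.shape[1]]
    samples = []
    for i, lab in enumerate(labels):
        calls = {
            l.name: make_call(l.name, str(int(x[i, j])))
            for j, l in enumerate(loci)
        }
        samples.append(SampleRecord(f"s{i}", lab, Haplotype(calls), {}))
    return PopulationDataset(samples, tuple(loci), ())


class TestAmovaRst:
    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(300):
            x, labels = random_instance(rng)
            ds = dataset_from_matrix(x, labels)
            res = amova_rst(ds, grouping=labels, n_perm=0)
            ssa, ssw, s2a, s2w, rst = amova_oracle(x, labels)
            assert res.ss_among == pytest.approx(ssa, abs=1e-9)
            assert res.ss_within == pytest.approx(ssw, abs=1e-9)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-9)
            assert res.sigma2_within == pytest.approx(s2w, abs=1e-9)
            if not res.degenerate:
                assert res.rst == pytest.approx(rst, abs=1e-9)
            n_checked += 1
        assert n_checked == 300

    def test_strong_structure_rst_near_one(self):
        # group means 10 vs 20 with +-1 jitter at one locus
        x = np.array([[10.0], [11.0], [9.0], [20.0], [21.0], [19.0]])
        labels = ["a"] * 3 + ["b"] * 3
        res = amova_rst(dataset_from_matrix(x, labels), grouping=labels, n_perm=0)
        assert res.rst > 0.9

    def test_degenerate_zero_variance_flagged(self):
        x = np.full((6, 2), 12.0)
        labels = ["a"] * 3 + ["b"] * 3
        res = amova_rst(dataset_from_matrix(x, labels), grouping=labels, n_perm=99)
        assert res.degenerate and res.rst == 0.0

    def test_group_smaller_than_two_rejected(self):
        x = np.arange(8.0).reshape(4, 2) + 10
        with pytest.raises(ValueError, match="fewer than 2"):
            amova_rst(
                dataset_from_matrix(x, ["a", "a", "a", "b"]),
                grouping=["a", "a", "a", "b"],
                n_perm=0,
            )

    def test_permutation_p_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(7)
        x, labels = random_instance(rng)
        ds = dataset_from_matrix(x, labels)
        r1 = amova_rst(ds, grouping=labels, n_perm=200, seed=5)
        r2 = amova_rst(ds, grouping=labels, n_perm=200, seed=5)
        assert r1.p_value == r2.p_value
        order = list(np.random.default_rng(1).permutation(len(labels)))
        ds_perm = PopulationDataset(
            [ds.samples[i] for i in order], ds.panel, ds.snp_panel
        )
        r3 = amova_rst(
            ds_perm, grouping=[labels[i] for i in order], n_perm=200, seed=5
        )
        assert r3.rst == pytest.approx(r1.rst)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(3)
        x, labels = random_instance(rng)
        res = amova_rst(dataset_from_matrix(x, labels), grouping=labels, n_perm=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0


class TestPairwiseRst:
    def test_bonferroni_thresholds(self):
        # 15 populations -> 105 pairs -> 0.05/105; printed rounding 0.0005
        assert 0.05 / 105 == pytest.approx(0.000476, abs=1e-6)
        rng = np.random.default_rng(0)
        ds, _ = simulate(
            SimConfig(
                seed=8,
                populations=(
                    PopulationSpec("A", 12, {"C2": 1.0}),
                    PopulationSpec("B", 12, {"C2": 1.0}),
                ),
            )
        )
        _, _, thr = pairwise_rst(ds, n_perm=0)
        assert thr == pytest.approx(0.05)

    def test_duplicated_population_rst_near_zero(self):
        ds, _ = simulate(
            SimConfig(
                seed=21,
                populations=(PopulationSpec("A", 20, {"C2": 0.5, "O1a": 0.5}),),
            )
        )
        # the same samples twice, labelled as two "populations"
        doubled = PopulationDataset(
            [
                SampleRecord(f"{s.sample_id}-{tag}", tag, s.haplotype, s.snp_profile)
                for tag in ("x", "y")
                for s in ds
            ],
            ds.panel,
            ds.snp_panel,
        )
        res = amova_rst(doubled, n_perm=199, seed=1)
        # identical groups: SS_among is exactly 0, so the unbiased
        # variance-component estimate is slightly negative (order 1/n)
        assert res.ss_among == pytest.approx(0.0, abs=1e-9)
        assert -0.1 < res.rst <= 0.0
        assert res.p_value > 0.05


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]), "rst")
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]), "rst")
    dm = DistanceMatrix(("a", "b"), np.array([[0.0, -0.2], [-0.2, 0.0]]), "rst")
    assert dm.has_negative and not dm.floored().has_negative
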