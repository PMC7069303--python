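"""Microsatellite statistics: GENEPOP I/O, diversity, HWE/LD, theta."""

import numpy as np
import pytest

from respoly.popgen import (GenotypeTable, diversity, hwe_test, ld_test,
                            rarefied_richness, read_genepop, wc_fst,
                            write_genepop)

TOY_GENEPOP = """toy data
Loc1
Loc2
Pop
a1 ,  0101 0102
a2 ,  0102 0202
a3 ,  0101 0000
Pop
b1 ,  0202 0101
b2 ,  0201 0102
b3 ,  0202 0202
"""


def test_read_genepop_toy(tmp_path):
    path = tmp_path / "toy.gen"
    path.write_text(TOY_GENEPOP)
    table = read_genepop(path)
    assert table.n == 6
    assert table.loci == ["Loc1", "Loc2"]
    assert len(np.unique(table.pops)) == 2
    # code 0000 is a missing call
    assert tuple(table.calls[2, 1]) == (0, 0)
    assert tuple(table.calls[3, 0]) == (2, 2)


def test_genepop_round_trip(tmp_path, data):
    table = data["genotypes"]
    path = tmp_path / "rt.gen"
    write_genepop(table, path)
    back = read_genepop(path)
    assert back.loci == table.loci
    assert back.individuals == table.individuals
    np.testing.assert_array_equal(back.calls, table.calls)
    # GENEPOP names each Pop block by its last individual; the lake-habitat
    # prefix must survive the round trip
    np.testing.assert_array_equal(
        np.array([p.rsplit("-", 1)[0] for p in back.pops]), table.pops)


@pytest.mark.parametrize("bad_line", ["x1 ,  010 0102", "x1 ,  0101"])
def test_read_genepop_errors(tmp_path, bad_line):
    path = tmp_path / "bad.gen"
    path.write_text(f"t\nLoc1\nLoc2\nPop\n{bad_line}\n")
    with pytest.raises(ValueError, match="line"):
        read_genepop(path)


def make_table(calls, pops=None):
    calls = np.asarray(calls)
    n = calls.shape[0]
    pops = np.array(["P-littoral"] * n) if pops is None else np.asarray(pops)
    loci = [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeTable([f"i{k}" for k in range(n)], pops, loci, calls)


def test_unbiased_he_worked_example():
    """10 individuals, two alleles at counts 10/10:
    He = (2n / (2n-1)) (1 - sum p^2) = (20/19) * 0.5."""
    calls = np.array([[[1, 2]]] * 5 + [[[1, 1]]] * 2 + [[[2, 2]]] * 2
                     + [[[2, 1]]])
    div = diversity(make_table(calls))
    row = div.iloc[0]
    assert row["He"] == pytest.approx((20 / 19) * 0.5, abs=1e-12)
    assert row["Ho"] == pytest.approx(0.6)
    assert row["F_IS"] == pytest.approx(1 - 0.6 / ((20 / 19) * 0.5), abs=1e-12)


def test_rarefied_richness_worked_example():
    """Counts (10, 10) rarefied to g=2: 2 (1 - C(10,2)/C(20,2))."""
    expected = 2 * (1 - 45 / 190)
    assert rarefied_richness({1: 10, 2: 10}, 2) == pytest.approx(expected,
                                                                 abs=1e-12)


def test_rarefaction_at_full_size_returns_na_and_is_monotone():
    counts = {1: 6, 2: 3, 3: 1}
    total = sum(counts.values())
    assert rarefied_richness(counts, total) == pytest.approx(3.0, abs=1e-9)
    values = [rarefied_richness(counts, g) for g in range(1, total + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        rarefied_richness(counts, total + 1)


def test_diversity_invariant_to_allele_relabeling():
    rng = np.random.default_rng(0)
    calls = rng.integers(1, 5, size=(30, 2, 2))
    pops = np.repeat(["A-littoral", "A-pelagic"], 15)
    d1 = diversity(make_table(calls, pops))
    relabel = {1: 7, 2: 3, 3: 9, 4: 1}
    calls2 = np.vectorize(relabel.get)(calls)
    d2 = diversity(make_table(calls2, pops))
    for col in ("NA", "Ho", "He", "F_IS", "A_R"):
        np.testing.assert_allclose(d1[col], d2[col], atol=1e-12)


def test_theta_invariant_to_relabeling_and_order():
    rng = np.random.default_rng(1)
    calls = rng.integers(1, 4, size=(40, 3, 2))
    pops = np.repeat(["A-littoral", "A-pelagic"], 20)
    t1 = wc_fst(make_table(calls, pops), grouping="pop", n_boot=50, seed=0)
    relabel = {1: 5, 2: 2, 3: 8}
    t2 = wc_fst(make_table(np.vectorize(relabel.get)(calls), pops),
                grouping="pop", n_boot=50, seed=0)
    perm = rng.permutation(40)
    t3 = wc_fst(make_table(calls[perm], pops[perm]), grouping="pop",
                n_boot=50, seed=0)
    assert t1.theta_global == pytest.approx(t2.theta_global, abs=1e-12)
    assert t1.theta_global == pytest.approx(t3.theta_global, abs=1e-12)


def test_hwe_detects_total_heterozygote_deficit():
    rng = np.random.default_rng(2)
    hom = rng.integers(1, 3, size=(50, 1, 1))
    calls = np.repeat(hom, 2, axis=2)      # all homozygotes at p ~ 0.5
    res = hwe_test(make_table(calls), "L0", "P-littoral", n_perm=5000, seed=0)
    assert res["p_deficit"] < 0.001
    res2 = hwe_test(make_table(calls), "L0", "P-littoral", n_perm=5000, seed=0)
    assert res["p_deficit"] == res2["p_deficit"]   # seeded determinism


def test_hwe_monomorphic_undefined():
    calls = np.ones((10, 1, 2), dtype=int)
    res = hwe_test(make_table(calls), "L0", "P-littoral", n_perm=99, seed=0)
    assert np.isnan(res["p_deficit"])


def test_ld_detects_duplicated_locus():
    rng = np.random.default_rng(3)
    one = rng.integers(1, 4, size=(60, 1, 2))
    calls = np.concatenate([one, one], axis=1)   # perfect LD
    res = ld_test(make_table(calls), ("L0", "L1"), "P-littoral",
                  n_perm=2000, seed=0)
    assert res["p"] < 0.001
    res2 = ld_test(make_table(calls), ("L0", "L1"), "P-littoral",
                   n_perm=2000, seed=0)
    assert res["p"] == res2["p"]


def test_theta_one_for_fixed_difference():
    calls = np.concatenate([np.full((10, 1, 2), 1), np.full((10, 1, 2), 2)])
    pops = np.repeat(["A-littoral", "A-pelagic"], 10)
    est = wc_fst(make_table(calls, pops), grouping="pop", n_boot=50, seed=0)
    assert est.theta_global == pytest.approx(1.0, abs=1e-12)


def test_theta_near_zero_when_population_split_at_random():
    rng = np.random.default_rng(4)
    p = np.array([0.4, 0.35, 0.25])
    calls = rng.choice([1, 2, 3], size=(80, 5, 2), p=p)
    pops = rng.permutation(np.repeat(["A-littoral", "A-pelagic"], 40))
    est = wc_fst(make_table(calls, pops), grouping="pop", n_boot=2000, seed=0)
    assert abs(est.theta_global) < 0.05
    assert est.ci95[0] <= 0.0 <= est.ci95[1] + 1e-9


@pytest.mark.parametrize("theta_true", [0.05, 0.15])
def test_theta_recovers_balding_nichols_parameter(theta_true):
    """Theta on frequencies diverged with parameter t recovers t."""
    rng = np.random.default_rng(5)
    n_pop, n_loci, n_ind = 8, 20, 50
    calls = np.zeros((n_pop * n_ind, n_loci, 2), dtype=int)
    pops = np.repeat([f"L{i}-littoral" for i in range(n_pop)], n_ind)
    for li in range(n_loci):
        p = rng.dirichlet(np.full(4, 3.0))
        for pi in range(n_pop):
            q = rng.dirichlet(p * (1 - theta_true) / theta_true)
            rows = slice(pi * n_ind, (pi + 1) * n_ind)
            calls[rows, li, :] = rng.choice(
                np.arange(1, 5), size=(n_ind, 2), p=q)
    est = wc_fst(make_table(calls, pops), grouping="pop", n_boot=100, seed=0)
    assert est.theta_global == pytest.approx(theta_true, abs=0.04)


def test_missing_data_uses_complete_cases():
    calls = np.array([[[1, 2]], [[0, 0]], [[1, 1]], [[2, 2]], [[1, 2]],
                      [[2, 1]]])
    div = diversity(make_table(calls))
    assert div.iloc[0]["N"] == 5
    assert div.iloc[0]["Ho"] == pytest.approx(3 / 5)


def test_half_missing_call_rejected():
    calls = np.array([[[1, 0]], [[1, 2]]])
    with pytest.raises(ValueError, match="half-missing"):
        make_table(calls)
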