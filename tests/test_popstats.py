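"""Diversity statistics: arithmetic examples, brute-force oracles, invariants."""

from itertools import combinations

import numpy as np
import pytest

from eruptpop.genio import MISSING
from eruptpop.popstats import (
    FoldedSFS,
    fold_counts,
    folded_sfs,
    inbreeding_f,
    mean_heterozygosity,
    per_site_diversity,
    private_alleles,
    shared_alleles_pairwise,
    tajimas_d_windows,
)

from conftest import make_matrix


# -- heterozygosity ----------------------------------------------------------


def test_het_single_site_half():
    m = make_matrix([[0], [1]])
    assert mean_heterozygosity(m) == pytest.approx(0.5)


def test_het_all_homozygous_zero_both_modes():
    m = make_matrix([[0, 2], [2, 0]])
    assert mean_heterozygosity(m) == 0.0
    assert mean_heterozygosity(m, "all_callable_sites", callable_length=100) == 0.0


def test_het_callable_length_denominator():
    """10 heterozygous genotypes over 6,000 callable bp -> ~0.00167 per bp."""
    d = np.zeros((3, 20), dtype=np.int8)
    d[:, :10] = 1
    m = make_matrix(d)
    got = mean_heterozygosity(m, "all_callable_sites", callable_length=6000)
    assert got == pytest.approx(10 / 6000)


def test_het_missing_excluded_from_both_counts():
    m = make_matrix([[1, MISSING], [0, 0]])
    # individual 0: 1 het / 1 called; individual 1: 0 / 2
    assert mean_heterozygosity(m) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        mean_heterozygosity(m, "all_callable_sites")


# -- per-site theta and pi ---------------------------------------------------


def _pi_bruteforce(column):
    """Mean pairwise allele difference by exhaustive enumeration."""
    alleles = []
    for g in column:
        if g != MISSING:
            alleles += [1] * g + [0] * (2 - g)
    pairs = list(combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def test_per_site_pi_examples_and_bruteforce():
    m = make_matrix([[1], [1]])  # n=4 alleles, c=2
    div = per_site_diversity(m)
    assert div.pi[0] == pytest.approx(2 / 3)
    rng = np.random.default_rng(0)
    d = rng.choice([0, 1, 2, MISSING], size=(6, 30), p=[0.4, 0.3, 0.2, 0.1])
    mm = make_matrix(d)
    div = per_site_diversity(mm)
    for j, sid in enumerate(div.site_ids):
        col = mm.dosages[:, mm.site_ids.index(sid)]
        assert div.pi[j] == pytest.approx(_pi_bruteforce(col), abs=1e-12)


def test_per_site_theta_w():
    # n=2 alleles segregating: a_1 = 1
    assert per_site_diversity(make_matrix([[1]])).theta_w[0] == pytest.approx(1.0)
    # n=4 alleles segregating: 1/(1 + 1/2 + 1/3) = 6/11
    assert per_site_diversity(make_matrix([[1], [0]])).theta_w[0] == pytest.approx(6 / 11)
    # monomorphic: both statistics exactly zero
    div = per_site_diversity(make_matrix([[0], [0]]))
    assert div.pi[0] == 0.0 and div.theta_w[0] == 0.0


def test_per_site_excludes_undercalled_sites():
    m = make_matrix([[1, MISSING], [0, MISSING]])
    div = per_site_diversity(m)
    assert len(div.pi) == 1


# -- Tajima's D --------------------------------------------------------------


def _tajima_oracle(minor, n):
    """Independent textbook evaluation of Tajima's D from minor counts."""
    S = int((minor > 0).sum())
    pi = float(np.sum(minor * (n - minor) / (n * (n - 1) / 2)))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_zero_when_pi_equals_theta():
    """A window built so that summed pi equals S/a_1 exactly (n=4 alleles,
    8 singleton + 3 doubleton sites) has a vanishing D numerator."""
    cols = [(1, 0)] * 8 + [(1, 1)] * 3  # minor counts: 8x1, 3x2
    d = np.asarray(cols, dtype=np.int8).T
    m = make_matrix(d, regions=["r"] * 11, positions=list(range(1, 12)))
    w = tajimas_d_windows(m, window_bp=100)
    # pi_sum = 8*(1*3/6) + 3*(2*2/6) = 6 = 11 / (11/6) = S/a_1
    assert w.values[0] == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_singleton_window_negative_and_matches_oracle():
    # 2 individuals (n=4), 5 singleton sites in one window
    d = np.zeros((2, 5), dtype=np.int8)
    d[0] = 1
    m = make_matrix(d, regions=["r"] * 5, positions=[1, 2, 3, 4, 5])
    w = tajimas_d_windows(m, window_bp=100)
    want = _tajima_oracle(np.ones(5), 4)
    assert w.values[0] < 0
    assert w.values[0] == pytest.approx(want, abs=1e-10)


def test_tajimas_d_whole_matrix_matches_oracle_on_simulated_data():
    """Single whole-matrix windows agree with an independent implementation
    to >= 6 decimals over 50 simulated datasets."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        n_ind = int(rng.integers(4, 12))
        L = int(rng.integers(5, 40))
        p = rng.uniform(0.05, 0.95, size=L)
        d = rng.binomial(2, p, size=(n_ind, L)).astype(np.int8)
        m = make_matrix(d, regions=["r"] * L, positions=list(range(1, L + 1)))
        alt = d.sum(axis=0)
        minor = np.minimum(alt, 2 * n_ind - alt)
        if (minor > 0).sum() == 0:
            continue
        w = tajimas_d_windows(m, window_bp=L + 1)
        assert w.values[0] == pytest.approx(_tajima_oracle(minor, 2 * n_ind), abs=1e-6)


def test_tajimas_d_window_bounds_and_errors():
    m = make_matrix([[1], [0]])
    with pytest.raises(ValueError):
        tajimas_d_windows(m, window_bp=0)
    # windows are half-open [start, start+window): site at 101 not in [1,101)
    m2 = make_matrix([[1, 1], [0, 0]], regions=["r", "r"], positions=[100, 101])
    w = tajimas_d_windows(m2, window_bp=100, step_bp=100)
    assert [(s, e) for _, s, e in w.windows] == [(1, 101), (101, 201)]


# -- folded SFS --------------------------------------------------------------


def test_folding_tabulation():
    # 4 haplotypes; minor counts {1, 1, 2} -> classes {1: 2, 2: 1}
    alt = np.array([1, 3, 2])
    tot = np.array([4, 4, 4])
    np.testing.assert_array_equal(fold_counts(alt, tot, 4), [2, 1])


def test_folding_idempotent():
    """Folding counts already at the minor class is the identity."""
    alt = np.array([1, 2, 1])
    tot = np.array([6, 6, 6])
    once = fold_counts(alt, tot, 6)
    again = fold_counts(np.array([1, 2, 1]), tot, 6)  # already minor
    np.testing.assert_array_equal(once, again)


def test_folded_sfs_full_subsample_has_zero_spread(species_b_dataset):
    m, _ = species_b_dataset
    sfs = folded_sfs(m, subsample_n=m.n_samples, reps=5, seed=1)
    assert np.ptp(sfs.per_rep, axis=0).max() == 0
    assert sfs.n_haplotypes == 2 * m.n_samples
    # per-iteration class counts account for every segregating site
    assert sfs.per_rep.sum(axis=1).max() <= m.n_sites


def test_folded_sfs_errors(species_b_dataset):
    m, _ = species_b_dataset
    with pytest.raises(ValueError):
        folded_sfs(m, subsample_n=1)
    with pytest.raises(ValueError):
        folded_sfs(m, subsample_n=m.n_samples + 1)


def test_folded_sfs_matches_neutral_expectation():
    """Folded class proportions from neutral coalescent loci follow
    (1/i + 1/(2n-i))/(1 + [i == n]) within 3 SE of the mean."""
    msprime = pytest.importorskip("msprime")
    n_dip = 5  # 10 haplotypes
    reps = 400
    per_tree = []
    for ts in msprime.sim_ancestry(samples=n_dip, ploidy=2, population_size=1000,
                                   num_replicates=reps, random_seed=7):
        mts = msprime.sim_mutations(ts, rate=2e-4, random_seed=ts.num_edges + 1,
                                    model=msprime.BinaryMutationModel())
        g = mts.genotype_matrix()
        if g.shape[0] == 0:
            continue
        alt = g.sum(axis=1)
        tot = np.full(len(alt), 2 * n_dip)
        per_tree.append(fold_counts(alt, tot, 2 * n_dip))
    per_tree = np.asarray(per_tree)
    prop = per_tree.sum(axis=0) / per_tree.sum()
    i = np.arange(1, n_dip + 1)
    expected = (1 / i + 1 / (2 * n_dip - i)) / (1 + (i == n_dip))
    expected /= expected.sum()
    per_tree_prop = per_tree / np.maximum(per_tree.sum(axis=1, keepdims=True), 1)
    se = per_tree_prop.std(axis=0, ddof=1) / np.sqrt(len(per_tree))
    assert (np.abs(prop - expected) < 3 * se + 1e-3).all()


# -- inbreeding F ------------------------------------------------------------


def _f_oracle(dosages):
    """Independent per-individual method-of-moments F with loops."""
    dosages = np.asarray(dosages)
    n_ind, L = dosages.shape
    out = []
    for i in range(n_ind):
        o_hom = e_hom = used = 0.0
        for j in range(L):
            if dosages[i, j] == MISSING:
                continue
            col = dosages[:, j]
            called = col[col != MISSING]
            tot = 2 * len(called)
            if tot < 2:
                continue
            p = called.sum() / tot
            e_hom += 1 - 2 * p * (1 - p) * (tot / (tot - 1))
            o_hom += dosages[i, j] != 1
            used += 1
        out.append((o_hom - e_hom) / (used - e_hom))
    return np.asarray(out)


def test_inbreeding_zero_when_observed_matches_expected():
    rng = np.random.default_rng(3)
    d = rng.binomial(2, 0.5, size=(20, 200)).astype(np.int8)
    f = inbreeding_f(make_matrix(d))
    # outbred panel: mean F near 0
    assert abs(np.nanmean(f)) < 0.1


def test_inbreeding_fully_homozygous_individual_positive():
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.5, size=(30, 400)).astype(np.int8)
    d[0] = np.where(d[0] == 1, 2, d[0])  # make individual 0 homozygous everywhere
    f = inbreeding_f(make_matrix(d))
    assert f[0] > 0.8


def test_inbreeding_matches_reference_formula():
    rng = np.random.default_rng(5)
    d = rng.choice([0, 1, 2, MISSING], size=(20, 100), p=[0.35, 0.3, 0.25, 0.1]).astype(np.int8)
    got = inbreeding_f(make_matrix(d))
    want = _f_oracle(d)
    np.testing.assert_allclose(got, want, atol=1e-6)


# -- private / shared alleles ------------------------------------------------


def _pops(*dosage_blocks):
    return [make_matrix(b, sample_ids=[f"p{k}i{i}" for i in range(len(b))])
            for k, b in enumerate(dosage_blocks)]


def test_private_alleles_simple_case():
    # pop A = {0/1}, pop B = {0/0}: alt allele private to A
    pa, pb = _pops([[1], [1]], [[0], [0]])
    res = private_alleles([pa, pb], equalize_n=2, reps=3, seed=1)
    np.testing.assert_array_equal(res.mean, [1.0, 0.0])


def test_private_alleles_identical_populations_zero():
    d = [[0, 1], [1, 2]]
    res = private_alleles(_pops(d, d), equalize_n=2, reps=3, seed=1)
    np.testing.assert_array_equal(res.mean, [0.0, 0.0])


def _sharing_bruteforce(blocks):
    """Exhaustive set-operation oracle for private and pairwise-shared counts."""
    presence = []
    for b in blocks:
        b = np.asarray(b)
        pres = set()
        for j in range(b.shape[1]):
            col = b[:, j][b[:, j] != MISSING]
            if (col < 2).any():
                pres.add((j, "ref"))
            if (col > 0).any():
                pres.add((j, "alt"))
        presence.append(pres)
    k = len(blocks)
    priv = [len(presence[i] - set().union(*(presence[j] for j in range(k) if j != i)))
            for i in range(k)]
    shared = {}
    for a, b in combinations(range(k), 2):
        c = ({0, 1, 2} - {a, b}).pop()
        shared[(a, b)] = len((presence[a] & presence[b]) - presence[c])
    return priv, shared


def test_private_and_shared_match_bruteforce():
    rng = np.random.default_rng(9)
    blocks = [rng.choice([0, 1, 2], size=(4, 10), p=[0.6, 0.25, 0.15]) for _ in range(3)]
    priv_want, shared_want = _sharing_bruteforce(blocks)
    pops = _pops(*blocks)
    # equalize_n = full size -> subsampling is the identity, so exact
    priv = private_alleles(pops, equalize_n=4, reps=2, seed=0)
    np.testing.assert_array_equal(priv.mean, priv_want)
    shared = shared_alleles_pairwise(pops, equalize_n=4, reps=2, seed=0)
    for (a, b), m, in zip(shared.labels, shared.mean):
        assert m == shared_want[(a, b)]


def test_allele_classes_partition_everything():
    """private + shared-by-two + present-in-all-three covers every observed
    allele exactly once (3 populations, no missing data)."""
    rng = np.random.default_rng(10)
    blocks = [rng.choice([0, 1, 2], size=(5, 40), p=[0.5, 0.3, 0.2]) for _ in range(3)]
    priv_want, shared_want = _sharing_bruteforce(blocks)
    # total observed distinct (site, allele) presences across the union
    presences = set()
    universal = 0
    pres_sets = []
    for b in blocks:
        b = np.asarray(b)
        s = set()
        for j in range(b.shape[1]):
            col = b[:, j]
            if (col < 2).any():
                s.add((j, "ref"))
            if (col > 0).any():
                s.add((j, "alt"))
        pres_sets.append(s)
        presences |= s
    universal = len(pres_sets[0] & pres_sets[1] & pres_sets[2])
    assert sum(priv_want) + sum(shared_want.values()) + universal == len(presences)


def test_shared_requires_three_and_feasible_n():
    pops2 = _pops([[0]], [[1]])
    with pytest.raises(ValueError):
        shared_alleles_pairwise(pops2, equalize_n=1)
    pops3 = _pops([[0]], [[1]], [[2]])
    with pytest.raises(ValueError):
        private_alleles(pops3, equalize_n=2)
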