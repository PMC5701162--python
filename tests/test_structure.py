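"""Differentiation: Weir-Cockerham components, PCA geometry, admixture EM."""

import numpy as np
import pytest

from eruptpop.genio import MISSING
from eruptpop.structure import (
    admixture_em,
    hudson_fst,
    pca_genotypes,
    weir_cockerham_fst,
)

from conftest import make_matrix


# -- Weir-Cockerham FST ------------------------------------------------------


def _wc_oracle(dosage_blocks):
    """Independent loop-coded Weir & Cockerham (1984) variance components."""
    r = len(dosage_blocks)
    a_sum = d_sum = 0.0
    n_sites = dosage_blocks[0].shape[1]
    for j in range(n_sites):
        ns, ps, hs = [], [], []
        for b in dosage_blocks:
            col = b[:, j]
            col = col[col != MISSING]
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append((col == 1).sum() / len(col))
        if min(ns) < 2:
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b_ = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        d_sum += a + b_ + c
    return a_sum / d_sum


def test_fst_fixed_difference_is_one():
    d = np.array([[0] * 3 + [2] * 3]).T.reshape(6, 1).astype(np.int8)
    m = make_matrix(d)
    res = weir_cockerham_fst(m, ["A"] * 3 + ["B"] * 3)
    assert res.fst == pytest.approx(1.0)


def test_fst_duplicated_population_near_zero_negative_allowed():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, rng.uniform(0.2, 0.8, size=80), size=(24, 80)).astype(np.int8)
    m = make_matrix(d)
    vals = []
    for s in range(100):
        perm = np.random.default_rng(s).permutation(24)
        labels = np.empty(24, dtype=object)
        labels[perm[:12]], labels[perm[12:]] = "A", "B"
        vals.append(weir_cockerham_fst(m, labels).fst)
    vals = np.asarray(vals)
    # random splits of one population: centred on zero, negatives admissible
    assert abs(vals.mean()) < 3 * vals.std(ddof=1) / 10
    assert (vals < 0).any()


def test_fst_matches_independent_components_oracle():
    rng = np.random.default_rng(2)
    blocks = [
        rng.choice([0, 1, 2, MISSING], size=(8, 5), p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8),
        rng.choice([0, 1, 2, MISSING], size=(6, 5), p=[0.2, 0.3, 0.4, 0.1]).astype(np.int8),
    ]
    m = make_matrix(np.vstack(blocks))
    labels = ["A"] * 8 + ["B"] * 6
    got = weir_cockerham_fst(m, labels).fst
    assert got == pytest.approx(_wc_oracle(blocks), abs=1e-10)


def test_fst_three_populations_supported():
    rng = np.random.default_rng(3)
    blocks = [rng.binomial(2, p, size=(7, 20)).astype(np.int8)
              for p in (0.2, 0.5, 0.8)]
    m = make_matrix(np.vstack(blocks))
    labels = ["A"] * 7 + ["B"] * 7 + ["C"] * 7
    got = weir_cockerham_fst(m, labels).fst
    assert got == pytest.approx(_wc_oracle(blocks), abs=1e-10)
    assert got > 0.2


def test_hudson_cross_check_agrees_in_sign_and_scale(two_pop_dataset):
    m, meta = two_pop_dataset
    wc = weir_cockerham_fst(m, meta.column("population")).fst
    hu = hudson_fst(m, meta.column("population"))
    assert abs(wc - hu) < 0.05


def test_fst_errors():
    m = make_matrix([[0], [1]])
    with pytest.raises(ValueError):
        weir_cockerham_fst(m, ["A", "A"])


# -- PCA ---------------------------------------------------------------------


def _cluster_matrix(seed=0):
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(0.1, 0.9, 100), rng.uniform(0.1, 0.9, 100)
    a = rng.binomial(2, p1, size=(10, 100))
    b = rng.binomial(2, np.where(rng.uniform(size=100) < 0.3, p2, p1), size=(10, 100))
    return make_matrix(np.vstack([a, b]).astype(np.int8))


def test_pca_identical_clusters_separate_on_pc1():
    d = np.zeros((10, 40), dtype=np.int8)
    d[5:, :20] = 2
    d[:5, 20:] = 2
    m = make_matrix(d)
    res = pca_genotypes(m)
    pc1 = res.coordinates[:, 0]
    assert np.ptp(pc1[:5]) < 1e-8 and np.ptp(pc1[5:]) < 1e-8
    assert abs(pc1[0] - pc1[5]) > 1


def test_pca_duplicated_individual_identical_coordinates():
    m = _cluster_matrix(4)
    d = np.vstack([m.dosages, m.dosages[0][None, :]])
    m2 = make_matrix(d, sample_ids=[f"i{k}" for k in range(21)])
    res = pca_genotypes(m2)
    np.testing.assert_allclose(res.coordinates[0], res.coordinates[20], atol=1e-8)


def test_pca_axes_orthogonal_variance_sorted_sign_fixed():
    res = pca_genotypes(_cluster_matrix(5))
    v = res.coordinates
    gram = v.T @ v
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    assert (np.diff(res.explained_variance) <= 1e-10).all()
    for j in range(res.loadings.shape[1]):
        i = np.argmax(np.abs(res.loadings[:, j]))
        assert res.loadings[i, j] >= 0


def test_pca_matches_reference_eigensolver():
    """Coordinates equal an independently computed eigendecomposition of the
    Patterson-normalised covariance, up to per-axis sign."""
    m = _cluster_matrix(6)
    res = pca_genotypes(m)
    d = m.dosages.astype(float)
    p = d.sum(axis=0) / (2 * d.shape[0])
    keep = (p > 0) & (p < 1)
    x = (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    w, v = np.linalg.eigh(x @ x.T / keep.sum())
    w, v = w[::-1], v[:, ::-1]
    ref = v * np.sqrt(np.clip(w, 0, None))
    k = res.coordinates.shape[1]
    for j in range(k):
        assert (
            np.allclose(res.coordinates[:, j], ref[:, j], atol=1e-6)
            or np.allclose(res.coordinates[:, j], -ref[:, j], atol=1e-6)
        )


def test_pca_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        pca_genotypes(make_matrix([[0, 1], [1, 0]]))  # too few individuals
    with pytest.raises(ValueError):
        pca_genotypes(make_matrix([[0, 0], [0, 0], [0, 0]]))  # monomorphic


# -- admixture EM ------------------------------------------------------------


def test_admixture_k1_closed_form():
    """K=1: Q is all ones and the log-likelihood equals the binomial
    likelihood at the pooled frequencies."""
    rng = np.random.default_rng(7)
    d = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(12, 50)).astype(np.int8)
    m = make_matrix(d)
    fit = admixture_em(m, K=1, seed=1, n_starts=1)
    np.testing.assert_allclose(fit.Q, 1.0)
    p = d.sum(axis=0) / (2 * d.shape[0])
    from scipy.stats import binom

    want = binom.logpmf(d, 2, p[None, :]).sum()
    assert fit.loglik == pytest.approx(want, rel=1e-4)


def test_admixture_loglik_monotone_and_simplex(two_pop_dataset):
    m, _ = two_pop_dataset
    fit = admixture_em(m, K=3, seed=2, n_starts=2, max_iter=150)
    assert (np.diff(fit.loglik_trace) >= -1e-6).all()
    np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
    assert ((fit.P >= 0) & (fit.P <= 1)).all()


def test_admixture_recovers_diverged_demes():
    from eruptpop.simgen import (
        Cohort, SamplingPlan, SimulationConfig, draw_samples, simulate_populations,
    )

    cfg = SimulationConfig(n_loci=300, ne_pre=50, event_generation=80,
                           generations_post=0, migration_rate=0.0, n_demes=2,
                           initial_freq_spec="uniform", seed=42)
    h = simulate_populations(cfg)
    plan = SamplingPlan(cohorts=(Cohort(0, 80, 15, 15, "A", "pre"),
                                 Cohort(1, 80, 15, 15, "B", "pre")))
    m, meta = draw_samples(h, plan, seed=43)
    m = m.subset(sites=np.where(m.segregating_mask())[0].tolist())
    fit = admixture_em(m, K=2, seed=7, n_starts=4)
    # every individual assigned >= 0.95 to its source, up to label switching
    assert fit.Q.max(axis=1).min() >= 0.95
    src = meta.column("population")
    major = fit.Q.argmax(axis=1)
    assert len({(s, k) for s, k in zip(src, major)}) == 2


def test_admixture_rejects_bad_k():
    m = make_matrix([[0, 1], [1, 0], [2, 1]])
    with pytest.raises(ValueError):
        admixture_em(m, K=0)
    with pytest.raises(ValueError):
        admixture_em(m, K=4)
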