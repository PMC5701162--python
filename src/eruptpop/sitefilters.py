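"""Neutrality filters applied before diversity comparisons.

Two filters are provided, mirroring common practice for demographic
inference panels: (1) an exact Hardy-Weinberg equilibrium test per site
(Levene/Haldane conditional distribution of the heterozygote count given
the allele counts, two-sided by probability mass), applied per population
so that Wahlund structure cannot mask genotyping error; and (2) an
FST-outlier scan for putative directional selection, which simulates a
neutral heterozygosity-conditioned FST envelope under a symmetric island
model (Balding-Nichols beta-distributed deme frequencies matched to the
observed mean FST), assigns empirical upper-tail p-values within
heterozygosity bins and applies Benjamini-Hochberg control at a stated
FDR.  Only the upper (directional) tail is flagged.

The empirical p-value is the plain fraction of simulated sites in the bin
with FST at or above the observed value; an observation beyond the whole
simulated envelope therefore gets p = 0, giving the scan resolution below
1/n_sims where a pseudo-count convention would floor every p-value above
the Benjamini-Hochberg threshold at panel scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma, log as _ln

import numpy as np
from scipy.stats import false_discovery_control

from .genio import MISSING, GenotypeMatrix
from .structure import wc_components

log = logging.getLogger(__name__)


# -- Hardy-Weinberg exact test ----------------------------------------------


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic site.

    Uses Levene's conditional distribution of the heterozygote count given
    the observed allele counts; the p-value sums the probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count.  Monomorphic sites return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        log.debug("hwe_exact_pvalue: monomorphic site, p = 1 by convention")
        return 1.0
    rare = min(n_A, n_a)
    # valid heterozygote counts share the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)
    base = lgamma(n + 1) + lgamma(n_A + 1) + lgamma(n_a + 1) - lgamma(2 * n + 1)

    def logp(h: int) -> float:
        na_hom = (n_A - h) // 2
        nb_hom = (n_a - h) // 2
        return base + h * _ln(2.0) - lgamma(na_hom + 1) - lgamma(h + 1) - lgamma(nb_hom + 1)

    probs = {h: np.exp(logp(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return float(min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total))


def hwe_pvalues(matrix: GenotypeMatrix, pop_labels=None) -> np.ndarray:
    """Per-site HWE p-values; with ``pop_labels`` the minimum over populations.

    The per-population minimum implements "fails in any population".
    """
    if pop_labels is None:
        groups = [np.ones(matrix.n_samples, dtype=bool)]
    else:
        labels = np.asarray(list(pop_labels))
        groups = [labels == pop for pop in sorted(set(labels))]
    out = np.ones(matrix.n_sites)
    for sel in groups:
        sub = matrix.dosages[sel]
        n_aa0 = ((sub == 0)).sum(axis=0)
        n_het = ((sub == 1)).sum(axis=0)
        n_aa2 = ((sub == 2)).sum(axis=0)
        for j in range(matrix.n_sites):
            if n_aa0[j] + n_het[j] + n_aa2[j] >= 1:
                out[j] = min(out[j], hwe_exact_pvalue(int(n_aa0[j]), int(n_het[j]), int(n_aa2[j])))
    return out


# -- FST outlier scan --------------------------------------------------------


def _per_pop_site_stats(matrix: GenotypeMatrix, labels: np.ndarray):
    pops = sorted(set(labels))
    n = np.empty((matrix.n_sites, len(pops)))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for k, pop in enumerate(pops):
        sub = matrix.dosages[labels == pop]
        called = sub != MISSING
        nk = called.sum(axis=0).astype(float)
        n[:, k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(nk > 0, np.where(called, sub, 0).sum(axis=0) / (2 * nk), np.nan)
            h[:, k] = np.where(nk > 0, ((sub == 1) & called).sum(axis=0) / nk, np.nan)
    return pops, n, p, h


def _fst_he(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-site (FST, expected heterozygosity from the pooled frequency)."""
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, 0.0)
    pbar = (n * p).sum(axis=-1) / n.sum(axis=-1)
    he = 2 * pbar * (1 - pbar)
    return fst, he, a, denom


def fst_outlier_scan(
    matrix: GenotypeMatrix,
    pop_labels,
    n_sims: int = 50_000,
    fdr: float = 0.1,
    seed: int = 0,
    n_he_bins: int = 20,
) -> list[str]:
    """Flag putative directional-selection outliers against a neutral
    island-model FST envelope; returns the flagged site ids.

    For each analyzable site (>= 2 called individuals in every population)
    the observed (He, FST) pair is compared with ``n_sims`` neutral sites
    simulated at the observed multi-locus FST: ancestral frequencies are
    resampled from the observed pooled frequencies, deme frequencies drawn
    Balding-Nichols, genotypes drawn Hardy-Weinberg at the observed sample
    sizes.  Empirical upper-tail p-values are assigned within He bins and
    Benjamini-Hochberg control applied at ``fdr``.
    """
    if n_sims < 1000:
        raise ValueError("n_sims < 1000 gives too coarse a neutral envelope; refused")
    labels = np.asarray(list(pop_labels))
    if len(labels) != matrix.n_samples:
        raise ValueError("pop_labels length must match samples")
    pops, n, p, h = _per_pop_site_stats(matrix, labels)
    if len(pops) < 2:
        raise ValueError("outlier scan needs >= 2 populations")
    usable = (n >= 2).all(axis=1)
    if not usable.any():
        return []
    fst_obs, he_obs, a, denom = _fst_he(n[usable], p[usable], h[usable])
    total = denom.sum()
    f_mean = float(a.sum() / total) if total > 0 else 0.0
    f_mean = float(np.clip(f_mean, 1e-4, 0.99))

    rng = np.random.default_rng(seed)
    n_k = np.maximum(2, np.round(np.median(n[usable], axis=0)).astype(int))
    p_anc = rng.choice(((n[usable] * p[usable]).sum(axis=1) / n[usable].sum(axis=1)), size=n_sims)
    p_anc = np.clip(p_anc, 1e-3, 1 - 1e-3)
    shape = (1.0 - f_mean) / f_mean
    n_sim_arr = np.empty((n_sims, len(pops)))
    p_sim = np.empty((n_sims, len(pops)))
    h_sim = np.empty((n_sims, len(pops)))
    for k in range(len(pops)):
        pk = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        probs = np.stack([(1 - pk) ** 2, 2 * pk * (1 - pk), pk**2], axis=1)
        counts = rng.multinomial(int(n_k[k]), probs)
        n_sim_arr[:, k] = n_k[k]
        p_sim[:, k] = (2 * counts[:, 2] + counts[:, 1]) / (2.0 * n_k[k])
        h_sim[:, k] = counts[:, 1] / float(n_k[k])
    fst_sim, he_sim, _, _ = _fst_he(n_sim_arr, p_sim, h_sim)

    edges = np.unique(np.quantile(he_sim, np.linspace(0, 1, n_he_bins + 1)))
    inner = edges[1:-1] if len(edges) > 2 else np.array([])
    bin_sim = np.digitize(he_sim, inner)
    bin_obs = np.digitize(he_obs, inner)
    pvals = np.ones(fst_obs.shape[0])
    for b in np.unique(bin_obs):
        sims_b = fst_sim[bin_sim == b]
        if sims_b.size == 0:
            sims_b = fst_sim  # fall back to the full envelope
        obs_idx = np.where(bin_obs == b)[0]
        # upper-tail empirical proportion; p = 0 beyond the envelope
        pvals[obs_idx] = (sims_b[None, :] >= fst_obs[obs_idx][:, None]).mean(axis=1)
    adjusted = false_discovery_control(pvals, method="bh")
    flagged_local = np.where(adjusted <= fdr)[0]
    usable_ids = [sid for sid, u in zip(matrix.site_ids, usable) if u]
    return [usable_ids[i] for i in flagged_local]


# -- filter application ------------------------------------------------------


@dataclass
class SiteFilterReport:
    """Which sites were removed, and why."""

    hwe_removed: list[str]
    hwe_pvalues: dict[str, float]
    outlier_removed: list[str]
    kept: int
    n_input: int
    hwe_alpha: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "kept": self.kept,
            "hwe_removed": self.hwe_removed,
            "hwe_alpha": self.hwe_alpha,
            "outlier_removed": self.outlier_removed,
            "notes": self.notes,
        }


def apply_site_filters(
    matrix: GenotypeMatrix,
    hwe_alpha: float = 0.05,
    outliers: list[str] | None = None,
    pop_labels=None,
    bonferroni: bool = False,
) -> tuple[GenotypeMatrix, SiteFilterReport]:
    """Remove sites failing the exact HWE test (in any population when
    ``pop_labels`` is given) at ``hwe_alpha``, plus the named outliers.

    Idempotent: re-applying to its own output removes nothing further.
    """
    outliers = list(outliers or [])
    alpha = hwe_alpha / matrix.n_sites if bonferroni else hwe_alpha
    pvals = hwe_pvalues(matrix, pop_labels=pop_labels)
    ids = matrix.site_ids
    hwe_removed = [sid for sid, pv in zip(ids, pvals) if pv < alpha]
    drop = set(hwe_removed) | set(outliers)
    keep_ids = [sid for sid in ids if sid not in drop]
    if not keep_ids:
        raise ValueError("all sites removed by filters")
    filtered = matrix.subset(sites=keep_ids)
    notes = [
        "HWE: Levene/Haldane exact test, two-sided by probability mass",
        "HWE tested per population (removed if failing in any)" if pop_labels is not None
        else "HWE tested on the pooled sample",
    ]
    report = SiteFilterReport(
        hwe_removed=hwe_removed,
        hwe_pvalues={sid: float(pv) for sid, pv in zip(ids, pvals) if sid in drop},
        outlier_removed=[sid for sid in outliers if sid in set(ids)],
        kept=len(keep_ids),
        n_input=matrix.n_sites,
        hwe_alpha=alpha,
        notes=notes,
    )
    return filtered, report
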