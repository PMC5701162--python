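"""Core diversity statistics on diploid dosage matrices.

Implements the within-population summaries used throughout the package:
observed mean heterozygosity (with an explicit denominator mode), per-site
Watterson's theta and nucleotide diversity pi, Tajima's D in sliding
windows, the folded site frequency spectrum with equalised individual
subsampling, method-of-moments inbreeding F, and private / shared allele
counts under repeated equalised subsampling.

Missing genotypes are handled per-site complete-case: a site's allele
frequency and pairwise comparisons use only the non-missing genotypes at
that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genio import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# -- heterozygosity ----------------------------------------------------------


def mean_heterozygosity(
    matrix: GenotypeMatrix,
    denominator: str = "snp_sites",
    callable_length: int | None = None,
) -> float:
    """Mean over individuals of their observed heterozygosity.

    denominator='snp_sites': per individual, heterozygous genotypes divided
    by that individual's non-missing genotyped SNP count.
    denominator='all_callable_sites': heterozygous genotypes divided by the
    total callable sequence length (``callable_length`` bp), the convention
    that puts values on a per-base scale.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one individual")
    het = (matrix.dosages == 1).sum(axis=1).astype(float)
    if denominator == "snp_sites":
        called = (matrix.dosages != MISSING).sum(axis=1).astype(float)
        if (called == 0).any():
            raise ValueError("individual with zero called sites")
        return float(np.mean(het / called))
    if denominator == "all_callable_sites":
        if not callable_length or callable_length <= 0:
            raise ValueError("all_callable_sites mode requires a positive callable_length")
        return float(np.mean(het / float(callable_length)))
    raise ValueError(f"unknown denominator mode {denominator!r}")


def per_individual_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-individual heterozygous fraction over that individual's called sites."""
    het = (matrix.dosages == 1).sum(axis=1).astype(float)
    called = (matrix.dosages != MISSING).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        return het / called


def per_site_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site observed heterozygote proportion among called genotypes."""
    called = (matrix.dosages != MISSING).sum(axis=0).astype(float)
    het = (matrix.dosages == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, het / called, np.nan)


# -- per-site theta_W and pi -------------------------------------------------


@dataclass
class PerSiteDiversity:
    """Per-site Watterson theta and unbiased pairwise diversity pi."""

    theta_w: np.ndarray
    pi: np.ndarray
    n_alleles_used: np.ndarray
    site_ids: list[str]


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


def per_site_diversity(matrix: GenotypeMatrix) -> PerSiteDiversity:
    """Per-site pi = c(n-c)/C(n,2) and theta_W = S_site / a_{n-1}.

    ``n`` is the non-missing allele count at the site and ``c`` the minor
    allele count.  Sites with fewer than 2 called alleles are excluded
    (logged).
    """
    alt, tot = matrix.allele_counts()
    usable = tot >= 2
    if (~usable).any():
        log.info("per_site_diversity: excluded %d sites with <2 called alleles", int((~usable).sum()))
    alt, tot = alt[usable], tot[usable]
    minor = np.minimum(alt, tot - alt)
    pi = minor * (tot - minor) / (tot * (tot - 1) / 2.0)
    seg = (minor > 0).astype(float)
    a_nm1 = np.array([_harmonic(n - 1) for n in tot])
    theta = np.where(a_nm1 > 0, seg / np.where(a_nm1 > 0, a_nm1, 1.0), 0.0)
    ids = [sid for sid, u in zip(matrix.site_ids, usable) if u]
    return PerSiteDiversity(theta_w=theta, pi=pi, n_alleles_used=tot, site_ids=ids)


# -- Tajima's D in windows ---------------------------------------------------


@dataclass
class WindowedStatistic:
    windows: list[tuple[str, int, int]]
    values: np.ndarray
    window_size: int
    step: int


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating-site count, summed pairwise diversity and
    sample size n (allele count), using the 1989 normalisation constants."""
    if S <= 0 or n < 3:
        return np.nan
    a1 = _harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return np.nan
    return (pi_sum - S / a1) / np.sqrt(var)


def tajimas_d_windows(
    matrix: GenotypeMatrix, window_bp: int = 100, step_bp: int | None = None
) -> WindowedStatistic:
    """Tajima's D per half-open window [start, start+window) over each region.

    Within a window, S is the count of segregating sites, pi is summed from
    exact per-site pairwise diversity, and n is the minimum non-missing
    allele count across the window's sites.  Windows with no segregating
    site are omitted (the statistic is undefined there).
    """
    if window_bp < 1:
        raise ValueError("window must be at least 1 bp")
    step = step_bp if step_bp is not None else window_bp
    if step < 1:
        raise ValueError("step must be at least 1 bp")
    alt, tot = matrix.allele_counts()
    minor = np.minimum(alt, tot - alt)
    windows: list[tuple[str, int, int]] = []
    values: list[float] = []
    regions = matrix.site_regions.astype(str)
    for region in sorted(set(regions)):
        in_region = regions == region
        pos = matrix.site_positions[in_region]
        r_minor, r_tot = minor[in_region], tot[in_region]
        lo, hi = int(pos.min()), int(pos.max())
        start = 1 + step * ((lo - 1) // step)
        while start <= hi:
            in_win = (pos >= start) & (pos < start + window_bp) & (r_tot >= 2)
            if in_win.any():
                w_minor, w_tot = r_minor[in_win], r_tot[in_win]
                S = int((w_minor > 0).sum())
                if S > 0:
                    n = int(w_tot.min())
                    pi_sum = float(np.sum(w_minor * (w_tot - w_minor) / (w_tot * (w_tot - 1) / 2.0)))
                    d = tajimas_d(S, pi_sum, n)
                    if np.isfinite(d):
                        windows.append((region, start, start + window_bp))
                        values.append(d)
            start += step
    return WindowedStatistic(windows=windows, values=np.asarray(values), window_size=window_bp, step=step)


# -- folded SFS --------------------------------------------------------------


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum averaged over equalised subsamples.

    ``class_counts[i]`` is the mean number of sites with minor-allele count
    ``i`` (classes 1..n_haplotypes//2); ``per_rep`` holds each iteration's
    counts for dispersion summaries.
    """

    class_counts: np.ndarray
    n_haplotypes: int
    reps: int
    per_rep: np.ndarray

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, len(self.class_counts) + 1)

    def proportions(self) -> np.ndarray:
        total = self.class_counts.sum()
        return self.class_counts / total if total > 0 else self.class_counts


def fold_counts(alt: np.ndarray, tot: np.ndarray, n_haplotypes: int) -> np.ndarray:
    """Tabulate minor-allele counts into classes 1..n_haplotypes//2."""
    minor = np.minimum(alt, tot - alt)
    k = n_haplotypes // 2
    counts = np.zeros(k, dtype=float)
    seg = (minor > 0) & (tot >= 2)
    vals, cnt = np.unique(np.minimum(minor[seg], k), return_counts=True)
    counts[vals - 1] = cnt
    return counts


def folded_sfs(
    matrix: GenotypeMatrix, subsample_n: int, reps: int = 20, seed: int = 0
) -> FoldedSFS:
    """Folded SFS under repeated equalised subsampling of individuals.

    Each iteration draws ``subsample_n`` individuals without replacement,
    folds allele counts at each segregating site to the minor class and
    tabulates; class counts are averaged over iterations.
    """
    if subsample_n < 2:
        raise ValueError("subsample_n must be >= 2")
    if subsample_n > matrix.n_samples:
        raise ValueError("subsample_n exceeds available individuals")
    rng = np.random.default_rng(seed)
    n_hap = 2 * subsample_n
    per_rep = np.empty((reps, n_hap // 2))
    for r in range(reps):
        idx = np.sort(rng.choice(matrix.n_samples, size=subsample_n, replace=False))
        sub = matrix.dosages[idx]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        per_rep[r] = fold_counts(alt, tot, n_hap)
    return FoldedSFS(
        class_counts=per_rep.mean(axis=0), n_haplotypes=n_hap, reps=reps, per_rep=per_rep
    )


# -- inbreeding F ------------------------------------------------------------


def inbreeding_f(matrix: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per individual.

    F_i = (O_hom - E_hom) / (L_used - E_hom), with E_hom summed over the
    individual's non-missing sites as 1 - 2*p*q * 2n/(2n-1), p estimated
    from all samples at each site (n = called allele count / 2 ... the
    small-sample factor uses the site's called allele count 2n).
    Degenerate individuals (L_used == E_hom) get NaN (logged).
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 individuals to estimate allele frequencies")
    alt, tot = matrix.allele_counts()
    usable = tot >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.where(tot > 0, tot, 1), np.nan)
    e_hom_site = np.where(usable, 1.0 - 2.0 * p * (1.0 - p) * (tot / (tot - 1.0)), np.nan)
    called = (matrix.dosages != MISSING) & usable[None, :]
    o_hom = ((matrix.dosages != 1) & called).sum(axis=1).astype(float)
    e_hom = np.where(called, e_hom_site[None, :], 0.0).sum(axis=1)
    l_used = called.sum(axis=1).astype(float)
    denom = l_used - e_hom
    out = np.full(matrix.n_samples, np.nan)
    ok = np.abs(denom) > 1e-12
    out[ok] = (o_hom[ok] - e_hom[ok]) / denom[ok]
    if (~ok).any():
        log.warning("inbreeding_f: %d individuals with degenerate denominator", int((~ok).sum()))
    return out


# -- private / shared alleles ------------------------------------------------


def _allele_presence(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ref present, alt present) booleans per site from called genotypes."""
    called = dosages != MISSING
    ref = ((dosages < 2) & called).any(axis=0)
    alt = ((dosages > 0) & called).any(axis=0)
    return ref, alt


@dataclass
class AlleleSharingResult:
    """Mean +/- SE (SD across iterations) of an allele-class count."""

    labels: list
    mean: np.ndarray
    se: np.ndarray
    per_rep: np.ndarray
    reps: int
    equalize_n: int


def private_alleles(
    pop_matrices: list[GenotypeMatrix],
    equalize_n: int,
    reps: int = 100,
    seed: int = 0,
    labels: list | None = None,
) -> AlleleSharingResult:
    """Private-allele counts per population under equalised subsampling.

    An allele (ref or alt) is private to a population when it is present in
    that population's subsample and absent from every other population's
    subsample at the same site.
    """
    if len(pop_matrices) < 2:
        raise ValueError("need >= 2 populations")
    n_sites = {m.n_sites for m in pop_matrices}
    if len(n_sites) != 1:
        raise ValueError("populations must share the same site panel")
    for m in pop_matrices:
        if equalize_n > m.n_samples:
            raise ValueError("equalize_n exceeds the smallest population")
    rng = np.random.default_rng(seed)
    k = len(pop_matrices)
    per_rep = np.empty((reps, k))
    for r in range(reps):
        pres = []
        for m in pop_matrices:
            idx = rng.choice(m.n_samples, size=equalize_n, replace=False)
            pres.append(_allele_presence(m.dosages[idx]))
        ref = np.stack([p[0] for p in pres])  # (k, sites)
        alt = np.stack([p[1] for p in pres])
        for j in range(k):
            others = np.ones(k, dtype=bool)
            others[j] = False
            priv_ref = ref[j] & ~ref[others].any(axis=0)
            priv_alt = alt[j] & ~alt[others].any(axis=0)
            per_rep[r, j] = priv_ref.sum() + priv_alt.sum()
    return AlleleSharingResult(
        labels=labels or list(range(k)),
        mean=per_rep.mean(axis=0),
        se=per_rep.std(axis=0, ddof=1) if reps > 1 else np.zeros(k),
        per_rep=per_rep,
        reps=reps,
        equalize_n=equalize_n,
    )


def shared_alleles_pairwise(
    pop_matrices: list[GenotypeMatrix],
    equalize_n: int,
    reps: int = 100,
    seed: int = 0,
    labels: list | None = None,
) -> AlleleSharingResult:
    """Alleles shared by exactly two of three populations, per pair,
    under equalised subsampling."""
    if len(pop_matrices) != 3:
        raise ValueError("shared_alleles_pairwise requires exactly 3 populations")
    if len({m.n_sites for m in pop_matrices}) != 1:
        raise ValueError("populations must share the same site panel")
    for m in pop_matrices:
        if equalize_n > m.n_samples:
            raise ValueError("equalize_n exceeds the smallest population")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(3), 2))
    per_rep = np.empty((reps, len(pairs)))
    for r in range(reps):
        pres = []
        for m in pop_matrices:
            idx = rng.choice(m.n_samples, size=equalize_n, replace=False)
            pres.append(_allele_presence(m.dosages[idx]))
        ref = np.stack([p[0] for p in pres])
        alt = np.stack([p[1] for p in pres])
        for pi_, (a, b) in enumerate(pairs):
            c = 3 - a - b
            shared_ref = ref[a] & ref[b] & ~ref[c]
            shared_alt = alt[a] & alt[b] & ~alt[c]
            per_rep[r, pi_] = shared_ref.sum() + shared_alt.sum()
    lab = labels or [0, 1, 2]
    return AlleleSharingResult(
        labels=[(lab[a], lab[b]) for a, b in pairs],
        mean=per_rep.mean(axis=0),
        se=per_rep.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(pairs)),
        per_rep=per_rep,
        reps=reps,
        equalize_n=equalize_n,
    )
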