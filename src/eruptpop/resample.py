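"""Resampling designs and the two-sample tests used to compare them.

Four subsampling schemes over a genotype matrix are provided — equalised
bootstrap over individuals, random locus panels, one individual per burrow
(social group), and within-sex subsets — together with the locus-count /
standard-deviation curve that quantifies how marker number stabilises
heterozygosity estimates, and thin wrappers for the two-sample
Kolmogorov-Smirnov and Welch t tests.

Draws are without replacement within an iteration (locus panels switch to
with-replacement, with a warning, when the requested panel exceeds the
available sites).  Sample order is canonicalised (sorted ids) before any
draw, so results are invariant to input row permutation for a fixed seed.
Each iteration's generator is derived from (seed, iteration index), making
any single iteration reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .genio import GenotypeMatrix, SampleMetadata
from . import popstats

log = logging.getLogger(__name__)

SCHEMES = ("individuals", "loci", "one_per_group", "sex_partition")

#: named statistics a resampling run can evaluate on a (matrix) draw
STATISTICS: dict[str, Callable[[GenotypeMatrix], float]] = {
    "mean_het": lambda m: popstats.mean_heterozygosity(m, denominator="snp_sites"),
    "pi_mean": lambda m: float(np.mean(popstats.per_site_diversity(m).pi)),
    "theta_mean": lambda m: float(np.mean(popstats.per_site_diversity(m).theta_w)),
    "f_mean": lambda m: float(np.nanmean(popstats.inbreeding_f(m))),
}


@dataclass
class ResamplingResult:
    scheme: str
    n: int
    reps: int
    values: np.ndarray
    seed: int
    statistic: str
    notes: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _canonical(matrix: GenotypeMatrix, metadata: SampleMetadata | None):
    order = sorted(range(matrix.n_samples), key=lambda i: matrix.sample_ids[i])
    mat = matrix.subset(samples=[matrix.sample_ids[i] for i in order])
    meta = metadata.for_samples(mat.sample_ids) if metadata is not None else None
    return mat, meta


def resample_statistic(
    matrix: GenotypeMatrix,
    metadata: SampleMetadata | None = None,
    scheme: str = "individuals",
    n: int | None = None,
    reps: int = 100,
    statistic: str | Callable[[GenotypeMatrix], float] = "mean_het",
    seed: int = 0,
    sex: str | None = None,
    max_retries: int = 10,
) -> ResamplingResult:
    """Evaluate a named statistic on repeated scheme-specific subsamples.

    scheme='individuals': n individuals without replacement per iteration.
    scheme='loci': n sites per iteration (with replacement if n > panel).
    scheme='one_per_group': one random individual per burrow (n ignored).
    scheme='sex_partition': n individuals of the given ``sex``.

    Iterations on which the statistic is undefined are redrawn up to
    ``max_retries`` times (logged).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    stat_name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    stat_fn = STATISTICS[statistic] if isinstance(statistic, str) else statistic
    mat, meta = _canonical(matrix, metadata)
    notes: list[str] = []

    if scheme == "one_per_group":
        if meta is None:
            raise ValueError("one_per_group needs metadata with burrow labels")
        burrows = meta.column("burrow")
        if (burrows == "unknown").all():
            raise ValueError("one_per_group needs burrow labels")
        groups = [np.where(burrows == b)[0] for b in sorted(set(burrows))]
        n_eff = len(groups)
    elif scheme == "sex_partition":
        if meta is None or sex is None:
            raise ValueError("sex_partition needs metadata and a sex ('M' or 'F')")
        pool = np.where(meta.column("sex") == sex)[0]
        if n is None:
            n = len(pool)
        if n < 1 or n > len(pool):
            raise ValueError(f"infeasible n={n} for {len(pool)} individuals of sex {sex}")
        n_eff = n
    elif scheme == "individuals":
        if n is None:
            n = mat.n_samples
        if n < 1 or n > mat.n_samples:
            raise ValueError(f"infeasible n={n} for {mat.n_samples} individuals")
        n_eff = n
    else:  # loci
        if n is None or n < 1:
            raise ValueError("loci scheme needs n >= 1")
        n_eff = n
        if n > mat.n_sites:
            notes.append(f"n={n} exceeds the {mat.n_sites}-site panel; sampling with replacement")
            log.warning(notes[-1])

    values = np.empty(reps)
    for r in range(reps):
        for attempt in range(max_retries + 1):
            rng = np.random.default_rng([seed, r, attempt])
            try:
                if scheme == "individuals":
                    idx = np.sort(rng.choice(mat.n_samples, size=n_eff, replace=False))
                    draw = mat.subset(samples=idx.tolist())
                elif scheme == "sex_partition":
                    idx = np.sort(rng.choice(pool, size=n_eff, replace=False))
                    draw = mat.subset(samples=idx.tolist())
                elif scheme == "one_per_group":
                    idx = np.sort([int(rng.choice(g)) for g in groups])
                    draw = mat.subset(samples=list(idx))
                else:  # loci
                    replace = n_eff > mat.n_sites
                    cols = rng.choice(mat.n_sites, size=n_eff, replace=replace)
                    if replace:
                        # duplicate columns collide on coordinates; evaluate on
                        # the raw dosage view instead of a GenotypeMatrix
                        draw = _loci_view(mat, cols)
                    else:
                        draw = mat.subset(sites=np.sort(cols).tolist())
                v = stat_fn(draw)
                if np.isfinite(v):
                    values[r] = v
                    break
            except (ValueError, FloatingPointError):
                pass
            if attempt == max_retries:
                raise RuntimeError(f"statistic undefined after {max_retries} redraws at iteration {r}")
        else:  # pragma: no cover
            pass
    return ResamplingResult(
        scheme=scheme, n=n_eff, reps=reps, values=values, seed=seed,
        statistic=stat_name, notes=notes,
    )


def _loci_view(matrix: GenotypeMatrix, cols: np.ndarray) -> GenotypeMatrix:
    """Matrix over possibly-duplicated site columns; coordinates synthesised."""
    return GenotypeMatrix(
        dosages=matrix.dosages[:, cols].copy(),
        sample_ids=list(matrix.sample_ids),
        site_regions=np.asarray([f"draw{i:06d}" for i in range(len(cols))], dtype=object),
        site_positions=np.ones(len(cols), dtype=np.int64),
    )


DEFAULT_LOCI_GRID = tuple(range(50, 1001, 50)) + tuple(range(1500, 10_001, 500))


def loci_sd_curve(
    matrix: GenotypeMatrix,
    grid: tuple[int, ...] = DEFAULT_LOCI_GRID,
    reps: int = 100,
    seed: int = 0,
    statistic: str | Callable[[GenotypeMatrix], float] = "mean_het",
) -> list[tuple[int, float, float]]:
    """(n, mean, SD) of the statistic over ``reps`` random locus panels per
    grid value; the default grid steps by 50 to 1,000 loci and then by 500
    to 10,000."""
    if not grid:
        raise ValueError("empty grid")
    if any(g < 2 for g in grid):
        raise ValueError("grid values must be >= 2")
    out = []
    for i, g in enumerate(grid):
        res = resample_statistic(
            matrix, scheme="loci", n=int(g), reps=reps, statistic=statistic, seed=seed + i
        )
        out.append((int(g), res.mean, res.sd))
    return out


# -- two-sample tests --------------------------------------------------------


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D, p).

    Exact p by enumeration when min(n, m) <= 10, otherwise the asymptotic
    Kolmogorov distribution with the standard small-sample correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(x.size, y.size) <= 10 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t_two_sample(x, y) -> tuple[float, float]:
    """Welch two-sample t test (t, two-sided p) with Satterthwaite df.

    With zero variance in both samples the statistic is undefined; returns
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        log.warning("welch_t_two_sample: zero variance in both samples; undefined")
        return float("nan"), float("nan")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
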