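"""Demographic-signal analyses: mismatch distributions, Harpending's
raggedness index, centred/re-scaled distribution comparison, and the
random-survivorship drift simulation.

The pairwise difference between two diploid individuals is the L1 distance
between their dosage vectors over sites called in both — i.e. the number of
allele-copy differences — which is the natural unphased-genotype analogue
of a sequence mismatch count.  An identity-by-state mismatch alternative
(count of sites with differing genotypes) is available via ``metric``.

Raggedness convention (pinned by tests): observed classes are made
contiguous from 0 to the largest observed class K, absent classes padded
with frequency zero, one zero-frequency class K+1 appended, and
r = sum_{i=1..K+1} (x_i - x_{i-1})^2.  A single interior spike therefore
contributes both its rise and its fall (r = 2 for a point mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix
from .popstats import per_individual_heterozygosity
from .resample import ks_two_sample, welch_t_two_sample

log = logging.getLogger(__name__)


@dataclass
class MismatchDistribution:
    """Relative frequencies of pairwise genotype differences.

    ``diff_classes`` are the contiguous integer classes 0..K; ``rel_freq``
    their relative frequencies (sums to 1); ``pair_diffs`` retains the raw
    per-pair values for centred/re-scaled comparisons.
    """

    diff_classes: np.ndarray
    rel_freq: np.ndarray
    n_pairs: int
    pair_diffs: np.ndarray
    metric: str = "l1_dosage"

    def __post_init__(self) -> None:
        total = self.rel_freq.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError("relative frequencies must sum to 1")


def mismatch_distribution(matrix: GenotypeMatrix, metric: str = "l1_dosage") -> MismatchDistribution:
    """Distribution of pairwise differences across all pairs of individuals.

    metric='l1_dosage': sum over co-called sites of |dosage_i - dosage_j|.
    metric='ibs_mismatch': count of co-called sites with different genotypes.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    if metric not in ("l1_dosage", "ibs_mismatch"):
        raise ValueError(f"unknown metric {metric!r}")
    d = matrix.dosages.astype(np.int32)
    called = matrix.dosages != MISSING
    n = matrix.n_samples
    diffs = []
    for i in range(n - 1):
        both = called[i] & called[i + 1 :]
        delta = np.abs(d[i] - d[i + 1 :])
        if metric == "ibs_mismatch":
            delta = (delta > 0).astype(np.int32)
        diffs.extend((delta * both).sum(axis=1).tolist())
    diffs = np.asarray(diffs, dtype=np.int64)
    k_max = int(diffs.max())
    counts = np.bincount(diffs, minlength=k_max + 1).astype(float)
    return MismatchDistribution(
        diff_classes=np.arange(k_max + 1),
        rel_freq=counts / counts.sum(),
        n_pairs=len(diffs),
        pair_diffs=diffs,
        metric=metric,
    )


def raggedness(dist: MismatchDistribution) -> float:
    """Harpending's raggedness index under the module's padding convention.

    r = sum_{i=1..K+1} (x_i - x_{i-1})^2 over contiguous classes 0..K plus
    one zero-padded class K+1.
    """
    x = np.asarray(dist.rel_freq, dtype=float)
    if x.size == 0:
        raise ValueError("empty distribution")
    x = np.append(x, 0.0)  # class K+1 padding
    return float(np.sum(np.diff(x) ** 2))


def compare_mismatch(d1: MismatchDistribution, d2: MismatchDistribution) -> tuple[float, float]:
    """KS comparison of the centred, re-scaled per-pair difference samples.

    Each sample is centred by its mean and scaled by its SD before the
    two-sample KS test, so pure location (and scale) shifts do not register.
    """
    out = []
    for d in (d1, d2):
        v = d.pair_diffs.astype(float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError("zero SD in a mismatch distribution; cannot re-scale")
        # round so float rounding cannot split tie groups of the integer
        # difference classes between the two standardised samples
        out.append(np.round((v - v.mean()) / sd, 9))
    return ks_two_sample(out[0], out[1])


@dataclass
class SurvivorDriftResult:
    """Null drift expectation for heterozygosity under random survivorship."""

    pre_mean_het: float
    post_mean_het: float
    post_sd_het: float
    per_rep: np.ndarray
    fraction: float
    t: float
    p: float


def survivor_drift_sim(
    matrix: GenotypeMatrix, fraction: float = 0.5, reps: int = 100, seed: int = 0
) -> SurvivorDriftResult:
    """Randomly designate ``fraction`` of individuals as survivors and
    compare survivor heterozygosity with the full sample.

    Per replicate, floor(fraction * N) survivors are drawn uniformly without
    replacement and their mean observed heterozygosity recorded; the report
    gives the full-sample value, the survivor mean +/- SD over replicates,
    and a Welch t test of the full-sample per-individual heterozygosities
    against the replicate means.  Random survivorship does not change the
    expectation — the paper-level null this simulation quantifies.
    """
    if matrix.n_samples < 4:
        raise ValueError("need >= 4 individuals")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_surv = int(np.floor(fraction * matrix.n_samples))
    if n_surv < 2:
        raise ValueError("survivor count < 2; increase fraction or sample size")
    het = per_individual_heterozygosity(matrix)
    pre_mean = float(np.nanmean(het))
    rng = np.random.default_rng(seed)
    per_rep = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(matrix.n_samples, size=n_surv, replace=False)
        per_rep[r] = float(np.nanmean(het[idx]))
    if n_surv == matrix.n_samples:
        t, p = 0.0, 1.0
    else:
        t, p = welch_t_two_sample(het[np.isfinite(het)], per_rep)
    return SurvivorDriftResult(
        pre_mean_het=pre_mean,
        post_mean_het=float(per_rep.mean()),
        post_sd_het=float(per_rep.std(ddof=1)) if reps > 1 else 0.0,
        per_rep=per_rep,
        fraction=fraction,
        t=t,
        p=p,
    )
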