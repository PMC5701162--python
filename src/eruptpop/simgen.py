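"""Forward Wright-Fisher generator for pre/post-bottleneck genotype datasets.

A discrete-generation, per-locus binomial Wright-Fisher engine with an
instantaneous census reduction at a stated generation, optional symmetric
island-model migration between demes, and a diploid sampling layer that
emulates a two-time-point field design: cohorts sampled before and after the
event, with sex, age and burrow (social group) labels and optional full-sib
pairs within shared burrows.

No selection, no mutation during the simulated window, no linkage: loci are
independent and founded from a stated minor-allele-frequency distribution
(by default the neutral-SFS-shaped density proportional to 1/x, truncated to
[1/(2Ne), 0.5]).  Everything is driven by a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genio import GenotypeMatrix, MISSING, SampleMetadata, write_metadata, write_vcf

log = logging.getLogger(__name__)


# -- configuration -----------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for one forward simulation.

    ``ne_pre`` is the diploid census/effective size per deme before the
    event; at generation ``event_generation`` it drops instantaneously to
    ``floor(ne_pre * (1 - decline_fraction))`` and stays there for
    ``generations_post`` further generations.
    """

    n_loci: int
    ne_pre: int = 500
    decline_fraction: float = 0.0
    event_generation: int = 10
    generations_post: int = 2
    migration_rate: float = 0.0
    n_demes: int = 1
    initial_freq_spec: str | float = "neutral"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")
        if self.ne_pre < 2:
            raise ValueError(f"ne_pre must be >= 2, got {self.ne_pre}")
        if not (0.0 <= self.decline_fraction < 1.0):
            raise ValueError(f"decline_fraction must be in [0, 1), got {self.decline_fraction}")
        if not (0.0 <= self.migration_rate <= 0.5):
            raise ValueError(f"migration_rate must be in [0, 0.5], got {self.migration_rate}")
        if self.n_demes < 1:
            raise ValueError(f"n_demes must be >= 1, got {self.n_demes}")
        if self.event_generation < 0 or self.generations_post < 0:
            raise ValueError("generation counts must be non-negative")
        if isinstance(self.initial_freq_spec, str):
            if self.initial_freq_spec not in ("neutral", "uniform"):
                raise ValueError("initial_freq_spec must be 'neutral', 'uniform' or a float")
        elif not (0.0 < float(self.initial_freq_spec) < 1.0):
            raise ValueError("fixed initial frequency must lie in (0, 1)")

    @property
    def ne_post(self) -> int:
        return int(np.floor(self.ne_pre * (1.0 - self.decline_fraction)))

    @property
    def n_generations(self) -> int:
        return self.event_generation + self.generations_post


@dataclass
class TrueHistory:
    """Recorded truth of one simulation run.

    ``freqs`` has shape ``(n_generations + 1, n_demes, n_loci)``;
    ``deme_sizes`` has shape ``(n_generations + 1, n_demes)``.
    """

    freqs: np.ndarray
    deme_sizes: np.ndarray
    config: SimulationConfig


@dataclass(frozen=True)
class Cohort:
    """One sampling event: n individuals from one deme at one generation."""

    deme: int
    generation: int
    n_individuals: int
    n_burrows: int
    population: str
    period: str

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("cohort n_individuals must be >= 1")
        if not (1 <= self.n_burrows <= self.n_individuals):
            raise ValueError("n_burrows must satisfy 1 <= n_burrows <= n_individuals")


@dataclass(frozen=True)
class SamplingPlan:
    cohorts: tuple[Cohort, ...]
    sex_ratio: float = 0.5
    sibship_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("plan needs at least one cohort")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if not (0.0 <= self.sibship_rate <= 1.0):
            raise ValueError("sibship_rate must be in [0, 1]")


# -- core engine -------------------------------------------------------------


def _initial_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Founding minor-allele frequencies, one per locus (shared across demes)."""
    if isinstance(config.initial_freq_spec, (int, float)):
        return np.full(config.n_loci, float(config.initial_freq_spec))
    lo, hi = 1.0 / (2 * config.ne_pre), 0.5
    if config.initial_freq_spec == "uniform":
        return rng.uniform(lo, hi, size=config.n_loci)
    # density proportional to 1/x on [lo, hi]: inverse-CDF sampling
    u = rng.uniform(size=config.n_loci)
    return lo * (hi / lo) ** u


def simulate_populations(config: SimulationConfig) -> TrueHistory:
    """Run the forward binomial Wright-Fisher scenario.

    Per generation and deme the allele count for each locus is drawn
    Binomial(2N_g, p'), where p' is the post-migration frequency
    ``(1 - m) p_d + m mean(p_others)``.  The event is an instantaneous size
    change at ``event_generation``.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_gen = config.n_generations
    sizes = np.empty((n_gen + 1, config.n_demes), dtype=np.int64)
    sizes[: config.event_generation] = config.ne_pre
    sizes[config.event_generation:] = max(config.ne_post, 2)
    if config.ne_post < 2 and config.decline_fraction > 0:
        log.warning("post-event size %d clamped to 2", config.ne_post)

    freqs = np.empty((n_gen + 1, config.n_demes, config.n_loci))
    freqs[0] = _initial_freqs(config, rng)[None, :]
    m = config.migration_rate
    for g in range(1, n_gen + 1):
        p = freqs[g - 1]
        if m > 0 and config.n_demes > 1:
            others = (p.sum(axis=0, keepdims=True) - p) / (config.n_demes - 1)
            p = (1 - m) * p + m * others
        two_n = 2 * sizes[g][:, None]
        freqs[g] = rng.binomial(np.broadcast_to(two_n, p.shape), p) / two_n
    return TrueHistory(freqs=freqs, deme_sizes=sizes, config=config)


# -- sampling layer ----------------------------------------------------------


@dataclass
class _Individual:
    sample_id: str
    cohort: Cohort
    burrow: str
    sex: str
    age: str
    sib_group: int  # -1 when not part of a full-sib pair


def _build_roster(plan: SamplingPlan, rng: np.random.Generator) -> list[_Individual]:
    roster: list[_Individual] = []
    sib_counter = 0
    for ci, cohort in enumerate(plan.cohorts):
        ids = [f"{cohort.population}_{cohort.period}_{i:03d}" for i in range(cohort.n_individuals)]
        burrows = [f"{cohort.population}_B{(i % cohort.n_burrows) + 1:02d}" for i in range(cohort.n_individuals)]
        sexes = np.where(rng.uniform(size=cohort.n_individuals) < plan.sex_ratio, "F", "M")
        members: dict[str, list[int]] = {}
        for i, b in enumerate(burrows):
            members.setdefault(b, []).append(i)
        sib_group = np.full(cohort.n_individuals, -1, dtype=int)
        for b, idxs in members.items():
            for a, c in zip(idxs[0::2], idxs[1::2]):
                if rng.uniform() < plan.sibship_rate:
                    sib_group[a] = sib_group[c] = sib_counter
                    sib_counter += 1
        for i in range(cohort.n_individuals):
            age = "juvenile" if sib_group[i] >= 0 else "adult"
            roster.append(
                _Individual(ids[i], cohort, burrows[i], str(sexes[i]), age, int(sib_group[i]))
            )
    if len({ind.sample_id for ind in roster}) != len(roster):
        raise ValueError("cohort labels collide; give cohorts distinct population/period labels")
    return roster


def _genotype_roster(
    history: TrueHistory, roster: list[_Individual], rng: np.random.Generator
) -> np.ndarray:
    """Diploid dosages for the roster: HW draws from the deme frequency at the
    cohort's generation, except full-sib pairs, which segregate from two
    simulated parents."""
    n_gen = history.freqs.shape[0] - 1
    n_loci = history.freqs.shape[2]
    for ind in roster:
        c = ind.cohort
        if not (0 <= c.generation <= n_gen):
            raise ValueError(f"cohort generation {c.generation} outside simulated range 0..{n_gen}")
        if not (0 <= c.deme < history.freqs.shape[1]):
            raise ValueError(f"cohort deme {c.deme} does not exist")
        if c.n_individuals > history.deme_sizes[c.generation, c.deme]:
            raise ValueError(
                f"cohort of {c.n_individuals} exceeds deme census "
                f"{history.deme_sizes[c.generation, c.deme]} at generation {c.generation}"
            )
    dosages = np.empty((len(roster), n_loci), dtype=np.int8)
    # parents per sib group, drawn once
    parents: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, ind in enumerate(roster):
        p = history.freqs[ind.cohort.generation, ind.cohort.deme]
        if ind.sib_group >= 0:
            if ind.sib_group not in parents:
                parents[ind.sib_group] = (
                    rng.binomial(2, p).astype(np.int8),
                    rng.binomial(2, p).astype(np.int8),
                )
            g1, g2 = parents[ind.sib_group]
            dosages[i] = rng.binomial(1, g1 / 2.0) + rng.binomial(1, g2 / 2.0)
        else:
            dosages[i] = rng.binomial(2, p)
    return dosages


def draw_samples(
    history: TrueHistory, plan: SamplingPlan, seed: int | None = None
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Sample diploid genotypes and metadata according to the plan.

    Deterministic given (history, plan, seed); when seed is None the
    simulation's own seed + 1 is used.
    """
    import pandas as pd

    if seed is None:
        seed = history.config.seed + 1
    rng = np.random.default_rng(seed)
    roster = _build_roster(plan, rng)
    dosages = _genotype_roster(history, roster, rng)
    n_loci = dosages.shape[1]
    matrix = GenotypeMatrix(
        dosages=dosages,
        sample_ids=[ind.sample_id for ind in roster],
        site_regions=np.asarray([f"locus{j:05d}" for j in range(n_loci)], dtype=object),
        site_positions=np.arange(1, n_loci + 1),
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample": [ind.sample_id for ind in roster],
                "population": [ind.cohort.population for ind in roster],
                "period": [ind.cohort.period for ind in roster],
                "sex": [ind.sex for ind in roster],
                "age": [ind.age for ind in roster],
                "burrow": [ind.burrow for ind in roster],
            }
        )
    )
    return matrix, meta


# -- study emulation ---------------------------------------------------------


@dataclass(frozen=True)
class StudyPreset:
    """A two-time-point field design: scenario + sampling plan + SNP target."""

    config: SimulationConfig
    plan: SamplingPlan
    target_snps: int
    n_regions: int = 2027
    region_length: int = 1200


def _species_a() -> StudyPreset:
    # colonial species: focal population sampled pre and post, one extra
    # post-event population 3 km away; kin-structured burrows
    cfg = SimulationConfig(
        n_loci=1,  # placeholder; emulate_study batches loci
        ne_pre=500,
        decline_fraction=0.40,
        event_generation=10,
        generations_post=2,
        migration_rate=0.005,
        n_demes=2,
        initial_freq_spec="neutral",
    )
    plan = SamplingPlan(
        cohorts=(
            Cohort(0, cfg.event_generation - 1, 17, 13, "RinconGrande", "pre"),
            Cohort(0, cfg.n_generations, 31, 9, "RinconGrande", "post"),
            Cohort(1, cfg.n_generations, 9, 9, "LaLonja", "post"),
        ),
        sex_ratio=0.5,
        sibship_rate=0.3,
    )
    return StudyPreset(config=cfg, plan=plan, target_snps=531)


def _species_b() -> StudyPreset:
    # solitary species: one burrow per individual, no sibs
    cfg = SimulationConfig(
        n_loci=1,
        ne_pre=500,
        decline_fraction=0.25,
        event_generation=10,
        generations_post=2,
        migration_rate=0.0,
        n_demes=1,
        initial_freq_spec="neutral",
    )
    plan = SamplingPlan(
        cohorts=(
            Cohort(0, cfg.event_generation - 1, 12, 12, "SanRamon", "pre"),
            Cohort(0, cfg.n_generations, 17, 17, "SanRamon", "post"),
        ),
        sex_ratio=0.5,
        sibship_rate=0.0,
    )
    return StudyPreset(config=cfg, plan=plan, target_snps=449)


PRESETS = {"speciesA": _species_a, "speciesB": _species_b}


def emulate_study(
    species_preset: str,
    seed: int,
    out_dir: str | Path | None = None,
    keep_monomorphic: bool = False,
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Generate a dataset matching a study preset's sampling design.

    Simulates loci in batches and keeps sites segregating in the sampled
    individuals until the preset's target SNP count is reached (sites that
    drift to fixation are re-drawn); assigns each SNP to a random target
    region and position.  With ``out_dir`` set, writes ``<preset>.vcf`` and
    ``<preset>.meta.tsv`` there.  Byte-identical outputs for a given
    (preset, seed).
    """
    if species_preset not in PRESETS:
        raise ValueError(f"unknown preset {species_preset!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[species_preset]()
    rng = np.random.default_rng(seed)
    roster = _build_roster(preset.plan, rng)
    target = preset.target_snps
    batch = int(target * 2)
    columns: list[np.ndarray] = []
    n_kept = 0
    for attempt in range(50):
        cfg = replace(preset.config, n_loci=batch, seed=int(rng.integers(2**31 - 1)))
        history = simulate_populations(cfg)
        dosages = _genotype_roster(history, roster, rng)
        if keep_monomorphic:
            keep = np.ones(dosages.shape[1], dtype=bool)
        else:
            alt = dosages.sum(axis=0)
            keep = (alt > 0) & (alt < 2 * dosages.shape[0])
        cols = dosages[:, keep]
        columns.append(cols)
        n_kept += cols.shape[1]
        if n_kept >= target:
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("could not reach target segregating-site count")
    dosages = np.concatenate(columns, axis=1)[:, :target]

    # scatter SNPs over target regions, unique (region, position)
    coords: set[tuple[int, int]] = set()
    regions, positions = [], []
    while len(regions) < target:
        r = int(rng.integers(preset.n_regions))
        p = int(rng.integers(1, preset.region_length + 1))
        if (r, p) in coords:
            continue
        coords.add((r, p))
        regions.append(f"region{r + 1:04d}")
        positions.append(p)
    order = np.lexsort((np.asarray(positions), np.asarray(regions, dtype=object).astype(str)))
    matrix = GenotypeMatrix(
        dosages=dosages[:, order],
        sample_ids=[ind.sample_id for ind in roster],
        site_regions=np.asarray(regions, dtype=object)[order],
        site_positions=np.asarray(positions, dtype=np.int64)[order],
    )
    import pandas as pd

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample": [ind.sample_id for ind in roster],
                "population": [ind.cohort.population for ind in roster],
                "period": [ind.cohort.period for ind in roster],
                "sex": [ind.sex for ind in roster],
                "age": [ind.age for ind in roster],
                "burrow": [ind.burrow for ind in roster],
            }
        )
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix, out / f"{species_preset}.vcf")
        write_metadata(meta, out / f"{species_preset}.meta.tsv")
    return matrix, meta


def callable_length(species_preset: str) -> int:
    """Total callable target length (bp) implied by a preset's region design."""
    preset = PRESETS[species_preset]()
    return preset.n_regions * preset.region_length
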