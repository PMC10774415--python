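"""Discrete-generation stochastic simulation of a suppression-drive release.

A census population of constant size ``N`` reproduces in non-overlapping
generations.  Every offspring independently draws a mother uniformly from the
fertile females and a father uniformly from the fertile males (random mating
with replacement, full density compensation), receives one gamete from each,
takes its karyotype from the paternal sex chromosome, is exposed to maternal
Cas9 deposition, receives (or not) maternal *tra* product, and finally
develops a sex and fertility phenotype.  The population goes extinct at the
first generation that lacks fertile females or fertile males.

The population is stored column-wise in numpy arrays (one ``(n, 2)`` allele
array per locus) so that a whole generation is produced with vectorised
draws; the per-individual semantics are exactly those of
:mod:`medflydrive.genetics` and :mod:`medflydrive.germline`, which the test
suite verifies against the analytic gamete distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    DESIGNS,
    AlleleState,
    DriveDesign,
    Genotype,
    Individual,
    Karyotype,
    LocusId,
)
from .germline import (
    DriveParams,
    gamete_distribution,
    sample_gametes_batch,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "Population",
    "make_initial_population",
    "step_generation",
    "run_simulation",
    "run_replicates",
    "summarize_replicates",
    "ReplicateSummary",
    "expected_offspring_drive_frequency",
]

_WILD = int(AlleleState.WILD)
_DRIVE = int(AlleleState.DRIVE)
_R1 = int(AlleleState.R1)
_R2 = int(AlleleState.R2)
_FUNCTIONAL = (_WILD, _R1)


@dataclass(frozen=True)
class SimConfig:
    """Release scenario: design, rates, composition, horizon and seed.

    The default composition is 500 wild-type females, 250 wild-type males and
    250 drive males hemizygous at the home locus — a construct allele
    frequency of 12.5% in a census of 1000.
    """

    design: DriveDesign
    params: DriveParams = field(default_factory=DriveParams)
    population_size: int = 1000
    generations: int = 20
    n_wt_females: int = 500
    n_wt_males: int = 250
    n_drive_males: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        for name in ("n_wt_females", "n_wt_males", "n_drive_males"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.n_wt_females + self.n_wt_males + self.n_drive_males
        if total != self.population_size:
            raise ValueError(
                "initial composition must sum to population_size: "
                f"{self.n_wt_females} + {self.n_wt_males} + {self.n_drive_males} "
                f"= {total} != {self.population_size}"
            )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "design": self.design.name,
            "params": {
                "cleavage_rate": self.params.cleavage_rate,
                "hdr_rate": self.params.hdr_rate,
                "r2_fraction": self.params.r2_fraction,
                "maternal_factor": self.params.maternal_factor,
            },
            "population_size": self.population_size,
            "generations": self.generations,
            "n_wt_females": self.n_wt_females,
            "n_wt_males": self.n_wt_males,
            "n_drive_males": self.n_drive_males,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        design_name = data.pop("design", None)
        if design_name is None:
            raise ValueError("config is missing the required key 'design'")
        if design_name not in DESIGNS:
            raise ValueError(
                f"unknown design {design_name!r}; expected one of {sorted(DESIGNS)}"
            )
        params_data = data.pop("params", {})
        try:
            params = DriveParams(**params_data)
        except TypeError as exc:
            raise ValueError(f"invalid 'params' block: {exc}") from exc
        allowed = {
            "population_size",
            "generations",
            "n_wt_females",
            "n_wt_males",
            "n_drive_males",
            "seed",
        }
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=DESIGNS[design_name], params=params, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a JSON or YAML scenario file (dispatch on extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


class Population:
    """Column-wise population store: one row per living individual."""

    def __init__(
        self,
        karyotype_y: np.ndarray,
        alleles: dict[LocusId, np.ndarray],
        maternal_tra_intact: np.ndarray,
        design: DriveDesign,
    ) -> None:
        self.karyotype_y = np.asarray(karyotype_y, dtype=bool)
        self.alleles = {k: np.asarray(v, dtype=np.int8) for k, v in alleles.items()}
        self.maternal_tra_intact = np.asarray(maternal_tra_intact, dtype=bool)
        self.design = design
        self.sex_male, self.fertile = _assign_phenotypes(
            self.karyotype_y, self.alleles, self.maternal_tra_intact, design
        )

    @property
    def size(self) -> int:
        return self.karyotype_y.shape[0]

    @property
    def n_fertile_females(self) -> int:
        return int((self.fertile & ~self.sex_male).sum())

    @property
    def n_fertile_males(self) -> int:
        return int((self.fertile & self.sex_male).sum())

    @classmethod
    def empty(cls, design: DriveDesign) -> "Population":
        return cls(
            karyotype_y=np.zeros(0, dtype=bool),
            alleles={l: np.zeros((0, 2), dtype=np.int8) for l in design.loci},
            maternal_tra_intact=np.zeros(0, dtype=bool),
            design=design,
        )

    def allele_counts(self, locus: LocusId) -> dict[AlleleState, int]:
        arr = self.alleles[locus]
        return {s: int((arr == int(s)).sum()) for s in AlleleState}

    def drive_allele_frequency(self, locus: LocusId | None = None) -> float:
        """Construct allele frequency at ``locus`` (default: home locus)."""
        locus = locus or self.design.home_locus
        if self.size == 0:
            return float("nan")
        return float((self.alleles[locus] == _DRIVE).mean())

    def individuals(self) -> Iterable[Individual]:
        """Materialise row-level :class:`Individual` objects (for checks)."""
        for i in range(self.size):
            geno = Genotype(
                karyotype=Karyotype.XY if self.karyotype_y[i] else Karyotype.XX,
                alleles={
                    l: (AlleleState(int(a[i, 0])), AlleleState(int(a[i, 1])))
                    for l, a in self.alleles.items()
                },
            )
            yield Individual.develop(geno, bool(self.maternal_tra_intact[i]), self.design)


def _functional_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == _WILD) | (arr == _R1)


def _assign_phenotypes(
    karyotype_y: np.ndarray,
    alleles: dict[LocusId, np.ndarray],
    maternal_tra_intact: np.ndarray,
    design: DriveDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sex and fertility rules (see :mod:`medflydrive.genetics`)."""
    n = karyotype_y.shape[0]
    if LocusId.TRA in alleles:
        has_tra = _functional_mask(alleles[LocusId.TRA]).any(axis=1)
    else:
        has_tra = np.ones(n, dtype=bool)
    sex_male = karyotype_y | ~maternal_tra_intact | ~has_tra
    sterile_female = np.zeros(n, dtype=bool)
    for locus in design.fertility_loci:
        sterile_female |= ~_functional_mask(alleles[locus]).any(axis=1)
    fertile = sex_male | ~sterile_female
    return sex_male, fertile


def make_initial_population(config: SimConfig) -> Population:
    """Pre-release census: wild-type females and males plus hemizygous drive males.

    Drive males carry (construct, wild) at the home locus and wild-type pairs
    everywhere else; everyone received maternal *tra* normally.
    """
    design = config.design
    n = config.population_size
    nf, nm, nd = config.n_wt_females, config.n_wt_males, config.n_drive_males
    karyotype_y = np.zeros(n, dtype=bool)
    karyotype_y[nf:] = True  # wild-type males then drive males
    alleles = {l: np.zeros((n, 2), dtype=np.int8) for l in design.loci}
    # drive males: paternal-slot construct at the home locus
    alleles[design.home_locus][nf + nm :, 1] = _DRIVE
    return Population(
        karyotype_y=karyotype_y,
        alleles=alleles,
        maternal_tra_intact=np.ones(n, dtype=bool),
        design=design,
    )


def step_generation(
    population: Population,
    design: DriveDesign,
    params: DriveParams,
    rng: np.random.Generator,
    n_offspring: int | None = None,
) -> Population:
    """Produce the next generation (exactly ``n_offspring`` individuals).

    Returns the empty population when either fertile class is missing.
    """
    fem = np.nonzero(population.fertile & ~population.sex_male)[0]
    mal = np.nonzero(population.fertile & population.sex_male)[0]
    if fem.size == 0 or mal.size == 0:
        return Population.empty(design)
    n = population.size if n_offspring is None else n_offspring
    mothers = fem[rng.integers(0, fem.size, size=n)]
    fathers = mal[rng.integers(0, mal.size, size=n)]

    home = design.home_locus
    mother_active = (population.alleles[home][mothers] == _DRIVE).any(axis=1)
    father_active = (population.alleles[home][fathers] == _DRIVE).any(axis=1)

    child_alleles: dict[LocusId, np.ndarray] = {}
    for locus in design.loci:
        can_home = locus == home
        mg = sample_gametes_batch(
            population.alleles[locus][mothers], can_home, params, rng, active=mother_active
        )
        pg = sample_gametes_batch(
            population.alleles[locus][fathers], can_home, params, rng, active=father_active
        )
        child_alleles[locus] = np.stack([mg, pg], axis=1)

    # karyotype: Y transmitted by XY fathers with probability 1/2; XX fathers
    # (converted males) only ever transmit X
    karyotype_y = population.karyotype_y[fathers] & (rng.random(n) < 0.5)

    # maternal Cas9 deposition: NHEJ-only cleavage of zygotic wild-type sites
    rate = params.maternal_cleavage_rate
    if rate > 0.0 and mother_active.any():
        for locus in design.loci:
            arr = child_alleles[locus]
            cut = (
                (arr == _WILD)
                & mother_active[:, None]
                & (rng.random((n, 2)) < rate)
            )
            if cut.any():
                r2 = rng.random((n, 2)) < params.r2_fraction
                arr[cut & r2] = _R2
                arr[cut & ~r2] = _R1

    # maternal tra provision: per-offspring Bernoulli; only wild-type maternal
    # tra alleles are cleavable, R1 alleles always provide
    if design.targets_tra:
        tra_m = population.alleles[LocusId.TRA][mothers]
        n_wild = (tra_m == _WILD).sum(axis=1)
        has_r1 = (tra_m == _R1).any(axis=1)
        p_fail = np.where(
            mother_active & ~has_r1, params.cleavage_rate ** n_wild, 0.0
        )
        intact = rng.random(n) >= p_fail
    else:
        intact = np.ones(n, dtype=bool)

    return Population(
        karyotype_y=karyotype_y,
        alleles=child_alleles,
        maternal_tra_intact=intact,
        design=design,
    )


@dataclass
class SimResult:
    """Trajectory and outcome of one replicate.

    ``trajectory`` has one row per generation (including generation 0) with
    the census size, fertile counts and per-locus allele counts.  ``extinct``
    is true iff some recorded generation lacks fertile females or fertile
    males within the horizon; ``extinction_generation`` is the first such
    generation.
    """

    trajectory: pd.DataFrame
    extinct: bool
    extinction_generation: int | None
    config: SimConfig


def _record(generation: int, pop: Population, design: DriveDesign) -> dict:
    row = {
        "generation": generation,
        "size": pop.size,
        "fertile_females": pop.n_fertile_females,
        "fertile_males": pop.n_fertile_males,
    }
    for locus in design.loci:
        counts = pop.allele_counts(locus)
        row[f"{locus.value}_drive"] = counts[AlleleState.DRIVE]
        row[f"{locus.value}_r1"] = counts[AlleleState.R1]
        row[f"{locus.value}_r2"] = counts[AlleleState.R2]
        row[f"{locus.value}_wild"] = counts[AlleleState.WILD]
    return row


def run_simulation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """Run one replicate to extinction or the generation horizon.

    Fully reproducible: the same config (seed included) yields an identical
    trajectory.  An explicit ``rng`` overrides the config seed (used for
    replicate substreams).
    """
    design = config.design
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = make_initial_population(config)
    rows = [_record(0, pop, design)]
    extinct = pop.n_fertile_females == 0 or pop.n_fertile_males == 0
    ext_gen: int | None = 0 if extinct else None
    if not extinct:
        for g in range(1, config.generations + 1):
            pop = step_generation(pop, design, config.params, rng)
            rows.append(_record(g, pop, design))
            if pop.n_fertile_females == 0 or pop.n_fertile_males == 0:
                extinct = True
                ext_gen = g
                break
    return SimResult(
        trajectory=pd.DataFrame(rows),
        extinct=extinct,
        extinction_generation=ext_gen,
        config=config,
    )


def run_replicates(config: SimConfig, n_replicates: int) -> list[SimResult]:
    """Run independent replicates on spawned substreams of the master seed.

    Replicate ``r`` uses the ``r``-th child of ``SeedSequence(config.seed)``,
    so any single replicate can be reproduced in isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    return [run_simulation(config, rng=np.random.default_rng(ss)) for ss in children]


class ReplicateSummary(NamedTuple):
    extinction_fraction: float
    mean_time_to_extinction: float | None
    n_replicates: int


def summarize_replicates(
    results: Sequence[SimResult], include_censored: bool = False
) -> ReplicateSummary:
    """Extinction fraction and mean extinction time over replicates.

    By default the mean is taken over extinct runs only (``None`` when no run
    went extinct).  With ``include_censored`` surviving runs enter the mean at
    their horizon generation, the censoring-aware alternative.
    """
    if len(results) == 0:
        raise ValueError("need at least one replicate")
    n = len(results)
    times = [r.extinction_generation for r in results if r.extinct]
    frac = len(times) / n
    if include_censored:
        censored = [r.config.generations for r in results if not r.extinct]
        all_times = times + censored
        mean_time = float(np.mean(all_times)) if all_times else None
    else:
        mean_time = float(np.mean(times)) if times else None
    return ReplicateSummary(frac, mean_time, n)


def expected_offspring_drive_frequency(
    population: Population, design: DriveDesign, params: DriveParams
) -> float:
    """Infinite-population expectation of the next generation's construct frequency.

    Averages the analytic per-parent transmission probabilities
    (:func:`medflydrive.germline.gamete_distribution`) over the fertile
    females and fertile males; valid for the construct because neither
    deposition nor provision creates or destroys it.  Serves as the
    deterministic oracle for the stochastic generation step.
    """
    home = design.home_locus

    def _mean_p(idx: np.ndarray) -> float:
        arr = population.alleles[home][idx]
        kary = population.karyotype_y[idx]
        uniq, counts = np.unique(
            np.column_stack([arr, kary.astype(np.int8)]), axis=0, return_counts=True
        )
        total = counts.sum()
        p = 0.0
        for row, cnt in zip(uniq, counts):
            pair = (AlleleState(int(row[0])), AlleleState(int(row[1])))
            geno = Genotype(
                karyotype=Karyotype.XY if row[2] else Karyotype.XX,
                alleles={
                    l: (
                        pair
                        if l == home
                        else (AlleleState.WILD, AlleleState.WILD)
                    )
                    for l in design.loci
                },
            )
            # only home-locus alleles matter for construct transmission, but
            # drive activity requires the construct to be present at all
            dist = gamete_distribution(geno, design, params)[home]
            p += cnt / total * dist.get(AlleleState.DRIVE, 0.0)
        return p

    fem = np.nonzero(population.fertile & ~population.sex_male)[0]
    mal = np.nonzero(population.fertile & population.sex_male)[0]
    if fem.size == 0 or mal.size == 0:
        return 0.0
    return 0.5 * (_mean_p(fem) + _mean_p(mal))
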