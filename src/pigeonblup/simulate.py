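"""Synthetic racing-pigeon study generator with known ground truth.

Emulates the structure of the study cohort the pipeline targets: a
multi-generation pedigree (defaults: 237 founders plus 5 generations of
60 matings x 6 offspring = 2,037 animals, of which the youngest 867 are
phenotyped and 127 of those genotyped), breeding values gene-dropped down
the pedigree with additive variance sigma2_u, binary-liability phenotypes
mapped to an accumulated race distance (km), and a tri-allelic
microsatellite segregating at the study's allele frequencies with an
optional per-copy allelic effect on the liability.

Every stage is seeded and returns plain pipeline inputs (PedigreeRecord,
DistanceRecord, MicrosatGenotype) plus a ground-truth dossier, so parameter
recovery can be asserted end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import (
    Pedigree,
    PedigreeRecord,
    inbreeding_coefficients,
    validate_and_sort,
)
from .phenotypes import DEFAULT_THRESHOLDS_KM, DistanceRecord
from .microsat import MicrosatGenotype

#: Allele frequencies observed in the genotyped study cohort (S, M, L).
DEFAULT_ALLELE_FREQS: dict[str, float] = {"S": 0.146, "M": 0.614, "L": 0.240}

#: Fraction of phenotyped birds reaching each distance threshold.  Chosen as
#: a plausibly steep survival-like decay over the five cut-offs; the real
#: per-threshold incidences are not published.
DEFAULT_INCIDENCES: tuple[float, ...] = (0.55, 0.40, 0.25, 0.15, 0.08)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the study's scale and h2 = 0.30."""

    n_founders: int = 237
    n_generations: int = 5
    n_matings: int = 60
    offspring_per_mating: int = 6
    n_phenotyped: Optional[int] = 867   # youngest animals; None = all
    n_genotyped: Optional[int] = 127    # random subset of phenotyped; None = all phenotyped
    sex_effect: float = 0.2             # male minus female liability shift, liability SD units
    sigma2_u: float = 3.0 / 7.0         # h2 = sigma2_u/(sigma2_u+1) = 0.30
    allele_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQS)
    )
    target_allele: str = "S"
    beta: float = 0.0                   # liability shift per copy of target allele
    incidences: tuple[float, ...] = DEFAULT_INCIDENCES
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_KM
    seed: int = 0

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + 1.0)

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if self.sigma2_u < 0:
            raise ValueError("sigma2_u must be non-negative")
        if len(self.incidences) != len(self.thresholds):
            raise ValueError("need one incidence per distance threshold")
        if any(b > a for a, b in zip(self.incidences, self.incidences[1:])):
            raise ValueError("incidences must be non-increasing across thresholds")
        if any(not 0 <= p <= 1 for p in self.incidences):
            raise ValueError("incidences must be probabilities")


@dataclass
class SyntheticStudy:
    """A complete simulated dataset plus its ground truth."""

    pedigree: Pedigree
    true_u: np.ndarray                       # aligned with pedigree order
    distances: list[DistanceRecord]
    genotypes: list[MicrosatGenotype]
    liabilities: pd.DataFrame                # animal_id, sex, liability
    truth: dict

    @property
    def phenotyped_ids(self) -> list[str]:
        return [r.animal_id for r in self.distances]

    @property
    def genotyped_ids(self) -> list[str]:
        return [g.animal_id for g in self.genotypes]


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Random non-selfing matings, parents drawn from the previous generation.

    Founders get random 50/50 sexes; an error is raised if either sex is
    absent among candidates for any generation.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    records: list[PedigreeRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:05d}"

    sexes = rng.permutation(
        ["male"] * (config.n_founders // 2)
        + ["female"] * (config.n_founders - config.n_founders // 2)
    )
    gen = [
        PedigreeRecord(new_id(), None, None, s, birth_year=2000) for s in sexes
    ]
    records.extend(gen)
    for g in range(1, config.n_generations + 1):
        males = [r.animal_id for r in gen if r.sex == "male"]
        females = [r.animal_id for r in gen if r.sex == "female"]
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
        offspring: list[PedigreeRecord] = []
        for _ in range(config.n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for _ in range(config.offspring_per_mating):
                offspring.append(
                    PedigreeRecord(
                        new_id(),
                        sire,
                        dam,
                        "male" if rng.random() < 0.5 else "female",
                        birth_year=2000 + g,
                    )
                )
        records.extend(offspring)
        gen = offspring
    return validate_and_sort(records)


def gene_drop_breeding_values(
    pedigree: Pedigree,
    sigma2_u: float,
    rng: np.random.Generator,
    F: Optional[np.ndarray] = None,
    n_replicates: Optional[int] = None,
) -> np.ndarray:
    """Simulate breeding values down the pedigree: cov(u) = sigma2_u * A.

    Founders draw N(0, sigma2_u); an offspring is the parent average plus a
    Mendelian-sampling deviation with variance
    ``sigma2_u * (0.5 - 0.25 (F_sire + F_dam))`` (an unknown parent
    contributes 0 with its share of within-family variance retained).
    With ``n_replicates`` the return shape is (q, n_replicates), vectorized
    across replicates — the Monte-Carlo oracle for the A matrix.
    """
    q = len(pedigree)
    if F is None:
        F = inbreeding_coefficients(pedigree)
    shape = (q,) if n_replicates is None else (q, n_replicates)
    u = np.zeros(shape)
    if sigma2_u == 0:
        return u
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    sd_founder = np.sqrt(sigma2_u)
    for i in range(q):
        s, d = s_idx[i], d_idx[i]
        if s < 0 and d < 0:
            u[i] = rng.normal(0.0, sd_founder, size=shape[1:])
            continue
        mean = np.zeros(shape[1:])
        var = sigma2_u
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            var = sigma2_u * (0.5 - 0.25 * (F[s] + F[d]))
        elif s >= 0:
            mean = 0.5 * u[s]
            var = sigma2_u * (0.75 - 0.25 * F[s])
        else:
            mean = 0.5 * u[d]
            var = sigma2_u * (0.75 - 0.25 * F[d])
        u[i] = mean + rng.normal(0.0, np.sqrt(var), size=shape[1:])
    return u


def simulate_genotypes(
    pedigree: Pedigree,
    allele_freqs: dict[str, float],
    rng: np.random.Generator,
) -> list[MicrosatGenotype]:
    """Founders drawn at Hardy–Weinberg proportions, descendants by Mendelian
    transmission of one random allele from each known parent (an unknown
    parent transmits a fresh population allele)."""
    labels = list(allele_freqs)
    probs = np.array([allele_freqs[a] for a in labels])
    q = len(pedigree)
    a1 = np.empty(q, dtype=object)
    a2 = np.empty(q, dtype=object)
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    for i in range(q):
        s, d = s_idx[i], d_idx[i]
        if s >= 0:
            a1[i] = a1[s] if rng.random() < 0.5 else a2[s]
        else:
            a1[i] = labels[rng.choice(len(labels), p=probs)]
        if d >= 0:
            a2[i] = a1[d] if rng.random() < 0.5 else a2[d]
        else:
            a2[i] = labels[rng.choice(len(labels), p=probs)]
    return [
        MicrosatGenotype(aid, a1[i], a2[i]) for i, aid in enumerate(pedigree.ids)
    ]


def _liability_cutpoints(config: SimulationConfig) -> np.ndarray:
    """Cut-points c_k with P(liability > c_k) = incidence_k marginally.

    The marginal liability is a normal mixture over sex (+/- sex_effect/2)
    and target-allele copy number (Hardy–Weinberg weights, shift beta per
    copy), each component with variance sigma2_u + 1.
    """
    p = config.allele_freqs[config.target_allele]
    copy_w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    means = []
    weights = []
    for sex_shift, sw in ((+config.sex_effect / 2, 0.5), (-config.sex_effect / 2, 0.5)):
        for copies, cw in enumerate(copy_w):
            means.append(sex_shift + config.beta * copies)
            weights.append(sw * cw)
    means = np.array(means)
    weights = np.array(weights)
    sd = np.sqrt(config.sigma2_u + 1.0)

    def tail(c: float) -> float:
        return float((weights * stats.norm.sf(c, loc=means, scale=sd)).sum())

    lo = means.min() - 12 * sd
    hi = means.max() + 12 * sd

    def solve(t: float) -> float:
        if t >= 1.0:
            return -np.inf  # every liability exceeds the cut
        if t <= 0.0:
            return np.inf
        return optimize.brentq(lambda c: tail(c) - t, lo, hi)

    return np.array([solve(t) for t in config.incidences])


def simulate_phenotypes(
    pedigree: Pedigree,
    true_u: np.ndarray,
    sexes: np.ndarray,
    copies: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    phenotyped_idx: np.ndarray,
) -> tuple[list[DistanceRecord], pd.DataFrame]:
    """Liability per phenotyped bird, mapped monotonically to a distance.

    The liability is sex shift + allelic shift + u + e with e ~ N(0, 1).
    Distance bands are the intervals between consecutive thresholds (with
    [0, t1) below and [t5, t5 + band) above); the band is selected by how
    many liability cut-points the bird's liability exceeds, and the
    distance drawn uniformly inside it, so re-encoding the distances
    reproduces the liability cut-point pattern exactly.
    """
    cut = _liability_cutpoints(config)
    thr = np.array(config.thresholds)
    edges = np.concatenate([[0.0], thr, [thr[-1] + (thr[-1] - thr[-2])]])
    shift = np.where(sexes == "male", config.sex_effect / 2, -config.sex_effect / 2)
    ell = (
        shift[phenotyped_idx]
        + config.beta * copies[phenotyped_idx]
        + true_u[phenotyped_idx]
        + rng.standard_normal(len(phenotyped_idx))
    )
    band = (ell[:, None] > cut[None, :]).sum(axis=1)  # 0..5
    lo = edges[band]
    hi = edges[band + 1]
    td = rng.uniform(lo, hi)
    ids = [pedigree.records[i].animal_id for i in phenotyped_idx]
    distances = [DistanceRecord(a, float(t)) for a, t in zip(ids, td)]
    liab = pd.DataFrame(
        {
            "animal_id": ids,
            "sex": [pedigree.records[i].sex for i in phenotyped_idx],
            "liability": ell,
            "band": band,
        }
    )
    return distances, liab


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic study: pedigree, u, genotypes, distances."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    F = inbreeding_coefficients(ped)
    u = gene_drop_breeding_values(ped, config.sigma2_u, rng, F=F)
    genotypes = simulate_genotypes(ped, config.allele_freqs, rng)
    copies = np.array(
        [g.alleles().count(config.target_allele) for g in genotypes]
    )
    sexes = np.array(ped.sexes())
    q = len(ped)
    n_phen = q if config.n_phenotyped is None else min(config.n_phenotyped, q)
    phenotyped_idx = np.arange(q - n_phen, q)  # youngest animals
    distances, liab = simulate_phenotypes(
        ped, u, sexes, copies, config, rng, phenotyped_idx
    )
    if config.n_genotyped is None or config.n_genotyped >= n_phen:
        geno_idx = phenotyped_idx
    else:
        geno_idx = np.sort(rng.choice(phenotyped_idx, config.n_genotyped, replace=False))
    geno_set = set(int(i) for i in geno_idx)
    genotyped = [g for i, g in enumerate(genotypes) if i in geno_set]
    truth = {
        "sigma2_u": config.sigma2_u,
        "h2": config.h2,
        "beta": config.beta,
        "sex_effect": config.sex_effect,
        "seed": config.seed,
        "n_animals": q,
        "n_phenotyped": int(n_phen),
        "n_genotyped": len(genotyped),
        "incidences": list(config.incidences),
        "thresholds": list(config.thresholds),
        "allele_freqs": dict(config.allele_freqs),
        "target_allele": config.target_allele,
    }
    return SyntheticStudy(
        pedigree=ped,
        true_u=u,
        distances=distances,
        genotypes=genotyped,
        liabilities=liab,
        truth=truth,
    )
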