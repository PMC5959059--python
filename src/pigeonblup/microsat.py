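"""Microsatellite genotype summaries, Hardy–Weinberg tests, carrier groups.

The locus of interest is the LDHA intron-6 pentanucleotide repeat of the
racing pigeon, with three fragment-length alleles — S (595 bp), M (600 bp)
and L (605 bp) — and six genotypes.  Birds are grouped by carrier status of
the minor S allele: S+ (at least one S copy: S/S, S/M, S/L) versus S-
(M/M, M/L, L/L).  The same machinery works for any multi-allelic locus,
including the degenerate monomorphic case.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# LDHA fragment sizes (bp) -> allele labels, in the conventional S < M < L order.
LDHA_SIZE_MAP: dict[int, str] = {595: "S", 600: "M", 605: "L"}
LDHA_ALLELE_ORDER: tuple[str, ...] = ("S", "M", "L")

# Genotype counts of the 127-bird Japanese racing-pigeon study cohort in which
# the locus was characterized; used as reference input for reproductions and as
# default simulation frequencies.
LDHA_STUDY_GENOTYPE_COUNTS: dict[tuple[str, str], int] = {
    ("S", "S"): 4,
    ("S", "M"): 26,
    ("S", "L"): 3,
    ("M", "M"): 45,
    ("M", "L"): 40,
    ("L", "L"): 9,
}


@dataclass(frozen=True)
class MicrosatGenotype:
    """Unordered pair of allele labels for one animal; None = missing."""

    animal_id: str
    allele_1: Optional[str] = None
    allele_2: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.allele_1 is None) != (self.allele_2 is None):
            raise ValueError(
                f"animal {self.animal_id!r}: both alleles must be present or both missing"
            )

    @property
    def is_missing(self) -> bool:
        return self.allele_1 is None

    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValueError(f"animal {self.animal_id!r} has a missing genotype")
        return (self.allele_1, self.allele_2)  # type: ignore[return-value]


class AmbiguousSizeError(ValueError):
    """A fragment size is equidistant from two allele bins."""


def size_to_allele(
    fragment_bp: int,
    locus_map: Mapping[int, str] = LDHA_SIZE_MAP,
    tolerance: int = 2,
    on_ambiguous: str = "error",
) -> Optional[str]:
    """Map an electrophoresis fragment size to an allele label.

    Exact match wins; otherwise the nearest bin within ``tolerance`` bp is
    used.  Sizes outside tolerance of every bin return None (unassigned).
    A size equidistant from two bins raises, or returns None when
    ``on_ambiguous="unassign"``.
    """
    if fragment_bp in locus_map:
        return locus_map[fragment_bp]
    dists = {size: abs(fragment_bp - size) for size in locus_map}
    best = min(dists.values())
    if best > tolerance:
        return None
    nearest = [size for size, d in dists.items() if d == best]
    if len(nearest) > 1:
        if on_ambiguous == "unassign":
            return None
        raise AmbiguousSizeError(
            f"fragment {fragment_bp} bp equidistant from bins {sorted(nearest)}"
        )
    return locus_map[nearest[0]]


def classify_carrier(genotype: MicrosatGenotype, target_allele: str) -> bool:
    """True iff the genotype carries at least one copy of the target allele."""
    return target_allele in genotype.alleles()


def _canonical_pair(a: str, b: str, order: Sequence[str]) -> tuple[str, str]:
    rank = {al: i for i, al in enumerate(order)}
    key = lambda x: (rank.get(x, len(rank)), x)
    return tuple(sorted((a, b), key=key))  # type: ignore[return-value]


@dataclass
class HweResult:
    method: str
    statistic: Optional[float]
    df: Optional[int]
    p_value: float
    n_permutations: Optional[int] = None
    min_expected: Optional[float] = None

    @property
    def low_expected_warning(self) -> bool:
        return self.min_expected is not None and self.min_expected < 5


@dataclass
class GenotypeSummary:
    """Allele/genotype counts and frequencies plus carrier-group counts."""

    n: int
    allele_counts: pd.Series
    genotype_counts: pd.Series
    target_allele: Optional[str] = None
    carrier_counts: Optional[pd.Series] = None
    allele_order: tuple[str, ...] = field(default=LDHA_ALLELE_ORDER)

    @property
    def allele_freqs(self) -> pd.Series:
        return self.allele_counts / self.allele_counts.sum()

    @property
    def genotype_freqs(self) -> pd.Series:
        return self.genotype_counts / self.n

    @property
    def is_monomorphic(self) -> bool:
        return (self.allele_counts > 0).sum() == 1

    def hwe(self, method: str = "chi2", seed: int = 0, n_permutations: int = 100_000) -> HweResult:
        counts = {
            tuple(g.split("/")): int(c) for g, c in self.genotype_counts.items()
        }
        return hwe_test(counts, method=method, seed=seed, n_permutations=n_permutations)

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Human-readable layout: alleles, genotypes, carrier groups."""
        rows = []
        for a, c in self.allele_counts.items():
            rows.append(("allele", a, int(c), round(float(self.allele_freqs[a]), decimals)))
        for g, c in self.genotype_counts.items():
            rows.append(("genotype", g, int(c), round(float(c / self.n), decimals)))
        if self.carrier_counts is not None:
            t = self.target_allele
            for grp, c in self.carrier_counts.items():
                rows.append((f"carrier({t})", grp, int(c), round(float(c / self.n), decimals)))
        return pd.DataFrame(rows, columns=["kind", "label", "count", "frequency"])


def summarize(
    genotypes: Iterable[MicrosatGenotype],
    target_allele: Optional[str] = None,
    allele_order: Sequence[str] = LDHA_ALLELE_ORDER,
) -> GenotypeSummary:
    """Count alleles, genotypes, and (optionally) carrier groups.

    Missing genotypes are excluded from every denominator.  Genotype labels
    are canonical unordered pairs ("S/M", never "M/S").  Frequencies keep
    full precision; rounding happens only in :meth:`GenotypeSummary.to_frame`.
    """
    observed = [g for g in genotypes if not g.is_missing]
    if not observed:
        raise ValueError("no non-missing genotypes")
    seen = sorted(
        {a for g in observed for a in g.alleles()},
        key=lambda x: (
            {al: i for i, al in enumerate(allele_order)}.get(x, len(allele_order)),
            x,
        ),
    )
    acounts = {a: 0 for a in seen}
    gcounts: dict[str, int] = {}
    # All unordered pairs, so zero-count genotypes still appear in output.
    for a, b in itertools.combinations_with_replacement(seen, 2):
        gcounts[f"{a}/{b}"] = 0
    for g in observed:
        a, b = g.alleles()
        acounts[a] += 1
        acounts[b] += 1
        pa, pb = _canonical_pair(a, b, seen)
        gcounts[f"{pa}/{pb}"] += 1
    summary = GenotypeSummary(
        n=len(observed),
        allele_counts=pd.Series(acounts, name="count"),
        genotype_counts=pd.Series(gcounts, name="count"),
        target_allele=target_allele,
        allele_order=tuple(seen),
    )
    if target_allele is not None:
        plus = sum(1 for g in observed if classify_carrier(g, target_allele))
        summary.carrier_counts = pd.Series(
            {f"{target_allele}+": plus, f"{target_allele}-": len(observed) - plus},
            name="count",
        )
    return summary


def _expected_counts(
    genotype_counts: Mapping[tuple[str, str], int]
) -> tuple[dict[tuple[str, str], float], dict[str, float], int]:
    n = sum(genotype_counts.values())
    ac: dict[str, int] = {}
    for (a, b), c in genotype_counts.items():
        ac[a] = ac.get(a, 0) + c
        ac[b] = ac.get(b, 0) + c
    p = {a: c / (2 * n) for a, c in ac.items()}
    alleles = sorted(p)
    exp: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations_with_replacement(alleles, 2):
        exp[(a, b)] = n * p[a] * p[b] * (1 if a == b else 2)
    return exp, p, n


def _table_log_prob(genotype_counts: Mapping[tuple[str, str], int]) -> float:
    """Log-probability of a genotype table conditional on its allele counts."""
    n = sum(genotype_counts.values())
    ac: dict[str, int] = {}
    n_het = 0
    lp = math.lgamma(n + 1) - math.lgamma(2 * n + 1)
    for (a, b), c in genotype_counts.items():
        ac[a] = ac.get(a, 0) + c
        ac[b] = ac.get(b, 0) + c
        if a != b:
            n_het += c
        lp -= math.lgamma(c + 1)
    lp += n_het * math.log(2.0)
    for c in ac.values():
        lp += math.lgamma(c + 1)
    return lp


def hwe_test(
    genotype_counts: Mapping[tuple[str, str], int],
    method: str = "chi2",
    seed: int = 0,
    n_permutations: int = 100_000,
) -> HweResult:
    """Test genotype counts for deviation from Hardy–Weinberg proportions.

    ``chi2``: asymptotic goodness-of-fit with expected counts from the
    observed allele frequencies and df = k(k-1)/2 for k alleles.  Flags
    (via ``min_expected``) when any expected count is below 5.

    ``exact_mc``: seeded Monte-Carlo permutation of the observed alleles
    into genotypes; the p-value is the fraction of permuted tables whose
    conditional probability is no larger than the observed table's.

    Raises
    ------
    ValueError
        For a monomorphic locus (HWE undefined) or empty counts.
    """
    counts = {tuple(sorted(k)): int(v) for k, v in genotype_counts.items()}
    if not counts or sum(counts.values()) == 0:
        raise ValueError("empty genotype counts")
    exp, p, n = _expected_counts(counts)
    k = len(p)
    if k < 2:
        raise ValueError("HWE undefined for a monomorphic locus")

    if method == "chi2":
        chi2 = 0.0
        for pair, e in exp.items():
            o = counts.get(pair, 0)
            chi2 += (o - e) ** 2 / e
        df = k * (k - 1) // 2
        return HweResult(
            method="chi2",
            statistic=chi2,
            df=df,
            p_value=float(stats.chi2.sf(chi2, df)),
            min_expected=min(exp.values()),
        )
    if method == "exact_mc":
        rng = np.random.default_rng(seed)
        labels = sorted(p)
        code = {a: i for i, a in enumerate(labels)}
        pool = np.empty(2 * n, dtype=np.int64)
        pos = 0
        for (a, b), c in counts.items():
            pool[pos : pos + c] = code[a]
            pool[pos + c : pos + 2 * c] = code[b]
            pos += 2 * c
        # Conditional on allele counts, a table's log-probability is a constant
        # plus n_het*log(2) minus sum(lgamma(c_g + 1)); compare on that scale.
        from scipy.special import gammaln

        def rel_lp(cell_counts: np.ndarray, het_mask: np.ndarray) -> np.ndarray:
            return (cell_counts * het_mask).sum(axis=1) * math.log(2.0) - gammaln(
                cell_counts + 1.0
            ).sum(axis=1)

        obs_cells = np.zeros((1, k * k), dtype=np.int64)
        for (a, b), c in counts.items():
            obs_cells[0, code[a] * k + code[b]] = c
        het = (np.arange(k * k) // k != np.arange(k * k) % k).astype(np.int64)
        lp_obs_rel = rel_lp(obs_cells, het)[0]
        n_le = 0
        batch = 20_000
        done = 0
        while done < n_permutations:
            r = min(batch, n_permutations - done)
            perms = rng.permuted(np.tile(pool, (r, 1)), axis=1).reshape(r, n, 2)
            lo = perms.min(axis=2)
            hi = perms.max(axis=2)
            idx = lo * k + hi
            flat = (np.arange(r)[:, None] * (k * k) + idx).ravel()
            cells = np.bincount(flat, minlength=r * k * k).reshape(r, k * k)
            n_le += int((rel_lp(cells, het) <= lp_obs_rel + 1e-9).sum())
            done += r
        return HweResult(
            method="exact_mc",
            statistic=None,
            df=None,
            p_value=n_le / n_permutations,
            n_permutations=n_permutations,
        )
    raise ValueError(f"unknown HWE method {method!r}")
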