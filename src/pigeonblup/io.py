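"""Readers and writers for the pipeline's CSV/TSV dialects.

Pedigree CSV: ``animal_id,sire_id,dam_id,sex,birth_year`` with empty string
or ``0`` for an unknown parent.  Phenotype CSV: ``animal_id,
total_distance_km``.  Genotype CSV: ``animal_id,allele_1,allele_2`` holding
either allele labels or fragment sizes in bp (auto-detected).  All machine
outputs are TSV with headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import microsat
from .gibbs import GibbsConfig, PosteriorSamples
from .pedigree import Pedigree, PedigreeRecord, validate_and_sort
from .phenotypes import DistanceRecord
from .microsat import MicrosatGenotype, size_to_allele

PathLike = Union[str, Path]

_MISSING_PARENT = ("", "0", "NA", "na", "nan", "None")


def read_pedigree_csv(path: PathLike) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal_id", "sire_id", "dam_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        sire = None if row.sire_id in _MISSING_PARENT else row.sire_id
        dam = None if row.dam_id in _MISSING_PARENT else row.dam_id
        sex = getattr(row, "sex", "unknown") or "unknown"
        by_raw = getattr(row, "birth_year", "")
        birth_year = int(by_raw) if by_raw not in ("", "NA") else None
        records.append(PedigreeRecord(row.animal_id, sire, dam, sex, birth_year))
    return validate_and_sort(records)


def write_pedigree_csv(pedigree: Pedigree, path: PathLike) -> None:
    df = pedigree.to_frame()
    df["birth_year"] = df["birth_year"].map(lambda v: "" if v is None else str(v))
    df.to_csv(path, index=False)


def read_phenotype_csv(path: PathLike) -> list[DistanceRecord]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if not {"animal_id", "total_distance_km"}.issubset(df.columns):
        raise ValueError("phenotype CSV needs columns animal_id,total_distance_km")
    return [
        DistanceRecord(str(a), float(t))
        for a, t in zip(df["animal_id"], df["total_distance_km"])
    ]


def write_phenotype_csv(records: list[DistanceRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "total_distance_km": [r.total_distance_km for r in records],
        }
    ).to_csv(path, index=False)


def read_genotype_csv(
    path: PathLike,
    locus_map: Optional[dict[int, str]] = None,
    size_tolerance: int = 2,
) -> list[MicrosatGenotype]:
    """Read genotypes; numeric allele columns are treated as fragment sizes
    and mapped through ``locus_map`` (default: the LDHA S/M/L bins)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"animal_id", "allele_1", "allele_2"}.issubset(df.columns):
        raise ValueError("genotype CSV needs columns animal_id,allele_1,allele_2")
    if locus_map is None:
        locus_map = microsat.LDHA_SIZE_MAP
    values = [v for v in pd.concat([df["allele_1"], df["allele_2"]]) if v != ""]
    numeric = bool(values) and all(v.strip().lstrip("+-").isdigit() for v in values)
    out = []
    for row in df.itertuples(index=False):
        a1, a2 = row.allele_1.strip(), row.allele_2.strip()
        if a1 == "" or a2 == "":
            out.append(MicrosatGenotype(row.animal_id, None, None))
            continue
        if numeric:
            a1 = size_to_allele(int(a1), locus_map, size_tolerance)
            a2 = size_to_allele(int(a2), locus_map, size_tolerance)
            if a1 is None or a2 is None:
                out.append(MicrosatGenotype(row.animal_id, None, None))
                continue
        out.append(MicrosatGenotype(row.animal_id, a1, a2))
    return out


def write_genotype_csv(genotypes: list[MicrosatGenotype], path: PathLike) -> None:
    pd.DataFrame(
        {
            "animal_id": [g.animal_id for g in genotypes],
            "allele_1": [g.allele_1 or "" for g in genotypes],
            "allele_2": [g.allele_2 or "" for g in genotypes],
        }
    ).to_csv(path, index=False)


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gibbs_config(path: PathLike) -> GibbsConfig:
    """Load a Gibbs schedule/prior from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mapping = {
        "n_iterations": int,
        "burn_in": int,
        "thinning": int,
        "seed": int,
        "sigma2_e": float,
        "threshold": float,
        "prior_u_df": float,
        "prior_u_scale": float,
        "sigma2_u_floor": float,
        "sigma2_u_init": float,
    }
    kwargs = {}
    for key, cast in mapping.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    if raw.get("fix_sigma2_u") is not None:
        kwargs["fix_sigma2_u"] = float(raw["fix_sigma2_u"])
    return GibbsConfig(**kwargs)


def write_posterior_tsv(samples: PosteriorSamples, path: PathLike) -> None:
    """Retained scalar draws: iteration index, sigma2_u, h2, sex effects."""
    cfg = samples.config
    iters = cfg.burn_in + np.arange(samples.n_draws) * cfg.thinning
    df = pd.DataFrame(
        {"iteration": iters, "sigma2_u": samples.sigma2_u, "h2": samples.h2}
    )
    for i, lev in enumerate(samples.sex_levels):
        df[f"sex_{lev}"] = samples.sex_effects[:, i]
    write_tsv(df, path)
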