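"""Estimated breeding values and their mean-50 / SD-10 deviation scores.

The EBV of an animal is the posterior mean of its breeding value u_j over
the retained Gibbs draws.  For reporting and association testing, EBVs are
rescaled to deviation scores (DEBV) with mean 50 and standard deviation 10
over a chosen reference set; animals outside the reference set are mapped
through the same affine transform, so a subset's DEBV mean need not be 50.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples

REFERENCE_CHOICES = ("all_pedigree", "phenotyped", "genotyped")


def posterior_mean_ebv(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-animal EBV (posterior mean of u) and posterior SD.

    Requires at least two retained draws so the SD is defined.
    """
    if samples.n_draws < 2:
        raise ValueError("need at least 2 retained draws to summarize EBVs")
    return pd.DataFrame(
        {
            "animal_id": samples.animal_ids,
            "ebv": samples.u.mean(axis=0),
            "ebv_sd": samples.u.std(axis=0, ddof=1),
        }
    )


def standardize_debv(
    ebvs: np.ndarray,
    reference: Optional[np.ndarray] = None,
    ddof: int = 1,
    target_mean: float = 50.0,
    target_sd: float = 10.0,
) -> np.ndarray:
    """Affine-rescale EBVs so the reference set has mean 50 and SD 10.

    ``reference`` is a boolean mask selecting the animals the centring and
    scaling are computed on (default: all).  The sample (n-1) SD is used
    unless ``ddof=0``.

    Raises
    ------
    ValueError
        If the reference set has fewer than two animals or zero variance.
    """
    ebvs = np.asarray(ebvs, dtype=float)
    mask = np.ones(len(ebvs), dtype=bool) if reference is None else np.asarray(reference, bool)
    ref = ebvs[mask]
    if len(ref) < 2:
        raise ValueError("reference set must contain at least 2 animals")
    sd = ref.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance in reference-set EBVs")
    return target_mean + target_sd * (ebvs - ref.mean()) / sd


def ebv_table(
    samples_by_trait: dict[str, PosteriorSamples],
    reference: str = "all_pedigree",
    phenotyped_ids: Optional[Iterable[str]] = None,
    genotyped_ids: Optional[Iterable[str]] = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Long-format table of EBV, posterior SD, and DEBV per animal x trait.

    ``reference`` selects the standardization set: every pedigree animal,
    the phenotyped subset, or the genotyped subset.
    """
    if reference not in REFERENCE_CHOICES:
        raise ValueError(f"reference must be one of {REFERENCE_CHOICES}")
    frames = []
    for trait, samples in samples_by_trait.items():
        df = posterior_mean_ebv(samples)
        if reference == "all_pedigree":
            mask = None
        else:
            ids = phenotyped_ids if reference == "phenotyped" else genotyped_ids
            if ids is None:
                raise ValueError(f"reference {reference!r} requires the matching id set")
            idset = set(ids)
            mask = df["animal_id"].isin(idset).to_numpy()
        df["debv"] = standardize_debv(df["ebv"].to_numpy(), mask, ddof=ddof)
        df.insert(1, "trait", trait)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
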