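"""Binary race-trait coding from accumulated lifetime race distance.

A pigeon's survivability proxy is its accumulated total race distance (TD,
km) over its athletic life.  TD is dichotomized at five ascending
thresholds — by default 500, 1000, 2000, 3000 and 4000 km — giving five
binary traits Race1..Race5 coded 1 (below) / 2 (at or above), each analysed
as an independent binary trait downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS_KM: tuple[float, ...] = (500.0, 1000.0, 2000.0, 3000.0, 4000.0)


@dataclass(frozen=True)
class DistanceRecord:
    """Accumulated total race distance (km) for one animal."""

    animal_id: str
    total_distance_km: float

    def __post_init__(self) -> None:
        td = self.total_distance_km
        if not np.isfinite(td) or td < 0:
            raise ValueError(
                f"total distance must be finite and non-negative, got {td!r} "
                f"for animal {self.animal_id!r}"
            )


@dataclass
class RaceTraitMatrix:
    """Per-animal binary categories (1/2) for each distance threshold."""

    ids: list[str]
    Y: np.ndarray  # shape (n_animals, n_thresholds), values in {1, 2}
    thresholds: tuple[float, ...]

    @property
    def trait_names(self) -> list[str]:
        return [f"race{k + 1}" for k in range(len(self.thresholds))]

    def trait(self, name: str) -> np.ndarray:
        return self.Y[:, self.trait_names.index(name)]

    def incidence(self) -> pd.Series:
        """Fraction of animals in category 2 per trait."""
        return pd.Series(
            (self.Y == 2).mean(axis=0), index=self.trait_names, name="incidence"
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, columns=self.trait_names)
        df.insert(0, "animal_id", self.ids)
        return df


def encode_race_traits(
    records: Iterable[DistanceRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_KM,
    comparison: str = "ge",
) -> RaceTraitMatrix:
    """Code each animal's TD against every threshold.

    Category 2 means the animal reached the threshold.  ``comparison`` sets
    the boundary convention: ``"ge"`` (default) counts TD exactly equal to a
    threshold as reached, ``"gt"`` does not.

    Raises
    ------
    ValueError
        If thresholds are not strictly ascending and positive, or the
        comparison flag is unknown.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly ascending, got {thresholds}")
    if comparison not in ("ge", "gt"):
        raise ValueError(f"comparison must be 'ge' or 'gt', got {comparison!r}")
    records = list(records)
    if not records:
        raise ValueError("no distance records")
    td = np.array([r.total_distance_km for r in records])
    thr = np.array(thresholds)
    reached = td[:, None] >= thr[None, :] if comparison == "ge" else td[:, None] > thr[None, :]
    Y = np.where(reached, 2, 1).astype(np.int8)
    return RaceTraitMatrix([r.animal_id for r in records], Y, thresholds)
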