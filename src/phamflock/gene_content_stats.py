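"""Gene Content Similarity (GCS), Dissimilarity (GCD), and MaxGCDGap.

GCS between two phages averages the two directional fractions of shared
phams:

    GCS(A, B) = 100 * (|A ∩ B| / |A| + |A ∩ B| / |B|) / 2

where A and B are the sets of distinct phams present in each genome
(duplicated phams within one genome count once).  GCD = 1 - GCS/100 on the
0-1 scale.  MaxGCDGap is the largest jump in a focal phage's ascending
sorted GCD values, including the leading gap from zero (the focal phage's
distance to itself): it measures how isolated the phage is from the rest of
the population, and for a phage whose nearest neighbour is far away the gap
is simply that nearest-neighbour GCD expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GcsMatrix",
    "GcdProfile",
    "gcs",
    "gcd_profile",
    "max_gcd_gap",
    "gcs_matrix",
]


def gcs(profile_a: set[str], profile_b: set[str]) -> float:
    """Gene Content Similarity (percent) between two pham profiles."""
    if not profile_a or not profile_b:
        raise ValueError("GCS is undefined for a phage with no phams")
    s = len(profile_a & profile_b)
    return 100.0 * (s / len(profile_a) + s / len(profile_b)) / 2.0


@dataclass
class GcsMatrix:
    """Symmetric matrix of pairwise GCS percents with diagonal 100."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} names")
        if not np.allclose(v, v.T):
            raise ValueError("GCS matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("GCS matrix diagonal must be 100")
        if v.min() < -1e-9 or v.max() > 100 + 1e-9:
            raise ValueError("GCS values must lie in [0, 100]")
        self.values = v

    def value(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().round(2).to_csv(path)


@dataclass
class GcdProfile:
    """One focal phage's sorted pairwise GCD values against a population."""

    focal: str
    pairs: list[tuple[str, float]]  # (other phage, GCD in [0,1]), ascending
    max_gcd_gap: float  # percent
    gap_partner: str

    def to_dataframe(self) -> pd.DataFrame:
        gcds = [g for _, g in self.pairs]
        prev = [0.0] + gcds[:-1]
        return pd.DataFrame(
            {
                "phage": [p for p, _ in self.pairs],
                "gcd": gcds,
                "gap_from_previous": [g - p for g, p in zip(gcds, prev)],
            }
        )


def gcd_profile(
    focal: str,
    population: Mapping[str, set[str]],
    *,
    gap_from_zero: bool = True,
) -> GcdProfile:
    """GCD of ``focal`` against every other phage, sorted ascending.

    ``gap_from_zero`` controls whether MaxGCDGap includes the leading gap
    from 0 to the nearest neighbour (default) or only gaps between
    successive observed GCD values.
    """
    if focal not in population:
        raise KeyError(f"focal phage {focal!r} not in population")
    if len(population) < 2:
        raise ValueError("population must contain at least 2 phages")
    focal_profile = population[focal]
    pairs = sorted(
        ((other, 1.0 - gcs(focal_profile, profile) / 100.0)
         for other, profile in population.items() if other != focal),
        key=lambda t: (t[1], t[0]),
    )
    gap, partner = _max_gap(pairs, gap_from_zero=gap_from_zero)
    return GcdProfile(focal=focal, pairs=pairs, max_gcd_gap=gap, gap_partner=partner)


def max_gcd_gap(
    pairs: Sequence[tuple[str, float]] | GcdProfile,
    *,
    gap_from_zero: bool = True,
) -> tuple[float, str]:
    """MaxGCDGap (percent) and the phage whose GCD value closes the gap.

    The sorted GCD list is prepended with 0 (the focal phage's distance to
    itself) unless ``gap_from_zero`` is off; the gap is the maximum
    difference between consecutive values, ties broken toward the earlier
    (smaller-GCD) gap.
    """
    if isinstance(pairs, GcdProfile):
        pairs = pairs.pairs
    if not pairs:
        raise ValueError("empty GCD profile")
    ordered = sorted(pairs, key=lambda t: (t[1], t[0]))
    return _max_gap(ordered, gap_from_zero=gap_from_zero)


def _max_gap(ordered: Sequence[tuple[str, float]], *, gap_from_zero: bool) -> tuple[float, str]:
    values = [g for _, g in ordered]
    partners = [p for p, _ in ordered]
    if gap_from_zero:
        values = [0.0] + values
    else:
        partners = partners[1:]
        if not partners:  # single pair without the leading gap: no interval
            return 0.0, ordered[0][0]
    best_gap, best_partner = -1.0, ""
    for prev, cur, partner in zip(values[:-1], values[1:], partners):
        gap = cur - prev
        if gap > best_gap + 1e-12:  # strict: ties keep the earlier gap
            best_gap, best_partner = gap, partner
    return 100.0 * best_gap, best_partner


def gcs_matrix(population: Mapping[str, set[str]]) -> GcsMatrix:
    """All pairwise GCS values over a population of pham profiles."""
    names = list(population)
    if len(names) < 2:
        raise ValueError("need at least 2 phages for a GCS matrix")
    n = len(names)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = gcs(population[names[i]], population[names[j]])
            values[i, j] = values[j, i] = v
    return GcsMatrix(names=names, values=values)
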