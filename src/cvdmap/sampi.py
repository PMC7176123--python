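"""South African Multidimensional Poverty Index (SAMPI).

The index follows the Alkire–Foster counting approach: a household is
multidimensionally poor when its weighted share of deprivation indicators
reaches the poverty cutoff k; the district score is the product of the
poor headcount ratio H and the average deprivation intensity A among the
poor.  Indicators are grouped into four dimensions — education, health,
living standards and economic activity — with nested equal weighting by
default (each dimension carries 1/4, split equally across its indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical dimension -> indicator layout (Stats SA census indicators)
DEFAULT_DIMENSIONS: dict[str, list[str]] = {
    "education": ["years_of_schooling", "school_attendance"],
    "health": ["nutrition", "child_mortality"],
    "living_standards": [
        "cooking_fuel",
        "sanitation",
        "water",
        "electricity",
        "floor",
        "assets",
    ],
    "economic_activity": ["unemployment"],
}

DEFAULT_POVERTY_CUTOFF = 1.0 / 3.0


def nested_equal_weights(
    dimensions: dict[str, list[str]] | None = None,
) -> dict[str, float]:
    """Equal weight per dimension, split equally within each dimension."""
    dims = dimensions or DEFAULT_DIMENSIONS
    weights: dict[str, float] = {}
    for indicators in dims.values():
        for ind in indicators:
            weights[ind] = (1.0 / len(dims)) / len(indicators)
    return weights


@dataclass
class DeprivationProfile:
    """Binary deprivation flags for one household, with indicator weights."""

    deprived: dict[str, int]
    weights: dict[str, float] = field(default_factory=nested_equal_weights)

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"indicator weights must sum to 1, got {total:.6f}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("indicator weights must be positive")
        unknown = set(self.deprived) - set(self.weights)
        if unknown:
            raise ValueError(f"deprivation flags for unweighted indicators: {sorted(unknown)}")
        if any(flag not in (0, 1) for flag in self.deprived.values()):
            raise ValueError("deprivation flags must be binary")

    @property
    def deprivation_share(self) -> float:
        """Weighted share of indicators on which the household is deprived."""
        return sum(self.weights[i] for i, flag in self.deprived.items() if flag)

    def is_poor(self, poverty_cutoff: float = DEFAULT_POVERTY_CUTOFF) -> bool:
        return self.deprivation_share >= poverty_cutoff


@dataclass(frozen=True)
class SampiScore:
    headcount: float
    intensity: float  # nan when no household is poor
    sampi: float
    quintile: str | None = None


def _shares(profiles, poverty_cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    if len(profiles) == 0:
        raise ValueError("at least one household profile is required")
    if not 0 < poverty_cutoff <= 1:
        raise ValueError(f"poverty cutoff must be in (0, 1], got {poverty_cutoff}")
    shares = np.array([p.deprivation_share for p in profiles])
    return shares, shares >= poverty_cutoff


def compute_headcount(profiles, poverty_cutoff: float = DEFAULT_POVERTY_CUTOFF) -> float:
    """H: proportion of households that are multidimensionally poor."""
    _, poor = _shares(profiles, poverty_cutoff)
    return float(poor.mean())


def compute_intensity(profiles, poverty_cutoff: float = DEFAULT_POVERTY_CUTOFF) -> float:
    """A: mean weighted deprivation share among poor households (nan if none poor)."""
    shares, poor = _shares(profiles, poverty_cutoff)
    if not poor.any():
        return float("nan")
    return float(shares[poor].mean())


def compute_sampi(headcount: float, intensity: float) -> float:
    """SAMPI = H × A (with H=0 forcing 0 regardless of undefined intensity)."""
    if not 0 <= headcount <= 1:
        raise ValueError(f"headcount must be in [0, 1], got {headcount}")
    if headcount == 0:
        return 0.0
    if not 0 <= intensity <= 1:
        raise ValueError(f"intensity must be in [0, 1], got {intensity}")
    return headcount * intensity


def score_district(
    profiles, poverty_cutoff: float = DEFAULT_POVERTY_CUTOFF
) -> SampiScore:
    """Headcount, intensity and SAMPI for one district's households."""
    h = compute_headcount(profiles, poverty_cutoff)
    a = compute_intensity(profiles, poverty_cutoff)
    s = compute_sampi(h, a if h > 0 else 0.0)
    return SampiScore(headcount=h, intensity=a, sampi=s)


QUINTILE_LABELS = ["SAMPI1", "SAMPI2", "SAMPI3", "SAMPI4", "SAMPI5"]


def sampi_quintiles(scores) -> list[str]:
    """Rank-based quintile labels, SAMPI1 = least deprived (lowest scores).

    Rule: with ascending 1-based rank r over n districts (ties broken by
    stable input order), quintile = ceil(5·r/n).  For n = 52 this yields
    partition sizes (10, 10, 11, 10, 11).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 5:
        raise ValueError(f"quintile assignment needs at least 5 districts, got {n}")
    order = np.argsort(scores, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    q = np.ceil(5 * rank / n).astype(int)
    return [QUINTILE_LABELS[i - 1] for i in q]


def district_sampi_table(
    households: pd.DataFrame,
    district_col: str = "district",
    poverty_cutoff: float = DEFAULT_POVERTY_CUTOFF,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score every district from a household-level indicator table.

    *households* holds one row per household: a district code column plus one
    binary column per indicator named in *weights* (default nested-equal).
    Returns one row per district with headcount, intensity, sampi, quintile.
    """
    w = weights or nested_equal_weights()
    rows = []
    for code, grp in households.groupby(district_col, sort=False):
        profiles = [
            DeprivationProfile(
                deprived={k: int(r[k]) for k in w}, weights=w
            )
            for _, r in grp.iterrows()
        ]
        sc = score_district(profiles, poverty_cutoff)
        rows.append(
            {
                district_col: code,
                "headcount": sc.headcount,
                "intensity": sc.intensity,
                "sampi": sc.sampi,
            }
        )
    out = pd.DataFrame(rows)
    out["quintile"] = sampi_quintiles(out["sampi"].to_numpy())
    return out
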