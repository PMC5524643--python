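"""Time-shift analysis of an all-against-all infection matrix.

Each phage x bacterium pair gets a temporal offset (phage isolation year
minus bacterium isolation year): negative offsets are phages from the
bacterium's past, zero is contemporary, positive is the future. The curve
reports the mean proportion of resistant hosts per offset; under
arms-race coevolution it falls from near-complete resistance to the deep
past toward near-complete susceptibility to the far future.

Resistance is the absence of plaques (outcome 0 in the matrix). The
category effect (past vs future) is tested with a label permutation of
phage years — a deliberately simple surrogate, not a mixed-model fit;
outputs label it as a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAST, CONTEMPORARY, FUTURE = "past", "contemporary", "future"


@dataclass
class InfectionMatrix:
    """Binary plaque outcomes, phages as rows, bacteria as columns (1 = infection)."""

    outcomes: pd.DataFrame
    phage_years: pd.Series
    bacterium_years: pd.Series

    def __post_init__(self) -> None:
        if self.outcomes.isna().any().any():
            raise ValueError("infection matrix has missing cells; the design is all-against-all")
        vals = self.outcomes.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("infection outcomes must be binary (1 = plaques)")
        missing_p = set(self.outcomes.index) - set(self.phage_years.index)
        missing_b = set(self.outcomes.columns) - set(self.bacterium_years.index)
        if missing_p or missing_b:
            raise ValueError(f"isolates without years: {sorted(missing_p | missing_b)}")

    @property
    def n_phages(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_bacteria(self) -> int:
        return self.outcomes.shape[1]


@dataclass
class TimeShiftCurve:
    per_offset: pd.DataFrame   # offset, mean_resistance, se, n_bacteria, n_pairs
    per_category: pd.DataFrame # category, mean_resistance, se, n_pairs
    se_mode: str = "bacteria"

    def category_mean(self, category: str) -> float:
        row = self.per_category[self.per_category["category"] == category]
        return float(row["mean_resistance"].iloc[0])


def categorize(offset: int) -> str:
    if offset < 0:
        return PAST
    if offset == 0:
        return CONTEMPORARY
    return FUTURE


def compute_offsets(matrix: InfectionMatrix) -> pd.DataFrame:
    """Long table of every pair: phage, bacterium, years, offset, category,
    outcome and resistance (1 - outcome)."""
    rows = []
    for phage in matrix.outcomes.index:
        py = int(matrix.phage_years[phage])
        for bact in matrix.outcomes.columns:
            by = int(matrix.bacterium_years[bact])
            outcome = int(matrix.outcomes.loc[phage, bact])
            offset = py - by
            rows.append(
                {
                    "phage": phage,
                    "bacterium": bact,
                    "phage_year": py,
                    "bacterium_year": by,
                    "offset": offset,
                    "category": categorize(offset),
                    "infected": outcome,
                    "resistant": 1 - outcome,
                }
            )
    return pd.DataFrame(rows)


def timeshift_curve(matrix: InfectionMatrix, se_mode: str = "bacteria") -> TimeShiftCurve:
    """Mean (± SE) proportion of resistant hosts per offset and per category.

    Default SE is across bacteria: each bacterium contributes one
    resistance proportion per offset (its proportion over the phages at
    that offset), and the mean/SE are taken over those host proportions.
    ``se_mode="pairs"`` instead treats every pair as a Bernoulli draw and
    uses the binomial SE — offered because figure conventions differ.
    Offsets with zero pairs simply do not appear.
    """
    if se_mode not in {"bacteria", "pairs"}:
        raise ValueError("se_mode must be 'bacteria' or 'pairs'")
    pairs = compute_offsets(matrix)
    per_offset = _aggregate(pairs, "offset", se_mode)
    per_cat = _aggregate(pairs, "category", se_mode)
    rank = {PAST: 0, CONTEMPORARY: 1, FUTURE: 2}
    per_cat = (
        per_cat.sort_values("category", key=lambda s: s.map(rank))
        .reset_index(drop=True)
    )
    return TimeShiftCurve(per_offset, per_cat, se_mode)


def _aggregate(pairs: pd.DataFrame, key: str, se_mode: str) -> pd.DataFrame:
    rows = []
    for value, group in pairs.groupby(key, sort=True):
        by_bact = group.groupby("bacterium")["resistant"].mean()
        if se_mode == "bacteria":
            mean = float(by_bact.mean())
            se = float(by_bact.std(ddof=1) / np.sqrt(len(by_bact))) if len(by_bact) > 1 else 0.0
        else:
            mean = float(group["resistant"].mean())
            se = float(np.sqrt(mean * (1 - mean) / len(group)))
        rows.append(
            {
                key: value,
                "mean_resistance": mean,
                "se": se,
                "n_bacteria": int(group["bacterium"].nunique()),
                "n_pairs": int(len(group)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CategoryEffectResult:
    observed_statistic: float
    p_value: float
    n_perm: int
    n_effective: int
    seed: int | None
    description: str = field(
        default="permutation test (phage-year label shuffle); not a mixed-model fit"
    )

    def to_dict(self) -> dict:
        return {
            "test": "past_minus_future_resistance",
            "method": self.description,
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n_effective": self.n_effective,
            "seed": self.seed,
        }


def category_effect_test(
    matrix: InfectionMatrix, n_perm: int = 10_000, seed: int | None = None
) -> CategoryEffectResult:
    """Permutation test of the past-vs-future resistance asymmetry.

    Statistic: mean pairwise resistance to past phages minus mean pairwise
    resistance to future phages. The null shuffles the phage-year labels
    among phages *n_perm* times; one-tailed p is the proportion of
    permuted statistics >= the observed one. Permutations in which either
    category empties (possible only in tiny designs) are dropped from
    both numerator and denominator.
    """
    rng = np.random.default_rng(seed)
    py = matrix.phage_years.loc[matrix.outcomes.index].to_numpy()
    by = matrix.bacterium_years.loc[matrix.outcomes.columns].to_numpy()
    resist = 1 - matrix.outcomes.to_numpy()

    def stat(phage_years: np.ndarray) -> float:
        offsets = phage_years[:, None] - by[None, :]
        past, future = offsets < 0, offsets > 0
        if not past.any() or not future.any():
            return np.nan
        return float(resist[past].mean() - resist[future].mean())

    observed = stat(py)
    if np.isnan(observed):
        raise ValueError("need pairs in both the past and the future category")
    perms = np.array([stat(rng.permutation(py)) for _ in range(n_perm)])
    valid = ~np.isnan(perms)
    n_eff = int(valid.sum())
    if n_eff == 0:
        raise ValueError("no valid permutation retained both categories")
    p = float((perms[valid] >= observed).sum() / n_eff)
    return CategoryEffectResult(observed, p, n_perm, n_eff, seed)
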