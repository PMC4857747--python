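"""Evidence rules for donor-unique miRNA counts and uptake stoichiometry.

A donor-unique (e.g. bovine-specific) miRNA detected in host plasma is
only credible evidence of dietary uptake if its counts behave like an
ingested substance: non-trivial abundance, presence across the time
course, and a temporal profile that is low at baseline and peaks after
intake.  This module implements those rules as a cascade of explicit
filters, plus the cross-reference of plasma changes against a milk
abundance profile, and the mass-balance ("how much milk would that take")
feasibility arithmetic.

Count tables here are plain DataFrames: one row per miRNA, one column per
time-point label (e.g. T0, T3, T6, T9), raw read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "EvidenceVerdict",
    "UptakeScenario",
    "filter_min_count",
    "ubiquitous",
    "intake_consistency",
    "evaluate_evidence",
    "crossref_milk",
    "required_milk_volume",
    "required_uptake_fraction",
    "pmol_per_l_to_fmol_per_l",
]


# ---------------------------------------------------------------------------
# Count-based evidence cascade
# ---------------------------------------------------------------------------

def filter_min_count(table: pd.DataFrame, min_count: float = 10) -> pd.DataFrame:
    """Rows whose maximum count across time points reaches *min_count*.

    Single-digit counts of a foreign miRNA are within the noise floor of
    mis-mapping and index hopping; the default threshold of 10 raw counts
    in at least one sample is the first credibility gate.
    """
    if table.empty:
        return table.copy()
    return table.loc[table.max(axis=1) >= min_count]


def ubiquitous(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with a nonzero count at every time point."""
    if table.shape[1] < 2:
        raise InputError("ubiquity needs at least 2 time-point columns")
    return table.loc[(table > 0).all(axis=1)]


@dataclass(frozen=True)
class EvidenceVerdict:
    """Outcome of the evidence rules for one candidate miRNA.

    ``consistency`` is ``"consistent"`` when the count profile looks like
    dietary uptake (peak in the post-intake window, baseline below
    ``peak_ratio`` x peak), ``"inconsistent"`` when the peak is at baseline
    or the baseline is too high relative to the peak, and
    ``"insufficient"`` when all counts are zero.
    """

    mirna: str
    passes_count_filter: bool
    present_all_timepoints: bool
    peak_timepoint: str | None
    consistency: str


def intake_consistency(
    series: pd.Series,
    baseline: str,
    post_window,
    peak_ratio: float = 0.5,
    name: str | None = None,
    passes_count_filter: bool = True,
) -> EvidenceVerdict:
    """Judge whether a count time course is consistent with dietary intake.

    *series* maps time-point labels to raw counts.  Consistency requires
    the maximum to fall inside *post_window* AND the baseline count to be
    below ``peak_ratio`` x peak.  A miRNA most abundant *before* intake
    cannot plausibly derive from the meal.
    """
    if not 0 < peak_ratio <= 1:
        raise ConfigError("peak_ratio must be in (0, 1]")
    labels = list(series.index)
    if baseline not in labels:
        raise InputError(f"baseline label {baseline!r} not in series {labels}")
    post = list(post_window)
    if not post or any(t not in labels for t in post):
        raise InputError(f"post window {post} must be non-empty and within {labels}")
    mirna = name if name is not None else (series.name or "?")
    counts = series.astype(float)
    present_all = bool((counts > 0).all())
    if (counts == 0).all():
        return EvidenceVerdict(mirna, passes_count_filter, present_all, None, "insufficient")
    peak_tp = counts.idxmax()  # earliest label wins ties (pandas first occurrence)
    peak = counts[peak_tp]
    ok = peak_tp in post and counts[baseline] < peak_ratio * peak
    return EvidenceVerdict(
        mirna, passes_count_filter, present_all, str(peak_tp),
        "consistent" if ok else "inconsistent",
    )


def evaluate_evidence(
    table: pd.DataFrame,
    baseline: str,
    post_window,
    min_count: float = 10,
    peak_ratio: float = 0.5,
) -> list[EvidenceVerdict]:
    """Run the full cascade over a donor-unique count table.

    Every row gets a verdict; ``passes_count_filter`` records whether it
    survived :func:`filter_min_count`, and consistency is evaluated for
    surviving rows only (others are reported but carry no evidential
    weight).
    """
    kept = set(filter_min_count(table, min_count).index)
    out = []
    for mirna, row in table.iterrows():
        out.append(
            intake_consistency(
                row, baseline, post_window, peak_ratio,
                name=str(mirna), passes_count_filter=mirna in kept,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Milk-abundance cross-reference
# ---------------------------------------------------------------------------

def crossref_milk(
    changes: pd.Series,
    milk_profile: pd.Series,
    top_k: int = 10,
) -> dict:
    """Cross-reference plasma fold changes with a milk abundance profile.

    *changes* maps miRNA name to fold change (baseline to post-intake;
    negative values denote decline).  *milk_profile* maps miRNA name to
    milk abundance (share or any monotone abundance measure; larger =
    more abundant).  Returns three views:

    * ``top_increasers``: the top-k plasma increasers annotated with their
      milk abundance rank (1 = most abundant) or "ND" if absent from milk;
    * ``top_milk``: the top-k milk miRNAs annotated with their plasma fold
      change or "ND" if not seen in plasma;
    * ``overlap``: how many top-k plasma increasers are also top-k in milk.

    If dietary transfer drove the plasma changes, the abundant milk
    species should dominate the increasers; a near-zero overlap is the
    null expectation.
    """
    changes = pd.Series(changes, dtype=float).dropna()
    milk = pd.Series(milk_profile, dtype=float).dropna()
    milk_rank = milk.rank(ascending=False, method="min").astype(int)

    inc = changes.sort_values(ascending=False).head(top_k)
    top_increasers = pd.DataFrame(
        {
            "fold_change": inc,
            "milk_rank": [int(milk_rank[m]) if m in milk_rank.index else None for m in inc.index],
        }
    )
    top_milk_names = milk.sort_values(ascending=False).head(top_k)
    top_milk = pd.DataFrame(
        {
            "milk_abundance": top_milk_names,
            "fold_change": [float(changes[m]) if m in changes.index else None for m in top_milk_names.index],
        }
    )
    overlap = len(set(inc.index) & set(top_milk_names.index))
    return {"top_increasers": top_increasers, "top_milk": top_milk, "overlap": overlap}


# ---------------------------------------------------------------------------
# Uptake stoichiometry
# ---------------------------------------------------------------------------

def pmol_per_l_to_fmol_per_l(x: float) -> float:
    """Concentration unit boundary: 1 pmol/L = 1000 fmol/L."""
    return 1000.0 * x


@dataclass(frozen=True)
class UptakeScenario:
    """Mass-balance parameters for dietary miRNA uptake feasibility.

    All concentrations in fmol/L (use :func:`pmol_per_l_to_fmol_per_l` at
    the boundary).  Defaults: 5 L of blood (adult plasma-accessible
    volume) and 1 L of ingested milk.
    """

    milk_concentration: float  # fmol/L in milk
    target_increase: float     # fmol/L increase in blood
    blood_volume: float = 5.0  # L
    milk_volume: float = 1.0   # L ingested
    efficiency: float = 1.0    # fraction of ingested copies reaching blood

    def __post_init__(self) -> None:
        if self.milk_concentration <= 0:
            raise ConfigError("milk concentration must be > 0")
        if self.target_increase < 0:
            raise ConfigError("target increase must be >= 0")
        if self.blood_volume <= 0 or self.milk_volume <= 0:
            raise ConfigError("volumes must be > 0")
        if not 0 < self.efficiency <= 1:
            raise ConfigError("efficiency must be in (0, 1]")


def required_milk_volume(scenario: UptakeScenario) -> float:
    """Liters of milk needed to raise blood concentration by the target.

    Copies needed = target_increase x blood_volume; copies delivered per
    liter = milk_concentration x efficiency; hence

        volume = (target x blood volume) / (milk concentration x efficiency).

    At 20 fmol/L milk, a 300 fmol/L rise in 5 L of blood needs 75 L of
    milk even at 100% uptake efficiency.
    """
    return (scenario.target_increase * scenario.blood_volume) / (
        scenario.milk_concentration * scenario.efficiency
    )


def required_uptake_fraction(scenario: UptakeScenario) -> tuple[float, bool]:
    """Uptake efficiency needed given a fixed ingested milk volume.

        fraction = (target x blood volume) / (milk concentration x milk volume)

    Returns ``(fraction, infeasible)``; the scenario is flagged infeasible
    when the required fraction exceeds 1 (more copies needed than the meal
    contains).
    """
    frac = (scenario.target_increase * scenario.blood_volume) / (
        scenario.milk_concentration * scenario.milk_volume
    )
    return frac, frac > 1.0
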