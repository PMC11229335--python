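"""Red/white recombination-assay outcome classification and statistics.

The assay reads the repair of an I-SceI break between ade2 heteroalleles
on homologous chromosomes of a diploid. Colony color encodes the
gene-conversion tract length of each sister chromatid (white = short
tract restores ADE2, red = long tract keeps it broken; one of each gives
a red/white sectored colony), and two antibiotic markers (hygromycin B,
nourseothricin) flank the locus so that marker segregation distinguishes
outcomes:

  chromosome loss  -- the colony fails the -Ura/-Met segregation control
  crossover (CO)   -- the two sectors are each resistant to exactly one,
                      different, antibiotic (markers switched chromosomes)
  non-crossover    -- marker segregation unchanged: resistant to both
  BIR              -- red sector resistant to both while the white sector
                      is resistant to only one (the marker was copied)

Unsectored colonies are classified by the same marker logic on their
single phenotype; patterns outside the tree are counted as
"unclassifiable", never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContractViolationError,
    InsufficientReplicatesError,
    InvalidParameterError,
)

OUTCOMES = ("NCO", "CO", "BIR", "chromosome_loss")
CATEGORIES = OUTCOMES + ("unclassifiable",)
POPULATIONS = ("sectored", "solid_red", "total")


@dataclass(frozen=True)
class SectorPhenotype:
    color: str  # "red" or "white"
    hyg_resistant: bool
    nat_resistant: bool

    def n_resistances(self) -> int:
        return int(self.hyg_resistant) + int(self.nat_resistant)


@dataclass(frozen=True)
class ColonyRecord:
    replicate_id: int
    strain: str
    color: str  # "white", "red" or "sectored"
    sectors: Tuple[SectorPhenotype, ...]
    ura_met_growth: bool = True
    generating_outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.color == "sectored" and len(self.sectors) != 2:
            raise ContractViolationError("sectored colonies carry exactly two sectors")
        if self.color in ("white", "red") and len(self.sectors) != 1:
            raise ContractViolationError("unsectored colonies carry one phenotype")


@dataclass
class OutcomeTally:
    """Per-replicate outcome fractions and across-replicate mean +/- SD."""

    population: str
    counts: pd.DataFrame  # replicates x categories
    fractions: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    n_replicates: int


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_colony(record: ColonyRecord) -> str:
    """Map a colony's color and marker phenotype to an outcome label."""
    if not record.ura_met_growth:
        return "chromosome_loss"

    if record.color == "sectored":
        red = [s for s in record.sectors if s.color == "red"]
        white = [s for s in record.sectors if s.color == "white"]
        if len(red) != 1 or len(white) != 1:
            return "unclassifiable"
        r, w = red[0], white[0]
        if r.n_resistances() == 2 and w.n_resistances() == 2:
            return "NCO"
        if (
            r.n_resistances() == 1
            and w.n_resistances() == 1
            and r.hyg_resistant != w.hyg_resistant
        ):
            return "CO"
        if r.n_resistances() == 2 and w.n_resistances() == 1:
            return "BIR"
        return "unclassifiable"

    (s,) = record.sectors
    if s.n_resistances() == 2:
        return "NCO"
    if s.n_resistances() == 1:
        return "CO"
    return "unclassifiable"


def phenotype_for_outcome(
    outcome: str,
    color_class: str,
    rng: np.random.Generator,
    replicate_id: int = 0,
    strain: str = "WT",
) -> ColonyRecord:
    """Build the colony phenotype that the decision tree maps back to
    ``outcome`` (inverse of classify_colony; used by the simulator)."""
    if outcome not in OUTCOMES:
        raise InvalidParameterError(f"unknown outcome {outcome!r}")
    swap = bool(rng.random() < 0.5)  # which antibiotic ended up where

    def sector(color: str, hyg: bool, nat: bool) -> SectorPhenotype:
        return SectorPhenotype(color, hyg, nat)

    ura_met = outcome != "chromosome_loss"
    if color_class == "sectored":
        color = "sectored"
        if outcome == "CO":
            sectors = (sector("red", swap, not swap), sector("white", not swap, swap))
        elif outcome == "NCO" or outcome == "chromosome_loss":
            sectors = (sector("red", True, True), sector("white", True, True))
        elif outcome == "BIR":
            sectors = (sector("red", True, True), sector("white", swap, not swap))
    else:
        color = "red" if color_class == "solid_red" else "white"
        if outcome == "CO":
            sectors = (sector(color, swap, not swap),)
        elif outcome in ("NCO", "chromosome_loss"):
            sectors = (sector(color, True, True),)
        else:
            raise InvalidParameterError("BIR is only identifiable in sectored colonies")
    return ColonyRecord(
        replicate_id=replicate_id,
        strain=strain,
        color=color,
        sectors=sectors,
        ura_met_growth=ura_met,
        generating_outcome=outcome,
    )


# ---------------------------------------------------------------------------
# Tallies and comparisons
# ---------------------------------------------------------------------------


def _in_population(record: ColonyRecord, population: str) -> bool:
    if population == "total":
        return True
    if population == "sectored":
        return record.color == "sectored"
    if population == "solid_red":
        return record.color == "red"
    raise InvalidParameterError(f"unknown population {population!r}")


def tally_outcomes(
    records: Sequence[ColonyRecord],
    population: str = "sectored",
) -> OutcomeTally:
    """Per-replicate outcome fractions within a colony population.

    Fractions in each replicate are counts over the replicate's total in
    the chosen population (all categories, including unclassifiable, so
    they sum to 1). Replicates with no colonies in the population are
    excluded with a warning. Mean and unbiased SD are across replicates.
    """
    if not records:
        raise InvalidParameterError("no colony records supplied")
    rows: Dict[int, Dict[str, int]] = {}
    for record in records:
        if not _in_population(record, population):
            continue
        label = classify_colony(record)
        row = rows.setdefault(record.replicate_id, {c: 0 for c in CATEGORIES})
        row[label] += 1

    all_reps = sorted({r.replicate_id for r in records})
    empty = [rep for rep in all_reps if rep not in rows]
    if empty:
        warnings.warn(
            f"replicates {empty} have no colonies in population {population!r}; excluded",
            stacklevel=2,
        )
    if not rows:
        raise InvalidParameterError(f"no colonies in population {population!r}")

    counts = pd.DataFrame.from_dict(rows, orient="index").sort_index()[list(CATEGORIES)]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return OutcomeTally(
        population=population,
        counts=counts,
        fractions=fractions,
        mean=fractions.mean(),
        sd=fractions.std(ddof=1) if len(fractions) > 1 else fractions.iloc[0] * 0.0,
        n_replicates=len(fractions),
    )


@dataclass(frozen=True)
class StrainComparison:
    statistic: float
    df: float
    pvalue: float
    category: str


def compare_strains(
    tally_a: OutcomeTally,
    tally_b: OutcomeTally,
    category: str = "CO",
) -> StrainComparison:
    """Two-sided Welch t-test on per-replicate outcome fractions."""
    if tally_a.n_replicates < 2 or tally_b.n_replicates < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per strain")
    a = tally_a.fractions[category].to_numpy()
    b = tally_b.fractions[category].to_numpy()
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: identical within-arm values; equal means imply p = 1
        if np.mean(a) == np.mean(b):
            return StrainComparison(0.0, float(len(a) + len(b) - 2), 1.0, category)
    res = stats.ttest_ind(a, b, equal_var=False)
    return StrainComparison(
        float(res.statistic), float(res.df), float(res.pvalue), category
    )


def permutation_pvalue(
    fractions_a: Sequence[float],
    fractions_b: Sequence[float],
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of replicate means.

    Independent validation of the Welch test; exact enumeration when the
    permutation count is small.
    """
    res = stats.permutation_test(
        (np.asarray(fractions_a, dtype=float), np.asarray(fractions_b, dtype=float)),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_resamples,
        random_state=seed,
        vectorized=True,
    )
    return float(res.pvalue)
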