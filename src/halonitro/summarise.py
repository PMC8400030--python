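"""Cohort statistics: family classification table, enzyme totals,
marker-combination counts and gas-emitter fractions.

All percentages use genome-available species as denominator (species
with no available genome are listed but never enter a percentage), and
are rounded half-up to one decimal.  Emitter fractions are reported
over both denominators: potential denitrifiers and genome-available
species.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .errors import ConsistencyError
from .homology import MarkerProfile
from .phenotype import ENZYME_CHAIN, PhenotypeCall


def pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    exact = Decimal(100 * numerator) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n_species: int
    n_no_genome: int
    n_non: int
    n_partial: int
    n_complete: int
    pct_non: Optional[float]
    pct_partial: Optional[float]
    pct_complete: Optional[float]


def family_table(
    calls: Sequence[PhenotypeCall],
    taxonomy: dict[str, tuple[str, bool]],
) -> list[FamilySummary]:
    """Per-family classification counts plus a TOTAL row.

    Species flagged genome_available=False contribute to n_species and
    n_no_genome only; percentages are over genome-available species.
    """
    by_species = {c.species: c for c in calls}
    for sp in by_species:
        if sp not in taxonomy:
            raise ConsistencyError(f"species {sp!r} missing from taxonomy")
    families: dict[str, dict[str, int]] = {}
    for sp, (fam, available) in taxonomy.items():
        row = families.setdefault(
            fam, {"n_species": 0, "n_no_genome": 0, "non": 0, "partial": 0, "complete": 0}
        )
        row["n_species"] += 1
        if not available:
            row["n_no_genome"] += 1
            continue
        call = by_species.get(sp)
        if call is None:
            raise ConsistencyError(
                f"genome-available species {sp!r} has no phenotype call"
            )
        row[call.completeness] += 1

    out = []
    totals = {"n_species": 0, "n_no_genome": 0, "non": 0, "partial": 0, "complete": 0}
    for fam in sorted(families):
        row = families[fam]
        for key in totals:
            totals[key] += row[key]
        out.append(_family_row(fam, row))
    out.append(_family_row("TOTAL", totals))
    return out


def _family_row(name: str, row: dict[str, int]) -> FamilySummary:
    denom = row["n_species"] - row["n_no_genome"]
    return FamilySummary(
        family=name,
        n_species=row["n_species"],
        n_no_genome=row["n_no_genome"],
        n_non=row["non"],
        n_partial=row["partial"],
        n_complete=row["complete"],
        pct_non=pct(row["non"], denom) if denom else None,
        pct_partial=pct(row["partial"], denom) if denom else None,
        pct_complete=pct(row["complete"], denom) if denom else None,
    )


def family_table_frame(rows: Sequence[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def enzyme_distribution(profiles: Sequence[MarkerProfile]) -> dict[str, int]:
    """Number of genome-available species possessing each enzyme, with
    the nitrite-reductase class broken out."""
    counts = {"nar": 0, "nir": 0, "nirk": 0, "nirs": 0, "nor": 0, "nos": 0, "non_denitrifier": 0}
    for p in profiles:
        counts["nar"] += p.nar
        counts["nir"] += p.nir
        counts["nirk"] += p.nir_type == "NirK"
        counts["nirs"] += p.nir_type == "NirS"
        counts["nor"] += p.nor
        counts["nos"] += p.nos
        counts["non_denitrifier"] += p.n_enzymes == 0
    return counts


def combination_counts(profiles: Sequence[MarkerProfile]) -> dict[tuple[str, ...], int]:
    """Count of species per marker combination (all 16 subsets)."""
    counts: dict[tuple[str, ...], int] = {}
    for size in range(5):
        for combo in _subsets_of_size(size):
            counts[combo] = 0
    for p in profiles:
        counts[p.present()] += 1
    return counts


def _subsets_of_size(k: int):
    from itertools import combinations

    for combo in combinations(ENZYME_CHAIN, k):
        yield combo


def emitter_fractions(calls: Sequence[PhenotypeCall]) -> dict:
    """Gas-emitter statistics over both denominators.

    Returns counts plus percentages of NO-enders, N2O-enders, their
    union (potential greenhouse-gas emitters) and Nos-bearing genomes,
    each over (a) potential denitrifiers and (b) genome-available
    species.  With zero denitrifiers the (a) percentages are None
    (undefined), never 0.
    """
    n_genomes = len(calls)
    if n_genomes == 0:
        raise ConsistencyError("no genome-available species")
    denitrifiers = [c for c in calls if c.n_enzymes >= 1]
    n_den = len(denitrifiers)
    n_no = sum(1 for c in calls if c.end_product == "NO")
    n_n2o = sum(1 for c in calls if c.end_product == "N2O")
    n_nos = sum(1 for c in calls if c.end_product == "N2")
    n_gas = n_no + n_n2o

    def over_den(k: int) -> Optional[float]:
        return pct(k, n_den) if n_den else None

    return {
        "n_genomes": n_genomes,
        "n_denitrifiers": n_den,
        "n_NO_enders": n_no,
        "n_N2O_enders": n_n2o,
        "n_gas_emitters": n_gas,
        "n_nos_bearing": n_nos,
        "pct_NO_enders_of_denitrifiers": over_den(n_no),
        "pct_NO_enders_of_genomes": pct(n_no, n_genomes),
        "pct_N2O_enders_of_denitrifiers": over_den(n_n2o),
        "pct_N2O_enders_of_genomes": pct(n_n2o, n_genomes),
        "pct_gas_emitters_of_denitrifiers": over_den(n_gas),
        "pct_gas_emitters_of_genomes": pct(n_gas, n_genomes),
        "pct_nos_bearing_of_denitrifiers": over_den(n_nos),
        "pct_nos_bearing_of_genomes": pct(n_nos, n_genomes),
    }


def cohort_summary(
    calls: Sequence[PhenotypeCall],
    profiles: Sequence[MarkerProfile],
    n_species_total: Optional[int] = None,
) -> dict:
    """Headline cohort statistics (denitrifier share, completeness
    fractions, enzyme totals, combination counts, emitter fractions)."""
    n_genomes = len(calls)
    n_den = sum(1 for c in calls if c.n_enzymes >= 1)
    n_partial = sum(1 for c in calls if c.completeness == "partial")
    n_complete = sum(1 for c in calls if c.completeness == "complete")
    combos = combination_counts(profiles)
    return {
        "n_species_total": n_species_total if n_species_total is not None else n_genomes,
        "n_genomes": n_genomes,
        "n_denitrifiers": n_den,
        "n_non_denitrifiers": n_genomes - n_den,
        "pct_denitrifiers": pct(n_den, n_genomes),
        "pct_non_denitrifiers": pct(n_genomes - n_den, n_genomes),
        "pct_partial": pct(n_partial, n_genomes),
        "pct_complete": pct(n_complete, n_genomes),
        "enzyme_totals": enzyme_distribution(profiles),
        "combination_counts": {"+".join(k) if k else "none": v for k, v in combos.items()},
        "emitters": emitter_fractions(calls),
    }
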