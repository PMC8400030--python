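"""Genome-to-phenotype classification for the denitrification chain.

The four marker enzymes act in the fixed order

    Nar (NO3- -> NO2-)  ->  Nir (NO2- -> NO)  ->  Nor (NO -> N2O)  ->  Nos (N2O -> N2)

A species with at least one marker is a (potential) denitrifier; with
all four, a complete denitrifier.  The theoretical end product is the
product of the most downstream enzyme present: this reproduces every
marker combination enumerated in the source data (NarG-NirK or NirK
alone end in NO; Nar-Nir-Nor, Nar-Nor, Nir-Nor or Nor alone end in
N2O; any Nos-bearing genome can close the chain to N2) and extends the
rule consistently to combinations not explicitly enumerated, which are
flagged ``rule_derived``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import MarkerProfile

ENZYME_CHAIN = ("nar", "nir", "nor", "nos")
PRODUCT_OF = {"nar": "nitrite", "nir": "NO", "nor": "N2O", "nos": "N2"}

# combinations whose end product the source enumeration states directly;
# everything else is classified by the same most-downstream rule but
# flagged as rule-derived.
_ENUMERATED = {
    frozenset(),
    frozenset({"nar", "nir"}),
    frozenset({"nir"}),
    frozenset({"nar", "nir", "nor"}),
    frozenset({"nar", "nor"}),
    frozenset({"nir", "nor"}),
    frozenset({"nor"}),
    frozenset({"nar", "nir", "nor", "nos"}),
}


@dataclass(frozen=True)
class PhenotypeCall:
    species: str
    status: str  # denitrifier | non_denitrifier
    completeness: str  # non | partial | complete
    end_product: str  # none | nitrite | NO | N2O | N2
    emitter: str  # none | NO_emitter | N2O_emitter | N2_reducer
    consecutive: bool
    n_enzymes: int
    nir_type: str
    rule_derived: bool


def end_product(profile: MarkerProfile) -> str:
    """Product of the most downstream enzyme present; 'none' if empty."""
    present = profile.present()
    if not present:
        return "none"
    for enzyme in reversed(ENZYME_CHAIN):
        if enzyme in present:
            return PRODUCT_OF[enzyme]
    raise AssertionError("unreachable")


def is_consecutive(profile: MarkerProfile) -> bool:
    """True iff the present enzymes form a contiguous block of the chain
    (an empty profile is consecutive by convention)."""
    idx = [ENZYME_CHAIN.index(e) for e in profile.present()]
    if not idx:
        return True
    return max(idx) - min(idx) + 1 == len(idx)


def classify(profile: MarkerProfile, strict: bool = False) -> PhenotypeCall:
    """Full phenotype call for one species.

    With ``strict=True`` a single-enzyme genome is not counted as a
    denitrifier (the canonical-definition caveat); the default follows
    the at-least-one-enzyme convention used for all cohort statistics.
    """
    n = profile.n_enzymes
    min_enzymes = 2 if strict else 1
    status = "denitrifier" if n >= min_enzymes else "non_denitrifier"
    completeness = "non" if n == 0 else ("complete" if n == 4 else "partial")
    product = end_product(profile)
    if product == "NO":
        emitter = "NO_emitter"
    elif product == "N2O":
        emitter = "N2O_emitter"
    elif product == "N2":
        emitter = "N2_reducer"
    else:
        emitter = "none"
    return PhenotypeCall(
        species=profile.species,
        status=status,
        completeness=completeness,
        end_product=product,
        emitter=emitter,
        consecutive=is_consecutive(profile),
        n_enzymes=n,
        nir_type=profile.nir_type,
        rule_derived=frozenset(profile.present()) not in _ENUMERATED,
    )
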