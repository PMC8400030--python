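"""Synthetic per-species cohort matching the published family marginals.

The published survey reports, per haloarchaeal family, the number of
species, the number lacking an available genome, and the counts of
non/partial/complete denitrifiers (147 species, 122 genomes, 36/71/15).
It also reports cohort-wide gas-emitter fractions.  The per-species
marker assignments below are a synthetic reconstruction: family-level
class counts equal the published table exactly, and the global
composition of the 71 partial profiles is chosen so that the cohort
reproduces the published emitter fractions (11 NO-enders, 40
N2O-enders, 34 Nos-bearing genomes among 86 denitrifiers).  The
within-family distribution of individual marker combinations is
arbitrary (the published table is family-marginal), weighted towards
NirK-Nor-containing sets, which the survey reports as most frequent.
All nitrite reductases are NirK, as observed for haloarchaea.
"""

from __future__ import annotations

from .homology import MarkerProfile

# family, n_species, n_no_genome, n_non, n_partial, n_complete
FAMILY_MARGINALS: list[tuple[str, int, int, int, int, int]] = [
    ("Natrialbaceae", 44, 4, 15, 23, 2),
    ("Halobacteriaceae", 11, 6, 4, 1, 0),
    ("Halococcaceae", 7, 2, 1, 4, 0),
    ("Haloarculaceae", 21, 2, 3, 7, 9),
    ("Halorubraceae", 29, 7, 8, 14, 0),
    ("Haloferacaceae", 27, 0, 3, 20, 4),
    ("Natronoarchaceae", 2, 2, 0, 0, 0),
    ("Salinarchaceae", 1, 1, 0, 0, 0),
    ("Haladaptataceae", 3, 0, 1, 2, 0),
    ("Halalkalicoccaceae", 2, 1, 1, 0, 0),
]

# Global pool of partial-denitrifier marker sets (71 entries), dealt to
# families in table order.  Composition: 11 NO-enders ({nar,nir} x6,
# {nir} x5), 40 N2O-enders ({nir,nor} x25, {nar,nir,nor} x8, {nor} x5,
# {nar,nor} x2), 19 Nos-bearing partials ({nir,nor,nos} x12,
# {nor,nos} x6, {nos} x1) and one nitrite-ender ({nar} x1).
_PARTIAL_POOL: list[tuple[str, ...]] = (
    [("nar", "nir")] * 6
    + [("nir",)] * 5
    + [("nir", "nor")] * 25
    + [("nar", "nir", "nor")] * 8
    + [("nor",)] * 5
    + [("nar", "nor")] * 2
    + [("nir", "nor", "nos")] * 12
    + [("nor", "nos")] * 6
    + [("nos",)] * 1
    + [("nar",)] * 1
)


def _profile(species: str, markers: tuple[str, ...]) -> MarkerProfile:
    nir = "nir" in markers
    return MarkerProfile(
        species=species,
        nar="nar" in markers,
        nir=nir,
        nir_type="NirK" if nir else "absent",
        nor="nor" in markers,
        nos="nos" in markers,
    )


def cohort_fixture() -> tuple[dict[str, tuple[str, bool]], list[MarkerProfile]]:
    """Deterministic (taxonomy, profiles) pair for the 147-species cohort.

    Taxonomy maps species -> (family, genome_available); profiles cover
    exactly the 122 genome-available species.
    """
    assert len(_PARTIAL_POOL) == 71
    taxonomy: dict[str, tuple[str, bool]] = {}
    profiles: list[MarkerProfile] = []
    pool = iter(_PARTIAL_POOL)
    for family, n_species, n_nga, n_non, n_partial, n_complete in FAMILY_MARGINALS:
        assert n_non + n_partial + n_complete == n_species - n_nga
        idx = 0

        def next_species() -> str:
            nonlocal idx
            idx += 1
            return f"{family}_sp{idx:02d}"

        for _ in range(n_non):
            sp = next_species()
            taxonomy[sp] = (family, True)
            profiles.append(_profile(sp, ()))
        for _ in range(n_partial):
            sp = next_species()
            taxonomy[sp] = (family, True)
            profiles.append(_profile(sp, next(pool)))
        for _ in range(n_complete):
            sp = next_species()
            taxonomy[sp] = (family, True)
            profiles.append(_profile(sp, ("nar", "nir", "nor", "nos")))
        for _ in range(n_nga):
            sp = next_species()
            taxonomy[sp] = (family, False)
    return taxonomy, profiles
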