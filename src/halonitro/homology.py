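"""Marker-enzyme detection by pairwise global alignment.

Candidate proteins are detected by exact affine-gap global alignment
(Needleman-Wunsch with Gotoh's three-state recurrence) against a small
reference panel of well-described denitrification enzymes, one or more
sequences per family (NarG, NarH, NirK, NirS, Nor, NosZ).  A hit is
accepted when its percent identity reaches the acceptance threshold
(default 65%, inclusive); for nitrate reductase the catalytic subunit
NarG additionally requires a narH gene adjacent in the gene order
(same replicon, within a small ordinal window), mirroring the operon
organisation of the respiratory enzyme.

Identity is computed as matches / alignment columns, where columns
belonging to terminal gap overhangs are excluded from the denominator:
a domain fragment aligned to a full-length reference is judged on the
region it actually covers.  The threshold comparison is carried out on
the exact rational matches/length, never on a pre-rounded percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AmbiguityError,
    ConfigError,
    ConsistencyError,
    ContextError,
)
from .seqio import GeneOrder, SequenceRecord, read_fasta

ENZYME_FAMILIES = ("NarG", "NarH", "NirK", "NirS", "Nor", "NosZ")

_NEG = -1.0e30  # sentinel for unreachable DP states (avoids inf-inf NaN)


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    matches: int
    alignment_length: int  # columns excluding terminal gap overhangs
    percent_identity: float
    score: float

    @property
    def identity_fraction(self) -> Fraction:
        if self.alignment_length == 0:
            return Fraction(0)
        return Fraction(self.matches, self.alignment_length)


@dataclass
class MarkerHit:
    species: str
    enzyme: str
    protein_id: str
    subject_id: str
    percent_identity: float
    matches: int
    alignment_length: int
    accepted: bool
    context_verified: Optional[bool] = None  # NarG only


@dataclass
class MarkerProfile:
    """Presence/absence of the four marker enzymes for one species."""

    species: str
    nar: bool = False
    nir: bool = False
    nir_type: str = "absent"  # "NirK" | "NirS" | "absent"
    nor: bool = False
    nos: bool = False

    def __post_init__(self) -> None:
        if not self.nir and self.nir_type != "absent":
            raise ValueError("nir=False requires nir_type='absent'")

    @property
    def n_enzymes(self) -> int:
        return sum((self.nar, self.nir, self.nor, self.nos))

    def present(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, flag in (
                ("nar", self.nar),
                ("nir", self.nir),
                ("nor", self.nor),
                ("nos", self.nos),
            )
            if flag
        )


class ReferencePanel:
    """Reference sequences grouped by enzyme family.

    FASTA records declare their family in the description as
    ``family=NarG`` etc.
    """

    def __init__(self, members: dict[str, list[SequenceRecord]]):
        for fam in members:
            if fam not in ENZYME_FAMILIES:
                raise ConfigError(f"unknown enzyme family {fam!r}")
            if not members[fam]:
                raise ConfigError(f"panel family {fam!r} has no members")
        self.members = members

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        members: dict[str, list[SequenceRecord]] = {}
        for rec in read_fasta(path, alphabet="protein"):
            fam = None
            for token in rec.description.split():
                if token.startswith("family="):
                    fam = token.split("=", 1)[1]
            if fam is None:
                raise ConfigError(
                    f"panel record {rec.id!r} lacks a family=<enzyme> tag"
                )
            members.setdefault(fam, []).append(rec)
        return cls(members)

    def records(self) -> list[SequenceRecord]:
        return [rec for fam in self.members.values() for rec in fam]

    def families(self) -> list[str]:
        return list(self.members)


# ---------------------------------------------------------------------------
# Global alignment (Gotoh three-state affine gaps)


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment of two sequences with affine gaps.

    A gap of length L scores ``gap_open + (L-1)*gap_extend``.  End gaps
    are penalised (true global alignment); identity is then computed
    over columns excluding terminal-gap overhangs.  Traceback ties are
    broken by state priority substitution > gap-in-subject >
    gap-in-query, giving a single canonical alignment.
    """
    qid, sa = (a.id, a.residues) if isinstance(a, SequenceRecord) else ("query", a)
    sid, sb = (b.id, b.residues) if isinstance(b, SequenceRecord) else ("subject", b)
    if not sa or not sb:
        raise ConfigError("cannot align an empty sequence")

    n, m = len(sa), len(sb)
    A = np.frombuffer(sa.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(sb.encode("ascii"), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in subject (consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in query (consumes b)
    M[0, 0] = 0.0
    i_idx = np.arange(1, n + 1)
    j_idx = np.arange(1, m + 1)
    X[1:, 0] = gap_open + (i_idx - 1) * gap_extend
    Y[0, 1:] = gap_open + (j_idx - 1) * gap_extend

    jm = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        sub = np.where(A[i - 1] == B, match, mismatch)
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + gap_open,
            X[i - 1, 1:] + gap_extend,
        )
        # horizontal gaps via running max: Y[i,j] = go + max_k<j (Z[k] + (j-1-k)*ge)
        Z = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(Z - gap_extend * jm)
        Y[i, 1:] = gap_open + gap_extend * jm[:-1] + run[:-1]

    aligned_a, aligned_b = _traceback(
        sa, sb, M, X, Y, match, mismatch, gap_open, gap_extend
    )
    score = float(max(M[n, m], X[n, m], Y[n, m]))

    matches, length = _identity_counts(aligned_a, aligned_b)
    identity = matches / length if length else 0.0
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        aligned_query=aligned_a,
        aligned_subject=aligned_b,
        matches=matches,
        alignment_length=length,
        percent_identity=identity,
        score=score,
    )


def _traceback(sa, sb, M, X, Y, match, mismatch, gap_open, gap_extend):
    tol = 1e-9
    i, j = len(sa), len(sb)
    final = max(M[i, j], X[i, j], Y[i, j])
    # state priority on ties: M > X > Y
    state = _pick_state(M[i, j], X[i, j], Y[i, j], final, tol)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            target = M[i, j] - s
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target, tol)
        elif state == "X":
            target = X[i, j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            state = _pick_state(
                M[i, j] + gap_open, X[i, j] + gap_extend, Y[i, j] + gap_open, target, tol
            )
        else:
            target = Y[i, j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
            state = _pick_state(
                M[i, j] + gap_open, X[i, j] + gap_open, Y[i, j] + gap_extend, target, tol
            )
        if i == 0 and j == 0:
            break
        if state is None:  # pragma: no cover - defensive
            raise RuntimeError("alignment traceback failed")
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _pick_state(vm, vx, vy, target, tol):
    if abs(vm - target) <= tol:
        return "M"
    if abs(vx - target) <= tol:
        return "X"
    if abs(vy - target) <= tol:
        return "Y"
    return None


def _identity_counts(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """(matches, columns) over the alignment minus terminal gap overhangs."""
    ncol = len(aligned_a)
    start = 0
    while start < ncol and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    end = ncol
    while end > start and (aligned_a[end - 1] == "-" or aligned_b[end - 1] == "-"):
        end -= 1
    matches = sum(
        1 for k in range(start, end) if aligned_a[k] == aligned_b[k] and aligned_a[k] != "-"
    )
    return matches, end - start


# ---------------------------------------------------------------------------
# Proteome scanning and profile construction


def _exact_accept(matches: int, length: int, threshold: float) -> bool:
    if length == 0:
        return False
    return Fraction(matches, length) >= Fraction(str(threshold))


def scan_proteome(
    species: str,
    proteome: Sequence[SequenceRecord],
    panel: ReferencePanel,
    threshold: float = 0.65,
    **align_kwargs,
) -> list[MarkerHit]:
    """Align every proteome sequence to every panel member and keep, per
    enzyme family, the best hit (highest identity; ties to the
    lexicographically lower protein id).  Hits below the threshold are
    retained with ``accepted=False`` for reporting."""
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold must be in (0,1], got {threshold}")
    if not proteome:
        warnings.warn(f"{species}: empty proteome, no hits", stacklevel=2)
        return []
    best: dict[str, tuple] = {}
    for rec in sorted(proteome, key=lambda r: r.id):
        for fam, refs in panel.members.items():
            for ref in refs:
                aln = global_align(rec, ref, **align_kwargs)
                key = (aln.identity_fraction, _InvStr(rec.id))
                if fam not in best or key > best[fam][0]:
                    best[fam] = (key, rec.id, ref.id, aln)
    hits = []
    for fam in ENZYME_FAMILIES:
        if fam not in best:
            continue
        _, pid, sid, aln = best[fam]
        hits.append(
            MarkerHit(
                species=species,
                enzyme=fam,
                protein_id=pid,
                subject_id=sid,
                percent_identity=aln.percent_identity,
                matches=aln.matches,
                alignment_length=aln.alignment_length,
                accepted=_exact_accept(aln.matches, aln.alignment_length, threshold),
            )
        )
    return hits


class _InvStr(str):
    """String with inverted ordering, so max() prefers the lower id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _accepted(hits: Iterable[MarkerHit], enzyme: str) -> Optional[MarkerHit]:
    for h in hits:
        if h.enzyme == enzyme and h.accepted:
            return h
    return None


def verify_nar_context(
    species: str,
    hits: Sequence[MarkerHit],
    gene_order: GeneOrder,
    window: int = 2,
) -> bool:
    """True iff an accepted narH gene lies on the same replicon within
    ``window`` ordinal positions of the accepted narG gene."""
    narg = _accepted(hits, "NarG")
    if narg is None:
        raise ContextError(f"{species}: no accepted NarG hit to verify")
    loc_g = gene_order.position_of(narg.protein_id)
    if loc_g is None:
        raise ContextError(
            f"{species}: NarG gene {narg.protein_id!r} absent from gene order"
        )
    narh = _accepted(hits, "NarH")
    if narh is None:
        return False
    loc_h = gene_order.position_of(narh.protein_id)
    if loc_h is None:
        return False
    return loc_g[0] == loc_h[0] and abs(loc_g[1] - loc_h[1]) <= window


def type_nir(hits: Sequence[MarkerHit]) -> str:
    """Resolve the nitrite-reductase class from accepted hits."""
    nirk = _accepted(hits, "NirK")
    nirs = _accepted(hits, "NirS")
    if nirk and nirs:
        if nirk.protein_id == nirs.protein_id:
            raise AmbiguityError(
                f"protein {nirk.protein_id!r} accepted against both NirK and "
                f"NirS panels"
            )
        # distinct proteins: report the stronger match
        return "NirK" if nirk.percent_identity >= nirs.percent_identity else "NirS"
    if nirk:
        return "NirK"
    if nirs:
        return "NirS"
    return "absent"


def build_profiles(
    hits_by_species: dict[str, list[MarkerHit]],
    gene_orders: dict[str, GeneOrder],
    taxonomy: dict[str, tuple[str, bool]],
    window: int = 2,
) -> list[MarkerProfile]:
    """One profile per genome-available species.

    ``nar`` is set only when NarG is accepted AND its genetic context is
    verified (adjacent narH).  Species without genomes are excluded; a
    species claiming a genome but missing from the hit lists is a
    consistency error.
    """
    profiles = []
    for species in sorted(taxonomy):
        _, available = taxonomy[species]
        if not available:
            continue
        if species not in hits_by_species:
            raise ConsistencyError(
                f"{species}: genome_available but no proteome scan results"
            )
        hits = hits_by_species[species]
        nar = False
        narg = _accepted(hits, "NarG")
        if narg is not None:
            order = gene_orders.get(species)
            if order is None:
                raise ContextError(f"{species}: no gene order for NarG verification")
            nar = verify_nar_context(species, hits, order, window=window)
            narg.context_verified = nar
        nir_type = type_nir(hits)
        profiles.append(
            MarkerProfile(
                species=species,
                nar=nar,
                nir=nir_type != "absent",
                nir_type=nir_type,
                nor=_accepted(hits, "Nor") is not None,
                nos=_accepted(hits, "NosZ") is not None,
            )
        )
    return profiles
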