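"""Synthetic communities with known marker content, gene order and 16S tree.

The generator emulates the kind of cohort the pipeline is meant for: a
set of archaeal species, each with (or without) an available proteome,
in which denitrification-marker homologs are planted at a controlled
percent identity to a reference panel, together with decoy proteins
(mutated panel copies at sub-threshold identity, so the acceptance
threshold is genuinely exercised), a gene order in which narH is placed
adjacent to narG, and 16S-like sequences evolved along a random
ultrametric bifurcating tree by a Jukes-Cantor-style uniform
substitution process.  Every choice is driven by a single seed, so a
given configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import ConfigError
from .homology import ENZYME_FAMILIES, MarkerProfile, ReferencePanel
from .seqio import (
    GeneOrder,
    SequenceRecord,
    write_fasta,
    write_gene_orders,
    write_taxonomy,
)
from .tree import Tree, TreeNode
from . import seqio

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: reference lengths (residues) per marker family; moderate full-domain
#: scale so that thousands of pairwise alignments stay cheap
DEFAULT_FAMILY_LENGTHS: dict[str, int] = {
    "NarG": 400,
    "NarH": 250,
    "NirK": 300,
    "NirS": 300,
    "Nor": 350,
    "NosZ": 300,
}

CLASSES = ("non", "partial", "complete")

_PARTIAL_SUBSETS: list[tuple[str, ...]] = [
    combo
    for size in (1, 2, 3)
    for combo in combinations(("nar", "nir", "nor", "nos"), size)
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic community.

    family_spec: list of (family_name, n_species, class_mix) where
    class_mix maps {non, partial, complete} to fractions summing to 1.
    identity_true / identity_decoy: target identity of planted homologs
    and of decoy proteins to the reference panel.  p_no_genome: fraction
    of species without an available genome (present in the 16S set but
    excluded from classification).  tree_depth: expected root-to-tip
    divergence (substitutions/site) of the 16S tree.
    """

    family_spec: list[tuple[str, int, dict[str, float]]]
    identity_true: float = 0.85
    identity_decoy: float = 0.30
    p_no_genome: float = 0.0
    seed: int = 0
    tree_depth: float = 0.10
    n_decoys: int = 5
    seq_length_16s: int = 1200
    family_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_LENGTHS)
    )

    @property
    def n_species(self) -> int:
        return sum(n for _, n, _ in self.family_spec)

    def validate(self) -> None:
        if not self.family_spec:
            raise ConfigError("family_spec is empty")
        for fam, n, mix in self.family_spec:
            if set(mix) - set(CLASSES):
                raise ConfigError(f"{fam}: unknown classes {set(mix) - set(CLASSES)}")
            total = sum(mix.get(c, 0.0) for c in CLASSES)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{fam}: class_mix sums to {total}, not 1")
            if n <= 0 and any(mix.get(c, 0.0) > 0 for c in CLASSES):
                raise ConfigError(f"{fam}: positive class fractions with {n} species")
        if not 0 < self.identity_true <= 1:
            raise ConfigError(f"identity_true {self.identity_true} outside (0,1]")
        if not 0 < self.identity_decoy < 1:
            raise ConfigError(f"identity_decoy {self.identity_decoy} outside (0,1)")
        if self.identity_true < self.identity_decoy:
            raise ConfigError(
                "identity_true below identity_decoy: no detection threshold "
                "can separate homologs from decoys"
            )
        if not 0 <= self.p_no_genome <= 1:
            raise ConfigError("p_no_genome outside [0,1]")
        if self.n_decoys < 5:
            raise ConfigError("at least 5 decoy proteins per proteome")


@dataclass
class GroundTruth:
    profiles: dict[str, MarkerProfile]
    families: dict[str, str]
    genome_available: dict[str, bool]
    tree_newick: str
    marker_gene_ids: dict[str, str]  # gene_id -> enzyme family

    def to_json(self) -> str:
        payload = {
            "profiles": {
                sp: {
                    "nar": p.nar,
                    "nir": p.nir,
                    "nir_type": p.nir_type,
                    "nor": p.nor,
                    "nos": p.nos,
                }
                for sp, p in self.profiles.items()
            },
            "families": self.families,
            "genome_available": self.genome_available,
            "tree_newick": self.tree_newick,
            "marker_gene_ids": self.marker_gene_ids,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class Community:
    config: SimulationConfig
    panel: ReferencePanel
    proteomes: dict[str, list[SequenceRecord]]
    gene_orders: dict[str, GeneOrder]
    sixteen_s: list[SequenceRecord]
    taxonomy: dict[str, tuple[str, bool]]
    truth: GroundTruth

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
        for sp, records in self.proteomes.items():
            write_fasta(records, outdir / "proteomes" / f"{sp}.faa")
        panel_records = [
            SequenceRecord(id=r.id, residues=r.residues, description=f"family={fam}")
            for fam, recs in self.panel.members.items()
            for r in recs
        ]
        write_fasta(panel_records, outdir / "panel.faa")
        write_fasta(self.sixteen_s, outdir / "16s_aligned.fna")
        write_gene_orders(
            self.gene_orders.values(),
            outdir / "gene_order.tsv",
            marker_truth=self.truth.marker_gene_ids,
        )
        write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        (outdir / "ground_truth.json").write_text(self.truth.to_json() + "\n")
        (outdir / "truth_tree.nwk").write_text(self.truth.tree_newick + "\n")


# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_reference_panel(
    seed: int, family_lengths: Optional[dict[str, int]] = None
) -> ReferencePanel:
    """Random reference panel, one sequence per enzyme family.

    Stands in for a curated set of well-described enzymes; independent
    random draws keep the six families (in particular NirK vs NirS)
    far below any acceptance threshold from one another.
    """
    lengths = dict(DEFAULT_FAMILY_LENGTHS)
    if family_lengths:
        lengths.update(family_lengths)
    rng = np.random.default_rng(seed)
    members: dict[str, list[SequenceRecord]] = {}
    for fam in ENZYME_FAMILIES:
        length = lengths[fam]
        if length < 50:
            raise ConfigError(f"panel length for {fam} must be >= 50, got {length}")
        members[fam] = [
            SequenceRecord(
                id=f"ref_{fam}_1",
                residues=_random_protein(rng, length),
                description=f"family={fam}",
            )
        ]
    return ReferencePanel(members)


def mutate_to_identity(
    seq: str, target_identity: float, seed: Union[int, np.random.Generator]
) -> str:
    """Substitution-only mutant at a controlled identity to the input.

    Exactly round((1 - target) * len) positions, chosen uniformly
    without replacement, are replaced by a uniform draw from the 19
    alternative residues, so the realised identity equals the target to
    within half a position.
    """
    if not 0 < target_identity <= 1:
        raise ConfigError(f"target_identity {target_identity} outside (0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mut = int(math.floor((1.0 - target_identity) * len(seq) + 0.5))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [aa for aa in AMINO_ACIDS if aa != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    quotas = {c: n * fractions.get(c, 0.0) for c in CLASSES}
    base = {c: int(math.floor(quotas[c])) for c in CLASSES}
    remaining = n - sum(base.values())
    order = sorted(
        CLASSES, key=lambda c: (-(quotas[c] - base[c]), CLASSES.index(c))
    )
    for c in order[:remaining]:
        base[c] += 1
    return base


# --- 16S evolution ---------------------------------------------------------


def _random_ultrametric_tree(
    labels: list[str], depth: float, rng: np.random.Generator
) -> Tree:
    def build(subset: list[str], height: float) -> TreeNode:
        if len(subset) == 1:
            return TreeNode(label=subset[0], length=height)
        k = int(rng.integers(1, len(subset)))
        child_height = height * float(rng.uniform(0.3, 0.7))
        node = TreeNode(length=height - child_height)
        node.add_child(build(subset[:k], child_height))
        node.add_child(build(subset[k:], child_height))
        return node

    shuffled = list(labels)
    rng.shuffle(shuffled)
    root = build(shuffled, depth)
    root.length = None
    return Tree(root)


def _evolve_16s(
    tree: Tree, length: int, rng: np.random.Generator
) -> list[SequenceRecord]:
    """Jukes-Cantor-style evolution along the tree: along an edge of
    length t each site substitutes with probability 3/4(1 - e^{-4t/3}),
    uniformly to one of the three alternatives."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    root_seq = rng.choice(alphabet, size=length)

    records: dict[str, SequenceRecord] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.length:
            p_sub = 0.75 * (1.0 - math.exp(-4.0 * node.length / 3.0))
            hit = rng.random(length) < p_sub
            if hit.any():
                seq = seq.copy()
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                idx = np.searchsorted(alphabet, seq[hit])
                seq[hit] = alphabet[(idx + shifts) % 4]
        if node.is_leaf:
            records[node.label] = SequenceRecord(
                id=node.label, residues=bytes(seq).decode("ascii")
            )
        else:
            for child in node.children:
                descend(child, seq)

    descend(tree.root, root_seq)
    return [records[lab] for lab in sorted(records)]


# --- community assembly ----------------------------------------------------

_ENZYME_OF_MARKER = {"nar": "NarG", "nir": "NirK", "nor": "Nor", "nos": "NosZ"}


def generate_community(config: SimulationConfig) -> Community:
    """Generate a full community with ground truth.

    Proteomes of genome-available species contain homologs (at
    identity_true) exactly for the enzymes of their true marker set,
    plus n_decoys decoy proteins at identity_decoy; nar-positive species
    also receive a narH homolog adjacent to narG in the gene order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = generate_reference_panel(int(rng.integers(2**31)), config.family_lengths)

    species_class: list[tuple[str, str, str]] = []  # species, family, class
    for fam, n, mix in config.family_spec:
        alloc = _largest_remainder(n, mix)
        idx = 0
        for cls in CLASSES:
            for _ in range(alloc[cls]):
                idx += 1
                species_class.append((f"{fam}_sp{idx:02d}", fam, cls))

    all_species = [sp for sp, _, _ in species_class]
    n_nga = int(math.floor(config.p_no_genome * len(all_species) + 0.5))
    nga = set(
        rng.choice(all_species, size=n_nga, replace=False) if n_nga else []
    )

    profiles: dict[str, MarkerProfile] = {}
    proteomes: dict[str, list[SequenceRecord]] = {}
    gene_orders: dict[str, GeneOrder] = {}
    marker_gene_ids: dict[str, str] = {}
    taxonomy: dict[str, tuple[str, bool]] = {}
    families: dict[str, str] = {}

    for species, fam, cls in species_class:
        families[species] = fam
        available = species not in nga
        taxonomy[species] = (fam, available)
        if cls == "non":
            markers: tuple[str, ...] = ()
        elif cls == "complete":
            markers = ("nar", "nir", "nor", "nos")
        else:
            markers = _PARTIAL_SUBSETS[int(rng.integers(len(_PARTIAL_SUBSETS)))]
        nir = "nir" in markers
        profiles[species] = MarkerProfile(
            species=species,
            nar="nar" in markers,
            nir=nir,
            nir_type="NirK" if nir else "absent",
            nor="nor" in markers,
            nos="nos" in markers,
        )
        if not available:
            continue

        records: list[SequenceRecord] = []
        enzyme_of: dict[str, str] = {}
        k = 0

        def add_protein(template: SequenceRecord, identity: float, enzyme: str = "") -> None:
            nonlocal k
            k += 1
            gid = f"{species}_p{k:02d}"
            records.append(
                SequenceRecord(
                    id=gid,
                    residues=mutate_to_identity(template.residues, identity, rng),
                )
            )
            if enzyme:
                enzyme_of[gid] = enzyme

        for marker in markers:
            enzyme = _ENZYME_OF_MARKER[marker]
            add_protein(panel.members[enzyme][0], config.identity_true, enzyme)
            if marker == "nar":
                add_protein(panel.members["NarH"][0], config.identity_true, "NarH")
        decoy_templates = panel.records()
        for d in range(config.n_decoys):
            add_protein(decoy_templates[d % len(decoy_templates)], config.identity_decoy)

        marker_gene_ids.update(enzyme_of)
        gene_orders[species] = _lay_out_genes(species, records, enzyme_of, rng)
        proteomes[species] = records

    truth_tree = _random_ultrametric_tree(all_species, config.tree_depth, rng)
    sixteen_s = _evolve_16s(truth_tree, config.seq_length_16s, rng)

    truth = GroundTruth(
        profiles=profiles,
        families=families,
        genome_available={sp: sp not in nga for sp in all_species},
        tree_newick=seqio.write_newick(truth_tree),
        marker_gene_ids=marker_gene_ids,
    )
    return Community(
        config=config,
        panel=panel,
        proteomes=proteomes,
        gene_orders=gene_orders,
        sixteen_s=sixteen_s,
        taxonomy=taxonomy,
        truth=truth,
    )


def _lay_out_genes(
    species: str,
    records: list[SequenceRecord],
    enzyme_of: dict[str, str],
    rng: np.random.Generator,
) -> GeneOrder:
    """Random gene order on one replicon, with narH immediately after narG."""
    narg = next((g for g, e in enzyme_of.items() if e == "NarG"), None)
    narh = next((g for g, e in enzyme_of.items() if e == "NarH"), None)
    ids = [r.id for r in records if r.id != narh]
    order = [ids[i] for i in rng.permutation(len(ids))]
    if narh is not None:
        order.insert(order.index(narg) + 1, narh)
    return GeneOrder(
        species=species,
        entries=[("chr", pos, gid) for pos, gid in enumerate(order)],
    )
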