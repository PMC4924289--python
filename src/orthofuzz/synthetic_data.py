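"""Truth-known synthetic inputs for the homology pipeline.

The generator emulates the study design the pipeline is built for: a
reference species contributes seed proteins; N target species related by
a known tree carry homologues whose presence/absence was generated by a
single origin at the root plus per-branch Bernoulli losses; recent
duplications plant co-orthologues; and the published annotation of each
target genome is corrupted with the pathologies seen in draft genomes
(terminal truncations bracketing the 5 %/15 % refinement-tier
boundaries, one gene split across two models, one model fusing a gene
with its neighbour, or the model missing entirely while the locus
remains in the genome).  Uniform-rate read pileups over each present
protein supply the read-evidence stream.

Genomic loci are single-exon with a fixed 3:1 nucleotide:protein
correspondence and random intergenic spacers — enough to exercise
overlap/split/merge logic without a splice model.  Proteins evolve by
uniform substitution (no indels), with divergence kept low enough that
fuzzy reciprocal BLAST remains comfortably detectable; decoy (non-seed)
genes are planted as negative controls.

Planted losses are drawn conditioned on Dollo-identifiability: a loss
configuration whose event set differs from the canonical
maximal-absent-subtree representation of the leaf pattern it produces
(e.g. two sibling edges lost independently) is indistinguishable from
the canonical one given any presence data, so such draws are rejected
and resampled.  The recorded truth is then exactly the event set an
ideal observer could recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import (
    GeneModel,
    HitRecord,
    SequenceRecord,
    SupportTree,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_newick,
)
from .matrix_phylo import CellTier, GainLossReconstruction, dollo_reconstruct
from .model_reconciliation import OverlapClass, RefinementTier

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per amino acid: 3:1 nucleotide correspondence
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

CORRUPTION_MODES = (
    "intact",
    "truncated_minor",
    "truncated_major",
    "split",
    "merged",
    "model_absent",
)

#: assigned-reconciliation outcomes that count as recovering each planted mode
EXPECTED_ASSIGNMENT = {
    "intact": lambda tier, oclass: tier is RefinementTier.PUBLISHED_OK,
    "truncated_minor": lambda tier, oclass: tier is RefinementTier.MINOR_REFINEMENT,
    "truncated_major": lambda tier, oclass: tier is RefinementTier.MAJOR_REFINEMENT,
    "split": lambda tier, oclass: oclass is OverlapClass.SPLIT,
    "merged": lambda tier, oclass: oclass is OverlapClass.MERGED,
    "model_absent": lambda tier, oclass: tier
    in (RefinementTier.MAJOR_REFINEMENT, RefinementTier.NOVEL),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults reflect a moderate comparative-genomics scenario: a dozen
    target species, a few dozen seed genes, a 5 % per-branch loss
    probability, 5 % recent-duplication probability, half the annotations
    intact with the remainder spread over the corruption pathologies, and
    20x read depth.
    """

    seed: int                                   # RNG seed, mandatory
    n_species: int = 12
    n_genes: int = 40
    tree: SupportTree | None = None             # None -> random topology
    loss_rate: float = 0.05
    duplication_rate: float = 0.05
    corruption_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "intact": 0.5,
            "truncated_minor": 0.15,
            "truncated_major": 0.15,
            "split": 0.1,
            "merged": 0.05,
            "model_absent": 0.05,
        }
    )
    read_depth: float = 20.0
    read_length: int = 33                       # residues (~100 bp)
    mutation_rate: float = 0.02                 # per residue per branch
    duplicate_divergence: float = 0.01          # extra divergence of a recent copy
    decoy_rate: float = 0.25                    # decoy genes per seed gene
    protein_length: tuple[int, int] = (120, 300)
    spacer_length: tuple[int, int] = (200, 400)
    minor_truncation: tuple[float, float] = (0.06, 0.14)
    major_truncation: tuple[float, float] = (0.17, 0.40)
    reference: str = "REF"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("an RNG seed is mandatory")
        if self.n_species < 2 or self.n_genes < 1:
            raise ValidationError("need at least 2 species and 1 gene")
        for name in ("loss_rate", "duplication_rate", "mutation_rate", "decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        unknown = set(self.corruption_mix) - set(CORRUPTION_MODES)
        if unknown:
            raise ValidationError(f"unknown corruption modes: {sorted(unknown)}")
        total = sum(self.corruption_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"corruption mix must sum to 1, got {total}")
        if any(p < 0 for p in self.corruption_mix.values()):
            raise ValidationError("corruption mix probabilities must be non-negative")
        if self.read_depth < 0 or self.read_length < 1:
            raise ValidationError("invalid read parameters")


@dataclass
class TruthSet:
    """A complete synthetic input bundle plus its planted ground truth."""

    config: SimulationConfig
    tree: SupportTree
    species: list[str]
    seeds: list[SequenceRecord]
    genomes: dict[str, str]                        # species -> contig sequence
    annotations: dict[str, list[GeneModel]]        # published models, proteins attached
    proteomes: dict[str, list[SequenceRecord]]     # published proteins (ids = model ids)
    candidates: dict[str, list[GeneModel]]         # predicted models, proteins attached
    reads: dict[str, list[HitRecord]]              # read-vs-seed-protein alignments
    truth_matrix: dict[tuple[str, str], bool]
    truth_tiers: dict[tuple[str, str], str]        # planted corruption mode, present cells
    truth_gainloss: dict[str, GainLossReconstruction]
    truth_coorthologs: set[tuple[str, str]]

    @property
    def gene_ids(self) -> list[str]:
        return [s.id for s in self.seeds]

    def write_bundle(self, out_dir: str | Path) -> Path:
        """Write the full input bundle in standard formats plus truth TSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.seeds, out / "seeds.fasta")
        write_newick(self.tree, out / "tree.nwk")
        for sp in self.species:
            d = out / "species" / sp
            d.mkdir(parents=True, exist_ok=True)
            with open(d / "genome.fasta", "w") as fh:
                fh.write(f">{sp}_contig1\n")
                seq = self.genomes[sp]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
            if self.proteomes[sp]:
                write_fasta(self.proteomes[sp], d / "proteome.fasta")
            write_gff3(self.annotations[sp], d / "published.gff3")
            write_gff3(self.candidates[sp], d / "candidates.gff3")
            cand_prot = [m.protein for m in self.candidates[sp] if m.protein is not None]
            if cand_prot:
                write_fasta(cand_prot, d / "candidate_proteins.fasta")
            write_hit_table(self.reads[sp], d / "reads.tsv")
        t = out / "truth"
        t.mkdir(exist_ok=True)
        rows = [
            {"gene": g, "species": sp, "present": int(self.truth_matrix[(g, sp)])}
            for g in self.gene_ids
            for sp in self.species
        ]
        pd.DataFrame(rows).to_csv(t / "matrix.tsv", sep="\t", index=False)
        rows = [
            {"gene": g, "species": sp, "mode": mode}
            for (g, sp), mode in sorted(self.truth_tiers.items())
        ]
        pd.DataFrame(rows).to_csv(t / "tiers.tsv", sep="\t", index=False)
        with open(t / "gainloss.tsv", "w") as fh:
            fh.write("gene\tgain\tn_losses\tloss_edges\n")
            for g in self.gene_ids:
                r = self.truth_gainloss[g]
                gain = "|".join(sorted(r.gain_leaves)) if r.gain_leaves else "none"
                edges = ";".join("|".join(sorted(e)) for e in r.loss_edges)
                fh.write(f"{g}\t{gain}\t{r.n_losses}\t{edges}\n")
        with open(t / "coorthologs.tsv", "w") as fh:
            fh.write("gene\tspecies\n")
            for g, sp in sorted(self.truth_coorthologs):
                fh.write(f"{g}\t{sp}\n")
        return out


# ---------------------------------------------------------------------------
# helpers


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> SupportTree:
    """A random rooted binary tree over the given leaf labels."""
    nodes = [lab for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return SupportTree.from_newick(nodes[0] + ";")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(residues: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return residues
    out = list(residues)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _encode_cds(residues: str) -> str:
    return "".join(_CODON[c] for c in residues)


def _sample_losses(
    tree: SupportTree,
    loss_rate: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[dict[str, int], GainLossReconstruction]:
    """Draw a presence pattern by per-branch Bernoulli loss below a root gain.

    Rejected and resampled until the planted event set is the canonical
    Dollo representation of the resulting pattern (see module docstring);
    an all-absent pattern is accepted as-is.
    """
    all_leaves = frozenset(tree.leaf_labels())
    for _ in range(max_tries):
        present_at: dict[int, bool] = {id(tree.dtree.seed_node): True}
        events: list[frozenset[str]] = []
        pattern: dict[str, int] = {}
        for node in tree.dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_present = present_at[id(node.parent_node)]
            lost_here = bool(parent_present and rng.random() < loss_rate)
            if lost_here:
                events.append(SupportTree.leaf_set(node))
            present_at[id(node)] = parent_present and not lost_here
            if node.is_leaf():
                pattern[node.taxon.label] = int(present_at[id(node)])
        if not any(pattern.values()):
            # a gene absent from every target is unobservable: no loss event
            # is identifiable, so the canonical truth is the empty history
            return pattern, GainLossReconstruction(gain_leaves=None, loss_edges=())
        recon = dollo_reconstruct(pattern, tree)
        if recon.gain_leaves == all_leaves and set(recon.loss_edges) == set(events):
            return pattern, recon
    raise ValidationError(
        "could not draw a Dollo-identifiable loss configuration; "
        "loss_rate is likely too extreme for this tree"
    )


# ---------------------------------------------------------------------------
# main generator


def simulate(config: SimulationConfig) -> TruthSet:
    """Generate a complete truth-known input bundle.

    Fully deterministic given ``config.seed``: ancestral proteins are
    drawn per gene, presence is evolved down the tree, sequences mutate
    per branch, duplicates and annotation corruptions are planted, and
    read pileups are laid over every present protein.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i + 1:03d}" for i in range(config.n_genes)]
    species = [f"SP{i + 1:02d}" for i in range(config.n_species)]
    tree = config.tree if config.tree is not None else random_topology(species, rng)
    if set(tree.leaf_labels()) != set(species) and config.tree is not None:
        species = sorted(tree.leaf_labels())

    lo, hi = config.protein_length
    lengths = {g: int(rng.integers(lo, hi + 1)) for g in genes}

    # ancestral proteins at the tree root, and the reference (seed) copies
    root_protein = {g: _random_protein(rng, lengths[g]) for g in genes}
    seeds = [
        SequenceRecord(
            id=g,
            residues=_mutate(root_protein[g], config.mutation_rate, rng),
            description=f"{config.reference} seed protein",
        )
        for g in genes
    ]

    # evolve proteins down the tree (preorder, one substitution pass per branch)
    node_seq: dict[int, dict[str, str]] = {id(tree.dtree.seed_node): root_protein}
    leaf_protein: dict[str, dict[str, str]] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node_seq[id(node.parent_node)]
        mine = {g: _mutate(parent[g], config.mutation_rate, rng) for g in genes}
        node_seq[id(node)] = mine
        if node.is_leaf():
            leaf_protein[node.taxon.label] = mine

    # presence/absence with planted, identifiable losses
    truth_matrix: dict[tuple[str, str], bool] = {}
    truth_gainloss: dict[str, GainLossReconstruction] = {}
    for g in genes:
        pattern, recon = _sample_losses(tree, config.loss_rate, rng)
        truth_gainloss[g] = recon
        for sp in species:
            truth_matrix[(g, sp)] = bool(pattern[sp])

    # corruption modes, duplications
    modes = list(config.corruption_mix.keys())
    probs = np.array([config.corruption_mix[m] for m in modes], dtype=float)
    probs = probs / probs.sum()
    truth_tiers: dict[tuple[str, str], str] = {}
    truth_coorthologs: set[tuple[str, str]] = set()
    for sp in species:
        for g in genes:
            if not truth_matrix[(g, sp)]:
                continue
            truth_tiers[(g, sp)] = modes[int(rng.choice(len(modes), p=probs))]
            if rng.random() < config.duplication_rate:
                truth_coorthologs.add((g, sp))

    # per-species genomes, annotations, candidate models, proteomes, reads
    genomes: dict[str, str] = {}
    annotations: dict[str, list[GeneModel]] = {}
    candidates: dict[str, list[GeneModel]] = {}
    proteomes: dict[str, list[SequenceRecord]] = {}
    reads: dict[str, list[HitRecord]] = {}
    n_decoys = int(round(config.decoy_rate * config.n_genes))
    s_lo, s_hi = config.spacer_length

    for sp in species:
        contig = f"{sp}_contig1"
        chunks: list[str] = []
        cursor = 0
        published: list[GeneModel] = []
        cands: list[GeneModel] = []
        prots: list[SequenceRecord] = []
        sp_reads: list[HitRecord] = []

        def place_locus(residues: str) -> tuple[int, int]:
            nonlocal cursor
            spacer = int(rng.integers(s_lo, s_hi + 1))
            chunks.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=spacer)))
            cursor += spacer
            cds = _encode_cds(residues)
            start = cursor
            chunks.append(cds)
            cursor += len(cds)
            return start, cursor

        def add_candidate(stem: str, start: int, end: int, residues: str) -> None:
            cand_id = f"{stem}.cand"
            prot = SequenceRecord(id=cand_id, residues=residues)
            cands.append(
                GeneModel(
                    model_id=cand_id,
                    species=sp,
                    seqid=contig,
                    strand="+",
                    exons=((start, end),),
                    protein=prot,
                    provenance="predicted",
                )
            )

        def add_published(stem: str, exons, residues: str) -> None:
            pub_id = f"{stem}.pub"
            prot = SequenceRecord(id=pub_id, residues=residues)
            published.append(
                GeneModel(
                    model_id=pub_id,
                    species=sp,
                    seqid=contig,
                    strand="+",
                    exons=exons,
                    protein=prot,
                    provenance="published",
                )
            )
            prots.append(prot)

        for g in genes:
            if not truth_matrix[(g, sp)]:
                continue
            residues = leaf_protein[sp][g]
            L = len(residues)
            mode = truth_tiers[(g, sp)]
            start, end = place_locus(residues)
            stem = f"{sp}.{g}"
            add_candidate(stem, start, end, residues)

            if mode == "intact":
                add_published(stem, ((start, end),), residues)
            elif mode in ("truncated_minor", "truncated_major"):
                f_lo, f_hi = (
                    config.minor_truncation
                    if mode == "truncated_minor"
                    else config.major_truncation
                )
                n_cut = int(np.clip(
                    round(float(rng.uniform(f_lo, f_hi)) * L),
                    int(np.ceil((f_lo - 0.005) * L)),
                    int(np.floor((f_hi + 0.005) * L)),
                ))
                n_cut = max(1, min(L - 10, n_cut))
                if rng.random() < 0.5:  # cut the N-terminus
                    kept = residues[n_cut:]
                    exons = ((start + 3 * n_cut, end),)
                else:
                    kept = residues[: L - n_cut]
                    exons = ((start, end - 3 * n_cut),)
                add_published(stem, exons, kept)
            elif mode == "split":
                s1 = max(10, int(round(0.45 * L)))
                s2 = min(L - 10, int(round(0.55 * L)))
                add_published(f"{stem}.a", ((start, start + 3 * s1),), residues[:s1])
                add_published(f"{stem}.b", ((start + 3 * s2, end),), residues[s2:])
            elif mode == "merged":
                # fuse with a freshly planted decoy neighbour (short spacer)
                nbr_len = int(rng.integers(lo, hi + 1))
                nbr_res = _random_protein(rng, nbr_len)
                gap = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
                chunks.append(gap)
                cursor += 30
                nbr_start = cursor
                chunks.append(_encode_cds(nbr_res))
                cursor += 3 * nbr_len
                nbr_end = cursor
                add_candidate(f"{stem}.nbr", nbr_start, nbr_end, nbr_res)
                add_published(stem, ((start, nbr_end),), residues + nbr_res)
            elif mode == "model_absent":
                pass  # locus in genome, candidate emitted, no published model
            else:  # pragma: no cover
                raise AssertionError(mode)

            if (g, sp) in truth_coorthologs:
                dup_res = _mutate(residues, config.duplicate_divergence, rng)
                d_start, d_end = place_locus(dup_res)
                dup_stem = f"{stem}.dup"
                add_candidate(dup_stem, d_start, d_end, dup_res)
                add_published(dup_stem, ((d_start, d_end),), dup_res)

            # read pileup over the seed protein (protein-space intervals)
            rl = min(config.read_length, L)
            n_reads = int(rng.poisson(config.read_depth * L / rl))
            if n_reads:
                starts = rng.integers(1, L - rl + 2, size=n_reads)
                for k, st in enumerate(sorted(starts.tolist())):
                    sp_reads.append(
                        HitRecord(
                            query_id=f"{sp}.{g}.r{k + 1}",
                            subject_id=g,
                            percent_identity=0.95,
                            aln_len=rl,
                            q_start=1,
                            q_end=rl,
                            s_start=int(st),
                            s_end=int(st) + rl - 1,
                            evalue=1e-20,
                            bitscore=60.0,
                        )
                    )

        for k in range(n_decoys):
            dec_len = int(rng.integers(lo, hi + 1))
            dec_res = _random_protein(rng, dec_len)
            d_start, d_end = place_locus(dec_res)
            dec_stem = f"{sp}.dec{k + 1:02d}"
            add_candidate(dec_stem, d_start, d_end, dec_res)
            add_published(dec_stem, ((d_start, d_end),), dec_res)

        genomes[sp] = "".join(chunks)
        annotations[sp] = published
        candidates[sp] = cands
        proteomes[sp] = prots
        reads[sp] = sp_reads

    return TruthSet(
        config=config,
        tree=tree,
        species=species,
        seeds=seeds,
        genomes=genomes,
        annotations=annotations,
        proteomes=proteomes,
        candidates=candidates,
        reads=reads,
        truth_matrix=truth_matrix,
        truth_tiers=truth_tiers,
        truth_gainloss=truth_gainloss,
        truth_coorthologs=truth_coorthologs,
    )


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted truth."""

    cell_accuracy: float
    n_cells: int
    tier_agreement: float
    n_corrupted: int
    tier_confusion: pd.DataFrame
    loss_precision: float
    loss_recall: float
    n_truth_losses: int
    n_inferred_losses: int

    def to_dict(self) -> dict:
        return {
            "cell_accuracy": self.cell_accuracy,
            "n_cells": self.n_cells,
            "tier_agreement": self.tier_agreement,
            "n_corrupted": self.n_corrupted,
            "loss_precision": self.loss_precision,
            "loss_recall": self.loss_recall,
            "n_truth_losses": self.n_truth_losses,
            "n_inferred_losses": self.n_inferred_losses,
        }


def score_recovery(
    truth: TruthSet,
    matrix: pd.DataFrame,
    gainloss: Mapping[str, GainLossReconstruction],
    reconciliation: Mapping[tuple[str, str], tuple[RefinementTier, OverlapClass]] | None = None,
) -> RecoveryReport:
    """Score a pipeline result against the planted truth.

    Presence/absence accuracy is computed cell-wise from the evidence
    matrix; the planted-mode-vs-assigned-tier confusion uses the
    reconciliation assignments (corrupted present cells only; with no
    reconciliation given, matrix tiers stand in); loss-branch precision
    and recall are micro-averaged over genes against the planted events.
    """
    genes = truth.gene_ids
    species = truth.species
    if set(matrix.index) != set(genes) or set(matrix.columns) != set(species):
        raise ValidationError("result matrix universe does not match the truth set")

    n_cells = len(genes) * len(species)
    n_correct = sum(
        1
        for g in genes
        for sp in species
        if matrix.at[g, sp].present == truth.truth_matrix[(g, sp)]
    )

    confusion_rows = []
    n_corrupted = 0
    n_agree = 0
    for (g, sp), mode in sorted(truth.truth_tiers.items()):
        if reconciliation is not None:
            assigned = reconciliation.get((g, sp))
            tier, oclass = assigned if assigned is not None else (None, None)
            ok = (
                tier is not None
                and EXPECTED_ASSIGNMENT[mode](tier, oclass)
            )
            label = tier.value if tier is not None else "none"
            if oclass is not None and oclass in (OverlapClass.SPLIT, OverlapClass.MERGED):
                label += f"+{oclass.value}"
        else:
            cell = matrix.at[g, sp]
            label = cell.value
            ok = {
                "intact": cell is CellTier.PUBLISHED_OK,
                "truncated_minor": cell is CellTier.MINOR_REFINEMENT,
                "truncated_major": cell is CellTier.MAJOR_REFINEMENT,
                "split": cell is CellTier.MAJOR_REFINEMENT,
                "merged": cell is CellTier.PUBLISHED_OK,
                "model_absent": cell is CellTier.MAJOR_REFINEMENT,
            }[mode]
        confusion_rows.append({"mode": mode, "assigned": label, "n": 1})
        if mode != "intact":
            n_corrupted += 1
            n_agree += int(ok)
    confusion = (
        pd.DataFrame(confusion_rows).groupby(["mode", "assigned"]).sum().reset_index()
        if confusion_rows
        else pd.DataFrame(columns=["mode", "assigned", "n"])
    )

    tp = fp = fn = 0
    for g in genes:
        truth_edges = set(truth.truth_gainloss[g].loss_edges)
        inferred = gainloss.get(g)
        inferred_edges = set(inferred.loss_edges) if inferred is not None else set()
        tp += len(truth_edges & inferred_edges)
        fp += len(inferred_edges - truth_edges)
        fn += len(truth_edges - inferred_edges)

    return RecoveryReport(
        cell_accuracy=n_correct / n_cells,
        n_cells=n_cells,
        tier_agreement=(n_agree / n_corrupted) if n_corrupted else 1.0,
        n_corrupted=n_corrupted,
        tier_confusion=confusion,
        loss_precision=tp / (tp + fp) if (tp + fp) else 1.0,
        loss_recall=tp / (tp + fn) if (tp + fn) else 1.0,
        n_truth_losses=tp + fn,
        n_inferred_losses=tp + fp,
    )
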