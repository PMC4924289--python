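"""End-to-end orchestration of the homology-evidence pipeline.

A *bundle* directory holds the inputs in standard formats::

    seeds.fasta                     seed proteins (reference species)
    tree.nwk                        species tree
    species/<SP>/proteome.fasta     published proteins (ids = model ids)
    species/<SP>/published.gff3     published gene models
    species/<SP>/candidates.gff3    externally predicted gene models
    species/<SP>/candidate_proteins.fasta
    species/<SP>/reads.tsv          read-vs-seed-protein alignments (12-col)

Stages communicate exclusively through files in the output directory, so
running :func:`run_all` is exactly equivalent to invoking the stage
functions (or CLI subcommands) in sequence:

    search -> frb -> reconcile -> depth -> matrix -> dollo -> summary

Every stage is deterministic given its inputs; reruns with an identical
bundle and configuration produce byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .alignment_core import ScoringScheme, default_scheme, search_all
from .errors import ConfigurationError, ValidationError
from .formats_io import (
    GeneModel,
    HitRecord,
    SequenceRecord,
    read_fasta,
    read_gff3,
    read_hit_table,
    read_newick,
    write_hit_table,
)
from .frb import FuzzyConfig, HomologyCall, admit_hits, call_species
from .matrix_phylo import (
    GainLossReconstruction,
    build_matrix,
    dollo_reconstruct,
    read_matrix,
    summarize_matrix,
    write_matrix,
)
from .model_reconciliation import (
    CoverageReport,
    OverlapClass,
    RefinementTier,
    classify_refinement,
    detect_merged,
    genomic_overlap,
)
from .read_evidence import consistency_test, coverage_only_verdict, pileup

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the bundle itself."""

    bundle_dir: Path
    out_dir: Path
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    min_bitscore: float = 25.0
    min_shared: int = 30
    minor_delta: float = 0.05
    major_delta: float = 0.15
    min_read_coverage: float = 0.8
    depth_k: float = 3.0

    def __post_init__(self) -> None:
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)
        for name in ("minor_delta", "major_delta", "min_read_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not self.bundle_dir.is_dir():
            raise ConfigurationError(f"bundle directory not found: {self.bundle_dir}")


@dataclass
class SpeciesInputs:
    name: str
    proteome: list[SequenceRecord]
    published: list[GeneModel]
    candidates: list[GeneModel]
    reads: list[HitRecord]


@dataclass
class Bundle:
    seeds: list[SequenceRecord]
    tree: object
    species: list[SpeciesInputs]

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]


def load_bundle(bundle_dir: str | Path) -> Bundle:
    bundle_dir = Path(bundle_dir)
    seeds = read_fasta(bundle_dir / "seeds.fasta")
    tree = read_newick(bundle_dir / "tree.nwk")
    species = []
    species_root = bundle_dir / "species"
    if not species_root.is_dir():
        raise ConfigurationError(f"no species/ directory under {bundle_dir}")
    for d in sorted(p for p in species_root.iterdir() if p.is_dir()):
        name = d.name
        proteome = read_fasta(d / "proteome.fasta") if (d / "proteome.fasta").exists() else []
        prot_by_id = {p.id: p for p in proteome}
        published = read_gff3(d / "published.gff3", species=name)
        for m in published:
            m.protein = prot_by_id.get(m.model_id)
        candidates = read_gff3(d / "candidates.gff3", species=name)
        if (d / "candidate_proteins.fasta").exists():
            cand_prot = {p.id: p for p in read_fasta(d / "candidate_proteins.fasta")}
            for m in candidates:
                m.protein = cand_prot.get(m.model_id)
        reads = read_hit_table(d / "reads.tsv") if (d / "reads.tsv").exists() else []
        species.append(
            SpeciesInputs(
                name=name,
                proteome=proteome,
                published=published,
                candidates=candidates,
                reads=reads,
            )
        )
    if not species:
        raise ConfigurationError(f"no species inputs under {species_root}")
    return Bundle(seeds=seeds, tree=tree, species=species)


# ---------------------------------------------------------------------------
# stage: search


def stage_search(config: RunConfig, scheme: ScoringScheme | None = None) -> None:
    """Internal all-vs-all alignment producing forward/reverse/candidate hits."""
    scheme = scheme or default_scheme()
    bundle = load_bundle(config.bundle_dir)
    hits_dir = config.out_dir / "hits"
    hits_dir.mkdir(parents=True, exist_ok=True)
    for sp in bundle.species:
        fwd = search_all(bundle.seeds, sp.proteome, scheme, config.min_bitscore) if sp.proteome else []
        rev = search_all(sp.proteome, bundle.seeds, scheme, config.min_bitscore) if sp.proteome else []
        cand_prot = [m.protein for m in sp.candidates if m.protein is not None]
        cand = search_all(bundle.seeds, cand_prot, scheme, config.min_bitscore) if cand_prot else []
        write_hit_table(fwd, hits_dir / f"{sp.name}.fwd.tsv")
        write_hit_table(rev, hits_dir / f"{sp.name}.rev.tsv")
        write_hit_table(cand, hits_dir / f"{sp.name}.cand.tsv")


# ---------------------------------------------------------------------------
# stage: frb


def _calls_path(config: RunConfig) -> Path:
    return config.out_dir / "calls.tsv"


def write_calls(calls: Sequence[HomologyCall], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("seed\tspecies\tmembers\tco_orthologous\tsupport\n")
        for c in calls:
            members = ",".join(c.members) if c.members else "-"
            support = ";".join(
                f"{m}:{c.support[m][0]:.1f}:{c.support[m][1]:.1f}" for m in c.members if m in c.support
            )
            fh.write(f"{c.seed_gene}\t{c.species}\t{members}\t{int(c.co_orthologous)}\t{support or '-'}\n")


def read_calls(path: Path) -> list[HomologyCall]:
    calls = []
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    for row in df.itertuples(index=False):
        members = tuple(row.members.split(",")) if row.members != "-" else ()
        support = {}
        if row.support != "-":
            for part in row.support.split(";"):
                m, f, r = part.rsplit(":", 2)
                support[m] = (float(f), float(r))
        calls.append(
            HomologyCall(seed_gene=row.seed, species=row.species, members=members, support=support)
        )
    return calls


def stage_frb(config: RunConfig) -> list[HomologyCall]:
    bundle = load_bundle(config.bundle_dir)
    hits_dir = config.out_dir / "hits"
    all_calls: list[HomologyCall] = []
    for sp in bundle.species:
        fwd = read_hit_table(hits_dir / f"{sp.name}.fwd.tsv")
        rev = read_hit_table(hits_dir / f"{sp.name}.rev.tsv")
        all_calls.extend(
            call_species(
                bundle.seeds, sp.proteome, sp.name, config.fuzzy, hit_source=(fwd, rev)
            )
        )
    write_calls(all_calls, _calls_path(config))
    return all_calls


# ---------------------------------------------------------------------------
# stage: reconcile


def reconcile_cell(
    seed: SequenceRecord,
    species: SpeciesInputs,
    fwd_hits: Sequence[HitRecord],
    cand_hits: Sequence[HitRecord],
    call: HomologyCall,
    config: RunConfig,
) -> tuple[RefinementTier, OverlapClass, float, str] | None:
    """Best-evidence refinement assignment for one (seed, species) cell.

    Returns (tier, overlap class, coverage delta, best model id), or None
    when neither a published match nor a candidate model exists.
    """
    pub_by_id = {m.model_id: m for m in species.published}
    cand_by_id = {m.model_id: m for m in species.candidates}
    seed_len = len(seed)

    pub_matched: list[tuple[GeneModel, CoverageReport]] = []
    for h in fwd_hits:
        m = pub_by_id.get(h.subject_id)
        if m is None:
            continue
        pub_matched.append(
            (m, CoverageReport(m.model_id, seed.id, min(1.0, h.query_span / seed_len), h.bitscore))
        )
    cand_matched: list[tuple[GeneModel, CoverageReport]] = []
    for h in cand_hits:
        m = cand_by_id.get(h.subject_id)
        if m is None:
            continue
        cand_matched.append(
            (m, CoverageReport(m.model_id, seed.id, min(1.0, h.query_span / seed_len), h.bitscore))
        )

    if not cand_matched:
        if call.positive and pub_matched:
            best = max(pub_matched, key=lambda mr: (mr[1].bitscore, mr[0].model_id))
            return RefinementTier.PUBLISHED_OK, OverlapClass.ONE_TO_ONE, 0.0, best[0].model_id
        return None

    cand_matched.sort(key=lambda mr: (-mr[1].bitscore, mr[0].model_id))
    best_model, best_report = cand_matched[0]
    tier, oclass = classify_refinement(
        best_report,
        pub_matched,
        overlap_fn=lambda m: genomic_overlap(best_model, m),
        min_shared=config.min_shared,
        minor_delta=config.minor_delta,
        major_delta=config.major_delta,
    )
    delta = float("nan")
    if oclass is OverlapClass.ONE_TO_ONE:
        overlapped = [
            (m, r)
            for m, r in pub_matched
            if genomic_overlap(best_model, m) >= config.min_shared
        ]
        pub_model, pub_report = overlapped[0]
        delta = best_report.coverage - pub_report.coverage
        if detect_merged(pub_model, species.candidates, config.min_shared) is OverlapClass.MERGED:
            oclass = OverlapClass.MERGED
    return tier, oclass, delta, best_model.model_id


def write_reconciliation(rows: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("seed\tspecies\tmodel_id\ttier\toverlap_class\tdelta_coverage\n")
        for r in rows:
            delta = "nan" if math.isnan(r["delta_coverage"]) else f"{r['delta_coverage']:.4f}"
            fh.write(
                f"{r['seed']}\t{r['species']}\t{r['model_id']}\t{r['tier']}\t{r['overlap_class']}\t{delta}\n"
            )


def read_reconciliation(path: Path) -> dict[tuple[str, str], tuple[RefinementTier, OverlapClass]]:
    out = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for row in df.itertuples(index=False):
        out[(row.seed, row.species)] = (
            RefinementTier(row.tier),
            OverlapClass(row.overlap_class),
        )
    return out


def stage_reconcile(config: RunConfig) -> dict[tuple[str, str], tuple[RefinementTier, OverlapClass]]:
    bundle = load_bundle(config.bundle_dir)
    hits_dir = config.out_dir / "hits"
    calls = {(c.seed_gene, c.species): c for c in read_calls(_calls_path(config))}
    seed_lengths = {s.id: len(s) for s in bundle.seeds}
    rows = []
    assignments: dict[tuple[str, str], tuple[RefinementTier, OverlapClass]] = {}
    for sp in bundle.species:
        fwd = read_hit_table(hits_dir / f"{sp.name}.fwd.tsv")
        cand = read_hit_table(hits_dir / f"{sp.name}.cand.tsv")
        fwd = admit_hits(fwd, seed_lengths, config.fuzzy)
        cand = admit_hits(cand, seed_lengths, config.fuzzy)
        fwd_by_seed: dict[str, list[HitRecord]] = {}
        for h in fwd:
            fwd_by_seed.setdefault(h.query_id, []).append(h)
        cand_by_seed: dict[str, list[HitRecord]] = {}
        for h in cand:
            cand_by_seed.setdefault(h.query_id, []).append(h)
        for seed in bundle.seeds:
            call = calls.get(
                (seed.id, sp.name),
                HomologyCall(seed_gene=seed.id, species=sp.name, members=()),
            )
            result = reconcile_cell(
                seed,
                sp,
                fwd_by_seed.get(seed.id, []),
                cand_by_seed.get(seed.id, []),
                call,
                config,
            )
            if result is None:
                continue
            tier, oclass, delta, model_id = result
            assignments[(seed.id, sp.name)] = (tier, oclass)
            rows.append(
                {
                    "seed": seed.id,
                    "species": sp.name,
                    "model_id": model_id,
                    "tier": tier.value,
                    "overlap_class": oclass.value,
                    "delta_coverage": delta,
                }
            )
    write_reconciliation(rows, config.out_dir / "reconciliation.tsv")
    return assignments


# ---------------------------------------------------------------------------
# stage: read depth


def stage_depth(config: RunConfig) -> list:
    bundle = load_bundle(config.bundle_dir)
    calls = {(c.seed_gene, c.species): c for c in read_calls(_calls_path(config))}
    verdicts = []
    rows = []
    for sp in bundle.species:
        by_gene: dict[str, list[HitRecord]] = {}
        for h in sp.reads:
            by_gene.setdefault(h.subject_id, []).append(h)
        seed_by_id = {s.id: s for s in bundle.seeds}
        profiles = {
            g: pileup(hits, g, sp.name, len(seed_by_id[g]))
            for g, hits in sorted(by_gene.items())
            if g in seed_by_id
        }
        confirmed = {
            g for g in profiles if calls.get((g, sp.name)) and calls[(g, sp.name)].positive
        }
        for g, profile in profiles.items():
            reference = [profiles[r] for r in sorted(confirmed - {g})]
            if reference:
                v = consistency_test(
                    profile, reference, config.min_read_coverage, config.depth_k
                )
            else:
                v = coverage_only_verdict(profile, config.min_read_coverage)
            verdicts.append(v)
            rows.append(
                {
                    "seed": g,
                    "species": sp.name,
                    "coverage": f"{profile.coverage:.4f}",
                    "median_depth": f"{profile.median_depth:.1f}",
                    "z_like": "nan" if math.isnan(v.z_like) else f"{v.z_like:.3f}",
                    "supported": int(v.supported),
                }
            )
    with open(config.out_dir / "verdicts.tsv", "w") as fh:
        fh.write("seed\tspecies\tcoverage\tmedian_depth\tz_like\tsupported\n")
        for r in rows:
            fh.write(
                f"{r['seed']}\t{r['species']}\t{r['coverage']}\t{r['median_depth']}\t{r['z_like']}\t{r['supported']}\n"
            )
    return verdicts


def read_verdicts(path: Path):
    from .read_evidence import ConsistencyVerdict

    out = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for row in df.itertuples(index=False):
        out.append(
            ConsistencyVerdict(
                seed_gene=row.seed,
                species=row.species,
                supported=bool(int(row.supported)),
                z_like=float(row.z_like),
                reference_median=float("nan"),
                reference_mad=float("nan"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage: matrix, dollo, summary


def stage_matrix(config: RunConfig) -> pd.DataFrame:
    bundle = load_bundle(config.bundle_dir)
    calls = read_calls(_calls_path(config))
    tiers = read_reconciliation(config.out_dir / "reconciliation.tsv")
    verdicts = read_verdicts(config.out_dir / "verdicts.tsv")
    matrix = build_matrix(
        calls,
        {k: t for k, (t, _c) in tiers.items()},
        verdicts,
        genes=[s.id for s in bundle.seeds],
        species=bundle.species_names,
    )
    write_matrix(matrix, config.out_dir / "matrix.tsv")
    return matrix


def stage_dollo(config: RunConfig) -> dict[str, GainLossReconstruction]:
    bundle = load_bundle(config.bundle_dir)
    matrix = read_matrix(config.out_dir / "matrix.tsv")
    out: dict[str, GainLossReconstruction] = {}
    with open(config.out_dir / "gainloss.tsv", "w") as fh:
        fh.write("gene\tgain\tn_losses\tloss_edges\n")
        for g in matrix.index:
            presence = {sp: int(matrix.at[g, sp].present) for sp in matrix.columns}
            recon = dollo_reconstruct(presence, bundle.tree)
            out[g] = recon
            gain = "|".join(sorted(recon.gain_leaves)) if recon.gain_leaves else "none"
            edges = ";".join("|".join(sorted(e)) for e in recon.loss_edges)
            fh.write(f"{g}\t{gain}\t{recon.n_losses}\t{edges}\n")
    return out


def read_gainloss(path: Path) -> dict[str, GainLossReconstruction]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, gain, n_losses, edges = (line.rstrip("\n").split("\t") + [""])[:4]
            gain_set = frozenset(gain.split("|")) if gain != "none" else None
            loss = tuple(
                frozenset(e.split("|")) for e in edges.split(";") if e
            )
            out[gene] = GainLossReconstruction(gain_leaves=gain_set, loss_edges=loss)
    return out


def stage_summary(config: RunConfig, groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    matrix = read_matrix(config.out_dir / "matrix.tsv")
    summary = summarize_matrix(matrix, groups)
    summary.to_csv(config.out_dir / "summary.tsv", sep="\t", float_format="%.4f")
    return summary


# ---------------------------------------------------------------------------
# run-all


@dataclass
class PipelineResult:
    config: RunConfig
    calls: list[HomologyCall]
    reconciliation: dict[tuple[str, str], tuple[RefinementTier, OverlapClass]]
    verdicts: list
    matrix: pd.DataFrame
    gainloss: dict[str, GainLossReconstruction]
    summary: pd.DataFrame


def run_all(config: RunConfig, scheme: ScoringScheme | None = None) -> PipelineResult:
    """Execute every stage in sequence, persisting all intermediate files."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    stage_search(config, scheme)
    calls = stage_frb(config)
    reconciliation = stage_reconcile(config)
    verdicts = stage_depth(config)
    matrix = stage_matrix(config)
    gainloss = stage_dollo(config)
    summary = stage_summary(config)
    manifest = {
        "orthofuzz_version": __version__,
        "bundle_dir": str(config.bundle_dir),
        "fuzzy": {
            "fuzz": config.fuzzy.fuzz,
            "max_evalue": config.fuzzy.max_evalue,
            "min_query_coverage": config.fuzzy.min_query_coverage,
        },
        "min_bitscore": config.min_bitscore,
        "min_shared": config.min_shared,
        "minor_delta": config.minor_delta,
        "major_delta": config.major_delta,
        "min_read_coverage": config.min_read_coverage,
        "depth_k": config.depth_k,
    }
    with open(config.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        config=config,
        calls=calls,
        reconciliation=reconciliation,
        verdicts=verdicts,
        matrix=matrix,
        gainloss=gainloss,
        summary=summary,
    )
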