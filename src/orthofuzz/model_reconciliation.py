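"""Refinement tiers for newly predicted gene models vs published annotations.

Draft-genome annotations exhibit recurring pathologies: missing coding
regions, one true gene split across several published models, or one
published model fusing several true genes.  When a protein-to-genome
prediction overlaps published models, both are aligned back to the seed
protein and compared by how much of the seed each covers:

* new coverage at least 15 percentage points greater  -> major refinement
* at least 5 but less than 15 points greater          -> minor refinement
* less than 5 points greater                          -> published model stands

A prediction overlapping two or more published models is a major
refinement with overlap class ``split``; overlapping none, it is a major
refinement (``novel`` when no published model matched the seed at all).
Coverage deltas are absolute percentage points with inclusive
thresholds.  Genomic overlap requires the same contig and strand;
antisense overlaps are distinct loci.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

from .alignment_core import LocalAlignment
from .errors import ValidationError
from .formats_io import GeneModel


class RefinementTier(enum.Enum):
    PUBLISHED_OK = "published_ok"
    MINOR_REFINEMENT = "minor_refinement"
    MAJOR_REFINEMENT = "major_refinement"
    NOVEL = "novel"

    @property
    def rank(self) -> int:
        """Best-case order: published_ok > minor > major > novel."""
        return {"published_ok": 3, "minor_refinement": 2, "major_refinement": 1, "novel": 0}[self.value]


class OverlapClass(enum.Enum):
    ONE_TO_ONE = "one_to_one"
    SPLIT = "split"          # one true gene spread over multiple published models
    MERGED = "merged"        # one published model containing multiple true genes
    NONE = "none"


@dataclass
class CoverageReport:
    """Seed-protein coverage achieved by one gene model's product."""

    model_id: str
    seed_gene: str
    coverage: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError(
                f"coverage for {self.model_id} vs {self.seed_gene} outside [0,1]: {self.coverage}"
            )


def alignment_coverage(aln: LocalAlignment, seed_length: int) -> float:
    """Fraction of the seed protein covered by the alignment's query interval."""
    if seed_length < 1:
        raise ValidationError("seed_length must be >= 1")
    if aln.q_interval is None:
        return 0.0
    q_start, q_end = aln.q_interval
    if q_start < 1 or q_end > seed_length:
        raise ValidationError(
            f"alignment interval {aln.q_interval} outside seed bounds [1, {seed_length}]"
        )
    return min(1.0, (q_end - q_start + 1) / seed_length)


def genomic_overlap(a: GeneModel, b: GeneModel) -> int:
    """Total exonic bases shared by two models (0 across contigs/strands)."""
    if a.seqid != b.seqid or a.strand != b.strand:
        return 0
    shared = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            shared += max(0, min(e1, e2) - max(s1, s2))
    return shared


def classify_refinement(
    new: CoverageReport,
    published: Sequence[tuple[GeneModel, CoverageReport]],
    overlap_fn: Callable[[GeneModel], int],
    min_shared: int = 30,
    minor_delta: float = 0.05,
    major_delta: float = 0.15,
) -> tuple[RefinementTier, OverlapClass]:
    """Assign the refinement tier of a new model against published models.

    ``published`` lists the published models that matched the same seed,
    with their own seed-coverage reports; ``overlap_fn`` maps a published
    model to the number of exonic bases it shares with the new model.
    The result is invariant to the order of the published list.
    """
    if min_shared < 1:
        raise ValidationError("min_shared must be >= 1")
    if not published:
        return RefinementTier.NOVEL, OverlapClass.NONE
    overlapping = [(m, r) for m, r in published if overlap_fn(m) >= min_shared]
    if not overlapping:
        return RefinementTier.MAJOR_REFINEMENT, OverlapClass.NONE
    if len(overlapping) >= 2:
        return RefinementTier.MAJOR_REFINEMENT, OverlapClass.SPLIT
    _, pub_report = overlapping[0]
    delta = new.coverage - pub_report.coverage
    # thresholds are inclusive; the epsilon keeps them inclusive under the
    # rounding noise of float coverage arithmetic
    eps = 1e-9
    if delta >= major_delta - eps:
        return RefinementTier.MAJOR_REFINEMENT, OverlapClass.ONE_TO_ONE
    if delta >= minor_delta - eps:
        return RefinementTier.MINOR_REFINEMENT, OverlapClass.ONE_TO_ONE
    return RefinementTier.PUBLISHED_OK, OverlapClass.ONE_TO_ONE


def detect_merged(
    published: GeneModel,
    new_models: Sequence[GeneModel],
    min_shared: int = 30,
) -> OverlapClass:
    """Detect a published model that fuses several true genes.

    ``merged`` iff at least two distinct new models each share at least
    ``min_shared`` exonic bases with the published model.
    """
    if min_shared < 1:
        raise ValidationError("min_shared must be >= 1")
    n = sum(
        1
        for m in new_models
        if m.model_id != published.model_id and genomic_overlap(published, m) >= min_shared
    )
    if n >= 2:
        return OverlapClass.MERGED
    if n == 1:
        return OverlapClass.ONE_TO_ONE
    return OverlapClass.NONE
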