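"""Read-depth rescue of genes missing from assemblies or annotations.

When a homologue cannot be found in the gene models or the assembled
genome, raw sequencing reads aligned against the seed protein can still
reveal its presence.  This module piles protein-space read alignments
into per-residue depth profiles and tests whether a candidate profile
has depth and coverage consistent with the confirmed homologues of the
same species: a candidate is *supported* when its breadth of coverage
reaches ``min_coverage`` and its median depth lies within ``depth_k``
median-absolute-deviations of the reference median (MAD floored at 1 so
that perfectly uniform references do not degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .formats_io import HitRecord


@dataclass
class DepthProfile:
    """Per-residue read depth over one seed protein in one species."""

    seed_gene: str
    species: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or len(self.depth) < 1:
            raise ValidationError("depth must be a non-empty 1-d vector")
        if (self.depth < 0).any():
            raise ValidationError("depth values must be non-negative")

    @property
    def coverage(self) -> float:
        """Fraction of seed positions with depth >= 1."""
        return float((self.depth >= 1).mean())

    @property
    def median_depth(self) -> float:
        return float(np.median(self.depth))


@dataclass
class ConsistencyVerdict:
    """Outcome of the depth/coverage consistency test for one candidate."""

    seed_gene: str
    species: str
    supported: bool
    z_like: float
    reference_median: float
    reference_mad: float


def pileup(
    read_hits: Sequence[HitRecord],
    seed_gene: str,
    species: str,
    seed_length: int,
) -> DepthProfile:
    """Stack read-vs-protein alignments into a depth profile.

    ``depth[i]`` counts the read hits whose subject interval covers seed
    position i+1; the result is invariant to read order.
    """
    if seed_length < 1:
        raise ValidationError("seed_length must be >= 1")
    diff = np.zeros(seed_length + 1, dtype=np.int64)
    for h in read_hits:
        if h.s_start < 1 or h.s_end > seed_length:
            raise ValidationError(
                f"read {h.query_id}: subject interval {h.s_start}..{h.s_end} outside "
                f"[1, {seed_length}]"
            )
        diff[h.s_start - 1] += 1
        diff[h.s_end] -= 1
    depth = np.cumsum(diff[:-1])
    return DepthProfile(seed_gene=seed_gene, species=species, depth=depth)


def consistency_test(
    candidate: DepthProfile,
    reference: Sequence[DepthProfile],
    min_coverage: float = 0.8,
    depth_k: float = 3.0,
) -> ConsistencyVerdict:
    """Judge whether a candidate profile matches confirmed homologues.

    ``reference`` must hold profiles of confirmed homologues of the same
    species; when empty, a :class:`ConfigurationError` instructs falling
    back to a coverage-only rule.
    """
    if not reference:
        raise ConfigurationError(
            "consistency_test needs at least one confirmed reference profile; "
            "with none available fall back to the coverage-only rule "
            "(supported iff coverage >= min_coverage)"
        )
    medians = np.array([r.median_depth for r in reference], dtype=float)
    ref_median = float(np.median(medians))
    ref_mad = float(np.median(np.abs(medians - ref_median)))
    ref_mad = max(ref_mad, 1.0)
    z = (candidate.median_depth - ref_median) / ref_mad
    supported = candidate.coverage >= min_coverage and abs(z) <= depth_k
    return ConsistencyVerdict(
        seed_gene=candidate.seed_gene,
        species=candidate.species,
        supported=supported,
        z_like=float(z),
        reference_median=ref_median,
        reference_mad=ref_mad,
    )


def coverage_only_verdict(candidate: DepthProfile, min_coverage: float = 0.8) -> ConsistencyVerdict:
    """Fallback rule when no confirmed reference profiles exist."""
    return ConsistencyVerdict(
        seed_gene=candidate.seed_gene,
        species=candidate.species,
        supported=candidate.coverage >= min_coverage,
        z_like=float("nan"),
        reference_median=float("nan"),
        reference_mad=float("nan"),
    )
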