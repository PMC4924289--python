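"""Fuzzy reciprocal best-hit (FRB) homology assignment.

Classical reciprocal best-hit orthology requires a unique mutual best
hit.  FRB relaxes this: every subject whose bitscore is within a factor
``f`` of the best hit qualifies, in both search directions.  A seed gene
and a subject are called homologous when the subject lies in the seed's
fuzzy forward set *and* the seed lies in the subject's fuzzy reverse
set.  Two or more members for one seed in one species indicate a recent
duplication — a co-orthologous relationship.

Fuzziness operates on bitscores (length-stable and comparable across
databases), not E-values.  The fuzz factor defaults to 0.9 of the best
bitscore and is logged on every run; permissive E-value and
query-coverage pre-filters admit hits before the reciprocal test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment_core import ScoringScheme, search_all
from .errors import ValidationError
from .formats_io import HitRecord, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FuzzyConfig:
    """Parameters of the fuzzy reciprocal test.

    fuzz : a subject qualifies when its bitscore >= fuzz * best bitscore.
    max_evalue, min_query_coverage : permissive hit-admission pre-filters
    applied to both directions before the reciprocal test; final judgement
    on borderline homologues is deferred to model reconciliation and read
    evidence, so these only need to exclude noise.
    """

    fuzz: float = 0.9
    max_evalue: float = 1e-5
    min_query_coverage: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.fuzz <= 1.0:
            raise ValidationError("fuzz factor must lie in (0, 1]")
        if self.max_evalue < 0:
            raise ValidationError("max_evalue must be non-negative")
        if not 0.0 <= self.min_query_coverage <= 1.0:
            raise ValidationError("min_query_coverage must lie in [0, 1]")


@dataclass
class HomologyCall:
    """Outcome of the FRB test for one (seed gene, species) pair."""

    seed_gene: str
    species: str
    members: tuple[str, ...]                       # sorted subject tokens
    support: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = tuple(sorted(self.members))

    @property
    def positive(self) -> bool:
        return len(self.members) > 0

    @property
    def co_orthologous(self) -> bool:
        return len(self.members) >= 2


def admit_hits(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    config: FuzzyConfig,
) -> list[HitRecord]:
    """Apply the E-value and query-coverage admission filters."""
    out = []
    for h in hits:
        if h.evalue > config.max_evalue:
            continue
        qlen = query_lengths.get(h.query_id)
        if qlen is None:
            raise ValidationError(f"no length known for query {h.query_id!r}")
        if h.query_span / qlen < config.min_query_coverage:
            continue
        out.append(h)
    return out


def fuzzy_set(hits: Sequence[HitRecord], fuzz: float) -> set[str]:
    """Subjects whose (best) bitscore is within ``fuzz`` of the top hit.

    All hits must share one query id; an empty hit list gives an empty set.
    """
    if not 0.0 < fuzz <= 1.0:
        raise ValidationError("fuzz factor must lie in (0, 1]")
    if not hits:
        return set()
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValidationError(f"fuzzy_set requires hits of a single query, got {sorted(queries)}")
    best_per_subject: dict[str, float] = {}
    for h in hits:
        prev = best_per_subject.get(h.subject_id)
        if prev is None or h.bitscore > prev:
            best_per_subject[h.subject_id] = h.bitscore
    top = max(best_per_subject.values())
    return {s for s, b in best_per_subject.items() if b >= fuzz * top}


def fuzzy_reciprocal_best(
    seed_id: str,
    species: str,
    forward: Sequence[HitRecord],
    reverse: Sequence[HitRecord],
    config: FuzzyConfig,
) -> HomologyCall:
    """Evaluate the FRB membership test for one seed against one species.

    ``forward`` holds the seed's hits against the species proteome,
    ``reverse`` the species proteome's hits against the whole seed
    proteome; both are expected to be admission-filtered already.  A
    subject is a member iff it is in the seed's fuzzy forward set and the
    seed is in the subject's fuzzy reverse set.
    """
    fwd = [h for h in forward if h.query_id == seed_id]
    fwd_set = fuzzy_set(fwd, config.fuzz)
    rev_by_query: dict[str, list[HitRecord]] = {}
    for h in reverse:
        rev_by_query.setdefault(h.query_id, []).append(h)

    members: list[str] = []
    support: dict[str, tuple[float, float]] = {}
    fwd_best = {h.subject_id: h.bitscore for h in sorted(fwd, key=lambda h: h.bitscore)}
    for subject in sorted(fwd_set):
        rev_hits = rev_by_query.get(subject, [])
        if seed_id in fuzzy_set(rev_hits, config.fuzz):
            members.append(subject)
            rev_best = max(h.bitscore for h in rev_hits if h.subject_id == seed_id)
            support[subject] = (fwd_best[subject], rev_best)
    return HomologyCall(seed_gene=seed_id, species=species, members=tuple(members), support=support)


def call_species(
    seeds: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    species: str,
    config: FuzzyConfig,
    hit_source: tuple[Sequence[HitRecord], Sequence[HitRecord]] | None = None,
    scheme: ScoringScheme | None = None,
) -> list[HomologyCall]:
    """One FRB homology call per seed gene against one species proteome.

    ``hit_source`` supplies pre-computed (forward, reverse) tables; when
    None the internal aligner is used.  The result is deterministic given
    the inputs: exactly one call per seed, in seed order.  A seed absent
    from the forward table yields a negative call with a logged warning.
    """
    logger.info(
        "FRB on species %s: fuzz=%.3g max_evalue=%.3g min_query_coverage=%.3g",
        species, config.fuzz, config.max_evalue, config.min_query_coverage,
    )
    if hit_source is None:
        if proteome:
            forward = search_all(seeds, proteome, scheme)
            reverse = search_all(proteome, seeds, scheme)
        else:
            forward, reverse = [], []
    else:
        forward, reverse = hit_source
    seed_lengths = {s.id: len(s) for s in seeds}
    prot_lengths = {p.id: len(p) for p in proteome}
    forward = admit_hits(forward, seed_lengths, config)
    reverse = admit_hits(reverse, prot_lengths, config)

    calls = []
    forward_ids = {h.query_id for h in forward}
    for seed in seeds:
        if seed.id not in forward_ids:
            logger.warning("seed %s has no admitted forward hits against %s", seed.id, species)
            calls.append(HomologyCall(seed_gene=seed.id, species=species, members=()))
            continue
        calls.append(fuzzy_reciprocal_best(seed.id, species, forward, reverse, config))
    return calls
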