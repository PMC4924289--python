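"""Deterministic local protein alignment (Smith-Waterman, affine gaps).

This lets the pipeline run with zero external search tools and serves as
the oracle against which externally supplied hit tables are
interchangeable.  Scoring follows the standard protein-search
parameterisation: BLOSUM62, gap open -11, gap extend -1, and the gapped
Karlin-Altschul constants lambda = 0.267, K = 0.041 so that internal
bitscores are commensurate with external tabular hits:

    bitscore = (lambda * S - ln K) / ln 2
    E        = K * m * n * exp(-lambda * S)

A gap of length g scores ``gap_open + g * gap_extend`` (so the first gap
residue costs open + extend, as in BLAST's parameter convention).

Traceback tie-breaking is fixed — prefer diagonal, then up (query
residue against a gap), then left — and the highest-scoring cell is the
first in row-major order, so alignments are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .errors import ValidationError
from .formats_io import PROTEIN_ALPHABET, HitRecord, SequenceRecord

_LN2 = math.log(2.0)


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine-gap and bitscore constants."""

    matrix: np.ndarray          # len(alphabet) x len(alphabet), int32, symmetric
    alphabet: str = PROTEIN_ALPHABET
    gap_open: int = -11
    gap_extend: int = -1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        n = len(self.alphabet)
        if self.matrix.shape != (n, n):
            raise ValidationError("substitution matrix does not match alphabet size")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValidationError("substitution matrix must be symmetric")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValidationError("require gap_open <= gap_extend < 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValidationError("Karlin-Altschul constants must be positive")
        self._index = {c: i for i, c in enumerate(self.alphabet)}

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.fromiter(
                (self._index[c] for c in residues), dtype=np.int8, count=len(residues)
            )
        except KeyError as exc:
            raise ValidationError(f"residue outside alphabet: {exc.args[0]!r}") from exc

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / _LN2

    def evalue(self, raw_score: float, query_len: int, db_len: int) -> float:
        return self.K * query_len * db_len * math.exp(-self.lam * raw_score)


@lru_cache(maxsize=1)
def default_scheme() -> ScoringScheme:
    """BLOSUM62 with gap open -11 / extend -1 (cached singleton)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    m = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            m[i, j] = int(blosum[a, b])
    return ScoringScheme(matrix=m)


@dataclass
class LocalAlignment:
    """One optimal local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    q_interval: tuple[int, int] | None   # 1-based inclusive, None when empty
    s_interval: tuple[int, int] | None
    identity: float                      # identical columns / all columns
    n_columns: int
    n_identical: int
    n_gap_openings: int

    @property
    def is_empty(self) -> bool:
        return self.raw_score == 0


@njit(cache=False)
def _sw_kernel(q, s, sub, go, ge):  # pragma: no cover - exercised via smith_waterman
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + go + ge
            e_ext = E[i, j - 1] + ge
            E[i, j] = e_open if e_open >= e_ext else e_ext
            f_open = H[i - 1, j] + go + ge
            f_ext = F[i - 1, j] + ge
            F[i, j] = f_open if f_open >= f_ext else f_ext
            diag = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            h = diag
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj); preference diagonal > up > left, and gaps
    # close as early as possible.  Columns are emitted in reverse order:
    # codes per column: 0 = aligned pair, 1 = query residue vs gap (up),
    # 2 = gap vs subject residue (left).
    max_cols = m + n
    ops = np.empty(max_cols, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F(up run), 2=E(left run)
    while best > 0 and (i > 0 or j > 0):
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and h == F[i, j]:
                state = 1
            elif j > 0 and h == E[i, j]:
                state = 2
            else:
                break
        elif state == 1:
            ops[k] = 1
            k += 1
            if F[i, j] == H[i - 1, j] + go + ge:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] + go + ge:
                state = 0
            j -= 1
    return best, bi, bj, i, j, ops[:k]


def smith_waterman(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> LocalAlignment:
    """Optimal local alignment of two protein sequences under affine gaps.

    Returns a zero-score, empty-interval alignment when no positive-scoring
    local alignment exists.
    """
    scheme = scheme or default_scheme()
    q = scheme.encode(query.residues)
    s = scheme.encode(subject.residues)
    raw, bi, bj, ti, tj, ops = _sw_kernel(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    raw = int(raw)
    if raw <= 0:
        return LocalAlignment(
            query_id=query.id,
            subject_id=subject.id,
            raw_score=0,
            bitscore=scheme.bitscore(0),
            q_interval=None,
            s_interval=None,
            identity=0.0,
            n_columns=0,
            n_identical=0,
            n_gap_openings=0,
        )
    n_cols = len(ops)
    n_ident = 0
    n_gap_open = 0
    prev = -1
    qi, sj = ti, tj
    for op in ops[::-1]:
        if op == 0:
            if q[qi] == s[sj]:
                n_ident += 1
            qi += 1
            sj += 1
        elif op == 1:
            if prev != 1:
                n_gap_open += 1
            qi += 1
        else:
            if prev != 2:
                n_gap_open += 1
            sj += 1
        prev = op
    return LocalAlignment(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=raw,
        bitscore=scheme.bitscore(raw),
        q_interval=(ti + 1, bi),
        s_interval=(tj + 1, bj),
        identity=n_ident / n_cols,
        n_columns=n_cols,
        n_identical=n_ident,
        n_gap_openings=n_gap_open,
    )


def alignment_to_hit(aln: LocalAlignment, scheme: ScoringScheme, db_len: int, query_len: int) -> HitRecord:
    """Express a non-empty local alignment as a 12-column tabular hit."""
    if aln.is_empty:
        raise ValidationError("cannot convert an empty alignment to a hit record")
    q_span = aln.q_interval[1] - aln.q_interval[0] + 1
    s_span = aln.s_interval[1] - aln.s_interval[0] + 1
    n_pairs = q_span + s_span - aln.n_columns
    return HitRecord(
        query_id=aln.query_id,
        subject_id=aln.subject_id,
        percent_identity=aln.identity,
        aln_len=aln.n_columns,
        mismatch=n_pairs - aln.n_identical,
        gapopen=aln.n_gap_openings,
        q_start=aln.q_interval[0],
        q_end=aln.q_interval[1],
        s_start=aln.s_interval[0],
        s_end=aln.s_interval[1],
        evalue=scheme.evalue(aln.raw_score, query_len, db_len),
        bitscore=aln.bitscore,
    )


def search_all(
    queries: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    min_bitscore: float = 25.0,
) -> list[HitRecord]:
    """Align every query against every proteome member.

    Hits below ``min_bitscore`` are dropped; per query, hits are sorted by
    descending bitscore then subject id.
    """
    if not proteome:
        raise ValidationError("search_all requires a non-empty proteome")
    scheme = scheme or default_scheme()
    db_len = sum(len(p) for p in proteome)
    out: list[HitRecord] = []
    for query in queries:
        hits: list[HitRecord] = []
        for subject in proteome:
            aln = smith_waterman(query, subject, scheme)
            if aln.is_empty or aln.bitscore < min_bitscore:
                continue
            hits.append(alignment_to_hit(aln, scheme, db_len, len(query)))
        hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
        out.extend(hits)
    return out
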