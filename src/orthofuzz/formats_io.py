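"""Readers and writers for the external formats the pipeline touches.

Dialects are fixed so results are bit-reproducible:

* protein FASTA over the 20-letter amino-acid alphabet plus ``X``;
* 12-column BLAST tabular hit tables (``qseqid sseqid pident length
  mismatch gapopen qstart qend sstart send evalue bitscore``);
* GFF3 with ``gene``/``mRNA``/``CDS`` features;
* Newick with numeric internal-node labels read as branch support.

Internally all genomic coordinates are 0-based half-open; the file
interfaces convert at the boundary (GFF3 and BLAST tabular are 1-based
inclusive).  Exon intervals are always stored on the forward-strand
coordinate system with strand carried as a flag, so interval arithmetic
is strand-agnostic.

Readers reject rather than silently repair malformed records, and error
messages carry line numbers where the format is line-oriented.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, ValidationError

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHABET_SET = frozenset(PROTEIN_ALPHABET)


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceRecord:
    """A protein sequence with a whitespace-free identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id must be non-empty and free of whitespace: {self.id!r}")
        self.residues = self.residues.upper()
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains residues outside the protein alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file, preserving record order.

    A trailing ``*`` (stop) on a record is stripped; duplicate ids raise
    :class:`ValidationError` and an empty file raises :class:`FormatError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        try:
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = []
    for r in records:
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# hit tables


@dataclass
class HitRecord:
    """One directed pairwise similarity hit (12-column BLAST tabular row).

    ``percent_identity`` is held as a fraction in [0, 1]; coordinates are
    1-based inclusive residue positions as in the tabular dialect.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: q_start > q_end")
        if self.s_start > self.s_end:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: s_start > s_end")
        if self.bitscore < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative bitscore")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if not 0.0 <= self.percent_identity <= 1.0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity fraction outside [0,1]"
            )

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start + 1


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table, preserving line order.

    Percent identity is divided by 100 into a fraction.  Lines with fewer
    than 12 columns raise :class:`FormatError` naming the line; extra
    columns are ignored with a warning.
    """
    path = Path(path)
    records: list[HitRecord] = []
    extra_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 columns, found {len(cols)}")
            if len(cols) > 12:
                extra_lines.append(lineno)
            try:
                rec = HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]) / 100.0,
                    aln_len=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    if extra_lines:
        warnings.warn(
            f"{path}: ignored extra columns beyond 12 on {len(extra_lines)} line(s) "
            f"(first at line {extra_lines[0]})",
            stacklevel=2,
        )
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity * 100.0:.2f}",
                        str(r.aln_len),
                        str(r.mismatch),
                        str(r.gapopen),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.evalue:.3g}",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A genomic gene structure with an optional protein product.

    Exons are 0-based half-open intervals on the forward strand, sorted
    and non-overlapping; ``strand`` records coding orientation.
    """

    model_id: str
    species: str
    seqid: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein: SequenceRecord | None = None
    provenance: str = "published"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"model {self.model_id}: strand must be '+' or '-'")
        if self.provenance not in ("published", "predicted"):
            raise ValidationError(f"model {self.model_id}: unknown provenance {self.provenance!r}")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        if not exons:
            raise ValidationError(f"model {self.model_id}: no exons")
        for start, end in exons:
            if start >= end:
                raise ValidationError(f"model {self.model_id}: empty exon interval [{start},{end})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"model {self.model_id}: exons overlap or are unsorted")
        self.exons = exons
        if self.protein is not None and len(self.protein) * 3 > self.coding_length + 3:
            raise ValidationError(
                f"model {self.model_id}: protein of {len(self.protein)} aa cannot be encoded by "
                f"{self.coding_length} exonic bases"
            )

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gff3(path: str | Path, species: str = "") -> list[GeneModel]:
    """Read gene models (one per mRNA) from a GFF3 file.

    File coordinates (1-based inclusive) are converted to internal 0-based
    half-open intervals; CDS features are grouped into exons by their mRNA
    parent.  A CDS without a resolvable parent raises
    :class:`ValidationError`.  Proteins are not carried by GFF3 and are
    left unset.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # pragma: no cover - gffutils raises various types
        raise FormatError(f"{path}: not parseable as GFF3: {exc}") from exc

    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise ValidationError(
                f"{path}: CDS at {cds.seqid}:{cds.start}-{cds.end} has no mRNA parent"
            )

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start", "file_order")):
        cds_list = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds_list:
            raise ValidationError(f"{path}: mRNA {mrna.id} has no CDS children")
        exons = tuple((c.start - 1, c.end) for c in cds_list)
        prov = mrna.attributes.get("provenance", ["published"])[0]
        models.append(
            GeneModel(
                model_id=mrna.id,
                species=species or mrna.attributes.get("species", [""])[0],
                seqid=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                provenance=prov,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/CDS triples (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            attrs = f"ID={m.model_id};provenance={m.provenance}"
            if m.species:
                attrs += f";species={m.species}"
            fh.write(
                f"{m.seqid}\torthofuzz\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\tID={m.model_id}.gene\n"
            )
            fh.write(
                f"{m.seqid}\torthofuzz\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs};Parent={m.model_id}.gene\n"
            )
            phase = 0
            exons = m.exons if m.strand == "+" else tuple(reversed(m.exons))
            rows = []
            for i, (s, e) in enumerate(exons):
                rows.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for s, e, ph in sorted(rows):
                fh.write(
                    f"{m.seqid}\torthofuzz\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{ph}\tID={m.model_id}.cds;Parent={m.model_id}\n"
                )


# ---------------------------------------------------------------------------
# trees


class SupportTree:
    """A rooted species tree whose internal-node labels are branch supports.

    Thin wrapper over a :class:`dendropy.Tree`: leaf labels are species
    tokens (unique), numeric internal labels are interpreted as support
    values, polytomies are preserved.
    """

    def __init__(self, dtree: dendropy.Tree):
        self.dtree = dtree
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValidationError("tree leaf labels are not unique")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise FormatError(f"malformed Newick: {exc}") from exc
        dtree.is_rooted = True
        return cls(dtree)

    def clone(self) -> "SupportTree":
        return SupportTree.from_newick(self.to_newick())

    # -- accessors --------------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @staticmethod
    def node_support(node: dendropy.Node) -> float | None:
        """Numeric internal-node label, or None when absent/non-numeric."""
        if node.is_leaf() or node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    @staticmethod
    def leaf_set(node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = set(labels)
        node = self.dtree.mrca(taxon_labels=labels)
        if node is None:
            raise ValidationError(f"no MRCA found for leaves {sorted(labels)}")
        return node

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets below every internal, non-root edge."""
        out: set[frozenset[str]] = set()
        for node in self.dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            out.add(self.leaf_set(node))
        return out

    # -- serialisation ----------------------------------------------------
    def to_newick(self) -> str:
        text = self.dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return text.strip() + ("\n" if not text.endswith("\n") else "")


def read_newick(path: str | Path) -> SupportTree:
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty Newick file")
    try:
        return SupportTree.from_newick(text)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())
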