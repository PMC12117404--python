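"""Readers for annotated proteomes, gene sets, and flat term-annotation tables.

The substrate-prediction pipeline starts from an annotated proteome: a FASTA
file of translated open reading frames (ORFs) plus a GFF3 gene annotation that
says which genes are protein-coding.  Ensembl-style protein FASTA and
Gencode-style protein-coding transcript FASTA (with an embedded ``CDS:``
range in the header) are both supported.  Gene sets (e.g. cytoplasmic
ribosomal proteins, split by small/large subunit) are plain-text identifier
lists, and functional annotations are flat ``gene_id -> term`` TSV tables that
are assumed to be pre-propagated up the ontology.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: canonical one-letter amino-acid codes plus selenocysteine (U) and ambiguity (X)
VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "U"}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


class GFFParseError(ValueError):
    """Raised for malformed GFF3 input, listing the offending line numbers."""


@dataclass(frozen=True)
class ProteinRecord:
    """One translated ORF: the unit of substrate classification."""

    protein_id: str
    gene_id: str
    species: str
    sequence: str


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. ``RP_large``)."""

    name: str
    species: str
    gene_ids: frozenset


@dataclass(frozen=True)
class AnnotationTable:
    """Flat, pre-propagated gene -> functional-term annotation."""

    species: str
    gene_to_terms: Mapping[str, frozenset]
    term_names: Mapping[str, str]

    def genes_for_term(self, term_id: str) -> frozenset:
        return frozenset(
            g for g, terms in self.gene_to_terms.items() if term_id in terms
        )


def _extract_gene_id(record_id: str, description: str, gene_id_from) -> str:
    """Pull the gene identifier out of a FASTA header.

    ``gene_id_from`` may be:

    * ``None`` — use the record id (first whitespace token) as-is;
    * an ``int`` — index into the ``|``-split record id (Gencode dialect);
    * a regex ``str`` with one capture group, applied to the full description
      (e.g. ``r"gene:(\\S+)"`` for Ensembl headers).
    """
    if gene_id_from is None:
        return record_id
    if isinstance(gene_id_from, int):
        fields = record_id.split("|")
        if gene_id_from >= len(fields):
            raise FastaParseError(
                f"record {record_id!r}: header has {len(fields)} '|' fields, "
                f"cannot take field {gene_id_from}"
            )
        return fields[gene_id_from]
    m = re.search(gene_id_from, description)
    if not m:
        raise FastaParseError(
            f"record {record_id!r}: gene-id pattern {gene_id_from!r} "
            f"did not match header {description!r}"
        )
    return m.group(1)


def _validated_sequence(protein_id: str, raw: str) -> str | None:
    """Strip one trailing stop symbol and validate residues.

    Returns None (with a logged warning) for sequences carrying an internal
    stop, which are excluded from downstream classification.
    """
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FastaParseError(f"record {protein_id!r}: empty sequence")
    if "*" in seq:
        log.warning("record %r has an internal stop codon; excluded", protein_id)
        return None
    bad = set(seq) - VALID_AA
    if bad:
        raise FastaParseError(
            f"record {protein_id!r}: invalid residue(s) {sorted(bad)}"
        )
    return seq


def read_protein_fasta(
    path, species: str, gene_id_from=None
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    A single trailing ``*`` stop symbol is stripped; records with internal
    stops are excluded with a logged warning.  ``gene_id_from`` configures the
    header-field rule for the gene identifier (see :func:`_extract_gene_id`).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validated_sequence(rec.id, str(rec.seq))
        if seq is None:
            continue
        if rec.id in seen:
            raise FastaParseError(f"duplicate protein_id {rec.id!r}")
        seen.add(rec.id)
        gene_id = _extract_gene_id(rec.id, rec.description, gene_id_from)
        records.append(ProteinRecord(rec.id, gene_id, species, seq))
    if not records:
        raise FastaParseError(f"no FASTA records parsed from {path}")
    return records


_CDS_RANGE = re.compile(r"CDS:(\d+)-(\d+)")


def read_transcript_fasta(
    path, species: str, gene_id_from=None
) -> list[ProteinRecord]:
    """Read a protein-coding transcript FASTA and translate the CDS.

    The coding range is taken from the ``CDS:start-end`` tag that Gencode
    embeds in each transcript header (1-based, inclusive, transcript
    coordinates) and translated with the standard genetic code.  Transcripts
    without a CDS tag are skipped with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CDS_RANGE.search(rec.description)
        if not m:
            log.warning("transcript %r has no CDS: tag; skipped", rec.id)
            continue
        start, end = int(m.group(1)), int(m.group(2))
        cds = str(rec.seq)[start - 1 : end]
        # drop a trailing partial codon rather than erroring on real-world
        # annotation edge cases
        cds = cds[: len(cds) - len(cds) % 3]
        protein = str(Seq(cds).translate())
        seq = _validated_sequence(rec.id, protein)
        if seq is None:
            continue
        if rec.id in seen:
            raise FastaParseError(f"duplicate protein_id {rec.id!r}")
        seen.add(rec.id)
        gene_id = _extract_gene_id(rec.id, rec.description, gene_id_from)
        records.append(ProteinRecord(rec.id, gene_id, species, seq))
    if not records:
        raise FastaParseError(f"no coding transcripts parsed from {path}")
    return records


def _parse_gff3_attributes(col: str) -> dict:
    attrs = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_coding_genes(path) -> set:
    """Return the identifiers of genes with at least one CDS feature.

    Used to restrict FASTA entries to protein-coding genes.  Genes with
    multiple mRNA isoforms are counted once.  A GFF3 where CDS or mRNA
    features lack both ``ID`` and ``Parent`` attributes is rejected with the
    offending line numbers.
    """
    parent_of: dict[str, str] = {}
    feature_type: dict[str, str] = {}
    cds_parents: list[str] = []
    bad_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"line {lineno}: expected 9 columns")
            ftype, attr_col = cols[2], cols[8]
            attrs = _parse_gff3_attributes(attr_col)
            fid, parent = attrs.get("ID"), attrs.get("Parent")
            if ftype in ("CDS", "mRNA", "transcript") and fid is None and parent is None:
                bad_lines.append(lineno)
                continue
            if fid is not None:
                feature_type[fid] = ftype
                if parent is not None:
                    parent_of[fid] = parent.split(",")[0]
            if ftype == "CDS":
                cds_parents.append(parent if parent is not None else fid)
    if bad_lines:
        raise GFFParseError(
            "missing ID/Parent attributes on line(s) "
            + ", ".join(str(n) for n in bad_lines)
        )
    coding: set[str] = set()
    for start_id in cds_parents:
        node, hops = start_id, 0
        while node is not None and hops < 10:
            if feature_type.get(node) == "gene":
                coding.add(node)
                break
            nxt = parent_of.get(node)
            if nxt is None:
                # CDS attached directly below a top-level feature (e.g. a
                # bacterial gene without an mRNA level)
                coding.add(node)
                break
            node, hops = nxt, hops + 1
    if not coding:
        log.warning("no CDS features found in %s; returning empty set", path)
    return coding


def select_representative_orf(
    records: Sequence[ProteinRecord],
) -> list[ProteinRecord]:
    """Collapse isoforms to one ORF per gene.

    The longest sequence wins; ties break to the lexicographically smallest
    protein_id.  Output preserves the order of first appearance of each gene.
    """
    by_gene: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.gene_id not in by_gene:
            by_gene[rec.gene_id] = rec
            order.append(rec.gene_id)
            continue
        cur = by_gene[rec.gene_id]
        if (len(rec.sequence), _neg_lex(rec.protein_id)) > (
            len(cur.sequence),
            _neg_lex(cur.protein_id),
        ):
            by_gene[rec.gene_id] = rec
    log.info(
        "representative ORF rule: longest sequence per gene, "
        "ties to smallest protein_id (%d genes from %d records)",
        len(by_gene),
        len(records),
    )
    return [by_gene[g] for g in order]


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def read_gene_set(path, name: str, species: str) -> GeneSet:
    """Read a plain-text gene list (one id per line, ``#`` comments allowed)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    if not ids:
        raise ValueError(f"gene set {name!r}: no identifiers parsed from {path}")
    return GeneSet(name=name, species=species, gene_ids=frozenset(ids))


def read_annotation_table(path, species: str) -> AnnotationTable:
    """Read a flat TSV annotation table (gene_id, term_id, term_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"annotation table {path}: no rows")
    names = {}
    for term_id, term_name in zip(df["term_id"], df["term_name"]):
        if term_id in names and names[term_id] != term_name:
            raise ValueError(
                f"term {term_id!r} has conflicting names "
                f"{names[term_id]!r} and {term_name!r}"
            )
        names[term_id] = term_name
    gene_to_terms = {
        gene: frozenset(sub["term_id"])
        for gene, sub in df.groupby("gene_id", sort=False)
    }
    return AnnotationTable(
        species=species, gene_to_terms=gene_to_terms, term_names=names
    )


def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records back to FASTA (inverse of :func:`read_protein_fasta`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
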