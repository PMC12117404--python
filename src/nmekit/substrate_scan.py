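"""Second-amino-acid classification of methionine aminopeptidase substrates.

Methionine aminopeptidase (MetAP) removes the initiator methionine (iMet)
from nascent proteins whose second residue is small and uncharged.  The scan
applies that binary rule — second residue in {Ala, Cys, Gly, Ser, Thr, Val} —
to every ORF of a proteome and summarises substrate fractions genome-wide and
within user-supplied gene sets (e.g. small/large-subunit ribosomal proteins).
Methionine-count summaries support labelling-based iMet-retention assays,
where proteins with few internal methionines give the cleanest signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .proteome_io import GeneSet, ProteinRecord

log = logging.getLogger(__name__)

#: second residues accepted by MetAP: Ala, Cys, Gly, Ser, Thr, Val
SUBSTRATE_SET = frozenset("ACGSTV")

#: residues whose substrate status cannot be decided (ambiguity / selenocysteine)
AMBIGUOUS_AA = frozenset("XU")


@dataclass(frozen=True)
class SubstrateCall:
    """Per-ORF verdict under the second-amino-acid rule."""

    protein_id: str
    gene_id: str
    first_aa: str | None
    second_aa: str | None
    is_substrate: bool
    is_candidate: bool  # starts with Met and has >= 2 residues


@dataclass(frozen=True)
class SetFraction:
    n_in_set: int
    n_substrate: int
    fraction: float
    missing: tuple  # gene ids in the set but absent from the scanned proteome


@dataclass(frozen=True)
class ScanSummary:
    species: str
    n_orfs: int
    n_substrates: int
    fraction: float
    per_set: Mapping[str, SetFraction]


def classify_second_aa(record: ProteinRecord) -> SubstrateCall:
    """Classify one ORF; degenerate inputs are classified, never rejected.

    Sequences not starting with Met, or shorter than two residues, are
    non-candidates.  An ambiguous second residue (X or U) yields a
    non-substrate call with a logged note.
    """
    seq = record.sequence
    first = seq[0] if seq else None
    second = seq[1] if len(seq) >= 2 else None
    is_candidate = first == "M" and second is not None
    if is_candidate and second in AMBIGUOUS_AA:
        log.warning(
            "protein %s: ambiguous second residue %r; called non-substrate",
            record.protein_id,
            second,
        )
    is_substrate = is_candidate and second in SUBSTRATE_SET
    return SubstrateCall(
        protein_id=record.protein_id,
        gene_id=record.gene_id,
        first_aa=first,
        second_aa=second,
        is_substrate=is_substrate,
        is_candidate=is_candidate,
    )


def scan_proteome(
    records: Sequence[ProteinRecord], sets: Sequence[GeneSet] = ()
) -> tuple[ScanSummary, list[SubstrateCall]]:
    """Scan a one-ORF-per-gene proteome, with optional per-set fractions.

    Genes listed in a set but absent from the proteome are reported in the
    set's ``missing`` tuple, not silently dropped.
    """
    if not records:
        raise ValueError("scan_proteome: empty record list")
    calls = [classify_second_aa(r) for r in records]
    n = len(calls)
    n_sub = sum(c.is_substrate for c in calls)
    by_gene = {c.gene_id: c for c in calls}
    per_set = {}
    for gs in sets:
        present = [g for g in sorted(gs.gene_ids) if g in by_gene]
        missing = tuple(g for g in sorted(gs.gene_ids) if g not in by_gene)
        n_in = len(present)
        n_in_sub = sum(by_gene[g].is_substrate for g in present)
        per_set[gs.name] = SetFraction(
            n_in_set=n_in,
            n_substrate=n_in_sub,
            fraction=n_in_sub / n_in if n_in else 0.0,
            missing=missing,
        )
    species = records[0].species
    summary = ScanSummary(
        species=species,
        n_orfs=n,
        n_substrates=n_sub,
        fraction=n_sub / n,
        per_set=per_set,
    )
    return summary, calls


def count_methionines(record: ProteinRecord) -> int:
    """Number of Met residues in the sequence, including the initiator."""
    return record.sequence.count("M")


def met_count_summary(
    records: Sequence[ProteinRecord], threshold: int
) -> tuple[int, int]:
    """Count records with strictly fewer than ``threshold`` methionines.

    Returns ``(n_below, n_total)``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not records:
        raise ValueError("met_count_summary: empty record list")
    n_below = sum(count_methionines(r) < threshold for r in records)
    return n_below, len(records)


def percent(fraction: float, ndigits: int = 0) -> float:
    """Fraction as a percentage, rounded half-up to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))
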