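"""Overrepresentation testing of substrate sets against term annotations.

Whether a functional category (a GO term, here any flat term annotation) is
enriched among predicted MetAP substrates is decided by the one-sided
hypergeometric upper tail: with N background genes of which K are substrates,
and a term annotating n genes of which k are substrates, the p-value is
P(X >= k) for X ~ Hypergeom(N, K, n) — i.e. Fisher's exact test, greater.
p-values are Benjamini–Hochberg adjusted within species, and a term is
conserved when it is significant (FDR < alpha and fold enrichment > 1) in
every species analysed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .proteome_io import AnnotationTable
from .substrate_scan import SubstrateCall


@dataclass(frozen=True)
class ContingencyCounts:
    """k substrates of n term genes, against K substrates of N background genes."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        ok = (
            0 <= self.k <= min(self.n, self.K)
            and self.n <= self.N
            and self.K <= self.N
        )
        if not ok:
            raise ValueError(f"invalid contingency counts {self!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    counts: ContingencyCounts
    fold_enrichment: float | None
    p_value: float
    fdr: float


@dataclass(frozen=True)
class ConservedReport:
    term_id: str
    fdr_by_species: Mapping[str, float | None]
    conserved: bool


def hypergeometric_overrepresentation(c: ContingencyCounts) -> float:
    """Upper-tail p-value P(X >= k), in (0, 1]."""
    # sf(k-1) is the survival function at k-1, i.e. P(X >= k)
    p = float(hypergeom.sf(c.k - 1, c.N, c.K, c.n))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def fold_enrichment(c: ContingencyCounts) -> float | None:
    """Observed over expected substrate rate, (k/n) / (K/N); None if undefined."""
    if c.n == 0 or c.K == 0:
        return None
    return (c.k / c.n) / (c.K / c.N)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    ps = list(p_values)
    if not ps:
        return []
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1].tolist()


def enrich_terms(
    calls: Sequence[SubstrateCall],
    ann: AnnotationTable,
    min_term_size: int = 1,
) -> list[EnrichmentResult]:
    """Test every annotated term for substrate overrepresentation.

    The background is the set of classified genes present in the annotation
    table; the foreground is its substrate subset.  BH adjustment runs across
    all tested terms; results are sorted by FDR then term id.
    """
    background = {c.gene_id: c for c in calls if c.gene_id in ann.gene_to_terms}
    N = len(background)
    substrates = {g for g, c in background.items() if c.is_substrate}
    K = len(substrates)
    if K == 0:
        raise ValueError("enrich_terms: no substrate genes in the background")
    term_genes: dict[str, set] = {}
    for gene in background:
        for term in ann.gene_to_terms[gene]:
            term_genes.setdefault(term, set()).add(gene)
    tested = []
    for term_id in sorted(term_genes):
        genes = term_genes[term_id]
        n = len(genes)
        if n < min_term_size:
            continue
        k = len(genes & substrates)
        counts = ContingencyCounts(k=k, n=n, K=K, N=N)
        tested.append(
            (
                term_id,
                counts,
                fold_enrichment(counts),
                hypergeometric_overrepresentation(counts),
            )
        )
    fdrs = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=ann.term_names.get(term_id, term_id),
            counts=counts,
            fold_enrichment=fe,
            p_value=p,
            fdr=fdr,
        )
        for (term_id, counts, fe, p), fdr in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.term_id))
    return results


def conserved_terms(
    results_by_species: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
    min_fe: float = 1.0,
) -> list[ConservedReport]:
    """Intersect per-species significant terms.

    A term is significant in a species iff FDR < alpha and fold enrichment
    > min_fe; it is conserved iff significant in every species.  Terms absent
    from a species' results are non-significant there.
    """
    if len(results_by_species) < 2:
        raise ValueError("conserved_terms needs results for >= 2 species")
    species = sorted(results_by_species)
    by_species = {
        sp: {r.term_id: r for r in results_by_species[sp]} for sp in species
    }
    all_terms = sorted(set().union(*(d.keys() for d in by_species.values())))
    reports = []
    for term in all_terms:
        fdr_map: dict[str, float | None] = {}
        significant_everywhere = True
        for sp in species:
            r = by_species[sp].get(term)
            fdr_map[sp] = r.fdr if r is not None else None
            sig = (
                r is not None
                and r.fdr < alpha
                and r.fold_enrichment is not None
                and r.fold_enrichment > min_fe
            )
            significant_everywhere = significant_everywhere and sig
        reports.append(
            ConservedReport(
                term_id=term, fdr_by_species=fdr_map, conserved=significant_everywhere
            )
        )
    return reports
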