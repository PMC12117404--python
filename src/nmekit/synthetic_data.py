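"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the pipeline's real-world inputs:

* :func:`gen_proteome` — an annotated proteome (FASTA + GFF3 + gene sets +
  flat term annotation) with a controllable second-amino-acid composition and
  one term planted to be enriched with substrates;
* :func:`gen_peptide_table` — a label-free peptide quantification table with
  log-normal intensities, a planted log2 fold-change shift on iMet-retained
  N-terminal peptides, missing values, and peptides planted to fail the
  confidence filters;
* :func:`gen_luminescence` — dual- or single-luciferase replicate tables with
  a set true error rate and coefficient of variation.

Each artifact uses its own generator stream derived from ``(seed, role)``, so
regenerating one artifact never perturbs another, and the same seed produces
byte-identical files.  A ground-truth sidecar accompanies every artifact and
is sufficient to compute every expected downstream quantity without
re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ntermomics import (
    MOD_MASS,
    PROTEIN_NTERM,
    ModName,
    PeptideRecord,
    mod_event,
)
from .proteome_io import AnnotationTable, GeneSet, ProteinRecord
from .reporter_stats import ERROR_REPORTER, WT_CONTROL, LuminescenceRecord
from .substrate_scan import SUBSTRATE_SET

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NONSUBSTRATE_AA = "".join(sorted(set(AA20) - SUBSTRATE_SET))

# role tags for per-artifact generator streams
_ROLE_PROTEOME = 11
_ROLE_ANNOTATION = 12
_ROLE_GENE_SETS = 13
_ROLE_PEPTIDES = 21
_ROLE_LUMINESCENCE = 31


def _rng(seed: int, role: int) -> np.random.Generator:
    return np.random.default_rng([seed, role])


def _draw_letters(rng: np.random.Generator, alphabet: str, n: int) -> str:
    idx = rng.integers(0, len(alphabet), size=n)
    return "".join(alphabet[i] for i in idx)


def _weighted_choice(rng, alphabet: str, dist: Mapping[str, float] | None, n: int) -> list[str]:
    if dist is None:
        return list(_draw_letters(rng, alphabet, n))
    letters = sorted(dist)
    probs = np.array([dist[a] for a in letters], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("second-residue distribution must sum to 1")
    return list(rng.choice(letters, size=n, p=probs))


# ---------------------------------------------------------------------------
# proteome

@dataclass
class ProteomeSimConfig:
    """Study conditions for the synthetic annotated proteome."""

    n_genes: int = 1000
    substrate_fraction: float = 0.5
    substrate_second_dist: Mapping[str, float] | None = None  # None -> uniform
    nonsubstrate_second_dist: Mapping[str, float] | None = None
    length_range: tuple = (100, 400)
    n_noncoding: int = 20
    n_terms: int = 50
    genes_per_term: int = 40
    planted_substrate_prob: float = 0.9
    gene_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"RP_small": 15, "RP_large": 25}
    )
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substrate_fraction <= 1.0:
            raise ValueError("substrate_fraction must lie in [0, 1]")


@dataclass
class SyntheticProteome:
    records: list
    gene_sets: list
    annotation: AnnotationTable
    noncoding_gene_ids: tuple
    truth: dict


def gen_proteome(cfg: ProteomeSimConfig) -> SyntheticProteome:
    """Generate an annotated proteome with one planted enriched term.

    Every ORF starts with Met; the realised substrate count is
    Binomial(n_genes, substrate_fraction).  The planted term draws its genes
    with elevated substrate probability; null terms draw uniformly.
    """
    rng = _rng(cfg.seed, _ROLE_PROTEOME)
    n = cfg.n_genes
    is_sub = rng.random(n) < cfg.substrate_fraction
    n_sub = int(is_sub.sum())
    sub_seconds = _weighted_choice(
        rng, "".join(sorted(SUBSTRATE_SET)), cfg.substrate_second_dist, n_sub
    )
    non_seconds = _weighted_choice(
        rng, NONSUBSTRATE_AA, cfg.nonsubstrate_second_dist, n - n_sub
    )
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    tail_pool = _draw_letters(rng, AA20, int((lengths - 2).sum()))
    records, offset, i_sub, i_non = [], 0, 0, 0
    for i in range(n):
        if is_sub[i]:
            second = sub_seconds[i_sub]
            i_sub += 1
        else:
            second = non_seconds[i_non]
            i_non += 1
        tail_len = int(lengths[i]) - 2
        seq = "M" + second + tail_pool[offset : offset + tail_len]
        offset += tail_len
        gene = f"G{i:05d}"
        records.append(
            ProteinRecord(
                protein_id=f"P{i:05d}", gene_id=gene, species=cfg.species, sequence=seq
            )
        )
    gene_ids = [r.gene_id for r in records]
    substrate_genes = [g for g, s in zip(gene_ids, is_sub) if s]
    nonsub_genes = [g for g, s in zip(gene_ids, is_sub) if not s]

    # gene sets
    set_rng = _rng(cfg.seed, _ROLE_GENE_SETS)
    gene_sets, set_truth = [], {}
    for name in sorted(cfg.gene_set_sizes):
        size = cfg.gene_set_sizes[name]
        members = sorted(set_rng.choice(gene_ids, size=size, replace=False))
        gene_sets.append(
            GeneSet(name=name, species=cfg.species, gene_ids=frozenset(members))
        )
        set_truth[name] = members

    # annotation with one planted enriched term
    ann_rng = _rng(cfg.seed, _ROLE_ANNOTATION)
    gene_to_terms: dict[str, set] = {}
    term_names: dict[str, str] = {}
    m = min(cfg.genes_per_term, n)
    n_from_sub = int(ann_rng.binomial(m, cfg.planted_substrate_prob))
    n_from_sub = min(n_from_sub, len(substrate_genes))
    n_from_sub = max(n_from_sub, m - len(nonsub_genes))
    planted = list(ann_rng.choice(substrate_genes, size=n_from_sub, replace=False))
    planted += list(
        ann_rng.choice(nonsub_genes, size=m - n_from_sub, replace=False)
    )
    term_ids = [f"T{i:04d}" for i in range(cfg.n_terms)]
    term_names[term_ids[0]] = "planted pathway"
    for gene in planted:
        gene_to_terms.setdefault(gene, set()).add(term_ids[0])
    for t in term_ids[1:]:
        term_names[t] = f"null pathway {t[1:]}"
        for gene in ann_rng.choice(gene_ids, size=m, replace=False):
            gene_to_terms.setdefault(gene, set()).add(t)
    annotation = AnnotationTable(
        species=cfg.species,
        gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()},
        term_names=term_names,
    )
    noncoding = tuple(f"NC{i:05d}" for i in range(cfg.n_noncoding))
    truth = {
        "substrate_fraction_true": cfg.substrate_fraction,
        "n_genes": n,
        "n_substrates_realized": n_sub,
        "substrate_gene_ids": substrate_genes,
        "planted_term": term_ids[0],
        "planted_term_genes": sorted(planted),
        "gene_sets": set_truth,
        "seed": cfg.seed,
    }
    return SyntheticProteome(
        records=records,
        gene_sets=gene_sets,
        annotation=annotation,
        noncoding_gene_ids=noncoding,
        truth=truth,
    )


def write_proteome(sp: SyntheticProteome, outdir) -> dict:
    """Write the synthetic proteome artifacts; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "gff3": outdir / "annotation.gff3",
        "annotation": outdir / "terms.tsv",
        "truth": outdir / "proteome_truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for rec in sp.records:
            fh.write(f">{rec.protein_id} gene:{rec.gene_id}\n{rec.sequence}\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        pos = 1
        for rec in sp.records:
            span = len(rec.sequence) * 3 + 3
            g, mrna = rec.gene_id, f"{rec.gene_id}.t1"
            fh.write(
                f"chr1\tsim\tgene\t{pos}\t{pos + span - 1}\t.\t+\t.\tID={g}\n"
                f"chr1\tsim\tmRNA\t{pos}\t{pos + span - 1}\t.\t+\t.\tID={mrna};Parent={g}\n"
                f"chr1\tsim\tCDS\t{pos}\t{pos + span - 1}\t.\t+\t0\tID={mrna}.cds;Parent={mrna}\n"
            )
            pos += span + 100
        for nc in sp.noncoding_gene_ids:
            fh.write(
                f"chr1\tsim\tgene\t{pos}\t{pos + 199}\t.\t+\t.\tID={nc}\n"
                f"chr1\tsim\tncRNA\t{pos}\t{pos + 199}\t.\t+\t.\tID={nc}.t1;Parent={nc}\n"
            )
            pos += 300
    with open(paths["annotation"], "w") as fh:
        fh.write("gene_id\tterm_id\tterm_name\n")
        for gene in sorted(sp.annotation.gene_to_terms):
            for term in sorted(sp.annotation.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\t{sp.annotation.term_names[term]}\n")
    for gs in sp.gene_sets:
        p = outdir / f"set_{gs.name}.txt"
        paths[f"set_{gs.name}"] = p
        with open(p, "w") as fh:
            fh.write(f"# gene set {gs.name} ({gs.species})\n")
            for g in sorted(gs.gene_ids):
                fh.write(g + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sp.truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# peptide tables

@dataclass
class PeptideSimConfig:
    """Study conditions for the synthetic peptide quantification table.

    Defaults emulate the scale of a crude-ribosome label-free experiment:
    two conditions (WT and MUT) with 2 biological x 3 technical replicates,
    ~30 protein families of 10-16 peptides (~780 peptide-by-replicate fold
    changes, of which ~18 come from iMet-retained N-terminal peptides), a
    planted log2 shift delta on retained N-terminal peptides, log-normal
    intensity noise, and missing-completely-at-random dropout.
    """

    n_proteins: int = 30
    peptides_per_protein: tuple = (10, 16)
    retained_fraction: float = 0.3
    delta: float = 3.0  # planted log2 MUT/WT shift on retained N-term peptides
    sigma: float = 0.5  # log2 intensity noise sd
    missing_rate: float = 0.1
    # 'censor' drops each run's lowest-intensity measurements (the dominant
    # mechanism in label-free MS, and the regime low-abundance resampling is
    # designed for); 'mcar' drops cells completely at random
    missing_mechanism: str = "censor"
    n_biological: int = 2
    n_technical: int = 3
    n_fail_filter: int = 20
    retained_second_aas: str = "GPSV"  # small/uncharged residues
    processed_second_aas: str = "AST"
    family_log2fc: Mapping[str, float] = field(default_factory=dict)
    paralog_family_size: int = 2
    base_log2_abundance: tuple = (20.0, 2.0)  # mean, sd
    # N-terminal peptidoforms are a minor share of total ion current, so a
    # planted shift on them must not distort total-intensity normalisation
    nterm_abundance_offset: float = -3.0
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.missing_mechanism not in ("censor", "mcar"):
            raise ValueError("missing_mechanism must be 'censor' or 'mcar'")


@dataclass
class SyntheticPeptides:
    records: list  # PeptideRecord, analysis peptides then planted filter failures
    run_design: dict  # run_id -> (condition, biological replicate)
    proteins: list  # ProteinRecord, for N-terminal mapping
    paralog_map: dict  # protein_id -> family name
    truth: dict


def _family_name(i: int, fam_size: int) -> str:
    return f"F{i // max(fam_size, 1):03d}"


def gen_peptide_table(cfg: PeptideSimConfig) -> SyntheticPeptides:
    """Generate peptide records with planted iMet-retention fold changes.

    Retained proteins contribute an N-terminal peptide starting at residue 1
    with no Met-loss and a planted MUT/WT log2 shift of ``delta`` (plus any
    per-family shift); processed proteins contribute a start-2 or Met-loss
    N-terminal peptide with only the family shift; internal peptides carry
    the family shift.  A known set of extra peptides fails the
    confidence filters.
    """
    rng = _rng(cfg.seed, _ROLE_PEPTIDES)
    run_design = {}
    for cond in ("WT", "MUT"):
        for b in range(1, cfg.n_biological + 1):
            for t in range(1, cfg.n_technical + 1):
                run_design[f"{cond}_b{b}_t{t}"] = (cond, b)
    runs = sorted(run_design)

    n_ret = int(round(cfg.n_proteins * cfg.retained_fraction))
    retained_flags = np.zeros(cfg.n_proteins, dtype=bool)
    retained_flags[rng.permutation(cfg.n_proteins)[:n_ret]] = True

    proteins, paralog_map = [], {}
    for i in range(cfg.n_proteins):
        length = int(rng.integers(150, 301))
        second_pool = (
            cfg.retained_second_aas if retained_flags[i] else cfg.processed_second_aas
        )
        second = second_pool[int(rng.integers(0, len(second_pool)))]
        seq = "M" + second + _draw_letters(rng, AA20, length - 2)
        pid = f"RP{i:03d}"
        proteins.append(
            ProteinRecord(
                protein_id=pid, gene_id=pid, species=cfg.species, sequence=seq
            )
        )
        paralog_map[pid] = _family_name(i, cfg.paralog_family_size)

    def intensities_for(base_log2: float, shift: float) -> dict:
        vals = {}
        for run in runs:
            cond, _ = run_design[run]
            mu = base_log2 + (shift if cond == "MUT" else 0.0)
            vals[run] = float(2.0 ** (mu + rng.normal(0.0, cfg.sigma)))
        return vals

    base_mu, base_sd = cfg.base_log2_abundance
    rows: list[dict] = []
    retained_peptides: list[str] = []
    for i, prot in enumerate(proteins):
        fam_shift = float(cfg.family_log2fc.get(paralog_map[prot.protein_id], 0.0))
        n_pep = int(rng.integers(cfg.peptides_per_protein[0], cfg.peptides_per_protein[1] + 1))
        # N-terminal peptide
        nlen = int(rng.integers(8, 15))
        if retained_flags[i]:
            seq, start, mods = prot.sequence[:nlen], 1, ()
            shift = cfg.delta + fam_shift
            retained_peptides.append(seq)
        else:
            shift = fam_shift
            if rng.random() < 0.5:
                seq, start, mods = prot.sequence[1 : nlen + 1], 2, ()
            else:
                seq, start = prot.sequence[1 : nlen + 1], 1
                mods = (mod_event(ModName.MET_LOSS),)
        rows.append(
            dict(
                sequence=seq,
                protein_ids=(prot.protein_id,),
                protein_start=start,
                modifications=mods,
                psm_count=int(rng.integers(3, 31)),
                fdr_class="high",
                intensities=intensities_for(
                    float(rng.normal(base_mu + cfg.nterm_abundance_offset, base_sd)),
                    shift,
                ),
            )
        )
        # internal peptides
        for _ in range(n_pep - 1):
            plen = int(rng.integers(8, 21))
            start = int(rng.integers(5, len(prot.sequence) - plen + 1))
            seq = prot.sequence[start - 1 : start - 1 + plen]
            mods = ()
            if "C" in seq and rng.random() < 0.2:
                mods = (
                    mod_event(ModName.CARBAMIDOMETHYL, position=seq.index("C") + 1),
                )
            rows.append(
                dict(
                    sequence=seq,
                    protein_ids=(prot.protein_id,),
                    protein_start=start,
                    modifications=mods,
                    psm_count=int(rng.integers(3, 31)),
                    fdr_class="high",
                    intensities=intensities_for(
                        float(rng.normal(base_mu, base_sd)), fam_shift
                    ),
                )
            )
    n_analysis = len(rows)

    # planted filter failures: valid internal peptides that miss the PSM or
    # FDR-confidence cut
    failing: list[str] = []
    for j in range(cfg.n_fail_filter):
        prot = proteins[int(rng.integers(0, len(proteins)))]
        plen = int(rng.integers(8, 21))
        start = int(rng.integers(5, len(prot.sequence) - plen + 1))
        seq = prot.sequence[start - 1 : start - 1 + plen]
        if j % 2 == 0:
            psm, fdr_class = int(rng.integers(0, 3)), "high"
        else:
            psm = int(rng.integers(3, 31))
            fdr_class = "medium" if j % 4 == 1 else "low"
        failing.append(seq)
        rows.append(
            dict(
                sequence=seq,
                protein_ids=(prot.protein_id,),
                protein_start=start,
                modifications=(),
                psm_count=psm,
                fdr_class=fdr_class,
                intensities=intensities_for(float(rng.normal(base_mu, base_sd)), 0.0),
            )
        )

    # equal peptide loading: each run is measured from the same total peptide
    # amount, so run totals are equalised before dropout.  Label-free
    # intensities are therefore relative, and the expected *measured* fold
    # change of a family is its absolute shift minus the compositional term
    # log2(raw MUT total / raw WT total).
    raw_totals = {run: sum(row["intensities"][run] for row in rows) for run in runs}
    target = sum(raw_totals.values()) / len(raw_totals)
    for row in rows:
        for run in runs:
            row["intensities"][run] *= target / raw_totals[run]
    wt_raw = np.mean([raw_totals[r] for r in runs if run_design[r][0] == "WT"])
    mut_raw = np.mean([raw_totals[r] for r in runs if run_design[r][0] == "MUT"])
    composition_log2 = float(np.log2(mut_raw / wt_raw))

    # missingness: left-censor each run's lowest measurements (default), or
    # drop cells completely at random
    if cfg.missing_rate > 0:
        if cfg.missing_mechanism == "censor":
            n_drop = int(cfg.missing_rate * len(rows))
            for run in runs:
                order = sorted(range(len(rows)), key=lambda i: rows[i]["intensities"][run])
                for i in order[:n_drop]:
                    rows[i]["intensities"][run] = None
        else:
            for row in rows:
                for run in runs:
                    if rng.random() < cfg.missing_rate:
                        row["intensities"][run] = None

    records = [PeptideRecord(**row) for row in rows]
    families = sorted(set(paralog_map.values()))
    truth = {
        "delta": cfg.delta,
        "sigma": cfg.sigma,
        "missing_rate": cfg.missing_rate,
        "retained_protein_ids": [
            p.protein_id for p, f in zip(proteins, retained_flags) if f
        ],
        "retained_peptide_sequences": retained_peptides,
        "failing_peptide_sequences": failing,
        "n_analysis_peptides": n_analysis,
        "n_fail_filter": cfg.n_fail_filter,
        "family_log2fc": {f: float(cfg.family_log2fc.get(f, 0.0)) for f in families},
        "composition_log2": composition_log2,
        "family_log2fc_measured": {
            f: float(cfg.family_log2fc.get(f, 0.0)) - composition_log2
            for f in families
        },
        "seed": cfg.seed,
    }
    return SyntheticPeptides(
        records=records,
        run_design=run_design,
        proteins=proteins,
        paralog_map=paralog_map,
        truth=truth,
    )


def write_peptides(sp: SyntheticPeptides, outdir) -> dict:
    """Write peptide TSV, run design, proteome FASTA, paralog map, and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "design": outdir / "run_design.tsv",
        "fasta": outdir / "proteins.fasta",
        "paralogs": outdir / "paralogs.tsv",
        "truth": outdir / "peptides_truth.json",
    }
    runs = sorted(sp.run_design)
    with open(paths["peptides"], "w") as fh:
        fh.write(
            "sequence\tprotein_ids\tprotein_start\tmodifications\tpsm_count\t"
            "fdr_confidence\t" + "\t".join(runs) + "\n"
        )
        for r in sp.records:
            mods = "; ".join(str(m) for m in r.modifications)
            cells = [
                "" if r.intensities[run] is None else repr(r.intensities[run])
                for run in runs
            ]
            fh.write(
                f"{r.sequence}\t{';'.join(r.protein_ids)}\t{r.protein_start}\t"
                f"{mods}\t{r.psm_count}\t{r.fdr_class}\t" + "\t".join(cells) + "\n"
            )
    with open(paths["design"], "w") as fh:
        fh.write("run_id\tcondition\tbiological_replicate\n")
        for run in runs:
            cond, b = sp.run_design[run]
            fh.write(f"{run}\t{cond}\t{b}\n")
    with open(paths["fasta"], "w") as fh:
        for p in sp.proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    with open(paths["paralogs"], "w") as fh:
        fh.write("protein_id\tfamily\n")
        for pid in sorted(sp.paralog_map):
            fh.write(f"{pid}\t{sp.paralog_map[pid]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sp.truth, fh, indent=1, sort_keys=True)
    return paths


def read_run_design(path) -> dict:
    """Inverse of the run-design TSV written by :func:`write_peptides`."""
    design = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            run, cond, b = line.rstrip("\n").split("\t")
            design[run] = (cond, int(b))
    return design


# ---------------------------------------------------------------------------
# luminescence

@dataclass
class ReporterSimConfig:
    """Study conditions for synthetic luciferase replicate tables."""

    true_rate: float = 0.01  # fraction; 0.01 -> a 1% error rate
    wt_ratio: float = 2.0  # wild-type Fluc/Rluc (DUAL) level
    rluc_level: float = 1e5
    signal_level: float = 1e5  # SINGLE-assay wild-type Nluc level
    cv: float = 0.1  # multiplicative noise, log scale
    n_replicates: int = 3
    assay: str = "DUAL"
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")


def gen_luminescence(
    cfg: ReporterSimConfig,
) -> tuple[list[LuminescenceRecord], list[LuminescenceRecord], dict]:
    """Generate error-reporter and wild-type replicates.

    Wild-type Fluc/Rluc ratios centre on ``wt_ratio``; the error construct's
    ratio is ``true_rate`` times that, with multiplicative log-normal noise of
    scale ``cv`` on each measured channel ratio.  Returns
    ``(error_records, wt_records, truth)``.
    """
    rng = _rng(cfg.seed, _ROLE_LUMINESCENCE)
    dual = cfg.assay == "DUAL"

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, cfg.cv))) if cfg.cv > 0 else 1.0

    def make(construct: str, rate: float, rep: int) -> LuminescenceRecord:
        if dual:
            rluc = cfg.rluc_level * noise()
            fluc = rate * cfg.wt_ratio * rluc * noise()
            return LuminescenceRecord(
                construct=construct,
                assay="DUAL",
                rluc=rluc,
                signal=fluc,
                condition=cfg.condition,
                replicate=rep,
            )
        return LuminescenceRecord(
            construct=construct,
            assay="SINGLE",
            rluc=None,
            signal=rate * cfg.signal_level * noise(),
            condition=cfg.condition,
            replicate=rep,
        )

    wt = [make(WT_CONTROL, 1.0, i + 1) for i in range(cfg.n_replicates)]
    err = [make(ERROR_REPORTER, cfg.true_rate, i + 1) for i in range(cfg.n_replicates)]
    truth = {
        "true_rate_percent": 100.0 * cfg.true_rate,
        "cv": cfg.cv,
        "n_replicates": cfg.n_replicates,
        "assay": cfg.assay,
        "seed": cfg.seed,
    }
    return err, wt, truth


def write_luminescence(
    error_records: Sequence[LuminescenceRecord],
    wt_records: Sequence[LuminescenceRecord],
    truth: dict,
    outdir,
) -> dict:
    """Write the luminescence replicate table and its ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "luminescence.tsv",
        "truth": outdir / "luminescence_truth.json",
    }
    with open(paths["table"], "w") as fh:
        fh.write("construct\tassay\trluc\tsignal\tcondition\treplicate\n")
        for rec in list(wt_records) + list(error_records):
            rluc = "" if rec.rluc is None else repr(rec.rluc)
            fh.write(
                f"{rec.construct}\t{rec.assay}\t{rluc}\t{rec.signal!r}\t"
                f"{rec.condition}\t{rec.replicate}\n"
            )
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def read_luminescence(path) -> tuple[list[LuminescenceRecord], list[LuminescenceRecord]]:
    """Read a luminescence TSV back into (error_records, wt_records)."""
    err, wt = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            construct, assay, rluc, signal, condition, rep = line.rstrip("\n").split("\t")
            rec = LuminescenceRecord(
                construct=construct,
                assay=assay,
                rluc=float(rluc) if rluc else None,
                signal=float(signal),
                condition=condition,
                replicate=int(rep),
            )
            (err if construct == ERROR_REPORTER else wt).append(rec)
    return err, wt
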