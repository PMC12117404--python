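"""Peptide-level N-terminomics: filtering, normalisation, fold changes, and
iMet-retention statistics.

The module consumes a search-engine peptide export (sequence, protein
accessions, start position, modification events, PSM count, FDR confidence
class, per-run intensities) and runs the downstream label-free quantification
procedure:

1. keep peptides with high FDR confidence (q < 0.01) and > 2 PSMs;
2. rescale each run so its total intensity matches the grand mean of run
   totals ("normalised by the total peptide amount");
3. impute missing intensities by low-abundance resampling — seeded uniform
   draws between the 0th and 5th percentile of the run's observed values;
4. compute per-peptide log2 fold changes MUT/WT within each biological
   replicate (technical runs averaged first);
5. collapse peptides to paralog-aware protein families by the median fold
   change (families with < 3 peptides excluded; peptides bearing any
   modification other than carbamidomethyl omitted);
6. classify each peptide's N-terminal peptidoform (iMet retained/processed,
   with or without N-terminal acetylation) from its start position and
   modification mass deltas, and compare iMet-retained fold changes against
   all peptides with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import math
import re
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_1samp

from .enrichment import bh_adjust

log = logging.getLogger(__name__)

PROTEIN_NTERM = "protein N-term"


class ModName(str, Enum):
    ACETYL = "Acetyl"
    MET_LOSS = "MetLoss"
    MET_LOSS_ACETYL = "MetLossAcetyl"
    DEAMIDATED = "Deamidated"
    OXIDATION = "Oxidation"
    CARBAMIDOMETHYL = "Carbamidomethyl"


#: canonical monoisotopic mass deltas (Da)
MOD_MASS = {
    ModName.ACETYL: 42.010565,
    ModName.MET_LOSS: -131.040485,
    ModName.MET_LOSS_ACETYL: -89.02992,
    ModName.DEAMIDATED: 0.984016,
    ModName.OXIDATION: 15.994915,
    ModName.CARBAMIDOMETHYL: 57.021464,
}

MASS_TOL = 1e-6


@dataclass(frozen=True)
class ModificationEvent:
    """One modification: name, mass delta, and position within the peptide
    (1-based residue index) or the literal ``"protein N-term"``."""

    name: ModName
    mass_delta: float
    position: int | str

    def __post_init__(self):
        if abs(self.mass_delta - MOD_MASS[self.name]) > MASS_TOL:
            raise ValueError(
                f"{self.name.value}: mass delta {self.mass_delta} does not match "
                f"canonical {MOD_MASS[self.name]}"
            )
        if self.name in (ModName.MET_LOSS, ModName.MET_LOSS_ACETYL):
            if self.position != PROTEIN_NTERM:
                raise ValueError(
                    f"{self.name.value} is only valid at the protein N-terminus, "
                    f"got position {self.position!r}"
                )

    def __str__(self) -> str:
        return f"{self.name.value} ({self.mass_delta:+.6f}) @ {self.position}"


def mod_event(name: ModName, position: int | str | None = None) -> ModificationEvent:
    """Convenience constructor with the canonical mass delta filled in."""
    if position is None:
        position = (
            PROTEIN_NTERM
            if name in (ModName.ACETYL, ModName.MET_LOSS, ModName.MET_LOSS_ACETYL)
            else 1
        )
    return ModificationEvent(name=name, mass_delta=MOD_MASS[name], position=position)


@dataclass(frozen=True)
class PeptideRecord:
    """One quantified peptide; ``intensities`` maps run_id to a non-negative
    value or None for missing."""

    sequence: str
    protein_ids: tuple
    protein_start: int  # 1-based residue index in the mature ORF
    modifications: tuple
    psm_count: int
    fdr_class: str  # 'high' (q < 0.01), 'medium', or 'low'
    intensities: Mapping[str, float | None]
    imputed: frozenset = frozenset()

    def __post_init__(self):
        if self.protein_start < 1:
            raise ValueError("protein_start must be >= 1")
        if self.psm_count < 0:
            raise ValueError("psm_count must be >= 0")
        for run, v in self.intensities.items():
            if v is not None and v < 0:
                raise ValueError(f"negative intensity in run {run!r}")

    @property
    def key(self) -> tuple:
        """Peptidoform identity: sequence plus its modification events."""
        return (self.sequence, tuple(str(m) for m in self.modifications))


class NTermKind(str, Enum):
    IMET_RETAINED = "IMET_RETAINED"
    IMET_RETAINED_ACETYL = "IMET_RETAINED_ACETYL"
    PROCESSED = "PROCESSED"
    PROCESSED_ACETYL = "PROCESSED_ACETYL"
    INTERNAL = "INTERNAL"


RETAINED_KINDS = frozenset({NTermKind.IMET_RETAINED, NTermKind.IMET_RETAINED_ACETYL})


@dataclass(frozen=True)
class NTermStatus:
    kind: NTermKind
    second_aa: str | None  # set only for N-terminal statuses


@dataclass(frozen=True)
class PeptideFoldChange:
    sequence: str
    modifications: tuple
    protein_ids: tuple
    biorep: int
    log2fc: float  # log2 MUT/WT
    n_wt: int
    n_mut: int

    @property
    def key(self) -> tuple:
        return (self.sequence, tuple(str(m) for m in self.modifications))


@dataclass(frozen=True)
class ProteinFoldChange:
    family: str  # paralog-collapsed protein family name
    median_log2fc: float
    n_peptides: int
    p_value: float
    fdr: float
    ambiguous: bool  # contains peptides shared with another family


@dataclass(frozen=True)
class WilcoxonComparison:
    p_value: float
    n_imet: int
    n_all: int
    median_imet: float
    median_all: float


@dataclass(frozen=True)
class FoldChangePartition:
    threshold: float  # fold ratio defining the high group
    high: tuple
    low: tuple
    high_composition: Mapping[str, int]
    low_composition: Mapping[str, int]


# ---------------------------------------------------------------------------
# parsing

_MOD_RE = re.compile(r"^\s*(\w+)\s*\(([-+]?[0-9.]+)\)\s*@\s*(.+?)\s*$")

_REQUIRED_COLUMNS = (
    "sequence",
    "protein_ids",
    "protein_start",
    "modifications",
    "psm_count",
    "fdr_confidence",
)


def parse_modifications(text: str) -> tuple:
    """Parse a ``;``-separated list of ``Name (delta) @ position`` events."""
    events = []
    unknown = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _MOD_RE.match(chunk)
        if not m:
            raise ValueError(f"unparseable modification string {chunk!r}")
        name_str, delta_str, pos_str = m.groups()
        try:
            name = ModName(name_str)
        except ValueError:
            unknown.append(name_str)
            continue
        position: int | str = (
            PROTEIN_NTERM if pos_str == PROTEIN_NTERM else int(pos_str)
        )
        events.append(
            ModificationEvent(name=name, mass_delta=float(delta_str), position=position)
        )
    if unknown:
        raise ValueError(f"unknown modification name(s): {sorted(set(unknown))}")
    return tuple(events)


def parse_peptide_table(path, run_design: Mapping[str, tuple]) -> list[PeptideRecord]:
    """Read a peptide TSV/CSV export into :class:`PeptideRecord` objects.

    Columns beyond the required set are per-run intensities; every intensity
    column must appear in ``run_design`` (run_id -> (condition, biological
    replicate)).  Empty cells are recorded as missing, a literal 0 is kept as
    a measured zero.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str})
    missing_cols = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"peptide table missing columns {sorted(missing_cols)}")
    run_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    bad_runs = [c for c in run_cols if c not in run_design]
    if bad_runs:
        raise ValueError(f"run(s) {bad_runs} not present in the run design")
    records = []
    unknown: list[str] = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        mods_text = d["modifications"]
        if isinstance(mods_text, float) and math.isnan(mods_text):
            mods_text = ""
        try:
            mods = parse_modifications(str(mods_text))
        except ValueError as exc:
            if "unknown modification" in str(exc):
                unknown.append(str(exc))
                continue
            raise
        fdr_class = str(d["fdr_confidence"]).strip().lower()
        if fdr_class not in ("high", "medium", "low"):
            raise ValueError(f"invalid FDR confidence class {fdr_class!r}")
        intensities = {}
        for run in run_cols:
            v = d[run]
            intensities[run] = (
                None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            )
        records.append(
            PeptideRecord(
                sequence=str(d["sequence"]),
                protein_ids=tuple(str(d["protein_ids"]).split(";")),
                protein_start=int(d["protein_start"]),
                modifications=mods,
                psm_count=int(d["psm_count"]),
                fdr_class=fdr_class,
                intensities=intensities,
            )
        )
    if unknown:
        raise ValueError("; ".join(unknown))
    return records


# ---------------------------------------------------------------------------
# filtering / normalisation / imputation

def filter_confident(records: Sequence[PeptideRecord]) -> list[PeptideRecord]:
    """Keep peptides with high FDR confidence and strictly more than 2 PSMs."""
    return [r for r in records if r.fdr_class == "high" and r.psm_count > 2]


def normalize_total_intensity(
    records: Sequence[PeptideRecord],
) -> list[PeptideRecord]:
    """Rescale every run so its intensity total equals the grand mean of the
    raw run totals.  Within-run intensity ratios are preserved exactly;
    missing values stay missing."""
    if not records:
        return []
    runs = sorted({run for r in records for run in r.intensities})
    totals = {}
    for run in runs:
        observed = [
            r.intensities[run]
            for r in records
            if r.intensities.get(run) is not None
        ]
        if not observed:
            raise ValueError(f"run {run!r} has no observed intensities")
        totals[run] = sum(observed)
    target = sum(totals.values()) / len(totals)
    scale = {run: target / totals[run] for run in runs}
    out = []
    for r in records:
        scaled = {
            run: (None if v is None else v * scale[run])
            for run, v in r.intensities.items()
        }
        out.append(replace(r, intensities=scaled))
    return out


def _run_rng(seed: int, run_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(run_id.encode())])


def impute_low_abundance(
    records: Sequence[PeptideRecord], seed: int
) -> list[PeptideRecord]:
    """Replace missing intensities by low-abundance resampling.

    Each missing cell is drawn uniformly between the 0th and 5th percentile of
    that run's observed intensities, from a generator seeded by
    ``(seed, run_id)``; imputed cells are flagged on the record.
    """
    if not records:
        return []
    runs = sorted({run for r in records for run in r.intensities})
    bounds = {}
    rngs = {}
    for run in runs:
        observed = [
            r.intensities[run] for r in records if r.intensities.get(run) is not None
        ]
        if observed:
            bounds[run] = (
                float(np.percentile(observed, 0)),
                float(np.percentile(observed, 5)),
            )
            rngs[run] = _run_rng(seed, run)
    out = []
    for r in records:
        filled = dict(r.intensities)
        flagged = set(r.imputed)
        for run in sorted(filled):
            if filled[run] is None:
                if run not in bounds:
                    raise ValueError(f"run {run!r} has no observed intensities")
                lo, hi = bounds[run]
                filled[run] = float(rngs[run].uniform(lo, hi))
                flagged.add(run)
        out.append(replace(r, intensities=filled, imputed=frozenset(flagged)))
    return out


# ---------------------------------------------------------------------------
# fold changes

def peptide_fold_changes(
    records: Sequence[PeptideRecord], run_design: Mapping[str, tuple]
) -> list[PeptideFoldChange]:
    """log2(MUT/WT) per peptide and biological replicate.

    Technical-replicate runs within one biological replicate are averaged
    before the ratio is taken, so there is one fold change per (peptidoform,
    biological-replicate pair).
    """
    # (condition, biorep) -> run ids
    groups: dict[tuple, list[str]] = {}
    for run, (condition, biorep) in run_design.items():
        groups.setdefault((condition, biorep), []).append(run)
    bioreps = sorted(
        {b for (c, b) in groups} & {b for (c, b) in groups if c == "MUT"}
        & {b for (c, b) in groups if c == "WT"}
    )
    out = []
    for r in records:
        for b in bioreps:
            wt_runs = [x for x in groups.get(("WT", b), []) if x in r.intensities]
            mut_runs = [x for x in groups.get(("MUT", b), []) if x in r.intensities]
            wt_vals = [r.intensities[x] for x in wt_runs]
            mut_vals = [r.intensities[x] for x in mut_runs]
            if not wt_vals or not mut_vals or any(v is None for v in wt_vals + mut_vals):
                raise ValueError(
                    f"peptide {r.sequence!r}: unusable intensities in biological "
                    f"replicate {b} (impute before computing fold changes)"
                )
            wt_mean = sum(wt_vals) / len(wt_vals)
            mut_mean = sum(mut_vals) / len(mut_vals)
            if wt_mean == 0:
                raise ValueError(
                    f"peptide {r.sequence!r}: zero WT mean in biological replicate {b}"
                )
            out.append(
                PeptideFoldChange(
                    sequence=r.sequence,
                    modifications=r.modifications,
                    protein_ids=r.protein_ids,
                    biorep=b,
                    log2fc=math.log2(mut_mean / wt_mean),
                    n_wt=len(wt_vals),
                    n_mut=len(mut_vals),
                )
            )
    return out


def collapse_to_protein(
    fcs: Sequence[PeptideFoldChange],
    paralog_map: Mapping[str, str],
    min_peptides: int = 3,
) -> list[ProteinFoldChange]:
    """Aggregate peptide fold changes to paralog-collapsed protein families.

    Peptides bearing any modification other than carbamidomethyl are omitted;
    families with fewer than ``min_peptides`` distinct peptides are excluded.
    The family summary is the median peptide log2 fold change; the per-family
    p-value is a two-sided one-sample t-test of peptide log2 fold changes
    against zero, BH-adjusted across families.
    """
    fam_values: dict[str, list[float]] = {}
    fam_peptides: dict[str, set] = {}
    fam_ambiguous: dict[str, bool] = {}
    for fc in fcs:
        if any(m.name is not ModName.CARBAMIDOMETHYL for m in fc.modifications):
            continue
        families = {paralog_map.get(p, p) for p in fc.protein_ids}
        for fam in families:
            fam_values.setdefault(fam, []).append(fc.log2fc)
            fam_peptides.setdefault(fam, set()).add(fc.sequence)
            fam_ambiguous[fam] = fam_ambiguous.get(fam, False) or len(families) > 1
    rows = []
    for fam in sorted(fam_values):
        n_pep = len(fam_peptides[fam])
        if n_pep < min_peptides:
            continue
        vals = fam_values[fam]
        if len(set(vals)) == 1:
            # degenerate: zero variance; the t statistic is undefined
            p = 1.0 if vals[0] == 0 else 0.0
        else:
            p = float(ttest_1samp(vals, 0.0).pvalue)
        rows.append((fam, float(median(vals)), n_pep, p, fam_ambiguous[fam]))
    fdrs = bh_adjust([row[3] for row in rows])
    return [
        ProteinFoldChange(
            family=fam,
            median_log2fc=med,
            n_peptides=n_pep,
            p_value=p,
            fdr=fdr,
            ambiguous=amb,
        )
        for (fam, med, n_pep, p, amb), fdr in zip(rows, fdrs)
    ]


# ---------------------------------------------------------------------------
# N-terminal peptidoform classification

def classify_nterm_status(
    record: PeptideRecord, protein_sequence: str
) -> NTermStatus:
    """Assign the N-terminal peptidoform of one peptide.

    A peptide starting at residue 1 whose sequence begins with Met retains the
    initiator methionine; a peptide starting at residue 2, or reported at
    residue 1 with a Met-loss event, is processed; anything starting beyond
    residue 2 is internal.  N-terminal acetylation refines retained/processed
    into their acetylated forms.  The peptide sequence must agree with the
    protein at its reported position.
    """
    names = {m.name for m in record.modifications}
    has_metloss = bool(names & {ModName.MET_LOSS, ModName.MET_LOSS_ACETYL})
    has_nterm_acetyl = any(
        m.name in (ModName.ACETYL, ModName.MET_LOSS_ACETYL)
        and m.position == PROTEIN_NTERM
        for m in record.modifications
    )
    start = record.protein_start
    pep = record.sequence
    second_aa = protein_sequence[1] if len(protein_sequence) >= 2 else None

    def check(offset: int):
        expected = protein_sequence[offset : offset + len(pep)]
        if expected != pep:
            raise ValueError(
                f"peptide {pep!r} does not match protein sequence at residue "
                f"{offset + 1}"
            )

    if start == 1 and not has_metloss:
        check(0)
        kind = (
            NTermKind.IMET_RETAINED_ACETYL
            if has_nterm_acetyl
            else NTermKind.IMET_RETAINED
        )
        return NTermStatus(kind=kind, second_aa=second_aa)
    if start == 2 or (start == 1 and has_metloss):
        check(1)
        kind = (
            NTermKind.PROCESSED_ACETYL if has_nterm_acetyl else NTermKind.PROCESSED
        )
        return NTermStatus(kind=kind, second_aa=second_aa)
    check(start - 1)
    return NTermStatus(kind=NTermKind.INTERNAL, second_aa=None)


# ---------------------------------------------------------------------------
# iMet-retention statistics

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small untied samples (combined n <= 20), the
    tie-corrected normal approximation otherwise.
    """
    pooled = list(x) + list(y)
    small = len(pooled) <= 20
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if small and no_ties else "asymptotic"
    p = float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return min(p, 1.0)


def compare_imet_vs_all(
    fcs: Sequence[PeptideFoldChange], statuses: Sequence[NTermStatus]
) -> WilcoxonComparison:
    """Two-sided Wilcoxon rank-sum test of iMet-retained fold changes against
    all peptide fold changes (retained included in the reference group)."""
    if len(fcs) != len(statuses):
        raise ValueError("fold changes and statuses must be parallel")
    all_vals = [fc.log2fc for fc in fcs]
    imet_vals = [
        fc.log2fc for fc, st in zip(fcs, statuses) if st.kind in RETAINED_KINDS
    ]
    if not imet_vals:
        raise ValueError("no iMet-retained fold changes")
    if len(all_vals) < 2:
        raise ValueError("need at least 2 fold changes in total")
    p = rank_sum_test(imet_vals, all_vals)
    return WilcoxonComparison(
        p_value=p,
        n_imet=len(imet_vals),
        n_all=len(all_vals),
        median_imet=float(median(imet_vals)),
        median_all=float(median(all_vals)),
    )


@dataclass(frozen=True)
class NTermPipelineResult:
    fold_changes: tuple
    statuses: tuple
    comparison: "WilcoxonComparison"
    partition: "FoldChangePartition"
    proteins: tuple


def nterm_pipeline(
    records: Sequence[PeptideRecord],
    run_design: Mapping[str, tuple],
    protein_sequences: Mapping[str, str],
    paralog_map: Mapping[str, str],
    seed: int,
    threshold: float = 5.0,
) -> NTermPipelineResult:
    """Run the full downstream procedure on parsed peptide records.

    filter -> normalise -> impute -> peptide fold changes -> N-terminal
    classification -> retained-vs-all Wilcoxon -> fold-change partition ->
    paralog-collapsed protein medians.
    """
    kept = filter_confident(records)
    normalized = normalize_total_intensity(kept)
    imputed = impute_low_abundance(normalized, seed)
    fcs = peptide_fold_changes(imputed, run_design)
    record_by_key = {r.key: r for r in imputed}
    statuses = [
        classify_nterm_status(
            record_by_key[fc.key], protein_sequences[fc.protein_ids[0]]
        )
        for fc in fcs
    ]
    comparison = compare_imet_vs_all(fcs, statuses)
    partition = partition_by_fold_change(fcs, statuses, threshold)
    proteins = collapse_to_protein(fcs, paralog_map)
    return NTermPipelineResult(
        fold_changes=tuple(fcs),
        statuses=tuple(statuses),
        comparison=comparison,
        partition=partition,
        proteins=tuple(proteins),
    )


def partition_by_fold_change(
    fcs: Sequence[PeptideFoldChange],
    statuses: Sequence[NTermStatus],
    threshold: float = 5.0,
) -> FoldChangePartition:
    """Split iMet-retained peptides at a fold-change threshold.

    A retained peptide with log2fc >= log2(threshold) goes to the high group
    (the boundary belongs to the high group); per-group second-residue
    composition is reported as raw residues without any substrate-list
    masking.
    """
    if len(fcs) != len(statuses):
        raise ValueError("fold changes and statuses must be parallel")
    cut = math.log2(threshold)
    high, low = [], []
    high_comp: dict[str, int] = {}
    low_comp: dict[str, int] = {}
    for fc, st in zip(fcs, statuses):
        if st.kind not in RETAINED_KINDS:
            continue
        if fc.log2fc >= cut:
            high.append(fc)
            if st.second_aa:
                high_comp[st.second_aa] = high_comp.get(st.second_aa, 0) + 1
        else:
            low.append(fc)
            if st.second_aa:
                low_comp[st.second_aa] = low_comp.get(st.second_aa, 0) + 1
    return FoldChangePartition(
        threshold=threshold,
        high=tuple(high),
        low=tuple(low),
        high_composition=high_comp,
        low_composition=low_comp,
    )
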