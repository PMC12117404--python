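"""Translation-error rates from luciferase reporter replicates.

Gain-of-activity reporters quantify translation errors: in the dual-luciferase
design, Renilla (Rluc) and Firefly (Fluc) luciferases are encoded in tandem
with a stop codon between them, so Fluc is produced only on stop-codon
readthrough and Fluc/Rluc corrects for expression input.  The error rate is
the stop-construct Fluc/Rluc ratio as a percentage of the ratio from a
matched wild-type construct without the stop codon.  Single-luciferase (Nluc)
reporters for in vitro translation work the same way on a single channel,
with frameshift reporters handled identically.  The module also converts
A260 readings to ribosomal particle concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ttest_ind

ERROR_REPORTER = "ERROR_REPORTER"
WT_CONTROL = "WT_CONTROL"

#: nM of particles per A260 unit, by sedimentation species
A260_NM_PER_UNIT = {"S80": 20.0, "S40": 60.0, "S60": 30.0}
#: ng/ul RNA per A260 unit
A260_RNA_NG_PER_UL = 40.0


@dataclass(frozen=True)
class LuminescenceRecord:
    construct: str  # ERROR_REPORTER or WT_CONTROL
    assay: str  # 'DUAL' or 'SINGLE'
    rluc: float | None  # DUAL only
    signal: float  # Fluc (DUAL) or Nluc (SINGLE)
    condition: str
    replicate: int

    def __post_init__(self):
        if self.construct not in (ERROR_REPORTER, WT_CONTROL):
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.assay not in ("DUAL", "SINGLE"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.signal < 0:
            raise ValueError("signal must be non-negative")
        if self.assay == "DUAL" and (self.rluc is None or self.rluc <= 0):
            raise ValueError("DUAL records require rluc > 0")


@dataclass(frozen=True)
class ErrorRate:
    """Normalised mistranslation percentage with replicate summary."""

    condition: str
    percents: tuple
    mean: float
    sd: float
    n: int


def _ratio(rec: LuminescenceRecord, dual: bool) -> float:
    return rec.signal / rec.rluc if dual else rec.signal


def _error_rate(
    error_records: Sequence[LuminescenceRecord],
    wt_records: Sequence[LuminescenceRecord],
    dual: bool,
    pairing: str,
) -> ErrorRate:
    if not error_records or not wt_records:
        raise ValueError("need at least one replicate of each construct")
    if pairing not in ("mean", "paired"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    if pairing == "mean":
        wt_mean = float(np.mean([_ratio(r, dual) for r in wt_records]))
        if wt_mean == 0:
            raise ValueError("wild-type mean ratio is zero")
        percents = [100.0 * _ratio(r, dual) / wt_mean for r in error_records]
    else:
        wt_by_rep = {r.replicate: r for r in wt_records}
        percents = []
        for r in error_records:
            if r.replicate not in wt_by_rep:
                raise ValueError(
                    f"no wild-type replicate matching replicate {r.replicate}"
                )
            denom = _ratio(wt_by_rep[r.replicate], dual)
            if denom == 0:
                raise ValueError(f"wild-type ratio is zero in replicate {r.replicate}")
            percents.append(100.0 * _ratio(r, dual) / denom)
    arr = np.asarray(percents, dtype=float)
    return ErrorRate(
        condition=error_records[0].condition,
        percents=tuple(percents),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=int(arr.size),
    )


def error_rate_dual(
    stop_records: Sequence[LuminescenceRecord],
    wt_records: Sequence[LuminescenceRecord],
    pairing: str = "mean",
) -> ErrorRate:
    """Error rate from a dual-luciferase assay.

    Per stop-construct replicate, percent = 100 x (Fluc/Rluc)_stop divided by
    the mean wild-type (Fluc/Rluc) ratio (``pairing='mean'``), or by the
    matched wild-type replicate (``pairing='paired'``).  Values are not
    clipped at 100: a wild-type construct measured against itself can exceed
    100 by noise.
    """
    return _error_rate(stop_records, wt_records, dual=True, pairing=pairing)


def error_rate_single(
    error_records: Sequence[LuminescenceRecord],
    wt_records: Sequence[LuminescenceRecord],
    pairing: str = "mean",
) -> ErrorRate:
    """Error rate from a single-channel (Nluc) assay; same normalisation as
    :func:`error_rate_dual` on raw signals."""
    return _error_rate(error_records, wt_records, dual=False, pairing=pairing)


def compare_conditions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, str]:
    """Two-sided Welch two-sample t-test on replicate error rates.

    Returns ``(p_value, stars)`` with ``**`` for p < 0.01, ``*`` for
    p < 0.05, ``NS`` otherwise.  Two identical zero-variance groups give
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(ttest_ind(a, b, equal_var=False).pvalue)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else "NS"
    return p, stars


def a260_to_particle_concentration(
    a260: float, particle: str
) -> tuple[float, float]:
    """Convert an A260 reading to particle concentration and RNA mass.

    One A260 unit (40 ng/ul RNA) corresponds to 20 nM of 80S ribosomes, 60 nM
    of 40S subunits, or 30 nM of 60S subunits.  Returns ``(nM, ng_per_ul)``.
    """
    if a260 < 0:
        raise ValueError("a260 must be >= 0")
    if particle not in A260_NM_PER_UNIT:
        raise ValueError(
            f"unknown particle {particle!r}; expected one of {sorted(A260_NM_PER_UNIT)}"
        )
    return a260 * A260_NM_PER_UNIT[particle], a260 * A260_RNA_NG_PER_UL
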