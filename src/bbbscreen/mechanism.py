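"""Transport-mechanism calling: recovery filter, lysosomal-trapping
correction, and the four-quadrant Papp x ER classification.

A compound measured in the P-gp-overexpressing (MDR1) monolayer is placed in
one of four quadrants of the (Papp(A-B), ER) plane:

====================  ==========================  ============
category              Papp(A-B) vs 3e-6 cm/s      ER vs 2
====================  ==========================  ============
PASSIVE_HIGH          >= cut                      <= cut
PASSIVE_LOW           <  cut                      <= cut
PGP_LIMITED_LOW       <  cut                      >  cut
PGP_RETAINED_HIGH     >= cut                      >  cut
====================  ==========================  ============

Ties go to the high-permeability / passive side: a Papp exactly at the cut
counts as moderate-to-high, and an ER of exactly 2 counts as passive
(polarized efflux requires ER strictly above 2).

Compounds whose mass-balance recovery falls below 80% in any direction or
cell line are suspected of intracellular (lysosomal) accumulation; their
apparent permeability is an artifact.  If the assay was repeated with the
v-ATPase inhibitor bafilomycin A1 (which de-acidifies lysosomes and releases
the trapped pool) the corrected summary replaces the original; otherwise the
compound is called TRAPPED_UNRESOLVED rather than mis-binned.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .assay import CellLine, PermeabilitySummary, ValidationError, is_blq


class Category(str, Enum):
    PASSIVE_HIGH = "PASSIVE_HIGH"
    PASSIVE_LOW = "PASSIVE_LOW"
    PGP_LIMITED_LOW = "PGP_LIMITED_LOW"
    PGP_RETAINED_HIGH = "PGP_RETAINED_HIGH"
    TRAPPED_UNRESOLVED = "TRAPPED_UNRESOLVED"


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs (Papp on the 1e-6 cm/s scale)."""

    papp_cut: float = 3.0
    er_cut: float = 2.0
    recovery_min: float = 80.0

    def __post_init__(self) -> None:
        if not (self.papp_cut > 0 and self.er_cut > 0 and self.recovery_min > 0):
            raise ValidationError("thresholds must be positive")


@dataclass
class MechanismCall:
    compound_id: str
    category: Category
    papp_used: float | None
    er_used: float | None
    corrected_by_bafA1: bool = False
    recovery_pass: bool = True


@dataclass
class RecoveryFilterResult:
    passing: list[str]
    flagged: list[str]
    unevaluable: list[str]


# --------------------------------------------------------------------------
# Recovery filter
# --------------------------------------------------------------------------

def recovery_filter(
    summaries: Sequence[PermeabilitySummary],
    thresholds: Thresholds | None = None,
) -> RecoveryFilterResult:
    """Partition compounds by worst-case mass balance.

    A compound is flagged iff its minimum recovery over all four
    direction x cell-line combinations is below ``recovery_min`` (a recovery
    of exactly 80% passes).  Compounds missing any of the four recoveries are
    reported unevaluable, never silently passed.
    """
    thresholds = thresholds or Thresholds()
    by_compound: dict[str, list[PermeabilitySummary]] = {}
    for s in summaries:
        by_compound.setdefault(s.compound_id, []).append(s)

    result = RecoveryFilterResult([], [], [])
    for cid in by_compound:
        rows = by_compound[cid]
        lines = {r.cell_line for r in rows}
        recoveries: list[float] = []
        complete = lines == {CellLine.MOCK, CellLine.MDR1}
        for r in rows:
            if r.recovery_ab is None or r.recovery_ba is None:
                complete = False
            else:
                recoveries.extend([r.recovery_ab, r.recovery_ba])
        if not complete:
            result.unevaluable.append(cid)
        elif min(recoveries) < thresholds.recovery_min:
            result.flagged.append(cid)
        else:
            result.passing.append(cid)
    return result


# --------------------------------------------------------------------------
# Bafilomycin A1 substitution
# --------------------------------------------------------------------------

def apply_bafA1_correction(
    base: PermeabilitySummary,
    bafA1: PermeabilitySummary,
    thresholds: Thresholds | None = None,
) -> PermeabilitySummary:
    """Substitute the bafilomycin-A1 rerun for a trapping-suspect summary.

    Returns the Baf-A1 summary marked ``corrected_by_bafA1``; the trapping
    flag is retained when even the corrected recovery stays below the
    threshold (correction failed).  Applying the correction to a compound
    whose base recovery already passed is allowed but warned about.
    """
    thresholds = thresholds or Thresholds()
    if base.compound_id != bafA1.compound_id or base.cell_line != bafA1.cell_line:
        raise ValidationError("base and Baf-A1 summaries must match compound and cell line")
    base_min = base.min_recovery()
    if base_min is not None and base_min >= thresholds.recovery_min:
        warnings.warn(
            f"{base.compound_id}: Baf-A1 correction applied although base "
            f"recovery ({base_min:.1f}%) already passes",
            UserWarning,
            stacklevel=2,
        )
    corrected_min = bafA1.min_recovery()
    still_trapped = corrected_min is not None and corrected_min < thresholds.recovery_min
    return replace(
        bafA1,
        corrected_by_bafA1=True,
        trapping_flag=still_trapped,
    )


# --------------------------------------------------------------------------
# Quadrant classification
# --------------------------------------------------------------------------

def classify(
    summary: PermeabilitySummary,
    thresholds: Thresholds | None = None,
    *,
    recovery_pass: bool = True,
) -> MechanismCall:
    """Quadrant call from an MDR1-cell summary (post any Baf-A1 substitution)."""
    thresholds = thresholds or Thresholds()
    if summary.cell_line is not CellLine.MDR1:
        raise ValidationError("classification uses the MDR1 (efflux-competent) cell line")
    papp = summary.papp_ab
    er = summary.er
    if is_blq(papp) or papp is None or er is None:
        raise ValidationError(
            f"{summary.compound_id}: cannot classify, Papp(A-B) or ER undefined (BLQ)"
        )
    high = papp >= thresholds.papp_cut
    efflux = er > thresholds.er_cut
    if high:
        category = Category.PGP_RETAINED_HIGH if efflux else Category.PASSIVE_HIGH
    else:
        category = Category.PGP_LIMITED_LOW if efflux else Category.PASSIVE_LOW
    return MechanismCall(
        compound_id=summary.compound_id,
        category=category,
        papp_used=papp,
        er_used=er,
        corrected_by_bafA1=summary.corrected_by_bafA1,
        recovery_pass=recovery_pass,
    )


def classify_cohort(
    mdr1_summaries: Sequence[PermeabilitySummary],
    all_summaries: Sequence[PermeabilitySummary] | None = None,
    bafA1_summaries: Sequence[PermeabilitySummary] = (),
    thresholds: Thresholds | None = None,
) -> list[MechanismCall]:
    """Call every compound: recovery filter, Baf-A1 substitution, quadrants.

    ``all_summaries`` (both cell lines) feeds the recovery filter; it
    defaults to the MDR1 summaries alone when only those exist.  Flagged
    compounds with a Baf-A1 rerun are classified from the corrected record;
    flagged compounds without one are TRAPPED_UNRESOLVED.
    """
    thresholds = thresholds or Thresholds()
    filt = recovery_filter(list(all_summaries or mdr1_summaries), thresholds)
    flagged = set(filt.flagged)
    baf_by_id = {
        s.compound_id: s
        for s in bafA1_summaries
        if s.cell_line is CellLine.MDR1
    }
    calls: list[MechanismCall] = []
    for s in mdr1_summaries:
        if s.compound_id not in flagged:
            calls.append(classify(s, thresholds, recovery_pass=True))
            continue
        baf = baf_by_id.get(s.compound_id)
        if baf is None:
            calls.append(
                MechanismCall(
                    compound_id=s.compound_id,
                    category=Category.TRAPPED_UNRESOLVED,
                    papp_used=None if is_blq(s.papp_ab) else s.papp_ab,
                    er_used=s.er,
                    recovery_pass=False,
                )
            )
        else:
            corrected = apply_bafA1_correction(s, baf, thresholds)
            call = classify(corrected, thresholds, recovery_pass=False)
            calls.append(call)
    return calls


# --------------------------------------------------------------------------
# Cohort report
# --------------------------------------------------------------------------

def cohort_report(calls: Iterable[MechanismCall]) -> dict:
    """Category counts and percentages (one call per compound)."""
    calls = list(calls)
    ids = [c.compound_id for c in calls]
    dupes = [cid for cid, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate compound ids in cohort: {dupes}")
    n = len(calls)
    if n == 0:
        raise ValidationError("empty cohort")
    counts = Counter(c.category.value for c in calls)
    return {
        "n": n,
        "counts": {cat.value: counts.get(cat.value, 0) for cat in Category},
        "fractions_pct": {
            cat.value: round(100.0 * counts.get(cat.value, 0) / n, 1)
            for cat in Category
        },
    }
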