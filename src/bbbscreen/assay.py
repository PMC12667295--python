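"""Bidirectional Transwell assay analytics.

Converts raw per-well measurements from a two-chamber (Transwell) monolayer
assay into the three quantities a permeability screen reports per compound
and cell line:

* the apparent permeability coefficient ``Papp = (dQ/dt) / (A * C0)``,
  estimated from the single endpoint receiver amount under a sink assumption,
* the efflux ratio ``ER = Papp(B->A) / Papp(A->B)``, and
* the mass-balance recovery
  ``100 * (receiver + donor_final [+ lysate]) / donor_initial``.

All Papp values in this package are expressed in units of 1e-6 cm/s, the
scale on which assay results are conventionally tabulated (a "Papp of 3"
means 3e-6 cm/s).  Internally the arithmetic is done in consistent
nmol / uM / mL / cm2 / s units: 1 uM = 1 nmol/mL = 1 nmol/cm3, so
``(nmol/s) / (cm2 * nmol/cm3)`` is cm/s with no hidden conversion factor.

Quantities below the LC-MS/MS quantification limit are carried as the
distinguished :data:`BLQ` sentinel, never as zero: a BLQ receiver amount
yields a BLQ permeability and an undefined efflux ratio (rendered ``\\``),
mirroring how such cells appear in assay report tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from statistics import mean, stdev
from typing import Mapping, Sequence


# --------------------------------------------------------------------------
# Sentinels, enums and defaults
# --------------------------------------------------------------------------

class _BlqType:
    """Singleton marker for a below-limit-of-quantification measurement."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "BLQ"

    def __bool__(self) -> bool:
        return False


#: Below-limit-of-quantification sentinel. Not a number, not zero.
BLQ = _BlqType()


def is_blq(value) -> bool:
    return value is BLQ


class CellLine(str, Enum):
    MOCK = "MOCK"
    MDR1 = "MDR1"


class Direction(str, Enum):
    AtoB = "AtoB"
    BtoA = "BtoA"


class Inhibitor(str, Enum):
    NONE = "none"
    TARIQUIDAR = "tariquidar"
    BAFILOMYCIN_A1 = "bafilomycinA1"


#: Insert membrane area (cm2) of the 24-well Transwell format used.
DEFAULT_AREA_CM2 = 0.33
#: Apical and basolateral chamber working volumes (mL) for that plate format.
APICAL_VOLUME_ML = 0.200
BASOLATERAL_VOLUME_ML = 0.850


def default_volumes(direction: Direction) -> tuple[float, float]:
    """(donor, receiver) volumes in mL for a direction under default geometry.

    A->B doses the apical (upper) chamber; B->A doses the basolateral.
    """
    direction = Direction(direction)
    if direction is Direction.AtoB:
        return APICAL_VOLUME_ML, BASOLATERAL_VOLUME_ML
    return BASOLATERAL_VOLUME_ML, APICAL_VOLUME_ML


class ValidationError(ValueError):
    """Raised when an input record violates its physical invariants."""


class SinkConditionWarning(UserWarning):
    """Endpoint receiver/donor concentration ratio exceeds the sink bound."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class TransportRecord:
    """One well x direction x condition raw measurement set.

    Amounts are nmol, concentrations uM, volumes mL, area cm2, duration s.
    ``c_donor_final``, ``receiver_amount_nmol`` and ``lysate_amount_nmol``
    may be the :data:`BLQ` sentinel; ``lysate_amount_nmol`` may be None when
    the monolayer was not lysed.
    """

    compound_id: str
    cell_line: CellLine
    direction: Direction
    c0_donor: float                      # uM at t=0 in the donor chamber
    c_donor_final: float | _BlqType      # uM at t=end in the donor chamber
    receiver_amount: float | _BlqType    # nmol in the receiver at t=end
    v_donor: float | None = None         # mL; default from plate geometry
    v_receiver: float | None = None      # mL
    area: float = DEFAULT_AREA_CM2       # cm2
    duration: float = 7200.0             # s
    lysate_amount: float | _BlqType | None = None  # nmol recovered from cells
    inhibitor: Inhibitor = Inhibitor.NONE
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.cell_line = CellLine(self.cell_line)
        self.direction = Direction(self.direction)
        self.inhibitor = Inhibitor(self.inhibitor)
        if self.v_donor is None or self.v_receiver is None:
            vd, vr = default_volumes(self.direction)
            self.v_donor = vd if self.v_donor is None else self.v_donor
            self.v_receiver = vr if self.v_receiver is None else self.v_receiver
        if not self.c0_donor > 0:
            raise ValidationError(f"c0_donor must be > 0, got {self.c0_donor}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if not self.area > 0:
            raise ValidationError(f"area must be > 0, got {self.area}")
        if not (self.v_donor > 0 and self.v_receiver > 0):
            raise ValidationError("chamber volumes must be > 0")
        for name in ("c_donor_final", "receiver_amount", "lysate_amount"):
            v = getattr(self, name)
            if v is None or is_blq(v):
                continue
            if v < 0:
                raise ValidationError(f"{name} must be >= 0 or BLQ, got {v}")

    @property
    def donor_amount_initial(self) -> float:
        """Initial donor amount Cdi * VD (nmol)."""
        return self.c0_donor * self.v_donor


@dataclass
class PermeabilitySummary:
    """Per compound x cell line aggregate of replicate wells.

    Papp fields are in 1e-6 cm/s; recoveries in percent. ``er`` is None when
    undefined (A->B permeability BLQ or zero), matching the ``\\`` table
    convention.
    """

    compound_id: str
    cell_line: CellLine
    papp_ab: float | _BlqType
    papp_ba: float | _BlqType
    er: float | None
    recovery_ab: float | None = None
    recovery_ba: float | None = None
    papp_ab_sd: float | None = None
    papp_ba_sd: float | None = None
    recovery_ab_sd: float | None = None
    recovery_ba_sd: float | None = None
    recovery_lysate_corrected: float | None = None
    n_replicates: int = 0
    qc_pass: bool | None = None
    trapping_flag: bool = False
    corrected_by_bafA1: bool = False

    def __post_init__(self) -> None:
        self.cell_line = CellLine(self.cell_line)
        for name in ("papp_ab_sd", "papp_ba_sd", "recovery_ab_sd", "recovery_ba_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")

    def min_recovery(self) -> float | None:
        vals = [v for v in (self.recovery_ab, self.recovery_ba) if v is not None]
        return min(vals) if vals else None


@dataclass(frozen=True)
class TeerMeasurement:
    """One transepithelial electrical resistance reading."""

    r_total: float            # Ohm, insert with monolayer
    r_blank: float            # Ohm, blank insert
    area: float = DEFAULT_AREA_CM2  # cm2
    day: int = 0


@dataclass(frozen=True)
class QCPolicy:
    """Batch acceptance gates for a monolayer transport assay.

    * Lucifer Yellow Papp inside ``ly_papp_window`` certifies tight junctions.
    * TEER at the assay day must be at least ``teer_min``.
    * The replicate CV of each control drug's Papp(A-B) must stay below
      ``control_cv_max``.
    * Per-well mass balance should land in ``recovery_window``; lower values
      flag intracellular accumulation (handled downstream, not a batch fail).
    * ``sink_ratio_max`` bounds the endpoint receiver/donor concentration
      ratio below which the single-endpoint Papp estimator is trusted.
    """

    ly_papp_window: tuple[float, float] = (0.2, 2.0)   # 1e-6 cm/s
    teer_min: float = 70.0                             # Ohm*cm2
    control_cv_max: float = 15.0                       # percent
    recovery_window: tuple[float, float] = (80.0, 120.0)  # percent
    sink_ratio_max: float = 0.10                       # receiver/donor conc

    def __post_init__(self) -> None:
        for lo, hi in (self.ly_papp_window, self.recovery_window):
            if not (0 < lo < hi):
                raise ValidationError("QC windows need 0 < lower < upper")
        if not (self.teer_min > 0 and self.control_cv_max > 0 and self.sink_ratio_max > 0):
            raise ValidationError("QC bounds must be positive")


@dataclass
class BatchQC:
    """Result of the QC gate for one assay batch."""

    batch_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    ly_papp: float | None = None
    teer: float | None = None
    control_cv: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Per-well operations
# --------------------------------------------------------------------------

def compute_papp(record: TransportRecord, *, policy: QCPolicy | None = None):
    """Endpoint apparent permeability in 1e-6 cm/s, or :data:`BLQ`.

    ``Papp = (Q_receiver / t) / (A * C0)`` with Q in nmol, t in s, A in cm2
    and C0 in uM (= nmol/cm3).  Valid under sink conditions; when the final
    receiver/donor concentration ratio exceeds ``policy.sink_ratio_max`` a
    :class:`SinkConditionWarning` is emitted (the estimate is still
    returned — it is biased low, not wrong in kind).
    """
    if is_blq(record.receiver_amount):
        return BLQ
    rate = record.receiver_amount / record.duration          # nmol/s
    papp_cm_s = rate / (record.area * record.c0_donor)       # cm/s
    policy = policy or QCPolicy()
    if (record.c_donor_final is not None and not is_blq(record.c_donor_final)
            and record.c_donor_final > 0):
        ratio = (record.receiver_amount / record.v_receiver) / record.c_donor_final
        if ratio > policy.sink_ratio_max:
            warnings.warn(
                f"{record.compound_id} {record.direction.value}: receiver/donor "
                f"concentration ratio {ratio:.2f} exceeds sink bound "
                f"{policy.sink_ratio_max:g}; endpoint Papp is biased low",
                SinkConditionWarning,
                stacklevel=2,
            )
    return papp_cm_s * 1e6


def compute_efflux_ratio(papp_ab, papp_ba) -> float | None:
    """``Papp(B->A) / Papp(A->B)``; None when undefined (rendered ``\\``)."""
    if is_blq(papp_ab) or is_blq(papp_ba) or papp_ab is None or papp_ba is None:
        return None
    if papp_ab <= 0:
        return None
    return papp_ba / papp_ab


def compute_recovery(record: TransportRecord, include_lysate: bool = False) -> float:
    """Mass-balance recovery in percent.

    ``100 * (TR_cum + Cdf*VD [+ lysate]) / (Cdi*VD)``. BLQ receiver or donor
    terms contribute zero mass (they are below quantification, and recovery
    is a sum of measured masses).
    """
    initial = record.donor_amount_initial
    if not initial > 0:
        raise ValidationError("initial donor amount must be positive")
    receiver = 0.0 if is_blq(record.receiver_amount) else record.receiver_amount
    donor_final = 0.0 if is_blq(record.c_donor_final) else record.c_donor_final * record.v_donor
    total = receiver + donor_final
    if include_lysate:
        if record.lysate_amount is None:
            raise ValidationError(
                f"{record.compound_id}: lysate amount requested but not measured"
            )
        total += 0.0 if is_blq(record.lysate_amount) else record.lysate_amount
    return 100.0 * total / initial


def compute_teer(m: TeerMeasurement) -> float:
    """Blank-corrected TEER in Ohm*cm2: ``(R_total - R_blank) * area``."""
    if not m.area > 0:
        raise ValidationError("area must be > 0")
    teer = (m.r_total - m.r_blank) * m.area
    if teer < 0:
        warnings.warn(
            f"negative TEER ({teer:.1f} Ohm*cm2): blank exceeds total resistance, "
            "check electrodes/blank insert",
            UserWarning,
            stacklevel=2,
        )
    return teer


# --------------------------------------------------------------------------
# Replicate aggregation
# --------------------------------------------------------------------------

def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    return mean(values), (stdev(values) if len(values) > 1 else 0.0)


def summarize_permeability(
    records: Sequence[TransportRecord],
    *,
    include_lysate: bool = False,
    policy: QCPolicy | None = None,
) -> PermeabilitySummary:
    """Aggregate replicate wells of one compound x cell line into a summary.

    Papp and recovery are computed per well then averaged (mean +/- sd); the
    efflux ratio is the ratio of the direction means, matching how assay
    tables are assembled.  If any replicate in a direction is BLQ the whole
    direction is reported BLQ (a mean of quantifiable and non-quantifiable
    wells is not meaningful).
    """
    if not records:
        raise ValidationError("no records to summarize")
    ids = {r.compound_id for r in records}
    lines = {r.cell_line for r in records}
    if len(ids) != 1 or len(lines) != 1:
        raise ValidationError("records must share compound_id and cell_line")

    by_dir: dict[Direction, list[TransportRecord]] = {d: [] for d in Direction}
    for r in records:
        by_dir[r.direction].append(r)

    papp_stats: dict[Direction, tuple] = {}
    rec_stats: dict[Direction, tuple] = {}
    n_max = 0
    lysate_recoveries: list[float] = []
    for d, recs in by_dir.items():
        if not recs:
            papp_stats[d] = (None, None)
            rec_stats[d] = (None, None)
            continue
        n_max = max(n_max, len(recs))
        papps = [compute_papp(r, policy=policy) for r in recs]
        if any(is_blq(p) for p in papps):
            papp_stats[d] = (BLQ, None)
        else:
            papp_stats[d] = _mean_sd(papps)
        rec_stats[d] = _mean_sd([compute_recovery(r) for r in recs])
        if include_lysate and all(r.lysate_amount is not None for r in recs):
            lysate_recoveries.extend(
                compute_recovery(r, include_lysate=True) for r in recs
            )

    ab, ab_sd = papp_stats[Direction.AtoB]
    ba, ba_sd = papp_stats[Direction.BtoA]
    return PermeabilitySummary(
        compound_id=next(iter(ids)),
        cell_line=next(iter(lines)),
        papp_ab=ab,
        papp_ba=ba,
        er=compute_efflux_ratio(ab, ba),
        recovery_ab=rec_stats[Direction.AtoB][0],
        recovery_ba=rec_stats[Direction.BtoA][0],
        papp_ab_sd=ab_sd,
        papp_ba_sd=ba_sd,
        recovery_ab_sd=rec_stats[Direction.AtoB][1],
        recovery_ba_sd=rec_stats[Direction.BtoA][1],
        recovery_lysate_corrected=(
            mean(lysate_recoveries) if lysate_recoveries else None
        ),
        n_replicates=n_max,
    )


# --------------------------------------------------------------------------
# Batch QC
# --------------------------------------------------------------------------

def run_qc(
    *,
    batch_id: str,
    ly_papp: float,
    teer: float,
    control_papp_ab: Mapping[str, Sequence[float]],
    policy: QCPolicy | None = None,
) -> BatchQC:
    """Gate one assay batch on monolayer integrity and control-drug precision.

    ``ly_papp`` is the Lucifer Yellow A->B Papp (1e-6 cm/s) for the batch,
    ``teer`` the blank-corrected resistance (Ohm*cm2) on the assay day, and
    ``control_papp_ab`` maps each control drug to its replicate Papp(A-B)
    values.  The batch fails if LY is outside its window (paracellular leak
    or over-tight/blocked insert), TEER is below the minimum, or any control
    drug's replicate CV (sd/mean) reaches the CV ceiling.
    """
    policy = policy or QCPolicy()
    if not control_papp_ab:
        raise ValidationError("QC needs at least one control drug per batch")
    reasons: list[str] = []
    lo, hi = policy.ly_papp_window
    if not (lo <= ly_papp <= hi):
        reasons.append(
            "paracellular leak" if ly_papp > hi
            else f"LY Papp {ly_papp:g} below window [{lo:g}, {hi:g}]"
        )
    if teer < policy.teer_min:
        reasons.append(f"TEER {teer:g} below minimum {policy.teer_min:g} Ohm*cm2")
    cvs: dict[str, float] = {}
    for drug, reps in control_papp_ab.items():
        if not reps:
            raise ValidationError(f"control drug {drug} has no replicates")
        m, sd = _mean_sd(list(reps))
        cv = 100.0 * sd / m if m > 0 else math.inf
        cvs[drug] = cv
        if cv >= policy.control_cv_max:
            reasons.append(
                f"control {drug} CV {cv:.1f}% >= {policy.control_cv_max:g}%"
            )
    return BatchQC(
        batch_id=batch_id,
        passed=not reasons,
        reasons=reasons,
        ly_papp=ly_papp,
        teer=teer,
        control_cv=cvs,
    )


# --------------------------------------------------------------------------
# Table-style rendering
# --------------------------------------------------------------------------

def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def format_papp(value) -> str:
    """Papp cell on the 1e-6 cm/s scale: 3 significant figures or BLQ."""
    if is_blq(value) or value is None:
        return "BLQ"
    return f"{round_sig(value, 3):g}"


def format_er(value) -> str:
    """Efflux-ratio cell: 3 significant figures, or the undefined marker."""
    if value is None:
        return "\\"
    return f"{round_sig(value, 3):g}"


def format_recovery(value) -> str:
    if value is None:
        return ""
    return f"{value:.1f}"
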