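"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* Transwell bidirectional transport with optional polarized efflux and a
  phenomenological lysosomal sink,
* equilibrium dialysis of plasma and diluted brain homogenate, and
* one-compartment IV pharmacokinetics in plasma and brain.

The transport model is the two-compartment (donor/receiver) membrane system

    dQ_D/dt = -J,   J = P_eff * A * (C_D - C_R)
    dQ_R/dt = (1 - f) * J,    dQ_cell/dt = f * J

where ``f`` is the fraction of transcellular flux diverted into a cell
compartment (the trapping sink; the observable phenomenology of lysosomal
sequestration — depressed recovery and apparent permeability, mass in the
lysate — without a kinetic lysosome model).  The concentration difference
decays as ``exp(-k t)`` with ``k = P_eff*A*(1/V_D + (1-f)/V_R)``, giving a
closed-form endpoint used by the simulator; tests check it against an
independent numerical ODE solution.

Polarized efflux in the MDR1 line uses the symmetric square-root
convention: ``P_eff(B->A) = P * sqrt(m)`` and ``P_eff(A->B) = P / sqrt(m)``
for an efflux multiplier ``m``, so the simulated efflux ratio equals ``m``.
A bafilomycin-A1 condition is the same run with the sink disabled.

All noise is multiplicative lognormal with unit mean at a given CV, and all
generators are deterministic given their seed: changing only the seed
changes the noise, never the noiseless limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import (
    BASOLATERAL_VOLUME_ML,
    APICAL_VOLUME_ML,
    DEFAULT_AREA_CM2,
    CellLine,
    Direction,
    Inhibitor,
    TransportRecord,
    ValidationError,
)
from .brainpk import (
    BindingRecord,
    ConcentrationProfile,
    Matrix,
    apparent_fu,
)


@dataclass(frozen=True)
class Geometry:
    """Transwell plate geometry (mL, cm2)."""

    v_apical: float = APICAL_VOLUME_ML
    v_basolateral: float = BASOLATERAL_VOLUME_ML
    area: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        if not (self.v_apical > 0 and self.v_basolateral > 0 and self.area > 0):
            raise ValidationError("geometry volumes and area must be positive")

    def volumes(self, direction: Direction) -> tuple[float, float]:
        if Direction(direction) is Direction.AtoB:
            return self.v_apical, self.v_basolateral
        return self.v_basolateral, self.v_apical


@dataclass
class AssayTruth:
    """Ground truth for one simulated compound's transport behaviour.

    ``efflux_multiplier`` m >= 1 acts only in the MDR1 line via the
    square-root convention (simulated ER = m); ``trapping_fraction`` is the
    share of transcellular flux sequestered in the cell compartment.
    """

    compound_id: str
    papp_true: float                 # 1e-6 cm/s, intrinsic passive Papp
    efflux_multiplier: float = 1.0
    trapping_fraction: float = 0.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.papp_true > 0:
            raise ValidationError("papp_true must be positive")
        if self.efflux_multiplier < 1:
            raise ValidationError("efflux_multiplier must be >= 1")
        if not 0 <= self.trapping_fraction < 1:
            raise ValidationError("trapping_fraction must be in [0, 1)")


@dataclass
class PKTruth:
    """Ground truth for one simulated compound's in vivo disposition."""

    compound_id: str
    k_elim: float                    # 1/h terminal elimination rate
    c0_plasma: float = 1000.0        # concentration scale at t=0 (e.g. ng/mL)
    kp_brain_true: float = 1.0
    fu_plasma_true: float = 0.5
    fu_brain_true: float = 0.5
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k_elim > 0 and self.c0_plasma > 0 and self.kp_brain_true > 0):
            raise ValidationError("rates and scales must be positive")
        for name in ("fu_plasma_true", "fu_brain_true"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


# --------------------------------------------------------------------------
# Transwell transport
# --------------------------------------------------------------------------

def transport_endpoint(
    papp_1e6: float,
    c0: float,
    v_donor: float,
    v_receiver: float,
    area: float,
    duration: float,
    trapping_fraction: float = 0.0,
) -> tuple[float, float, float]:
    """Exact noiseless endpoint (Q_donor, Q_receiver, Q_cell) in nmol.

    Closed-form solution of the two-compartment system for a permeability
    ``papp_1e6`` (1e-6 cm/s), initial donor concentration ``c0`` (uM) and an
    initially empty receiver.
    """
    p = papp_1e6 * 1e-6                       # cm/s
    f = trapping_fraction
    k = p * area * (1.0 / v_donor + (1.0 - f) / v_receiver)   # 1/s
    q0 = c0 * v_donor
    transported = p * area * c0 * (1.0 - math.exp(-k * duration)) / k
    return q0 - transported, (1.0 - f) * transported, f * transported


def effective_papp(truth: AssayTruth, cell_line: CellLine, direction: Direction) -> float:
    """Direction- and cell-line-specific permeability (1e-6 cm/s)."""
    if CellLine(cell_line) is not CellLine.MDR1 or truth.efflux_multiplier == 1.0:
        return truth.papp_true
    root = math.sqrt(truth.efflux_multiplier)
    if Direction(direction) is Direction.BtoA:
        return truth.papp_true * root
    return truth.papp_true / root


def simulate_transport_assay(
    truth: AssayTruth,
    geometry: Geometry | None = None,
    duration: float = 7200.0,
    c0: float = 2.0,
    n_replicates: int = 3,
    bafA1: bool = False,
    measure_lysate: bool = True,
) -> list[TransportRecord]:
    """Simulate one compound's bidirectional assay in both cell lines.

    Returns ``2 directions x 2 cell lines x n_replicates`` records.  With
    ``bafA1`` the lysosomal sink is disabled and the inhibitor flag set —
    the in silico analogue of the bafilomycin-A1 rerun.  Emits a non-sink
    warning when the noiseless endpoint receiver/donor concentration ratio
    exceeds 0.5.
    """
    geometry = geometry or Geometry()
    rng = np.random.default_rng(truth.seed + (1 if bafA1 else 0))
    f = 0.0 if bafA1 else truth.trapping_fraction
    records: list[TransportRecord] = []
    for cell_line in (CellLine.MOCK, CellLine.MDR1):
        for direction in (Direction.AtoB, Direction.BtoA):
            vd, vr = geometry.volumes(direction)
            p_eff = effective_papp(truth, cell_line, direction)
            qd, qr, qc = transport_endpoint(
                p_eff, c0, vd, vr, geometry.area, duration, f
            )
            if (qr / vr) / (qd / vd) > 0.5:
                import warnings

                warnings.warn(
                    f"{truth.compound_id} {cell_line.value} {direction.value}: "
                    "non-sink regime (receiver/donor ratio > 0.5)",
                    UserWarning, stacklevel=2,
                )
            for rep in range(1, n_replicates + 1):
                noise = _lognormal_factor(rng, truth.noise_cv, size=3)
                records.append(
                    TransportRecord(
                        compound_id=truth.compound_id,
                        cell_line=cell_line,
                        direction=direction,
                        c0_donor=c0,
                        c_donor_final=(qd / vd) * noise[0],
                        receiver_amount=qr * noise[1],
                        v_donor=vd,
                        v_receiver=vr,
                        area=geometry.area,
                        duration=duration,
                        lysate_amount=(qc * noise[2]) if measure_lysate else None,
                        inhibitor=Inhibitor.BAFILOMYCIN_A1 if bafA1 else Inhibitor.NONE,
                        replicate_id=rep,
                    )
                )
    return records


# --------------------------------------------------------------------------
# Equilibrium dialysis
# --------------------------------------------------------------------------

def simulate_dialysis(
    fu_true: float,
    D: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    compound_id: str = "synthetic",
    matrix: Matrix = Matrix.PLASMA,
    c_sample: float = 5.0,
) -> BindingRecord:
    """Simulate one equilibrium-dialysis measurement.

    Forward-applies the dilution relation to get the apparent free fraction
    in a D-fold diluted sample, then produces noisy buffer/sample chamber
    concentrations whose ratio is the measured apparent fu.  The noiseless
    round-trip through the undiluted-fu correction recovers ``fu_true``
    exactly.
    """
    rng = np.random.default_rng(seed)
    fu_app = apparent_fu(fu_true, D)
    conc_buffer = fu_app * c_sample * float(_lognormal_factor(rng, noise_cv))
    conc_sample = c_sample * float(_lognormal_factor(rng, noise_cv))
    measured = min(conc_buffer / conc_sample, 1.0)
    return BindingRecord(
        compound_id=compound_id,
        matrix=matrix,
        fu_apparent=measured,
        dilution_factor=D,
    )


# --------------------------------------------------------------------------
# IV pharmacokinetics
# --------------------------------------------------------------------------

def simulate_iv_pk(
    truth: PKTruth,
    timepoints: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
) -> tuple[ConcentrationProfile, ConcentrationProfile]:
    """Mono-exponential plasma and brain profiles after an IV bolus.

    The brain profile is the plasma profile scaled by ``kp_brain_true`` with
    the same elimination rate, so the AUC(0-inf) ratio equals the true Kp.
    """
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 3:
        raise ValidationError("need at least 3 timepoints")
    rng = np.random.default_rng(truth.seed)
    base = truth.c0_plasma * np.exp(-truth.k_elim * t)
    plasma = base * _lognormal_factor(rng, truth.noise_cv, size=len(t))
    brain = truth.kp_brain_true * base * _lognormal_factor(rng, truth.noise_cv, size=len(t))
    mk = lambda conc, matrix: ConcentrationProfile(
        compound_id=truth.compound_id,
        matrix=matrix,
        times=t,
        concentrations=conc,
        dose=1.0,
    )
    return mk(plasma, Matrix.PLASMA), mk(brain, Matrix.BRAIN)


# --------------------------------------------------------------------------
# End-to-end cohort
# --------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for a synthetic IVIVC cohort."""

    slope: float
    intercept: float
    sigma_log10: float
    assays: list[AssayTruth] = field(default_factory=list)
    pk: list[PKTruth] = field(default_factory=list)
    kpuu_true: dict[str, float] = field(default_factory=dict)


def simulate_ivivc_cohort(
    n_compounds: int = 20,
    slope: float = 0.8,
    intercept: float = -1.2,
    sigma_log10: float = 0.1,
    papp_range: tuple[float, float] = (0.5, 40.0),
    noise_cv: float = 0.05,
    seed: int = 0,
) -> CohortTruth:
    """A cohort whose Kp,uu lies on a known log-log line in Papp.

    True permeabilities are log-uniform over ``papp_range``; each compound's
    Kp,uu is drawn from the line with lognormal scatter ``sigma_log10``, and
    in vivo truths (elimination rate, binding, Kp) are chosen consistently
    so the full pipeline — assay simulation, Papp estimation, PK/dialysis
    simulation, Kp,uu derivation, IVIVC fit — should recover the line.
    """
    rng = np.random.default_rng(seed)
    log_lo, log_hi = math.log10(papp_range[0]), math.log10(papp_range[1])
    truth = CohortTruth(slope=slope, intercept=intercept, sigma_log10=sigma_log10)
    for i in range(n_compounds):
        papp = 10.0 ** rng.uniform(log_lo, log_hi)
        kpuu = 10.0 ** (intercept + slope * math.log10(papp) + rng.normal(0.0, sigma_log10))
        cid = f"SYN{i:03d}"
        fu_plasma = float(rng.uniform(0.05, 0.9))
        fu_brain = float(rng.uniform(0.05, 0.9))
        truth.assays.append(
            AssayTruth(
                compound_id=cid,
                papp_true=papp,
                noise_cv=noise_cv,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        truth.pk.append(
            PKTruth(
                compound_id=cid,
                k_elim=float(rng.uniform(0.2, 1.5)),
                kp_brain_true=kpuu * fu_plasma / fu_brain,
                fu_plasma_true=fu_plasma,
                fu_brain_true=fu_brain,
                noise_cv=noise_cv,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        truth.kpuu_true[cid] = kpuu
    return truth
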