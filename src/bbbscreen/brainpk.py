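"""In vivo brain partitioning: noncompartmental AUC, equilibrium-dialysis
fraction unbound with homogenate-dilution correction, and Kp,uu,brain.

The total brain-to-plasma partition coefficient is the exposure ratio

    Kp,brain = AUC(0-inf, brain) / AUC(0-inf, plasma)

and the unbound partition coefficient — the quantity that reflects barrier
transport under the free-drug hypothesis — corrects it for differential
nonspecific binding:

    Kp,uu,brain = Kp,brain * fu,brain / fu,plasma.

Fractions unbound come from equilibrium dialysis, fu = C_buffer / C_sample.
Brain fu is measured on diluted homogenate (D-fold total dilution) and
corrected back to undiluted tissue with the standard dilution relation

    fu = (1/D) / ((1/fu_apparent - 1) + 1/D),

which reduces to fu_apparent at D = 1 and is strictly decreasing in D for a
partially bound drug.  For drugs with reported protein binding above 99%
(printed ">99") fu defaults to 0.01.

AUC uses the linear-up/log-down trapezoid with optional extrapolation to
infinity via C_last / lambda_z, lambda_z from a log-linear fit of the last
three quantifiable concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .assay import ValidationError


class Matrix(str, Enum):
    PLASMA = "plasma"
    BRAIN = "brain"


#: Brain homogenate prepared with 4 volumes of water -> 5-fold total dilution.
DEFAULT_BRAIN_DILUTION = 5.0


@dataclass
class ConcentrationProfile:
    """A concentration-time profile in one matrix after an IV dose."""

    compound_id: str
    matrix: Matrix
    times: Sequence[float]          # h, strictly increasing
    concentrations: Sequence[float]  # any consistent concentration unit
    dose: float = 1.0               # mg/kg
    route: str = "iv"

    def __post_init__(self) -> None:
        self.matrix = Matrix(self.matrix)
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValidationError("times and concentrations must be 1-D and equal length")
        if len(t) < 3:
            raise ValidationError("need at least 3 timepoints")
        if t[0] < 0:
            raise ValidationError("times must start at or after 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        self.times = t
        self.concentrations = c


@dataclass
class BindingRecord:
    """Equilibrium-dialysis result for one compound x matrix.

    Exactly one of ``percent_bound`` / ``fu_apparent`` is given;
    ``dilution_factor`` is 1 for plasma, the homogenate dilution for brain.
    """

    compound_id: str
    matrix: Matrix
    percent_bound: float | str | None = None   # may be the ">99" literal
    fu_apparent: float | None = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = Matrix(self.matrix)
        if (self.percent_bound is None) == (self.fu_apparent is None):
            raise ValidationError(
                "exactly one of percent_bound / fu_apparent must be present"
            )
        if self.fu_apparent is not None and not (0 < self.fu_apparent <= 1):
            raise ValidationError("fu_apparent must be in (0, 1]")
        if self.dilution_factor < 1:
            raise ValidationError("dilution factor must be >= 1")

    def fu(self) -> float:
        """Fraction unbound in the undiluted matrix."""
        if self.percent_bound is not None:
            return default_fu_rule(self.percent_bound)
        return undiluted_fu(self.fu_apparent, self.dilution_factor)


@dataclass
class CompoundInVivo:
    """Compound-level in vivo brain-exposure parameters with provenance."""

    compound_id: str
    kp_brain: float | None
    fu_plasma: float | None
    fu_brain: float | None
    kp_uu_brain: float | None
    source: str = "computed"            # "computed" | "literature"
    kp_uu_recomputed: float | None = None
    discrepant: bool = False            # printed vs recomputed disagree


# --------------------------------------------------------------------------
# Noncompartmental AUC
# --------------------------------------------------------------------------

def _log_trapezoid(t1, t2, c1, c2) -> float:
    """Log trapezoid for a declining segment (exact for mono-exponentials)."""
    if c1 <= 0 or c2 <= 0 or c1 == c2:
        return 0.5 * (c1 + c2) * (t2 - t1)
    return (t2 - t1) * (c1 - c2) / math.log(c1 / c2)


def terminal_slope(profile: ConcentrationProfile, n_points: int = 3) -> float | None:
    """lambda_z (1/h) from a log-linear fit of the last quantifiable points.

    Returns None when fewer than ``n_points`` positive concentrations exist
    or the fitted slope does not describe a decline.
    """
    t = profile.times
    c = profile.concentrations
    mask = c > 0
    if mask.sum() < n_points:
        return None
    tq, cq = t[mask][-n_points:], c[mask][-n_points:]
    slope = np.polyfit(tq, np.log(cq), 1)[0]
    lam = -slope
    return lam if lam > 0 else None


def auc(profile: ConcentrationProfile, extrapolate: bool = False) -> float:
    """Linear-up/log-down trapezoidal AUC(0-tlast), optionally to infinity.

    Rising or flat segments use the linear trapezoid; declining segments the
    log trapezoid.  With ``extrapolate`` the tail C_last/lambda_z is added;
    if no positive lambda_z can be estimated the extrapolation is refused
    with a warning and AUC(0-tlast) is returned.
    """
    t = profile.times
    c = profile.concentrations
    if np.all(c == 0):
        raise ValidationError(f"{profile.compound_id}/{profile.matrix.value}: no quantifiable exposure")
    total = 0.0
    for i in range(len(t) - 1):
        if c[i + 1] < c[i]:
            total += _log_trapezoid(t[i], t[i + 1], c[i], c[i + 1])
        else:
            total += 0.5 * (c[i] + c[i + 1]) * (t[i + 1] - t[i])
    if extrapolate:
        lam = terminal_slope(profile)
        c_last = c[c > 0][-1] if np.any(c > 0) else 0.0
        if lam is None:
            warnings.warn(
                f"{profile.compound_id}/{profile.matrix.value}: no positive terminal "
                "slope; extrapolation refused, returning AUC(0-tlast)",
                UserWarning,
                stacklevel=2,
            )
        else:
            total += c_last / lam
    return total


def kp_brain_from_profiles(
    plasma: ConcentrationProfile,
    brain: ConcentrationProfile,
    extrapolate: bool = True,
) -> float:
    """AUC-ratio total partition coefficient Kp,brain."""
    return auc(brain, extrapolate=extrapolate) / auc(plasma, extrapolate=extrapolate)


# --------------------------------------------------------------------------
# Fraction unbound
# --------------------------------------------------------------------------

def fu_from_dialysis(conc_buffer: float, conc_sample: float) -> float:
    """fu = C_buffer / C_sample from equilibrium dialysis chambers."""
    if conc_sample <= 0:
        raise ValidationError("sample-chamber concentration must be positive")
    if conc_buffer < 0:
        raise ValidationError("buffer-chamber concentration must be >= 0")
    if conc_buffer == 0:
        warnings.warn("fu = 0: compound fully bound (buffer below detection)",
                      UserWarning, stacklevel=2)
        return 0.0
    fu = conc_buffer / conc_sample
    if fu > 1:
        warnings.warn(
            f"buffer concentration exceeds sample ({fu:.3f} > 1); clipping fu to 1",
            UserWarning, stacklevel=2,
        )
        return 1.0
    return fu


def undiluted_fu(fu_apparent: float, D: float) -> float:
    """Correct a diluted-homogenate fu back to undiluted tissue."""
    if not (0 < fu_apparent <= 1):
        raise ValidationError("fu_apparent must be in (0, 1]")
    if D < 1:
        raise ValidationError("dilution factor must be >= 1")
    if D == 1:
        return fu_apparent
    return (1.0 / D) / ((1.0 / fu_apparent - 1.0) + 1.0 / D)


def apparent_fu(fu_true: float, D: float) -> float:
    """Forward dilution relation (inverse of :func:`undiluted_fu`)."""
    if not (0 < fu_true <= 1):
        raise ValidationError("fu_true must be in (0, 1]")
    if D < 1:
        raise ValidationError("dilution factor must be >= 1")
    return D * fu_true / (D * fu_true + 1.0 - fu_true)


def default_fu_rule(percent_bound: float | str) -> float:
    """fu from a printed protein-binding percentage.

    Accepts the literal ``">99"``; binding above 99% maps to the floor
    fu = 0.01 (a dialysis measurement cannot resolve smaller free fractions
    reliably), otherwise fu = (100 - percent_bound)/100.
    """
    if isinstance(percent_bound, str):
        s = percent_bound.strip()
        if s.startswith(">"):
            pb = float(s[1:])
            if not 0 <= pb <= 100:
                raise ValidationError(f"percent bound out of range: {percent_bound}")
            return 0.01 if pb >= 99 else (100.0 - pb) / 100.0
        pb = float(s)
    else:
        pb = float(percent_bound)
    if not 0 <= pb <= 100:
        raise ValidationError(f"percent bound out of range: {pb}")
    if pb > 99:
        return 0.01
    return (100.0 - pb) / 100.0


def kp_uu(kp_brain: float, fu_plasma: float | None, fu_brain: float | None) -> float:
    """Kp,uu,brain = Kp,brain * fu,brain / fu,plasma."""
    missing = [name for name, v in (("plasma", fu_plasma), ("brain", fu_brain)) if v is None]
    if missing:
        raise ValidationError(f"missing fraction unbound for matrix: {', '.join(missing)}")
    if fu_plasma <= 0:
        raise ValidationError("fu_plasma must be positive")
    return kp_brain * fu_brain / fu_plasma


# --------------------------------------------------------------------------
# Table reconciliation
# --------------------------------------------------------------------------

def last_digit_unit(printed: str) -> float:
    """One unit in the last place of a printed decimal (e.g. '0.72' -> 0.01)."""
    s = printed.strip()
    if "." not in s:
        return 1.0
    return 10.0 ** -(len(s) - s.index(".") - 1)


def reconcile_kp_uu(
    compound_id: str,
    kp_brain: float,
    fu_plasma: float | None,
    fu_brain: float | None,
    kp_uu_printed: str,
) -> CompoundInVivo:
    """Recompute Kp,uu from binding data and compare with a printed value.

    When both free fractions are available the recomputed value is compared
    with the printed one at one unit of its last printed digit; disagreement
    sets ``discrepant`` and the printed value is preserved as a literature
    value rather than silently replaced.  Without binding data the printed
    value is taken as literature.
    """
    printed = float(kp_uu_printed)
    if fu_plasma is None or fu_brain is None:
        return CompoundInVivo(
            compound_id=compound_id,
            kp_brain=kp_brain,
            fu_plasma=fu_plasma,
            fu_brain=fu_brain,
            kp_uu_brain=printed,
            source="literature",
        )
    recomputed = kp_uu(kp_brain, fu_plasma, fu_brain)
    tol = last_digit_unit(kp_uu_printed)
    agrees = abs(round(recomputed, -int(round(math.log10(tol)))) - printed) <= tol * 1.000001
    return CompoundInVivo(
        compound_id=compound_id,
        kp_brain=kp_brain,
        fu_plasma=fu_plasma,
        fu_brain=fu_brain,
        kp_uu_brain=printed if not agrees else recomputed,
        source="computed" if agrees else "literature",
        kp_uu_recomputed=recomputed,
        discrepant=not agrees,
    )
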