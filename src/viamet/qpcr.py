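"""qPCR viability arithmetic: standard curves, copy numbers, loads, depletion.

Viability PCR (PMA/PMAxx) blocks amplification of exposed DNA from dead or
lysed cells, so the shift in threshold cycle (Ct) between an untreated and a
dye-treated aliquot of the same sample encodes the fraction of amplifiable
template that was removed:

    fraction_removed = 1 - (1 + E) ** (-(ct_treated - ct_control))

where E is the per-cycle amplification efficiency (E = 1 means perfect
doubling, so the expression reduces to ``1 - 2**(-dCt)``). Copy numbers come
from a plasmid standard curve ``ct = intercept + slope * log10(copies)``, and
a sample's *microbiota load* (total 16S rRNA gene copies per mL of saliva or
g of feces) is the reaction copy number scaled by the extraction and dilution
bookkeeping.

Default behaviour follows common practice for these assays: perfect-doubling
efficiency unless a per-assay standard curve says otherwise, arithmetic
averaging of technical-replicate Cts before conversion, and censoring at the
cycler's cycle cap (40) with censored values propagated as bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (
    CalibrationError,
    InvalidInputError,
    UndefinedRatioError,
    UnitMismatchError,
)

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "MicrobiotaLoad",
    "DepletionResult",
    "fit_standard_curve",
    "ct_to_copies",
    "depletion_efficiency",
    "microbiota_load",
    "survival_fraction",
    "survival_percent",
    "mean_killed_percent",
    "spike_in_dose",
    "average_replicate_ct",
    "round_half_up",
    "MAX_CYCLES",
]

#: Cycle cap of the qPCR programme; Ct values at or beyond it are censored.
MAX_CYCLES = 40


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as bench software prints values.

    Python's builtin ``round`` is banker's rounding; printed percentages in
    qPCR reports use half-up (e.g. 64.53 -> 65 at integer precision).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(copies) calibration.

    Attributes
    ----------
    slope : float
        Ct change per decade of template; negative for a working assay
        (more template -> earlier threshold crossing).
    intercept : float
        Ct at one copy of template.
    r_squared : float
        Coefficient of determination of the fit, in [0, 1].
    efficiency : float
        Per-cycle amplification gain E = 10**(-1/slope) - 1; E = 1 for a
        slope of -1/log10(2) ~ -3.3219.
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    efficiency: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.slope >= 0:
            raise CalibrationError(
                f"standard-curve slope must be negative, got {self.slope}"
            )
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidInputError(f"r_squared must be in [0,1], got {self.r_squared}")
        derived = 10.0 ** (-1.0 / self.slope) - 1.0
        if self.efficiency is None:
            object.__setattr__(self, "efficiency", derived)
        elif abs(self.efficiency - derived) > 1e-9:
            raise InvalidInputError(
                f"stored efficiency {self.efficiency} inconsistent with slope "
                f"{self.slope} (expected {derived})"
            )
        if not 0.0 < self.efficiency <= 1.2:
            raise CalibrationError(
                f"amplification efficiency {self.efficiency:.4f} outside (0, 1.2]"
            )

    def ct(self, copies: float) -> float:
        """Expected Ct for a given template copy number (the forward model)."""
        if copies <= 0:
            raise InvalidInputError("copies must be positive to evaluate the curve")
        return self.intercept + self.slope * math.log10(copies)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: a Ct observation (or censored non-detection) for one assay."""

    sample_id: str
    assay: str
    ct: float | None
    replicate: int = 1
    censored: bool = False

    def __post_init__(self):
        if self.replicate < 1:
            raise InvalidInputError("replicate must be a positive integer")
        if self.censored:
            if self.ct is not None:
                raise InvalidInputError("censored measurements carry no ct value")
        else:
            if self.ct is None or not self.ct > 0:
                raise InvalidInputError(
                    f"uncensored ct must be positive, got {self.ct!r}"
                )


@dataclass(frozen=True)
class MicrobiotaLoad:
    """Total 16S rRNA gene copies per unit of sample (mL saliva / g feces)."""

    sample_id: str
    copies_per_unit: float
    unit: Literal["per_mL", "per_g"]
    dilution_factor: float = 1.0

    def __post_init__(self):
        if self.copies_per_unit < 0:
            raise InvalidInputError("copies_per_unit must be nonnegative")
        if self.unit not in ("per_mL", "per_g"):
            raise InvalidInputError(f"unknown unit {self.unit!r}")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class DepletionResult:
    """Removal of amplifiable template inferred from a Ct pair.

    ``fraction_removed`` may be negative when the treated aliquot amplifies
    earlier than the control (flagged via ``negative_warning``); a censored
    treated Ct yields a conservative lower bound (``censored_bound``).
    """

    assay: str
    ct_control: float
    ct_treated: float
    fraction_removed: float
    percent_removed: float
    efficiency: float
    censored_bound: bool = False
    negative_warning: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a standard curve by ordinary least squares of Ct on log10(copies).

    Parameters
    ----------
    points : sequence of (log10_copies, ct)
        At least three dilution points spanning at least two decades, all
        with positive Ct.

    Raises
    ------
    InvalidInputError
        Fewer than 3 points, insufficient dynamic range, or nonpositive Ct.
    CalibrationError
        The fitted slope is nonnegative (assay did not amplify sensibly).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidInputError("need at least 3 (log10_copies, ct) points")
    log10_copies, ct = pts[:, 0], pts[:, 1]
    if np.any(ct <= 0):
        raise InvalidInputError("all ct values must be positive")
    if log10_copies.max() - log10_copies.min() < 2.0:
        raise InvalidInputError("standard-curve points must span >= 2 decades")
    fit = stats.linregress(log10_copies, ct)
    if fit.slope >= 0:
        raise CalibrationError(
            f"fitted slope {fit.slope:.4f} is nonnegative; calibration failed"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def ct_to_copies(
    ct: float | None, curve: StandardCurve, *, censored: bool = False
) -> float:
    """Invert the standard curve: copies = 10**((ct - intercept)/slope).

    A censored observation (no amplification within the cycle cap) maps to
    zero copies.
    """
    if censored:
        return 0.0
    if ct is None or not ct > 0:
        raise InvalidInputError(f"ct must be positive, got {ct!r}")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def depletion_efficiency(
    ct_control: float,
    ct_treated: float | None,
    efficiency: float = 1.0,
    *,
    assay: str = "",
    treated_censored: bool = False,
    max_cycles: float = MAX_CYCLES,
) -> DepletionResult:
    """Fraction of amplifiable template removed by a treatment, from a Ct pair.

    ``fraction_removed = 1 - (1+E)**(-(ct_treated - ct_control))``. With the
    default perfect-doubling efficiency E = 1 this is ``1 - 2**(-dCt)``; a
    4.37-cycle delay therefore corresponds to 95.16% removal.

    A censored treated Ct (no amplification within ``max_cycles``) returns the
    conservative lower bound obtained by plugging in the cycle cap, flagged
    ``censored_bound``. A treated Ct *earlier* than control gives a negative
    fraction, reported as-is with ``negative_warning`` set.
    """
    if not ct_control > 0:
        raise InvalidInputError("ct_control must be positive and uncensored")
    if not 0.0 < efficiency <= 1.2:
        raise InvalidInputError(f"efficiency {efficiency} outside (0, 1.2]")
    if treated_censored:
        ct_used = float(max_cycles)
    else:
        if ct_treated is None or not ct_treated > 0:
            raise InvalidInputError("ct_treated must be positive or censored")
        ct_used = float(ct_treated)
    delta_ct = ct_used - ct_control
    fraction = 1.0 - (1.0 + efficiency) ** (-delta_ct)
    negative = fraction < 0
    if negative:
        warnings.warn(
            f"treated Ct earlier than control (dCt={delta_ct:.2f}); "
            "negative removal reported as-is",
            stacklevel=2,
        )
    return DepletionResult(
        assay=assay,
        ct_control=float(ct_control),
        ct_treated=ct_used,
        fraction_removed=fraction,
        percent_removed=round_half_up(100.0 * fraction, 2),
        efficiency=float(efficiency),
        censored_bound=treated_censored,
        negative_warning=negative,
    )


def microbiota_load(
    copies_in_reaction: float,
    reaction_input_volume_ul: float,
    elution_volume_ul: float,
    sample_amount: float,
    sample_unit: Literal["per_mL", "per_g"],
    dilution_factor: float = 1.0,
    *,
    sample_id: str = "",
) -> MicrobiotaLoad:
    """Scale a per-reaction copy number to copies per mL (or g) of sample.

    ``copies_per_unit = copies * (elution/reaction_input) * dilution / amount``.
    All volume/mass factors must be positive; the conversion is refused rather
    than guessed when any is missing (callers supply them via config).
    """
    factors = (reaction_input_volume_ul, elution_volume_ul, sample_amount, dilution_factor)
    if any(not f > 0 for f in factors):
        raise InvalidInputError(f"all conversion factors must be positive, got {factors}")
    if copies_in_reaction < 0:
        raise InvalidInputError("copies_in_reaction must be nonnegative")
    copies_per_unit = (
        copies_in_reaction
        * (elution_volume_ul / reaction_input_volume_ul)
        * dilution_factor
        / sample_amount
    )
    return MicrobiotaLoad(
        sample_id=sample_id,
        copies_per_unit=copies_per_unit,
        unit=sample_unit,
        dilution_factor=dilution_factor,
    )


def survival_fraction(
    load_treated: MicrobiotaLoad, load_control: MicrobiotaLoad
) -> float:
    """Ratio of treated to control microbiota load (1.0 = no loss)."""
    if load_treated.unit != load_control.unit:
        raise UnitMismatchError(
            f"unit mismatch: {load_treated.unit} vs {load_control.unit}"
        )
    if load_control.copies_per_unit <= 0:
        raise UndefinedRatioError("control load is zero; survival undefined")
    return load_treated.copies_per_unit / load_control.copies_per_unit


def survival_percent(load_treated: MicrobiotaLoad, load_control: MicrobiotaLoad) -> float:
    """Survival as a percent rendered to one decimal (display form)."""
    return round_half_up(100.0 * survival_fraction(load_treated, load_control), 1)


def mean_killed_percent(
    survival_percents: Iterable[float],
    rounding: Literal["integer", "one_decimal"] = "one_decimal",
) -> float:
    """Mean dead/injured percentage: 100 minus the mean of per-host survivals.

    E.g. survivals (39.8, 44.7, 36.3) -> 59.7% of the community dead/injured.
    """
    values = [float(v) for v in survival_percents]
    if not values:
        raise InvalidInputError("survival_percents must be nonempty")
    if any(v < 0 or v > 100 for v in values):
        raise InvalidInputError("survival percentages must lie in [0, 100]")
    killed = 100.0 - sum(values) / len(values)
    return round_half_up(killed, 0 if rounding == "integer" else 1)


def spike_in_dose(native_load: MicrobiotaLoad | float, target_fraction: float) -> float:
    """Copies (or CFU) per unit to add so the spike is ``target_fraction`` of
    the post-spike total: ``dose = native * f / (1 - f)``.

    Spike-in experiments aim for a small fraction (5-15%) of total bacteria so
    the exogenous strains calibrate quantification without distorting the
    endogenous community.
    """
    native = (
        native_load.copies_per_unit
        if isinstance(native_load, MicrobiotaLoad)
        else float(native_load)
    )
    if native < 0:
        raise InvalidInputError("native load must be nonnegative")
    if not 0.0 <= target_fraction < 1.0:
        raise InvalidInputError(f"target_fraction {target_fraction} outside [0, 1)")
    return native * target_fraction / (1.0 - target_fraction)


def average_replicate_ct(
    measurements: Iterable[QpcrMeasurement],
    *,
    domain: Literal["ct", "copies"] = "ct",
    curve: StandardCurve | None = None,
) -> tuple[float | None, bool]:
    """Collapse technical replicates of one (sample, assay) to a single Ct.

    Default is the arithmetic mean in Ct space (matching mean +/- SEM
    reporting); ``domain='copies'`` averages in copy space through a standard
    curve instead. Censored replicates are dropped; if every replicate is
    censored the result is ``(None, True)``.
    """
    ms = list(measurements)
    if not ms:
        raise InvalidInputError("no measurements to average")
    keys = {(m.sample_id, m.assay) for m in ms}
    if len(keys) > 1:
        raise InvalidInputError(f"measurements mix several (sample, assay) keys: {keys}")
    cts = [m.ct for m in ms if not m.censored]
    if not cts:
        return None, True
    if domain == "ct":
        return float(np.mean(cts)), False
    if curve is None:
        raise InvalidInputError("copies-domain averaging requires a standard curve")
    mean_copies = float(np.mean([ct_to_copies(c, curve) for c in cts]))
    return curve.ct(mean_copies), False
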