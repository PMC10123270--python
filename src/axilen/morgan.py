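"""Closed-form ocular-optics computations built on the Morgan equation.

The Morgan equation estimates the axial length (AL, mm) of an eye from its
anterior corneal radius of curvature (CR, mm) and spherical equivalent
refractive error (SER, diopters, corneal plane)::

    AL_Morgan = 1 / (a / CR + b * SER + c)

with fixed constants ``a = 0.22273``, ``b = 0.00070`` mm^-1 D^-1 and
``c = 0.01368`` mm^-1.  Setting SER = 0 gives the *emmetropic* axial
length for that cornea, and the axial increment

    dAL = AL - AL_emmetropia

decomposes a measured AL into a corneal-refraction-matched component and a
myopia-attributable elongation.

All functions accept scalars or numpy arrays and are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "MorganConstants",
    "DEFAULT_CONSTANTS",
    "KERATOMETRIC_INDEX",
    "al_morgan",
    "al_emmetropia",
    "delta_al",
    "implied_ser",
    "cr_from_al_emmetropia",
    "keratometry_to_radius",
    "radius_to_keratometry",
]

ArrayLike = Union[float, np.ndarray]

#: Conventional keratometric refractive index used by clinical keratometers.
KERATOMETRIC_INDEX = 1.3375


@dataclass(frozen=True)
class MorganConstants:
    """The three fixed coefficients of the Morgan axial-length equation.

    Attributes
    ----------
    a : float
        Reciprocal-length numerator scale; ``a / CR`` has units mm^-1 when
        CR is in mm.
    b : float
        Diopter-to-reciprocal-mm coefficient, mm^-1 D^-1.
    c : float
        Additive reciprocal-length offset, mm^-1.
    """

    a: float = 0.22273
    b: float = 0.00070
    c: float = 0.01368

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(
                f"Morgan constants must be positive, got a={self.a}, b={self.b}, c={self.c}"
            )


DEFAULT_CONSTANTS = MorganConstants()


def _require_positive(value: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    return arr


def al_morgan(
    cr: ArrayLike, ser: ArrayLike, constants: MorganConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Morgan-formula axial-length estimate in mm.

    Parameters
    ----------
    cr : float or ndarray
        Anterior corneal radius of curvature, mm (> 0).
    ser : float or ndarray
        Spherical equivalent refractive error, diopters, at the corneal
        plane; negative values are myopic.
    constants : MorganConstants
        Formula coefficients; defaults are the published values.

    Returns
    -------
    float or ndarray
        ``1 / (a/cr + b*ser + c)`` — strictly increasing in ``cr`` and
        strictly decreasing in ``ser``.

    Raises
    ------
    ValueError
        If ``cr <= 0`` or the reciprocal-length denominator is not
        positive (extreme hyperopia / very steep cornea).
    """
    cr_arr = _require_positive(cr, "cr")
    ser_arr = np.asarray(ser, dtype=float)
    denom = constants.a / cr_arr + constants.b * ser_arr + constants.c
    if np.any(~np.isfinite(denom)) or np.any(denom <= 0):
        raise ValueError(
            "Morgan reciprocal length is non-positive for "
            f"cr={cr!r}, ser={ser!r}: no physical axial length exists"
        )
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def al_emmetropia(
    cr: ArrayLike, constants: MorganConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Emmetropic axial length (mm) for a cornea of radius ``cr`` mm.

    Identical to ``al_morgan(cr, 0)``: the axial length at which an eye
    with this corneal power would have zero refractive error.
    """
    return al_morgan(cr, 0.0, constants)


def delta_al(al: ArrayLike, al_emmetropia: ArrayLike) -> ArrayLike:
    """Axial increment dAL = AL - AL_emmetropia, mm (signed).

    Positive values mean the eye is longer than its emmetropic focal
    length (axial myopia); both inputs must be finite.
    """
    al_arr = np.asarray(al, dtype=float)
    emm_arr = np.asarray(al_emmetropia, dtype=float)
    if np.any(~np.isfinite(al_arr)) or np.any(~np.isfinite(emm_arr)):
        raise ValueError("delta_al requires finite al and al_emmetropia")
    out = al_arr - emm_arr
    return float(out) if out.ndim == 0 else out


def implied_ser(
    al: ArrayLike, cr: ArrayLike, constants: MorganConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Algebraic inverse of the Morgan formula: the SER (D) implied by an AL.

    Returns ``(1/al - a/cr - c) / b`` so that
    ``al_morgan(cr, implied_ser(al, cr)) == al`` to machine precision.
    """
    al_arr = _require_positive(al, "al")
    cr_arr = _require_positive(cr, "cr")
    out = (1.0 / al_arr - constants.a / cr_arr - constants.c) / constants.b
    return float(out) if out.ndim == 0 else out


def cr_from_al_emmetropia(
    al_emm: ArrayLike, constants: MorganConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Corneal radius (mm) whose emmetropic axial length equals ``al_emm``.

    Inverts ``al_emmetropia``: ``cr = a / (1/al_emm - c)``.  Requires
    ``0 < al_emm < 1/c`` (~73 mm) so the reciprocal length stays positive.
    """
    al_arr = _require_positive(al_emm, "al_emmetropia")
    u = 1.0 / al_arr - constants.c
    if np.any(u <= 0):
        raise ValueError(
            f"al_emmetropia={al_emm!r} exceeds the Morgan asymptote 1/c; no corneal radius exists"
        )
    out = constants.a / u
    return float(out) if out.ndim == 0 else out


def keratometry_to_radius(k: ArrayLike, index: float = KERATOMETRIC_INDEX) -> ArrayLike:
    """Convert keratometric power (D) to corneal radius (mm).

    Uses the thin-lens keratometer convention ``r = (index - 1) * 1000 / k``
    (337.5 / k for the standard index 1.3375).
    """
    k_arr = _require_positive(k, "keratometry")
    out = (index - 1.0) * 1000.0 / k_arr
    return float(out) if out.ndim == 0 else out


def radius_to_keratometry(r: ArrayLike, index: float = KERATOMETRIC_INDEX) -> ArrayLike:
    """Inverse of :func:`keratometry_to_radius`: ``k = (index - 1) * 1000 / r``."""
    r_arr = _require_positive(r, "radius")
    out = (index - 1.0) * 1000.0 / r_arr
    return float(out) if out.ndim == 0 else out
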