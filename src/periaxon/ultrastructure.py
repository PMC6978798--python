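"""Closed-form algebra linking cable parameters to axo-myelin ultrastructure.

A myelinated internode is electrically characterised by the axolemma
(specific resistance ``R_m``, capacitance ``C_m``), the compacted myelin
sheath (whole-sheath radial ``R_my``, ``C_my``), and two axial pathways:
the axon core (per-length resistance ``r_i``) and the fluid-filled
periaxonal space between axolemma and innermost myelin membrane
(per-length resistance ``r_pa``, partially sealed at the paranodes by
``r_pn``).  Because compact myelin is a serial stack of ``n_my`` lamellae
(two membranes each), sheath resistance adds and sheath capacitance
reciprocal-adds over membranes, which ties the fitted electrical
parameters to countable ultrastructure: lamellae number, sheath
thickness, periaxonal width and g-ratio.

All functions are pure, operate on scalars or numpy arrays, and use the
unit conventions declared per argument (the field mixes nm/um/cm and
Ohm/kOhm/GOhm, so conversions live here and nowhere else).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "CableParams",
    "MyelinGeometry",
    "SubmyelinGeometry",
    "core_axial_resistance",
    "periaxonal_resistivity",
    "periaxonal_axial_resistance",
    "periaxonal_width",
    "lamellae_from_sheath",
    "sheath_from_lamellae",
    "membrane_props_from_sheath",
    "sheath_thickness",
    "g_ratio",
    "resolving_distance",
    "DELTA_M_NM",
    "DELTA_PN_NM",
]

#: Default single-membrane thickness (nm), a typical bilayer including proteins.
DELTA_M_NM: float = 8.0

#: Default paranodal gap width (nm), from freeze-fracture measurements.
DELTA_PN_NM: float = 7.4

_UM_TO_CM = 1e-4
_NM_TO_CM = 1e-7


def _require_positive(**kwargs: Any) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(arr > 0.0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class CableParams:
    """Full passive parameter vector of the double-cable circuit.

    Attributes
    ----------
    R_i : float
        Axoplasmic (intracellular) resistivity, Ohm*cm.
    R_m : float
        Axolemma specific membrane resistance, kOhm*cm^2.
    C_m : float
        Axolemma specific membrane capacitance, uF/cm^2.
    R_my : float
        Whole-sheath radial specific resistance, kOhm*cm^2.
    C_my : float
        Whole-sheath radial specific capacitance, uF/cm^2.
    r_pa : float
        Periaxonal axial resistance per unit length, Ohm/cm.
    r_pn : float
        Paranodal axial resistance per unit length, Ohm/cm.
    C_pip : float
        Residual pipette wall capacitance, uF/cm^2 of modelled pipette area.
    """

    R_i: float = 100.0
    R_m: float = 20.0
    C_m: float = 1.0
    R_my: float = 240.0
    C_my: float = 1.0 / 30.0
    r_pa: float = 1.25e11
    r_pn: float = 2.45e12
    C_pip: float = 1.29e-4

    # optional per-section overrides used by alternative single-cable circuits
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_positive(
            R_i=self.R_i, R_m=self.R_m, C_m=self.C_m, R_my=self.R_my,
            C_my=self.C_my, r_pa=self.r_pa, r_pn=self.r_pn, C_pip=self.C_pip,
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("overrides")
        return d

    def replace(self, **kwargs: float) -> "CableParams":
        d = asdict(self)
        d.update(kwargs)
        return CableParams(**d)


@dataclass
class MyelinGeometry:
    """Geometric description of one compact myelin sheath."""

    n_my: float                 # lamellae (1 lamella = 2 membranes)
    delta_my: float             # sheath radial thickness, nm
    d: float                    # axon core diameter, um
    D: float                    # outer fibre diameter, um
    delta_m: float = DELTA_M_NM     # single membrane thickness, nm
    R_mm: float | None = None   # single-membrane resistance, kOhm*cm^2
    C_mm: float | None = None   # single-membrane capacitance, uF/cm^2

    def __post_init__(self) -> None:
        _require_positive(n_my=self.n_my, delta_my=self.delta_my,
                          d=self.d, D=self.D, delta_m=self.delta_m)
        if not self.d < self.D:
            raise ValueError("axon core diameter d must be smaller than fibre diameter D")
        if self.delta_my < self.delta_m:
            raise ValueError("sheath thickness cannot be below one membrane thickness")

    @property
    def g(self) -> float:
        return g_ratio(self.d, self.D)


@dataclass
class SubmyelinGeometry:
    """Geometry and fluid resistivities of the submyelin pathway."""

    delta_pa: float = 12.3          # periaxonal width, nm
    delta_pn: float = DELTA_PN_NM   # paranodal gap width, nm
    R_pa: float = 53.7              # periaxonal fluid resistivity, Ohm*cm
    R_pn: float = 550.0             # paranodal path resistivity, Ohm*cm

    # Debye screening limit for extracellular fluid: widths below this are unphysical.
    DEBYE_LIMIT_NM = 0.78

    def __post_init__(self) -> None:
        _require_positive(R_pa=self.R_pa, R_pn=self.R_pn)
        for name, w in (("delta_pa", self.delta_pa), ("delta_pn", self.delta_pn)):
            if w < 1.0:
                raise ValueError(
                    f"{name} = {w} nm is below the 1 nm floor "
                    f"(Debye limit ~{self.DEBYE_LIMIT_NM} nm)"
                )


def core_axial_resistance(R_i: float, d: float):
    """Axial resistance per length of the cylindrical axon core.

    Parameters
    ----------
    R_i : Ohm*cm axoplasmic resistivity.
    d : axon core diameter, um.

    Returns
    -------
    r_i : Ohm/cm, ``4*R_i / (pi*d^2)``.
    """
    _require_positive(R_i=R_i, d=d)
    d_cm = np.asarray(d, dtype=float) * _UM_TO_CM
    out = 4.0 * np.asarray(R_i, dtype=float) / (np.pi * d_cm**2)
    return float(out) if np.isscalar(R_i) and np.isscalar(d) else out


def periaxonal_resistivity(r_pa: float, d: float, delta_pa: float):
    """Fluid resistivity of the periaxonal annulus from its axial resistance.

    The periaxonal space is the annulus of width ``delta_pa`` between the
    axon core (diameter ``d``) and the innermost myelin membrane, with
    cross-sectional area ``pi*delta_pa*(d + delta_pa)``.

    Parameters
    ----------
    r_pa : Ohm/cm axial resistance per length.
    d : axon core diameter, um.
    delta_pa : periaxonal width, nm.

    Returns
    -------
    R_pa : Ohm*cm.
    """
    _require_positive(r_pa=r_pa, d=d, delta_pa=delta_pa)
    d_cm = np.asarray(d, dtype=float) * _UM_TO_CM
    dpa_cm = np.asarray(delta_pa, dtype=float) * _NM_TO_CM
    out = np.asarray(r_pa, dtype=float) * np.pi * dpa_cm * (d_cm + dpa_cm)
    if all(np.isscalar(x) for x in (r_pa, d, delta_pa)):
        return float(out)
    return out


def periaxonal_axial_resistance(R_pa: float, d: float, delta_pa: float):
    """Axial resistance per length of the periaxonal annulus.

    Forward form of the annulus relation: ``r_pa = R_pa / (pi*delta_pa*(d +
    delta_pa))``.  Also applies to the paranodal seal with its own
    resistivity and gap width.

    Parameters
    ----------
    R_pa : Ohm*cm fluid resistivity.
    d : axon core diameter, um.
    delta_pa : periaxonal width, nm.

    Returns
    -------
    r_pa : Ohm/cm.
    """
    _require_positive(R_pa=R_pa, d=d, delta_pa=delta_pa)
    d_cm = np.asarray(d, dtype=float) * _UM_TO_CM
    dpa_cm = np.asarray(delta_pa, dtype=float) * _NM_TO_CM
    out = np.asarray(R_pa, dtype=float) / (np.pi * dpa_cm * (d_cm + dpa_cm))
    if all(np.isscalar(x) for x in (R_pa, d, delta_pa)):
        return float(out)
    return out


def periaxonal_width(r_pa: float, d: float, R_pa: float):
    """Periaxonal width implied by an axial resistance and a fluid resistivity.

    Inverts the annulus relation for ``delta_pa``; the positive root of the
    quadratic is always real because the discriminant ``d^2 + 4 R_pa/(pi r_pa)``
    exceeds ``d^2``.

    Returns
    -------
    delta_pa : nm.
    """
    _require_positive(r_pa=r_pa, d=d, R_pa=R_pa)
    d_cm = np.asarray(d, dtype=float) * _UM_TO_CM
    disc = d_cm**2 + 4.0 * np.asarray(R_pa, dtype=float) / (np.pi * np.asarray(r_pa, dtype=float))
    dpa_cm = 0.5 * (-d_cm + np.sqrt(disc))
    out = dpa_cm / _NM_TO_CM
    if all(np.isscalar(x) for x in (r_pa, d, R_pa)):
        return float(out)
    return out


def lamellae_from_sheath(C_m: float, C_my: float):
    """Lamellae count predicted from sheath capacitance.

    Membranes stack in series radially, so sheath capacitance reciprocal-adds:
    with each myelin membrane electrically identical to the axolemma
    (``C_mm = C_m``), ``n_my = C_m / (2*C_my)``.  Continuous by design;
    rounding to integer lamellae is a reporting decision.
    """
    _require_positive(C_m=C_m, C_my=C_my)
    if not np.all(np.asarray(C_my) < np.asarray(C_m)):
        raise ValueError(
            "C_my must be smaller than C_m: a serial sheath cannot exceed "
            "one membrane's capacitance (would imply < 1 lamella)"
        )
    out = np.asarray(C_m, dtype=float) / (2.0 * np.asarray(C_my, dtype=float))
    if np.isscalar(C_m) and np.isscalar(C_my):
        return float(out)
    return out


def sheath_from_lamellae(R_mm: float, C_mm: float, n_my: float):
    """Whole-sheath radial properties from per-membrane properties.

    ``R_my = 2*n_my*R_mm`` (series resistances add) and
    ``C_my = C_mm / (2*n_my)`` (series capacitances reciprocal-add).
    """
    _require_positive(R_mm=R_mm, C_mm=C_mm, n_my=n_my)
    R_my = 2.0 * np.asarray(n_my, dtype=float) * np.asarray(R_mm, dtype=float)
    C_my = np.asarray(C_mm, dtype=float) / (2.0 * np.asarray(n_my, dtype=float))
    if all(np.isscalar(x) for x in (R_mm, C_mm, n_my)):
        return float(R_my), float(C_my)
    return R_my, C_my


def membrane_props_from_sheath(R_my: float, C_my: float, n_my: float):
    """Per-membrane properties from whole-sheath values (inverse of
    :func:`sheath_from_lamellae`)."""
    _require_positive(R_my=R_my, C_my=C_my, n_my=n_my)
    R_mm = np.asarray(R_my, dtype=float) / (2.0 * np.asarray(n_my, dtype=float))
    C_mm = np.asarray(C_my, dtype=float) * 2.0 * np.asarray(n_my, dtype=float)
    if all(np.isscalar(x) for x in (R_my, C_my, n_my)):
        return float(R_mm), float(C_mm)
    return R_mm, C_mm


def sheath_thickness(C_m: float, C_my: float, delta_m: float = DELTA_M_NM):
    """Radial sheath thickness from the parallel-plate relation.

    With the same dielectric constant for myelin and axolemma,
    ``delta_m * C_m = delta_my * C_my``, so ``delta_my = delta_m * C_m / C_my``.

    Returns
    -------
    delta_my : nm.
    """
    _require_positive(C_m=C_m, C_my=C_my, delta_m=delta_m)
    out = np.asarray(delta_m, dtype=float) * np.asarray(C_m, dtype=float) / np.asarray(C_my, dtype=float)
    if all(np.isscalar(x) for x in (C_m, C_my, delta_m)):
        return float(out)
    return out


def g_ratio(d: float, D: float):
    """Inner-to-outer fibre diameter ratio ``g = d/D`` (0 < g < 1)."""
    _require_positive(d=d, D=D)
    if not np.all(np.asarray(d) < np.asarray(D)):
        raise ValueError("g-ratio requires d < D")
    out = np.asarray(d, dtype=float) / np.asarray(D, dtype=float)
    if np.isscalar(d) and np.isscalar(D):
        return float(out)
    return out


def resolving_distance(lambda_nm: float, NA_obj: float, NA_cond: float):
    """Optical resolving distance of a bright-field setup.

    ``rd = 1.22 * lambda / (NA_obj + NA_cond)``; used to bound the
    measurement error of light-microscopic diameter reconstructions.

    Returns
    -------
    rd : nm.
    """
    _require_positive(lambda_nm=lambda_nm, NA_obj=NA_obj, NA_cond=NA_cond)
    out = 1.22 * np.asarray(lambda_nm, dtype=float) / (
        np.asarray(NA_obj, dtype=float) + np.asarray(NA_cond, dtype=float)
    )
    if all(np.isscalar(x) for x in (lambda_nm, NA_obj, NA_cond)):
        return float(out)
    return out
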