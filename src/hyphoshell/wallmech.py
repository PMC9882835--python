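"""Thin-shell wall mechanics: elastic strains, Young's modulus, turgor.

A turgid hypha is a pressurized thin shell.  Releasing the pressure (laser
ablation) or cancelling it osmotically lets the wall relax elastically; the
relative shrinkage is the elastic strain.  Force balance in the shell then
relates the Young's modulus ``Y`` to the turgor ``P``:

* cylindrical sides:  Y/P = R1 / (h_side * strain_radial)
* hemispherical tip:  Y/P = Rt1 / (2 * h_tip * strain_tip)

Turgor itself is obtained from an osmotic chain: the external molarity that
shrinks the cell as much as ablation fixes the internal osmolyte
concentration, a Boyle-van't Hoff correction with inaccessible volume
fraction ``beta`` converts it to the concentration in the turgid state, and
the van 't Hoff relation converts the excess over the medium into pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

R_GAS = 8.314  # J / (mol K)

__all__ = [
    "GeometrySnapshot",
    "ElasticStrains",
    "TurgorEstimate",
    "ModulusResult",
    "elastic_strain",
    "modulus_ratio_side",
    "modulus_ratio_tip",
    "surface_modulus",
    "iso_ablation_molarity",
    "turgor_from_osmotics",
    "anisotropy_ratio",
]


@dataclass(frozen=True)
class GeometrySnapshot:
    """Cell geometry at one time point.

    Parameters
    ----------
    R : float
        Lateral (cylinder) radius, um.
    L : float, optional
        Cell length, um.
    Rt : float, optional
        Tip radius of curvature, um.
    h_side, h_tip : float, optional
        Wall thickness on sides and at the tip, nm.
    """

    R: float
    L: float | None = None
    Rt: float | None = None
    h_side: float | None = None
    h_tip: float | None = None

    def __post_init__(self):
        for name in ("R", "L", "Rt", "h_side", "h_tip"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class ElasticStrains:
    """Per-axis elastic strains (dimensionless) measured by deflation."""

    radial: float
    longitudinal: float | None = None
    tip: float | None = None


@dataclass(frozen=True)
class TurgorEstimate:
    """All quantities of the osmotic turgor chain.

    Concentrations in mol/L, temperature in K, pressure in MPa.
    """

    c0_tilde: float
    c_media: float
    c0_bar: float
    c1_bar: float
    volume_ratio: float
    beta_osm: float
    temperature: float
    P: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ModulusResult:
    """Young's modulus over pressure, and derived absolute quantities."""

    Y_over_P: float
    Y: float | None = None          # MPa, if P supplied
    sigma_surface: float | None = None  # N/m = h*Y

    def to_dict(self) -> dict:
        return asdict(self)


def elastic_strain(before: GeometrySnapshot, after: GeometrySnapshot) -> ElasticStrains:
    """Elastic strains from a turgid/deflated geometry pair.

    Each strain is (turgid - deflated) / deflated, e.g. (R1 - R0)/R0 for the
    radius: the relative stretch the pressurized wall carries.
    """

    def one(b, a, axis):
        if b is None or a is None:
            return None
        if a <= 0:
            raise ValueError(f"deflated {axis} must be positive, got {a}")
        return (b - a) / a

    return ElasticStrains(
        radial=one(before.R, after.R, "radius"),
        longitudinal=one(before.L, after.L, "length"),
        tip=one(before.Rt, after.Rt, "tip radius"),
    )


def modulus_ratio_side(R1: float, h_side: float, radial_strain: float) -> float:
    """Y/P for the cylindrical sides: R1 / (h_side * strain).

    ``R1`` and ``h_side`` must be in the same length unit (the ratio is
    dimensionless): pass both in nm or both in um.
    """
    if R1 <= 0 or h_side <= 0:
        raise ValueError("R1 and h_side must be positive")
    if radial_strain <= 0:
        raise ValueError("zero or negative strain: modulus undefined")
    return R1 / (h_side * radial_strain)


def modulus_ratio_tip(Rt1: float, h_tip: float, tip_strain: float) -> float:
    """Y/P for the hemispherical tip: Rt1 / (2 * h_tip * strain).

    Exactly half the cylindrical formula for the same numbers (hoop stress in
    a sphere is half that in a cylinder of equal radius).
    """
    if Rt1 <= 0 or h_tip <= 0:
        raise ValueError("Rt1 and h_tip must be positive")
    if tip_strain <= 0:
        raise ValueError("zero or negative strain: modulus undefined")
    return Rt1 / (2.0 * h_tip * tip_strain)


def surface_modulus(h_nm: float, Y_mpa: float) -> float:
    """Surface (areal) modulus sigma = h*Y in N/m.

    1 nm * 1 MPa = 1e-9 m * 1e6 Pa = 1e-3 N/m.
    """
    if h_nm < 0:
        raise ValueError("thickness must be non-negative")
    return h_nm * Y_mpa * 1e-3


def iso_ablation_molarity(osmotic_series, ablation_strain: float) -> float:
    """External molarity at which osmotic shrinkage equals ablation shrinkage.

    Parameters
    ----------
    osmotic_series : sequence of (molarity_M, lateral_strain)
        Elastic strain measured after hyperosmotic shocks of increasing
        molarity.  Strain must be non-decreasing in molarity.
    ablation_strain : float
        Lateral strain measured after laser ablation (full turgor release).

    Returns
    -------
    float
        Piecewise-linearly interpolated molarity where the osmotic strain
        curve crosses the ablation strain.  This is the external osmolarity
        that just cancels turgor.
    """
    series = sorted((float(m), float(e)) for m, e in osmotic_series)
    if len(series) < 2:
        raise ValueError("need at least two (molarity, strain) points")
    mol = np.array([p[0] for p in series])
    eps = np.array([p[1] for p in series])
    if np.any(np.diff(eps) < 0):
        raise ValueError("strain must be non-decreasing with molarity")
    if not (eps[0] <= ablation_strain <= eps[-1]):
        raise ValueError(
            f"ablation strain {ablation_strain} outside measured range "
            f"[{eps[0]}, {eps[-1]}]; refusing to extrapolate"
        )
    return float(np.interp(ablation_strain, eps, mol))


def turgor_from_osmotics(
    c0_tilde: float,
    c_media: float,
    volume_ratio: float,
    beta_osm: float = 0.22,
    temperature: float = 298.0,
) -> TurgorEstimate:
    """Turgor pressure from the osmotic chain.

    Steps:

    1. internal osmolyte molarity at zero turgor:  c0_bar = c0_tilde + c_media
    2. Boyle-van't Hoff back to the turgid state:
       c1_bar = c0_bar * (V0/V1 - beta) / (1 - beta)
    3. van 't Hoff:  P = (c1_bar - c_media) * R * T

    Parameters
    ----------
    c0_tilde : float
        Sorbitol molarity (M) at which the cell shrinks as much as with
        ablation (from :func:`iso_ablation_molarity`).
    c_media : float
        Medium osmolarity, M.
    volume_ratio : float
        V0/V1, deflated over turgid cell volume, in (0, 1].
    beta_osm : float
        Osmotically inaccessible volume fraction, in [0, 1).
    temperature : float
        K.
    """
    if not (0 <= beta_osm < 1):
        raise ValueError("beta_osm must be in [0, 1)")
    if not (0 < volume_ratio <= 1):
        raise ValueError("volume_ratio must be in (0, 1]")
    if volume_ratio <= beta_osm:
        raise ValueError(
            "volume_ratio <= beta_osm implies a negative osmolyte "
            "concentration; non-physical input"
        )
    c0_bar = c0_tilde + c_media
    c1_bar = c0_bar * (volume_ratio - beta_osm) / (1.0 - beta_osm)
    # mol/L -> mol/m^3 is *1000; Pa -> MPa is /1e6
    P = (c1_bar - c_media) * 1000.0 * R_GAS * temperature / 1e6
    if P < 0:
        warnings.warn("negative turgor estimate clipped to 0", stacklevel=2)
        P = 0.0
    return TurgorEstimate(
        c0_tilde=c0_tilde,
        c_media=c_media,
        c0_bar=c0_bar,
        c1_bar=c1_bar,
        volume_ratio=volume_ratio,
        beta_osm=beta_osm,
        temperature=temperature,
        P=P,
    )


def anisotropy_ratio(radial_strain: float, longitudinal_strain: float) -> float:
    """Radial over longitudinal elastic strain.

    For an isotropic thin-walled cylinder the hoop stress is twice the axial
    stress, so this ratio is exactly 2; large deviations indicate material
    anisotropy.
    """
    if longitudinal_strain <= 0:
        raise ValueError("longitudinal strain must be positive")
    return radial_strain / longitudinal_strain


def modulus_result(Y_over_P: float, P: float | None = None,
                   h_nm: float | None = None) -> ModulusResult:
    """Bundle Y/P with absolute Y (needs P) and surface modulus (needs h)."""
    if Y_over_P <= 0:
        raise ValueError("Y_over_P must be positive")
    Y = Y_over_P * P if P is not None else None
    sigma = surface_modulus(h_nm, Y) if (Y is not None and h_nm is not None) else None
    return ModulusResult(Y_over_P=Y_over_P, Y=Y, sigma_surface=sigma)
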