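"""Materials and the four scaffold designs used in the ovine defect study.

Two substrate materials (laser-sintered commercially pure titanium and
polyamide PA12) are combined with three strut architectures (octet truss,
orthogonal cubic grid, Poisson-disk stochastic network) to give four designs
spanning roughly two orders of magnitude in apparent modulus:

====== ========= =========== ================ ==================
acronym material  generator   nominal porosity apparent modulus
====== ========= =========== ================ ==================
TC     titanium  octetruss    0.60            7100 MPa (max:min 1.5)
TB     titanium  stochastic   0.80            1400 MPa (max:min 1)
PB     polyamide octetruss    0.45             220 MPa (max:min 1.5)
PC     polyamide cubic        0.35             220 MPa (max:min 5.3)
====== ========= =========== ================ ==================

The published apparent moduli above are the characterization used for the
stiffness covariate in the cohort statistics; the frame solver in
:mod:`scaffold_regen.mechanics` recomputes apparent moduli for the in-repo
geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "Material",
    "ScaffoldDesign",
    "TITANIUM",
    "POLYAMIDE",
    "DESIGNS",
    "APPARENT_MODULUS_MPA",
    "COMPLIANCE_ORDER",
    "compliance_rank",
    "DEFECT_DIAMETER_MM",
    "DEFECT_DEPTH_MM",
]

#: Implant cylinder (press-fit oversize relative to the 15 mm defect).
SCAFFOLD_DIAMETER_MM = 16.0
SCAFFOLD_HEIGHT_MM = 15.0

#: Cylindrical metaphyseal defect created surgically.
DEFECT_DIAMETER_MM = 15.0
DEFECT_DEPTH_MM = 15.0


@dataclass(frozen=True)
class Material:
    """Linear-elastic solid phase of a scaffold.

    Parameters
    ----------
    name : str
        Human-readable name.
    elastic_modulus : float
        Young's modulus of the solid material, MPa.
    poisson_ratio : float
        Poisson's ratio (dimensionless, in [0, 0.5)).
    """

    name: str
    elastic_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.elastic_modulus > 0:
            raise ValueError("elastic_modulus must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        """Shear modulus G = E / (2 (1 + nu)), MPa."""
        return self.elastic_modulus / (2.0 * (1.0 + self.poisson_ratio))


TITANIUM = Material("CP-Ti grade 2", elastic_modulus=100_000.0, poisson_ratio=0.34)
POLYAMIDE = Material("PA12 nylon", elastic_modulus=2_000.0, poisson_ratio=0.40)


@dataclass(frozen=True)
class ScaffoldDesign:
    """Parametric description of one scaffold type.

    ``unit_cell`` is the tiling period in mm for the periodic generators and
    ``None`` for the stochastic network, which is parameterized by point
    density instead.
    """

    acronym: str
    material: Material
    generator: str  # octetruss | cubic | stochastic
    nominal_porosity: float
    unit_cell: float | None = None
    cylinder_diameter: float = SCAFFOLD_DIAMETER_MM
    cylinder_height: float = SCAFFOLD_HEIGHT_MM
    #: stochastic generator controls (ignored by periodic generators)
    point_density: float | None = None  # points per mm^3
    target_connectivity: float = 4.5

    def __post_init__(self) -> None:
        if not (0.0 < self.nominal_porosity < 1.0):
            raise ValueError("nominal_porosity must lie in (0, 1)")
        if self.generator not in ("octetruss", "cubic", "stochastic"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.generator != "stochastic" and self.unit_cell is None:
            raise ValueError("periodic generators require unit_cell")

    def with_(self, **kw) -> "ScaffoldDesign":
        return replace(self, **kw)


# Octet unit cell for PB is a repo fixture (3 mm); the titanium octet cell is
# scaled up by 1.3 relative to it, reflecting the metal-sintering constraint
# on minimum feature size.
_PB_CELL_MM = 3.0
_TC_CELL_SCALE = 1.3

#: The full-size stochastic design places ~5000 Poisson-disk points in the
#: implant cylinder (pi * 8^2 * 15 ~ 3016 mm^3) -> ~1.66 points / mm^3.
_TB_POINT_DENSITY = 5000.0 / 3015.93

DESIGNS: dict[str, ScaffoldDesign] = {
    "TC": ScaffoldDesign("TC", TITANIUM, "octetruss", 0.60,
                         unit_cell=_PB_CELL_MM * _TC_CELL_SCALE),
    "TB": ScaffoldDesign("TB", TITANIUM, "stochastic", 0.80,
                         point_density=_TB_POINT_DENSITY),
    "PB": ScaffoldDesign("PB", POLYAMIDE, "octetruss", 0.45,
                         unit_cell=_PB_CELL_MM),
    "PC": ScaffoldDesign("PC", POLYAMIDE, "cubic", 0.35,
                         unit_cell=_PB_CELL_MM),
}

#: Published apparent-modulus characterization (MPa), used as the stiffness
#: covariate in the cohort regression.
APPARENT_MODULUS_MPA: dict[str, float] = {
    "TC": 7100.0,
    "TB": 1400.0,
    "PB": 220.0,
    "PC": 220.0,
}

#: Designs ordered from most compliant to stiffest.  PB and PC share the same
#: axial apparent modulus; the tie is broken by anisotropy (the cubic grid is
#: soft in every non-axial direction, so its direction-averaged modulus is the
#: lowest of the four).
COMPLIANCE_ORDER: tuple[str, ...] = ("PC", "PB", "TB", "TC")


def compliance_rank(acronym: str) -> int:
    """Rank of a design in the compliance ordering (0 = most compliant)."""
    return COMPLIANCE_ORDER.index(acronym)
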