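"""Synthetic micro-CT phantoms of a scaffold-filled metaphyseal defect.

A phantom is a grayscale voxel volume plus ground-truth masks.  Gray levels
follow the radiographic ordering of the imaged tissues: marrow background <
polyamide (soft-tissue density) < mineralized bone < titanium, with an
additive structureless beam-hardening halo decaying away from titanium
struts.  Partial-volume effects are emulated with a Gaussian blur and
acquisition noise with additive Gaussian noise.

Bone is placed from the latent cohort truth in two disjoint compartments:

* peripheral (injury-driven): a contact rim at the defect wall engulfing
  the outer scaffold struts, identical for every design and animal;
* central (strain-driven): on interior strut surfaces for polyamide
  (lamellar-apposition proxy) or as free-floating reticulate deposits kept
  clear of the metal for titanium (woven-bone proxy).

The truth bone-voxel count is exact by construction: voxels are filled in
priority order until the requested fraction of the pore volume is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .designs import DEFECT_DEPTH_MM, DEFECT_DIAMETER_MM, ScaffoldDesign
from .lattice import Cylinder, build_design, solve_radius_for_porosity, voxelize

__all__ = [
    "Phantom",
    "FluorSection",
    "CapacityError",
    "GRAY",
    "build_phantom",
    "render_fluor_section",
    "clear_design_cache",
]


class CapacityError(ValueError):
    """Requested bone volume exceeds the available pore volume."""


#: Nominal gray levels (arbitrary reconstruction units).
GRAY = {
    "marrow": 0.20,
    "polyamide": 0.30,   # same radiographic density as soft tissue
    "bone": 0.70,
    "titanium": 1.60,   # metal attenuation far above bone; halo and blur leave it distinct
}

#: Beam-hardening halo: additive amplitude at the metal surface and its
#: exponential decay length in voxels (structureless, ~3 voxels visible).
HALO_AMPLITUDE = 0.30
HALO_DECAY_VOX = 1.0

#: Partial-volume blur (voxels) and acquisition noise (5% of the
#: bone-marrow contrast).  The blur is calibrated so the quantification
#: chain resolves the study's bone structures at the desk-scale voxel size
#: (recovery error below half a percentage point of pore volume).
BLUR_SD_VOX = 0.5
NOISE_SD = 0.05 * (GRAY["bone"] - GRAY["marrow"])

#: Outermost pore tier: radial shell at the defect wall hosting the
#: peripheral compartment (about half a unit cell).
SHELL_MM = 1.5

#: Bone in titanium phantoms keeps a fibrous-tissue clearance from the
#: metal: nascent woven bone and titanium struts interdigitate without
#: intimate contact (unlike polyamide, which shows direct interlocking
#: apposition).
TITANIUM_CLEARANCE_MM = 0.3
TITANIUM_RIM_CLEARANCE_MM = 0.3

_XY_MARGIN_MM = 2.0
_Z_MARGIN_MM = 1.0

#: Edge length of the pore-scale blocks from which central deposits are
#: assembled (comparable to the unit-cell pore size).
_BLOCK_MM = 1.5

#: Scaffold geometry is a manufacturing design: one geometry per design
#: acronym (fixed generator seed), reused across animals and cohort seeds.
_DESIGN_GEOMETRY_SEED = 0


@dataclass
class Phantom:
    """Gray volume + ground-truth masks for one implanted defect."""

    volume: np.ndarray              # float32 (nx, ny, nz)
    voxel_size_um: float
    origin_mm: np.ndarray           # world position of the (0,0,0) corner
    scaffold_mask: np.ndarray
    bone_mask: np.ndarray
    defect_mask: np.ndarray
    bone_peripheral_mask: np.ndarray
    bone_central_mask: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if (self.scaffold_mask & self.bone_mask).any():
            raise ValueError("scaffold and bone masks must be disjoint")
        if not (27.0 <= self.voxel_size_um <= 136.0):
            raise ValueError("voxel size outside the supported 27-136 um")

    @property
    def voxel_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def defect_cylinder(self) -> Cylinder:
        return Cylinder(DEFECT_DIAMETER_MM, DEFECT_DEPTH_MM)

    @property
    def periosteal_z_mm(self) -> float:
        """World z of the periosteal (top) face of the defect."""
        return DEFECT_DEPTH_MM / 2.0


@dataclass
class FluorSection:
    """2D fluorescence section with a mineral-bound label band.

    The label was administered ``interval_days`` before endpoint; the band
    sits ``band_offset_truth_um`` from the current bone front (deeper bone
    is older, so the band lies closer to the defect wall).
    """

    image: np.ndarray
    pixel_size_um: float
    band_offset_truth_um: float
    interval_days: float = 14.0
    center_px: tuple[float, float] = (0.0, 0.0)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.band_offset_truth_um < 0:
            raise ValueError("band offset must be non-negative")


# ---------------------------------------------------------------------------
# per-design cached voxel model
# ---------------------------------------------------------------------------

_design_cache: dict = {}


def clear_design_cache() -> None:
    _design_cache.clear()


class _DesignVoxelModel:
    """Voxelized scaffold + placement priority orders, cached per design."""

    def __init__(self, design: ScaffoldDesign, voxel_size_um: float):
        h = voxel_size_um / 1000.0
        self.h = h
        rad = DEFECT_DIAMETER_MM / 2.0
        self.origin = np.array([-(rad + _XY_MARGIN_MM),
                                -(rad + _XY_MARGIN_MM),
                                -(DEFECT_DEPTH_MM / 2.0 + _Z_MARGIN_MM)])
        ext = np.array([2 * (rad + _XY_MARGIN_MM),
                        2 * (rad + _XY_MARGIN_MM),
                        DEFECT_DEPTH_MM + 2 * _Z_MARGIN_MM])
        self.shape = np.ceil(ext / h - 1e-9).astype(int)

        # radius is a design property: always solved on the fine 50 um grid,
        # independent of the phantom rendering resolution
        self.radius_mm = solve_radius_for_porosity(
            design, seed=_DESIGN_GEOMETRY_SEED, voxel_size=0.05)
        lat = build_design(design, seed=_DESIGN_GEOMETRY_SEED,
                           radius=self.radius_mm)
        # the seated implant: the press-fit oversize sits in the host wall,
        # so only the defect-cylinder part is voxelized
        from .lattice import trim_to_cylinder
        lat = trim_to_cylinder(lat, DEFECT_DIAMETER_MM, DEFECT_DEPTH_MM)
        from .lattice import Box
        dom = Box(tuple(self.origin), tuple(self.origin + self.shape * h))
        solid, _ = voxelize(lat, h, domain=dom)
        self.scaffold = solid

        xs = self.origin[0] + (np.arange(self.shape[0]) + 0.5) * h
        ys = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * h
        zs = self.origin[2] + (np.arange(self.shape[2]) + 0.5) * h
        r2 = xs[:, None] ** 2 + ys[None, :] ** 2
        self.radial = np.sqrt(r2)[:, :, None] * np.ones_like(zs)
        inz = (np.abs(zs) <= DEFECT_DEPTH_MM / 2.0)
        self.defect = (self.radial <= rad) & inz[None, None, :]
        self.pore = self.defect & ~self.scaffold
        # distance to metal/polymer surface, mm
        self.edt_mm = ndimage.distance_transform_edt(~self.scaffold,
                                                     sampling=h)
        shell = self.defect & (self.radial >= rad - SHELL_MM)
        self.shell_pore = shell & self.pore
        self.interior_pore = self.pore & ~shell

        # peripheral priority: a contact rim that follows the defect wall.
        # Voxels are filled round-robin over (slice, angular-sector) bins,
        # outermost pore voxel of each sector first, so the rim is
        # angularly complete and dips inward around wall-crossing struts
        # (engulfing them) instead of leaving shadows behind them.
        zi = np.broadcast_to(np.arange(self.shape[2]), self.shape)
        theta = np.arctan2(ys[None, :, None] * np.ones_like(zs),
                           xs[:, None, None] * np.ones_like(zs))
        sector = ((theta + np.pi) / (2 * np.pi) * 720).astype(np.int32)

        def rim_order(region: np.ndarray) -> np.ndarray:
            idx = np.flatnonzero(region.ravel())
            r = self.radial.ravel()[idx]
            grp = zi.ravel()[idx].astype(np.int64) * 721 + sector.ravel()[idx]
            by_grp = np.lexsort((-r, grp))
            g = grp[by_grp]
            starts = np.r_[0, np.flatnonzero(np.diff(g)) + 1]
            rank = np.arange(len(g))
            rank -= np.repeat(starts, np.diff(np.r_[starts, len(g)]))
            return idx[by_grp][np.lexsort((-r[by_grp], rank))]

        self.peripheral_order = rim_order(self.shell_pore)
        # titanium variant: the rim keeps the fibrous clearance from metal
        self.peripheral_order_clear = rim_order(
            self.shell_pore & (self.edt_mm >= TITANIUM_RIM_CLEARANCE_MM))
        # pore-scale block labels for central deposits: deposits are built
        # from whole ~1.5 mm blocks of pore space (elongated axially, like
        # deposits following the pore channels) so they stay several voxels
        # thick in every direction and coherent from slice to slice
        block_vox = max(2, int(round(_BLOCK_MM / h)))
        block_z = 2 * block_vox
        ii, jj, kk = np.meshgrid(np.arange(self.shape[0]) // block_vox,
                                 np.arange(self.shape[1]) // block_vox,
                                 np.arange(self.shape[2]) // block_z,
                                 indexing="ij")
        self.block_id = (ii * 10_000 + jj * 100 + kk).astype(np.int64)
        # titanium central eligibility: clear of the metal (and its halo)
        self.central_free = (self.interior_pore
                             & (self.edt_mm >= TITANIUM_CLEARANCE_MM))
        self.n_defect = int(self.defect.sum())
        self.design = design


def _design_model(design: ScaffoldDesign,
                  voxel_size_um: float) -> _DesignVoxelModel:
    key = (design.acronym, round(voxel_size_um, 3))
    if key not in _design_cache:
        _design_cache[key] = _DesignVoxelModel(design, voxel_size_um)
    return _design_cache[key]


# ---------------------------------------------------------------------------
# phantom builder
# ---------------------------------------------------------------------------

def build_phantom(design: ScaffoldDesign, latent_total_pp: float,
                  peripheral_pp: float, voxel_size_um: float = 100.0,
                  seed: int | None = 0, blur: bool = True,
                  noise: bool = True) -> Phantom:
    """Render one defect volume from its latent truth.

    ``latent_total_pp`` and ``peripheral_pp`` are percentages of the pore
    volume (defect volume x nominal porosity); the central compartment is
    their difference.
    """
    if not (0.0 <= latent_total_pp <= 60.0):
        raise ValueError("latent_total_pp must lie in [0, 60]")
    if voxel_size_um < 27.0:
        raise ValueError("voxel size below the 27 um acquisition range")
    if peripheral_pp < 0 or peripheral_pp > latent_total_pp:
        raise ValueError("peripheral_pp must lie in [0, latent_total_pp]")
    model = _design_model(design, voxel_size_um)
    rng = np.random.default_rng(seed)
    porosity_used = design.nominal_porosity
    pore_budget = porosity_used * model.n_defect  # voxels of pore by design

    n_total = int(round(latent_total_pp / 100.0 * pore_budget))
    n_periph = int(round(peripheral_pp / 100.0 * pore_budget))
    n_central = n_total - n_periph

    titanium_like = design.material.elastic_modulus > 10_000
    periph_order = (model.peripheral_order_clear if titanium_like
                    else model.peripheral_order)
    bone_p = np.zeros(model.shape, dtype=bool)
    if n_periph > len(periph_order):
        raise CapacityError("peripheral compartment exceeds the outer tier")
    bone_p.ravel()[periph_order[:n_periph]] = True

    bone_c = np.zeros(model.shape, dtype=bool)
    if n_central > 0:
        # central deposits fill randomly ordered pore-scale blocks so they
        # are several voxels thick in every direction; polyamide deposits
        # seat directly on the strut surfaces (lamellar apposition), the
        # titanium ones keep a fibrous-tissue clearance from the metal
        # (free-floating woven bone)
        region = model.central_free if titanium_like else model.interior_pore
        elig = np.flatnonzero(region.ravel())
        if n_central > len(elig):
            raise CapacityError(
                "central compartment exceeds the available pore volume")
        blocks = model.block_id.ravel()[elig]
        uniq = np.unique(blocks)
        rank_of = {b: r for r, b in
                   enumerate(rng.permutation(uniq))}
        ranks = np.array([rank_of[b] for b in blocks])
        # within the final, partially filled block: core-outward
        depth = model.edt_mm.ravel()[elig]
        order = elig[np.lexsort((-depth, ranks))]
        bone_c.ravel()[order[:n_central]] = True
    bone = bone_p | bone_c

    vol = np.full(model.shape, GRAY["marrow"], dtype=np.float32)
    mat_gray = GRAY["titanium"] if titanium_like else GRAY["polyamide"]
    vol[model.scaffold] = mat_gray
    if titanium_like:
        halo = HALO_AMPLITUDE * np.exp(
            -model.edt_mm / (HALO_DECAY_VOX * model.h))
        halo_zone = ~model.scaffold & ~bone
        vol[halo_zone] += halo[halo_zone].astype(np.float32)
    vol[bone] = GRAY["bone"]
    if blur:
        vol = ndimage.gaussian_filter(vol, BLUR_SD_VOX)
    if noise:
        vol = vol + rng.normal(0.0, NOISE_SD, vol.shape).astype(np.float32)

    params = {
        "design": design.acronym,
        "material_kind": "titanium" if titanium_like else "polyamide",
        "latent_total_pp": float(latent_total_pp),
        "peripheral_pp": float(peripheral_pp),
        "central_pp": float(latent_total_pp - peripheral_pp),
        "porosity_used": porosity_used,
        "voxel_size_um": float(voxel_size_um),
        "seed": seed,
        "truth_bone_voxels": int(bone.sum()),
        "scaffold_radius_mm": model.radius_mm,
    }
    return Phantom(vol, voxel_size_um, model.origin.copy(), model.scaffold,
                   bone, model.defect, bone_p, bone_c, params)


# ---------------------------------------------------------------------------
# fluorescence sections
# ---------------------------------------------------------------------------

#: Fluorescence rendering levels (arbitrary units).
_FLUOR = {"marrow": 0.05, "bone": 0.35, "band": 1.00}


def render_fluor_section(depth_mm: float = 7.5, band_offset_um: float = 35.0,
                         seed: int | None = 0, central_level: float = 0.0,
                         pixel_size_um: float = 5.0,
                         rim_thickness_mm: float = 0.3,
                         field_mm: float = 16.5) -> FluorSection:
    """Render a cross-section through the defect with the label band.

    The peripheral rim at the bone-implant interface is bright in every
    design; interior brightness scales with ``central_level`` (0-1).  The
    14-day mineral-bound band is a thin ring ``band_offset_um`` outside the
    current bone front (toward the wall: the front advances inward).
    """
    if not (0.0 <= band_offset_um <= 200.0):
        raise ValueError("band offset must lie in [0, 200] um")
    h = pixel_size_um / 1000.0
    n = int(round(field_mm / h))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_mm = np.hypot(xx - c, yy - c) * h

    r_wall = DEFECT_DIAMETER_MM / 2.0
    r_front = r_wall - rim_thickness_mm
    img = np.full((n, n), _FLUOR["marrow"], dtype=np.float32)
    if central_level > 0:
        interior = r_mm < r_front - 0.2
        img[interior] = _FLUOR["marrow"] + central_level * (
            _FLUOR["bone"] - _FLUOR["marrow"])
    img[(r_mm >= r_front) & (r_mm <= r_wall)] = _FLUOR["bone"]
    r_band = r_front + band_offset_um / 1000.0
    band_half = 0.006  # 6 um half-width line
    img[np.abs(r_mm - r_band) <= band_half] = _FLUOR["band"]
    img = ndimage.gaussian_filter(img, 1.0)
    rng = np.random.default_rng(seed)
    img = img + rng.normal(0.0, 0.02, img.shape).astype(np.float32)
    return FluorSection(img, pixel_size_um, band_offset_um,
                        center_px=(c, c),
                        params={"depth_mm": depth_mm,
                                "central_level": central_level,
                                "r_front_mm": r_front})
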