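"""Regional osteogenesis scoring and mineral apposition rate.

Virtual cross-sections are scored 0-4 separately for the bone-implant
interface (periphery of the defect) and the implant interior, following an
ordinal rubric: interface scores grade the fraction of the defect outline
in contact with bone (none, ~one third, ~two thirds, complete, engulfing
the outermost pore tier); interior scores grade the interior bone area and
its morphology (nothing, specks, thin/reticulate networks, substantial
semilunar deposits or extensive networks, massive bone in all discernible
pores).

Three simulated raters score each image independently; when their scores
disagree by more than 1 unit the image is rescored until consensus, and the
consensus value is the three-rater mean.

The mineral apposition rate (MAR) is measured on fluorescence sections as
the distance from the label band to the current bone front divided by the
14-day labelling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import FluorSection, Phantom, SHELL_MM
from .quantify import SECTION_DEPTHS_MM, virtual_sections

__all__ = [
    "DetectionError",
    "ConsensusError",
    "InterfaceMetrics",
    "interface_metrics",
    "score_interface",
    "score_interior",
    "true_scores_for_phantom",
    "consensus_scores",
    "mineral_apposition_rate",
]

#: Interface rubric cut points on the contact-arc fraction (between the
#: rubric's "none / one third / two thirds / complete" anchors).
ARC_CUTS = (1.0 / 6.0, 1.0 / 2.0, 5.0 / 6.0)

#: Interior rubric cut points on the interior bone area fraction (of the
#: interior pore area).
AREA_CUTS = (0.02, 0.08, 0.20)

#: Outermost-tier occupancy that counts as engulfment (score 4).
ENGULFMENT_OCCUPANCY = 0.8

#: Component half-thickness (voxels) separating thin/reticulate from
#: substantial (semilunar) deposits.
THICK_HALF_VOX = 1.5

#: Pore coverage required for interior score 4 ("all discernible pores").
PORE_COVERAGE = 0.9


class DetectionError(RuntimeError):
    """A required image feature (outline, label band) was not found."""


class ConsensusError(RuntimeError):
    """Raters failed to converge within the retry budget."""


@dataclass(frozen=True)
class InterfaceMetrics:
    """Peripheral contact measurements on one section."""

    contact_arc_fraction: float
    engulfment: bool


def _radial_map(shape, voxel_mm: float, center_px=None):
    if center_px is None:
        center_px = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    xx, yy = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(xx - center_px[0], yy - center_px[1]) * voxel_mm
    theta = np.arctan2(yy - center_px[1], xx - center_px[0])
    return r, theta


def interface_metrics(bone2d: np.ndarray, scaffold2d: np.ndarray,
                      defect2d: np.ndarray, voxel_size_um: float,
                      n_bins: int = 360,
                      band_mm: float = SHELL_MM) -> InterfaceMetrics:
    """Contact-arc fraction and engulfment flag for one axial section.

    The contact arc is the fraction of the defect circumference where bone
    lies within ``band_mm`` (at least 2 voxels) of the outline.  The
    default band is the outermost pore tier: the rubric treats that tier as
    part of the interface ("engulfs the outer scaffold struts"), so contact
    hiding behind wall-crossing struts is seen.  Angular bins whose band is
    entirely scaffold (a strut cross-section fills the outline there) are
    excluded: a scorer grades contact where tissue can contact, not the
    implant material itself.  Engulfment means the outermost pore tier is
    at least 80% occupied by bone.
    """
    if not defect2d.any():
        raise DetectionError("defect outline not present in this section")
    h = voxel_size_um / 1000.0
    r, theta = _radial_map(defect2d.shape, h)
    r_wall = float(r[defect2d].max())
    band = defect2d & (r >= r_wall - max(band_mm, 2.0 * h))

    def bins_of(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n_bins, dtype=bool)
        if mask.any():
            b = ((theta[mask] + np.pi) / (2 * np.pi) * n_bins).astype(int)
            out[np.clip(b, 0, n_bins - 1)] = True
        return out

    contactable = bins_of(band & ~scaffold2d)
    hit = bins_of(band & bone2d)
    arc = float((hit & contactable).sum() / max(contactable.sum(), 1))
    tier = defect2d & (r >= r_wall - SHELL_MM) & ~scaffold2d
    occupancy = float(bone2d[tier].mean()) if tier.any() else 0.0
    return InterfaceMetrics(arc, occupancy >= ENGULFMENT_OCCUPANCY)


def score_interface(metrics: InterfaceMetrics) -> int:
    """Map interface metrics to the 0-4 rubric."""
    if metrics.engulfment:
        return 4
    arc = metrics.contact_arc_fraction
    if arc < ARC_CUTS[0]:
        return 0
    if arc < ARC_CUTS[1]:
        return 1
    if arc < ARC_CUTS[2]:
        return 2
    return 3


def score_interior(bone2d: np.ndarray, scaffold2d: np.ndarray,
                   defect2d: np.ndarray, voxel_size_um: float) -> int:
    """Interior (central) osteogenesis score 0-4 for one axial section.

    The graded quantity is the bone area fraction of the interior pore
    space (defect minus the outermost tier and the scaffold), refined by
    morphology: thin/reticulate components cap at 2, substantial deposits
    reach 3, and massive fill covering >=90% of the pore space scores 4.
    """
    h = voxel_size_um / 1000.0
    r, _ = _radial_map(defect2d.shape, h)
    if not defect2d.any():
        raise DetectionError("defect outline not present in this section")
    r_wall = float(r[defect2d].max())
    interior = defect2d & (r < r_wall - SHELL_MM)
    pore = interior & ~scaffold2d
    if not pore.any():
        return 0
    bone = bone2d & pore
    a = float(bone.sum() / pore.sum())
    if a <= 0.0:
        return 0
    if a < AREA_CUTS[0]:
        return 1
    # morphology: half-thickness of the deposits via in-component EDT
    half = ndimage.distance_transform_edt(bone)
    thick = float(half.max()) >= THICK_HALF_VOX
    if a < AREA_CUTS[1]:
        return 3 if thick else 2
    if a < AREA_CUTS[2]:
        return 3
    # coverage: fraction of the pore space within one pore-block of bone
    reach = ndimage.distance_transform_edt(~bone) * h
    coverage = float((reach[pore] <= 1.5).mean())
    return 4 if coverage >= PORE_COVERAGE else 3


def true_scores_for_phantom(ph: Phantom, sample_id: str,
                            depths_mm=SECTION_DEPTHS_MM) -> pd.DataFrame:
    """Deterministic rubric scores of the ground-truth masks, one row per
    virtual section."""
    kw = dict(origin_mm=ph.origin_mm, voxel_size_um=ph.voxel_size_um,
              periosteal_z_mm=ph.periosteal_z_mm, depths_mm=depths_mm)
    bones = virtual_sections(ph.bone_mask, **kw)
    scafs = virtual_sections(ph.scaffold_mask, **kw)
    defects = virtual_sections(ph.defect_mask, **kw)
    rows = []
    for depth in bones:
        m = interface_metrics(bones[depth], scafs[depth], defects[depth],
                              ph.voxel_size_um)
        rows.append({
            "sample_id": sample_id,
            "depth_mm": depth,
            "interface_score": score_interface(m),
            "interior_score": score_interior(bones[depth], scafs[depth],
                                             defects[depth],
                                             ph.voxel_size_um),
        })
    return pd.DataFrame(rows)


def consensus_scores(records: pd.DataFrame, seed: int | None = 0,
                     p_up: float = 0.1, p_down: float = 0.1,
                     max_retries: int = 25,
                     score_columns: tuple[str, ...] = ("interface_score",
                                                       "interior_score"),
                     image_keys: tuple[str, ...] = ("sample_id", "depth_mm"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve 3-rater records into consensus scores.

    Per image and score column: if the inter-rater range is <= 1 unit the
    consensus is the three-rater mean; otherwise the image is flagged and
    rescored (raters redraw around their current median) until the range
    closes, a :class:`ConsensusError` after ``max_retries``.  Returns
    ``(consensus, rescore_log)``.
    """
    n_raters = records["rater"].nunique()
    if n_raters != 3:
        raise ValueError(f"expected exactly 3 raters, got {n_raters}")
    rng = np.random.default_rng(seed)
    out, log = [], []
    for key, grp in records.groupby(list(image_keys), sort=True):
        row = dict(zip(image_keys, key if isinstance(key, tuple) else (key,)))
        for col in score_columns:
            scores = grp[col].to_numpy().astype(int)
            flagged = scores.max() - scores.min() > 1
            tries = 0
            while scores.max() - scores.min() > 1:
                if tries >= max_retries:
                    raise ConsensusError(
                        f"image {key} column {col} did not reach consensus")
                med = int(round(np.median(scores)))
                e = rng.choice([-1, 0, 1], size=len(scores),
                               p=[p_down, 1 - p_up - p_down, p_up])
                scores = np.clip(med + e, 0, 4)
                tries += 1
            row[col] = float(scores.mean())
            if flagged:
                log.append({**{k: row[k] for k in image_keys},
                            "column": col, "rescores": tries})
        out.append(row)
    return pd.DataFrame(out), pd.DataFrame(log)


def mineral_apposition_rate(section: FluorSection) -> float:
    """MAR in um/day from one fluorescence section.

    The bone front is the innermost radius of the peripheral rim (subpixel,
    from the 50% crossing of the radial occupancy of the bone signal); the
    label band is the intensity-weighted mean radius of the band pixels.
    Their distance divided by the labelling interval is the MAR.
    """
    img = section.image
    h_um = section.pixel_size_um
    cx, cy = section.center_px
    xx, yy = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    r_px = np.hypot(xx - cx, yy - cy)

    band_w = np.clip(img - 0.7, 0.0, None)
    if band_w.sum() <= 0:
        raise DetectionError("no label band detected")
    r_band = float((band_w * r_px).sum() / band_w.sum())

    # radial occupancy of the bone-level signal in 1-px annuli
    bone = img > 0.2
    nbins = int(r_px.max()) + 1
    idx = r_px.astype(int).ravel()
    occ_num = np.bincount(idx, weights=bone.ravel().astype(float),
                          minlength=nbins)
    occ_den = np.bincount(idx, minlength=nbins).astype(float)
    occ = np.where(occ_den > 0, occ_num / np.maximum(occ_den, 1), 0.0)
    # walk inward from the rim while the annuli stay occupied
    k = int(np.floor(r_band))
    if occ[k] < 0.5:
        raise DetectionError("label band does not sit inside the bone rim")
    while k > 0 and occ[k - 1] >= 0.5:
        k -= 1
    if k == 0:
        raise DetectionError("bone front not found inside the section")
    # subpixel 50% crossing between bins k-1 and k
    frac = (0.5 - occ[k - 1]) / max(occ[k] - occ[k - 1], 1e-9)
    r_front = (k - 1) + frac + 0.5  # bin centers at integer + 0.5
    offset_um = (r_band - r_front) * h_um
    if offset_um < 0:
        raise DetectionError("label band located inside the bone front")
    return offset_um / section.interval_days
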