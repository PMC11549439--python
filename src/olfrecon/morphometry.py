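"""Stereological quantification of the reconstructed specimen.

Implements the counting chain used to estimate the total number of olfactory
sensory neurons (OSNs): voxel-count volumes with linear interpolation over
non-included sections, the morphologically closed olfactory-epithelium
envelope, Abercrombie-corrected linear densities, the volumetric OSN density
as a ratio of two estimates (Fieller or Delta standard errors), the total
count extrapolated over the envelope volume with its 90 % confidence
interval, sphere-model glomerulus estimates, derived per-glomerulus and
per-gene ratios, and interleaved-sampling error analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats
from skimage.measure import label as cc_label

#: normal quantile for the 90 % confidence interval
Z90 = 1.645


@dataclass(frozen=True)
class VoxelGeometry:
    """Pixel size and section thickness in µm."""

    pixel_size: float = 1.097
    section_thickness: float = 10.0

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size**2 * self.section_thickness

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size**2


@dataclass(frozen=True)
class LinearDensity:
    """OSNs per mm of OSN-bearing epithelium length (mean ± SEM)."""

    mean: float
    sem: float
    n_counted: int = 0
    n_sections: int = 0


@dataclass(frozen=True)
class ThicknessEstimate:
    """Olfactory-epithelium thickness in µm (mean ± SEM)."""

    mean: float
    sem: float
    n_measurements: int = 0


@dataclass(frozen=True)
class CountEstimate:
    mean: float
    sem: float
    ci90: tuple[float, float]
    method: str = "delta"

    def __post_init__(self) -> None:
        lo, hi = self.ci90
        slack = 1e-9 * max(1.0, abs(self.mean))  # rounding headroom
        if not lo - slack <= self.mean <= hi + slack:
            raise ValueError("mean must lie inside its confidence interval")


@dataclass
class EnvelopeResult:
    """Per-section envelope masks plus their interpolated volume in mm³."""

    masks: np.ndarray  # (n_sections, H, W) bool
    volume_mm3: float
    disk_diameter_um: float = 80.0


@dataclass(frozen=True)
class SphereModel:
    """Glomerulus count implied by a mean spherical diameter."""

    diameter_um: float
    glomerular_volume_mm3: float
    count_float: float
    count: int


# ---------------------------------------------------------------------------
# volumes


def interpolated_areas(areas_px: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Fill non-included sections' areas by linear interpolation.

    Interior gaps interpolate between the nearest included neighbours;
    boundary gaps take the nearest included value (constant extrapolation).
    """
    areas = np.asarray(areas_px, dtype=float)
    inc = np.asarray(included, dtype=bool)
    if areas.shape != inc.shape:
        raise ValueError("areas and included flags must align")
    if not inc.any():
        raise ValueError("all sections excluded; nothing to interpolate from")
    pos = np.arange(len(areas))
    return np.interp(pos, pos[inc], areas[inc])


def structure_volume(masks: np.ndarray, included: np.ndarray,
                     geometry: VoxelGeometry) -> float:
    """Voxel-count volume in mm³ with interpolation over missing sections.

    ``masks`` is (n_sections, H, W); masks of non-included sections are
    ignored and replaced by interpolated per-section areas.
    """
    masks = np.asarray(masks)
    areas = masks.reshape(masks.shape[0], -1).sum(axis=1).astype(float)
    filled = interpolated_areas(areas, included)
    total_um3 = filled.sum() * geometry.pixel_area_um2 * geometry.section_thickness
    return total_um3 * 1e-9  # µm³ -> mm³


# ---------------------------------------------------------------------------
# the olfactory-epithelium envelope


def _expand_to_thickness(epithelium: np.ndarray, core: np.ndarray) -> np.ndarray:
    """Fill, per epithelium connected component, every apical-basal column
    that carries at least one OSN pixel across the component's thickness."""
    out = np.zeros_like(epithelium, dtype=bool)
    labels = cc_label(epithelium, connectivity=2)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        cols = (core & comp).any(axis=0)
        if cols.any():
            out |= comp & cols[None, :]
    return out


def disk_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a Euclidean disk.

    Computed by thresholding distance transforms, which is exactly the
    dilation/erosion by the disk of pixels at distance <= radius and is far
    faster than sliding the footprint.  The image is padded by the radius
    first, so the closing behaves as in free space (the border does not act
    as foreground).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    pad = int(np.ceil(radius_px)) + 1
    big = np.pad(mask, pad)
    dilated = ndimage.distance_transform_edt(~big) <= radius_px
    closed = ndimage.distance_transform_edt(dilated) > radius_px
    return closed[pad:-pad, pad:-pad]


def envelope_section(epithelium_mask: np.ndarray, osn_mask: np.ndarray,
                     disk_radius_px: float) -> np.ndarray:
    """Single-section envelope: intersect, expand to thickness, close."""
    core = np.asarray(osn_mask, dtype=bool) & np.asarray(epithelium_mask, dtype=bool)
    if not core.any():
        return core
    expanded = _expand_to_thickness(np.asarray(epithelium_mask, dtype=bool), core)
    closed = disk_closing(expanded, disk_radius_px)
    # closing may bridge across the background; keep it inside the epithelium
    return closed & np.asarray(epithelium_mask, dtype=bool) | expanded


def olfactory_envelope(epithelium_masks: np.ndarray, osn_masks: np.ndarray,
                       included: np.ndarray, geometry: VoxelGeometry,
                       disk_diameter_um: float = 80.0) -> EnvelopeResult:
    """The morphologically closed olfactory-epithelium envelope.

    Per section, the OSN-epithelium intersection is expanded to the
    epithelium's full thickness and the in-plane gaps smaller than the
    structuring element (an 80 µm disk by default) are closed by dilation
    followed by erosion.  The envelope volume uses the same interpolation
    over non-included sections as every other structure volume.
    """
    if disk_diameter_um < geometry.pixel_size:
        raise ValueError("structuring element smaller than one pixel")
    epi = np.asarray(epithelium_masks, dtype=bool)
    osn = np.asarray(osn_masks, dtype=bool)
    if epi.shape != osn.shape:
        raise ValueError("mask stacks must share a shape")
    radius_px = max(1, int(round((disk_diameter_um / 2.0) / geometry.pixel_size)))
    env = np.zeros_like(epi)
    for z in range(epi.shape[0]):
        if included[z]:
            env[z] = envelope_section(epi[z], osn[z], radius_px)
    volume = structure_volume(env, included, geometry)
    return EnvelopeResult(masks=env, volume_mm3=volume,
                          disk_diameter_um=disk_diameter_um)


# ---------------------------------------------------------------------------
# counting statistics


def abercrombie_correct(raw_count: float, section_thickness_um: float,
                        nucleus_diameter_um: float) -> float:
    """Classical Abercrombie profile-count correction: raw * T / (T + D)."""
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    if nucleus_diameter_um < 0 or raw_count < 0:
        raise ValueError("counts and diameters must be non-negative")
    return raw_count * section_thickness_um / (
        section_thickness_um + nucleus_diameter_um
    )


def delta_ratio_sem(a: float, sa: float, b: float, sb: float) -> float:
    """First-order (Delta-method) SEM of the ratio a/b of independent means."""
    r = a / b
    return abs(r) * np.sqrt((sa / a) ** 2 + (sb / b) ** 2)


def fieller_ratio_ci(a: float, sa: float, b: float, sb: float,
                     z: float = Z90) -> tuple[float, float]:
    """Fieller confidence limits for the ratio a/b of independent estimates."""
    g = (z * sb / b) ** 2
    if g >= 1:
        raise ValueError("denominator indistinguishable from zero at this level")
    r = a / b
    disc = sa**2 + r**2 * sb**2 - g * sa**2
    half = (z / b) * np.sqrt(disc)
    return ((r - half) / (1 - g), (r + half) / (1 - g))


def volumetric_density(lin: LinearDensity, thick: ThicknessEstimate,
                       section_thickness_um: float = 10.0,
                       method: str = "fieller") -> CountEstimate:
    """OSNs per mm³: linear density over (thickness x section depth).

    The point estimate is ``lin.mean / (thickness_mm * depth_mm)``.  The
    ratio's SEM comes from Fieller's theorem (interval width over 2z) or,
    with ``method='delta'``, from first-order error propagation.  When the
    linear density records how many sections it was counted on, the Fieller
    limits use the Student-t quantile at n_sections - 1 degrees of freedom
    (the classical form of the theorem); otherwise the normal 1.645.
    """
    if lin.mean <= 0 or thick.mean <= 0 or section_thickness_um <= 0:
        raise ValueError("means and thicknesses must be positive")
    scale = 1e6 / section_thickness_um  # 1/(mm * mm) per (per-mm / µm)
    mean = scale * (lin.mean / thick.mean)
    if method == "fieller":
        q = Z90
        if lin.n_sections >= 2:
            q = float(stats.t.ppf(0.95, lin.n_sections - 1))
        lo, hi = fieller_ratio_ci(lin.mean, lin.sem, thick.mean, thick.sem, z=q)
        lo, hi = scale * lo, scale * hi
        sem = (hi - lo) / (2 * Z90)
    elif method == "delta":
        sem = scale * delta_ratio_sem(lin.mean, lin.sem, thick.mean, thick.sem)
        lo, hi = mean - Z90 * sem, mean + Z90 * sem
    else:
        raise ValueError("method must be 'fieller' or 'delta'")
    return CountEstimate(mean=mean, sem=sem, ci90=(lo, hi), method=method)


def total_osn(density: CountEstimate, envelope_volume_mm3: float) -> CountEstimate:
    """Total OSNs: density extrapolated over the envelope volume.

    The envelope volume is treated as fixed, so the SEM scales linearly and
    the 90 % interval is the Delta-method mean ± 1.645 SEM.
    """
    if envelope_volume_mm3 <= 0:
        raise ValueError("envelope volume must be positive")
    mean = density.mean * envelope_volume_mm3
    sem = density.sem * envelope_volume_mm3
    return CountEstimate(
        mean=mean, sem=sem,
        ci90=(mean - Z90 * sem, mean + Z90 * sem), method="delta",
    )


def epithelium_surface_area(envelope_volume_mm3: float,
                            thick: ThicknessEstimate) -> CountEstimate:
    """Olfactory-epithelium surface area: envelope volume over thickness."""
    if thick.mean <= 0:
        raise ValueError("thickness must be positive")
    t_mm = thick.mean * 1e-3
    mean = envelope_volume_mm3 / t_mm
    sem = mean * (thick.sem / thick.mean)  # Delta method from thickness SEM
    return CountEstimate(
        mean=mean, sem=sem,
        ci90=(mean - Z90 * sem, mean + Z90 * sem), method="delta",
    )


def sphere_glomerulus_count(glomerular_volume_mm3: float,
                            diameter_um: float) -> SphereModel:
    """Glomeruli as identical spheres: count = volume / sphere volume."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    sphere_mm3 = (4.0 / 3.0) * np.pi * (diameter_um / 2.0) ** 3 * 1e-9
    cf = glomerular_volume_mm3 / sphere_mm3
    return SphereModel(
        diameter_um=diameter_um, glomerular_volume_mm3=glomerular_volume_mm3,
        count_float=cf, count=int(round(cf)),
    )


def ratio_report(total: float, glomeruli_total: float,
                 n_genes: int) -> dict:
    """Convergence ratios: OSNs per glomerulus and per odorant-receptor gene."""
    if glomeruli_total <= 0 or n_genes <= 0:
        raise ValueError("denominators must be positive")
    per_glom = total / glomeruli_total
    per_gene = total / n_genes
    return {
        "osns_per_glomerulus": per_glom,
        "osns_per_glomerulus_rounded": int(round(per_glom)),
        "osns_per_gene": per_gene,
        "osns_per_gene_rounded": int(round(per_gene)),
    }


# ---------------------------------------------------------------------------
# interleaved sampling


def interleave_included(included: np.ndarray, rate: int) -> np.ndarray:
    """Keep every ``rate``-th included section, drop the rest."""
    if rate < 1:
        raise ValueError("rate must be >= 1")
    inc = np.asarray(included, dtype=bool)
    keep = np.zeros_like(inc)
    idx = np.flatnonzero(inc)[::rate]
    keep[idx] = True
    return keep


def interleaved_error(masks: np.ndarray, included: np.ndarray,
                      geometry: VoxelGeometry,
                      rates=(4, 16, 32)) -> dict[int, float]:
    """Percent volume error from sampling every r-th included section."""
    full = structure_volume(masks, included, geometry)
    out = {}
    for r in rates:
        keep = interleave_included(included, r)
        if keep.sum() < 2:
            raise ValueError(f"rate {r} leaves fewer than 2 sections")
        sub = structure_volume(masks, keep, geometry)
        out[r] = abs(sub - full) / full * 100.0 if full > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# measuring density and thickness on a mask series (the "virtual anatomist")


def measure_linear_density(series, nucleus_diameter_um: float = 0.0,
                           section_indices=None,
                           disk_diameter_um: float = 80.0,
                           thickness_um: float | None = None) -> LinearDensity:
    """Count OSN somata per mm of OSN-bearing epithelium on chosen sections.

    The OSN-bearing length is measured on the section's closed envelope (the
    same 80 µm closing used for the volume): with a mean epithelial
    thickness supplied, length is envelope area over thickness — the same
    quantity the envelope-volume extrapolation divides by, which keeps the
    counting chain internally consistent; without one it falls back to the
    envelope's column count.  The counted somata are the connected
    components of the OSN mask inside the envelope.  The density is the
    pooled ratio estimator (total corrected count over total measured
    length), whose SEM follows the standard ratio-estimator variance over
    sections; pooling avoids the small-sample bias of averaging per-section
    ratios.  An Abercrombie correction with the given nucleus diameter
    adjusts for profiles split across sections.
    """
    chosen = series.included if section_indices is None else [
        s for s in series.sections if s.index in set(section_indices) and s.included
    ]
    if not chosen:
        raise ValueError("no included sections to measure")
    px_mm = series.pixel_size * 1e-3
    radius_px = max(1, int(round((disk_diameter_um / 2.0) / series.pixel_size)))
    counts, lengths, total_counted = [], [], 0
    for sec in chosen:
        epi = sec.mask("nasal_epithelium")
        core = sec.mask("osn") & epi
        if not core.any():
            continue
        env = envelope_section(epi, core, radius_px)
        n_raw = int(cc_label(core & env, connectivity=2).max())
        if thickness_um is not None:
            length_mm = env.sum() * px_mm**2 / (thickness_um * 1e-3)
        else:
            length_mm = env.any(axis=0).sum() * px_mm
        if length_mm > 0:
            counts.append(abercrombie_correct(
                n_raw, series.section_thickness, nucleus_diameter_um
            ))
            lengths.append(length_mm)
            total_counted += n_raw
    if not counts:
        raise ValueError("no OSN-bearing epithelium found")
    counts = np.asarray(counts)
    lengths = np.asarray(lengths)
    m = len(counts)
    mean = float(counts.sum() / lengths.sum())
    if m > 1:
        resid = counts - mean * lengths
        sem = float(np.sqrt(m * resid.var(ddof=1)) / lengths.sum())
    else:
        sem = 0.0
    return LinearDensity(mean=mean, sem=sem,
                         n_counted=total_counted, n_sections=m)


def measure_thickness(series, section_indices=None) -> ThicknessEstimate:
    """Mean apical-basal epithelium thickness (µm) where OSNs are present."""
    chosen = series.included if section_indices is None else [
        s for s in series.sections if s.index in set(section_indices) and s.included
    ]
    samples = []
    for sec in chosen:
        epi = sec.mask("nasal_epithelium")
        core = sec.mask("osn") & epi
        cols = core.any(axis=0)
        if not cols.any():
            continue
        runs = epi[:, cols].sum(axis=0)  # column heights in px
        samples.extend((runs[runs > 0] * series.pixel_size).tolist())
    if not samples:
        raise ValueError("no OSN-bearing epithelium found")
    arr = np.asarray(samples)
    sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return ThicknessEstimate(mean=float(arr.mean()), sem=float(sem),
                             n_measurements=len(arr))
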