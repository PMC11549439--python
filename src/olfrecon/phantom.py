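"""Virtual *en-bloc* specimen generator.

Builds a small 3D phantom of the olfactory region — nasal epithelium with
embedded olfactory sensory neurons (OSNs), arterial vasculature in the lamina
propria, a bone plate, and an olfactory bulb carrying a glomerular shell —
renders it as a series of 4-channel fluorescence sections (Hoechst, UEA1, OMP,
VGLUT2), and degrades it with the artifacts a real serial-section dataset
shows: per-section smooth deformation, a global quadratic lateral drift (the
"banana" curvature) and random section dropout.  Exact ground-truth masks are
carried through every transform, so segmentation, registration and stereology
can all be tested against known truth.

The scene is geometrically condensed: the pixel size is the real 1.097 µm but
all six structures co-exist inside a ~140 µm field of view, so the phantom is
a miniature of the specimen, not a photorealistic replica.  Epithelium
thickness and OSN linear density default to the measured study values
(67.23 µm, 78.31 OSNs per mm) so the counting chain runs under realistic
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

#: canonical structure order used for every 6-mask array in the package
STRUCTURES = (
    "nasal_epithelium",
    "osn",
    "glomeruli",
    "olfactory_bulb",
    "vasculature",
    "bone",
)

#: canonical fluorescence channel order
CHANNELS = ("hoechst", "uea1", "omp", "vglut2")

# per-structure emission intensity in each channel, rows follow STRUCTURES,
# columns follow CHANNELS.  OMP is OSN-specific, VGLUT2 glomerulus-dominant,
# UEA1 broad, Hoechst generic nuclear; bone is unstained (recognised by the
# absence of signal, as in the tissue).
DEFAULT_STAIN_MODEL = {
    "nasal_epithelium": (0.50, 0.30, 0.00, 0.00),
    "osn": (0.25, 0.45, 0.90, 0.15),
    "glomeruli": (0.20, 0.10, 0.35, 0.90),
    "olfactory_bulb": (0.45, 0.05, 0.00, 0.05),
    "vasculature": (0.40, 0.60, 0.00, 0.00),
    "bone": (0.00, 0.00, 0.00, 0.00),
}


class PhantomGeometryError(ValueError):
    """Raised when the requested structures cannot fit the grid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the virtual specimen.

    All physical lengths are µm.  ``banana_curvature`` is the lateral pixel
    offset per squared 1-based section index; ``deform_amplitude`` bounds the
    per-section random smooth displacement in pixels.
    """

    grid_shape: tuple[int, int, int] = (60, 128, 128)
    pixel_size: float = 1.097
    section_thickness: float = 10.0
    # structure geometry
    epithelium_thickness_um: float = 67.23
    epithelium_apical_row_um: float = 9.0
    epithelium_wave_amplitude_um: float = 4.0
    osn_patch_density: float = 0.6
    osn_per_mm: float = 78.31
    osn_soma_radius_um: float = 2.5
    vessel_radius_um: float = 6.0
    n_vessels: int = 3
    bone_thickness_um: float = 11.0
    bulb_axes_um: tuple[float, float] = (15.0, 44.0)
    bulb_z_fraction: float = 0.75
    glomerulus_radius_um: float = 5.0
    n_glomeruli: int = 40
    # stain / noise model
    stain_model: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_MODEL))
    noise_sigma: float = 0.02
    # section artifacts
    deform_amplitude: float = 1.5
    banana_curvature: float = 0.002
    dropout_rate: float = 0.358
    seed: int = 0

    def __post_init__(self) -> None:
        n, h, w = self.grid_shape
        if n < 1 or h < 8 or w < 8:
            raise PhantomGeometryError(f"grid_shape {self.grid_shape} too small")
        for name in (
            "pixel_size",
            "section_thickness",
            "epithelium_thickness_um",
            "vessel_radius_um",
            "bone_thickness_um",
            "glomerulus_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise PhantomGeometryError(f"{name} must be strictly positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise PhantomGeometryError("dropout_rate must be in [0, 1)")
        if self.deform_amplitude < 0:
            raise PhantomGeometryError("deform_amplitude must be >= 0")

    @property
    def px(self) -> float:
        return self.pixel_size

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size


@dataclass
class SectionRecord:
    """One rendered serial section: 4 channels, 6 truth masks, inclusion flag."""

    index: int  # 1-based anterior -> posterior
    channels: np.ndarray  # (4, H, W) float32 in [0, 1]
    masks: np.ndarray  # (6, H, W) bool, order = STRUCTURES
    included: bool = True

    def mask(self, structure: str) -> np.ndarray:
        return self.masks[STRUCTURES.index(structure)]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNELS.index(name)]


@dataclass
class SectionSeries:
    """Ordered serial sections plus acquisition geometry.

    ``n_cut`` counts every section that was cut, included or not; the included
    subset is the "complete dataset" all quantification runs on.
    """

    sections: list[SectionRecord]
    n_cut: int
    pixel_size: float = 1.097
    section_thickness: float = 10.0

    def __post_init__(self) -> None:
        idx = [s.index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")
        if sum(s.included for s in self.sections) > self.n_cut:
            raise ValueError("more included sections than sections cut")

    @property
    def included(self) -> list[SectionRecord]:
        return [s for s in self.sections if s.included]

    @property
    def included_indices(self) -> list[int]:
        return [s.index for s in self.sections if s.included]

    def mask_stack(self, structure: str) -> np.ndarray:
        """All sections' masks for one structure, shape (n_sections, H, W)."""
        return np.stack([s.mask(structure) for s in self.sections])

    def included_flags(self) -> np.ndarray:
        return np.array([s.included for s in self.sections], dtype=bool)


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(config: PhantomConfig):
    """Build the 3D label volumes and noiseless channel volumes.

    Returns ``(labels, channels)`` where ``labels`` maps structure name to a
    (n, H, W) boolean volume and ``channels`` is a (4, n, H, W) float32 volume.
    Containment rules hold by construction: glomeruli lie inside the bulb,
    vasculature never enters the nasal epithelium, OSN somata sit inside the
    epithelium.
    """
    n, h, w = config.grid_shape
    rng = np.random.default_rng(config.seed)
    to_px = config.um_to_px

    epi_top = to_px(config.epithelium_apical_row_um)
    epi_thick = to_px(config.epithelium_thickness_um)
    wave = to_px(config.epithelium_wave_amplitude_um)
    if epi_top + epi_thick + 2 * to_px(config.vessel_radius_um) + to_px(
        config.bone_thickness_um
    ) + 4 >= h:
        raise PhantomGeometryError(
            "epithelium + lamina propria + bone do not fit the grid height"
        )

    rows = np.arange(h)[:, None, None]  # (h,1,1)
    cols = np.arange(w)[None, None, :]  # broadcast over (z, h, w) as needed
    zz = np.arange(n)[None, :, None]

    # apical surface row varies smoothly in x and z
    phase = rng.uniform(0, 2 * np.pi)
    apical = epi_top + wave * np.sin(2 * np.pi * cols / w + 0.08 * zz + phase)
    apical = np.broadcast_to(apical, (1, n, w))[0]  # (n, w)

    epithelium = np.zeros((n, h, w), dtype=bool)
    rr = np.arange(h)[None, :, None]
    a = apical[:, None, :]
    epithelium = (rr >= a) & (rr < a + epi_thick)
    epi_bottom = float(np.max(apical) + epi_thick)

    # OSN patches: smooth z-coherent column indicator with target coverage
    noise = rng.normal(size=(n, w))
    smooth = ndimage.gaussian_filter(noise, sigma=(6.0, 8.0), mode="wrap")
    thr = np.quantile(smooth, 1.0 - config.osn_patch_density)
    patch = smooth >= thr  # (n, w) columns that carry OSNs

    # discrete OSN somata: per section, Poisson along the patched columns with
    # the configured linear density (per mm of epithelium length)
    soma_r = max(1, int(round(to_px(config.osn_soma_radius_um))))
    osn = np.zeros((n, h, w), dtype=bool)
    lam_per_col = config.osn_per_mm * (config.pixel_size / 1000.0)
    for z in range(n):
        cols_z = np.flatnonzero(patch[z])
        if cols_z.size == 0:
            continue
        n_cells = rng.poisson(lam_per_col * cols_z.size)
        if n_cells == 0:
            continue
        # hard-core placement: nuclei do not interpenetrate, so connected
        # components of the rendered mask equal the placed cell count
        accepted: list[tuple[int, int]] = []
        min_d2 = (2 * soma_r + 1) ** 2
        for _ in range(n_cells):
            for _attempt in range(30):
                cx = int(rng.choice(cols_z))
                # somata occupy the mid-depth of the epithelium, as in tissue
                cy = int(apical[z, cx] + rng.uniform(0.25, 0.9) * epi_thick)
                if all((cy - ay) ** 2 + (cx - ax) ** 2 >= min_d2 for ay, ax in accepted):
                    accepted.append((cy, cx))
                    break
        for cy, cx in accepted:
            y0, y1 = max(0, cy - soma_r), min(h, cy + soma_r + 1)
            x0, x1 = max(0, cx - soma_r), min(w, cx + soma_r + 1)
            yy, xx = np.ogrid[y0:y1, x0:x1]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= soma_r**2
            osn[z, y0:y1, x0:x1] |= blob
    osn &= epithelium  # somata stay inside the epithelium

    # vasculature: tubes along z in the lamina propria, below the epithelium
    vr = to_px(config.vessel_radius_um)
    vessel_row_lo = epi_bottom + vr + 1
    bone_top = max(vessel_row_lo + 2 * vr + 2, h * 0.62)
    vasculature = np.zeros((n, h, w), dtype=bool)
    zf = np.arange(n)
    for _ in range(config.n_vessels):
        c0 = rng.uniform(0.1 * w, 0.9 * w)
        r0 = rng.uniform(vessel_row_lo, bone_top - vr - 2)
        amp = rng.uniform(0.0, 3.0)
        ph = rng.uniform(0, 2 * np.pi)
        cx = c0 + amp * np.sin(2 * np.pi * zf / n + ph)
        cy = np.full(n, r0)
        for z in range(n):
            yy, xx = np.ogrid[0:h, 0:w]
            tube = (yy - cy[z]) ** 2 + (xx - cx[z]) ** 2 <= vr**2
            vasculature[z] |= tube
    vasculature &= ~epithelium  # no vasculature within the olfactory epithelium

    # bone plate (cribriform-like) separating mucosa from the cranial side
    bt = to_px(config.bone_thickness_um)
    bone = (rows >= bone_top) & (rows < bone_top + bt)
    bone = np.broadcast_to(np.transpose(bone, (1, 0, 2)), (n, h, w)).copy()
    bone[:, :, :] &= ~epithelium & ~vasculature

    # olfactory bulb: ellipsoid on the cranial side of the plate
    ay = to_px(config.bulb_axes_um[0])
    ax = to_px(config.bulb_axes_um[1])
    az = max(2.0, config.bulb_z_fraction * n / 2.0)
    cy_b = min(h - 2.0, bone_top + bt + ay + 1)
    bulb = _ellipsoid_mask((n, h, w), (n / 2.0, cy_b, w / 2.0), (az, ay, ax))
    bulb &= ~bone
    if not bulb.any():
        raise PhantomGeometryError("olfactory bulb does not fit below the bone plate")

    # glomerular shell: blobs seeded on the outer 30 % of the bulb radius
    nd = np.zeros((n, h, w), dtype=float)
    for g, c, a_ in zip(
        np.ogrid[0:n, 0:h, 0:w], (n / 2.0, cy_b, w / 2.0), (az, ay, ax)
    ):
        nd = nd + ((g - c) / a_) ** 2
    shell = (nd <= 1.0) & (nd >= 0.55)
    shell_idx = np.argwhere(shell)
    glomeruli = np.zeros((n, h, w), dtype=bool)
    gr = to_px(config.glomerulus_radius_um)
    if shell_idx.size:
        picks = shell_idx[rng.choice(len(shell_idx), size=config.n_glomeruli)]
        for pz, py, px_ in picks:
            z0, z1 = max(0, pz - 2), min(n, pz + 3)
            y0, y1 = max(0, int(py - gr) - 1), min(h, int(py + gr) + 2)
            x0, x1 = max(0, int(px_ - gr) - 1), min(w, int(px_ + gr) + 2)
            zz2, yy2, xx2 = np.ogrid[z0:z1, y0:y1, x0:x1]
            blob = ((zz2 - pz) * 2.0) ** 2 + (yy2 - py) ** 2 + (xx2 - px_) ** 2 <= gr**2
            glomeruli[z0:z1, y0:y1, x0:x1] |= blob
    glomeruli &= bulb  # strict containment

    labels = {
        "nasal_epithelium": epithelium,
        "osn": osn,
        "glomeruli": glomeruli,
        "olfactory_bulb": bulb,
        "vasculature": vasculature,
        "bone": bone,
    }

    channels = np.zeros((len(CHANNELS), n, h, w), dtype=np.float32)
    for s_i, name in enumerate(STRUCTURES):
        inten = np.asarray(config.stain_model[name], dtype=np.float32)
        vol = labels[name]
        for c_i in range(len(CHANNELS)):
            if inten[c_i] > 0:
                channels[c_i][vol] = np.maximum(channels[c_i][vol], inten[c_i])
    return labels, channels


def _random_smooth_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth random 2D displacement field with max |component| <= amplitude."""
    h, w = shape
    f = rng.normal(size=(2, h, w))
    f = ndimage.gaussian_filter(f, sigma=(0, h / 8.0, w / 8.0))
    peak = np.max(np.abs(f))
    if peak > 0:
        f *= amplitude / peak
    return f.astype(np.float32)


def _warp(img: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    """Resample ``img`` at x + disp(x); out-of-domain samples become 0."""
    h, w = img.shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([gy + disp[0], gx + disp[1]])
    out = ndimage.map_coordinates(
        img.astype(np.float32), coords, order=order, mode="constant", cval=0.0
    )
    return out


def render_sections(phantom, config: PhantomConfig) -> SectionSeries:
    """Slice the phantom into a degraded serial-section series.

    Each section is warped by a rigid lateral shift quadratic in the 1-based
    section index (``banana_curvature * i**2`` pixels, the programmed banana
    artifact) composed with a seeded smooth random deformation.  Ground-truth
    masks are warped with the identical transform using nearest-neighbour
    resampling, channels bilinearly.  Sections are then dropped i.i.d.
    Bernoulli(``dropout_rate``).
    """
    labels, channels = phantom
    n, h, w = config.grid_shape
    rng = np.random.default_rng(config.seed + 1)
    drop = rng.random(n) < config.dropout_rate
    noise_rng = np.random.default_rng(config.seed + 2)

    records = []
    for z in range(n):
        i = z + 1
        disp = np.zeros((2, h, w), dtype=np.float32)
        disp[1] -= config.banana_curvature * i**2  # sample at x - off => shift +off
        if config.deform_amplitude > 0:
            disp += _random_smooth_field((h, w), config.deform_amplitude, rng)
        elif config.banana_curvature == 0:
            disp = None  # identity: keep raw slices bit-exact

        chans = np.empty((len(CHANNELS), h, w), dtype=np.float32)
        for c_i in range(len(CHANNELS)):
            sl = channels[c_i, z]
            chans[c_i] = sl if disp is None else _warp(sl, disp, order=1)
            if config.noise_sigma > 0:
                chans[c_i] = chans[c_i] + noise_rng.normal(
                    0, config.noise_sigma, size=(h, w)
                ).astype(np.float32)
        np.clip(chans, 0.0, 1.0, out=chans)

        masks = np.empty((len(STRUCTURES), h, w), dtype=bool)
        for s_i, name in enumerate(STRUCTURES):
            sl = labels[name][z]
            masks[s_i] = (
                sl if disp is None else _warp(sl.astype(np.float32), disp, order=0) > 0.5
            )
        records.append(
            SectionRecord(index=i, channels=chans, masks=masks, included=not drop[z])
        )
    return SectionSeries(
        sections=records,
        n_cut=n,
        pixel_size=config.pixel_size,
        section_thickness=config.section_thickness,
    )


def make_series(config: PhantomConfig) -> SectionSeries:
    """Convenience: phantom construction and section rendering in one call."""
    return render_sections(make_phantom(config), config)


def with_overrides(config: PhantomConfig, **kwargs) -> PhantomConfig:
    return replace(config, **kwargs)
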