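"""Seedable synthetic ICH cases for testing the pipeline without patient data.

Each case comprises co-registered T2* GRE and FLAIR volumes, a reduced
MALP-EM-style label map, a small-vessel-disease (SVD) probability map, and
ground-truth haematoma/oedema masks.  The generator emulates the contrast
regimes seen in acute/early-subacute haemorrhage:

* the haematoma is hypo-intense on T2* GRE, optionally with an iso-intense
  centre, and blooms beyond its true extent by a susceptibility margin;
* on FLAIR the haematoma appears at its true size (hypo or iso, optionally
  with a darker core to force a negatively skewed intensity distribution);
* a hyper-intense oedema rim surrounds the haematoma on FLAIR;
* optional decoy hypo-intense components (with or without a surrounding
  susceptibility-prone label region) and distant leukoaraiosis lesions
  (optionally connected to the rim by a thin hyper-intense tract, with high
  SVD probability) reproduce the confounds the algorithm defends against.

Brain tissue carries a deterministic Gaussian heterogeneity field (seeded from
the case seed) so that robust scale estimation is well-posed even when the
separate acquisition-noise level is zero; acquisition noise is added on top.
Voxels outside the brain are exactly zero (padding).  All structures are kept
at least 4 voxels from the grid border so the morphological stages never
interact with the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas_masks import LabelMap
from .volume_core import BinaryMask, IntensityVolume

#: reduced label catalogue used by generated cases
TISSUE_LABEL = 100  # generic cortex/tissue, not in any special set
WM_LESION_LABEL = 27  # putamen: member of the haemorrhage-prone lesion set
SUSCEPT_LABEL = 133  # temporal pole: member of the susceptibility set
CSF_SHELL_LABEL = 18
VENTRICLE_LABEL = 23


@dataclass(frozen=True)
class DecoySpec:
    """A spurious hypo-intense T2* component with no adjacent hyper-intensity."""

    centre: tuple[int, int, int]
    radii: tuple[float, float, float]
    in_susceptibility_region: bool = True


@dataclass(frozen=True)
class LeukoaraiosisSpec:
    """A distant FLAIR-hyper-intense white-matter lesion."""

    centre: tuple[int, int, int]
    radius: float
    connected_to_rim: bool = False
    svd_probability: float = 0.9


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case; deterministic given ``seed``."""

    name: str = "case"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    haematoma_centre: tuple[int, int, int] = (32, 32, 32)
    haematoma_radii: tuple[float, float, float] = (10.0, 9.0, 8.0)
    iso_core_fraction: float = 0.0  # linear fraction of radii iso-intense on T2*
    oedema_rim_thickness: int = 4
    susceptibility_bloom: int = 1  # extra hypo margin on T2* (voxels)
    ventricle_centre: tuple[int, int, int] = (32, 50, 32)
    ventricle_radii: tuple[float, float, float] = (4.0, 5.0, 4.0)
    decoys: tuple[DecoySpec, ...] = ()
    leukoaraiosis_lesions: tuple[LeukoaraiosisSpec, ...] = ()
    # intensity levels (arbitrary MR units)
    t2s_background: float = 100.0
    t2s_hypo: float = 30.0
    t2s_csf: float = 115.0
    flair_background: float = 100.0
    flair_haematoma: float = 60.0
    flair_hyper: float = 200.0
    flair_csf: float = 40.0
    flair_core_fraction: float = 0.0  # linear fraction of radii with a darker FLAIR core
    flair_core_intensity: float = 10.0
    flair_decoy_intensity: float = 90.0  # mildly hypo: keeps decoys clear of hyper-intensity
    texture_sd: float = 3.0  # intrinsic tissue heterogeneity (always present)
    noise_sd: float = 5.0  # additional acquisition noise
    seed: int = 0

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        if np.any(shape < 16):
            raise ValueError("grid dimensions must be at least 16")
        if not (self.t2s_hypo < self.t2s_background):
            raise ValueError("T2* haematoma must be hypo-intense relative to background")
        if not (self.flair_background < self.flair_hyper):
            raise ValueError("FLAIR oedema must be hyper-intense relative to background")
        if not (0.0 <= self.iso_core_fraction < 1.0):
            raise ValueError("iso_core_fraction must lie in [0, 1)")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValueError("noise levels must be non-negative")
        margin = 4
        brain_radii = shape / 2 - margin
        if np.any(brain_radii < 4):
            raise ValueError("grid too small for the brain ellipsoid")
        reach = np.asarray(self.haematoma_radii) + self.oedema_rim_thickness + self.susceptibility_bloom
        self._check_inside(self.haematoma_centre, reach, "haematoma")
        self._check_inside(self.ventricle_centre, self.ventricle_radii, "ventricle")
        for d in self.decoys:
            self._check_inside(d.centre, np.asarray(d.radii) + 2, f"decoy at {d.centre}")
        for l in self.leukoaraiosis_lesions:
            self._check_inside(l.centre, (l.radius + 2,) * 3, f"lesion at {l.centre}")

    def _check_inside(self, centre, reach, what: str) -> None:
        centre = np.asarray(centre, float)
        reach = np.asarray(reach, float)
        shape = np.asarray(self.grid_shape, float)
        if np.any(centre - reach < 4) or np.any(centre + reach > shape - 4):
            raise ValueError(f"{what} comes within 4 voxels of the grid border")


@dataclass
class PhantomCase:
    """Generated volumes, maps, and ground truth for one synthetic case."""

    t2s: IntensityVolume
    flair: IntensityVolume
    labels: LabelMap
    svd: IntensityVolume
    truth_haematoma: BinaryMask
    truth_oedema: BinaryMask
    spec: PhantomSpec = field(repr=False, default=None)

    def __iter__(self):
        yield from (self.t2s, self.flair, self.labels, self.svd, self.truth_haematoma, self.truth_oedema)


def _ellipsoid(shape, centre, radii) -> np.ndarray:
    centre = np.asarray(centre, float)
    radii = np.maximum(np.asarray(radii, float), 1e-6)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return q <= 1.0


def _ball(shape, centre, radius) -> np.ndarray:
    return _ellipsoid(shape, centre, (radius, radius, radius))


def _dilate(mask: np.ndarray, n: int) -> np.ndarray:
    from scipy import ndimage

    if n <= 0:
        return mask
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool), iterations=n)


def _line(shape, start, end) -> np.ndarray:
    """A 1-voxel-wide straight tract between two points."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    n = int(np.ceil(np.linalg.norm(end - start) * 3)) + 2
    pts = np.rint(np.linspace(start, end, n)).astype(int)
    out = np.zeros(shape, dtype=bool)
    out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return out


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Render one synthetic case; bit-identical for identical specs."""
    spec.validate()
    shape = tuple(spec.grid_shape)
    centre = np.asarray(shape, float) / 2 - 0.5
    brain = _ellipsoid(shape, centre, np.asarray(shape, float) / 2 - 4)
    brain_core = _ellipsoid(shape, centre, np.asarray(shape, float) / 2 - 6)
    csf_shell = brain & ~brain_core

    haem = _ellipsoid(shape, spec.haematoma_centre, spec.haematoma_radii)
    bloom = _dilate(haem, spec.susceptibility_bloom) & brain_core
    rim = _dilate(haem, spec.oedema_rim_thickness) & ~haem
    ventricle = _ellipsoid(shape, spec.ventricle_centre, spec.ventricle_radii) & brain_core

    # label map: paint in increasing priority; ventricle and CSF win last
    labels = np.zeros(shape, dtype=np.int32)
    labels[brain] = TISSUE_LABEL
    lesion_region = _ellipsoid(
        shape, spec.haematoma_centre, np.asarray(spec.haematoma_radii) + spec.susceptibility_bloom + 3
    ) & brain_core
    labels[lesion_region] = WM_LESION_LABEL
    for d in spec.decoys:
        if d.in_susceptibility_region:
            region = _ellipsoid(shape, d.centre, np.asarray(d.radii) + 2) & brain_core
            labels[region] = SUSCEPT_LABEL
    labels[csf_shell] = CSF_SHELL_LABEL
    labels[ventricle] = VENTRICLE_LABEL

    tissue = brain & (labels != CSF_SHELL_LABEL) & (labels != VENTRICLE_LABEL)
    rim = rim & tissue
    truth_haematoma = haem & ~ventricle & brain

    # base intensities
    t2s = np.zeros(shape, dtype=np.float64)
    flair = np.zeros(shape, dtype=np.float64)
    t2s[brain] = spec.t2s_background
    flair[brain] = spec.flair_background
    t2s[csf_shell | ventricle] = spec.t2s_csf
    flair[csf_shell | ventricle] = spec.flair_csf

    # haematoma: bloomed hypo-intensity on T2*, true extent on FLAIR
    t2s[bloom] = spec.t2s_hypo
    if spec.iso_core_fraction > 0:
        core = _ellipsoid(shape, spec.haematoma_centre, np.asarray(spec.haematoma_radii) * spec.iso_core_fraction)
        t2s[core] = spec.t2s_background
    flair[haem] = spec.flair_haematoma
    flair[rim] = spec.flair_hyper
    if spec.flair_core_fraction > 0:
        fcore = _ellipsoid(shape, spec.haematoma_centre, np.asarray(spec.haematoma_radii) * spec.flair_core_fraction)
        flair[fcore & haem] = spec.flair_core_intensity

    # decoy hypo-intense components (no adjacent FLAIR hyper-intensity)
    for d in spec.decoys:
        blob = _ellipsoid(shape, d.centre, d.radii) & tissue
        t2s[blob] = spec.t2s_hypo
        flair[blob] = spec.flair_decoy_intensity

    # leukoaraiosis: FLAIR-hyper lesions with an SVD probability footprint
    svd = np.zeros(shape, dtype=np.float64)
    truth_oedema = rim.copy()
    for l in spec.leukoaraiosis_lesions:
        blob = _ball(shape, l.centre, l.radius) & tissue
        flair[blob] = spec.flair_hyper
        svd[_dilate(blob, 1) & tissue] = l.svd_probability
        if l.connected_to_rim:
            tract = _line(shape, spec.haematoma_centre, l.centre) & tissue & ~haem
            flair[tract & ~rim] = spec.flair_hyper
            svd[tract & ~rim & ~blob] = l.svd_probability

    # deterministic tissue heterogeneity plus optional acquisition noise
    rng_texture = np.random.default_rng(int(spec.seed) * 2 + 1)
    n_brain = int(brain.sum())
    if spec.texture_sd > 0:
        t2s[brain] += rng_texture.normal(0.0, spec.texture_sd, n_brain)
        flair[brain] += rng_texture.normal(0.0, spec.texture_sd, n_brain)
    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng(int(spec.seed) * 2 + 2)
        t2s[brain] += rng_noise.normal(0.0, spec.noise_sd, n_brain)
        flair[brain] += rng_noise.normal(0.0, spec.noise_sd, n_brain)

    spacing = np.ones(3)
    return PhantomCase(
        t2s=IntensityVolume(t2s, spacing=spacing),
        flair=IntensityVolume(flair, spacing=spacing),
        labels=LabelMap(labels, spacing=spacing),
        svd=IntensityVolume(svd, spacing=spacing),
        truth_haematoma=BinaryMask(truth_haematoma, spacing=spacing),
        truth_oedema=BinaryMask(truth_oedema, spacing=spacing),
        spec=spec,
    )


def scale_spec(spec: PhantomSpec, factor: int, name: str | None = None) -> PhantomSpec:
    """Scale a spec's geometry by an integer factor (intensities unchanged)."""

    def sv(v):
        return tuple(np.asarray(v, float) * factor)

    def si(v):
        return tuple(int(round(x * factor)) for x in v)

    return replace(
        spec,
        name=name or f"{spec.name}_x{factor}",
        grid_shape=si(spec.grid_shape),
        haematoma_centre=si(spec.haematoma_centre),
        haematoma_radii=sv(spec.haematoma_radii),
        oedema_rim_thickness=spec.oedema_rim_thickness * factor,
        ventricle_centre=si(spec.ventricle_centre),
        ventricle_radii=sv(spec.ventricle_radii),
        decoys=tuple(replace(d, centre=si(d.centre), radii=sv(d.radii)) for d in spec.decoys),
        leukoaraiosis_lesions=tuple(
            replace(l, centre=si(l.centre), radius=l.radius * factor) for l in spec.leukoaraiosis_lesions
        ),
    )


def fixture_catalogue() -> list[PhantomSpec]:
    """Named cases covering the contrast regimes and confounds the pipeline handles.

    * ``clean`` — single haematoma with oedema rim, zero acquisition noise;
    * ``iso_core`` — T2* haematoma with an iso-intense centre;
    * ``susceptibility_decoy`` — larger hypo-intense decoy inside a
      susceptibility-prone region, with no adjacent hyper-intensity;
    * ``intraventricular`` — haematoma extending into a ventricle;
    * ``connected_leukoaraiosis`` — distant lesion joined to the rim by a thin
      hyper-intense tract with high SVD probability, plus an unconnected one;
    * ``negative_skew`` — iso-intense FLAIR haematoma with a dark core,
      forcing the skew-corrected haemorrhage-threshold branch;
    * ``clean_noisy`` — the clean geometry at the default noise level.
    """
    clean = PhantomSpec(name="clean", noise_sd=0.0)
    return [
        clean,
        replace(clean, name="iso_core", iso_core_fraction=0.45),
        replace(
            clean,
            name="susceptibility_decoy",
            grid_shape=(80, 64, 64),
            haematoma_centre=(48, 32, 32),
            decoys=(DecoySpec(centre=(20, 32, 32), radii=(10.0, 10.0, 9.0), in_susceptibility_region=True),),
        ),
        replace(
            clean,
            name="intraventricular",
            haematoma_centre=(32, 38, 32),
            ventricle_centre=(32, 48, 32),
            ventricle_radii=(5.0, 6.0, 5.0),
        ),
        replace(
            clean,
            name="connected_leukoaraiosis",
            leukoaraiosis_lesions=(
                LeukoaraiosisSpec(centre=(32, 32, 12), radius=3.5, connected_to_rim=True, svd_probability=1.0),
                LeukoaraiosisSpec(centre=(12, 32, 32), radius=3.0, connected_to_rim=False, svd_probability=0.8),
            ),
        ),
        # heavy blooming sweeps mostly normal iso-intense tissue into the
        # selected component: median sits at tissue intensity while the dark
        # haematoma drags the mean below it (negative skew)
        replace(
            clean,
            name="negative_skew",
            susceptibility_bloom=4,
            oedema_rim_thickness=1,
            flair_haematoma=30.0,
        ),
        replace(clean, name="clean_noisy", noise_sd=5.0),
    ]


def get_fixture(name: str) -> PhantomSpec:
    for spec in fixture_catalogue():
        if spec.name == name:
            return spec
    raise KeyError(f"no phantom fixture named {name!r}")
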