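"""Anatomical masks derived from a subject-space whole-brain parcellation.

The label map is a MALP-EM-style integer parcellation already transformed to
the subject grid.  Five masks are built from it and the two MR sequences:

* whole-brain — intersection of the binarised label map with the
  hole-filling-closed nonzero masks of T2* GRE and FLAIR, then two erosions;
* susceptibility — labels prone to susceptibility artefact on T2* GRE
  (orbital/temporal/occipital cortex, cerebellum exterior, poles);
* lesion — subcortical structures where spontaneous haemorrhage is common
  (basal ganglia, thalamus, white matter, brain stem, cerebellar WM);
* ventricle — the ventricular system;
* WM-GM — whole-brain minus CSF (label 18) and ventricular voxels.

The default label sets are the standard MALP-EM indices for those regions;
they are configuration so that reduced catalogues (e.g. synthetic phantoms or
label maps carrying an extra manual "lesion" label) can be used unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volume_core import BinaryMask, IntensityVolume, binarize_nonzero, erode, hole_filling_closing

log = logging.getLogger(__name__)

#: MALP-EM labels in regions prone to susceptibility artefact on T2* GRE
SUSCEPTIBILITY_LABELS = frozenset(
    {
        10, 11,  # cerebellum exterior
        45, 46,  # anterior orbital gyrus
        59, 60,  # frontal pole
        61, 62,  # fusiform gyrus
        63, 64,  # gyrus rectus
        65, 66,  # inferior occipital gyrus
        67, 68,  # inferior temporal gyrus
        71, 72,  # lateral orbital gyrus
        75, 76,  # medial frontal cortex
        81, 82,  # medial orbital gyrus
        89, 90,  # middle temporal gyrus
        91, 92,  # occipital pole
        93, 94,  # occipital fusiform gyrus
        111, 112,  # posterior orbital gyrus
        119, 120,  # subcallosal area
        133, 134,  # temporal pole
    }
)

#: MALP-EM labels of subcortical areas where haemorrhage commonly occurs
LESION_LABELS = frozenset(
    {
        3, 4,  # accumbens area
        7,  # brain stem
        8, 9,  # caudate
        12, 13,  # cerebellum white matter
        16, 17,  # cerebral white matter
        19, 20,  # hippocampus
        25, 26,  # pallidum
        27, 28,  # putamen
        29, 30,  # thalamus proper
    }
)

#: MALP-EM ventricular labels (3rd, 4th, inferior lateral, lateral)
VENTRICLE_LABELS = frozenset({1, 2, 21, 22, 23, 24})

#: MALP-EM cerebrospinal-fluid label
CSF_LABEL = 18


@dataclass
class LabelMap:
    """Subject-space integer parcellation; 0 means unlabelled/background."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None
    label_catalogue: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D label map, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data).astype(np.int64)
            if not np.allclose(self.data, rounded):
                raise ValueError("label map must contain integer labels")
            self.data = rounded
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def _mask(self, data: np.ndarray) -> BinaryMask:
        return BinaryMask(data, spacing=self.spacing, affine=self.affine)


@dataclass
class MaskBundle:
    """The five anatomical masks consumed by the segmentation stages."""

    brain: BinaryMask
    susceptibility: BinaryMask
    lesion: BinaryMask
    ventricle: BinaryMask
    wm_gm: BinaryMask

    def check_invariants(self) -> None:
        if np.any(self.wm_gm.data & ~self.brain.data):
            raise AssertionError("WM-GM mask must be a subset of the brain mask")
        if np.any(self.wm_gm.data & self.ventricle.data):
            raise AssertionError("WM-GM mask must not intersect the ventricle mask")


def load_label_map(path) -> LabelMap:
    from .volume_core import load_volume

    vol = load_volume(path)
    return LabelMap(data=vol.data, spacing=vol.spacing, affine=vol.affine)


def build_region_mask(labels: LabelMap, label_set) -> BinaryMask:
    """True exactly where the label value belongs to ``label_set``."""
    label_set = set(label_set)
    if not label_set:
        raise ValueError("label_set must be non-empty")
    present = set(np.unique(labels.data)) & label_set
    missing = label_set - present
    if missing:
        log.debug("labels absent from map (no voxels contributed): %s", sorted(missing))
    mask = np.isin(labels.data, sorted(label_set))
    return labels._mask(mask)


def build_brain_mask(labels: LabelMap, t2s: IntensityVolume, flair: IntensityVolume) -> BinaryMask:
    """Intersection of label-map, T2* and FLAIR coverage, then two erosions.

    The T2* and FLAIR nonzero masks each receive hole-filling-closing with one
    iteration so that zero-valued voxels inside the parenchyma are retained;
    the label-derived mask is used as-is.
    """
    if labels.shape != t2s.shape or labels.shape != flair.shape:
        raise ValueError("label map and volumes must share one grid")
    label_mask = labels._mask(labels.data != 0)
    t2s_mask = hole_filling_closing(binarize_nonzero(t2s), 1)
    flair_mask = hole_filling_closing(binarize_nonzero(flair), 1)
    inter = label_mask.like(label_mask.data & t2s_mask.data & flair_mask.data)
    brain = erode(inter, 2)
    if brain.count == 0:
        raise ValueError("empty whole-brain mask: no brain found in the input volumes")
    return brain


def build_wm_gm_mask(
    brain: BinaryMask, labels: LabelMap, ventricle: BinaryMask, csf_label: int = CSF_LABEL
) -> BinaryMask:
    """Whole-brain minus CSF-labelled and ventricular voxels."""
    if brain.shape != labels.shape or brain.shape != ventricle.shape:
        raise ValueError("inputs must share one grid")
    data = brain.data & ~(labels.data == csf_label) & ~ventricle.data
    return brain.like(data)


def build_mask_bundle(
    labels: LabelMap,
    t2s: IntensityVolume,
    flair: IntensityVolume,
    susceptibility_labels=SUSCEPTIBILITY_LABELS,
    lesion_labels=LESION_LABELS,
    ventricle_labels=VENTRICLE_LABELS,
    csf_label: int = CSF_LABEL,
) -> MaskBundle:
    brain = build_brain_mask(labels, t2s, flair)
    ventricle = build_region_mask(labels, ventricle_labels)
    bundle = MaskBundle(
        brain=brain,
        susceptibility=build_region_mask(labels, susceptibility_labels),
        lesion=build_region_mask(labels, lesion_labels),
        ventricle=ventricle,
        wm_gm=build_wm_gm_mask(brain, labels, ventricle, csf_label),
    )
    bundle.check_invariants()
    return bundle
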