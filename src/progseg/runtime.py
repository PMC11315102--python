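"""Online adaptive-radiotherapy inference workflow.

Per fraction: rigidly align the prior image (and its contours) to the
current fraction's image, stack prior image / prior contour label map /
current image into a 3-channel input, run the network, carry the LSTM
memory forward, and binarize the per-structure probabilities.  Memory is
zeroed at the start and end of every course so patients are isolated.

Prior modes
-----------
revised
    The prior-contour channel holds the *ground-truth* contours of the
    previous fraction, emulating the clinical workflow where each past
    fraction's contours were clinician-approved.  Default.
auto
    The model's own previous prediction is fed back as the prior.
dir
    Deformably-registered contours on the *current* grid serve as the
    prior, and the current image fills both image channels (so prior image
    and prior contours stay consistent).  Deformable registration itself
    is external; at phantom scale the simulator's known field acts as a
    DIR oracle of controllable accuracy (``simulated_dir_contours``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .fractions import PatientSeries
from .grids import GridMismatchError, ImageVolume, StructureSet
from .model import SegmentationUNet
from .phantom import make_smooth_dvf, warp_structures

ROTATION_BOUND = 0.2  # radians; larger solutions are treated as failures

PRIOR_MODES = ("revised", "auto", "dir")


@dataclasses.dataclass
class RigidTransform:
    """Maps fixed-grid voxel coords v to moving-grid coords R@(v-c)+c+t (zyx)."""

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray
    converged: bool = True

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls, shape=(0, 0, 0), converged: bool = True) -> "RigidTransform":
        c = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
        return cls(np.eye(3), np.zeros(3), c, converged)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-12)
                and np.allclose(self.translation, 0.0, atol=1e-12))

    @property
    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    @property
    def rotation_angle(self) -> float:
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(cos, -1.0, 1.0)))

    def _matrix_offset(self):
        offset = self.center + self.translation - self.rotation @ self.center
        return self.rotation, offset

    def apply_to_image(self, img: ImageVolume) -> ImageVolume:
        if self.is_identity:
            return ImageVolume(img.data.copy(), img.spacing)
        m, o = self._matrix_offset()
        out = ndimage.affine_transform(img.data, m, offset=o, order=1, mode="nearest")
        return ImageVolume(out, img.spacing)

    def apply_to_mask(self, mask: np.ndarray) -> np.ndarray:
        if self.is_identity:
            return np.asarray(mask, dtype=np.uint8).copy()
        m, o = self._matrix_offset()
        out = ndimage.affine_transform(np.asarray(mask, dtype=np.uint8), m,
                                       offset=o, order=0, mode="nearest")
        return out.astype(np.uint8)

    def apply_to_structures(self, ss: StructureSet) -> StructureSet:
        return StructureSet({n: self.apply_to_mask(m) for n, m in ss.masks.items()})


def rigid_register(moving: ImageVolume, fixed: ImageVolume) -> tuple[RigidTransform, ImageVolume]:
    """Rigidly align ``moving`` to ``fixed`` (mean-squared-error metric,
    centered multi-resolution search, translation-dominant scaling).

    Returns the transform and the resampled moving image.  Identical inputs
    short-circuit to the identity; a failed or implausibly rotated solution
    falls back to the identity with ``converged=False``.
    """
    if moving.shape != fixed.shape:
        raise GridMismatchError(f"moving {moving.shape} vs fixed {fixed.shape}")
    if moving.spacing != fixed.spacing:
        raise GridMismatchError("rigid_register requires equal voxel spacing")
    if np.array_equal(moving.data, fixed.data):
        return RigidTransform.identity(moving.shape), ImageVolume(moving.data.copy(), moving.spacing)

    import SimpleITK as sitk

    fixed_itk = sitk.GetImageFromArray(fixed.data)
    moving_itk = sitk.GetImageFromArray(moving.data)
    try:
        initial = sitk.CenteredTransformInitializer(
            fixed_itk, moving_itk, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-3, numberOfIterations=100, relaxationFactor=0.5)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([2, 1])
        reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(initial, inPlace=False)
        result = reg.Execute(fixed_itk, moving_itk)
    except RuntimeError:
        return RigidTransform.identity(moving.shape, converged=False), \
            ImageVolume(moving.data.copy(), moving.spacing)

    euler = sitk.Euler3DTransform(sitk.CompositeTransform(result).GetNthTransform(0))
    r_xyz = np.asarray(euler.GetMatrix()).reshape(3, 3)
    t_xyz = np.asarray(euler.GetTranslation())
    c_xyz = np.asarray(euler.GetCenter())
    # sitk works in xyz physical coords; our grids are zyx with unit spacing
    tf = RigidTransform(r_xyz[::-1, ::-1], t_xyz[::-1], c_xyz[::-1])
    if tf.rotation_angle > ROTATION_BOUND:
        return RigidTransform.identity(moving.shape, converged=False), \
            ImageVolume(moving.data.copy(), moving.spacing)
    return tf, tf.apply_to_image(moving)


# -- input assembly -----------------------------------------------------

def encode_structures(ss: StructureSet, shape=None) -> np.ndarray:
    """All structures in one channel: structure k of K encodes as k/K.

    Background is 0; later structures overwrite earlier ones where masks
    would overlap (phantom organs never do).
    """
    if len(ss) == 0:
        if shape is None:
            raise ValueError("cannot encode an empty StructureSet without a shape")
        return np.zeros(shape)
    out = np.zeros(ss.shape)
    K = len(ss)
    for k, name in enumerate(ss.names, start=1):
        out[ss[name] > 0] = k / K
    return out


def assemble_input(prior_image: ImageVolume, prior_contours: StructureSet,
                   current_image: ImageVolume) -> np.ndarray:
    """3-channel stack: (prior image, encoded prior contours, current image)."""
    if prior_image.shape != current_image.shape:
        raise GridMismatchError(
            f"prior {prior_image.shape} vs current {current_image.shape}")
    if prior_contours.shape is not None and prior_contours.shape != prior_image.shape:
        raise GridMismatchError(
            f"prior contours {prior_contours.shape} vs prior image {prior_image.shape}")
    label = encode_structures(prior_contours, shape=prior_image.shape)
    return np.stack([prior_image.data, label, current_image.data])


def assemble_dir_input(current_image: ImageVolume, dir_contours: StructureSet) -> np.ndarray:
    """DIR variant: the current image fills both image channels so it stays
    consistent with the deformably-registered contours on the current grid."""
    if dir_contours.shape is not None and dir_contours.shape != current_image.shape:
        raise GridMismatchError(
            f"dir contours {dir_contours.shape} vs current image {current_image.shape}")
    label = encode_structures(dir_contours, shape=current_image.shape)
    return np.stack([current_image.data, label, current_image.data])


def contour_prior_baseline(prior_contours: StructureSet,
                           transform: RigidTransform) -> StructureSet:
    """No-learning baseline: the prior contours, rigidly resampled."""
    return transform.apply_to_structures(prior_contours)


def simulated_dir_contours(series: PatientSeries, error_amplitude: float = 0.0,
                           error_smoothness: float = 3.0, seed: int = 0) -> list[StructureSet]:
    """A DIR oracle from the simulator: per-fraction ground-truth contours,
    optionally corrupted by a smooth random field of the given amplitude
    (voxels) to emulate imperfect deformable registration."""
    out = []
    sub = np.random.SeedSequence(seed).spawn(series.n_fractions)
    for frac, ss in zip(series.fractions, sub):
        cts = frac.contours
        if error_amplitude > 0:
            err = make_smooth_dvf(frac.image.shape, error_amplitude, error_smoothness,
                                  seed=int(ss.generate_state(1)[0] % (2 ** 31)))
            cts = warp_structures(cts, err)
        out.append(cts)
    return out


# -- course inference ---------------------------------------------------

@dataclasses.dataclass
class FractionPrediction:
    index: int
    contours: StructureSet
    probabilities: np.ndarray
    prior_source: str
    memory_snapshot: list | None = None


@dataclasses.dataclass
class CoursePrediction:
    patient_id: str
    structure_names: list[str]
    records: list[FractionPrediction]
    initial_memory: list | None = None

    def __post_init__(self):
        indices = [r.index for r in self.records]
        if indices != sorted(indices):
            raise ValueError("prediction records must be chronological")

    @property
    def n_fractions(self) -> int:
        return len(self.records)


def _binarize(probs: np.ndarray, names: list[str], threshold: float) -> StructureSet:
    return StructureSet({n: (probs[i] >= threshold).astype(np.uint8)
                         for i, n in enumerate(names)})


def run_course(model: SegmentationUNet, series: PatientSeries,
               prior_mode: str = "revised", dir_contours: list[StructureSet] | None = None,
               register: bool = True, threshold: float = 0.5,
               keep_memory_snapshots: bool = False) -> CoursePrediction:
    """Sequentially predict every fraction of one course.

    The LSTM memory starts at zero, is updated after every fraction, and is
    re-zeroed when the course ends.  Fraction 1 uses the planning image and
    contours as the prior; later fractions use the previous fraction's
    image with ground-truth (revised), predicted (auto) or DIR-oracle (dir)
    contours.  The prior is rigidly registered to the current image before
    assembly unless ``register=False`` (phantom grids are constructed
    aligned, so registration there resolves to near-identity).
    """
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
    if prior_mode == "dir":
        if dir_contours is None or len(dir_contours) != series.n_fractions:
            raise ValueError("dir mode needs one StructureSet per fraction")
    if series.n_fractions < 1:
        raise ValueError("series has no fractions")
    names = series.structure_names
    if model.config.out_channels != len(names):
        raise ValueError(
            f"model predicts {model.config.out_channels} structures, series has {len(names)}")

    spatial = series.planning_image.shape
    memory = model.init_memory(spatial) if model.has_lstm else None
    model.memory = memory
    initial_memory = model.detach_memory(memory) if memory is not None else None

    records: list[FractionPrediction] = []
    prior_img, prior_cts = series.planning_image, series.planning_contours
    prior_source = "planning"
    for k, frac in enumerate(series.fractions):
        if model.config.in_channels == 1:  # direct-segmentation baseline: no prior
            x = frac.image.data[None]
            source = "none"
        elif prior_mode == "dir":
            x = assemble_dir_input(frac.image, dir_contours[k])
            source = "dir_deformed"
        else:
            p_img, p_cts = prior_img, prior_cts
            if register:
                tf, p_img = rigid_register(prior_img, frac.image)
                p_cts = contour_prior_baseline(prior_cts, tf)
            x = assemble_input(p_img, p_cts, frac.image)
            source = prior_source
        probs, memory = model.predict(x, memory)
        pred = _binarize(probs, names, threshold)
        records.append(FractionPrediction(
            index=frac.index, contours=pred, probabilities=probs, prior_source=source,
            memory_snapshot=(model.detach_memory(memory)
                             if (keep_memory_snapshots and memory is not None) else None)))
        prior_img = frac.image
        prior_cts = frac.contours if prior_mode == "revised" else pred
        prior_source = "previous_fraction"
        model.memory = memory
    model.memory = model.init_memory(spatial) if model.has_lstm else None
    return CoursePrediction(series.patient_id, names, records, initial_memory)


def run_contour_prior_course(series: PatientSeries, register: bool = True) -> CoursePrediction:
    """The Contour-prior baseline over a whole course: each fraction's
    prediction is the previous fraction's ground-truth contours, rigidly
    registered to the current image (the planning contours for fraction 1)."""
    records = []
    prior_img, prior_cts = series.planning_image, series.planning_contours
    source = "planning"
    for frac in series.fractions:
        if register:
            tf, _ = rigid_register(prior_img, frac.image)
        else:
            tf = RigidTransform.identity(frac.image.shape)
        pred = contour_prior_baseline(prior_cts, tf)
        probs = np.stack([pred[n].astype(np.float64) for n in series.structure_names])
        records.append(FractionPrediction(frac.index, pred, probs, source))
        prior_img, prior_cts = frac.image, frac.contours
        source = "previous_fraction"
    return CoursePrediction(series.patient_id, series.structure_names, records)
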