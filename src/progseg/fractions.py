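"""Simulated multi-fraction treatment courses.

Pre-training data are produced by interpolating a single displacement
field: scaling one DVF by s in [-1, -0.5, 0, 0.5, 1] and applying each
scaled field to a base image and its contours yields five plausible
"fractions" of gradually changing anatomy.  The negated field is a literal
negation of the vectors, not a true inverse deformation; the small
discrepancy with true inversion is accepted as part of the method.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .grids import (
    DisplacementField,
    GridMismatchError,
    ImageVolume,
    StructureSet,
    load_dvf,
    load_image,
    load_mask,
    save_dvf,
    save_image,
    save_mask,
)
from .phantom import PhantomConfig, make_phantom, make_smooth_dvf, warp_image, warp_structures

DEFAULT_SCALES = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclasses.dataclass
class FractionRecord:
    """One treatment fraction: an image and its (ground-truth) contours."""

    index: int
    image: ImageVolume
    contours: StructureSet
    provenance: str = "simulated"

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("fraction index must be >= 1")
        if self.contours.shape is not None and self.image.shape != self.contours.shape:
            raise GridMismatchError(
                f"fraction {self.index}: image {self.image.shape} vs contours {self.contours.shape}")
        if self.provenance not in ("simulated", "clinical-like"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclasses.dataclass
class PatientSeries:
    """Planning image + contours followed by chronologically ordered fractions."""

    patient_id: str
    planning_image: ImageVolume
    planning_contours: StructureSet
    fractions: list[FractionRecord]

    def __post_init__(self):
        indices = [f.index for f in self.fractions]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError(f"fraction indices must be strictly increasing, got {indices}")
        shapes = {self.planning_image.shape} | {f.image.shape for f in self.fractions}
        if len(shapes) > 1:
            raise GridMismatchError(f"grids differ within series: {shapes}")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def structure_names(self) -> list[str]:
        return self.planning_contours.names

    def truncated(self, k: int) -> "PatientSeries":
        """The same series restricted to its first ``k`` fractions."""
        return PatientSeries(self.patient_id, self.planning_image,
                             self.planning_contours, self.fractions[:k])


def scale_dvf(dvf: DisplacementField, s: float) -> DisplacementField:
    """Multiply every displacement vector by the scalar ``s``."""
    if not np.isfinite(s):
        raise ValueError("scale must be finite")
    return DisplacementField(dvf.vectors * float(s))


def simulate_fractions(
    base_image: ImageVolume,
    base_contours: StructureSet,
    dvf: DisplacementField,
    scales=DEFAULT_SCALES,
    patient_id: str = "sim",
) -> PatientSeries:
    """Expand one image+contours into a multi-fraction series.

    One fraction per scale, in list order; images are warped with trilinear
    interpolation and contours with nearest-neighbour by the scaled field.
    The s=0 fraction reproduces the base image and contours exactly.  The
    planning record of the returned series is the undeformed base.
    """
    scales = list(scales)
    if not scales:
        raise ValueError("scale list must be nonempty")
    if base_image.shape != dvf.shape:
        raise GridMismatchError(f"image {base_image.shape} vs DVF {dvf.shape}")
    fractions = []
    for i, s in enumerate(scales, start=1):
        sd = scale_dvf(dvf, s)
        fractions.append(FractionRecord(
            index=i,
            image=warp_image(base_image, sd),
            contours=warp_structures(base_contours, sd),
        ))
    return PatientSeries(patient_id, base_image, base_contours, fractions)


def build_pretrain_cohort(
    n_patients: int,
    phantom_config: PhantomConfig | None = None,
    scales=DEFAULT_SCALES,
    seed: int = 0,
) -> list[PatientSeries]:
    """Independent phantom patients, each expanded into simulated fractions.

    Per-patient phantoms and DVFs use sub-seeds spawned from ``seed`` so the
    cohort is reproducible as a whole and patients are independent.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = phantom_config or PhantomConfig()
    sub = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = []
    for i, ss in enumerate(sub):
        s1, s2 = ss.generate_state(2) % (2 ** 31)
        cfg = dataclasses.replace(base, seed=int(s1))
        img, contours = make_phantom(cfg)
        dvf = make_smooth_dvf(cfg.shape, cfg.dvf_amplitude, cfg.dvf_smoothness, seed=int(s2))
        cohort.append(simulate_fractions(img, contours, dvf, scales,
                                         patient_id=f"phantom_{i + 1:03d}"))
    return cohort


# -- on-disk layout -----------------------------------------------------

def save_series(series: PatientSeries, root: str | Path) -> None:
    """Write ``patient_<id>/fx_<k>/{image.nii.gz, <structure>.nii.gz}`` plus
    a JSON manifest recording order, structures and provenance."""
    root = Path(root)
    pdir = root / f"patient_{series.patient_id}"
    plan = pdir / "planning"
    plan.mkdir(parents=True, exist_ok=True)
    sp = series.planning_image.spacing
    save_image(series.planning_image, plan / "image.nii.gz")
    for name, m in series.planning_contours.masks.items():
        save_mask(m, plan / f"{name}.nii.gz", sp)
    for f in series.fractions:
        fdir = pdir / f"fx_{f.index}"
        fdir.mkdir(parents=True, exist_ok=True)
        save_image(f.image, fdir / "image.nii.gz")
        for name, m in f.contours.masks.items():
            save_mask(m, fdir / f"{name}.nii.gz", sp)
    manifest = {
        "patient_id": series.patient_id,
        "structures": series.structure_names,
        "fractions": [{"index": f.index, "provenance": f.provenance} for f in series.fractions],
    }
    (pdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_series(pdir: str | Path) -> PatientSeries:
    pdir = Path(pdir)
    manifest = json.loads((pdir / "manifest.json").read_text())
    names = manifest["structures"]

    def read_record(d: Path):
        img = load_image(d / "image.nii.gz")
        contours = StructureSet({n: load_mask(d / f"{n}.nii.gz") for n in names})
        return img, contours

    pimg, pcts = read_record(pdir / "planning")
    fractions = []
    for entry in manifest["fractions"]:
        img, cts = read_record(pdir / f"fx_{entry['index']}")
        fractions.append(FractionRecord(entry["index"], img, cts, entry["provenance"]))
    return PatientSeries(manifest["patient_id"], pimg, pcts, fractions)


def load_cohort(root: str | Path) -> list[PatientSeries]:
    root = Path(root)
    return [load_series(p) for p in sorted(root.glob("patient_*"))]
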