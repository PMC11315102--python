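"""Segmentation evaluation: Dice, Hausdorff distances, summaries, t-test.

Conventions: two empty masks agree perfectly (DSC 1.0); exactly one empty
mask scores 0.  Surface distances are computed between boundary voxels of
the binary masks (no sub-voxel meshing), converted to mm via the voxel
spacing; HD is the symmetric maximum and HD95 the 95th percentile of the
pooled directed nearest-surface distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .fractions import PatientSeries
from .runtime import CoursePrediction


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|) for binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


class EmptyMaskError(ValueError):
    """Surface distance is undefined for an empty mask."""


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical (mm) coordinates of boundary voxels (face connectivity)."""
    mask = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    boundary = mask & ~interior
    coords = np.argwhere(boundary)
    return coords * np.asarray(spacing, dtype=np.float64)


def hausdorff_distance(a: np.ndarray, b: np.ndarray,
                       spacing=(1.0, 1.0, 1.0)) -> tuple[float, float]:
    """Symmetric (HD, HD95) in mm between the boundaries of two masks."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise EmptyMaskError("Hausdorff distance undefined for empty mask")
    pa = _boundary_coords(a, spacing)
    pb = _boundary_coords(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.max()), float(np.percentile(pooled, 95))


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test (n-1 degrees of freedom).

    Raises on degenerate input (all differences identical), where the
    statistic is undefined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t_test needs two equal-length 1D arrays")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# -- report assembly ----------------------------------------------------

ATOM_COLUMNS = ["patient", "fraction", "structure", "dsc", "hd_mm", "hd95_mm"]


def evaluate_course(pred: CoursePrediction, series: PatientSeries,
                    with_hausdorff: bool = True) -> pd.DataFrame:
    """Per (fraction, structure) metric atoms for one predicted course."""
    spacing = series.planning_image.spacing
    rows = []
    for rec in pred.records:
        truth = next(f for f in series.fractions if f.index == rec.index).contours
        for name in pred.structure_names:
            p, g = rec.contours[name], truth[name]
            row = {"patient": series.patient_id, "fraction": rec.index,
                   "structure": name, "dsc": dice_coefficient(p, g),
                   "hd_mm": np.nan, "hd95_mm": np.nan}
            if with_hausdorff and p.any() and g.any():
                row["hd_mm"], row["hd95_mm"] = hausdorff_distance(p, g, spacing)
            rows.append(row)
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def summarize(atoms: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate metric atoms.

    Returns ``per_structure`` (mean +- sd over all patient/fraction pairs,
    the layout of a results table), ``per_fraction`` (mean DSC per fraction
    across patients, the fraction-Dice curve) and ``overall`` (the flat
    mean over the concatenated structure atoms).
    """
    if atoms.empty:
        raise ValueError("no metric atoms to summarize")
    per_structure = (atoms.groupby("structure", sort=False)
                     .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", lambda s: s.std(ddof=0)),
                          hd_mean=("hd_mm", "mean"), hd95_mean=("hd95_mm", "mean"),
                          n=("dsc", "size"))
                     .reset_index())
    per_fraction = (atoms.groupby("fraction", sort=True)
                    .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", lambda s: s.std(ddof=0)))
                    .reset_index())
    overall = pd.DataFrame({"dsc_mean": [atoms["dsc"].mean()],
                            "dsc_sd": [atoms["dsc"].std(ddof=0)],
                            "n": [len(atoms)]})
    return {"per_structure": per_structure, "per_fraction": per_fraction, "overall": overall}


def paired_structure_test(atoms_a: pd.DataFrame, atoms_b: pd.DataFrame) -> tuple[float, float]:
    """Paired t-test on the concatenated per-structure DSC atoms of two
    models evaluated on the same (patient, fraction, structure) triples."""
    key = ["patient", "fraction", "structure"]
    merged = atoms_a.merge(atoms_b, on=key, suffixes=("_a", "_b"))
    if len(merged) != len(atoms_a) or len(merged) != len(atoms_b):
        raise ValueError("metric atoms do not cover the same evaluation triples")
    return paired_t_test(merged["dsc_a"].to_numpy(), merged["dsc_b"].to_numpy())


def plot_fraction_dice(curves: dict[str, pd.DataFrame], path) -> None:
    """Fraction-Dice curves (one line per model) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in curves.items():
        ax.plot(df["fraction"], df["dsc_mean"], marker="o", label=label)
    ax.set_xlabel("Fraction")
    ax.set_ylabel("Mean DSC")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
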