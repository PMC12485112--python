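"""Per-cell quantification of LNP uptake from multi-channel FOVs.

Per field of view: segment nuclei (for the per-cell normalizer), threshold
the membrane (or lysosome) channel into a binary mask, sum the Cy5 (LNP)
signal inside the mask and normalize by the nuclei count.  The erosion
analysis splits the cell mask into an inner region (n-fold morphological
erosion, n = 10 by default, full 3x3 structuring element) and the outer rim
(exclusive disjunction of mask and inner), attributing Cy5 signal to the
cell surface vs interior.  Lysosomal co-localization is the Cy5 signal
inside the lysosome mask per nucleus.  Three FOVs average to one technical
replicate; technical replicates average to one biological replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "segment_nuclei",
    "make_mask",
    "quantify_uptake",
    "erosion_partition",
    "outer_signal_fraction",
    "lysosome_colocalization",
    "FovMeasurement",
    "measure_fov",
    "aggregate_replicates",
]


def segment_nuclei(
    nuclei_channel: np.ndarray, min_area_px: int = 50
) -> tuple[np.ndarray, int]:
    """Threshold (Otsu) + 8-connected labeling of the nuclei channel.

    Components smaller than ``min_area_px`` are removed.  Returns the label
    image (0 = background) and the surviving nucleus count.
    """
    img = np.asarray(nuclei_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty nuclei channel")
    if np.ptp(img) == 0:
        warnings.warn("uniform nuclei channel: 0 nuclei detected", stacklevel=2)
        return np.zeros(img.shape, dtype=int), 0
    mask = img >= threshold_otsu(img)
    labels = sk_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    if small.size:
        labels[np.isin(labels, small)] = 0
    surviving = np.unique(labels)
    surviving = surviving[surviving > 0]
    relabeled = np.zeros_like(labels)
    for new, old in enumerate(surviving, start=1):
        relabeled[labels == old] = new
    return relabeled, int(surviving.size)


def make_mask(channel: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binary mask of a channel: pixels >= threshold are mask members.

    ``method`` is "otsu" (global Otsu threshold, applied uniformly) or
    "fixed" (explicit ``threshold``).  A constant channel cannot be Otsu
    thresholded.
    """
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty channel")
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("constant channel: Otsu undefined, use a fixed threshold")
        t = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        t = float(threshold)
    else:
        raise ValueError(f"unknown method: {method}")
    return img >= t


def quantify_uptake(cy5: np.ndarray, membrane_mask: np.ndarray, nuclei_count: int) -> float:
    """Summed Cy5 signal inside the membrane mask, normalized per nucleus."""
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1 (FOVs without nuclei are excluded)")
    return float(np.asarray(cy5, dtype=float)[np.asarray(membrane_mask, bool)].sum()) / nuclei_count


def erosion_partition(
    membrane_mask: np.ndarray, n: int = 10, structuring_element: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split a cell mask into inner (n-fold erosion) and outer rim (XOR).

    The structuring element defaults to the full 3x3 square (8-connectivity),
    so each iteration trims one pixel in the Chebyshev metric.  Full erosion
    to an empty inner mask is valid: the outer rim is then the whole mask.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = np.asarray(membrane_mask, dtype=bool)
    se = np.ones((3, 3), bool) if structuring_element is None else structuring_element
    inner = ndimage.binary_erosion(mask, structure=se, iterations=n)
    outer = mask ^ inner
    return inner, outer


def outer_signal_fraction(
    cy5: np.ndarray, membrane_mask: np.ndarray, outer_mask: np.ndarray
) -> float:
    """Fraction of in-mask Cy5 signal located in the outer rim."""
    cy5 = np.asarray(cy5, dtype=float)
    total = float(cy5[np.asarray(membrane_mask, bool)].sum())
    if total <= 0:
        raise ValueError("no Cy5 signal inside the membrane mask; FOV excluded")
    outer = float(cy5[np.asarray(outer_mask, bool)].sum())
    return outer / total


def lysosome_colocalization(
    cy5: np.ndarray, lysosome_mask: np.ndarray, nuclei_count: int
) -> float:
    """Summed Cy5 signal inside the lysosome mask, normalized per nucleus."""
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1 (FOVs without nuclei are excluded)")
    return float(np.asarray(cy5, dtype=float)[np.asarray(lysosome_mask, bool)].sum()) / nuclei_count


@dataclass
class FovMeasurement:
    """Per-FOV quantification results (undefined FOVs are never constructed)."""

    condition: str
    biological_replicate: str
    technical_replicate: str
    fov_index: int
    nuclei_count: int
    cy5_per_cell: float
    outer_fraction: float | None = None
    lyso_coloc_per_cell: float | None = None


def measure_fov(
    fov,
    erosion_n: int = 10,
    nuclei_min_area_px: int = 50,
    mask_method: str = "otsu",
    mask_threshold: float | None = None,
    lysosome_channel: str | None = None,
) -> FovMeasurement | None:
    """Run the full per-FOV quantification on an :class:`ImageFOV`-like object.

    Returns ``None`` (with a warning) when the FOV must be excluded: zero
    nuclei or zero in-mask Cy5 signal.  When ``lysosome_channel`` is given,
    lysosomal co-localization is quantified from that channel's Otsu/fixed
    mask; otherwise the erosion partition of the membrane mask is measured.
    """
    _, count = segment_nuclei(fov.channels["nuclei"], min_area_px=nuclei_min_area_px)
    if count == 0:
        warnings.warn(f"FOV {fov.fov_index}: no nuclei; excluded", stacklevel=2)
        return None
    cy5 = fov.channels["cy5"]
    membrane_mask = make_mask(
        fov.channels["membrane"], method=mask_method, threshold=mask_threshold
    )
    if float(np.asarray(cy5)[membrane_mask].sum()) <= 0:
        warnings.warn(f"FOV {fov.fov_index}: no in-mask Cy5 signal; excluded", stacklevel=2)
        return None
    meas = FovMeasurement(
        condition=fov.condition,
        biological_replicate=fov.biological_replicate,
        technical_replicate=fov.technical_replicate,
        fov_index=fov.fov_index,
        nuclei_count=count,
        cy5_per_cell=quantify_uptake(cy5, membrane_mask, count),
    )
    if lysosome_channel is not None:
        lyso_mask = make_mask(
            fov.channels[lysosome_channel], method=mask_method, threshold=mask_threshold
        )
        meas.lyso_coloc_per_cell = lysosome_colocalization(cy5, lyso_mask, count)
    else:
        _, outer = erosion_partition(membrane_mask, n=erosion_n)
        meas.outer_fraction = outer_signal_fraction(cy5, membrane_mask, outer)
    return meas


def aggregate_replicates(measurements: list[FovMeasurement]) -> pd.DataFrame:
    """Mean-aggregate FOVs to technical replicates and those to biological.

    Returns a tidy table with one row per (condition, biological replicate,
    technical replicate) plus the biological-replicate means, both levels
    retained for nested statistics: columns condition, biological_replicate,
    technical_replicate, cy5_per_cell, outer_fraction, lyso_coloc_per_cell,
    and boolean ``is_bio_mean`` marking the aggregated biological rows.
    """
    if not measurements:
        raise ValueError("no retained FOV measurements to aggregate")
    df = pd.DataFrame(
        [
            {
                "condition": m.condition,
                "biological_replicate": m.biological_replicate,
                "technical_replicate": m.technical_replicate,
                "cy5_per_cell": m.cy5_per_cell,
                "outer_fraction": m.outer_fraction,
                "lyso_coloc_per_cell": m.lyso_coloc_per_cell,
            }
            for m in measurements
        ]
    )
    for col in ("cy5_per_cell", "outer_fraction", "lyso_coloc_per_cell"):
        df[col] = pd.to_numeric(df[col])  # None -> NaN, keep column numeric
    tech = (
        df.groupby(["condition", "biological_replicate", "technical_replicate"], sort=False)
        .mean(numeric_only=True)
        .reset_index()
    )
    tech["is_bio_mean"] = False
    bio = (
        tech.groupby(["condition", "biological_replicate"], sort=False)
        .mean(numeric_only=True)
        .reset_index()
    )
    bio["technical_replicate"] = "__bio_mean__"
    bio["is_bio_mean"] = True
    return pd.concat([tech, bio], ignore_index=True)[
        [
            "condition",
            "biological_replicate",
            "technical_replicate",
            "cy5_per_cell",
            "outer_fraction",
            "lyso_coloc_per_cell",
            "is_bio_mean",
        ]
    ]
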