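"""Morphology inference: class-wise deformation behavior inside the ROIs.

Once the discriminative regions are fixed, the question becomes *what*
the classes do differently there. Per region we report, at an exemplar
pixel (the member pixel nearest the region centroid): each class's mean
displacement vector, each class's principal displacement direction
(first PC of the 2D displacements, sign-aligned with the class mean),
and the angular separation between the class directions. A pooled PCA
over the stacked ROI displacement vectors of all subjects summarizes
how concentrated the deformation variability is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .registration import DeformationField
from .roi_refinement import Region


@dataclass
class ClassMorphology:
    mean_vector: tuple[float, float]
    principal_direction: tuple[float, float] | None
    direction_defined: bool


@dataclass
class RegionMorphology:
    exemplar: tuple[int, int]
    per_class: dict[str, ClassMorphology]
    angular_separation_deg: float | None


@dataclass
class MorphologySummary:
    regions: list[RegionMorphology]
    explained_variance_ratio: np.ndarray  # pooled PCA over all ROI vectors

    def to_dict(self) -> dict:
        return {
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio],
            "regions": [
                {
                    "exemplar": list(rm.exemplar),
                    "angular_separation_deg": rm.angular_separation_deg,
                    "classes": {
                        name: {
                            "mean_vector": list(cm.mean_vector),
                            "principal_direction": (
                                list(cm.principal_direction) if cm.principal_direction else None
                            ),
                            "direction_defined": cm.direction_defined,
                        }
                        for name, cm in rm.per_class.items()
                    },
                }
                for rm in self.regions
            ],
        }


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------


def exemplar_pixel(region: Region) -> tuple[int, int]:
    """Member pixel nearest the region's coordinate centroid (ties: raster)."""
    px = region.sorted_pixels
    centroid = np.mean(np.asarray(px, dtype=float), axis=0)
    d2 = [(r - centroid[0]) ** 2 + (c - centroid[1]) ** 2 for r, c in px]
    return px[int(np.argmin(d2))]  # argmin takes the first (raster) minimum


def collect_roi_vectors(
    regions: list[Region],
    fields: dict[str, DeformationField],
    subject_ids: list[str],
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Stack each subject's (drow, dcol) over all region pixels.

    Returns the subjects x (2 * total pixels) matrix and the pixel
    ordering as (region_index, row, col) triples — region index first,
    then raster within each region, identically for every subject.
    """
    order = [(i, r, c) for i, rg in enumerate(regions) for r, c in rg.sorted_pixels]
    vectors = np.empty((len(subject_ids), 2 * len(order)))
    for si, sid in enumerate(subject_ids):
        if sid not in fields:
            raise KeyError(f"no deformation field for subject {sid}")
        d = fields[sid].d
        for pi, (_, r, c) in enumerate(order):
            vectors[si, 2 * pi : 2 * pi + 2] = d[r, c]
    return vectors, order


def pooled_pca(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA over mean-centered subject vectors.

    Returns orthonormal components and explained-variance ratios
    (nonnegative, nonincreasing, summing to 1; trailing ratios are 0
    for rank-deficient input).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 3:
        raise ValueError("pooled PCA needs at least 3 subjects")
    pca = PCA()
    pca.fit(vectors)
    return pca.components_, pca.explained_variance_ratio_


def angular_separation(v1, v2) -> float:
    """Angle between two 2-vectors in degrees, in [0, 180]."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angular separation undefined for zero vectors")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def class_morphology(
    vectors: np.ndarray,
    order: list[tuple[int, int, int]],
    labels: np.ndarray,
    exemplar: tuple[int, int],
    class_names: tuple[str, str] = ("control", "disease"),
) -> dict[str, ClassMorphology]:
    """Per-class mean displacement and principal direction at a pixel.

    The principal direction is the first PC of that class's 2D
    displacements at the exemplar pixel, sign-aligned with the class
    mean (nonnegative dot product). A single-subject class gets its
    mean but an undefined direction.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    try:
        pi = next(i for i, (_, r, c) in enumerate(order) if (r, c) == tuple(exemplar))
    except StopIteration:
        raise ValueError(f"exemplar {exemplar} not among region pixels") from None
    xy = vectors[:, 2 * pi : 2 * pi + 2]

    out: dict[str, ClassMorphology] = {}
    for code, name in enumerate(class_names):
        sub = xy[labels == code]
        mean = sub.mean(axis=0)
        if sub.shape[0] < 2:
            out[name] = ClassMorphology(tuple(map(float, mean)), None, False)
            continue
        # first right-singular vector of the raw (uncentered) 2D cloud:
        # the direction most deformations can be measured against,
        # carrying the class's systematic displacement, not just its spread
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        direction = vt[0]
        if np.dot(direction, mean) < 0:
            direction = -direction
        out[name] = ClassMorphology(
            tuple(map(float, mean)), tuple(map(float, direction)), True
        )
    return out


def summarize_morphology(
    regions: list[Region],
    fields: dict[str, DeformationField],
    subject_ids: list[str],
    labels: np.ndarray,
    class_names: tuple[str, str] = ("control", "disease"),
) -> MorphologySummary:
    """Full morphology report over a final region set."""
    vectors, order = collect_roi_vectors(regions, fields, subject_ids)
    _, evr = pooled_pca(vectors)
    region_reports = []
    for i, rg in enumerate(regions):
        ex = exemplar_pixel(rg)
        per_class = class_morphology(vectors, order, labels, ex, class_names)
        dirs = [cm.principal_direction for cm in per_class.values() if cm.direction_defined]
        sep = angular_separation(dirs[0], dirs[1]) if len(dirs) == 2 else None
        region_reports.append(RegionMorphology(ex, per_class, sep))
    return MorphologySummary(regions=region_reports, explained_variance_ratio=evr)
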