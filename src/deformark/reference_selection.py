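"""Reference-subject selection by PCA of landmark configurations.

From the control group's seven-landmark configurations, select the
subject whose shape is most representative of the group average: each
configuration is centered on its landmark 1 (translation removal only,
matching the later rigid step which also centers on landmark 1), PCA is
run on the flattened 14-D configuration matrix, and the subject nearest
the group mean in the subspace of components explaining at least 95% of
the variance (the medoid in PC space) becomes the reference. An
optional full Procrustes mode (rotation + scale removal) is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

N_LANDMARKS = 7


@dataclass(frozen=True)
class LandmarkSet:
    """Seven ordered (row, col) landmark positions for one subject.

    Landmark 1 is the centering/rotation point (the center of the
    intra-thalamic adhesion in the anatomical convention this layout
    follows).
    """

    subject_id: str
    points: np.ndarray  # (7, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"subject {self.subject_id}: expected {N_LANDMARKS} (row, col) points, "
                f"got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"subject {self.subject_id}: landmarks must be finite")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class ReferenceChoice:
    subject_id: str
    pc_scores: dict[str, np.ndarray]
    distance_to_mean: dict[str, float]
    explained_variance_ratio: np.ndarray
    n_components_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if evr.size and (np.any(evr < -1e-12) or np.any(np.diff(evr) > 1e-12)):
            raise ValueError("explained variance ratios must be nonnegative and nonincreasing")


def landmark_matrix(sets: list[LandmarkSet], procrustes: bool = False) -> np.ndarray:
    """Stack configurations into a subjects x 14 matrix.

    Each configuration is translated so its landmark 1 sits at the
    origin, then flattened row-major as (row1, col1, ..., row7, col7).
    With ``procrustes=True`` the configurations are additionally
    rescaled to unit centroid size and rotated to best match the first
    subject (full generalized alignment is out of scope; pairwise
    alignment to the first configuration suffices for medoid picking).
    """
    if len(sets) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(sets)}")
    rows = []
    for s in sets:
        pts = s.points - s.points[0]
        rows.append(pts)
    if procrustes:
        ref = rows[0] / (np.linalg.norm(rows[0]) or 1.0)
        aligned = []
        for pts in rows:
            scale = np.linalg.norm(pts)
            p = pts / scale if scale > 0 else pts
            dot = float(np.sum(ref[:, 0] * p[:, 0] + ref[:, 1] * p[:, 1]))
            cross = float(np.sum(p[:, 0] * ref[:, 1] - p[:, 1] * ref[:, 0]))
            phi = np.arctan2(cross, dot) if (dot or cross) else 0.0
            c, sn = np.cos(phi), np.sin(phi)
            R = np.array([[c, -sn], [sn, c]])
            aligned.append(p @ R.T)
        rows = aligned
    return np.stack([p.reshape(-1) for p in rows])


def select_reference(
    sets: list[LandmarkSet],
    variance_threshold: float = 0.95,
    procrustes: bool = False,
) -> ReferenceChoice:
    """Pick the medoid subject in landmark-PCA score space.

    PCA scores are centered, so the group mean is the origin of score
    space and the medoid is the subject with the smallest score norm
    over the leading components that explain at least
    ``variance_threshold`` of the variance. Ties break by lexicographic
    subject id. A degenerate (all-identical) configuration matrix
    returns the lexicographically first subject with distance 0 and a
    warning flag.
    """
    X = landmark_matrix(sets, procrustes=procrustes)
    ids = [s.subject_id for s in sets]
    if np.allclose(X, X[0], atol=1e-12):
        order = sorted(range(len(ids)), key=lambda i: ids[i])
        return ReferenceChoice(
            subject_id=ids[order[0]],
            pc_scores={sid: np.zeros(1) for sid in ids},
            distance_to_mean={sid: 0.0 for sid in ids},
            explained_variance_ratio=np.array([1.0]),
            n_components_used=0,
            degenerate=True,
        )

    pca = PCA()
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    n_comp = int(np.searchsorted(np.cumsum(evr), variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, scores.shape[1])

    dist = np.linalg.norm(scores[:, :n_comp], axis=1)
    best = min(range(len(ids)), key=lambda i: (dist[i], ids[i]))
    return ReferenceChoice(
        subject_id=ids[best],
        pc_scores={sid: scores[i] for i, sid in enumerate(ids)},
        distance_to_mean={sid: float(dist[i]) for i, sid in enumerate(ids)},
        explained_variance_ratio=evr,
        n_components_used=n_comp,
    )


def choice_to_dict(choice: ReferenceChoice) -> dict:
    return {
        "subject_id": choice.subject_id,
        "distance_to_mean": choice.distance_to_mean,
        "explained_variance_ratio": list(map(float, choice.explained_variance_ratio)),
        "n_components_used": choice.n_components_used,
        "degenerate": choice.degenerate,
    }
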