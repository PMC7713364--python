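"""Cristae/matrix compartment segmentation.

Below ~35 nm resolution the outer membrane, inner membrane and
intermembrane space cannot be told apart, so segmentation targets two
classes: the merged membrane compartment ("cristae") and the enclosed
matrix.  The procedure is a trainable per-voxel classifier — a random
forest over a fixed bank of intensity, smoothing, edge and texture
features, seeded from sparse manual-style annotations — followed by a
watershed on the distance transform of the binary cristae image, which
separates the cristae shell from the interior cavities it encloses
(the matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.ensemble import RandomForestClassifier

from .grid import Units, VoxelGrid3D
from .io import RunConfig

CRISTAE, MATRIX = 1, 2  # seed-volume class codes (0 = unlabeled)


class TrainingError(RuntimeError):
    """Seed annotations are unusable (missing class or too few voxels)."""


class FeatureConfigError(RuntimeError):
    """Classifier was trained with a different feature configuration."""


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

def feature_stack(data: np.ndarray, sigmas: tuple[float, ...]) -> np.ndarray:
    """Per-voxel feature bank, shape (n_features, *volume shape).

    Raw intensity; Gaussian smoothings at each sigma (voxels); gradient
    magnitude and Laplacian at the smallest sigma; local variance in a
    3³ window.  Mirrors the grey-level/edge/texture banks of trainable
    pixel-classification tools.
    """
    data = np.asarray(data, dtype=np.float32)
    s0 = min(sigmas)
    feats = [data]
    feats += [ndimage.gaussian_filter(data, s) for s in sigmas]
    feats.append(ndimage.gaussian_gradient_magnitude(data, s0))
    feats.append(ndimage.gaussian_laplace(data, s0))
    mean = ndimage.uniform_filter(data, 3)
    feats.append(ndimage.uniform_filter(data**2, 3) - mean**2)
    return np.stack(feats)


def feature_names(sigmas: tuple[float, ...]) -> list[str]:
    return (
        ["raw"]
        + [f"gauss_{s:g}" for s in sigmas]
        + [f"gradmag_{min(sigmas):g}", f"laplace_{min(sigmas):g}", "var_3"]
    )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class PixelClassifier:
    """A trained two-class voxel classifier with its provenance."""

    model: RandomForestClassifier
    sigmas: tuple[float, ...]
    seed: int
    n_training_voxels: int

    @property
    def feature_signature(self) -> tuple:
        return ("v1", self.sigmas)


def train_pixel_classifier(
    volume: VoxelGrid3D,
    seeds: np.ndarray,
    cfg: RunConfig,
    n_min: int = 50,
) -> PixelClassifier:
    """Train the cristae/matrix voxel classifier from sparse annotations.

    ``seeds`` is a full-grid integer volume: 0 = unlabeled, 1 = cristae,
    2 = matrix, emulating manually selected input voxels.  Each class
    must contribute at least ``n_min`` voxels.  Deterministic given
    ``cfg.seed``.
    """
    seeds = np.asarray(seeds)
    if seeds.shape != volume.shape:
        raise ValueError(f"seed shape {seeds.shape} != volume shape {volume.shape}")
    counts = {cls: int((seeds == cls).sum()) for cls in (CRISTAE, MATRIX)}
    missing = [cls for cls, n in counts.items() if n == 0]
    if missing:
        raise TrainingError(f"seeds contain no voxels of class(es) {missing}")
    low = [cls for cls, n in counts.items() if n < n_min]
    if low:
        raise TrainingError(f"classes {low} have fewer than {n_min} seed voxels: {counts}")

    sigmas = tuple(cfg.feature_sigmas)
    feats = feature_stack(volume.data, sigmas)
    idx = seeds > 0
    X = feats[:, idx].T
    y = seeds[idx]
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(
        model=model, sigmas=sigmas, seed=cfg.seed, n_training_voxels=int(idx.sum())
    )


def classify_compartments(
    volume: VoxelGrid3D,
    object_mask: np.ndarray,
    classifier: PixelClassifier,
    sigmas: tuple[float, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel cristae probability and hard labels inside one object.

    Returns ``(prob_cristae, cristae_mask)``; probabilities are zero and
    labels False outside ``object_mask``.  Hard labels use a 0.5
    threshold with no post-hoc morphology, keeping the measurable
    surface honest.
    """
    if sigmas is not None and tuple(sigmas) != classifier.sigmas:
        raise FeatureConfigError(
            f"classifier trained with sigmas {classifier.sigmas}, got {tuple(sigmas)}"
        )
    # features computed on a padded bounding box: cheap, and identical to
    # full-volume features away from the crop border
    margin = int(np.ceil(4 * max(classifier.sigmas))) + 2
    sl = _padded_bbox(object_mask, margin, volume.shape)
    feats = feature_stack(volume.data[sl], classifier.sigmas)
    sub_mask = object_mask[sl]
    X = feats[:, sub_mask].T
    proba = classifier.model.predict_proba(X)
    cristae_col = list(classifier.model.classes_).index(CRISTAE)

    prob = np.zeros(volume.shape, dtype=np.float64)
    sub_prob = np.zeros(sub_mask.shape)
    sub_prob[sub_mask] = proba[:, cristae_col]
    prob[sl] = sub_prob
    hard = prob >= 0.5
    hard &= object_mask
    return prob, hard


def _padded_bbox(mask: np.ndarray, margin: int, shape) -> tuple[slice, ...]:
    objs = ndimage.find_objects(mask.astype(np.int8))
    if not objs or objs[0] is None:
        raise ValueError("empty object mask")
    sl = objs[0]
    return tuple(
        slice(max(s.start - margin, 0), min(s.stop + margin, dim))
        for s, dim in zip(sl, shape)
    )


# ---------------------------------------------------------------------------
# watershed split
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSegmentation:
    """Paired cristae/matrix labels for one object."""

    object_id: int
    cristae_label: np.ndarray  # full-grid boolean
    matrix_label: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def object_mask(self) -> np.ndarray:
        return self.cristae_label | self.matrix_label


_CONN6 = ndimage.generate_binary_structure(3, 1)


def watershed_interior_split(
    cristae_mask: np.ndarray,
    object_mask: np.ndarray,
    object_id: int = 0,
    min_hole_voxels: int = 8,
) -> CompartmentSegmentation:
    """Split the non-cristae space into matrix and exterior by watershed.

    The Euclidean distance transform of the binary non-cristae space is
    flooded from (a) its local maxima inside the object and (b) the
    exterior; basins that the exterior does not claim become matrix,
    everything else in the object is cristae.  Matrix components below
    ``min_hole_voxels`` are treated as speckle and merged back into
    cristae; sub-threshold non-matrix pockets enclosed in matrix are
    filled.  Matrix is finally barred from touching the background so
    the shell stays closed.
    """
    cristae_mask = np.asarray(cristae_mask, dtype=bool)
    object_mask = np.asarray(object_mask, dtype=bool)
    if not cristae_mask.any():
        raise ValueError("empty cristae mask: no shell to split")
    if (cristae_mask & ~object_mask).any():
        raise ValueError("cristae mask extends outside the object mask")

    space = ~cristae_mask
    edt = ndimage.distance_transform_edt(space)

    markers = np.zeros(cristae_mask.shape, dtype=np.int32)
    exterior = space & ~object_mask
    markers[exterior] = 1
    interior = space & object_mask
    if interior.any():
        peaks = peak_local_max(
            edt, labels=interior.astype(np.int32), min_distance=2, exclude_border=False
        )
        for i, (z, y, x) in enumerate(peaks, start=2):
            markers[z, y, x] = i

    ws = watershed(-edt, markers, mask=space)
    matrix = (ws >= 2) & object_mask

    # speckle cleanup
    lab, n = ndimage.label(matrix, structure=_CONN6)
    if n:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_hole_voxels)
        matrix[np.isin(lab, small[small > 0])] = False
    pockets, n = ndimage.label(~matrix & object_mask, structure=_CONN6)
    if n:
        sizes = np.bincount(pockets.ravel())
        for lab_id in range(1, n + 1):
            if sizes[lab_id] < min_hole_voxels:
                region = pockets == lab_id
                if not (region & cristae_mask).any():  # enclosed in matrix
                    matrix[region] = True

    # a closed shell: matrix may not touch the background
    touches_bg = ndimage.binary_dilation(~object_mask, structure=_CONN6)
    matrix &= ~touches_bg

    cristae = object_mask & ~matrix
    return CompartmentSegmentation(
        object_id=object_id,
        cristae_label=cristae,
        matrix_label=matrix,
        provenance={"method": "edt-watershed", "min_hole_voxels": min_hole_voxels},
    )


def segment_object(
    volume: VoxelGrid3D,
    object_mask: np.ndarray,
    classifier: PixelClassifier,
    cfg: RunConfig,
    object_id: int = 0,
) -> CompartmentSegmentation:
    """Classifier + watershed pipeline for one identified object."""
    _, cristae_hard = classify_compartments(volume, object_mask, classifier)
    seg = watershed_interior_split(
        cristae_hard, object_mask, object_id=object_id, min_hole_voxels=cfg.min_hole_voxels
    )
    seg.provenance.update(
        features=feature_names(classifier.sigmas),
        classifier_seed=classifier.seed,
        n_training_voxels=classifier.n_training_voxels,
    )
    return seg


def seeds_from_masks(
    cristae_mask: np.ndarray,
    matrix_mask: np.ndarray,
    fraction: float = 0.02,
    rng: np.random.Generator | int | None = 0,
    erode: int = 1,
) -> np.ndarray:
    """Sparse training seeds sampled from reference masks.

    Emulates an annotator clicking confidently identifiable voxels: each
    mask is eroded by ``erode`` voxels to stay clear of ambiguous
    boundaries, then ``fraction`` of the remaining voxels per class is
    sampled uniformly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = np.zeros(cristae_mask.shape, dtype=np.int8)
    for cls, mask in ((CRISTAE, cristae_mask), (MATRIX, matrix_mask)):
        core = ndimage.binary_erosion(mask, structure=_CONN6, iterations=erode) if erode else mask
        if not core.any():
            core = mask
        idx = np.flatnonzero(core)
        n = max(int(round(fraction * idx.size)), 1)
        chosen = rng.choice(idx, size=min(n, idx.size), replace=False)
        seeds.ravel()[chosen] = cls
    return seeds
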