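"""Shared fixtures: phantoms at the study's imaging conditions.

The "fixture suite" is a noisy two-object phantom degraded by the 35-nm
optic PSF and photon noise, segmented once per session and reused by
the recovery and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from sxtmorph import RunConfig
from sxtmorph.compartments import (
    CompartmentSegmentation,
    seeds_from_masks,
    segment_object,
    train_pixel_classifier,
)
from sxtmorph.identify import identify_objects
from sxtmorph.phantom import PhantomSpec, PhantomTruth, apply_optics, make_phantom

FIXTURE_SEED = 7
FIXTURE_NOISE = 3000.0  # incident photons per 1-µm ray: LAC noise ~0.02 µm^-1


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def noiseless_truth() -> PhantomTruth:
    """Two-object ideal phantom, no optics degradation."""
    spec = PhantomSpec(n_objects=2, shape=(96, 96, 96), noise_scale=0.0, seed=FIXTURE_SEED)
    return make_phantom(spec)


@dataclass
class FixtureSuite:
    truth: PhantomTruth
    lac: object  # degraded VoxelGrid3D
    cfg: RunConfig
    objects: list
    matched_truth: list           # truth objects ordered to match `objects`
    segmentations: list[CompartmentSegmentation]


@pytest.fixture(scope="session")
def fixture_suite() -> FixtureSuite:
    """Degraded phantom (PSF 35 nm, photon noise) segmented end-to-end."""
    spec = PhantomSpec(
        n_objects=2, shape=(96, 96, 96), psf_fwhm=0.035,
        noise_scale=FIXTURE_NOISE, seed=FIXTURE_SEED,
    )
    truth = make_phantom(spec)
    lac = apply_optics(truth.lac_volume, spec.psf_fwhm, spec.noise_scale, seed=spec.seed)
    cfg = RunConfig(seed=FIXTURE_SEED)
    objects = identify_objects(lac, cfg)

    cristae = np.zeros(lac.shape, dtype=bool)
    matrix = np.zeros(lac.shape, dtype=bool)
    for t in truth.objects:
        cristae |= t.cristae_mask
        matrix |= t.matrix_mask
    seeds = seeds_from_masks(cristae, matrix, rng=cfg.seed)
    classifier = train_pixel_classifier(lac, seeds, cfg)
    segs = [
        segment_object(lac, o.mask, classifier, cfg, object_id=o.object_id)
        for o in objects
    ]
    matched = [
        max(truth.objects, key=lambda t: (t.object_mask & o.mask).sum()) for o in objects
    ]
    return FixtureSuite(
        truth=truth, lac=lac, cfg=cfg, objects=objects,
        matched_truth=matched, segmentations=segs,
    )
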