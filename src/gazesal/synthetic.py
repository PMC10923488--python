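"""Synthetic eye-tracking studies with known ground truth.

The real study's raw eye-tracking recordings are not public, so this
module generates complete stand-in studies: a schematic face layout with
named landmarks and a per-condition discriminative feature region, group
gaze profiles (clinicians attend condition features, non-clinicians
mostly the universal eyes/nose/mouth landmarks), per-participant
idiosyncrasy, fixation streams rendered into attention maps, response
tables with group-specific accuracy, and a deterministic prototype
classifier ensemble whose truly salient region is the feature region.

Everything is reproducible from a single integer seed, fanned out into
per-participant and per-trial substreams with ``numpy.random.SeedSequence``
spawn keys, so adding participants or images never perturbs existing
streams.

Defaults emulate the study conditions: 22 clinicians + 22 non-clinicians,
16 images (10 conditions + 6 unaffected controls), 7-second trials,
720×720 stimulus frames and a 25-pixel fixation rendering radius, with
group accuracies matching the observed 85.6% / 76.9%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .maps import (DEFAULT_RADIUS, VIEWING_WINDOW_MS, AttentionMap, FaceMask,
                   FixationEvent, render_from_fixations)
from .metrics import AOIRegion
from .saliency import PrototypeClassifier
from .stats import ResponseRecord

__all__ = [
    "FaceLayout",
    "GazeProfile",
    "CohortData",
    "ToyStudy",
    "CLINICIAN_PROFILE",
    "NONCLINICIAN_PROFILE",
    "generate_layout",
    "generate_cohort",
    "generate_toy_study",
    "default_image_ids",
]

# canonical landmark centres as fractions of (W, H)
_LANDMARKS_FRAC = {
    "left_eye": (0.36, 0.40),
    "right_eye": (0.64, 0.40),
    "nose": (0.50, 0.55),
    "mouth": (0.50, 0.70),
    "left_ear": (0.16, 0.50),
    "right_ear": (0.84, 0.50),
    "forehead": (0.50, 0.24),
    "chin": (0.50, 0.86),
}

# candidate centres for condition-specific feature regions (fractions of W, H)
_FEATURE_SITES_FRAC = [
    (0.36, 0.31),  # left eyebrow
    (0.64, 0.31),  # right eyebrow
    (0.50, 0.625),  # philtrum
    (0.29, 0.60),  # left cheek
    (0.71, 0.60),  # right cheek
    (0.50, 0.80),  # jaw
    (0.50, 0.30),  # mid forehead
    (0.50, 0.46),  # nasal bridge
    (0.26, 0.44),  # left temple
    (0.74, 0.44),  # right temple
]

# feature-region semi-axes as fractions of (W, H); large enough that the
# 20-px occlusion box halo stays a minor share of the salient mass
_FEATURE_RADII_FRAC = (0.16, 0.125)


@dataclass
class FaceLayout:
    """Schematic face geometry shared by all stimuli of one study."""

    shape: tuple[int, int]
    landmarks: dict[str, tuple[float, float]]  # name -> (x, y)
    mask: FaceMask
    feature_regions: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    # image_id -> ((cx, cy), (rx, ry)), affected images only

    def feature_mask(self, image_id: str,
                     shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Boolean mask of the condition feature region of ``image_id``."""
        (cx, cy), (rx, ry) = self.feature_regions[image_id]
        h, w = shape if shape is not None else self.shape
        sx = w / self.shape[1]
        sy = h / self.shape[0]
        yy, xx = np.mgrid[0:h, 0:w]
        return ((xx - cx * sx) / (rx * sx)) ** 2 + ((yy - cy * sy) / (ry * sy)) ** 2 <= 1.0


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    rx, ry = radii
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class GazeProfile:
    """Where a participant group looks, and how reliably it answers.

    ``weights`` is a mixture over landmark names plus the special region
    ``"feature"`` (the image's condition-specific region); on unaffected
    images the feature weight is redistributed over the landmarks.
    ``sigma`` is the per-fixation spatial spread in pixels around the
    chosen region centre; ``n_fixations`` the mean fixation count per
    7-second trial; ``idiosyncrasy`` the pixel scale of each participant's
    fixed gaze offset (and, divided by 50, the log-scale of their mixture
    weight jitter); ``accuracy`` the probability of a correct
    affected/unaffected response.
    """

    weights: dict[str, float]
    sigma: float = 20.0
    n_fixations: int = 18
    idiosyncrasy: float = 15.0
    accuracy: float = 0.85

    def __post_init__(self):
        total = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("profile weights must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile weights must sum to 1, got {total}")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must be a probability")


#: Default group profiles: both groups share the universal landmark bias;
#: clinicians devote a third of their gaze to the condition feature.
CLINICIAN_PROFILE = GazeProfile(
    weights={"left_eye": 0.14, "right_eye": 0.14, "nose": 0.12, "mouth": 0.12,
             "forehead": 0.06, "chin": 0.06, "feature": 0.36},
    accuracy=0.856)

NONCLINICIAN_PROFILE = GazeProfile(
    weights={"left_eye": 0.25, "right_eye": 0.25, "nose": 0.20, "mouth": 0.20,
             "forehead": 0.05, "chin": 0.05, "feature": 0.0},
    accuracy=0.769)


def default_image_ids(n_images: int) -> tuple[list[str], list[str]]:
    """Split ``n_images`` into condition and control image ids (10:6 ratio)."""
    if n_images < 1:
        raise ValueError("need at least one image")
    n_affected = max(1, round(n_images * 10 / 16))
    n_affected = min(n_affected, n_images)
    affected = [f"cond{i + 1:02d}" for i in range(n_affected)]
    controls = [f"ctrl{i + 1:02d}" for i in range(n_images - n_affected)]
    return affected, controls


def generate_layout(seed: int, shape: tuple[int, int] = (720, 720),
                    image_ids: Optional[Sequence[str]] = None) -> FaceLayout:
    """Deterministic face layout: jittered canonical landmarks, an
    elliptical face mask, and one feature region per affected image."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    h, w = shape
    jitter = 0.015 * min(h, w)
    landmarks = {}
    for name, (fx, fy) in _LANDMARKS_FRAC.items():
        landmarks[name] = (float(fx * w + rng.normal(0, jitter)),
                           float(fy * h + rng.normal(0, jitter)))
    mask = FaceMask(_ellipse_mask(shape, (0.5 * w, 0.52 * h), (0.38 * w, 0.46 * h)))
    area_frac = mask.area / (h * w)
    if not (0.2 <= area_frac <= 0.8):  # pragma: no cover - geometry is fixed
        raise RuntimeError(f"face mask covers {area_frac:.0%} of the frame")

    if image_ids is None:
        image_ids, _ = default_image_ids(16)
    sites = list(_FEATURE_SITES_FRAC)
    feature_regions = {}
    for i, image_id in enumerate(image_ids):
        fx, fy = sites[i % len(sites)]
        cx = fx * w + rng.normal(0, jitter)
        cy = fy * h + rng.normal(0, jitter)
        feature_regions[image_id] = (
            (float(cx), float(cy)),
            (float(_FEATURE_RADII_FRAC[0] * w), float(_FEATURE_RADII_FRAC[1] * h)))
    return FaceLayout(shape=(h, w), landmarks=landmarks, mask=mask,
                      feature_regions=feature_regions)


@dataclass
class CohortData:
    """One synthetic cohort: fixation streams, optional rendered maps,
    and the response table."""

    fixations: list[FixationEvent]
    maps: list[AttentionMap]
    responses: list[ResponseRecord]
    image_ids: list[str]
    affected_ids: list[str]
    participants: dict[str, str]  # participant_id -> group


def _participant_rng(seed: int, group_code: int, index: int,
                     trial: Optional[int] = None) -> np.random.Generator:
    key = (1, group_code, index) if trial is None else (2, group_code, index, trial)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _trial_fixations(rng: np.random.Generator, participant_id: str, image_id: str,
                     layout: FaceLayout, weights: dict[str, float],
                     offset: np.ndarray, profile: GazeProfile,
                     affected: bool, window_ms: float) -> list[FixationEvent]:
    h, w = layout.shape
    names = sorted(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    if not affected and "feature" in names:
        probs[names.index("feature")] = 0.0
    if probs.sum() <= 0:
        raise ValueError("gaze profile has no usable regions for this image")
    probs = probs / probs.sum()

    n_fix = max(1, int(rng.poisson(profile.n_fixations)))
    raw = rng.gamma(3.0, 1.0, size=n_fix)
    durations = raw / raw.sum() * 0.8 * window_ms
    gaps = rng.dirichlet(np.ones(n_fix)) * 0.15 * window_ms
    onset = 0.0
    events = []
    for i in range(n_fix):
        onset += gaps[i]
        name = names[rng.choice(len(names), p=probs)]
        if name == "feature":
            (cx, cy), (rx, ry) = layout.feature_regions[image_id]
            # uniform-ish draw inside the elliptical feature region
            ang = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform())
            center = (cx + rad * rx * 0.8 * math.cos(ang),
                      cy + rad * ry * 0.8 * math.sin(ang))
        else:
            center = layout.landmarks[name]
        x = center[0] + offset[0] + rng.normal(0, profile.sigma)
        y = center[1] + offset[1] + rng.normal(0, profile.sigma)
        events.append(FixationEvent(
            participant_id=participant_id, image_id=image_id,
            x=int(np.clip(round(x), 0, w - 1)), y=int(np.clip(round(y), 0, h - 1)),
            onset_ms=float(onset), duration_ms=float(durations[i])))
        onset += durations[i]
    return events


def generate_cohort(n_clin: int, n_nonclin: int, n_images: int,
                    clin_profile: GazeProfile = CLINICIAN_PROFILE,
                    nonclin_profile: GazeProfile = NONCLINICIAN_PROFILE,
                    seed: int = 0, *,
                    layout: Optional[FaceLayout] = None,
                    radius: int = DEFAULT_RADIUS,
                    window_ms: float = VIEWING_WINDOW_MS,
                    naming_rates: tuple[float, float] = (0.35, 0.05),
                    render: bool = True) -> CohortData:
    """Generate fixation streams, maps, and responses for a full cohort.

    Each participant gets a fixed idiosyncratic gaze offset and jittered
    mixture weights; each trial draws fixation counts, positions from the
    (perturbed) group mixture, and durations summing to at most the
    viewing window.  Responses are Bernoulli draws at the profile's
    accuracy.  Set ``render=False`` to skip map rendering (fixations are
    sufficient to rebuild maps on demand).
    """
    if n_clin < 1 or n_nonclin < 1:
        raise ValueError("need at least one participant per group")
    affected, controls = default_image_ids(n_images)
    image_ids = affected + controls
    if layout is None:
        layout = generate_layout(seed, image_ids=affected)
    for prof in (clin_profile, nonclin_profile):
        for name in prof.weights:
            if name != "feature" and name not in layout.landmarks:
                raise ValueError(f"profile references unknown region {name!r}")
    missing = [i for i in affected if i not in layout.feature_regions]
    if missing:
        raise ValueError(f"layout lacks feature regions for {missing}")

    fixations: list[FixationEvent] = []
    maps: list[AttentionMap] = []
    responses: list[ResponseRecord] = []
    participants: dict[str, str] = {}

    groups = [("clinician", 0, n_clin, clin_profile, naming_rates[0]),
              ("nonclinician", 1, n_nonclin, nonclin_profile, naming_rates[1])]
    for group, gcode, n, profile, naming_rate in groups:
        for i in range(n):
            pid = f"{'C' if gcode == 0 else 'N'}{i:02d}"
            participants[pid] = group
            prng = _participant_rng(seed, gcode, i)
            offset = prng.normal(0, profile.idiosyncrasy, size=2)
            log_jitter = prng.normal(0, profile.idiosyncrasy / 50.0,
                                     size=len(profile.weights))
            names = sorted(profile.weights)
            jw = np.array([profile.weights[nm] for nm in names]) * np.exp(log_jitter)
            jw = jw / jw.sum()
            weights = dict(zip(names, jw))
            for t, image_id in enumerate(image_ids):
                trng = _participant_rng(seed, gcode, i, trial=t)
                is_affected = image_id in affected
                evs = _trial_fixations(trng, pid, image_id, layout, weights,
                                       offset, profile, is_affected, window_ms)
                fixations.extend(evs)
                if render:
                    maps.append(render_from_fixations(evs, layout.shape,
                                                      radius=radius, group=group))
                correct = bool(trng.random() < profile.accuracy)
                named = None
                if is_affected:
                    named = bool(correct and trng.random() < naming_rate)
                responses.append(ResponseRecord(
                    participant_id=pid, group=group, image_id=image_id,
                    truth_affected=is_affected,
                    response_affected=is_affected if correct else not is_affected,
                    condition_named_correctly=named))
    return CohortData(fixations=fixations, maps=maps, responses=responses,
                      image_ids=image_ids, affected_ids=affected,
                      participants=participants)


def _gauss_blob(shape: tuple[int, int], center: tuple[float, float],
                sigma: tuple[float, float], amplitude: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    sx, sy = sigma
    return amplitude * np.exp(-0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2))


def synth_face_image(layout: FaceLayout, image_id: Optional[str] = None) -> np.ndarray:
    """Schematic grayscale stimulus: soft landmark blobs on the face
    ellipse, plus a brighter bump in the feature region for affected
    images.  All images of a study share the identical base face, so
    label-discriminative content lives only in the feature regions."""
    h, w = layout.shape
    img = 0.25 * layout.mask.mask.astype(float)
    blob_sigma = (0.045 * w, 0.035 * h)
    for name, (cx, cy) in sorted(layout.landmarks.items()):
        img += _gauss_blob(layout.shape, (cx, cy), blob_sigma, 0.5)
    if image_id is not None and image_id in layout.feature_regions:
        (cx, cy), (rx, ry) = layout.feature_regions[image_id]
        # sigma = radius/2.4 keeps ~94% of the bump's energy inside the
        # advertised elliptical feature region
        img += _gauss_blob(layout.shape, (cx, cy), (rx / 2.4, ry / 2.4), 0.9)
    return img


@dataclass
class ToyStudy:
    """A complete synthetic study fixture with known ground truth."""

    seed: int
    layout: FaceLayout
    cohort: CohortData
    images: dict[str, np.ndarray]          # full-resolution stimuli
    classifiers: list[PrototypeClassifier]  # the model ensemble
    labels: list[str]
    target_labels: dict[str, str]          # image_id -> ground-truth label
    aois: list[AOIRegion]
    radius: int = DEFAULT_RADIUS
    clin_profile: GazeProfile = CLINICIAN_PROFILE
    nonclin_profile: GazeProfile = NONCLINICIAN_PROFILE

    @property
    def mask(self) -> FaceMask:
        return self.layout.mask


def generate_toy_study(seed: int, *, n_clin: int = 22, n_nonclin: int = 22,
                       n_images: int = 16, shape: tuple[int, int] = (720, 720),
                       clf_resolution: tuple[int, int] = (224, 224),
                       n_models: int = 5,
                       clin_profile: GazeProfile = CLINICIAN_PROFILE,
                       nonclin_profile: GazeProfile = NONCLINICIAN_PROFILE,
                       radius: int = DEFAULT_RADIUS,
                       render_maps: bool = False) -> ToyStudy:
    """Bundle a layout, cohort, stimuli, classifier ensemble, and AOIs.

    Each affected image's classifier prototype is the image itself
    (downsampled to the classifier resolution), so the discriminative —
    hence truly salient — region is exactly the image's feature region.
    The ensemble consists of ``n_models`` classifiers with slightly
    jittered prototypes, mimicking independently trained folds.
    """
    affected, controls = default_image_ids(n_images)
    layout = generate_layout(seed, shape=shape, image_ids=affected)
    cohort = generate_cohort(n_clin, n_nonclin, n_images, clin_profile,
                             nonclin_profile, seed, layout=layout,
                             radius=radius, render=render_maps)

    images: dict[str, np.ndarray] = {}
    target_labels: dict[str, str] = {}
    labels = list(affected) + ["unaffected"]
    protos_full = {lab: synth_face_image(layout, lab if lab != "unaffected" else None)
                   for lab in labels}
    for image_id in cohort.image_ids:
        if image_id in affected:
            images[image_id] = protos_full[image_id]
            target_labels[image_id] = image_id
        else:
            images[image_id] = protos_full["unaffected"]
            target_labels[image_id] = "unaffected"

    protos_small = {lab: resize(img, clf_resolution, anti_aliasing=True,
                                preserve_range=True)
                    for lab, img in protos_full.items()}
    crng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    classifiers = []
    for _ in range(n_models):
        jittered = {lab: np.clip(p + crng.normal(0, 1e-3, p.shape), 0.0, None)
                    for lab, p in protos_small.items()}
        classifiers.append(PrototypeClassifier(labels, jittered, temperature=0.01))

    aois = []
    for image_id in affected:
        (cx, cy), (rx, ry) = layout.feature_regions[image_id]
        aois.append(AOIRegion(image_id=image_id, name="condition_feature",
                              polygon=((cx - rx, cy - ry), (cx + rx, cy - ry),
                                       (cx + rx, cy + ry), (cx - rx, cy + ry))))
    return ToyStudy(seed=seed, layout=layout, cohort=cohort, images=images,
                    classifiers=classifiers, labels=labels,
                    target_labels=target_labels, aois=aois, radius=radius,
                    clin_profile=clin_profile, nonclin_profile=nonclin_profile)
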