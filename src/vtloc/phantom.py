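"""Synthetic midsagittal vocal-tract phantom corpus with exact ground truth.

The MRI corpora used in articulatory studies are rarely shareable, so this
module renders a schematic stand-in: grayscale images of smooth bright
curves on a dark background laid out like a midsagittal head — facial
profile, hard palate, tongue, lips, velum, epiglottis, pharyngeal wall —
with the 21 landmarks of the schema placed *analytically* on (or, for the
teeth points UT/LT, at fixed offsets from) those curves.  The corpus is
structured as subjects x articulation classes:

* per **subject**, morphological parameters are drawn once (global scale,
  head offset, palate curvature, jaw length);
* per **(subject, class)**, articulatory parameters are drawn (tongue-body
  shape, tongue-tip elevation, jaw opening, lip protrusion/aperture, velum
  angle, larynx height);
* additive Gaussian intensity noise emulates acquisition noise.

The phantom is schematic, not anatomically faithful: its job is to give
the codec / network / evaluator inputs with the statistical structure of
the real task (inter-subject morphology variation, intra-subject
articulation variation, landmarks anchored to image structure, invisible
teeth landmarks).  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import AnnotatedImage
from .schema import load_schema

__all__ = ["PhantomConfig", "SubjectMorphology", "ArticulationParams",
           "generate_corpus", "corpus_statistics", "layout_landmarks"]


@dataclass(frozen=True)
class PhantomConfig:
    """Corpus-level parameters of the phantom generator.

    ``morphology_spread`` and ``articulation_spread`` scale the canonical
    inter-subject and intra-subject variations (0 = every draw identical;
    the default 1.0 = the variation the generator was designed around).
    ``noise_sd`` is the additive Gaussian intensity noise on the 8-bit
    scale (default 4, near the noise level used by the augmentation
    battery).
    """

    n_subjects: int = 9
    n_classes: int = 62
    image_size: tuple[int, int] = (256, 256)
    rng_seed: int = 0
    noise_sd: float = 4.0
    morphology_spread: float = 1.0
    articulation_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_classes < 1:
            raise ValueError("n_subjects and n_classes must be >= 1")
        if min(self.image_size) < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.morphology_spread <= 2):
            raise ValueError("morphology_spread must lie in [0, 2]")
        if not (0 <= self.articulation_spread <= 2):
            raise ValueError("articulation_spread must lie in [0, 2]")


@dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject anatomy parameters (drawn once per subject)."""

    scale: float = 1.0          # global head scale about the frame centre
    offset: tuple[float, float] = (0.0, 0.0)   # head position, normalised units
    palate_curvature: float = 0.04             # palate dome depth
    jaw_length: float = 1.0     # scales jaw points' distance from the condyle


@dataclass(frozen=True)
class ArticulationParams:
    """Per-(subject, class) articulation parameters."""

    tongue_body: tuple[float, float] = (0.0, 0.0)  # dorsum control offsets
    tt_elevation: float = 0.0   # + = tongue tip raised (smaller y)
    jaw_open_deg: float = 0.0   # + = jaw opens (chin moves down)
    lip_protrusion: float = 0.0
    lip_aperture: float = 0.0
    velum_angle_deg: float = 0.0   # + = velum swings toward the pharynx
    larynx_height: float = 0.0     # + = larynx raised


# jaw-attached landmarks rotate about the condyle with jaw opening
_JAW_POINTS = {"LT", "LC", "LLV", "LLSV", "NM", "TJ", "TS", "_chin", "_neck",
               "_lgum", "_floor1"}
_CONDYLE = np.array([0.52, 0.40])


def _rot(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    # positive angle moves anterior jaw points downward (y grows)
    return np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])


def layout_landmarks(morph: SubjectMorphology,
                     artic: ArticulationParams) -> tuple[dict, list]:
    """Place all landmarks and curve control points in normalised [0,1]^2.

    Returns ``(points, curves)`` where ``points`` maps point names
    (landmark abbreviations plus internal ``_``-prefixed helpers) to
    ``(x, y)`` and ``curves`` is a list of point-name sequences to render.
    Landmarks are on the curves by construction, except UT and LT which sit
    at fixed offsets from the palate/jaw curves (teeth are invisible on the
    images, as on real MRI).
    """
    p: dict[str, np.ndarray] = {}

    # --- skull-fixed points (anterior = left, y down) -------------------
    p["_crown"] = np.array([0.38, 0.10])
    p["_forehead"] = np.array([0.22, 0.17])
    p["_bridge"] = np.array([0.17, 0.25])
    p["N"] = np.array([0.15, 0.30])
    p["NP"] = np.array([0.175, 0.355])
    p["ANS"] = np.array([0.245, 0.385])
    p["_palmid"] = np.array([0.37, 0.40 + morph.palate_curvature])
    p["PNS"] = np.array([0.50, 0.40])
    p["NPX"] = np.array([0.60, 0.32])
    p["_phar1"] = np.array([0.635, 0.45])
    p["UT"] = p["ANS"] + np.array([-0.005, 0.055])      # offset, not drawn

    # --- lips -----------------------------------------------------------
    prot = 0.020 * artic.lip_protrusion
    ap = 0.014 * artic.lip_aperture
    p["ULPV"] = np.array([0.155 - prot, 0.425])
    p["ULV"] = np.array([0.185 - prot, 0.450 - ap])
    p["LLV"] = np.array([0.185 - prot, 0.505 + ap])
    p["LLSV"] = np.array([0.155 - prot, 0.530])

    # --- jaw-fixed points (before jaw rotation) -------------------------
    p["_lgum"] = np.array([0.245, 0.505])
    p["LT"] = p["_lgum"] + np.array([-0.005, -0.050])   # offset, not drawn
    p["LC"] = np.array([0.165, 0.585])
    p["_chin"] = np.array([0.21, 0.655])
    p["NM"] = np.array([0.33, 0.715])
    p["_neck"] = np.array([0.44, 0.78])
    p["TJ"] = np.array([0.295, 0.560])
    p["_floor1"] = np.array([0.33, 0.545])
    p["TS"] = np.array([0.315, 0.525])

    # --- tongue ---------------------------------------------------------
    tb = np.asarray(artic.tongue_body)
    p["TT"] = np.array([0.280, 0.490 - 0.050 * artic.tt_elevation])
    p["_dors1"] = np.array([0.365 + 0.030 * tb[0], 0.475 + 0.040 * tb[1]])
    p["_dors2"] = np.array([0.455 + 0.030 * tb[0], 0.500 + 0.040 * tb[1]])
    p["TE"] = np.array([0.525, 0.585])

    # --- epiglottis / larynx / pharynx ---------------------------------
    lar = np.array([0.0, -0.035 * artic.larynx_height])
    p["ET"] = np.array([0.560, 0.540]) + lar
    p["EG"] = np.array([0.575, 0.680]) + lar
    p["PL"] = np.array([0.645, 0.655]) + lar
    p["_phar2"] = np.array([0.660, 0.78]) + lar

    # --- velum ----------------------------------------------------------
    va = np.deg2rad(55.0 + 3.0 * artic.velum_angle_deg)
    p["VT"] = p["PNS"] + 0.085 * np.array([np.cos(va), np.sin(va)])

    # jaw opening: rotate jaw points about the condyle, scaled by jaw length
    rot = _rot(artic.jaw_open_deg)
    for name in _JAW_POINTS:
        d = p[name] - _CONDYLE
        p[name] = _CONDYLE + rot @ (morph.jaw_length * d)

    # subject morphology: global scale about the frame centre plus offset
    centre = np.array([0.42, 0.45])
    off = np.asarray(morph.offset)
    for name in p:
        p[name] = centre + morph.scale * (p[name] - centre) + off

    curves = [
        # facial profile, upper part down to the upper lip
        ["_crown", "_forehead", "_bridge", "N", "NP", "ULPV"],
        # facial profile, lower lip to neck
        ["LLSV", "LC", "_chin", "NM", "_neck"],
        # inner lips
        ["ULPV", "ULV"],
        ["LLSV", "LLV"],
        # hard palate
        ["ANS", "_palmid", "PNS"],
        # velum
        ["PNS", "VT"],
        # tongue dorsum: tip over the back to the epiglottis junction
        ["TT", "_dors1", "_dors2", "TE"],
        # mouth floor / sublingual cavity
        ["TT", "TS", "_floor1", "TJ"],
        # epiglottis
        ["TE", "ET", "EG"],
        # posterior pharyngeal wall
        ["NPX", "_phar1", "PL", "_phar2"],
    ]
    return p, curves


def _draw_morphology(rng: np.random.Generator, spread: float) -> SubjectMorphology:
    u = rng.uniform(-1.0, 1.0, size=5)
    return SubjectMorphology(
        scale=1.0 + 0.06 * spread * u[0],
        offset=(0.02 * spread * u[1], 0.02 * spread * u[2]),
        palate_curvature=0.04 + 0.02 * spread * u[3],
        jaw_length=1.0 + 0.05 * spread * u[4],
    )


def _draw_articulation(rng: np.random.Generator, spread: float) -> ArticulationParams:
    u = rng.uniform(-1.0, 1.0, size=8)
    return ArticulationParams(
        tongue_body=(spread * u[0], spread * u[1]),
        tt_elevation=spread * u[2],
        jaw_open_deg=4.0 * spread * max(u[3], 0.0),   # jaw opens, never clenches past rest
        lip_protrusion=spread * u[4],
        lip_aperture=spread * max(u[5], 0.0),
        velum_angle_deg=spread * u[6] * 3.0,
        larynx_height=spread * u[7],
    )


def _catmull_rom(points: np.ndarray, samples_per_seg: int = 40) -> np.ndarray:
    """Interpolating Catmull-Rom spline through ``points`` ((n,2), n>=2)."""
    if len(points) == 2:
        t = np.linspace(0, 1, samples_per_seg)[:, None]
        return points[0] * (1 - t) + points[1] * t
    ext = np.vstack([2 * points[0] - points[1], points,
                     2 * points[-1] - points[-2]])
    out = []
    t = np.linspace(0.0, 1.0, samples_per_seg, endpoint=False)
    t2, t3 = t * t, t * t * t
    b = np.stack([-0.5 * t3 + t2 - 0.5 * t,
                  1.5 * t3 - 2.5 * t2 + 1.0,
                  -1.5 * t3 + 2.0 * t2 + 0.5 * t,
                  0.5 * t3 - 0.5 * t2], axis=1)   # (s, 4)
    for i in range(len(points) - 1):
        seg = ext[i:i + 4]                         # (4, 2)
        out.append(b @ seg)
    out.append(points[-1][None])
    return np.concatenate(out, axis=0)


def _render(points: dict, curves: list, image_size: tuple[int, int],
            line_peak: float = 185.0, background: float = 16.0) -> np.ndarray:
    rows, cols = image_size
    scale = np.array([cols - 1, rows - 1], dtype=float)
    canvas = np.zeros((rows, cols), dtype=float)
    for names in curves:
        pts = np.array([points[n] for n in names]) * scale
        dense = _catmull_rom(pts)
        # resample roughly every half pixel along the polyline
        seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        n = max(int(seglen.sum() * 2), 2)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        si = np.linspace(0.0, s[-1], n)
        xs = np.interp(si, s, dense[:, 0])
        ys = np.interp(si, s, dense[:, 1])
        ci = np.clip(np.rint(xs).astype(int), 0, cols - 1)
        ri = np.clip(np.rint(ys).astype(int), 0, rows - 1)
        canvas[ri, ci] = 1.0
    canvas = ndimage.gaussian_filter(canvas, sigma=1.0)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()
    return background + line_peak * canvas


def generate_corpus(config: PhantomConfig) -> list[AnnotatedImage]:
    """Render the full phantom corpus (``n_subjects x n_classes`` originals).

    Deterministic for a fixed ``config.rng_seed``: subject morphologies and
    articulation draws come from per-(subject, class) child seeds, so the
    corpus is byte-identical across runs and insensitive to iteration
    order.  All 21 landmarks are guaranteed in-frame.
    """
    schema = load_schema()
    rows, cols = config.image_size
    corpus: list[AnnotatedImage] = []
    root = np.random.SeedSequence(config.rng_seed)
    for s in range(config.n_subjects):
        m_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(s,)))
        morph = _draw_morphology(m_rng, config.morphology_spread)
        for c in range(config.n_classes):
            a_rng = np.random.default_rng(np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(s, c)))
            artic = _draw_articulation(a_rng, config.articulation_spread)
            points, curves = layout_landmarks(morph, artic)
            image = _render(points, curves, config.image_size)
            if config.noise_sd > 0:
                image = image + a_rng.normal(0.0, config.noise_sd, size=image.shape)
            image = np.clip(image, 0.0, 255.0)
            landmarks = np.array([points[a] for a in schema.abbreviations])
            landmarks = landmarks * np.array([cols - 1, rows - 1], dtype=float)
            if np.any(landmarks < 0) or np.any(
                    landmarks >= np.array([cols, rows], dtype=float)):
                raise ValueError(
                    f"phantom configuration pushed a landmark out of frame "
                    f"(subject {s}, class {c}); reduce the spreads")
            corpus.append(AnnotatedImage(
                image=image, landmarks=landmarks,
                subject_id=f"S{s:02d}", class_id=f"C{c:03d}",
                augmentation_tag="orig"))
    return corpus


@dataclass
class CorpusStatistics:
    """Per-landmark coordinate spreads plus per-image provenance."""

    per_landmark: pd.DataFrame   # 21 rows: overall / between- / within-subject sd
    provenance: pd.DataFrame     # one row per image: subject, class, tag


def corpus_statistics(corpus: list[AnnotatedImage]) -> CorpusStatistics:
    """Summarise landmark variability across a corpus.

    ``between_subject_sd`` is the sd of per-subject landmark means
    (inter-subject morphology variation); ``within_subject_sd`` is the
    pooled sd around those means (intra-subject articulation variation).
    """
    if not corpus:
        raise ValueError("empty corpus")
    schema = load_schema()
    coords = np.stack([it.landmarks for it in corpus])   # (n, 21, 2)
    subjects = np.array([it.subject_id for it in corpus])
    rows = []
    for j, abbr in enumerate(schema.abbreviations):
        xy = coords[:, j, :]
        subj_means = np.stack([xy[subjects == s].mean(axis=0)
                               for s in np.unique(subjects)])
        within = np.concatenate([xy[subjects == s] - xy[subjects == s].mean(axis=0)
                                 for s in np.unique(subjects)])
        rows.append({
            "landmark": abbr,
            "mean_x": xy[:, 0].mean(), "mean_y": xy[:, 1].mean(),
            "overall_sd": float(np.sqrt(((xy - xy.mean(0)) ** 2).sum(1).mean())),
            "between_subject_sd": float(np.sqrt(
                ((subj_means - subj_means.mean(0)) ** 2).sum(1).mean())),
            "within_subject_sd": float(np.sqrt((within ** 2).sum(1).mean())),
        })
    prov = pd.DataFrame({
        "subject": [it.subject_id for it in corpus],
        "class": [it.class_id for it in corpus],
        "tag": [it.augmentation_tag for it in corpus],
    })
    return CorpusStatistics(per_landmark=pd.DataFrame(rows), provenance=prov)
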