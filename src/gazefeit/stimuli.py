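"""Stimulus bookkeeping: face-number/emotion maps, per-stimulus AOIs, schematic images.

The facial-emotion task presents a fixed bank of face photographs (21 for
adults — 3 per emotion over 7 emotions; 32 for children — 8 per emotion over
4 emotions).  The photographs themselves are copyrighted, so this module
renders schematic grayscale face placeholders whose eye/nose/mouth geometry
matches the per-stimulus AOI polygons; every downstream stage (AOI counting,
heat-map channels) only needs that geometry.

Coordinates are normalized to [0, 1] x [0, 1] with the origin at the top-left
of the display, matching the gaze streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml
from shapely.geometry import Polygon
from skimage.draw import polygon as _draw_polygon

ADULT_EMOTIONS = ("happiness", "sadness", "fear", "anger", "surprise", "disgust", "neutral")
CHILD_EMOTIONS = ("happiness", "sadness", "anger", "surprise")

# Face number -> emotion correspondence of the stimulus bank.
FACE_EMOTION_ADULT: dict[int, str] = {}
for _emo, _faces in {
    "surprise": (1, 7, 14),
    "happiness": (3, 9, 11),
    "anger": (13, 15, 21),
    "sadness": (4, 16, 19),
    "neutral": (2, 8, 17),
    "fear": (5, 10, 20),
    "disgust": (6, 12, 18),
}.items():
    for _f in _faces:
        FACE_EMOTION_ADULT[_f] = _emo

FACE_EMOTION_CHILD: dict[int, str] = {}
for _emo, _faces in {
    "surprise": (3, 8, 10, 12, 19, 22, 25, 32),
    "happiness": (5, 7, 9, 14, 21, 23, 26, 30),
    "anger": (1, 6, 13, 15, 18, 24, 27, 29),
    "sadness": (2, 4, 11, 16, 17, 20, 28, 31),
}.items():
    for _f in _faces:
        FACE_EMOTION_CHILD[_f] = _emo


def face_emotion_map(population: str) -> dict[int, str]:
    if population == "adult":
        return dict(FACE_EMOTION_ADULT)
    if population == "child":
        return dict(FACE_EMOTION_CHILD)
    raise ValueError(f"unknown population {population!r}; valid options: 'adult', 'child'")


def emotions_for(population: str) -> tuple[str, ...]:
    return ADULT_EMOTIONS if population == "adult" else CHILD_EMOTIONS


AOI_NAMES = ("eyes", "nose", "mouth")


@dataclass(frozen=True)
class AOIMap:
    """Per-stimulus areas of interest: eyes (up to the eyebrows), nose, mouth.

    ``face_bbox`` is the (xmin, ymin, xmax, ymax) of the whole face region and
    anchors the center crop used when assembling model inputs.
    """

    stimulus_id: str
    polygons: dict[str, Polygon]
    face_bbox: tuple[float, float, float, float]

    def __post_init__(self):
        for name in AOI_NAMES:
            poly = self.polygons.get(name)
            if poly is None or poly.area <= 0:
                raise ValueError(f"AOI {name!r} missing or degenerate for {self.stimulus_id}")

    def to_dict(self) -> dict:
        return {
            "stimulus_id": self.stimulus_id,
            "face_bbox": [float(v) for v in self.face_bbox],
            "polygons": {
                name: [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]]
                for name, poly in self.polygons.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOIMap":
        return cls(
            stimulus_id=d["stimulus_id"],
            polygons={name: Polygon(pts) for name, pts in d["polygons"].items()},
            face_bbox=tuple(d["face_bbox"]),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load_yaml(cls, path) -> "AOIMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rect(cx: float, cy: float, w: float, h: float) -> Polygon:
    return Polygon(
        [
            (cx - w / 2, cy - h / 2),
            (cx + w / 2, cy - h / 2),
            (cx + w / 2, cy + h / 2),
            (cx - w / 2, cy + h / 2),
        ]
    )


@lru_cache(maxsize=64)
def default_aoi(population: str, face_number: int) -> AOIMap:
    """Schematic AOI layout for one stimulus.

    Region placement varies deterministically per stimulus (the real task
    re-drew AOIs per image so each region fully covered the feature); the
    mouth region additionally widens/narrows with the portrayed emotion.
    """
    emotion = face_emotion_map(population)[face_number]
    # Small deterministic per-stimulus geometry jitter (crc32: process-stable).
    rng = np.random.default_rng(zlib.crc32(f"{population}:{face_number}".encode()))
    jx, jy = rng.uniform(-0.015, 0.015, size=2)

    cx, cy = 0.5 + jx, 0.5 + jy
    face_w, face_h = 0.36, 0.62
    # Eyes band extends up to the eyebrows.
    eyes = _rect(cx, cy - 0.13 * (face_h / 0.62), 0.30, 0.16)
    nose = _rect(cx, cy + 0.02, 0.10, 0.14)
    mouth_w = {"happiness": 0.20, "surprise": 0.13, "anger": 0.15}.get(emotion, 0.17)
    mouth_h = 0.10 if emotion == "surprise" else 0.08
    mouth = _rect(cx, cy + 0.18, mouth_w, mouth_h)
    bbox = (cx - face_w / 2, cy - face_h / 2, cx + face_w / 2, cy + face_h / 2)
    return AOIMap(
        stimulus_id=f"{population}_face{face_number:02d}",
        polygons={"eyes": eyes, "nose": nose, "mouth": mouth},
        face_bbox=bbox,
    )


def _fill(img: np.ndarray, poly: Polygon, value: float) -> None:
    h, w = img.shape
    xs, ys = zip(*poly.exterior.coords[:-1])
    rr, cc = _draw_polygon(np.asarray(ys) * h, np.asarray(xs) * w, shape=img.shape)
    img[rr, cc] = value


@lru_cache(maxsize=64)
def stimulus_image(population: str, face_number: int, resolution: tuple[int, int] = (1920, 1080)) -> np.ndarray:
    """Schematic grayscale face, shape (height, width), values in [0, 1].

    A light face oval on a mid-gray background with darker eye, nose, and
    mouth features drawn from the stimulus's AOI geometry, so the image
    channel carries the facial layout the classifier is meant to exploit.
    """
    w, h = resolution
    aoi = default_aoi(population, face_number)
    img = np.full((h, w), 0.45, dtype=np.float32)
    xmin, ymin, xmax, ymax = aoi.face_bbox
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    fx = (np.arange(w, dtype=np.float32) / w - cx) / ((xmax - xmin) / 2)
    fy = (np.arange(h, dtype=np.float32) / h - cy) / ((ymax - ymin) / 2)
    oval = fx[None, :] ** 2 + fy[:, None] ** 2 <= 1.0
    img[oval] = 0.85
    emotion = face_emotion_map(population)[face_number]
    shade = {"anger": 0.10, "sadness": 0.20, "fear": 0.15, "disgust": 0.12}.get(emotion, 0.25)
    eyes = aoi.polygons["eyes"]
    exmin, eymin, exmax, eymax = eyes.bounds
    # Two pupils inside the eyes band rather than one dark slab.
    for side in (-1.0, 1.0):
        pupil = _rect((exmin + exmax) / 2 + side * (exmax - exmin) / 4, (eymin + eymax) / 2, 0.06, 0.05)
        _fill(img, pupil, shade)
    _fill(img, aoi.polygons["nose"], 0.60)
    _fill(img, aoi.polygons["mouth"], shade)
    img.setflags(write=False)
    return img
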