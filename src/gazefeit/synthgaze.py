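"""Synthetic gaze cohorts with group/emotion-dependent structure.

The clinical gaze recordings behind this analysis are not released, so this
module generates cohorts whose trial-level feature distributions are
calibrated to the published group x emotion summary statistics: eye/mouth
fixation-sample counts and scan-path magnitudes for control, ASD, and Sz
adults, and for control/ASD children.

Generative model (deliberately the simplest mechanism that independently
controls AOI dwell shares, saccade counts, and scan-path length):

* a trial is a two-state process alternating fixation epochs with
  single-sample saccadic transitions;
* each epoch targets one region (eyes / nose / mouth / other) drawn from the
  profile's per-emotion dwell fractions; the anchor is sampled uniformly
  inside the region and samples scatter around it with isotropic Gaussian
  jitter, clipped to the display;
* transitions overshoot: the transition sample sits at distance
  ``saccade_amplitude`` from the next anchor in a random direction, so the
  amplitude parameter controls scan-path length independently of AOI layout;
* samples are invalidated i.i.d. with ``invalid_sample_rate`` (both eyes);
  valid samples occasionally carry only one eye.

The published scan-path magnitudes (0.05-0.22 normalized units per 8.3 ms
sample) imply much larger and more frequent jumps than physiological
saccades; the generator reproduces those magnitudes, not plausible
kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import stimuli
from .stimuli import AOIMap, default_aoi, emotions_for, face_emotion_map

AOI_CATEGORIES = ("eyes", "nose", "mouth", "other")

#: group x emotion calibration targets: (eye fixation samples, mouth fixation
#: samples, scan-path length) per trial, from the published adult summary table.
ADULT_TARGETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "control": {
        "surprise": (288.33, 37.64, 0.05),
        "happiness": (266.68, 31.62, 0.06),
        "anger": (299.69, 23.94, 0.06),
        "sadness": (243.73, 37.95, 0.06),
        "neutral": (291.38, 27.05, 0.05),
        "fear": (253.91, 45.12, 0.05),
        "disgust": (228.74, 68.74, 0.06),
    },
    "ASD": {
        "surprise": (234.23, 62.63, 0.09),
        "happiness": (206.18, 65.21, 0.12),
        "anger": (210.11, 43.80, 0.12),
        "sadness": (187.35, 73.67, 0.12),
        "neutral": (200.11, 48.09, 0.12),
        "fear": (189.00, 73.17, 0.13),
        "disgust": (172.00, 86.21, 0.13),
    },
    "Sz": {
        "surprise": (140.35, 39.00, 0.15),
        "happiness": (146.67, 39.79, 0.20),
        "anger": (143.73, 25.50, 0.22),
        "sadness": (142.50, 41.63, 0.16),
        "neutral": (161.62, 37.48, 0.18),
        "fear": (153.38, 43.88, 0.15),
        "disgust": (118.41, 57.21, 0.20),
    },
}

#: same for children; group contrasts are small, largest for anger-trial eye dwell.
CHILD_TARGETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "control": {
        "surprise": (300.01, 51.76, 0.06),
        "happiness": (275.83, 57.28, 0.06),
        "anger": (285.29, 51.50, 0.05),
        "sadness": (280.54, 47.78, 0.07),
    },
    "ASD": {
        "surprise": (268.62, 50.81, 0.05),
        "happiness": (253.12, 54.22, 0.05),
        "anger": (243.84, 53.64, 0.07),
        "sadness": (267.56, 56.52, 0.06),
    },
}

_RATES = {"adult": {"control": 8.0, "ASD": 10.0, "Sz": 13.0}, "child": {"control": 8.0, "ASD": 8.0}}
_INVALID = {"adult": {"control": 0.03, "ASD": 0.05, "Sz": 0.08}, "child": {"control": 0.04, "ASD": 0.05}}
_JITTER_SD = 0.004
_NOSE_DWELL = 0.08
_EYE_DISPARITY = 0.002  # horizontal half-offset between the two eyes
_MONOCULAR_RATE = 0.10  # valid samples carrying only one eye


@dataclass
class GroupGazeProfile:
    """Generative parameters for one diagnostic group.

    ``per_emotion_dwell`` maps emotion -> fractions over eyes/nose/mouth/other
    (each summing to 1).  ``per_emotion_rate`` optionally overrides
    ``saccades_per_second`` for individual emotions; it is empty for the
    default calibrated profiles and exists so experiments can confine group
    signal to a subset of emotions.
    """

    group_label: str
    per_emotion_dwell: dict[str, dict[str, float]]
    fixation_jitter_sd: float
    saccades_per_second: float
    saccade_amplitude: float
    invalid_sample_rate: float
    per_emotion_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for emo, dwell in self.per_emotion_dwell.items():
            if set(dwell) != set(AOI_CATEGORIES):
                raise ValueError(f"dwell for {emo!r} must cover {AOI_CATEGORIES}")
            if abs(sum(dwell.values()) - 1.0) > 1e-9:
                raise ValueError(f"dwell fractions for {emo!r} must sum to 1")
            if min(dwell.values()) < 0:
                raise ValueError(f"negative dwell fraction for {emo!r}")
        if self.fixation_jitter_sd < 0 or self.saccade_amplitude < 0:
            raise ValueError("jitter and amplitude must be non-negative")
        if self.saccades_per_second < 0 or any(r < 0 for r in self.per_emotion_rate.values()):
            raise ValueError("saccade rates must be non-negative")
        if not 0.0 <= self.invalid_sample_rate <= 1.0:
            raise ValueError("invalid_sample_rate must be a probability")

    def rate_for(self, emotion: str) -> float:
        return self.per_emotion_rate.get(emotion, self.saccades_per_second)


@dataclass
class CohortConfig:
    groups: list[tuple[GroupGazeProfile, int]]
    population: str = "adult"
    sampling_rate_hz: float = 120.0
    trial_duration_s: float = 5.0
    display: tuple[int, int] = (1920, 1080)
    seed: int = 0

    @property
    def emotions(self) -> tuple[str, ...]:
        return emotions_for(self.population)

    @property
    def trials_per_participant(self) -> int:
        return len(face_emotion_map(self.population))

    @property
    def n_samples_per_trial(self) -> int:
        return int(round(self.sampling_rate_hz * self.trial_duration_s))

    def __post_init__(self):
        if self.trials_per_participant % len(self.emotions) != 0:
            raise ValueError("emotion count must divide the trial count")


def _n_jumps(profile: GroupGazeProfile, emotion: str, config: CohortConfig) -> int:
    return int(round(profile.rate_for(emotion) * config.trial_duration_s))


def _sample_in_polygon(poly: Polygon, rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = poly.bounds
    for _ in range(200):
        pt = rng.uniform([xmin, ymin], [xmax, ymax])
        if poly.covers(Point(pt)):
            return pt
    return np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])


def _anchor(category: str, aoi: AOIMap, rng: np.random.Generator) -> np.ndarray:
    if category in aoi.polygons:
        return _sample_in_polygon(aoi.polygons[category], rng)
    # "other": anywhere on the display outside the three feature regions.
    for _ in range(200):
        pt = rng.uniform([0.02, 0.02], [0.98, 0.98])
        if not any(p.covers(Point(pt)) for p in aoi.polygons.values()):
            return pt
    return np.array([0.05, 0.05])


def _representative_aoi(population: str, emotion: str) -> AOIMap:
    faces = [f for f, e in face_emotion_map(population).items() if e == emotion]
    return default_aoi(population, min(faces))


def simulate_trial(
    profile: GroupGazeProfile,
    emotion: str,
    config: CohortConfig,
    rng: np.random.Generator,
    aoi: AOIMap | None = None,
) -> pd.DataFrame:
    """One trial's gaze table (t_ms, lx, ly, rx, ry, lvalid, rvalid)."""
    if emotion not in profile.per_emotion_dwell:
        raise ValueError(f"no dwell fractions for emotion {emotion!r}")
    if aoi is None:
        aoi = _representative_aoi(config.population, emotion)
    n = config.n_samples_per_trial
    dwell = profile.per_emotion_dwell[emotion]
    probs = np.array([dwell[c] for c in AOI_CATEGORIES])
    n_jumps = min(_n_jumps(profile, emotion, config), n - 1)
    n_epochs = n_jumps + 1
    # Epoch lengths: multinomial split of the fixation slots, floor of 1 sample.
    lengths = rng.multinomial(n - n_jumps - n_epochs, np.full(n_epochs, 1.0 / n_epochs)) + 1
    cats = rng.choice(len(AOI_CATEGORIES), size=n_epochs, p=probs)
    pts = np.empty((n, 2))
    pos = 0
    for k in range(n_epochs):
        anchor = _anchor(AOI_CATEGORIES[cats[k]], aoi, rng)
        if k > 0:
            # Saccadic transition: overshoot point at saccade_amplitude from
            # the new anchor, kept on the display when possible.
            for _ in range(20):
                theta = rng.uniform(0, 2 * np.pi)
                t = anchor + profile.saccade_amplitude * np.array([np.cos(theta), np.sin(theta)])
                if (t >= 0).all() and (t <= 1).all():
                    break
            pts[pos] = np.clip(t, 0.0, 1.0)
            pos += 1
        m = lengths[k]
        pts[pos : pos + m] = np.clip(
            anchor + rng.normal(0.0, profile.fixation_jitter_sd, size=(m, 2)), 0.0, 1.0
        )
        pos += m
    assert pos == n
    t_ms = np.arange(n) / config.sampling_rate_hz * 1000.0
    invalid = rng.random(n) < profile.invalid_sample_rate
    mono = (~invalid) & (rng.random(n) < _MONOCULAR_RATE)
    drop_left = rng.random(n) < 0.5
    lvalid = ~invalid & ~(mono & drop_left)
    rvalid = ~invalid & ~(mono & ~drop_left)
    both = lvalid & rvalid
    # Disparity is symmetric so the cyclopean mean recovers the true point;
    # a monocular sample reports the true point directly for the same reason.
    lx = np.where(lvalid, np.where(both, np.clip(pts[:, 0] - _EYE_DISPARITY, 0, 1), pts[:, 0]), np.nan)
    rx = np.where(rvalid, np.where(both, np.clip(pts[:, 0] + _EYE_DISPARITY, 0, 1), pts[:, 0]), np.nan)
    ly = np.where(lvalid, pts[:, 1], np.nan)
    ry = np.where(rvalid, pts[:, 1], np.nan)
    return pd.DataFrame(
        {"t_ms": t_ms, "lx": lx, "ly": ly, "rx": rx, "ry": ry, "lvalid": lvalid, "rvalid": rvalid}
    )


# ---------------------------------------------------------------------------
# Calibration: profile parameters from the published summary-table targets.
# ---------------------------------------------------------------------------


def _jitter_step_mean(sd: float) -> float:
    # mean |N2(0, sd^2 I) - N2(0, sd^2 I)| = sd * sqrt(2) * sqrt(pi/2)
    return sd * np.sqrt(2.0) * np.sqrt(np.pi / 2.0)


def _mean_anchor_distance(population: str, dwell_by_emotion: dict[str, dict[str, float]]) -> float:
    """MC estimate of the expected distance between consecutive epoch anchors."""
    rng = np.random.default_rng(123456)
    dists = []
    for emotion, dwell in dwell_by_emotion.items():
        aoi = _representative_aoi(population, emotion)
        probs = np.array([dwell[c] for c in AOI_CATEGORIES])
        cats = rng.choice(len(AOI_CATEGORIES), size=400, p=probs)
        anchors = np.array([_anchor(AOI_CATEGORIES[c], aoi, rng) for c in cats])
        dists.append(np.linalg.norm(np.diff(anchors, axis=0), axis=1))
    return float(np.mean(np.concatenate(dists)))


def _calibrate_profile(
    population: str, group: str, targets: dict[str, tuple[float, float, float]]
) -> GroupGazeProfile:
    rate = _RATES[population][group]
    v = _INVALID[population][group]
    n = 600
    J = int(round(rate * 5.0))
    fix_budget = (n - 2 * J) * (1.0 - v)  # expected fixation-labeled valid samples
    dwell_by_emotion = {}
    for emotion, (eyes_t, mouth_t, _) in targets.items():
        eyes = eyes_t / fix_budget
        mouth = mouth_t / fix_budget
        other = 1.0 - eyes - mouth - _NOSE_DWELL
        if other < 0.02:
            raise ValueError(f"calibration infeasible for {group}/{emotion}")
        dwell_by_emotion[emotion] = {"eyes": eyes, "nose": _NOSE_DWELL, "mouth": mouth, "other": other}
    # Amplitude from the group-mean scan-path target.
    s_target = float(np.mean([t[2] for t in targets.values()]))
    n_pairs = (n - 1) * (1.0 - v) ** 2
    jump_pairs = 2.0 * J * (1.0 - v) ** 2
    j_step = _jitter_step_mean(_JITTER_SD)
    ed = _mean_anchor_distance(population, dwell_by_emotion)
    per_jump = (s_target * n_pairs - (n_pairs - jump_pairs) * j_step) / (J * (1.0 - v) ** 2)
    amp = max((per_jump**2 - ed**2) / (2.0 * per_jump), 0.01) if per_jump > ed else 0.01
    return GroupGazeProfile(
        group_label=group,
        per_emotion_dwell=dwell_by_emotion,
        fixation_jitter_sd=_JITTER_SD,
        saccades_per_second=rate,
        saccade_amplitude=amp,
        invalid_sample_rate=v,
    )


def default_profiles(population: str) -> dict[str, GroupGazeProfile]:
    """Calibrated per-group profiles reproducing the published group x emotion means."""
    if population == "adult":
        targets = ADULT_TARGETS
    elif population == "child":
        targets = CHILD_TARGETS
    else:
        raise ValueError(f"unknown population {population!r}; valid options: 'adult', 'child'")
    return {g: _calibrate_profile(population, g, t) for g, t in targets.items()}


def null_profiles(population: str) -> dict[str, GroupGazeProfile]:
    """All groups share the control generative process (labels differ only)."""
    base = default_profiles(population)["control"]
    return {g: replace(base, group_label=g) for g in default_profiles(population)}


def expected_features(
    profile: GroupGazeProfile, emotion: str, config: CohortConfig | None = None
) -> dict[str, float]:
    """Semi-analytic expectations of the trial features under one profile cell.

    Fixation counts and the saccade count are closed-form; the per-jump path
    length integrates the anchor geometry by a small fixed-seed Monte Carlo.
    """
    if config is None:
        config = CohortConfig(groups=[(profile, 1)])
    n = config.n_samples_per_trial
    v = profile.invalid_sample_rate
    J = _n_jumps(profile, emotion, config)
    dwell = profile.per_emotion_dwell[emotion]
    fix_budget = (n - 2 * J) * (1.0 - v)
    rng = np.random.default_rng(7654321)
    aoi = _representative_aoi(config.population, emotion)
    probs = np.array([dwell[c] for c in AOI_CATEGORIES])
    cats = rng.choice(len(AOI_CATEGORIES), size=600, p=probs)
    anchors = np.array([_anchor(AOI_CATEGORIES[c], aoi, rng) for c in cats])
    a_prev, a_next = anchors[:-1], anchors[1:]
    theta = rng.uniform(0, 2 * np.pi, size=len(a_next))
    t = a_next + profile.saccade_amplitude * np.column_stack([np.cos(theta), np.sin(theta)])
    t = np.clip(t, 0.0, 1.0)
    per_jump = np.linalg.norm(t - a_prev, axis=1) + np.linalg.norm(t - a_next, axis=1)
    n_pairs = (n - 1) * (1.0 - v) ** 2
    jump_pairs = 2.0 * J * (1.0 - v) ** 2
    scan = ((n_pairs - jump_pairs) * _jitter_step_mean(profile.fixation_jitter_sd)
            + J * (1.0 - v) ** 2 * float(per_jump.mean())) / n_pairs
    return {
        "fix_eyes": fix_budget * dwell["eyes"],
        "fix_nose": fix_budget * dwell["nose"],
        "fix_mouth": fix_budget * dwell["mouth"],
        "fix_anywhere": fix_budget,
        "n_saccades": float(J),
        "scan_path_length": scan,
        "valid_fraction": 1.0 - v,
    }


# ---------------------------------------------------------------------------
# Cohort assembly and on-disk layout.
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    population: str
    manifest: pd.DataFrame  # participant_id, group, trial_id, face_number, emotion, stimulus_id, presentation_order
    trials: dict[str, pd.DataFrame]
    aois: dict[int, AOIMap]
    config: CohortConfig


def simulate_cohort(config: CohortConfig) -> Cohort:
    """One participant record per configured slot, full stimulus bank each."""
    fmap = face_emotion_map(config.population)
    faces = sorted(fmap)
    ss = np.random.SeedSequence(config.seed)
    rows = []
    trials: dict[str, pd.DataFrame] = {}
    aois = {f: default_aoi(config.population, f) for f in faces}
    for profile, n_participants in config.groups:
        for i in range(n_participants):
            pid = f"{profile.group_label}{i + 1:02d}"
            prng = np.random.default_rng(ss.spawn(1)[0])
            order = prng.permutation(len(faces))
            for rank, idx in enumerate(order):
                face = faces[idx]
                emotion = fmap[face]
                trial_id = f"{pid}_f{face:02d}"
                trials[trial_id] = simulate_trial(profile, emotion, config, prng, aoi=aois[face])
                rows.append(
                    {
                        "participant_id": pid,
                        "group": profile.group_label,
                        "trial_id": trial_id,
                        "face_number": face,
                        "emotion": emotion,
                        "stimulus_id": aois[face].stimulus_id,
                        "presentation_order": rank,
                    }
                )
    manifest = pd.DataFrame(rows).sort_values(["participant_id", "face_number"]).reset_index(drop=True)
    return Cohort(config.population, manifest, trials, aois, config)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Manifest CSV + one gaze TSV per trial + AOI YAML per stimulus."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    gaze_dir = os.path.join(out_dir, "gaze")
    aoi_dir = os.path.join(out_dir, "aoi")
    os.makedirs(gaze_dir, exist_ok=True)
    os.makedirs(aoi_dir, exist_ok=True)
    cohort.manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    for trial_id, gaze in cohort.trials.items():
        gaze.to_csv(os.path.join(gaze_dir, f"{trial_id}.tsv"), sep="\t", index=False)
    for face, aoi in cohort.aois.items():
        aoi.save_yaml(os.path.join(aoi_dir, f"{aoi.stimulus_id}.yaml"))


def read_cohort(in_dir, population: str | None = None) -> Cohort:
    import os

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    if population is None:
        population = "adult" if manifest["face_number"].max() <= 21 else "child"
    trials = {}
    for trial_id in manifest["trial_id"]:
        trials[trial_id] = pd.read_csv(os.path.join(in_dir, "gaze", f"{trial_id}.tsv"), sep="\t")
    aois = {}
    for face, sid in manifest[["face_number", "stimulus_id"]].drop_duplicates().itertuples(index=False):
        aois[face] = AOIMap.load_yaml(os.path.join(in_dir, "aoi", f"{sid}.yaml"))
    base = default_profiles(population)
    fallback = replace(base["control"], group_label="unknown")
    groups = [
        (base.get(g, replace(fallback, group_label=g)), n)
        for g, n in manifest.groupby("group")["participant_id"].nunique().items()
    ]
    config = CohortConfig(groups=groups, population=population)
    return Cohort(population, manifest, trials, aois, config)
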