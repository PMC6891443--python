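"""Synthetic dermoscopy-like scene generator.

Stands in for clinical acquisition: renders dermoscope-vignetted skin-mole
scenes with controlled variability (mole colour from light brown to black,
three sizes, circle/oval/irregular shapes, regular/irregular borders,
optional hair or beard), negative scenes of lens artifacts and backgrounds
(dust, smudges, plain, fabric), and applies graded blur degradations with a
parameter-defined focus label: a Gaussian blur of ``sigma >=
FOCUS_SIGMA_THRESHOLD`` (or a motion streak of length >= 5 px) makes an
image *non-focused* by construction.

Everything is deterministic given the master seed.  Preview and acquired
pictures differ only by resolution (720 x 1280 vs 1080 x 1920), matching the
two assessment stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import convolve, gaussian_filter

from .image import RawImage, SourceRole

__all__ = [
    "SceneSpec",
    "DegradationSpec",
    "FOCUS_SIGMA_THRESHOLD",
    "FOCUS_MOTION_THRESHOLD",
    "PREVIEW_RESOLUTION",
    "ACQUIRED_RESOLUTION",
    "MOLE_PALETTES",
    "sample_scene_spec",
    "render_mole_scene",
    "render_artifact_scene",
    "degrade",
    "is_focused",
    "build_plan",
    "realize_record",
    "generate_feature_table",
    "generate_dataset",
    "ARTIFACT_KINDS",
]

PREVIEW_RESOLUTION = (720, 1280)   # (H, W)
ACQUIRED_RESOLUTION = (1080, 1920)

#: Gaussian sigma (px) at or above which a degraded scene is labelled
#: non-focused.  A parameter-defined ground truth, not a perceptual one.
FOCUS_SIGMA_THRESHOLD = 1.5
FOCUS_MOTION_THRESHOLD = 5  # px

MOLE_PALETTES = {
    "light_brown": (150, 110, 80),
    "brown": (120, 82, 55),
    "dark_brown": (82, 52, 36),
    "black": (42, 32, 26),
}

SKIN_TONES = [
    (239, 208, 187),
    (224, 172, 150),
    (198, 134, 103),
    (172, 112, 85),
    (141, 85, 60),
]

SIZE_RADIUS_FRACTION = {"small": 0.06, "medium": 0.10, "big": 0.14}
HAIR_COUNT = {"none": 0, "few": 3, "many": 10, "beard": 25}
ARTIFACT_KINDS = ("dust", "smudge", "plain", "fabric")


@dataclass
class SceneSpec:
    subject_id: str
    mole_color: str = "brown"
    size: str = "medium"
    shape: str = "circle"          # circle | oval | irregular
    border: str = "regular"        # regular | irregular
    hair: str = "none"             # none | few | many | beard
    skin_tone: tuple = SKIN_TONES[1]
    texture_amplitude: float = 6.0
    vignette_radius: float = 0.48  # fraction of min(H, W)
    resolution: tuple = PREVIEW_RESOLUTION

    def __post_init__(self) -> None:
        if self.mole_color not in MOLE_PALETTES:
            raise ValueError(f"unknown mole colour {self.mole_color!r}")
        if self.size not in SIZE_RADIUS_FRACTION:
            raise ValueError(f"unknown size {self.size!r}")
        if self.shape not in ("circle", "oval", "irregular"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.border not in ("regular", "irregular"):
            raise ValueError(f"unknown border {self.border!r}")
        if self.hair not in HAIR_COUNT:
            raise ValueError(f"unknown hair level {self.hair!r}")


@dataclass
class DegradationSpec:
    blur_kind: str = "none"        # none | gaussian | motion
    sigma: float = 0.0             # gaussian blur, px
    length: int = 0                # motion blur streak, px
    angle: float = 0.0             # motion blur direction, degrees
    sensor_noise_sd: float = 0.0   # additive Gaussian noise, intensity units

    def __post_init__(self) -> None:
        if self.blur_kind not in ("none", "gaussian", "motion"):
            raise ValueError(f"unknown blur kind {self.blur_kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")


def is_focused(spec: DegradationSpec) -> bool:
    """Parameter-defined focus label for a degradation."""
    if spec.blur_kind == "gaussian" and spec.sigma >= FOCUS_SIGMA_THRESHOLD:
        return False
    if spec.blur_kind == "motion" and spec.length >= FOCUS_MOTION_THRESHOLD:
        return False
    return True


# ----------------------------------------------------------------- scenes

def sample_scene_spec(
    subject_id: str, seed: int, resolution: tuple = PREVIEW_RESOLUTION
) -> SceneSpec:
    """Draw a scene specification from the study's attribute vocabulary."""
    rng = np.random.default_rng(seed)
    return SceneSpec(
        subject_id=subject_id,
        mole_color=str(rng.choice(list(MOLE_PALETTES))),
        size=str(rng.choice(list(SIZE_RADIUS_FRACTION))),
        shape=str(rng.choice(["circle", "oval", "irregular"])),
        border=str(rng.choice(["regular", "irregular"])),
        hair=str(rng.choice(list(HAIR_COUNT), p=[0.45, 0.25, 0.2, 0.1])),
        skin_tone=tuple(SKIN_TONES[rng.integers(len(SKIN_TONES))]),
        resolution=resolution,
    )


def _skin_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.resolution
    base = np.asarray(spec.skin_tone, dtype=np.float64)
    img = np.empty((h, w, 3))
    tex = gaussian_filter(rng.standard_normal((h, w)), 3.0)
    tex *= spec.texture_amplitude / max(tex.std(), 1e-9)
    gy, gx = np.mgrid[0:h, 0:w]
    shade = 6.0 * (gx / w - 0.5) + 4.0 * (gy / h - 0.5)  # gentle illumination tilt
    for c in range(3):
        img[:, :, c] = base[c] + tex + shade
    return img


def _mole_alpha(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Anti-aliased mole coverage in [0, 1] and its maximal extent in px."""
    h, w = spec.resolution
    m = min(h, w)
    radius = SIZE_RADIUS_FRACTION[spec.size] * m
    cy = h / 2 + rng.uniform(-0.03, 0.03) * m
    cx = w / 2 + rng.uniform(-0.03, 0.03) * m
    gy, gx = np.mgrid[0:h, 0:w]
    dy, dx = gy - cy, gx - cx

    if spec.shape == "oval":
        phi = rng.uniform(0, np.pi)
        ax_ratio = rng.uniform(0.55, 0.75)
        u = (dx * np.cos(phi) + dy * np.sin(phi))
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / ax_ratio
        dist = np.sqrt(u * u + v * v)
    else:
        dist = np.sqrt(dx * dx + dy * dy)

    theta = np.arctan2(dy, dx)
    boundary = np.full_like(theta, radius)
    wobble = 0.0
    if spec.shape == "irregular":
        for k in range(2, 6):
            a = rng.normal(0.0, 0.05)
            boundary += radius * a * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
            wobble += abs(a)
    if spec.border == "irregular":
        for k in rng.integers(8, 17, size=3):
            a = rng.normal(0.0, 0.02)
            boundary += radius * a * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
            wobble += abs(a)

    edge = 1.5 if spec.border == "regular" else 1.0
    alpha = np.clip((boundary - dist) / edge + 0.5, 0.0, 1.0)
    extent = radius * (1.0 + wobble) + 0.03 * m
    return alpha, extent


def _draw_hairs(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    n = HAIR_COUNT[spec.hair]
    if n == 0:
        return
    h, w = spec.resolution
    m = min(h, w)
    mask = np.zeros((h, w))
    t = np.linspace(0.0, 1.0, 400)
    for _ in range(n):
        # quadratic Bezier stroke through the central region
        p = rng.uniform([h * 0.2, w * 0.25], [h * 0.8, w * 0.75], size=(3, 2))
        curve = (
            np.outer((1 - t) ** 2, p[0])
            + np.outer(2 * (1 - t) * t, p[1])
            + np.outer(t**2, p[2])
        )
        ys = np.clip(np.round(curve[:, 0]).astype(int), 0, h - 1)
        xs = np.clip(np.round(curve[:, 1]).astype(int), 0, w - 1)
        mask[ys, xs] = 1.0
        mask[np.clip(ys + 1, 0, h - 1), xs] = 1.0  # ~2 px thickness
    mask = np.clip(gaussian_filter(mask, 0.6) * 3.0, 0.0, 1.0)
    hair_rgb = np.array([45.0, 35.0, 28.0])
    for c in range(3):
        img[:, :, c] = img[:, :, c] * (1 - 0.9 * mask) + hair_rgb[c] * 0.9 * mask


def _apply_vignette(img: np.ndarray, vignette_radius: float) -> None:
    h, w = img.shape[:2]
    rad = vignette_radius * min(h, w)
    gy, gx = np.mgrid[0:h, 0:w]
    dist = np.sqrt((gy - h / 2) ** 2 + (gx - w / 2) ** 2)
    factor = np.clip((rad - dist) / 15.0, 0.0, 1.0) * 0.97 + 0.03
    img *= factor[:, :, None]


def render_mole_scene(spec: SceneSpec, seed: int) -> RawImage:
    """Render an in-focus synthetic dermoscopy scene (sharp by construction)."""
    rng = np.random.default_rng(seed)
    img = _skin_background(spec, rng)
    alpha, extent = _mole_alpha(spec, rng)
    rad_v = spec.vignette_radius * min(spec.resolution)
    if extent >= rad_v:
        raise ValueError(
            f"mole extent {extent:.0f} px exceeds vignette radius {rad_v:.0f} px"
        )
    mole = np.asarray(MOLE_PALETTES[spec.mole_color], dtype=np.float64)
    speckle = gaussian_filter(rng.standard_normal(alpha.shape), 1.5) * 8.0
    for c in range(3):
        img[:, :, c] = img[:, :, c] * (1 - alpha) + (mole[c] + speckle) * alpha
    _draw_hairs(img, spec, rng)
    _apply_vignette(img, spec.vignette_radius)
    role = SourceRole.PREVIEW if spec.resolution == PREVIEW_RESOLUTION else SourceRole.ACQUIRED
    return RawImage(np.clip(np.round(img), 0, 255).astype(np.uint8), source_role=role)


def render_artifact_scene(
    kind: str, seed: int, resolution: tuple = PREVIEW_RESOLUTION
) -> RawImage:
    """Render a negative scene: lens artifacts or a mole-free background."""
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    rng = np.random.default_rng(seed)
    h, w = resolution
    meta: dict = {"kind": kind}
    gy, gx = np.mgrid[0:h, 0:w]
    base = rng.uniform(120, 210)
    img = np.full((h, w, 3), base)
    img += (8.0 * (gx / w - 0.5) + 5.0 * (gy / h - 0.5))[:, :, None]

    if kind == "dust":
        n = int(rng.integers(10, 41))
        meta["n_specks"] = n
        for _ in range(n):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            sig = rng.uniform(1.0, 3.0)
            amp = rng.uniform(40, 120) * rng.choice([-1.0, 1.0])
            yy0, yy1 = int(max(cy - 12, 0)), int(min(cy + 13, h))
            xx0, xx1 = int(max(cx - 12, 0)), int(min(cx + 13, w))
            sy, sx = np.mgrid[yy0:yy1, xx0:xx1]
            blob = amp * np.exp(-((sy - cy) ** 2 + (sx - cx) ** 2) / (2 * sig**2))
            img[yy0:yy1, xx0:xx1] += blob[:, :, None]
    elif kind == "smudge":
        blotch = gaussian_filter(rng.standard_normal((h, w)), 40.0)
        blotch *= 25.0 / max(blotch.std(), 1e-9)
        img += blotch[:, :, None]
    elif kind == "plain":
        img += rng.normal(0.0, 1.0, size=(h, w, 1))
    elif kind == "fabric":
        period = rng.uniform(8, 20)
        phi = rng.uniform(0, np.pi)
        u = gx * np.cos(phi) + gy * np.sin(phi)
        v = -gx * np.sin(phi) + gy * np.cos(phi)
        weave = 12.0 * np.sin(2 * np.pi * u / period) + 12.0 * np.sin(2 * np.pi * v / period)
        img += (weave + rng.normal(0, 2.0, size=(h, w)))[:, :, None]

    out = RawImage(
        np.clip(np.round(img), 0, 255).astype(np.uint8), source_role=SourceRole.PREVIEW
    )
    out.meta.update(meta)
    return out


def _motion_kernel(length: int, angle: float) -> np.ndarray:
    k = np.zeros((length, length))
    c = (length - 1) / 2
    t = np.linspace(-c, c, 4 * length)
    ys = np.round(c + t * np.sin(np.deg2rad(angle))).astype(int)
    xs = np.round(c + t * np.cos(np.deg2rad(angle))).astype(int)
    k[np.clip(ys, 0, length - 1), np.clip(xs, 0, length - 1)] = 1.0
    return k / k.sum()


def degrade(image: RawImage, spec: DegradationSpec, seed: int = 0) -> RawImage:
    """Apply blur then sensor noise; an identity spec returns the input copy."""
    px = image.pixels.astype(np.float64)
    if spec.blur_kind == "gaussian" and spec.sigma > 0:
        px = np.stack(
            [gaussian_filter(px[:, :, c], spec.sigma, mode="reflect") for c in range(3)],
            axis=2,
        )
    elif spec.blur_kind == "motion" and spec.length > 1:
        k = _motion_kernel(spec.length, spec.angle)
        px = np.stack(
            [convolve(px[:, :, c], k, mode="reflect") for c in range(3)], axis=2
        )
    if spec.sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        px = px + rng.normal(0.0, spec.sensor_noise_sd, size=px.shape)
    out = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return RawImage(out, source_role=image.source_role, meta=dict(image.meta))


# ----------------------------------------------------------------- dataset

_ROLE_RESOLUTION = {"preview": PREVIEW_RESOLUTION, "acquired": ACQUIRED_RESOLUTION}


def build_plan(
    n_subjects: int = 14,
    scenes_per_subject: int = 2,
    class_mix: dict | None = None,
    seed: int = 0,
    roles: tuple = ("preview", "acquired"),
    sensor_noise_sd: float = 2.0,
) -> list[dict]:
    """Deterministic dataset plan: one record per image to be emitted.

    Every focused mole image has a non-focused counterpart from the same
    scene; artifact scenes (preview role only) are added in the proportion
    given by ``class_mix`` (default: equal thirds).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    mix = class_mix or {"focused": 1 / 3, "non_focused": 1 / 3, "artifact": 1 / 3}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")

    root = np.random.SeedSequence(seed)
    records: list[dict] = []
    scene_states = root.generate_state(n_subjects * scenes_per_subject * 4 + 64)
    si = 0

    for s in range(n_subjects):
        subject = f"s{s + 1:02d}"
        for sc in range(scenes_per_subject):
            scene_seed = int(scene_states[si] % (2**31 - 1)); si += 1
            blur_seed = int(scene_states[si] % (2**31 - 1)); si += 1
            rng = np.random.default_rng(blur_seed)
            sigma = float(rng.uniform(2.0, 8.0))
            for role in roles:
                spec = sample_scene_spec(subject, scene_seed, _ROLE_RESOLUTION[role])
                common = {
                    "subject_id": subject,
                    "role": role,
                    "scene_seed": scene_seed,
                    "scene_index": sc,
                    "artifact_kind": "",
                }
                records.append(
                    {
                        **common,
                        "image_id": f"{subject}_{sc}_{role}_focused",
                        "label": "focused",
                        "blur_kind": "none",
                        "sigma": 0.0,
                        "noise_sd": sensor_noise_sd,
                        "noise_seed": blur_seed,
                    }
                )
                records.append(
                    {
                        **common,
                        "image_id": f"{subject}_{sc}_{role}_blurred",
                        "label": "non_focused",
                        "blur_kind": "gaussian",
                        "sigma": sigma,
                        "noise_sd": sensor_noise_sd,
                        "noise_seed": blur_seed + 1,
                    }
                )

    n_focused_preview = n_subjects * scenes_per_subject
    n_artifacts = int(round(n_focused_preview * mix["artifact"] / max(mix["focused"], 1e-9)))
    art_states = root.spawn(1)[0].generate_state(max(n_artifacts, 1))
    for a in range(n_artifacts):
        kind = ARTIFACT_KINDS[a % len(ARTIFACT_KINDS)]
        art_seed = int(art_states[a] % (2**31 - 1))
        records.append(
            {
                "subject_id": f"a{a + 1:02d}",
                "role": "preview",
                "scene_seed": art_seed,
                "scene_index": 0,
                "artifact_kind": kind,
                "image_id": f"artifact_{a:02d}_{kind}",
                "label": "artifact",
                "blur_kind": "none",
                "sigma": 0.0,
                "noise_sd": sensor_noise_sd,
                "noise_seed": art_seed + 1,
            }
        )
    return records


def realize_record(record: dict) -> RawImage:
    """Render (and degrade) the image a plan record describes."""
    resolution = _ROLE_RESOLUTION[record["role"]]
    if record["label"] == "artifact":
        img = render_artifact_scene(record["artifact_kind"], record["scene_seed"], resolution)
    else:
        spec = sample_scene_spec(record["subject_id"], record["scene_seed"], resolution)
        img = render_mole_scene(spec, record["scene_seed"])
    deg = DegradationSpec(
        blur_kind=record["blur_kind"],
        sigma=record["sigma"],
        sensor_noise_sd=record["noise_sd"],
    )
    return degrade(img, deg, seed=record["noise_seed"])


def generate_feature_table(
    n_subjects: int = 14,
    scenes_per_subject: int = 2,
    seed: int = 0,
    roles: tuple = ("preview", "acquired"),
    crop_fraction: float = 0.7,
    class_mix: dict | None = None,
) -> pd.DataFrame:
    """Generate the dataset in memory and extract the full feature table."""
    from .features import extract_features_image

    records = build_plan(
        n_subjects=n_subjects,
        scenes_per_subject=scenes_per_subject,
        class_mix=class_mix,
        seed=seed,
        roles=roles,
    )
    rows = []
    for rec in records:
        feats = extract_features_image(realize_record(rec), crop_fraction)
        rows.append(
            {
                "image_id": rec["image_id"],
                "label": rec["label"],
                "subject_id": rec["subject_id"],
                "role": rec["role"],
                **feats,
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(
    out_dir: str | Path,
    n_subjects: int = 14,
    scenes_per_subject: int = 2,
    class_mix: dict | None = None,
    seed: int = 0,
    roles: tuple = ("preview", "acquired"),
) -> pd.DataFrame:
    """Write PNG images, a CSV manifest and a JSON config snapshot.

    Returns the manifest (one row per emitted file)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "images").mkdir(exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e

    records = build_plan(
        n_subjects=n_subjects,
        scenes_per_subject=scenes_per_subject,
        class_mix=class_mix,
        seed=seed,
        roles=roles,
    )
    rows = []
    for rec in records:
        img = realize_record(rec)
        rel = f"images/{rec['image_id']}.png"
        Image.fromarray(img.pixels).save(out / rel)
        rows.append({**rec, "image_path": rel, "seed": seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "generation_config.json").write_text(
        json.dumps(
            {
                "n_subjects": n_subjects,
                "scenes_per_subject": scenes_per_subject,
                "class_mix": class_mix or {"focused": 1 / 3, "non_focused": 1 / 3, "artifact": 1 / 3},
                "seed": seed,
                "roles": list(roles),
                "focus_sigma_threshold": FOCUS_SIGMA_THRESHOLD,
            },
            indent=2,
        )
    )
    return manifest
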