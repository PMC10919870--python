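"""Procedural face-like stimuli with known, independent generative factors.

Each image is governed by a small set of factors that mirror the semantic
axes a disentangled generative model discovers on real face photographs:
viewpoint rotation, lighting direction, background shade, smile, face width,
skin tone, hair size, and a gender-proxy (brow prominence).  Factors are
sampled independently and uniformly within their ranges, so the generator's
ground truth is exactly the independence assumption a disentangled latent
space tries to recover.

Identity is defined by the identity-relevant factors (face width, skin tone,
hair size, gender proxy); rotation, lighting, background and smile can vary
without changing who the face "is".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FactorSpec",
    "FaceScene",
    "SyntheticDataset",
    "default_factor_specs",
    "render_face",
    "face_mask",
    "sample_dataset",
]

_RENDERER_ROLES = frozenset(
    {
        "rotation",
        "lighting",
        "background",
        "face_width",
        "skin_tone",
        "smile",
        "hair_size",
        "gender_proxy",
    }
)

# geometry of the mouth, shared with the renderer and exposed so tests can
# evaluate the curve formula independently of the rasterizer
MOUTH_HALF_WIDTH = 0.11
MOUTH_THICKNESS = 0.022
MOUTH_CURVE_AMP = 0.05
MOUTH_CENTER_Y = 0.70


@dataclass(frozen=True)
class FactorSpec:
    """One generative factor: a named real-valued axis with a closed range."""

    name: str
    identity_relevant: bool
    range: tuple[float, float] = (-1.0, 1.0)
    renderer_role: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not (np.isfinite(lo) and np.isfinite(hi)) or not lo < hi:
            raise ValueError(
                f"factor {self.name!r}: range must be finite and non-degenerate, got {self.range}"
            )
        role = self.renderer_role or self.name
        if role not in _RENDERER_ROLES:
            raise ValueError(f"factor {self.name!r}: unknown renderer_role {role!r}")
        object.__setattr__(self, "renderer_role", role)


@dataclass(frozen=True)
class FaceScene:
    """A single stimulus: one value per factor, each inside its range."""

    factor_values: tuple[float, ...]

    @staticmethod
    def from_array(values: np.ndarray) -> "FaceScene":
        return FaceScene(tuple(float(v) for v in np.asarray(values, dtype=float)))


def default_factor_specs() -> list[FactorSpec]:
    """Eight factors: four identity-irrelevant, four identity-relevant."""
    return [
        FactorSpec("rotation", False, (-1.0, 1.0), "rotation"),
        FactorSpec("lighting", False, (-1.0, 1.0), "lighting"),
        FactorSpec("background", False, (-1.0, 1.0), "background"),
        FactorSpec("smile", False, (-1.0, 1.0), "smile"),
        FactorSpec("face_width", True, (-1.0, 1.0), "face_width"),
        FactorSpec("skin_tone", True, (-1.0, 1.0), "skin_tone"),
        FactorSpec("hair_size", True, (-1.0, 1.0), "hair_size"),
        FactorSpec("gender_proxy", True, (-1.0, 1.0), "gender_proxy"),
    ]


def _validate_scene(scene: FaceScene, spec: list[FactorSpec]) -> dict[str, float]:
    if len(scene.factor_values) != len(spec):
        raise ValueError(
            f"scene has {len(scene.factor_values)} values but spec lists {len(spec)} factors"
        )
    names = [s.name for s in spec]
    if len(set(names)) != len(names):
        raise ValueError("factor names must be unique within a spec list")
    values: dict[str, float] = {}
    for s, v in zip(spec, scene.factor_values):
        lo, hi = s.range
        if not lo <= v <= hi:
            raise ValueError(
                f"factor {s.name!r} value {v} outside its range [{lo}, {hi}]"
            )
        # normalize to [-1, 1] for the renderer regardless of declared range
        values[s.renderer_role] = 2.0 * (v - lo) / (hi - lo) - 1.0
    return values


def _face_geometry(f: dict[str, float]) -> tuple[float, float, float, float]:
    """Center and semi-axes of the face ellipse in unit coordinates."""
    cx, cy = 0.5, 0.54
    a = 0.26 * (1.0 + 0.18 * f.get("face_width", 0.0))
    b = 0.36
    return cx, cy, a, b


def face_mask(scene: FaceScene, spec: list[FactorSpec], side: int) -> np.ndarray:
    """Boolean mask of pixels inside the face ellipse (background excluded)."""
    f = _validate_scene(scene, spec)
    cx, cy, a, b = _face_geometry(f)
    u = (np.arange(side) + 0.5) / side
    xx, yy = np.meshgrid(u, u)
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def mouth_dark_area(smile: float) -> float:
    """Analytic area (unit coords) of the dark mouth region as a function of smile.

    The mouth is the region between a straight bottom lip and a parabolic top
    lip whose bow scales with the smile factor; its area is the integral of
    max(0, thickness + smile*amp*(1-u^2)) over the mouth width.  Used as an
    independent oracle for the rendered mouth.
    """
    u = np.linspace(-1.0, 1.0, 2001)
    h = np.maximum(0.0, MOUTH_THICKNESS + smile * MOUTH_CURVE_AMP * (1.0 - u**2))
    return float(np.trapezoid(h, u) * MOUTH_HALF_WIDTH)


def render_face(scene: FaceScene, spec: list[FactorSpec], side: int = 64) -> np.ndarray:
    """Rasterize a scene to a grayscale float32 image in [0, 1].

    Deterministic given (scene, spec, side).  Each renderer role maps to a
    visually distinct property: background fills the region outside the face,
    lighting applies a horizontal brightness gradient, rotation shifts the
    internal features, smile bows the mouth, etc.
    """
    if side < 32:
        raise ValueError(f"side must be >= 32, got {side}")
    f = _validate_scene(scene, spec)

    u = (np.arange(side) + 0.5) / side
    xx, yy = np.meshgrid(u, u)
    cx, cy, a, b = _face_geometry(f)
    in_face = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    # hair: a cap ring above the face, thickness driven by hair_size
    t = 0.045 + 0.035 * (f.get("hair_size", 0.0) + 1.0) / 2.0
    in_hair = (
        (((xx - cx) / (a + t)) ** 2 + ((yy - cy) / (b + t)) ** 2 <= 1.0)
        & ~in_face
        & (yy < cy - 0.10)
    )

    img = np.full((side, side), 0.50 + 0.35 * f.get("background", 0.0))
    img[in_hair] = 0.12
    img[in_face] = 0.55 + 0.18 * f.get("skin_tone", 0.0)

    dx = 0.055 * f.get("rotation", 0.0)

    # eyes
    for sign in (-1.0, 1.0):
        ex = cx + sign * 0.105 * (1.0 - 0.25 * abs(f.get("rotation", 0.0))) + dx
        ey = cy - 0.085
        eye = ((xx - ex) ** 2 + (yy - ey) ** 2) <= 0.026**2
        img[eye & in_face] = 0.15

    # brow bar: thickness/darkness carry the gender proxy
    g = (f.get("gender_proxy", 0.0) + 1.0) / 2.0
    bt = 0.012 + 0.016 * g
    brow = (
        (np.abs(yy - (cy - 0.145)) <= bt)
        & (np.abs(xx - (cx + dx)) <= 0.16)
        & in_face
    )
    img[brow] = 0.38 - 0.18 * g

    # nose
    nose = (
        (np.abs(xx - (cx + 1.3 * dx)) <= 0.013)
        & (yy >= cy - 0.02)
        & (yy <= cy + 0.07)
        & in_face
    )
    img[nose] = 0.32

    # mouth: region between a straight bottom lip and a parabolic top lip;
    # the bow (and hence the dark area) grows monotonically with smile
    mx = cx + dx
    my = MOUTH_CENTER_Y
    un = (xx - mx) / MOUTH_HALF_WIDTH
    curve = f.get("smile", 0.0) * MOUTH_CURVE_AMP * (1.0 - un**2)
    mouth = (
        (np.abs(un) <= 1.0)
        & (yy <= my + MOUTH_THICKNESS / 2.0)
        & (yy >= my + MOUTH_THICKNESS / 2.0 - (MOUTH_THICKNESS + curve))
        & in_face
    )
    img[mouth] = 0.18

    # lighting: horizontal multiplicative gradient over the whole image
    grad = 1.0 + 0.30 * f.get("lighting", 0.0) * (2.0 * xx - 1.0)
    img = img * grad

    return np.clip(img, 0.0, 1.0).astype(np.float32)


def mouth_region_mask(scene: FaceScene, spec: list[FactorSpec], side: int) -> np.ndarray:
    """Fixed-size box around the mouth (for factor-locality checks)."""
    f = _validate_scene(scene, spec)
    u = (np.arange(side) + 0.5) / side
    xx, yy = np.meshgrid(u, u)
    dx = 0.055 * f.get("rotation", 0.0)
    cx = 0.5 + dx
    return (np.abs(xx - cx) <= MOUTH_HALF_WIDTH) & (
        np.abs(yy - MOUTH_CENTER_Y) <= 0.09
    )


@dataclass
class SyntheticDataset:
    """A train/test stimulus set with its ground-truth factor matrices."""

    spec: list[FactorSpec]
    train_images: np.ndarray  # (n_train, side, side) float32
    train_factors: np.ndarray  # (n_train, n_factors)
    test_images: np.ndarray  # (20, side, side)
    test_factors: np.ndarray  # (20, n_factors)
    test_repeats: int
    seed: int
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return len(self.spec)

    @property
    def identity_relevant_mask(self) -> np.ndarray:
        return np.array([s.identity_relevant for s in self.spec], dtype=bool)


N_TEST_IMAGES = 20  # fixed size of the repeated test set


def sample_dataset(
    spec: list[FactorSpec] | None = None,
    n_train: int = 500,
    seed: int = 0,
    side: int = 64,
    render: bool = True,
) -> SyntheticDataset:
    """Sample a stimulus set: ``n_train`` single-presentation training faces
    plus 20 repeated test faces, factors i.i.d. uniform within range.

    ``render=False`` skips rasterization (factor matrices only) for analyses
    that never touch pixels.
    """
    if spec is None:
        spec = default_factor_specs()
    if n_train < 50:
        raise ValueError(f"n_train must be >= 50, got {n_train}")
    rng = np.random.default_rng(seed)
    lo = np.array([s.range[0] for s in spec])
    hi = np.array([s.range[1] for s in spec])
    k = len(spec)

    train_factors = rng.uniform(lo, hi, size=(n_train, k))
    rel = np.array([s.identity_relevant for s in spec], dtype=bool)
    # redraw test scenes until identities (relevant-factor vectors) are
    # pairwise distinct; continuous uniforms collide with probability zero
    # but degenerate ranges are guarded anyway
    for _ in range(100):
        test_factors = rng.uniform(lo, hi, size=(N_TEST_IMAGES, k))
        ident = test_factors[:, rel] if rel.any() else test_factors
        d = np.linalg.norm(ident[:, None, :] - ident[None, :, :], axis=-1)
        if np.all(d[np.triu_indices(N_TEST_IMAGES, 1)] > 1e-6):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not sample 20 distinct test identities")

    test_repeats = int(rng.integers(40, 61))

    def _render_all(mat: np.ndarray) -> np.ndarray:
        return np.stack(
            [render_face(FaceScene.from_array(row), spec, side) for row in mat]
        )

    if render:
        train_images = _render_all(train_factors)
        test_images = _render_all(test_factors)
    else:
        train_images = np.zeros((0, side, side), dtype=np.float32)
        test_images = np.zeros((0, side, side), dtype=np.float32)

    return SyntheticDataset(
        spec=spec,
        train_images=train_images,
        train_factors=train_factors,
        test_images=test_images,
        test_factors=test_factors,
        test_repeats=test_repeats,
        seed=seed,
        train_ids=[f"train_{i:05d}" for i in range(n_train)],
        test_ids=[f"test_{i:02d}" for i in range(N_TEST_IMAGES)],
    )
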