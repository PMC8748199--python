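"""Linear species unmixing in phasor space.

Because the phasor of a photon mixture is the photon-weighted convex
combination of the component phasors, per-pixel species fractions follow
from simple geometry: projection onto the anchor chord for two species,
barycentric coordinates in the anchor triangle for three. Anchors are the
pure-species phasor positions, taken either from known lifetimes or from
single-species calibration images. Fractions are photon-weight fractions,
not molecular abundances (converting would require relative brightness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TCSPCImage, SpeciesModel
from .phasor import PhasorField, phasor_transform, pooled_phasor, theoretical_phasor

__all__ = [
    "AnchorSet",
    "FractionMap",
    "anchors_from_lifetimes",
    "anchors_from_images",
    "unmix_two",
    "unmix_three",
    "cluster_assign",
    "separate_species_images",
    "six_species",
]

DEFAULT_FOREGROUND_THRESHOLD = 100  # photons per pixel
_MIN_ANCHOR_DISTANCE = 1e-3
_MIN_TRIANGLE_AREA = 1e-6  # permits close-spaced lifetime triples (e.g. 3.1/3.4/3.7 ns)


@dataclass(frozen=True)
class AnchorSet:
    """Pure-species phasor positions for one spectral channel."""

    channel: str
    anchors: tuple[tuple[str, float, float], ...]  # (name, g, s)
    source: str = "lifetimes"  # lifetimes | calibration_images

    def __post_init__(self) -> None:
        if len(self.anchors) not in (2, 3):
            raise ValueError("an AnchorSet holds 2 or 3 anchors")
        pts = self.points
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = np.hypot(*(pts[i] - pts[j]))
                if d <= _MIN_ANCHOR_DISTANCE:
                    raise ValueError(
                        f"anchors {self.anchors[i][0]!r} and "
                        f"{self.anchors[j][0]!r} are not distinct (d={d:.2e})")
        if len(pts) == 3:
            u, v = pts[1] - pts[0], pts[2] - pts[0]
            area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
            if area <= _MIN_TRIANGLE_AREA:
                raise ValueError(f"anchor triangle is collinear (area={area:.2e})")

    @property
    def names(self) -> list[str]:
        return [a[0] for a in self.anchors]

    @property
    def points(self) -> np.ndarray:
        return np.array([[a[1], a[2]] for a in self.anchors])


@dataclass
class FractionMap:
    """Per-pixel species fractions in [0, 1], summing to 1 on foreground."""

    fractions: np.ndarray      # (rows, cols, n_species)
    clipped: np.ndarray        # bool, pixels projected back into the simplex
    foreground: np.ndarray     # bool
    species: list[str]
    channel: str = ""


def anchors_from_lifetimes(species: list[SpeciesModel], omega: float,
                           channel: str = "") -> AnchorSet:
    """Anchors at the theoretical mono-exponential phasor positions."""
    if len(species) not in (2, 3):
        raise ValueError("need 2 or 3 species")
    anchors = []
    for sp in species:
        if len(sp.components) != 1:
            raise ValueError(f"species {sp.name!r} is not mono-exponential")
        g, s = theoretical_phasor(sp.components[0][0], omega)
        anchors.append((sp.name, g, s))
    return AnchorSet(channel=channel, anchors=tuple(anchors), source="lifetimes")


def anchors_from_images(calibration_images: dict[str, TCSPCImage],
                        harmonic: int = 1, min_photons: float = 1e4,
                        foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD,
                        channel: str = "") -> AnchorSet:
    """Anchors from single-species calibration images (pooled foreground phasor).

    Supplying a mixed-species image places its anchor at the mixture's phasor
    (linearity): a documented misuse this routine cannot detect.
    """
    anchors = []
    for name, img in calibration_images.items():
        total = int(img.intensity.sum())
        if total < min_photons:
            raise ValueError(
                f"calibration image {name!r} has {total} photons; "
                f"need >= {min_photons:.0f}")
        field = phasor_transform(img, harmonic=harmonic)
        fg = field.intensity >= foreground_threshold
        if not fg.any():
            fg = field.valid
        g, s, _ = pooled_phasor(field, fg)
        anchors.append((name, g, s))
    return AnchorSet(channel=channel, anchors=tuple(anchors),
                     source="calibration_images")


def _foreground(field: PhasorField, threshold: float) -> np.ndarray:
    return field.valid & (field.intensity >= threshold)


def unmix_two(field: PhasorField, anchors: AnchorSet,
              foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD
              ) -> FractionMap:
    """Two-species fractions by orthogonal projection onto the anchor chord."""
    if len(anchors.anchors) != 2:
        raise ValueError("unmix_two needs exactly 2 anchors")
    A, B = anchors.points
    ab = B - A
    denom = float(ab @ ab)
    fg = _foreground(field, foreground_threshold)
    u_raw = ((field.g - A[0]) * ab[0] + (field.s - A[1]) * ab[1]) / denom
    u = np.clip(u_raw, 0.0, 1.0)
    fractions = np.stack([1.0 - u, u], axis=-1)
    fractions[~fg] = 0.0
    clipped = fg & ((u_raw < 0) | (u_raw > 1))
    return FractionMap(fractions=fractions, clipped=clipped, foreground=fg,
                       species=anchors.names, channel=anchors.channel)


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Project points (N, 2) onto segment a-b; return (u in [0,1], distance)."""
    ab = b - a
    u = np.clip(((p - a) @ ab) / float(ab @ ab), 0.0, 1.0)
    proj = a + u[:, None] * ab
    d = np.linalg.norm(p - proj, axis=1)
    return u, d


def unmix_three(field: PhasorField, anchors: AnchorSet,
                foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD
                ) -> FractionMap:
    """Three-species fractions as barycentric coordinates in the anchor
    triangle; out-of-triangle pixels are clipped to the nearest point of the
    triangle (fractions stay in the simplex, flagged)."""
    if len(anchors.anchors) != 3:
        raise ValueError("unmix_three needs exactly 3 anchors")
    pts = anchors.points  # (3, 2)
    M = np.vstack([pts.T, np.ones(3)])  # rows: g, s, 1
    Minv = np.linalg.inv(M)
    fg = _foreground(field, foreground_threshold)
    rows, cols = field.shape
    rhs = np.stack([field.g.ravel(), field.s.ravel(),
                    np.ones(rows * cols)])
    f = (Minv @ rhs).T  # (N, 3)
    outside = (f < -1e-12).any(axis=1)
    clipped_flat = outside & fg.ravel()
    if clipped_flat.any():
        idx = np.flatnonzero(clipped_flat)
        p = np.stack([field.g.ravel()[idx], field.s.ravel()[idx]], axis=1)
        best_d = np.full(idx.size, np.inf)
        best_f = np.zeros((idx.size, 3))
        for (i, j) in ((0, 1), (1, 2), (0, 2)):
            u, d = _project_to_segment(p, pts[i], pts[j])
            better = d < best_d
            best_d[better] = d[better]
            fr = np.zeros((idx.size, 3))
            fr[:, i] = 1.0 - u
            fr[:, j] = u
            best_f[better] = fr[better]
        f[idx] = best_f
    f = np.clip(f, 0.0, 1.0)
    f /= f.sum(axis=1, keepdims=True)
    fractions = f.reshape(rows, cols, 3)
    fractions[~fg] = 0.0
    return FractionMap(fractions=fractions,
                       clipped=clipped_flat.reshape(rows, cols),
                       foreground=fg, species=anchors.names,
                       channel=anchors.channel)


def cluster_assign(field: PhasorField, anchors: AnchorSet,
                   radius: float = 0.05,
                   foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD
                   ) -> tuple[np.ndarray, FractionMap]:
    """Hard cluster-circle assignment: each foreground pixel goes wholly to
    the nearest anchor if within ``radius`` in phasor space, else unassigned
    (-1). Returned fractions are one-hot."""
    pts = anchors.points
    fg = _foreground(field, foreground_threshold)
    d = np.stack([np.hypot(field.g - p[0], field.s - p[1]) for p in pts],
                 axis=-1)
    nearest = d.argmin(axis=-1)
    within = d.min(axis=-1) <= radius
    labels = np.where(fg & within, nearest, -1).astype(np.int32)
    k = len(pts)
    fractions = np.zeros(field.shape + (k,))
    assigned = labels >= 0
    fractions[assigned, labels[assigned]] = 1.0
    fmap = FractionMap(fractions=fractions, clipped=fg & ~within,
                       foreground=fg, species=anchors.names,
                       channel=anchors.channel)
    return labels, fmap


def separate_species_images(fmap: FractionMap, intensity: np.ndarray
                            ) -> dict[str, np.ndarray]:
    """Per-species intensity images (fraction x intensity); on foreground the
    per-species images sum exactly to the total intensity."""
    intensity = np.asarray(intensity, float)
    if intensity.shape != fmap.fractions.shape[:2]:
        raise ValueError("intensity shape does not match fraction map")
    out = {}
    for k, name in enumerate(fmap.species):
        img = fmap.fractions[..., k] * intensity
        img[~fmap.foreground] = 0.0
        out[name] = img
    return out


def six_species(channel_results: list[tuple[FractionMap, np.ndarray]]
                ) -> tuple[np.ndarray, list[str]]:
    """Compose two 3-species channels into a six-plane image stack.

    Returns (6, rows, cols) array plus "channel/species" labels.
    """
    if len(channel_results) != 2:
        raise ValueError("six_species needs exactly two channel results")
    planes, labels = [], []
    shape = None
    for fmap, intensity in channel_results:
        name = fmap.channel or f"channel{len(labels) // 3}"
        if not fmap.species:
            raise ValueError(f"channel {name!r} has no species")
        imgs = separate_species_images(fmap, intensity)
        if shape is None:
            shape = intensity.shape
        elif intensity.shape != shape:
            raise ValueError(
                f"channel {name!r} grid {intensity.shape} does not match {shape}")
        if not np.any(intensity):
            raise ValueError(f"channel {name!r} is empty (zero intensity)")
        for sp in fmap.species:
            planes.append(imgs[sp])
            labels.append(f"{name}/{sp}")
    return np.stack(planes), labels
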