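"""Synthetic FLIM scenes, TCSPC images, Fucci fields and kinetic traces.

Everything downstream (phasor transform, unmixing, reconvolution fitting,
biosensor classification, kinetics fits) is validated against data generated
here with known ground truth. Defaults emulate the study conditions: 80 MHz
repetition rate, ~1,000 photons per foreground pixel, mono-exponential
HaloTag7/9/10/11 species spanning 1.1-2.8 ns (MaP555) and 1.6-3.7 ns
(MaP618), subcellular structures (elliptical nuclei, curvilinear
mitochondria, Golgi-like blob clusters) and a uniform background.

Scene geometry is stylized - only the label/lifetime structure matters for
testing, not biophysical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk as disk_footprint

from .core import (
    AcquisitionConfig,
    IRF,
    SpeciesModel,
    TCSPCImage,
    histogram_times,
    sample_arrival_times,
)

__all__ = [
    "Structure",
    "Scene",
    "StructureSpec",
    "GroundTruth",
    "DEFAULT_SPECIES_MAP618",
    "DEFAULT_SPECIES_MAP555",
    "make_scene",
    "simulate_decay_histogram",
    "render_flim_image",
    "simulate_fucci_field",
    "simulate_anisotropy_trace",
    "simulate_titration",
]

# Mono-exponential lifetimes (ns) for the four HaloTag variants. The two MaP
# dyes span evenly spaced ranges of 1.1-2.8 ns and 1.6-3.7 ns across the
# tags, HaloTag9 longest and HaloTag10 shortest.
DEFAULT_SPECIES_MAP618: dict[str, SpeciesModel] = {
    "HaloTag10-MaP618": SpeciesModel.mono("HaloTag10-MaP618", 1.6),
    "HaloTag11-MaP618": SpeciesModel.mono("HaloTag11-MaP618", 2.3),
    "HaloTag7-MaP618": SpeciesModel.mono("HaloTag7-MaP618", 3.1),
    "HaloTag9-MaP618": SpeciesModel.mono("HaloTag9-MaP618", 3.7),
}
DEFAULT_SPECIES_MAP555: dict[str, SpeciesModel] = {
    "HaloTag10-MaP555": SpeciesModel.mono("HaloTag10-MaP555", 1.1),
    "HaloTag11-MaP555": SpeciesModel.mono("HaloTag11-MaP555", 1.7),
    "HaloTag7-MaP555": SpeciesModel.mono("HaloTag7-MaP555", 2.2),
    "HaloTag9-MaP555": SpeciesModel.mono("HaloTag9-MaP555", 2.8),
}

DEFAULT_FOREGROUND_PHOTONS = 1000.0  # photons per foreground pixel
DEFAULT_BACKGROUND_PHOTONS = 20.0    # photons per pixel, uniform in time


@dataclass(frozen=True)
class Structure:
    label: str
    mask: np.ndarray  # boolean (rows, cols)
    species_id: str
    mean_photons_per_pixel: float = DEFAULT_FOREGROUND_PHOTONS

    def __post_init__(self) -> None:
        if self.mean_photons_per_pixel < 0:
            raise ValueError(f"structure {self.label!r}: photon budget must be >= 0")


@dataclass
class Scene:
    shape: tuple[int, int]
    structures: list[Structure] = field(default_factory=list)
    background_rate: float = DEFAULT_BACKGROUND_PHOTONS

    def __post_init__(self) -> None:
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ValueError("structure labels must be unique")
        for s in self.structures:
            if s.mask.shape != tuple(self.shape):
                raise ValueError(f"mask of {s.label!r} does not match scene shape")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class StructureSpec:
    """Request for `make_scene`: how many structures of a kind and how big."""

    kind: str  # nucleus | mitochondria | golgi
    count: int
    size: float  # characteristic radius/half-length in pixels
    species_id: str
    mean_photons_per_pixel: float = DEFAULT_FOREGROUND_PHOTONS
    allow_overlap: bool = False


def _place_nucleus(rng, shape, size):
    r0 = rng.uniform(size, shape[0] - size)
    c0 = rng.uniform(size, shape[1] - size)
    a = size * rng.uniform(0.75, 1.0)
    b = size * rng.uniform(0.55, 0.85)
    rot = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(r0, c0, a, b, shape=shape, rotation=rot)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _place_mitochondria(rng, shape, size):
    # short correlated random walk, dilated to a 3-px-wide filament
    n_steps = max(8, int(4 * size))
    pos = np.array([rng.uniform(size, shape[0] - size),
                    rng.uniform(size, shape[1] - size)])
    ang = rng.uniform(0, 2 * np.pi)
    mask = np.zeros(shape, bool)
    for _ in range(n_steps):
        ang += rng.normal(0, 0.35)
        pos = pos + np.array([np.cos(ang), np.sin(ang)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            mask[r, c] = True
    return dilation(mask, disk_footprint(1)).astype(bool)


def _place_golgi(rng, shape, size):
    # cluster of small blobs around a center
    r0 = rng.uniform(size, shape[0] - size)
    c0 = rng.uniform(size, shape[1] - size)
    mask = np.zeros(shape, bool)
    for _ in range(rng.integers(3, 7)):
        dr, dc = rng.normal(0, size / 2, size=2)
        rad = max(1.5, size / 3 * rng.uniform(0.6, 1.2))
        rr, cc = draw_disk((r0 + dr, c0 + dc), rad, shape=shape)
        mask[rr, cc] = True
    return mask


_PLACERS = {"nucleus": _place_nucleus, "mitochondria": _place_mitochondria,
            "golgi": _place_golgi}


def make_scene(layout: Sequence[StructureSpec], shape: tuple[int, int],
               seed: int, background_rate: float = DEFAULT_BACKGROUND_PHOTONS,
               max_tries: int = 200) -> Scene:
    """Place the requested structures on the grid, deterministically per seed.

    Structures are kept disjoint unless a spec sets ``allow_overlap``.
    """
    shape = tuple(int(x) for x in shape)
    if shape[0] < 32 or shape[1] < 32:
        raise ValueError("scene must be at least 32x32")
    rng = np.random.default_rng(seed)
    occupied = np.zeros(shape, bool)
    structures: list[Structure] = []
    for spec in layout:
        if spec.kind not in _PLACERS:
            raise ValueError(f"unknown structure kind {spec.kind!r}")
        if 2 * spec.size >= min(shape):
            raise ValueError(
                f"structure {spec.kind!r} (size {spec.size}) does not fit the "
                f"{shape[0]}x{shape[1]} grid")
        placer = _PLACERS[spec.kind]
        for i in range(spec.count):
            for attempt in range(max_tries):
                mask = placer(rng, shape, spec.size)
                if mask.sum() == 0:
                    continue
                if spec.allow_overlap or not (mask & occupied).any():
                    break
            else:
                raise ValueError(
                    f"could not place {spec.kind!r} #{i} without overlap "
                    f"after {max_tries} tries")
            occupied |= mask
            structures.append(Structure(
                label=f"{spec.kind}_{len(structures)}", mask=mask,
                species_id=spec.species_id,
                mean_photons_per_pixel=spec.mean_photons_per_pixel))
    return Scene(shape=shape, structures=structures,
                 background_rate=background_rate)


def simulate_decay_histogram(species: SpeciesModel, n_photons: int, irf: IRF,
                             acq: AcquisitionConfig, seed: int) -> np.ndarray:
    """Draw ``n_photons`` arrival times from decay (x) IRF, folded into one
    period, and bin them. Total counts equal ``n_photons`` exactly."""
    rng = np.random.default_rng(seed)
    times = sample_arrival_times(species, int(n_photons), irf, acq, rng)
    return histogram_times(times, acq)


@dataclass
class GroundTruth:
    """Expected (not sampled) per-pixel photon attribution of a rendered image."""

    expected: dict[str, np.ndarray]  # species_id -> (rows, cols) expected photons
    background_rate: float
    species_ids: list[str]

    def fractions(self) -> np.ndarray:
        """Per-pixel expected photon fractions per species (bg excluded).

        Returns (rows, cols, n_species) with NaN where no species emits.
        """
        stack = np.stack([self.expected[s] for s in self.species_ids], axis=-1)
        tot = stack.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = stack / tot
        out[np.squeeze(tot, -1) == 0] = np.nan
        return out

    def foreground(self) -> np.ndarray:
        stack = np.stack([self.expected[s] for s in self.species_ids], axis=-1)
        return stack.sum(axis=-1) > 0


def _deposit_photons(counts: np.ndarray, pix_flat: np.ndarray,
                     times: np.ndarray, acq: AcquisitionConfig) -> None:
    tbin = np.clip((times / acq.bin_width).astype(np.intp), 0, acq.n_bins - 1)
    np.add.at(counts.reshape(-1, acq.n_bins), (pix_flat, tbin), 1)


def render_flim_image(scene: Scene, species_table: Mapping[str, SpeciesModel],
                      irf: IRF, acq: AcquisitionConfig, seed: int,
                      channel: str = "") -> tuple[TCSPCImage, GroundTruth]:
    """Render a scene into a TCSPC image plus its expectation ground truth.

    Per-pixel photon numbers are Poisson with mean = structure budget x
    species relative brightness (+ uniform background); arrival times follow
    the species decay convolved with the IRF, wrapped at the pulse period.
    """
    for s in scene.structures:
        if s.species_id not in species_table:
            raise KeyError(f"species_id {s.species_id!r} of structure "
                           f"{s.label!r} not in species table")
    rng = np.random.default_rng(seed)
    rows, cols = scene.shape
    counts = np.zeros((rows, cols, acq.n_bins), dtype=np.int64)
    expected: dict[str, np.ndarray] = {}
    for s in scene.structures:
        sp = species_table[s.species_id]
        mean = s.mean_photons_per_pixel * sp.relative_brightness
        exp_map = expected.setdefault(s.species_id, np.zeros((rows, cols)))
        exp_map[s.mask] += mean
        pix = np.flatnonzero(s.mask.ravel())
        n_px = rng.poisson(mean, size=pix.size)
        total = int(n_px.sum())
        if total == 0:
            continue
        times = sample_arrival_times(sp, total, irf, acq, rng)
        _deposit_photons(counts, np.repeat(pix, n_px), times, acq)
    if scene.background_rate > 0:
        n_px = rng.poisson(scene.background_rate, size=rows * cols)
        total = int(n_px.sum())
        if total > 0:
            times = rng.uniform(0, acq.period, size=total)
            _deposit_photons(counts, np.repeat(np.arange(rows * cols), n_px),
                             times, acq)
    img = TCSPCImage(counts=counts, acq=acq, channel=channel)
    gt = GroundTruth(expected=expected, background_rate=scene.background_rate,
                     species_ids=sorted(expected))
    return img, gt


_PHASES = ("G1", "S", "G2M")


def simulate_fucci_field(n_nuclei: int, phase_assignments: Sequence[str],
                         species_G1: SpeciesModel, species_S: SpeciesModel,
                         g2m_mixture: float, irf: IRF, acq: AcquisitionConfig,
                         seed: int, shape: tuple[int, int] = (128, 128),
                         photons_per_pixel: float = DEFAULT_FOREGROUND_PHOTONS,
                         background_rate: float = 0.0,
                         nucleus_radius: float = 10.0,
                         ) -> tuple[TCSPCImage, np.ndarray, pd.DataFrame]:
    """Nucleus field for the lifetime-Fucci readout.

    G1 nuclei emit pure ``species_G1`` photons (HaloTag9-hCdt), S nuclei pure
    ``species_S`` (HaloTag7-hGem), G2/M nuclei a ``g2m_mixture`` photon
    fraction of the G1 species. Returns the image, an integer label map and a
    truth table (label, phase, f_G1).
    """
    if len(phase_assignments) != n_nuclei:
        raise ValueError("need one phase per nucleus")
    for p in phase_assignments:
        if p not in _PHASES:
            raise ValueError(f"phase must be one of {_PHASES}, got {p!r}")
    if not 0.0 <= g2m_mixture <= 1.0:
        raise ValueError("g2m_mixture must be in [0, 1]")
    rng = np.random.default_rng(seed)
    label_map = np.zeros(shape, dtype=np.int32)
    structures: list[Structure] = []
    f_of_phase = {"G1": 1.0, "S": 0.0, "G2M": float(g2m_mixture)}
    records = []
    occupied = np.zeros(shape, bool)
    for i, phase in enumerate(phase_assignments):
        for _ in range(500):
            mask = _place_nucleus(rng, shape, nucleus_radius)
            if mask.any() and not (mask & occupied).any():
                break
        else:
            raise ValueError("could not place all nuclei without overlap; "
                             "reduce n_nuclei or nucleus_radius")
        occupied |= mask
        label_map[mask] = i + 1
        f = f_of_phase[phase]
        if f > 0:
            structures.append(Structure(f"nuc{i + 1}_G1", mask, "G1",
                                        photons_per_pixel * f))
        if f < 1:
            structures.append(Structure(f"nuc{i + 1}_S", mask, "S",
                                        photons_per_pixel * (1 - f)))
        records.append({"label": i + 1, "phase": phase, "f_G1": f})
    scene = Scene(shape=shape, structures=structures,
                  background_rate=background_rate)
    img, _ = render_flim_image(
        scene, {"G1": species_G1, "S": species_S}, irf, acq,
        seed=int(np.random.default_rng(seed + 1).integers(2 ** 31)))
    truth = pd.DataFrame.from_records(records, columns=["label", "phase", "f_G1"])
    return img, label_map, truth


def simulate_anisotropy_trace(k1: float, k_minus1: float, k2: float,
                              conc_protein: float, conc_substrate: float,
                              dead_time: float, noise_sd: float,
                              r_free: float, r_bound: float,
                              times: np.ndarray, seed: int = 0):
    """Stopped-flow anisotropy trace of the two-step labeling scheme.

    Integrates P + S <-> PS* -> PS from mixing at t=0; the observable is
    r(t) = r_free [S]/[S]0 + r_bound ([PS*]+[PS])/[S]0 plus Gaussian noise.
    Points before the instrument dead time are dropped (pretrigger removal).
    """
    from .kinetics import KineticTrace, two_step_progress

    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    for name, v in (("k1", k1), ("k_minus1", k_minus1), ("k2", k2)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if conc_protein < 0 or conc_substrate < 0:
        raise ValueError("concentrations must be nonnegative")
    S, PSstar, PS = two_step_progress(times, k1, k_minus1, k2,
                                      conc_protein, conc_substrate)
    r = (r_free * S + r_bound * (PSstar + PS)) / conc_substrate
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0, noise_sd, size=r.shape)
    keep = times >= dead_time
    return KineticTrace(times=times[keep], values=r[keep],
                        conc_protein=conc_protein,
                        conc_substrate=conc_substrate, dead_time=dead_time)


def simulate_titration(a: float, k: float, x_c: float,
                       x_values: Sequence[float], noise_sd: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Absorbance-vs-dielectric sigmoid y = a / (1 + e^(-k(x - x_c))) + noise."""
    x = np.asarray(x_values, float)
    if x.size == 0:
        raise ValueError("x_values must be nonempty")
    with np.errstate(over="ignore"):
        y = a / (1.0 + np.exp(-k * (x - x_c)))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, size=y.shape)
    return pd.DataFrame({"dielectric": x, "value": y})
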