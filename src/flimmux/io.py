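"""File formats, run configuration and the end-to-end pipeline.

TCSPC images travel as multi-page TIFF (page k = time bin k, 16-bit
unsigned) with a JSON metadata sidecar; phasor fields as 3-plane 32-bit
TIFF (g, s, intensity); traces and tables as plain CSV. Pixel indexing is
(row, col), origin top-left, 0-based, recorded in every sidecar.
Vendor FLIM formats are out of scope; the TIFF+JSON container is the
adapter point for them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .core import AcquisitionConfig, IRF, SpeciesModel, TCSPCImage
from .core import expected_decay
from .phasor import (
    PhasorField,
    bin_phasor,
    calibrate,
    estimate_background_rate,
    phasor_transform,
    subtract_background,
)
from .synthetic import (
    GroundTruth,
    Scene,
    StructureSpec,
    make_scene,
    render_flim_image,
)
from .unmixing import (
    anchors_from_lifetimes,
    cluster_assign,
    separate_species_images,
    unmix_three,
    unmix_two,
)

__all__ = [
    "write_tcspc_tiff",
    "read_tcspc_tiff",
    "IntensityOnlyImage",
    "write_phasor_tiff",
    "write_ground_truth_csv",
    "write_label_tiff",
    "write_trace_csv",
    "read_trace_csv",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("flimmux")

_PIXEL_INDEXING = "row-major, origin top-left, 0-based (row, col)"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _irf_to_dict(irf: IRF) -> dict:
    d = {"kind": irf.kind, "center": irf.center, "sigma": irf.sigma}
    if irf.curve is not None:
        d["curve"] = np.asarray(irf.curve).tolist()
    return d


def _irf_from_dict(d: dict) -> IRF:
    curve = np.asarray(d["curve"]) if d.get("curve") is not None else None
    return IRF(kind=d.get("kind", "gaussian"), center=d.get("center", 1.5),
               sigma=d.get("sigma", 0.15), curve=curve)


def write_tcspc_tiff(img: TCSPCImage, path: str | Path,
                     irf: IRF | None = None,
                     sidecar: str | Path | None = None) -> Path:
    """Multi-page TIFF (one page per time bin, uint16) + JSON sidecar."""
    path = Path(path)
    if img.counts.max() > np.iinfo(np.uint16).max:
        raise ValueError("per-bin counts exceed uint16; pool or rescale first")
    pages = img.counts.transpose(2, 0, 1).astype(np.uint16)
    tifffile.imwrite(path, pages)
    meta = {
        "rep_rate_MHz": img.acq.rep_rate,
        "n_bins": img.acq.n_bins,
        "bin_width_ns": img.acq.bin_width,
        "channel": img.channel,
        "irf": _irf_to_dict(irf) if irf is not None else None,
        "pixel_indexing": _PIXEL_INDEXING,
        "flimmux_version": __version__,
    }
    sc = Path(sidecar) if sidecar else _sidecar_path(path)
    sc.write_text(json.dumps(meta, indent=1))
    return path


@dataclass
class IntensityOnlyImage:
    """Fallback for images with too few time bins for lifetime analysis."""

    counts: np.ndarray
    rep_rate: float
    channel: str


def read_tcspc_tiff(path: str | Path, sidecar: str | Path | None = None
                    ) -> TCSPCImage | IntensityOnlyImage:
    """Read a TCSPC TIFF + sidecar; lossless round trip with the writer.

    The page count must equal the sidecar's n_bins. Images with fewer than
    16 bins are accepted as intensity-only data with a warning.
    """
    path = Path(path)
    sc = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar {sc} not found for {path}")
    meta = json.loads(sc.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages != meta["n_bins"]:
        raise ValueError(
            f"TIFF has {n_pages} pages but sidecar declares "
            f"{meta['n_bins']} bins")
    counts = pages.transpose(1, 2, 0).astype(np.int64)
    if n_pages < 16:
        warnings.warn(
            f"{path.name} has only {n_pages} time bin(s): intensity only; "
            "phasor analysis and decay fitting need >= 16 bins",
            UserWarning, stacklevel=2)
        return IntensityOnlyImage(counts=counts,
                                  rep_rate=meta["rep_rate_MHz"],
                                  channel=meta.get("channel", ""))
    acq = AcquisitionConfig(rep_rate=meta["rep_rate_MHz"],
                            n_bins=meta["n_bins"])
    return TCSPCImage(counts=counts, acq=acq,
                      channel=meta.get("channel", ""))


def write_phasor_tiff(field: PhasorField, path: str | Path) -> Path:
    """3-plane 32-bit TIFF (g, s, intensity) + JSON sidecar."""
    path = Path(path)
    planes = np.stack([field.g, field.s,
                       field.intensity.astype(np.float32)]).astype(np.float32)
    tifffile.imwrite(path, planes)
    meta = {"planes": ["g", "s", "intensity"], "harmonic": field.harmonic,
            "omega_rad_per_ns": field.omega,
            "pixel_indexing": _PIXEL_INDEXING}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def write_ground_truth_csv(gt: GroundTruth, path: str | Path) -> Path:
    """Long-format CSV (row, col, species, fraction) over foreground pixels."""
    frac = gt.fractions()
    fg = gt.foreground()
    rr, cc = np.nonzero(fg)
    rows = []
    for k, sp in enumerate(gt.species_ids):
        rows.append(pd.DataFrame({"row": rr, "col": cc, "species": sp,
                                  "fraction": frac[rr, cc, k]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def write_label_tiff(label_map: np.ndarray, path: str | Path) -> Path:
    tifffile.imwrite(Path(path), label_map.astype(np.int32))
    return Path(path)


def write_trace_csv(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, index=False)
    return Path(path)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run configuration (schema-validated; unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IRFBlock(_Strict):
    kind: Literal["gaussian", "delta"] = "gaussian"
    center: float = 1.5
    sigma: float = 0.15

    def build(self) -> IRF:
        return IRF(kind=self.kind, center=self.center, sigma=self.sigma)


class AcquisitionBlock(_Strict):
    rep_rate: float = 80.0
    n_bins: int = 256

    def build(self) -> AcquisitionConfig:
        return AcquisitionConfig(rep_rate=self.rep_rate, n_bins=self.n_bins)


class SpeciesBlock(_Strict):
    lifetime: float = Field(gt=0)
    brightness: float = Field(default=1.0, gt=0)


class StructureBlock(_Strict):
    kind: Literal["nucleus", "mitochondria", "golgi"]
    count: int = Field(ge=0)
    size: float = Field(gt=0)
    species: str
    photons_per_pixel: float = Field(default=1000.0, ge=0)


class UnmixBlock(_Strict):
    mode: Literal["simplex", "cluster"] = "simplex"
    foreground_threshold: float = 100.0
    cluster_radius: float = 0.05
    background_correction: bool = True
    binning: int = 1  # odd k for k x k phasor binning; 1 = off


class RunConfig(_Strict):
    """Resolved configuration of one pipeline run; written beside outputs."""

    acquisition: AcquisitionBlock = AcquisitionBlock()
    irf: IRFBlock = IRFBlock()
    species: dict[str, SpeciesBlock]
    scene: list[StructureBlock]
    shape: tuple[int, int] = (128, 128)
    background_rate: float = 20.0
    channel: str = "MaP618"
    unmixing: UnmixBlock = UnmixBlock()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not 2 <= len(self.species) <= 3:
            raise ValueError(
                f"{len(self.species)} species configured; phasor unmixing "
                "separates at most 3 species per spectral channel (and needs "
                "at least 2)")
        for s in self.scene:
            if s.species not in self.species:
                raise ValueError(f"scene references unknown species {s.species!r}")
        return self


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> phasor -> unmix -> report; deterministic given the seed.

    Writes the rendered image, the separated per-species images, the ground
    truth, truth-vs-estimate metrics and the resolved config to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = config.acquisition.build()
    irf = config.irf.build()
    species_table = {name: SpeciesModel.mono(name, blk.lifetime, blk.brightness)
                     for name, blk in config.species.items()}
    stage = "simulate"
    try:
        layout = [StructureSpec(kind=s.kind, count=s.count, size=s.size,
                                species_id=s.species,
                                mean_photons_per_pixel=s.photons_per_pixel)
                  for s in config.scene]
        scene = make_scene(layout, config.shape, seed=config.seed,
                           background_rate=config.background_rate)
        img, gt = render_flim_image(scene, species_table, irf, acq,
                                    seed=config.seed + 1,
                                    channel=config.channel)
        write_tcspc_tiff(img, out / "image.tif", irf=irf)
        write_ground_truth_csv(gt, out / "ground_truth.csv")

        stage = "phasor"
        field = phasor_transform(img)
        # calibrate against a noiseless reference of known lifetime so the
        # theoretical lifetime anchors apply (removes the IRF phase/scale)
        ref_tau = 2.0
        ref_hist = expected_decay(SpeciesModel.mono("ref", ref_tau), 1e6,
                                  irf, acq)
        ref_img = TCSPCImage(np.round(ref_hist)[None, None, :].astype(int),
                             acq)
        field, _ = calibrate(field, ref_img, ref_tau)
        thr = config.unmixing.foreground_threshold
        if config.unmixing.background_correction:
            field = subtract_background(
                field, estimate_background_rate(field, thr))
        if config.unmixing.binning > 1:
            field = bin_phasor(field, config.unmixing.binning)
        write_phasor_tiff(field, out / "phasor.tif")

        stage = "unmix"
        names = list(config.species)
        anchors = anchors_from_lifetimes(
            [species_table[n] for n in names], acq.omega(),
            channel=config.channel)
        if config.unmixing.mode == "cluster":
            _, fmap = cluster_assign(field, anchors,
                                     radius=config.unmixing.cluster_radius,
                                     foreground_threshold=thr)
        elif len(names) == 2:
            fmap = unmix_two(field, anchors, foreground_threshold=thr)
        else:
            fmap = unmix_three(field, anchors, foreground_threshold=thr)
        separated = separate_species_images(fmap, field.intensity)
        for name, plane in separated.items():
            tifffile.imwrite(out / f"separated_{name}.tif",
                             plane.astype(np.float32))

        stage = "report"
        metrics = _truth_metrics(fmap, gt)
        report = {
            "flimmux_version": __version__,
            "seed": config.seed,
            "stages": ["simulate", "phasor", "unmix", "report"],
            "n_structures": len(scene.structures),
            "total_photons": int(img.intensity.sum()),
            "metrics": metrics,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        (out / "config.json").write_text(config.model_dump_json(indent=1))
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _truth_metrics(fmap, gt: GroundTruth) -> dict:
    """Per-pixel RMSE and per-species mean fraction error on foreground."""
    truth = gt.fractions()
    fg = fmap.foreground & gt.foreground()
    metrics: dict = {"n_foreground_px": int(fg.sum())}
    if not fg.any():
        return metrics
    order = [fmap.species.index(s) for s in gt.species_ids]
    est = fmap.fractions[..., order]
    err = est[fg] - truth[fg]
    metrics["fraction_rmse"] = float(np.sqrt(np.mean(err ** 2)))
    per_species = {}
    for k, sp in enumerate(gt.species_ids):
        on = fg & (gt.expected[sp] > 0)
        if on.any():
            per_species[sp] = float(
                np.mean(est[..., k][on]) - np.mean(truth[..., k][on]))
    metrics["mean_fraction_error"] = per_species
    return metrics
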