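"""Shared helper: simulate a 3-species scene and measure separation errors."""

import numpy as np
from scipy.ndimage import uniform_filter

from flimmux import SpeciesModel, StructureSpec, TCSPCImage, make_scene, render_flim_image
from flimmux.core import expected_decay
from flimmux.phasor import (
    PhasorField,
    bin_phasor,
    estimate_background_rate,
    phasor_transform,
    pooled_phasor,
    subtract_background,
)
from flimmux.unmixing import AnchorSet, unmix_three


def run_scene_separation(acq, irf, taus, seed, shape=(96, 96)):
    """Simulate at 1,000 photons/px, unmix, return (pixel RMSE, worst
    per-structure pooled fraction error).

    Background is removed via its exact phasor correction and per-pixel
    fractions use 3x3 phasor binning; per-structure fractions come from the
    pooled structure phasor.
    """
    species = {f"sp{i}": SpeciesModel.mono(f"sp{i}", t)
               for i, t in enumerate(taus)}
    layout = [
        StructureSpec("nucleus", 1, 13.0, "sp0"),
        StructureSpec("mitochondria", 2, 10.0, "sp1"),
        StructureSpec("golgi", 1, 8.0, "sp2"),
    ]
    scene = make_scene(layout, shape, seed=seed, background_rate=20.0)
    img, gt = render_flim_image(scene, species, irf, acq, seed=seed + 100)
    raw = phasor_transform(img)
    corrected = subtract_background(raw, estimate_background_rate(raw, 100))
    binned = bin_phasor(corrected, 3)
    anchors = []
    for i, t in enumerate(taus):
        h = expected_decay(species[f"sp{i}"], 1e6, irf, acq)
        f = phasor_transform(TCSPCImage(h[None, None], acq))
        anchors.append((f"sp{i}", f.g[0, 0], f.s[0, 0]))
    aset = AnchorSet("c", tuple(anchors))
    fmap = unmix_three(binned, aset, foreground_threshold=100)

    exp = {s: uniform_filter(gt.expected[s], size=3, mode="constant")
           for s in gt.species_ids}
    tot = sum(exp.values())
    fg = fmap.foreground & (tot > 0)
    truth = np.stack([np.where(tot > 0, e / np.where(tot > 0, tot, 1), 0)
                      for e in exp.values()], axis=-1)
    rmse = float(np.sqrt(np.mean((fmap.fractions[fg] - truth[fg]) ** 2)))

    worst = 0.0
    for s in scene.structures:
        g, sp, _ = pooled_phasor(corrected, s.mask)
        point = PhasorField(g=np.array([[g]]), s=np.array([[sp]]),
                            intensity=np.array([[1e4]]),
                            valid=np.ones((1, 1), bool), harmonic=1,
                            omega=raw.omega, acq=acq)
        f1 = unmix_three(point, aset, foreground_threshold=0)
        idx = int(s.species_id[2])
        worst = max(worst, abs(f1.fractions[0, 0, idx] - 1.0))
    return rmse, worst
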