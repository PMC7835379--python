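"""Water-leaving reflectance correction.

Surface-reflectance products still carry skylight reflection, residual
aerosol signal and sun glint over water.  Because these additive terms are
spectrally nearly flat while clear-water reflectance beyond ~800 nm is close
to zero, subtracting the per-pixel minimum of the NIR-SWIR bands from every
band removes them.
"""

from __future__ import annotations

import numpy as np

from .sceneio import SceneStack

__all__ = ["correct_water_leaving", "DEFAULT_NIR_SWIR"]

#: bands treated as NIR-SWIR (nominal centre beyond 800 nm) when present
DEFAULT_NIR_SWIR = ("nir", "swir1640", "swir1240", "swir2130")


def correct_water_leaving(
    scene: SceneStack,
    nir_swir_band_names: list[str] | tuple[str, ...] | None = None,
) -> SceneStack:
    """Subtract the per-pixel NIR-SWIR minimum from all bands.

    Negative results are clamped to zero (negative reflectance is
    unphysical); clamped pixels are reported in the returned scene's
    ``clamped`` attribute as a boolean raster.  QA is propagated unchanged.
    The operation is idempotent where the NIR-SWIR minimum is already zero.
    """
    if nir_swir_band_names is None:
        nir_swir_band_names = [b for b in DEFAULT_NIR_SWIR if b in scene.bands]
    if not nir_swir_band_names:
        raise ValueError("no NIR-SWIR bands given or found in scene")
    for name in nir_swir_band_names:
        if name not in scene.bands:
            raise KeyError(f"NIR-SWIR band {name!r} missing from scene")

    floor = np.min(
        np.stack([scene.bands[n] for n in nir_swir_band_names]), axis=0
    )
    corrected = {}
    clamped = np.zeros(scene.shape, dtype=bool)
    for name, values in scene.bands.items():
        out = values - floor
        neg = out < 0
        clamped |= neg
        corrected[name] = np.where(neg, 0.0, out)
    result = scene.with_bands(corrected)
    result.clamped = clamped
    return result
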