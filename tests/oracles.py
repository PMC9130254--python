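"""Independent brute-force oracles shared between test modules."""

import numpy as np


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Direct transcription of the inscribed-sphere definition.

    For every foreground voxel c, the largest inscribed sphere centred at c
    has squared radius equal to the minimal squared distance to a background
    voxel centre; every foreground voxel strictly inside that sphere is
    assigned the sphere's diameter (2R - 1 voxel widths) if it exceeds the
    value already assigned.  Exhaustive over all (center, radius) candidate
    spheres; exact integer squared-distance comparisons.
    """
    fg = mask.astype(bool)
    bgc = np.argwhere(~fg)
    fgc = np.argwhere(fg)
    out = np.zeros(mask.shape)
    for c in fgc:
        r2 = int(((bgc - c) ** 2).sum(axis=1).min())
        value = 2.0 * np.sqrt(r2) - 1.0
        d2 = ((fgc - c) ** 2).sum(axis=1)
        for p in fgc[d2 < r2]:
            out[tuple(p)] = max(out[tuple(p)], value)
    return out
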