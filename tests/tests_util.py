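"""Small independent oracles shared by test modules."""

import numpy as np


def lattice_cell_coverage(spec, n: int = 2000) -> float:
    """Brute-force fraction of one square lattice cell covered by its rod."""
    s = spec.rod_spacing
    c = np.linspace(0, s, n, endpoint=False) + s / (2 * n)
    X, Z = np.meshgrid(c, c, indexing="ij")
    inside = (X - s / 2) ** 2 + (Z - s / 2) ** 2 <= (spec.fiber_diameter / 2) ** 2
    return float(inside.mean())
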