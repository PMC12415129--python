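"""Published 28-cluster composition (cluster id, total cells,
polytocous count and %, monotocous count and %)."""

import numpy as np

from gcgrader.simulate import MONO, POLY

# (cluster, total, n_poly, pct_poly, n_mono, pct_mono) — published composition
PUBLISHED_COMPOSITION = [
    (0, 336, 315, 93.75, 21, 6.25),
    (1, 332, 6, 1.81, 326, 98.19),
    (2, 298, 206, 69.13, 92, 30.87),
    (3, 199, 144, 72.36, 55, 27.64),
    (4, 172, 78, 45.35, 94, 54.65),
    (5, 152, 5, 3.29, 147, 96.71),
    (6, 121, 71, 58.68, 50, 41.32),
    (7, 114, 34, 29.82, 80, 70.18),
    (8, 112, 73, 65.18, 39, 34.82),
    (9, 102, 38, 37.25, 64, 62.75),
    (10, 101, 62, 61.39, 39, 38.61),
    (11, 97, 70, 72.16, 27, 27.84),
    (12, 92, 35, 38.04, 57, 61.96),
    (13, 85, 23, 27.06, 62, 72.94),
    (14, 83, 47, 56.63, 36, 43.37),
    (15, 83, 19, 22.89, 64, 77.11),
    (16, 79, 53, 67.09, 26, 32.91),
    (17, 76, 76, 100.00, 0, 0.00),
    (18, 76, 49, 64.47, 27, 35.53),
    (19, 65, 18, 27.69, 47, 72.31),
    (20, 56, 32, 57.14, 24, 42.86),
    (21, 53, 23, 43.40, 30, 56.60),
    (22, 52, 7, 13.46, 45, 86.54),
    (23, 51, 11, 21.57, 40, 78.43),
    (24, 44, 12, 27.27, 32, 72.73),
    (25, 42, 5, 11.90, 37, 88.10),
    (26, 31, 15, 48.39, 16, 51.61),
    (27, 20, 9, 45.00, 11, 55.00),
]


def composition_cells():
    """Expand the published per-cluster counts into per-cell vectors."""
    assignment, origin = [], []
    for cluster, total, n_poly, _, n_mono, _ in PUBLISHED_COMPOSITION:
        assert n_poly + n_mono == total
        assignment += [cluster] * total
        origin += [POLY] * n_poly + [MONO] * n_mono
    return np.asarray(assignment), np.asarray(origin)


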