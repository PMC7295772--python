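"""Independent brute-force oracles shared across test modules."""

import numpy as np

from ultrametric.histology import PofSample


def sphere_section_sample(nv_true, r_sphere, rng, n_fields=10,
                          field_area=6.0, grid=256):
    """Brute-force oracle: Poisson spheres in 3-D, sectioned by a plane.

    Profiles are circles where the plane cuts a sphere; grid points count as
    'on POF' when covered by any profile.  This simulates exactly what the
    reader scores at the microscope, independent of the Weibel estimator.
    """
    L = np.sqrt(field_area)
    g = int(np.sqrt(grid))
    pts, profs = [], []
    for _ in range(n_fields):
        pad = r_sphere
        vol = (L + 2 * pad) ** 2 * (2 * r_sphere)
        n = rng.poisson(nv_true * vol)
        xyz = rng.uniform(
            [-pad, -pad, -r_sphere], [L + pad, L + pad, r_sphere], size=(n, 3)
        )
        radii = np.sqrt(np.maximum(r_sphere**2 - xyz[:, 2] ** 2, 0))
        infield = (
            (xyz[:, 0] >= 0) & (xyz[:, 0] < L) & (xyz[:, 1] >= 0) & (xyz[:, 1] < L)
        )
        profs.append(int(np.count_nonzero(infield & (radii > 0))))
        gx, gy = np.meshgrid((np.arange(g) + 0.5) * L / g, (np.arange(g) + 0.5) * L / g)
        gp = np.stack([gx.ravel(), gy.ravel()], axis=1)
        covered = np.zeros(gp.shape[0], dtype=bool)
        for (cx, cy, _), r in zip(xyz, radii):
            if r > 0:
                covered |= (gp[:, 0] - cx) ** 2 + (gp[:, 1] - cy) ** 2 < r**2
        pts.append(int(covered.sum()))
    return PofSample(
        fish_id="oracle",
        points_on_pof=tuple(pts),
        pof_profiles=tuple(profs),
        n_fields=n_fields,
        field_area_mm2=field_area,
        grid_points=grid,
    )
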