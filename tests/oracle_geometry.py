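"""Independent brute-force ray-casting oracle for point-in-polygon tests.

Deliberately shares nothing with the package implementation: one point at a
time, a ray in a random direction, explicit 2x2 linear solves per edge, and a
re-cast whenever the ray passes near a vertex or runs parallel to an edge.
Even-odd semantics: inside iff the ray crosses the boundary an odd number of
times.
"""

import numpy as np


def ray_cast_inside(p, vertices, rng, max_tries=200):
    """Even-odd membership of point ``p`` by randomized ray casting."""
    p = np.asarray(p, dtype=float)
    v = np.asarray(vertices, dtype=float)
    edges = [(v[i], v[(i + 1) % len(v)]) for i in range(len(v))]
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        count = 0
        degenerate = False
        for a, b in edges:
            # solve p + t*d == a + u*(b - a)
            mat = np.array([[d[0], a[0] - b[0]], [d[1], a[1] - b[1]]])
            det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
            if abs(det) < 1e-12:
                degenerate = True  # ray parallel to edge: re-cast
                break
            t, u = np.linalg.solve(mat, a - p)
            if abs(u) < 1e-9 or abs(u - 1.0) < 1e-9 or abs(t) < 1e-12:
                degenerate = True  # ray grazes a vertex or starts on the edge
                break
            if t > 0.0 and 0.0 < u < 1.0:
                count += 1
        if not degenerate:
            return count % 2 == 1
    raise RuntimeError("could not find a non-degenerate ray")


def random_polygon(rng, n_vertices):
    """Random (generally self-intersecting) polygon in [-5, 5]^2."""
    return rng.uniform(-5.0, 5.0, size=(n_vertices, 2))
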