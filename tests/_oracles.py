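"""Independent reference computations used to check the implementation.

Everything here is deliberately brute force: removal-based bridge
detection, dense-grid marginal-likelihood maximization with trapezoid
integration, and Monte-Carlo geometry estimates.
"""

import numpy as np
import networkx as nx
from scipy.special import gammaln, logsumexp


def brute_force_bridges(net):
    """Bridge ids by removing each edge and checking connectivity."""
    g = net.to_multigraph()
    base = nx.number_connected_components(g)
    out = set()
    for e in net.edges:
        g.remove_edge(e.node_a, e.node_b, key=e.id)
        if nx.number_connected_components(g) > base:
            out.add(e.id)
        g.add_edge(e.node_a, e.node_b, key=e.id)
    return out


def spanning_tree_cycle_count(net):
    """Independent cycle count via a spanning forest: E − (V − components)."""
    g = nx.Graph()
    g.add_nodes_from(n.id for n in net.nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in net.edges)
    forest_edges = sum(len(t.edges)
                       for t in (g.subgraph(c) for c in nx.connected_components(g))
                       for t in [nx.minimum_spanning_tree(t)])
    return len(net.edges) - forest_edges


def grid_glmm_loglik(counts, n_points=2001, rounds=4, grid=21):
    """Maximize the 2-region Poisson random-intercept marginal likelihood
    over a dense (β₀, β₁, σ) grid with trapezoid integration over u.

    ``counts``: array (n_animals, 2); region areas all 1.  Returns the
    maximized marginal log-likelihood.
    """
    counts = np.asarray(counts, float)
    lgam = gammaln(counts + 1.0).sum()

    def loglik(b0, b1, sigma):
        # (G,) grids of params broadcast against u grid
        u = np.linspace(-6 * max(sigma, 1e-3), 6 * max(sigma, 1e-3), n_points)
        eta = np.array([b0, b0 + b1])                      # (2,)
        # per animal: log ∫ exp(Σ_j c_j(η_j+u) − e^{η_j+u}) φ(u) du
        ll = 0.0
        for c in counts:
            h = (c[:, None] * (eta[:, None] + u[None, :])
                 - np.exp(eta[:, None] + u[None, :])).sum(axis=0)
            if sigma < 1e-8:
                ll += h[n_points // 2]
                continue
            logphi = -0.5 * (u / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi))
            du = u[1] - u[0]
            ll += logsumexp(h + logphi) + np.log(du)
        return ll - lgam

    b0_rng = (0.0, 2.5)
    b1_rng = (-2.5, 0.5)
    s_rng = (0.0, 1.5)
    best = (-np.inf, None)
    for _ in range(rounds):
        b0s = np.linspace(*b0_rng, grid)
        b1s = np.linspace(*b1_rng, grid)
        ss = np.linspace(*s_rng, grid)
        for b0 in b0s:
            for b1 in b1s:
                for s in ss:
                    v = loglik(b0, b1, s)
                    if v > best[0]:
                        best = (v, (b0, b1, s))
        b0c, b1c, sc = best[1]
        w0 = (b0_rng[1] - b0_rng[0]) / (grid - 1)
        w1 = (b1_rng[1] - b1_rng[0]) / (grid - 1)
        ws = (s_rng[1] - s_rng[0]) / (grid - 1)
        b0_rng = (b0c - 2 * w0, b0c + 2 * w0)
        b1_rng = (b1c - 2 * w1, b1c + 2 * w1)
        s_rng = (max(0.0, sc - 2 * ws), sc + 2 * ws)
    return best[0]


def monte_carlo_cell_areas(seeds, slab, n=1_000_000, rng=None):
    """Voronoi cell areas by nearest-seed classification of uniform points."""
    if rng is None:
        rng = np.random.default_rng(7)
    minx, miny, maxx, maxy = slab.bounds
    ids = sorted(seeds)
    pts = np.array([seeds[i] for i in ids])
    areas = dict.fromkeys(ids, 0.0)
    from shapely import contains_xy
    hits = 0
    box_area = (maxx - minx) * (maxy - miny)
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = contains_xy(slab, xs, ys)
    xs, ys = xs[inside], ys[inside]
    d2 = (xs[:, None] - pts[None, :, 0]) ** 2 + (ys[:, None] - pts[None, :, 1]) ** 2
    nearest = np.argmin(d2, axis=1)
    w = box_area / n
    for j, i in enumerate(ids):
        areas[i] = float(np.sum(nearest == j) * w)
    return areas
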