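import numpy as np
import pytest

import rangeshift as rs


@pytest.fixture(scope="session")
def small_landscape() -> rs.LandscapeBundle:
    """A 12x12 km landscape shared by read-only tests."""
    cfg = rs.LandscapeConfig(extent_km=12, clump_km=1.0)
    return rs.generate_landscape(cfg, seed=42)


@pytest.fixture(scope="session")
def species_and_baseline(small_landscape):
    cfg = rs.SpeciesConfig(n_species=6, occupancy_p=0.25, range_limit_frac=(0.3, 0.6))
    return rs.generate_species_and_baseline(cfg, small_landscape, seed=7)


def random_network(rng: np.random.Generator, n: int = 20, p_edge: float = 0.35):
    """A random symmetric rate network for conductance oracle tests."""
    from scipy import sparse

    coords = rng.uniform(0, 10, size=(n, 2))
    K = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < p_edge
    vals = rng.uniform(0.1, 2.0, len(iu[0])) * mask
    K[iu] = vals
    K = K + K.T
    net = rs.HabitatNetwork(
        coords=coords,
        areas=np.ones(n),
        rates=sparse.csr_matrix(K),
        dispersal_km=5.0,
        rate_constant=1.0,
        truncation_km=np.inf,
    )
    return net, K


def dense_conductance_oracle(K: np.ndarray, sources, target: int) -> float:
    """Independent route: contract sources into a supernode, then compute the
    two-terminal resistance from the pseudo-inverse of the full Laplacian."""
    n = K.shape[0]
    sources = sorted(set(int(s) for s in np.atleast_1d(sources)))
    keep = [i for i in range(n) if i not in sources]
    m = len(keep) + 1  # contracted graph: supernode is index 0
    Kc = np.zeros((m, m))
    for a_new, a in enumerate(keep, start=1):
        for b_new, b in enumerate(keep, start=1):
            Kc[a_new, b_new] = K[a, b]
        Kc[0, a_new] = Kc[a_new, 0] = sum(K[s, a] for s in sources)
    np.fill_diagonal(Kc, 0.0)
    L = np.diag(Kc.sum(axis=1)) - Kc
    t_new = keep.index(target) + 1
    # breadth-first reachability: disconnected terminals mean zero conductance
    seen = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for a in frontier:
            for b in np.nonzero(Kc[a])[0]:
                if b not in seen:
                    seen.add(int(b))
                    nxt.append(int(b))
        frontier = nxt
    if t_new not in seen:
        return 0.0
    e = np.zeros(m)
    e[0], e[t_new] = 1.0, -1.0
    R = float(e @ np.linalg.pinv(L) @ e)
    return 1.0 / R
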