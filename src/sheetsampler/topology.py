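"""Sheet geometry: afferent fields, inhibition and excitation masks.

Network neurons live on a (possibly degenerate) grid laid over a torus-shaped
input grid.  Each neuron reads a contiguous window of inputs (its afferent
field I_k); neurons whose fields overlap must inhibit each other so that at
most one of them explains a shared input at a time.  Sparse recurrent
excitation connects neurons beyond the range of inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "build_grid_sheet",
    "build_population_topology",
    "sample_excitatory_mask",
]


@dataclass
class Topology:
    """Geometry of a neural sheet.

    ``aff_idx[k]`` holds the (sorted) input indices of neuron k's afferent
    field; all fields have equal size.  Masks are symmetric boolean K×K with
    zero diagonal and disjoint supports.
    """

    input_shape: tuple[int, int]
    neuron_shape: tuple[int, int]
    aff_idx: np.ndarray                   # (K, F) int64
    inh_mask: np.ndarray                  # (K, K) bool
    exc_mask: np.ndarray = None           # (K, K) bool
    torus: bool = True
    neuron_coords: np.ndarray = None      # (K, 2) grid coordinates

    def __post_init__(self) -> None:
        self.aff_idx = np.asarray(self.aff_idx, dtype=np.int64)
        self.inh_mask = np.asarray(self.inh_mask, dtype=bool)
        if self.exc_mask is None:
            self.exc_mask = np.zeros_like(self.inh_mask)
        self.exc_mask = np.asarray(self.exc_mask, dtype=bool)
        if self.neuron_coords is None:
            r, c = self.neuron_shape
            self.neuron_coords = np.stack(
                np.unravel_index(np.arange(r * c), (r, c)), axis=1)
        self.validate()

    @property
    def K(self) -> int:
        return self.aff_idx.shape[0]

    @property
    def N(self) -> int:
        return self.input_shape[0] * self.input_shape[1]

    @property
    def field_size(self) -> int:
        return self.aff_idx.shape[1]

    def afferent_fields(self) -> list[set[int]]:
        """I_k as index sets."""
        return [set(row.tolist()) for row in self.aff_idx]

    def projection_fields(self) -> list[set[int]]:
        """P_i = {k : i in I_k}, consistent with the afferent fields."""
        P: list[set[int]] = [set() for _ in range(self.N)]
        for k, row in enumerate(self.aff_idx):
            for i in row:
                P[int(i)].add(k)
        return P

    def aff_mask(self) -> np.ndarray:
        """Dense (K, N) boolean mask of afferent connections."""
        M = np.zeros((self.K, self.N), dtype=bool)
        for k, row in enumerate(self.aff_idx):
            M[k, row] = True
        return M

    def overlap_pairs(self) -> np.ndarray:
        """Boolean K×K mask of pairs with intersecting afferent fields."""
        M = self.aff_mask().astype(np.int64)
        ov = (M @ M.T) > 0
        np.fill_diagonal(ov, False)
        return ov

    def validate(self) -> None:
        for name, M in (("inh_mask", self.inh_mask), ("exc_mask", self.exc_mask)):
            if not np.array_equal(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if M.diagonal().any():
                raise ValueError(f"{name} must have zero diagonal")
        if np.any(self.inh_mask & self.exc_mask):
            raise ValueError("inhibition and excitation masks must be disjoint")
        missing = self.overlap_pairs() & ~self.inh_mask
        if np.any(missing):
            pairs = [tuple(p) for p in np.argwhere(np.triu(missing))]
            raise ValueError(
                "neurons with overlapping afferent fields must inhibit each "
                f"other; offending pairs: {pairs}")


def _window_indices(r0: int, c0: int, field_shape: tuple[int, int],
                    input_shape: tuple[int, int], torus: bool) -> np.ndarray:
    R, C = input_shape
    fr, fc = field_shape
    rows = np.arange(r0, r0 + fr)
    cols = np.arange(c0, c0 + fc)
    if torus:
        rows, cols = rows % R, cols % C
    elif rows[-1] >= R or cols[-1] >= C:
        raise ValueError("afferent field exceeds the input grid (torus=False)")
    idx = (rows[:, None] * C + cols[None, :]).ravel()
    return np.sort(idx)


def _torus_dist(a: np.ndarray, b: np.ndarray, size: int, torus: bool) -> np.ndarray:
    d = np.abs(a[:, None] - b[None, :])
    if torus:
        d = np.minimum(d, size - d)
    return d


def build_grid_sheet(input_shape: tuple[int, int], neuron_shape: tuple[int, int],
                     field_shape: tuple[int, int],
                     neuron_spacing: tuple[int, int],
                     inhibition_range: int | None = None,
                     torus: bool = True) -> Topology:
    """Build a regular sheet of neurons over a (torus) input grid.

    Neuron (r, c) reads the contiguous ``field_shape`` window anchored at
    input position ``(r·dr, c·dc)``.  Inhibition pairs are derived from
    afferent-field overlap; if ``inhibition_range`` (max-norm distance in
    neuron-grid units) is given, it is used instead and validated to cover
    every overlapping pair (an explicit range may extend beyond the minimal
    requirement but never fall short of it).
    """
    nr, nc = neuron_shape
    dr, dc = neuron_spacing
    K = nr * nc
    coords = np.stack(np.unravel_index(np.arange(K), (nr, nc)), axis=1)
    aff = np.stack([
        _window_indices(r * dr, c * dc, field_shape, input_shape, torus)
        for r, c in coords
    ])
    topo = object.__new__(Topology)
    topo.input_shape = tuple(input_shape)
    topo.neuron_shape = tuple(neuron_shape)
    topo.aff_idx = aff
    topo.inh_mask = np.zeros((K, K), dtype=bool)
    topo.exc_mask = np.zeros((K, K), dtype=bool)
    topo.torus = torus
    topo.neuron_coords = coords
    overlap = topo.overlap_pairs()
    if inhibition_range is None:
        inh = overlap
    else:
        dist_r = _torus_dist(coords[:, 0], coords[:, 0], nr, torus)
        dist_c = _torus_dist(coords[:, 1], coords[:, 1], nc, torus)
        dist = np.maximum(dist_r, dist_c)
        inh = dist <= inhibition_range
        np.fill_diagonal(inh, False)
        missing = overlap & ~inh
        if np.any(missing):
            pairs = [tuple(p) for p in np.argwhere(np.triu(missing))]
            raise ValueError(
                f"inhibition range {inhibition_range} does not cover all "
                f"overlapping afferent fields; offending pairs: {pairs}")
    return Topology(topo.input_shape, topo.neuron_shape, aff, inh,
                    np.zeros((K, K), dtype=bool), torus, coords)


def build_population_topology(n_pops: int, pop_size: int,
                              field_shape: tuple[int, int] = (6, 6),
                              all_to_all_excitation: bool = False) -> Topology:
    """Disjoint local populations sharing one afferent field each.

    ``n_pops`` populations of ``pop_size`` neurons are laid out side by side;
    the neurons of a population share an identical ``field_shape`` window and
    inhibit each other (winner-take-all).  With ``all_to_all_excitation``,
    every cross-population pair carries an excitatory connection.
    """
    fr, fc = field_shape
    input_shape = (fr, fc * n_pops)
    K = n_pops * pop_size
    aff = np.empty((K, fr * fc), dtype=np.int64)
    coords = np.empty((K, 2), dtype=np.int64)
    for l in range(n_pops):
        idx = _window_indices(0, l * fc, field_shape, input_shape, torus=True)
        for s in range(pop_size):
            k = l * pop_size + s
            aff[k] = idx
            coords[k] = (s, l)
    pop = np.repeat(np.arange(n_pops), pop_size)
    inh = pop[:, None] == pop[None, :]
    np.fill_diagonal(inh, False)
    exc = np.zeros((K, K), dtype=bool)
    if all_to_all_excitation:
        exc = pop[:, None] != pop[None, :]
    return Topology(input_shape, (pop_size, n_pops), aff, inh, exc,
                    True, coords)


def sample_excitatory_mask(topology: Topology, p_conn: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Sample a sparse symmetric excitatory mask outside the inhibition range.

    Each unordered non-inhibiting pair receives a reciprocal connection
    independently with probability ``p_conn``.
    """
    if not 0.0 <= p_conn <= 1.0:
        raise ValueError("p_conn must lie in [0, 1]")
    K = topology.K
    exc = np.zeros((K, K), dtype=bool)
    iu = np.triu_indices(K, k=1)
    draw = rng.random(iu[0].size) < p_conn
    exc[iu] = draw
    exc = exc | exc.T
    exc &= ~topology.inh_mask
    np.fill_diagonal(exc, False)
    return exc
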