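"""Spatial statistics of uncompressed-dimer islands on the ideal lattice.

Two uncompressed dimers belong to the same cluster when they share at least
one vertical or lateral subunit bond.  On the 13-protofilament, 3-start
lattice the seam couples a dimer on the seam's left protofilament to the
dimers one and two rows higher on the right (the accumulated three-monomer
shift); a naive circular ("wrap") adjacency is available as a toggle.
Histograms follow the per-5-um normalization convention with 555-row
lattices counted as 2.4 um each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .lattice import LatticeConfiguration

__all__ = [
    "ClusterSet", "ClusterHistogram", "adjacency_edges", "find_clusters",
    "cluster_histogram", "footprint", "is_laterally_percolating",
]

#: Paper convention: a 555-row clustering lattice corresponds to 2.4 um.
UM_PER_CLUSTER_LATTICE = 2.4
ROWS_PER_CLUSTER_LATTICE = 555

SeamMode = Literal["shifted", "wrap", "none"]


@dataclass
class ClusterSet:
    """Disjoint connected clusters of uncompressed dimers."""

    clusters: list                      # list of [(row, pf), ...]
    lattice_ref: LatticeConfiguration
    seam: str = "shifted"

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], np.int64)

    def validate(self) -> None:
        total = int(self.sizes.sum()) if self.clusters else 0
        if total != int(self.lattice_ref.composition.sum()):
            raise ValueError("clusters must partition the uncompressed dimers")


@dataclass
class ClusterHistogram:
    """Average count of clusters of size n per 5 um of microtubule."""

    h: dict                             # size -> count per 5 um
    n_lattices: int
    rows_per_lattice: int
    um_per_lattice: float

    def nh(self) -> dict:
        """Size-weighted histogram n*h(n) (the plotting convention)."""
        return {n: n * c for n, c in self.h.items()}

    @property
    def total_um(self) -> float:
        return self.n_lattices * self.um_per_lattice


def adjacency_edges(config: LatticeConfiguration,
                    seam: SeamMode = "shifted") -> list:
    """Subunit-bond edges between dimer coordinates.

    Each entry is ``((row1, pf1), (row2, pf2), kind)`` with one entry per
    shared subunit bond: a same-row lateral contact contributes two edges
    (the alpha-alpha and beta-beta bonds), a vertical contact one
    (beta-to-alpha), and each seam contact one (the half-staggered
    alpha-beta pairings with the dimers one and two rows up).
    """
    n_rows, n_pf = config.n_rows, config.n_pf
    left, right = config.seam_pf_pair
    edges = []
    for r in range(n_rows):
        for k in range(n_pf):
            if r + 1 < n_rows:
                edges.append(((r, k), (r + 1, k), "vertical"))
            kp = k + 1
            if kp < n_pf or seam == "wrap":
                kp %= n_pf
                edges.append(((r, k), (r, kp), "lateral_alpha"))
                edges.append(((r, k), (r, kp), "lateral_beta"))
    if seam == "shifted":
        for r in range(n_rows):
            if r + 1 < n_rows:
                edges.append(((r, left), (r + 1, right), "seam_beta_alpha"))
            if r + 2 < n_rows:
                edges.append(((r, left), (r + 2, right), "seam_alpha_beta"))
    return edges


def find_clusters(config: LatticeConfiguration,
                  seam: SeamMode = "shifted") -> ClusterSet:
    """Connected clusters of uncompressed dimers under the adjacency rule.

    Clusters are ordered by their minimal (row, protofilament) member.
    """
    grid = config.composition
    n_rows, n_pf = grid.shape
    occ = np.flatnonzero(grid.reshape(-1))
    if len(occ) == 0:
        return ClusterSet(clusters=[], lattice_ref=config, seam=seam)
    index = -np.ones(n_rows * n_pf, np.int64)
    index[occ] = np.arange(len(occ))

    rows_i, pfs_i = np.divmod(occ, n_pf)
    src, dst = [], []

    def link(r2, k2):
        valid = (r2 >= 0) & (r2 < n_rows)
        flat = r2 * n_pf + k2
        j = np.where(valid, index[np.clip(flat, 0, n_rows * n_pf - 1)], -1)
        ok = valid & (j >= 0)
        src.append(np.arange(len(occ))[ok])
        dst.append(j[ok])

    link(rows_i + 1, pfs_i)                       # vertical up
    inner = pfs_i < n_pf - 1
    r2 = np.where(inner, rows_i, -1)
    link(r2, np.minimum(pfs_i + 1, n_pf - 1))     # lateral right (non-seam)
    if seam == "wrap":
        at_seam = pfs_i == n_pf - 1
        link(np.where(at_seam, rows_i, -1), np.zeros_like(pfs_i))
    elif seam == "shifted":
        left, right = config.seam_pf_pair
        at_seam = pfs_i == left
        link(np.where(at_seam, rows_i + 1, -1), np.full_like(pfs_i, right))
        link(np.where(at_seam, rows_i + 2, -1), np.full_like(pfs_i, right))

    si = np.concatenate(src) if src else np.array([], np.int64)
    di = np.concatenate(dst) if dst else np.array([], np.int64)
    m = coo_matrix((np.ones(len(si), np.int8), (si, di)),
                   shape=(len(occ), len(occ)))
    n_comp, labels = connected_components(m, directed=False)
    clusters = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append((int(rows_i[i]), int(pfs_i[i])))
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])
    cs = ClusterSet(clusters=clusters, lattice_ref=config, seam=seam)
    cs.validate()
    return cs


def cluster_histogram(ensemble: Sequence[ClusterSet], *,
                      um_per_lattice: Optional[float] = None) -> ClusterHistogram:
    """Pooled per-5-um cluster size histogram over an ensemble of lattices.

    By default each lattice contributes the printed 2.4 um (the 555-row
    clustering-lattice convention) scaled by its actual row count.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    total_um = 0.0
    counts: dict = {}
    rows = ensemble[0].lattice_ref.n_rows
    for cs in ensemble:
        nr = cs.lattice_ref.n_rows
        um = (um_per_lattice if um_per_lattice is not None
              else UM_PER_CLUSTER_LATTICE * nr / ROWS_PER_CLUSTER_LATTICE)
        total_um += um
        for s in cs.sizes:
            counts[int(s)] = counts.get(int(s), 0) + 1
    if total_um <= 0:
        raise ValueError("zero total microtubule length in ensemble")
    scale = 5.0 / total_um
    h = {n: c * scale for n, c in sorted(counts.items())}
    return ClusterHistogram(h=h, n_lattices=len(ensemble),
                            rows_per_lattice=rows,
                            um_per_lattice=total_um / len(ensemble))


def footprint(cluster: Iterable, n_pf: int = 13) -> tuple[int, int]:
    """(rows_spanned, protofilaments_spanned) of one cluster.

    The protofilament span is the minimal circular arc covering all members
    (never more than the ``n_pf`` protofilaments of the ring).
    """
    members = list(cluster)
    if not members:
        raise ValueError("empty cluster")
    rows = np.array([m[0] for m in members])
    pfs = np.unique([m[1] for m in members])
    rows_spanned = int(rows.max() - rows.min() + 1)
    if len(pfs) == n_pf:
        return rows_spanned, n_pf
    gaps = np.diff(np.concatenate([pfs, [pfs[0] + n_pf]]))
    pfs_spanned = int(n_pf - gaps.max() + 1)
    return rows_spanned, pfs_spanned


def is_laterally_percolating(cluster: Iterable, n_pf: int = 13) -> bool:
    """True when the cluster covers every protofilament (closes the ring)."""
    members = list(cluster)
    if not members:
        raise ValueError("empty cluster")
    return len({m[1] for m in members}) == n_pf
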