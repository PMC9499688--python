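"""Ensemble statistics.

1D probability density functions, 2D potential-of-mean-force surfaces
(F = −RT ln H), gromos/Daura greedy RMSD clustering, cluster projection
onto a free-energy landscape, and a three-observable convergence check
based on Jensen–Shannon divergences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = [
    "Pdf1D", "PMFSurface", "ClusterResult",
    "pdf_1d", "pmf_2d", "pairwise_rmsd_matrix", "daura_cluster",
    "project_clusters", "jensen_shannon_divergence", "convergence_check",
    "GAS_CONSTANT_KCAL",
]

#: R in kcal/(mol·K).
GAS_CONSTANT_KCAL = 0.0019872


@dataclass
class Pdf1D:
    bin_edges: np.ndarray
    densities: np.ndarray
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PMFSurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray     # (nx, ny) kcal/mol, NaN on undefined bins
    defined_mask: np.ndarray    # (nx, ny) bool
    temperature: float          # K
    rt: float                   # kcal/mol


@dataclass
class ClusterResult:
    clusters: list[tuple[int, list[int]]]   # (medoid frame, member frames)
    cutoff: float                            # nm

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.clusters]


def pdf_1d(samples, bins=None) -> Pdf1D:
    """Normalized density histogram. Default binning is Freedman–Diaconis
    with a fallback to 50 bins; zero-variance input collapses to a single
    unit-mass bin."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("need at least one finite sample")
    if x.max() == x.min():
        width = max(abs(x[0]) * 1e-9, 1e-12)
        edges = np.array([x[0] - width / 2, x[0] + width / 2])
        return Pdf1D(bin_edges=edges, densities=np.array([1.0 / width]),
                     n_samples=x.size)
    if bins is None:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        if iqr > 0:
            width = 2 * iqr / np.cbrt(x.size)
            bins = max(1, int(np.ceil((x.max() - x.min()) / width)))
        else:
            bins = 50
    dens, edges = np.histogram(x, bins=bins, density=True)
    return Pdf1D(bin_edges=edges, densities=dens, n_samples=x.size)


def pmf_2d(x_samples, y_samples, temperature: float = 310.0,
           bins: tuple[int, int] = (50, 50)) -> PMFSurface:
    """2D potential of mean force F(x, y) = −RT ln H(x, y), with H the
    normalized occupancy histogram, shifted so the minimum over defined
    bins is zero; empty bins are undefined (NaN), never zero-filled."""
    x = np.asarray(x_samples, dtype=float).ravel()
    y = np.asarray(y_samples, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y samples must be equal-length and non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = GAS_CONSTANT_KCAL * temperature

    def padded_edges(v, n):
        lo, hi = v.min(), v.max()
        span = hi - lo
        half_bin = (span / n / 2) if span > 0 else max(abs(lo) * 1e-6, 1e-9)
        return np.linspace(lo - half_bin, hi + half_bin, n + 1)

    x_edges = padded_edges(x, bins[0])
    y_edges = padded_edges(y, bins[1])
    h, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    h /= h.sum()
    defined = h > 0
    f = np.full(h.shape, np.nan)
    f[defined] = -rt * np.log(h[defined])
    f[defined] -= np.nanmin(f[defined])
    return PMFSurface(x_edges=x_edges, y_edges=y_edges, free_energy=f,
                      defined_mask=defined, temperature=temperature, rt=rt)


# ---------------------------------------------------------------------------
# clustering

def pairwise_rmsd_matrix(traj: Trajectory, atom_indices) -> np.ndarray:
    """Full matrix of post-fit (Kabsch) RMSDs over the selected atoms,
    batched over all frame pairs."""
    sel = np.asarray(atom_indices, dtype=np.intp)
    if sel.size < 3:
        raise ValueError("selection too small for superposition")
    xyz = traj.coords()[:, sel, :]
    nf = xyz.shape[0]
    centered = xyz - xyz.mean(axis=1, keepdims=True)
    sq = (centered ** 2).sum(axis=(1, 2)) / sel.size
    # covariance for every ordered frame pair, then batched SVD
    cov = np.einsum("iak,jal->ijkl", centered, centered) / sel.size
    u, s, vt = np.linalg.svd(cov.reshape(nf * nf, 3, 3))
    det = np.linalg.det(u) * np.linalg.det(vt)
    s_corr = s.copy()
    s_corr[:, 2] *= np.sign(det)
    traced = s_corr.sum(axis=1).reshape(nf, nf)
    msd = sq[:, None] + sq[None, :] - 2.0 * traced
    msd = np.maximum(msd, 0.0)
    rmsd = np.sqrt(msd)
    np.fill_diagonal(rmsd, 0.0)
    return 0.5 * (rmsd + rmsd.T)


def daura_cluster(traj: Trajectory, atom_indices, cutoff: float = 0.45,
                  rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Daura (gromos) greedy clustering on the pairwise Cα-RMSD matrix.

    Repeatedly extract the structure with the most neighbours within the
    cutoff (self included) as a medoid, remove its cluster, and iterate;
    neighbour-count ties break to the lowest frame index. Every run is
    audited: member-to-medoid RMSD never exceeds the cutoff.
    """
    dm = rmsd_matrix if rmsd_matrix is not None \
        else pairwise_rmsd_matrix(traj, atom_indices)
    nf = dm.shape[0]
    alive = np.ones(nf, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    within = dm <= cutoff
    while alive.any():
        counts = (within & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        medoid = int(np.argmax(counts))  # argmax takes the lowest index tie
        members = np.flatnonzero(within[medoid] & alive)
        clusters.append((medoid, members.tolist()))
        alive[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[1][0]))
    for medoid, members in clusters:  # post-hoc audit invariant
        if (dm[medoid, members] > cutoff + 1e-12).any():
            raise AssertionError("cluster audit failed: member beyond cutoff")
    return ClusterResult(clusters=clusters, cutoff=cutoff)


def project_clusters(clusters: ClusterResult, x_samples, y_samples,
                     top_k: int = 10):
    """Top-k most populated clusters projected onto observable space:
    (medoid x, medoid y, occupancy fraction) per cluster."""
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    total = sum(clusters.sizes())
    out = []
    for medoid, members in clusters.clusters[:top_k]:
        out.append((medoid, float(x[medoid]), float(y[medoid]),
                    len(members) / total))
    return out


# ---------------------------------------------------------------------------
# convergence

def jensen_shannon_divergence(p, q) -> float:
    """JSD in bits between two distributions on a shared binning; symmetric,
    in [0, 1], and 0 iff p = q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a binning")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def convergence_check(traj: Trajectory, window_a, window_b,
                      threshold: float = 0.05) -> dict:
    """Compare two frame windows on three observables — secondary-structure
    category populations, the end-to-end-distance PDF, and the inter-peptide
    main-chain H-bond-count PDF — via Jensen–Shannon divergence (bits) on a
    shared binning. Converged iff all three JSDs are below ``threshold``."""
    from .geometry import end_to_end_distance
    from .interactions import detect_hbonds
    from .structure_metrics import CATEGORIES, assign_secondary_structure

    nf = traj.n_frames
    wins = []
    for w in (window_a, window_b):
        idx = np.arange(nf)[w] if isinstance(w, slice) \
            else np.asarray(list(w), dtype=int)
        if idx.size < 10:
            raise ValueError("each window needs at least 10 frames")
        if idx.min() < 0 or idx.max() >= nf:
            raise ValueError("window outside trajectory")
        wins.append(idx)

    ss = assign_secondary_structure(traj)
    cats = ss.categories

    def ss_pop(idx):
        return np.array([(cats[idx] == c).mean() for c in CATEGORIES])

    top = traj.topology
    chains = top.peptide_chains()

    def ree_samples(idx):
        vals = []
        for fi in idx:
            for c in chains:
                vals.append(end_to_end_distance(
                    [top.residues[ri] for ri in c.residues], top,
                    traj.frames[fi]))
        return np.asarray(vals)

    def hbond_counts(idx):
        out = []
        for fi in idx:
            ev = detect_hbonds(traj.frames[fi], top, scope="inter-peptide")
            out.append(sum(1 for e in ev if e.hb_class == "MC-MC"))
        return np.asarray(out)

    report = {}
    # secondary structure: categorical distribution
    report["secondary_structure"] = jensen_shannon_divergence(
        ss_pop(wins[0]) + 1e-15, ss_pop(wins[1]) + 1e-15)
    # end-to-end distance: shared histogram
    ra, rb = ree_samples(wins[0]), ree_samples(wins[1])
    lo, hi = min(ra.min(), rb.min()), max(ra.max(), rb.max())
    edges = np.linspace(lo, hi + 1e-12, 31)
    ha, _ = np.histogram(ra, bins=edges)
    hb, _ = np.histogram(rb, bins=edges)
    report["end_to_end"] = jensen_shannon_divergence(ha + 1e-15, hb + 1e-15)
    # H-bond count distribution on shared integer support
    ca, cb = hbond_counts(wins[0]), hbond_counts(wins[1])
    hi_n = int(max(ca.max(), cb.max()))
    pa = np.bincount(ca, minlength=hi_n + 1)
    pb = np.bincount(cb, minlength=hi_n + 1)
    report["hbond_count"] = jensen_shannon_divergence(pa + 1e-15, pb + 1e-15)
    report["threshold"] = threshold
    report["converged"] = all(report[k] < threshold for k in
                              ("secondary_structure", "end_to_end",
                               "hbond_count"))
    return report
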