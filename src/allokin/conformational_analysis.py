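"""Trajectory statistics: dihedrals, rotamer assignment, pooled bootstrap
histograms, transition rates, minimum distances, Kabsch superposition and
bootstrap pairwise-RMSD matrices, and distance-threshold frame filtering.

The workflow these operations serve: pool all trajectory frames of one
simulated condition, bootstrap fixed-size samples from the pool, and report
the mean and spread of the statistic over bootstrap samples — frequency
histograms of χ1 rotamers or ligand–residue distances, and pairwise
ligand-RMSD matrices that resolve pose heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory_synth import FrameEnsemble, StateSeries, wrap_angle

__all__ = [
    "BootstrapHistogram",
    "RmsdMatrixSummary",
    "dihedral",
    "chi1_series",
    "assign_rotamer",
    "bootstrap_histogram",
    "transition_rate",
    "min_distance",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "pairwise_rmsd_bootstrap",
    "filter_frames_by_distance",
    "CHI1_ATOMS",
]

#: χ1 dihedral atom quadruples by residue type (extendable)
CHI1_ATOMS = {
    "THR": ("N", "CA", "CB", "OG1"),
    "PHE": ("N", "CA", "CB", "CG"),
    "SER": ("N", "CA", "CB", "OG"),
    "TYR": ("N", "CA", "CB", "CG"),
    "LEU": ("N", "CA", "CB", "CG"),
    "GLU": ("N", "CA", "CB", "CG"),
    "ASP": ("N", "CA", "CB", "CG"),
    "LYS": ("N", "CA", "CB", "CG"),
    "ARG": ("N", "CA", "CB", "CG"),
    "ILE": ("N", "CA", "CB", "CG1"),
    "VAL": ("N", "CA", "CB", "CG1"),
    "CYS": ("N", "CA", "CB", "SG"),
    "MET": ("N", "CA", "CB", "CG"),
    "TRP": ("N", "CA", "CB", "CG"),
    "HIS": ("N", "CA", "CB", "CG"),
    "GLN": ("N", "CA", "CB", "CG"),
    "ASN": ("N", "CA", "CB", "CG"),
}


@dataclass
class BootstrapHistogram:
    """Per-bin mean and sd of relative frequency over bootstrap samples."""

    bin_edges: np.ndarray
    mean_freq: np.ndarray
    sd_freq: np.ndarray
    n_boot: int
    sample_size: int


@dataclass
class RmsdMatrixSummary:
    """Bootstrap pairwise-RMSD result: the per-bootstrap matrices plus the
    mean and sd (over bootstraps) of the mean off-diagonal RMSD."""

    matrices: list
    mean_rmsd_per_boot: np.ndarray
    mean_rmsd: float
    sd_rmsd: float
    n_boot: int
    sample_size: int


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, (−180, 180]) of four points.

    Uses the atan2 construction on the plane normals: positive angles follow
    the right-hand rule looking down the p2→p3 bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate geometry: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def _dihedral_frames(q: np.ndarray) -> np.ndarray:
    # q: (n_frames, 4, 3) -> angles per frame
    b1 = q[:, 1] - q[:, 0]
    b2 = q[:, 2] - q[:, 1]
    b3 = q[:, 3] - q[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def chi1_series(ensemble: FrameEnsemble, residue_id: int) -> np.ndarray:
    """Per-frame χ1 dihedral (degrees) for one residue of a frame ensemble.

    The ensemble must carry residue names/ids (as produced by the PDB
    reader); the χ1 atom quadruple comes from :data:`CHI1_ATOMS`.
    """
    if ensemble.residue_ids is None or ensemble.residue_names is None:
        raise ValueError("ensemble carries no residue annotation")
    rid = np.asarray(ensemble.residue_ids)
    mask = rid == residue_id
    if not mask.any():
        raise ValueError(f"residue id {residue_id} not present")
    resname = str(np.asarray(ensemble.residue_names)[mask][0]).upper()
    if resname not in CHI1_ATOMS:
        raise ValueError(f"no χ1 definition for residue type {resname}")
    quad = CHI1_ATOMS[resname]
    names = np.asarray(ensemble.atom_names)
    idx = []
    for atom in quad:
        hit = np.nonzero(mask & (names == atom))[0]
        if hit.size == 0:
            raise ValueError(f"residue {resname}{residue_id} is missing atom {atom}")
        idx.append(hit[0])
    return _dihedral_frames(ensemble.frames[:, idx, :])


def assign_rotamer(angle) -> np.ndarray | str:
    """Classify a χ1 angle into gauche+ (0, 120], gauche− (−120, 0], or trans.

    Input angles are wrapped to (−180, 180] first, so any real angle is
    accepted.
    """
    a = wrap_angle(np.asarray(angle, dtype=float))
    a = np.atleast_1d(a)
    out = np.where(
        (a > 0) & (a <= 120), "gauche+", np.where((a > -120) & (a <= 0), "gauche-", "trans")
    )
    return out.item() if np.isscalar(angle) or np.ndim(angle) == 0 else out


def bootstrap_histogram(
    pooled_values,
    bin_edges,
    n_boot: int = 500,
    sample_size: int = 5000,
    seed: int = 0,
    replace: bool = True,
) -> BootstrapHistogram:
    """Bootstrap frequency histogram of a pooled per-frame observable.

    Draws ``n_boot`` samples of ``sample_size`` frames (with replacement by
    default) from the pooled values of one condition and reports per-bin mean
    and sd of the relative frequency.  ``pooled_values`` may be numeric or
    categorical; for categorical input pass the category labels as
    ``bin_edges``.
    """
    pool = np.asarray(pooled_values)
    if pool.size == 0:
        raise ValueError("pooled values must be nonempty")
    categorical = pool.dtype.kind in "UOS"
    if categorical:
        cats = list(bin_edges)
        edges = np.arange(len(cats) + 1, dtype=float)
        lut = {c: i for i, c in enumerate(cats)}
        codes = np.asarray([lut[v] for v in pool])
        data = codes.astype(float) + 0.5
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        data = pool.astype(float)
    if not replace and sample_size > pool.size:
        raise ValueError("sample_size exceeds pool size for sampling without replacement")

    rng = np.random.default_rng(seed)
    freqs = np.empty((n_boot, edges.size - 1))
    for b in range(n_boot):
        idx = (
            rng.integers(0, data.size, size=sample_size)
            if replace
            else rng.choice(data.size, size=sample_size, replace=False)
        )
        counts, _ = np.histogram(data[idx], bins=edges)
        freqs[b] = counts / sample_size
    return BootstrapHistogram(
        bin_edges=edges,
        mean_freq=freqs.mean(axis=0),
        sd_freq=freqs.std(axis=0, ddof=0),
        n_boot=n_boot,
        sample_size=sample_size,
    )


def transition_rate(series, state_pair: tuple | None = None) -> float:
    """Transition events per µs from one or more frame-discretized state series.

    Counts consecutive-frame label changes (only direct changes between the
    two named states when ``state_pair`` is given), sums over trajectories,
    and divides by the total observed time in µs.  Frame discretization can
    only miss jumps, so this is a lower bound on the underlying jump rate.
    """
    if isinstance(series, StateSeries):
        series = [series]
    total_events = 0
    total_us = 0.0
    for s in series:
        if s.states.size < 2:
            raise ValueError("need at least 2 frames to count transitions")
        a, b = s.states[:-1], s.states[1:]
        if state_pair is None:
            total_events += int(np.count_nonzero(a != b))
        else:
            s1, s2 = state_pair
            total_events += int(
                np.count_nonzero(((a == s1) & (b == s2)) | ((a == s2) & (b == s1)))
            )
        total_us += s.duration_us
    if total_us <= 0:
        raise ValueError("total observed duration is zero")
    return total_events / total_us


def min_distance(point, point_set) -> float:
    """Minimum Euclidean distance (Å) from ``point`` to a nonempty point set."""
    p = np.asarray(point, dtype=float)
    ps = np.atleast_2d(np.asarray(point_set, dtype=float))
    if ps.size == 0:
        raise ValueError("point set must be nonempty")
    return float(np.min(np.linalg.norm(ps - p, axis=1)))


def kabsch_superpose(
    coords_x: np.ndarray,
    coords_y: np.ndarray,
    align_selection=None,
    rmsd_selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_y`` onto ``coords_x``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_y @ rotation.T + translation`` best matches ``coords_x`` over
    ``align_selection`` (all atoms by default); the RMSD is evaluated over
    ``rmsd_selection`` (defaults to the align selection) after applying the
    transform.  Reflections are corrected via the sign of the smallest
    singular value, so the rotation is always proper.
    """
    X = np.asarray(coords_x, dtype=float)
    Y = np.asarray(coords_y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n_atoms, 3)")
    sel = np.arange(X.shape[0]) if align_selection is None else np.asarray(align_selection)
    if sel.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    xa, ya = X[sel], Y[sel]
    cx, cy = xa.mean(axis=0), ya.mean(axis=0)
    H = (ya - cy).T @ (xa - cx)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] <= 1e-12 * max(S[0], 1e-300):
        raise ValueError("rank-deficient configuration: atoms nearly collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    rsel = sel if rmsd_selection is None else np.asarray(rmsd_selection)
    diff = (Y[rsel] @ R.T + t) - X[rsel]
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def pairwise_rmsd_matrix(
    coords: np.ndarray, align_selection=None, rmsd_selection=None
) -> np.ndarray:
    """Full pairwise Kabsch-RMSD matrix over frames (n, n_atoms, 3).

    Each frame pair is superposed on ``align_selection`` and the RMSD is
    evaluated over ``rmsd_selection``.  By default both selections are the
    RMSD selection itself (all atoms when neither is given) — a pure
    pose-shape comparison; pass a separate ``align_selection`` (e.g. the
    protein frame) to measure ligand displacement within a common reference.
    All pairs are computed with one batched SVD.
    """
    C = np.asarray(coords, dtype=float)
    n, n_atoms, _ = C.shape
    if align_selection is None:
        asel = np.arange(n_atoms) if rmsd_selection is None else np.asarray(rmsd_selection)
    else:
        asel = np.asarray(align_selection)
    rsel = asel if rmsd_selection is None else np.asarray(rmsd_selection)

    A = C[:, asel, :]
    cent = A.mean(axis=1, keepdims=True)
    A = A - cent
    iu, ju = np.triu_indices(n, k=1)
    # rotation taking frame ju onto frame iu, from the align selection
    H = np.einsum("pij,pik->pjk", A[ju], A[iu])  # Y^T X per pair
    U, S, Vt = np.linalg.svd(H)
    V = np.transpose(Vt, (0, 2, 1))
    det = np.linalg.det(np.einsum("pij,pkj->pik", V, U))
    D = np.repeat(np.eye(3)[None], iu.size, axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("pij,pjk,plk->pil", V, D, U)  # V D U^T

    same = rsel is asel or np.array_equal(rsel, asel)
    if same:
        sq = np.einsum("nij,nij->n", A, A)
        tr = S[:, 0] + S[:, 1] + np.sign(det) * S[:, 2]
        msd = np.maximum((sq[iu] + sq[ju] - 2.0 * tr) / asel.size, 0.0)
    else:
        X = C[:, rsel, :] - cent  # rmsd-selection coords in align-centroid frame
        Yrot = np.einsum("pij,pmj->pmi", R, X[ju])
        diff = Yrot - X[iu]
        msd = np.einsum("pmi,pmi->p", diff, diff) / rsel.size
    out = np.zeros((n, n))
    out[iu, ju] = out[ju, iu] = np.sqrt(msd)
    return out


def pairwise_rmsd_bootstrap(
    ensemble: FrameEnsemble,
    n_boot: int = 10,
    sample_size: int = 500,
    align_selection=None,
    rmsd_selection=None,
    seed: int = 0,
    replace: bool = True,
) -> RmsdMatrixSummary:
    """Bootstrap pairwise-RMSD matrices of a frame ensemble.

    For each of ``n_boot`` bootstrap draws of ``sample_size`` frames, all
    frame pairs are superposed and an RMSD matrix computed; the mean
    off-diagonal RMSD per bootstrap and its mean/sd across bootstraps are
    reported alongside the matrices.
    """
    if not replace and sample_size > ensemble.n_frames:
        raise ValueError("sample_size exceeds ensemble size for sampling without replacement")
    rng = np.random.default_rng(seed)
    mats = []
    means = np.empty(n_boot)
    iu = np.triu_indices(sample_size, k=1)
    for b in range(n_boot):
        idx = (
            rng.integers(0, ensemble.n_frames, size=sample_size)
            if replace
            else rng.choice(ensemble.n_frames, size=sample_size, replace=False)
        )
        mat = pairwise_rmsd_matrix(ensemble.frames[idx], align_selection, rmsd_selection)
        mats.append(mat)
        means[b] = float(mat[iu].mean())
    return RmsdMatrixSummary(
        matrices=mats,
        mean_rmsd_per_boot=means,
        mean_rmsd=float(means.mean()),
        sd_rmsd=float(means.std(ddof=0)),
        n_boot=n_boot,
        sample_size=sample_size,
    )


def filter_frames_by_distance(
    frames: np.ndarray, distance_series, threshold: float = 4.5, mode: str = "greater"
) -> np.ndarray:
    """Select frames whose paired distance satisfies a strict inequality.

    ``mode`` is "greater" (keep distance > threshold) or "less".  Values
    exactly at the threshold are excluded either way.
    """
    frames = np.asarray(frames)
    d = np.asarray(distance_series, dtype=float)
    if frames.shape[0] != d.shape[0]:
        raise ValueError(
            f"frame count {frames.shape[0]} and distance count {d.shape[0]} differ"
        )
    if mode == "greater":
        keep = d > threshold
    elif mode == "less":
        keep = d < threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frames[keep]
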