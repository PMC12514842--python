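"""Conformational-ensemble analytics.

Pairwise RMSD over main-chain + Cβ atoms, GROMOS-style neighbor-counting
clustering at a distance cutoff, per-frame catalytic-Ser SASA series, and
a deterministic two-component univariate Gaussian mixture fit (EM with a
median-split initialization, so no RNG is involved anywhere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError
from .sasa import SasaParams, ser_sidechain_sasa
from .structure_io import (
    MAINCHAIN_CB_ATOMS,
    AtomSelection,
    StructureModel,
    parse_structure,
    select_atoms,
)
from .superposition import kabsch_fit

__all__ = [
    "Ensemble",
    "ClusteringParams",
    "ClusteringResult",
    "GaussianMixtureFit",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "sasa_series",
    "fit_two_gaussians",
]


@dataclass
class Ensemble:
    """Ordered conformations sharing one atom topology."""

    frames: list[StructureModel]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("an ensemble needs at least one frame")
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.frames))]
        if len(self.labels) != len(self.frames):
            raise ValidationError("labels and frames length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Ensemble":
        models = parse_structure(path, ensemble=True)
        return cls(models, [m.id for m in models])

    @classmethod
    def from_files(cls, paths: Sequence[str | Path]) -> "Ensemble":
        models = [parse_structure(p) for p in paths]
        return cls(models, [m.id for m in models])

    def default_selection(self) -> AtomSelection:
        """Main-chain + Cβ atoms of every non-water residue of frame 0."""
        items = []
        for chain in self.frames[0].chains:
            for res in chain:
                if res.is_water:
                    continue
                for name in MAINCHAIN_CB_ATOMS:
                    if res.get(name) is not None:
                        items.append((res.ref, name))
        return AtomSelection(items)

    def coordinates(self, selection: AtomSelection | None = None) -> np.ndarray:
        """(n_frames, n_atoms, 3) array; strict in every frame."""
        sel = selection or self.default_selection()
        return np.stack([select_atoms(f, sel) for f in self.frames])


@dataclass
class ClusteringParams:
    cutoff: float = 1.0
    selection: AtomSelection | None = None
    fit_before_distance: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")


def pairwise_rmsd_matrix(
    ensemble: Ensemble, params: ClusteringParams | None = None
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix over the clustering selection.

    With ``fit_before_distance`` each pair is optimally superposed first,
    so pure rigid motions between frames contribute zero.
    """
    params = params or ClusteringParams()
    if len(ensemble) < 2:
        raise ValidationError("pairwise RMSD needs at least 2 frames")
    coords = ensemble.coordinates(params.selection)
    n = len(coords)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if params.fit_before_distance:
                rmsd = kabsch_fit(coords[j], coords[i]).rmsd
            else:
                diff = coords[j] - coords[i]
                rmsd = float(np.sqrt((diff * diff).sum() / len(diff)))
            matrix[i, j] = matrix[j, i] = rmsd
    return matrix


@dataclass
class ClusteringResult:
    """GROMOS clustering output: exhaustive, disjoint, size-ordered."""

    assignment: np.ndarray  # frame index -> cluster id
    representatives: list[int]  # cluster id -> frame index of the seed
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignment == cluster_id)[0]

    @property
    def populations(self) -> np.ndarray:
        counts = np.bincount(self.assignment, minlength=self.n_clusters)
        return counts / counts.sum()

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_clusters": self.n_clusters,
            "assignment": self.assignment.tolist(),
            "representatives": list(self.representatives),
            "populations": self.populations.tolist(),
        }


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusteringResult:
    """Neighbor-counting clustering of a distance matrix.

    Repeatedly: the frame with the most remaining neighbors within the
    cutoff (ties to the lowest frame index) seeds a cluster containing
    itself plus those neighbors; all are removed; repeat until empty.
    The cutoff comparison is inclusive.
    """
    D = np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValidationError("distance matrix diagonal must be zero")
    n = D.shape[0]
    within = D <= cutoff
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    seeds: list[int] = []
    cluster_id = 0
    while remaining.any():
        counts = (within & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(within[seed] & remaining)[0]
        assignment[members] = cluster_id
        seeds.append(seed)
        remaining[members] = False
        cluster_id += 1
    # reorder clusters by size (descending), stable in formation order
    sizes = np.bincount(assignment, minlength=cluster_id)
    order = sorted(range(cluster_id), key=lambda c: (-sizes[c], c))
    relabel = {old: new for new, old in enumerate(order)}
    assignment = np.array([relabel[c] for c in assignment])
    seeds = [seeds[old] for old in order]
    return ClusteringResult(assignment, seeds, cutoff)


def sasa_series(
    ensemble: Ensemble, site, params: SasaParams | None = None
) -> np.ndarray:
    """Catalytic-Ser sidechain SASA (Å²) per frame, in frame order."""
    params = params or SasaParams()
    return np.array([ser_sidechain_sasa(f, site, params) for f in ensemble.frames])


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture (univariate EM)
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureFit:
    """Two-component normal mixture; means reported in ascending order."""

    means: tuple[float, float]
    sigmas: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    ll_trajectory: list[float]
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigmas):
            raise FitError(f"non-positive sigma in fit: {self.sigmas}")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise FitError(f"weights must sum to 1: {self.weights}")

    @property
    def degenerate(self) -> bool:
        """True when the components are closer than one σ (collapsed fit)."""
        return abs(self.means[1] - self.means[0]) < max(self.sigmas)

    def to_dict(self) -> dict:
        return {
            "means": list(self.means),
            "sigmas": list(self.sigmas),
            "weights": list(self.weights),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


def _log_gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2.0 * math.pi))


def fit_two_gaussians(
    values: Sequence[float],
    init: tuple[float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GaussianMixtureFit:
    """Maximum-likelihood two-component univariate normal mixture via EM.

    Deterministic: initialization splits the data at the median (or uses
    the two supplied initial means) and EM runs until the log-likelihood
    improves by less than ``tol`` or ``max_iter`` iterations.  Raises
    :class:`FitError` on degenerate (near-constant) data.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 50:
        raise ValidationError(f"need at least 50 values for a mixture fit, got {x.size}")
    scale = float(x.std())
    if scale < 1e-12:
        raise FitError(
            "zero-variance data: a mixture fit is meaningless; "
            "report a single-component summary instead"
        )
    sigma_floor = 1e-6 * scale

    if init is None:
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if len(hi) == 0:  # heavy ties at the median
            lo, hi = x[x < med], x[x >= med]
        mu = np.array([lo.mean(), hi.mean()])
        sg = np.array([max(lo.std(), sigma_floor), max(hi.std(), sigma_floor)])
        w = np.array([len(lo), len(hi)], dtype=float)
        w /= w.sum()
    else:
        mu = np.asarray(sorted(init), dtype=float)
        sg = np.array([scale, scale])
        w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    trajectory: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        log_resp = np.stack(
            [np.log(w[k]) + _log_gauss(x, mu[k], sg[k]) for k in (0, 1)]
        )
        log_norm = np.logaddexp(log_resp[0], log_resp[1])
        ll = float(log_norm.sum())
        trajectory.append(ll)
        resp = np.exp(log_resp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in (0, 1)])
        sg = np.sqrt(np.maximum(var, sigma_floor**2))
        w = nk / len(x)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)
    return GaussianMixtureFit(
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sigmas=(float(sg[order[0]]), float(sg[order[1]])),
        weights=(float(w[order[0]]), float(w[order[1]])),
        log_likelihood=trajectory[-1],
        ll_trajectory=trajectory,
        n_iter=n_iter,
        converged=converged,
    )
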