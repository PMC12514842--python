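"""Rigid-body superposition.

Least-squares fitting of paired point sets (Kabsch, SVD form with the
determinant correction that excludes reflections) and the core-fit
convention used throughout the package: each mobile chain is fitted onto
its reference counterpart on the backbone atoms of configured core
segments, and the whole chain is then moved into the reference frame so
that local loop motions become measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, MissingAtomError, PairingError
from .structure_io import (
    AtomSelection,
    SegmentSpec,
    StructureModel,
    select_atoms,
)

__all__ = ["Transform", "kabsch_fit", "apply_transform", "transform_model", "core_superpose"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Transform:
    """Proper rigid motion y = R x + t with the RMSD of the fit behind it."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("Transform requires a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation has negative determinant (reflection)")
        if self.rmsd < 0:
            raise GeometryError("rmsd must be non-negative")

    @classmethod
    def identity(cls, n_atoms: int = 3) -> "Transform":
        return cls(np.eye(3), np.zeros(3), 0.0, n_atoms)

    def inverse(self) -> "Transform":
        R = self.rotation.T
        return Transform(R, -R @ self.translation, self.rmsd, self.n_atoms)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Optimal proper rigid motion of ``mobile`` onto ``reference``.

    Minimizes the RMSD over all rotations with det +1 and translations.
    Requires at least 3 non-collinear point pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"point sets must share an (n, 3) shape; got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"at least 3 point pairs required for a rigid fit; got {n}")

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc

    # collinearity check: centered cloud must span a plane
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2 or np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear) point configuration; fit is ill-defined")

    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc

    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    assert np.linalg.det(R) > 0
    return Transform(R, t, rmsd, n)


def apply_transform(t: Transform, coords: np.ndarray) -> np.ndarray:
    """Apply y = R x + t rowwise; preserves all pairwise distances."""
    X = np.asarray(coords, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) coordinates, got shape {X.shape}")
    Y = X @ t.rotation.T + t.translation
    return Y[0] if single else Y


def transform_model(
    model: StructureModel,
    transforms: Transform | Mapping[str, Transform],
) -> StructureModel:
    """Return a copy of the model with per-chain (or global) transforms applied."""
    out = model.copy()
    for chain in out.chains:
        t = transforms if isinstance(transforms, Transform) else transforms.get(chain.chain_id)
        if t is None:
            continue
        for res in chain:
            for atom in res.atoms.values():
                atom.coords = apply_transform(t, atom.coords)
    return out


def resolve_chain_pairing(
    mobile: StructureModel,
    reference: StructureModel,
    chain_pairing: str | Mapping[str, str] = "by_id",
) -> dict[str, str]:
    """Map mobile chain id -> reference chain id."""
    if chain_pairing == "by_id":
        common = [cid for cid in mobile.chain_ids if cid in reference.chain_ids]
        if not common:
            raise PairingError(
                f"no common chain ids between {mobile.id!r} ({mobile.chain_ids}) "
                f"and {reference.id!r} ({reference.chain_ids}); pass an explicit map"
            )
        return {cid: cid for cid in common}
    pairing = dict(chain_pairing)
    for mob, ref in pairing.items():
        if mobile.get_chain(mob) is None:
            raise PairingError(f"mobile model {mobile.id!r} has no chain {mob!r}")
        if reference.get_chain(ref) is None:
            raise PairingError(f"reference model {reference.id!r} has no chain {ref!r}")
    return pairing


def core_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    core: Sequence[SegmentSpec],
    chain_pairing: str | Mapping[str, str] = "by_id",
    lenient: bool = False,
) -> tuple[dict[str, Transform], StructureModel]:
    """Fit every mobile chain onto its reference counterpart on core atoms.

    The fit is per chain and unweighted, on the atoms named by the core
    segments (backbone N/CA/C/O by default).  Returns the per-chain
    transforms keyed by *mobile* chain id together with a transformed copy
    of the mobile model, so downstream shifts are measured in the
    reference frame.

    Strict mode (default) demands every core atom in both models and
    reports the full missing list; ``lenient=True`` fits on the
    intersection of atoms present in both (for depositions with
    unmodelled residues).
    """
    pairing = resolve_chain_pairing(mobile, reference, chain_pairing)
    transforms: dict[str, Transform] = {}
    for mob_id, ref_id in pairing.items():
        if lenient:
            mob_items = {
                (r.seq_num, r.icode, n): (r, n)
                for r, n in AtomSelection.from_segments(core, [mob_id], model=mobile)
            }
            ref_items = {
                (r.seq_num, r.icode, n): (r, n)
                for r, n in AtomSelection.from_segments(core, [ref_id], model=reference)
            }
            common = [k for k in mob_items if k in ref_items]
            sel_mob = AtomSelection([mob_items[k] for k in common])
            sel_ref = AtomSelection([ref_items[k] for k in common])
        else:
            sel_mob = AtomSelection.from_segments(core, [mob_id])
            sel_ref = AtomSelection.from_segments(core, [ref_id])
        try:
            mob_xyz = select_atoms(mobile, sel_mob)
            ref_xyz = select_atoms(reference, sel_ref)
        except MissingAtomError as exc:
            raise MissingAtomError(
                exc.missing, context=f"core fit of chain {mob_id!r} onto {ref_id!r}"
            ) from exc
        transforms[mob_id] = kabsch_fit(mob_xyz, ref_xyz)
    moved = transform_model(mobile, transforms)
    return transforms, moved
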