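"""Shrake-Rupley solvent-accessible surface area.

Classic sphere-sampling SASA with two reproducibility guarantees that the
usual implementations lack:

* the test-point lattice is a deterministic golden-spiral set (no RNG), so
  results are bit-reproducible, and
* each atom's lattice is oriented in a local frame derived covariantly from
  its occluding neighbors (polar axis toward the nearest neighbor, azimuth
  fixed by the nearest non-collinear one), so rigidly moving the whole
  system moves every test point with it and areas are exactly invariant.

Neighbor search uses a uniform spatial grid whose cell size bounds the
largest possible contact distance; it returns results identical to the
all-pairs computation by construction (asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingAtomError, ValidationError
from .structure_io import AtomSelection, ResidueRef, StructureModel

__all__ = [
    "DEFAULT_RADII",
    "SasaParams",
    "SasaResult",
    "shrake_rupley",
    "ser_sidechain_sasa",
    "golden_spiral_points",
]

#: Single published van der Waals set (Å); override via SasaParams.radii_table.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii_table: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValidationError(f"probe_radius must be positive, got {self.probe_radius}")
        if self.n_points < 60:
            raise ValidationError(f"n_points must be >= 60, got {self.n_points}")

    def radius_for(self, ref: ResidueRef, atom_name: str, element: str) -> float:
        key = element.upper()
        if key in self.radii_table:
            return float(self.radii_table[key])
        raise ValidationError(
            f"no van der Waals radius for element {element!r} "
            f"(atom {ref}:{atom_name}); extend SasaParams.radii_table"
        )

    def echo(self) -> dict:
        return {
            "probe_radius": self.probe_radius,
            "n_points": self.n_points,
            "radii_table": dict(self.radii_table),
        }


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic unit-sphere lattice of n points (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom areas plus residue/selection sums, with the params echoed."""

    refs: list[tuple[ResidueRef, str]]
    areas: np.ndarray
    radii: np.ndarray
    params: SasaParams

    def __post_init__(self) -> None:
        self._index = {
            (r.chain_id, r.seq_num, r.icode, name): i for i, (r, name) in enumerate(self.refs)
        }

    def atom_area(self, ref: ResidueRef, atom_name: str) -> float:
        key = (ref.chain_id, ref.seq_num, ref.icode, atom_name)
        if key not in self._index:
            raise MissingAtomError([(ref, atom_name)], context="SASA result")
        return float(self.areas[self._index[key]])

    def residue_area(self, ref: ResidueRef) -> float:
        total = 0.0
        found = False
        for i, (r, _) in enumerate(self.refs):
            if (r.chain_id, r.seq_num, r.icode) == (ref.chain_id, ref.seq_num, ref.icode):
                total += float(self.areas[i])
                found = True
        if not found:
            raise MissingAtomError([(ref, "*")], context="SASA result")
        return total

    def selection_sum(self, selection: AtomSelection) -> float:
        return float(sum(self.atom_area(ref, name) for ref, name in selection))

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r.chain_id for r, _ in self.refs],
                "seq_num": [r.seq_num for r, _ in self.refs],
                "icode": [r.icode for r, _ in self.refs],
                "res_name": [r.res_name for r, _ in self.refs],
                "atom": [name for _, name in self.refs],
                "radius": self.radii,
                "area": self.areas,
            }
        )

    def to_dict(self) -> dict:
        return {"total": self.total, "n_atoms": len(self.refs), "params": self.params.echo()}


def _local_frames(centers: np.ndarray, neighbor_lists: list[np.ndarray]) -> np.ndarray:
    """Covariant lattice orientation per atom.

    Polar axis e3 points at the nearest occluding neighbor; the azimuthal
    axis comes from the nearest neighbor direction not collinear with e3.
    Atoms whose occlusion geometry is axially symmetric (zero or collinear
    neighbors) get an arbitrary but deterministic completion, which cannot
    affect the buried-point count.
    """
    n = len(centers)
    frames = np.tile(np.eye(3), (n, 1, 1))
    for i in range(n):
        nbrs = neighbor_lists[i]
        if len(nbrs) == 0:
            continue  # no occluders: orientation irrelevant (full sphere)
        d = np.linalg.norm(centers[nbrs] - centers[i], axis=1)
        order = nbrs[np.lexsort((nbrs, d))]
        e3 = centers[order[0]] - centers[i]
        e3 /= np.linalg.norm(e3)
        e1 = None
        for j in order[1:]:
            v = centers[j] - centers[i]
            v = v - (v @ e3) * e3
            norm = np.linalg.norm(v)
            if norm > 1e-8:
                e1 = v / norm
                break
        if e1 is None:  # collinear occluders: axially symmetric, any azimuth
            pick = np.argmin(np.abs(e3))
            v = np.zeros(3)
            v[pick] = 1.0
            v = v - (v @ e3) * e3
            e1 = v / np.linalg.norm(v)
        e2 = np.cross(e3, e1)
        frames[i] = np.column_stack([e1, e2, e3]).T  # rows: e1, e2, e3
    return frames


def _neighbor_lists_allpairs(centers: np.ndarray, radii_ext: np.ndarray) -> list[np.ndarray]:
    n = len(centers)
    out = []
    for i in range(n):
        d = np.linalg.norm(centers - centers[i], axis=1)
        mask = d < (radii_ext + radii_ext[i])
        mask[i] = False
        out.append(np.nonzero(mask)[0])
    return out


def _neighbor_lists_grid(centers: np.ndarray, radii_ext: np.ndarray) -> list[np.ndarray]:
    """Grid-accelerated neighbor lists, identical to the all-pairs result."""
    cell = 2.0 * float(radii_ext.max())
    keys = np.floor(centers / cell).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for i, k in enumerate(map(tuple, keys)):
        buckets.setdefault(k, []).append(i)
    out = []
    for i in range(len(centers)):
        kx, ky, kz = keys[i]
        cand = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    cand.extend(buckets.get((kx + dx, ky + dy, kz + dz), ()))
        cand = np.array([j for j in cand if j != i], dtype=int)
        if len(cand) == 0:
            out.append(cand)
            continue
        d = np.linalg.norm(centers[cand] - centers[i], axis=1)
        out.append(np.sort(cand[d < (radii_ext[cand] + radii_ext[i])]))
    return out


def _compute_areas(
    centers: np.ndarray,
    radii: np.ndarray,
    params: SasaParams,
    use_grid: bool = True,
) -> np.ndarray:
    radii_ext = radii + params.probe_radius
    neighbor_fn = _neighbor_lists_grid if use_grid else _neighbor_lists_allpairs
    neighbors = neighbor_fn(centers, radii_ext)
    frames = _local_frames(centers, neighbors)
    lattice = golden_spiral_points(params.n_points)
    areas = np.empty(len(centers))
    for i in range(len(centers)):
        R = radii_ext[i]
        full = 4.0 * math.pi * R * R
        nbrs = neighbors[i]
        if len(nbrs) == 0:
            areas[i] = full
            continue
        points = centers[i] + R * (lattice @ frames[i])
        accessible = np.ones(len(points), dtype=bool)
        for j in nbrs:
            dj = np.linalg.norm(points - centers[j], axis=1)
            accessible &= dj >= radii_ext[j]
            if not accessible.any():
                break
        areas[i] = full * accessible.sum() / params.n_points
    return areas


def shrake_rupley(
    model: StructureModel,
    params: SasaParams | None = None,
    *,
    radii: Sequence[float] | None = None,
    include_waters: bool = False,
    include_hydrogens: bool = False,
    use_grid: bool = True,
) -> SasaResult:
    """Per-atom SASA of a model.

    Hydrogens and waters are excluded by default (the policy for all
    measurements in this package); HETATM ligand atoms are included since
    they occlude the catalytic serine.  ``radii`` overrides the element
    table with one explicit radius per included atom, in iteration order
    (used by the analytic sphere-system fixtures).
    """
    params = params or SasaParams()
    refs: list[tuple[ResidueRef, str]] = []
    centers = []
    for ref, atom in model.iter_atoms(
        include_hydrogens=include_hydrogens, include_waters=include_waters
    ):
        refs.append((ref, atom.name))
        centers.append(atom.coords)
    if not refs:
        raise ValidationError(f"model {model.id!r}: no atoms eligible for SASA")
    centers = np.asarray(centers)
    if radii is not None:
        radii_arr = np.asarray(radii, dtype=float)
        if radii_arr.shape != (len(refs),):
            raise ValidationError(
                f"explicit radii length {radii_arr.shape} != atom count {len(refs)}"
            )
    else:
        radii_arr = np.array(
            [
                params.radius_for(ref, name, model.get_atom(ref, name).element)
                for ref, name in refs
            ]
        )
    areas = _compute_areas(centers, radii_arr, params, use_grid=use_grid)
    return SasaResult(refs, areas, radii_arr, params)


SER_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


def ser_sidechain_sasa(
    model: StructureModel,
    site,
    params: SasaParams | None = None,
    chain: str | None = None,
) -> float:
    """SASA (Å²) of the catalytic-Ser sidechain heavy atoms, in full context.

    Computed over the entire model (ligands included) and summed over the
    Ser sidechain heavy atoms (Cβ, Oγ).  For oligomers the value is the
    mean over chains carrying the site unless ``chain`` is given.
    """
    params = params or SasaParams()
    result = shrake_rupley(model, params)
    chain_ids = [chain] if chain is not None else [
        cid for cid in model.chain_ids if model.get_residue(site.ser.bind(cid)) is not None
    ]
    if not chain_ids:
        raise MissingAtomError([(site.ser.bind("?"), "CA")], context=f"model {model.id!r}")
    values = []
    for cid in chain_ids:
        ref = site.ser.bind(cid)
        res = model.get_residue(ref)
        if res is None:
            raise MissingAtomError([(ref, "CA")], context=f"model {model.id!r}")
        side = [
            name
            for name, a in res.atoms.items()
            if name not in SER_BACKBONE and not a.is_hydrogen
        ]
        if not side:
            raise MissingAtomError([(ref, "CB/OG")], context=f"model {model.id!r}")
        values.append(sum(result.atom_area(res.ref, name) for name in side))
    return float(np.mean(values))
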