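"""Active-site geometry measurements.

The measurement core of the package: the d1/d2/d3 active-site triangle,
apo-to-holo loop shifts with toward/away direction classification, pairwise
contact distances, hydrogen-bond classification by heavy-atom distance, and
apo/holo delta tables.

All per-chain quantities are reported both individually and chain-averaged
(arithmetic mean with sample SD); display values round to 0.1 Å while raw
values are retained in JSON/CSV exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, MissingAtomError, ValidationError
from .structure_io import (
    AtomRecord,
    ResidueRef,
    ResidueSpec,
    SegmentSpec,
    StructureModel,
)
from .superposition import Transform, core_superpose

__all__ = [
    "LigandSpec",
    "SiteDefinition",
    "TriadTriangle",
    "ShiftRow",
    "ShiftReport",
    "DeltaTable",
    "atom_distance",
    "triad_triangle",
    "loop_shift",
    "hbond_classify",
    "delta_table",
]

#: Below this displacement (Å) a shift has no meaningful direction.
_DIRECTION_EPS = 1e-9

DELTA_COLUMNS = [
    "label",
    "d1_apo", "d2_apo", "d3_apo",
    "d1_holo", "d2_holo", "d3_holo",
    "dd1", "dd2", "dd3",
]


@dataclass(frozen=True)
class LigandSpec:
    """How to find the bound ligand and which of its atoms anchor geometry.

    ``key_atoms`` name the atoms whose centroid serves as the direction
    reference for shift classification (e.g. the tetrahedral/phosphoryl
    oxygen and the amide nitrogen).  ``seq_num=None`` matches the first
    residue with ``res_name`` in each chain.
    """

    res_name: str
    key_atoms: tuple[str, ...]
    seq_num: int | None = None
    icode: str = ""


@dataclass
class SiteDefinition:
    """Declarative description of one enzyme's catalytic machinery."""

    ser: ResidueSpec
    his: ResidueSpec
    asp: ResidueSpec
    oxyanion_donors: list[tuple[ResidueSpec, str]]
    oxyanion_loop: SegmentSpec
    his_loop: SegmentSpec
    core: list[SegmentSpec]
    distal_donor_index: int = 0
    ser_og: str = "OG"
    ligand: LigandSpec | None = None
    name: str = ""

    def __post_init__(self) -> None:
        triad = {(self.ser.seq_num, self.ser.icode), (self.his.seq_num, self.his.icode),
                 (self.asp.seq_num, self.asp.icode)}
        if len(triad) != 3:
            raise ValidationError(f"site {self.name!r}: triad residues must be distinct")
        if not self.oxyanion_donors:
            raise ValidationError(f"site {self.name!r}: at least one oxyanion donor required")
        if not 0 <= self.distal_donor_index < len(self.oxyanion_donors):
            raise ValidationError(
                f"site {self.name!r}: distal_donor_index {self.distal_donor_index} out of range"
            )
        if self.oxyanion_loop.overlaps(self.his_loop):
            raise ValidationError(f"site {self.name!r}: oxyanion and His loop segments overlap")

    @property
    def distal_donor(self) -> tuple[ResidueSpec, str]:
        return self.oxyanion_donors[self.distal_donor_index]


# ---------------------------------------------------------------------------
# Elementary measurements
# ---------------------------------------------------------------------------


def _require_atom(model: StructureModel, ref: ResidueRef, atom_name: str) -> AtomRecord:
    atom = model.get_atom(ref, atom_name)
    if atom is None:
        raise MissingAtomError([(ref, atom_name)], context=f"model {model.id!r}")
    return atom


def atom_distance(
    model: StructureModel,
    a: tuple[ResidueRef, str],
    b: tuple[ResidueRef, str],
) -> float:
    """Euclidean distance (Å) between two named atoms of one model."""
    xa = _require_atom(model, *a).coords
    xb = _require_atom(model, *b).coords
    return float(np.linalg.norm(xa - xb))


def hbond_classify(distance: float, cutoff: float = 3.5) -> str:
    """Classify a heavy-atom donor-acceptor distance: "bond" iff d <= cutoff.

    The boundary is inclusive.  No angular term is applied: the structures
    this package targets lack hydrogens.
    """
    if distance < 0:
        raise ValidationError(f"distance must be non-negative, got {distance}")
    return "bond" if distance <= cutoff else "too_far"


# ---------------------------------------------------------------------------
# Triad triangle
# ---------------------------------------------------------------------------


@dataclass
class TriadTriangle:
    """d1/d2/d3 active-site spaciousness triangle, per chain and averaged.

    d1: Cα(Ser)-Cα(His); d2: Cα(Ser)-donor heteroatom; d3: donor
    heteroatom-Cα(His).  The donor heteroatom is the configured distal
    oxyanion donor atom (backbone N usually; a sidechain O for sites where
    a tyrosine hydroxyl replaces the loop amide).
    """

    per_chain: list[tuple[str, float, float, float]]
    site_name: str = ""

    def __post_init__(self) -> None:
        for cid, d1, d2, d3 in self.per_chain:
            for d in (d1, d2, d3):
                if d <= 0:
                    raise GeometryError(f"chain {cid}: non-positive triangle edge {d}")
            for a, b, c in ((d1, d2, d3), (d2, d1, d3), (d3, d1, d2)):
                if a > b + c + 1e-9:
                    raise GeometryError(f"chain {cid}: triangle inequality violated")

    def _column(self, i: int) -> np.ndarray:
        return np.array([row[i] for row in self.per_chain], dtype=float)

    @property
    def d1(self) -> float:
        return float(self._column(1).mean())

    @property
    def d2(self) -> float:
        return float(self._column(2).mean())

    @property
    def d3(self) -> float:
        return float(self._column(3).mean())

    @property
    def sd(self) -> tuple[float | None, float | None, float | None]:
        """Sample SD of each edge over chains; None for single-chain models."""
        if len(self.per_chain) < 2:
            return (None, None, None)
        return tuple(float(self._column(i).std(ddof=1)) for i in (1, 2, 3))

    def to_dict(self) -> dict:
        sd1, sd2, sd3 = self.sd
        return {
            "site": self.site_name,
            "per_chain": [
                {"chain": c, "d1": d1, "d2": d2, "d3": d3} for c, d1, d2, d3 in self.per_chain
            ],
            "mean": {"d1": self.d1, "d2": self.d2, "d3": self.d3},
            "sd": {"d1": sd1, "d2": sd2, "d3": sd3},
        }


def triad_triangle(
    model: StructureModel,
    site: SiteDefinition,
    chains: Sequence[str] | None = None,
) -> TriadTriangle:
    """Measure the d1/d2/d3 triangle in every chain carrying the site."""
    chain_ids = list(chains) if chains is not None else model.chain_ids
    donor_spec, donor_atom = site.distal_donor
    rows = []
    for cid in chain_ids:
        if chains is None and model.get_residue(site.ser.bind(cid)) is None:
            continue  # chain without the catalytic machinery (e.g. ligand-only chain)
        ca_ser = _require_atom(model, site.ser.bind(cid), "CA").coords
        ca_his = _require_atom(model, site.his.bind(cid), "CA").coords
        donor = _require_atom(model, donor_spec.bind(cid), donor_atom).coords
        rows.append(
            (
                cid,
                float(np.linalg.norm(ca_ser - ca_his)),
                float(np.linalg.norm(ca_ser - donor)),
                float(np.linalg.norm(donor - ca_his)),
            )
        )
    if not rows:
        raise MissingAtomError(
            [(site.ser.bind(c), "CA") for c in chain_ids], context=f"model {model.id!r}"
        )
    return TriadTriangle(rows, site_name=site.name)


# ---------------------------------------------------------------------------
# Loop shifts
# ---------------------------------------------------------------------------


@dataclass
class ShiftRow:
    residue: ResidueSpec
    atom_name: str
    per_chain: dict[str, tuple[float, str]]  # chain -> (displacement Å, direction)

    @property
    def displacements(self) -> np.ndarray:
        return np.array([v[0] for v in self.per_chain.values()], dtype=float)

    @property
    def mean(self) -> float:
        return float(self.displacements.mean())

    @property
    def sd(self) -> float | None:
        if len(self.per_chain) < 2:
            return None
        return float(self.displacements.std(ddof=1))

    @property
    def display(self) -> float:
        """Chain-averaged displacement rounded to 0.1 Å for reporting."""
        return round(self.mean, 1)

    @property
    def direction(self) -> str:
        """Majority direction over chains; "n/a" when chains disagree evenly."""
        dirs = [v[1] for v in self.per_chain.values() if v[1] != "n/a"]
        if not dirs:
            return "n/a"
        toward = sum(1 for d in dirs if d == "toward")
        away = len(dirs) - toward
        if toward > away:
            return "toward"
        if away > toward:
            return "away"
        return "n/a"

    def to_dict(self) -> dict:
        return {
            "residue": str(self.residue),
            "atom": self.atom_name,
            "per_chain": {
                c: {"displacement": d, "direction": w} for c, (d, w) in self.per_chain.items()
            },
            "mean": self.mean,
            "sd": self.sd,
            "display": self.display,
            "direction": self.direction,
        }


@dataclass
class ShiftReport:
    rows: list[ShiftRow]
    reference_points: dict[str, list[float] | None]
    core_rmsd: dict[str, float]
    reference_kind: str  # "ligand_centroid" | "ser_og"

    def to_dict(self) -> dict:
        return {
            "reference_kind": self.reference_kind,
            "reference_points": self.reference_points,
            "core_rmsd": self.core_rmsd,
            "shifts": [r.to_dict() for r in self.rows],
        }

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "residue": str(row.residue),
                "atom": row.atom_name,
                "mean": row.mean,
                "sd": row.sd,
                "display": row.display,
                "direction": row.direction,
            }
            for cid, (disp, direction) in row.per_chain.items():
                rec[f"disp_{cid}"] = disp
                rec[f"dir_{cid}"] = direction
            records.append(rec)
        return pd.DataFrame.from_records(records)


def _ligand_centroid(
    model: StructureModel, chain_id: str, ligand: LigandSpec
) -> np.ndarray | None:
    chain = model.get_chain(chain_id)
    if chain is None:
        return None
    candidates = []
    if ligand.seq_num is not None:
        res = chain.get(ligand.seq_num, ligand.icode)
        if res is not None and res.ref.res_name == ligand.res_name.upper():
            candidates = [res]
    else:
        candidates = [r for r in chain if r.ref.res_name == ligand.res_name.upper()]
    for res in candidates:
        coords = [res.get(a).coords for a in ligand.key_atoms if res.get(a) is not None]
        if coords:
            return np.mean(coords, axis=0)
    return None


def loop_shift(
    apo: StructureModel,
    holo: StructureModel,
    site: SiteDefinition,
    atoms: Sequence[tuple[ResidueSpec, str]],
    chain_pairing: str | Mapping[str, str] = "by_id",
    lenient_core: bool = False,
) -> ShiftReport:
    """Displacement of named atoms between apo and holo, after core fitting.

    Each holo chain is superposed onto its apo counterpart on the core
    segments of the site definition; displacements are Euclidean distances
    in that common frame.  Direction is classified against a per-chain
    reference point: the centroid of the ligand key atoms when the holo
    structure carries the configured ligand, otherwise the holo catalytic
    Ser sidechain oxygen.  "toward" means the holo position is closer to
    the reference point than the apo position.
    """
    transforms, holo_fit = core_superpose(
        holo, apo, site.core, chain_pairing=chain_pairing, lenient=lenient_core
    )
    from .superposition import resolve_chain_pairing

    pairing = resolve_chain_pairing(holo, apo, chain_pairing)

    ref_points: dict[str, np.ndarray | None] = {}
    ref_kind = "ser_og"
    for holo_cid in transforms:
        point = None
        if site.ligand is not None:
            point = _ligand_centroid(holo_fit, holo_cid, site.ligand)
            if point is not None:
                ref_kind = "ligand_centroid"
        if point is None:
            og = holo_fit.get_atom(site.ser.bind(holo_cid), site.ser_og)
            point = og.coords if og is not None else None
        ref_points[holo_cid] = point

    rows = []
    for spec, atom_name in atoms:
        per_chain: dict[str, tuple[float, str]] = {}
        for holo_cid, apo_cid in pairing.items():
            x_apo = _require_atom(apo, spec.bind(apo_cid), atom_name).coords
            x_holo = _require_atom(holo_fit, spec.bind(holo_cid), atom_name).coords
            disp = float(np.linalg.norm(x_holo - x_apo))
            ref = ref_points[holo_cid]
            if disp < _DIRECTION_EPS or ref is None:
                direction = "n/a"
            else:
                direction = (
                    "toward"
                    if np.linalg.norm(x_holo - ref) < np.linalg.norm(x_apo - ref)
                    else "away"
                )
            per_chain[holo_cid] = (disp, direction)
        rows.append(ShiftRow(spec, atom_name, per_chain))

    return ShiftReport(
        rows=rows,
        reference_points={
            c: (p.tolist() if p is not None else None) for c, p in ref_points.items()
        },
        core_rmsd={c: t.rmsd for c, t in transforms.items()},
        reference_kind=ref_kind,
    )


def ligand_contact(
    model: StructureModel,
    site: SiteDefinition,
    protein_atom: tuple[ResidueSpec, str],
    ligand_atom: str,
) -> tuple[dict[str, float], float]:
    """Distance from a protein atom to one ligand key atom, per chain + mean.

    The ligand residue is located through the site's :class:`LigandSpec` in
    each chain that carries both the protein residue and the ligand.
    """
    if site.ligand is None:
        raise ValidationError(f"site {site.name!r} has no ligand definition")
    spec, atom_name = protein_atom
    per_chain: dict[str, float] = {}
    for cid in model.chain_ids:
        prot = model.get_atom(spec.bind(cid), atom_name)
        if prot is None:
            continue
        chain = model.get_chain(cid)
        lig_res = None
        for res in chain:
            if res.ref.res_name == site.ligand.res_name.upper() and (
                site.ligand.seq_num is None or res.ref.seq_num == site.ligand.seq_num
            ):
                lig_res = res
                break
        if lig_res is None or lig_res.get(ligand_atom) is None:
            continue
        per_chain[cid] = float(np.linalg.norm(prot.coords - lig_res.get(ligand_atom).coords))
    if not per_chain:
        raise MissingAtomError(
            [(spec.bind("*"), atom_name)],
            context=f"ligand contact {site.ligand.res_name}:{ligand_atom} in {model.id!r}",
        )
    return per_chain, float(np.mean(list(per_chain.values())))


# ---------------------------------------------------------------------------
# Delta tables
# ---------------------------------------------------------------------------


@dataclass
class DeltaTable:
    """Apo/holo d1-d3 comparison across structure pairs; CSV-serializable."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def sort_by(self, column: str, ascending: bool = True) -> "DeltaTable":
        return DeltaTable(self.frame.sort_values(column, ascending=ascending).reset_index(drop=True))


def delta_table(
    entries: Sequence[tuple[str, TriadTriangle, TriadTriangle]]
) -> DeltaTable:
    """Build the apo/holo delta table from (label, apo, holo) triangle pairs."""
    if not entries:
        raise ValidationError("delta_table requires at least one entry")
    records = []
    for label, apo_tri, holo_tri in entries:
        rec = {"label": label}
        for i, name in ((1, "d1"), (2, "d2"), (3, "d3")):
            a = getattr(apo_tri, name)
            h = getattr(holo_tri, name)
            rec[f"{name}_apo"] = a
            rec[f"{name}_holo"] = h
            rec[f"d{name}"] = h - a
        records.append(rec)
    frame = pd.DataFrame.from_records(records)[DELTA_COLUMNS]
    return DeltaTable(frame)
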