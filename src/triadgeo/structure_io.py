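"""Macromolecular coordinate I/O and atom selection.

Reads PDB (v3.3 fixed column) and mmCIF files through Bio.PDB and converts
them into a small, explicit hierarchy (:class:`StructureModel` -> chains ->
residues -> :class:`AtomRecord`) with a deterministic alternate-location
policy.  Writes PDB for fixtures and transformed models.

Policies
--------
* Altlocs: the conformer with the highest occupancy wins; ties go to the
  lexicographically smallest altloc identifier.  Resolution is deterministic:
  the same file always yields the same model.
* Residue numbering: author numbering is authoritative.
* Hydrogens and waters are retained but flagged; distance and SASA code
  excludes them.
* Multi-model files yield model 1 unless ``ensemble=True``.
"""

from __future__ import annotations

import copy as _copy
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, MissingAtomError, ParseError, ValidationError

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "ResidueSpec",
    "Residue",
    "Chain",
    "StructureModel",
    "SegmentSpec",
    "AtomSelection",
    "parse_structure",
    "write_pdb",
    "select_atoms",
    "select_atoms_lenient",
    "BACKBONE_ATOMS",
    "MAINCHAIN_CB_ATOMS",
    "WATER_NAMES",
]

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")
MAINCHAIN_CB_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O", "CB")
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of one residue: chain, author residue number, insertion code."""

    chain_id: str
    seq_num: int
    icode: str = ""
    res_name: str = ""

    def __str__(self) -> str:  # e.g. "A/GLY509" or "A/509A"
        name = self.res_name or "?"
        return f"{self.chain_id}/{name}{self.seq_num}{self.icode}"

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_num, self.icode)


@dataclass(frozen=True)
class ResidueSpec:
    """Chain-agnostic residue identity, bound to a chain at measurement time.

    Site definitions describe the catalytic machinery of one monomer; the same
    spec is applied to every chain of an oligomer by :meth:`bind`.
    """

    res_name: str
    seq_num: int
    icode: str = ""

    def bind(self, chain_id: str) -> ResidueRef:
        return ResidueRef(chain_id, self.seq_num, self.icode, self.res_name.upper())

    def __str__(self) -> str:
        return f"{self.res_name}{self.seq_num}{self.icode}"


@dataclass
class AtomRecord:
    """One atom: PDB v3 name, element, position (Å), occupancy, altloc, B."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    ref: ResidueRef
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    is_hetatm: bool = False

    @property
    def is_water(self) -> bool:
        return self.ref.res_name in WATER_NAMES

    def get(self, atom_name: str) -> AtomRecord | None:
        return self.atoms.get(atom_name)

    def copy(self) -> "Residue":
        return Residue(self.ref, {k: a.copy() for k, a in self.atoms.items()}, self.is_hetatm)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[int, str], Residue] = {}
        self.reindex()

    def reindex(self) -> None:
        self.residues.sort(key=lambda r: r.ref.key)
        self._index = {r.ref.key: r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise ValidationError(f"chain {self.chain_id}: duplicate residue identifiers")

    def get(self, seq_num: int, icode: str = "") -> Residue | None:
        return self._index.get((seq_num, icode))

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """Hierarchical coordinate model: ordered chains of ordered residues."""

    id: str
    chains: list[Chain]
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValidationError(f"model {self.id!r}: at least one chain required")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"model {self.id!r}: duplicate chain ids {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def get_residue(self, ref: ResidueRef) -> Residue | None:
        chain = self.get_chain(ref.chain_id)
        if chain is None:
            return None
        res = chain.get(ref.seq_num, ref.icode)
        if res is not None and ref.res_name and res.ref.res_name != ref.res_name:
            return None
        return res

    def get_atom(self, ref: ResidueRef, atom_name: str) -> AtomRecord | None:
        res = self.get_residue(ref)
        if res is None:
            return None
        return res.get(atom_name)

    def find_residues(self, res_name: str, chain_id: str | None = None) -> list[Residue]:
        """All residues with the given 3-letter code, optionally in one chain."""
        out = []
        for chain in self.chains:
            if chain_id is not None and chain.chain_id != chain_id:
                continue
            out.extend(r for r in chain if r.ref.res_name == res_name.upper())
        return out

    def iter_atoms(
        self, *, include_hydrogens: bool = True, include_waters: bool = True
    ) -> Iterator[tuple[ResidueRef, AtomRecord]]:
        for chain in self.chains:
            for res in chain:
                if not include_waters and res.is_water:
                    continue
                for atom in res.atoms.values():
                    if not include_hydrogens and atom.is_hydrogen:
                        continue
                    yield res.ref, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def copy(self) -> "StructureModel":
        return StructureModel(self.id, [c.copy() for c in self.chains], self.source_format)


@dataclass(frozen=True)
class SegmentSpec:
    """Contiguous author-numbered residue range with an atom-name set.

    ``atoms=None`` means every heavy atom of every residue in range.  A
    segment is chain-agnostic; it is expanded against a concrete chain.
    """

    start: int
    end: int
    atoms: tuple[str, ...] | None = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"segment {self.start}-{self.end}: end before start")

    def overlaps(self, other: "SegmentSpec") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class AtomSelection:
    """Ordered, duplicate-free list of (ResidueRef, atom-name) pairs."""

    items: list[tuple[ResidueRef, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for ref, name in self.items:
            key = (ref.chain_id, ref.seq_num, ref.icode, name)
            if key in seen:
                raise ValidationError(f"duplicate selection item {ref}:{name}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @classmethod
    def from_segments(
        cls,
        segments: Sequence[SegmentSpec],
        chain_ids: Sequence[str],
        model: StructureModel | None = None,
    ) -> "AtomSelection":
        """Expand segments over chains, in (chain, segment, residue, atom) order.

        With ``model`` given, only atoms actually present in the model are
        emitted (used to tolerate unmodelled loop residues in depositions);
        without it the expansion is purely nominal and strict selection will
        report anything absent.
        """
        items: list[tuple[ResidueRef, str]] = []
        for cid in chain_ids:
            chain = model.get_chain(cid) if model is not None else None
            if model is not None and chain is None:
                continue
            for seg in segments:
                for seq in range(seg.start, seg.end + 1):
                    if chain is not None:
                        res = chain.get(seq)
                        if res is None:
                            continue
                        names = seg.atoms if seg.atoms is not None else [
                            n for n, a in res.atoms.items() if not a.is_hydrogen
                        ]
                        for name in names:
                            if res.get(name) is not None:
                                items.append((res.ref, name))
                    else:
                        names = seg.atoms or ()
                        for name in names:
                            items.append((ResidueRef(cid, seq), name))
        return cls(items)


def select_atoms(model: StructureModel, selection: AtomSelection) -> np.ndarray:
    """Resolve a selection to an (n, 3) coordinate array, strictly.

    Raises :class:`MissingAtomError` listing *every* unresolved pair.
    Coordinates are returned in selection order regardless of file order.
    """
    coords, missing = _resolve(model, selection)
    if missing:
        raise MissingAtomError(missing, context=f"model {model.id!r}")
    return coords


def select_atoms_lenient(
    model: StructureModel, selection: AtomSelection
) -> tuple[np.ndarray, list[tuple[ResidueRef, str]]]:
    """Like :func:`select_atoms` but drops unresolved atoms, reporting them."""
    return _resolve(model, selection)


def _resolve(model, selection):
    rows, missing = [], []
    for ref, name in selection:
        atom = model.get_atom(ref, name)
        if atom is None:
            missing.append((ref, name))
        else:
            rows.append(atom.coords)
    coords = np.asarray(rows, dtype=float).reshape(len(rows), 3)
    return coords, missing


# ---------------------------------------------------------------------------
# Parsing (Bio.PDB backed)
# ---------------------------------------------------------------------------


def parse_structure(
    source: str | Path,
    fmt: str = "auto",
    *,
    ensemble: bool = False,
    model_id: str | None = None,
) -> StructureModel | list[StructureModel]:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    source : path to a coordinate file
    fmt : "pdb", "mmcif" or "auto" (extension, then content sniffing)
    ensemble : if True, return one model per MODEL record (a list)
    model_id : label for the returned model(s); defaults to the file stem
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"cannot read coordinate file: {path} (no such file)")
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown coordinate format {fmt!r} (expected 'pdb' or 'mmcif')")

    from Bio.PDB.MMCIFParser import MMCIFParser
    from Bio.PDB.PDBParser import PDBParser

    try:
        if fmt == "pdb":
            parser = PDBParser(QUIET=True)
        else:
            parser = MMCIFParser(QUIET=True)
        bio_structure = parser.get_structure(model_id or path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises several exception types
        raise ParseError(f"malformed {fmt} file {path}: {exc}") from exc

    bio_models = list(bio_structure)
    if not bio_models:
        raise ParseError(f"{path}: file contains no coordinate models")

    label = model_id or path.stem
    if ensemble:
        return [
            _convert_bio_model(m, f"{label}[{i}]", fmt) for i, m in enumerate(bio_models)
        ]
    return _convert_bio_model(bio_models[0], label, fmt)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    try:
        head = path.read_text(errors="replace")[:4096]
    except OSError as exc:
        raise ParseError(f"cannot read coordinate file: {path}: {exc}") from exc
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    for tag in ("ATOM  ", "HETATM", "HEADER", "MODEL "):
        if tag in head:
            return "pdb"
    raise FormatError(f"cannot determine format of {path}; pass fmt='pdb' or 'mmcif'")


def _convert_bio_model(bio_model, label: str, fmt: str) -> StructureModel:
    chains: list[Chain] = []
    for bio_chain in bio_model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            if bio_res.is_disordered() == 2:  # disordered residue (point mutation)
                bio_res = bio_res.selected_child
            hetflag, seq_num, icode = bio_res.get_id()
            is_het = hetflag.strip() != ""
            ref = ResidueRef(
                bio_chain.id,
                int(seq_num),
                icode.strip(),
                str(bio_res.get_resname()).strip().upper(),
            )
            atoms: dict[str, AtomRecord] = {}
            for bio_atom in bio_res:
                chosen = _resolve_altloc(bio_atom)
                name = chosen.get_name().strip()
                occ = chosen.get_occupancy()
                atoms[name] = AtomRecord(
                    name=name,
                    element=(chosen.element or "").strip().upper(),
                    coords=np.asarray(chosen.get_coord(), dtype=float),
                    occupancy=float(min(max(occ if occ is not None else 1.0, 0.0), 1.0)),
                    altloc=(chosen.get_altloc() or "").strip(),
                    b_iso=float(chosen.get_bfactor() or 0.0),
                    is_hetatm=is_het,
                )
            if atoms:
                residues.append(Residue(ref, atoms, is_hetatm=is_het))
        if residues:
            chains.append(Chain(bio_chain.id, residues))
    if not chains:
        raise ParseError(f"{label}: no atoms found in file")
    return StructureModel(label, chains, source_format=fmt)


def _resolve_altloc(bio_atom):
    """Highest occupancy wins; tie broken by smallest altloc id."""
    if not bio_atom.is_disordered():
        return bio_atom
    variants = bio_atom.disordered_get_list()
    return min(
        variants,
        key=lambda a: (-(a.get_occupancy() if a.get_occupancy() is not None else 0.0),
                       a.get_altloc()),
    )


# ---------------------------------------------------------------------------
# PDB writing (fixtures, transformed models)
# ---------------------------------------------------------------------------


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one model (or an ensemble, via MODEL/ENDMDL) in PDB v3.3 columns."""
    if isinstance(models, StructureModel):
        model_list: list[StructureModel] = [models]
        multi = False
    else:
        model_list = list(models)
        multi = len(model_list) > 1
    buf = io.StringIO()
    for i, model in enumerate(model_list, start=1):
        if multi:
            buf.write(f"MODEL     {i:4d}\n")
        serial = 1
        for chain in model.chains:
            last_ref = None
            for res in chain:
                for atom in res.atoms.values():
                    buf.write(_pdb_atom_line(serial, atom, res))
                    serial += 1
                last_ref = res.ref
            if last_ref is not None:
                buf.write(
                    f"TER   {serial:5d}      {last_ref.res_name:>3s} "
                    f"{chain.chain_id:1s}{last_ref.seq_num:4d}{last_ref.icode or ' ':1s}\n"
                )
                serial += 1
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def _pdb_atom_line(serial: int, atom: AtomRecord, res: Residue) -> str:
    record = "HETATM" if (res.is_hetatm or atom.is_hetatm) else "ATOM  "
    name = atom.name
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name  # element-aligned padding per PDB v3 convention
    x, y, z = atom.coords
    ref = res.ref
    return (
        f"{record}{serial % 100000:5d} {name:<4s}{(atom.altloc or ' '):1s}"
        f"{ref.res_name:>3s} {ref.chain_id:1s}{ref.seq_num:4d}{(ref.icode or ' '):1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_iso:6.2f}"
        f"          {atom.element:>2s}\n"
    )
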