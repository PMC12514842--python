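"""Synthetic test-input generators.

Everything the test suite needs without touching the network: a toy
four-chain "hydrolase" with labeled triad / oxyanion / loop / core atoms,
apo/holo pairs with planted rigid motions and localized loop displacements,
sphere systems with analytically known SASA, and conformational ensembles
with planted cluster structure and bimodal catalytic-Ser SASA.

All generation is deterministic per seed (no unordered iteration); each
fixture records its planted ground truths so tests assert recovery, and
fixtures are written as standard PDB files plus a JSON sidecar so the
downstream modules are exercised through their public file interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .site_metrics import LigandSpec, SiteDefinition
from .structure_io import (
    AtomRecord,
    Chain,
    Residue,
    ResidueRef,
    ResidueSpec,
    SegmentSpec,
    StructureModel,
    write_pdb,
)
from .superposition import Transform, apply_transform
from .ensemble import Ensemble

__all__ = [
    "EnsembleSpec",
    "FixtureSpec",
    "make_toy_hydrolase",
    "make_holo_from_apo",
    "make_sphere_system",
    "make_ensemble",
    "sample_gaussian_mixture",
    "validate_toy_geometry",
    "write_fixture_pair",
    "toy_site_definition",
]

# --- toy chain layout -------------------------------------------------------
# seq  res  role                       atoms
# 1-8  GLY  core segment 1 (strand)    N CA C O
# 9-12 GLY/PRO oxyanion loop           N CA C O      (donor: 10 N, distal)
# 13   HIS  second oxyanion donor      N CA C O CB
# 14   SER  catalytic                  N CA C O CB OG
# 15-22 ALA core segment 2 (helix)     N CA C O
# 23-26 GLY/HIS catalytic His loop     N CA C O (+CB on 25)
# 28   ASP  catalytic acid             N CA C O CB CG OD1 OD2

_CA_STEP = 3.8
_CHAIN_OPS: list[tuple[np.ndarray, np.ndarray]] = [
    (np.eye(3), np.zeros(3)),
    (np.diag([-1.0, -1.0, 1.0]), np.array([0.0, 60.0, 0.0])),
    (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.0, 60.0])),
    (np.diag([1.0, -1.0, -1.0]), np.array([0.0, 60.0, 60.0])),
]
_CHAIN_IDS = "ABCD"

_SEQUENCE: list[tuple[int, str]] = (
    [(i, "GLY") for i in range(1, 9)]
    + [(9, "GLY"), (10, "GLY"), (11, "PRO"), (12, "GLY")]
    + [(13, "HIS"), (14, "SER")]
    + [(i, "ALA") for i in range(15, 23)]
    + [(23, "GLY"), (24, "GLY"), (25, "HIS"), (26, "GLY")]
    + [(28, "ASP")]
)

LIGAND_RES_NAME = "LIG"
LIGAND_SEQ = 99
LIGAND_KEY_ATOMS = ("C1", "O1", "N1")


@dataclass
class EnsembleSpec:
    n_frames: int = 120
    open_fraction: float = 0.5
    jitter_sigma: float = 0.02
    close_offset: float = 3.0  # Å gap kept between moved loop and Ser Oγ

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("ensemble needs at least 2 frames")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValidationError("open_fraction must lie in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be non-negative")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_chains: int = 4
    noise_sigma: float = 0.0
    planted_transform: Transform | None = None
    planted_loop_shift: tuple[list[tuple[ResidueSpec, str]], np.ndarray] | None = None
    ensemble: EnsembleSpec | None = None
    ligand_distance: float = 5.0  # ligand centroid distance beyond shifted loop

    def __post_init__(self) -> None:
        if not 1 <= self.n_chains <= 4:
            raise ValidationError("n_chains must be between 1 and 4")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if self.planted_loop_shift is not None:
            atoms, vec = self.planted_loop_shift
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (3,) or not np.all(np.isfinite(vec)):
                raise ValidationError("planted loop shift vector must be a finite 3-vector")
            if not atoms:
                raise ValidationError("planted loop shift needs at least one atom")
            self.planted_loop_shift = (list(atoms), vec)


def _residue_atoms(seq: int, res_name: str) -> dict[str, np.ndarray]:
    """Idealized local geometry: bonds 1.2-1.6 Å, no non-bonded clash < 2 Å."""
    base = np.array([_CA_STEP * (seq - 1), 0.0, 0.0])
    atoms = {
        "N": base + np.array([-1.35, 0.5, 0.0]),
        "CA": base,
        "C": base + np.array([1.10, 0.5, 0.0]),
        "O": base + np.array([1.10, 1.75, 0.0]),
    }
    if res_name in ("HIS", "SER", "ASP"):
        atoms["CB"] = base + np.array([0.0, -1.0, 1.0])
    if res_name == "SER":
        atoms["OG"] = base + np.array([0.0, -2.0, 2.0])
    if res_name == "ASP":
        atoms["CG"] = base + np.array([0.0, -2.0, 2.0])
        atoms["OD1"] = atoms["CG"] + np.array([0.0, -1.1, 0.6])
        atoms["OD2"] = atoms["CG"] + np.array([0.9, -0.9, 0.0])
    return atoms


_ELEMENT_BY_NAME = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O",
                    "CG": "C", "OD1": "O", "OD2": "O", "C1": "C", "O1": "O", "N1": "N"}


def toy_site_definition(ligand: bool = True) -> SiteDefinition:
    """Site definition matching the toy layout above."""
    return SiteDefinition(
        name="toy",
        ser=ResidueSpec("SER", 14),
        his=ResidueSpec("HIS", 25),
        asp=ResidueSpec("ASP", 28),
        oxyanion_donors=[(ResidueSpec("GLY", 10), "N"), (ResidueSpec("HIS", 13), "N")],
        distal_donor_index=0,
        oxyanion_loop=SegmentSpec(9, 12),
        his_loop=SegmentSpec(23, 26),
        core=[SegmentSpec(1, 8), SegmentSpec(15, 22)],
        ligand=LigandSpec(LIGAND_RES_NAME, LIGAND_KEY_ATOMS, seq_num=LIGAND_SEQ)
        if ligand
        else None,
    )


def make_toy_hydrolase(spec: FixtureSpec) -> tuple[StructureModel, SiteDefinition]:
    """Deterministic toy hydrolase: D2-like replication of one labeled chain."""
    rng = np.random.default_rng(spec.seed)
    chains = []
    for ci in range(spec.n_chains):
        rot, trans = _CHAIN_OPS[ci]
        residues = []
        for seq, res_name in _SEQUENCE:
            ref = ResidueRef(_CHAIN_IDS[ci], seq, "", res_name)
            atoms = {}
            for name, xyz in _residue_atoms(seq, res_name).items():
                coords = rot @ xyz + trans
                if spec.noise_sigma > 0:
                    coords = coords + rng.normal(0.0, spec.noise_sigma, 3)
                atoms[name] = AtomRecord(
                    name=name, element=_ELEMENT_BY_NAME[name], coords=coords
                )
            residues.append(Residue(ref, atoms))
        chains.append(Chain(_CHAIN_IDS[ci], residues))
    model = StructureModel(f"toy-{spec.seed}", chains)
    return model, toy_site_definition()


def make_holo_from_apo(
    apo: StructureModel, spec: FixtureSpec
) -> tuple[StructureModel, dict]:
    """Holo fixture: rigid motion, then planted loop displacement, then noise.

    When a loop shift is planted, a three-atom ligand is added per chain at
    ``spec.ligand_distance`` Å beyond the shifted atoms along the shift
    vector, so "toward the ligand" is the planted direction by construction.
    Returns the holo model plus a ground-truth metadata dict.
    """
    rng = np.random.default_rng(spec.seed + 1)
    holo = apo.copy()
    holo.id = apo.id + "-holo"

    if spec.planted_transform is not None:
        t = spec.planted_transform
        for chain in holo.chains:
            for res in chain:
                for atom in res.atoms.values():
                    atom.coords = apply_transform(t, atom.coords)

    truth: dict = {
        "seed": spec.seed,
        "planted_transform": spec.planted_transform.to_dict()
        if spec.planted_transform
        else None,
        "planted_shift": None,
    }

    if spec.planted_loop_shift is not None:
        atoms, vec = spec.planted_loop_shift
        R = (
            spec.planted_transform.rotation
            if spec.planted_transform is not None
            else np.eye(3)
        )
        vec_global = R @ vec  # plant the shift in the moved frame
        unit = vec_global / np.linalg.norm(vec_global)
        for chain in holo.chains:
            moved = []
            for res_spec, atom_name in atoms:
                res = chain.get(res_spec.seq_num, res_spec.icode)
                if res is None or res.get(atom_name) is None:
                    raise ValidationError(
                        f"planted shift names absent atom {res_spec}:{atom_name}"
                    )
                atom = res.get(atom_name)
                atom.coords = atom.coords + vec_global
                moved.append(atom.coords)
            centroid = np.mean(moved, axis=0)
            lig_center = centroid + spec.ligand_distance * unit
            lig_atoms = {
                "C1": lig_center,
                "O1": lig_center + np.array([0.0, 0.0, 1.4]),
                "N1": lig_center - np.array([0.0, 0.0, 1.4]),
            }
            lig_ref = ResidueRef(chain.chain_id, LIGAND_SEQ, "", LIGAND_RES_NAME)
            chain.residues.append(
                Residue(
                    lig_ref,
                    {
                        n: AtomRecord(n, _ELEMENT_BY_NAME[n], xyz, is_hetatm=True)
                        for n, xyz in lig_atoms.items()
                    },
                    is_hetatm=True,
                )
            )
            chain.reindex()
        truth["planted_shift"] = {
            "atoms": [[str(rs), an] for rs, an in atoms],
            "vector": vec.tolist(),
            "magnitude": float(np.linalg.norm(vec)),
        }

    if spec.noise_sigma > 0:
        for chain in holo.chains:
            for res in chain:
                for atom in res.atoms.values():
                    atom.coords = atom.coords + rng.normal(0.0, spec.noise_sigma, 3)
    truth["noise_sigma"] = spec.noise_sigma
    return holo, truth


def make_sphere_system(
    radii: Sequence[float], centers: Sequence[Sequence[float]]
) -> tuple[StructureModel, np.ndarray]:
    """Pseudo-atom system for analytic SASA oracles.

    Returns the model and the per-atom radius array to pass as the explicit
    ``radii`` override of :func:`triadgeo.sasa.shrake_rupley`.
    """
    radii = np.asarray(radii, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if len(radii) != len(centers):
        raise ValidationError("radii and centers must have equal length")
    residues = []
    for i, xyz in enumerate(centers, start=1):
        ref = ResidueRef("A", i, "", "SPH")
        residues.append(
            Residue(ref, {"X1": AtomRecord("X1", "C", xyz, is_hetatm=True)}, is_hetatm=True)
        )
    return StructureModel("spheres", [Chain("A", residues)]), radii


def make_ensemble(spec: FixtureSpec) -> tuple[Ensemble, dict]:
    """Two-state (open/closed Ser) monomer ensemble with planted structure.

    The closed state translates the oxyanion loop next to the catalytic Ser
    sidechain, occluding Oγ; frames are drawn from the two states with
    per-frame isotropic jitter.  Ground truth (state labels and the exact
    SASA of each noiseless state) is measured by the generator itself and
    returned for recovery tests.
    """
    if spec.ensemble is None:
        raise ValidationError("FixtureSpec.ensemble must be set for make_ensemble")
    espec = spec.ensemble
    mono_spec = FixtureSpec(seed=spec.seed, n_chains=1)
    open_state, site = make_toy_hydrolase(mono_spec)

    closed_state = open_state.copy()
    chain = closed_state.chains[0]
    og = closed_state.get_atom(site.ser.bind(chain.chain_id), "OG").coords
    loop_refs = [
        chain.get(seq)
        for seq in range(site.oxyanion_loop.start, site.oxyanion_loop.end + 1)
    ]
    loop_atoms = [a for r in loop_refs for a in r.atoms.values()]
    anchor = chain.get(11).get("CA").coords  # middle loop residue
    target = og + np.array([0.0, -espec.close_offset, 0.0])
    shift = target - anchor
    for atom in loop_atoms:
        atom.coords = atom.coords + shift

    rng = np.random.default_rng(spec.seed)
    labels = rng.random(espec.n_frames) < espec.open_fraction
    frames = []
    for k in range(espec.n_frames):
        frame = (open_state if labels[k] else closed_state).copy()
        frame.id = f"frame{k}"
        if espec.jitter_sigma > 0:
            for ch in frame.chains:
                for res in ch:
                    for atom in res.atoms.values():
                        atom.coords = atom.coords + rng.normal(0, espec.jitter_sigma, 3)
        frames.append(frame)

    from .sasa import SasaParams, ser_sidechain_sasa

    params = SasaParams()
    truth = {
        "seed": spec.seed,
        "state_labels": ["open" if x else "closed" for x in labels],
        "n_open": int(labels.sum()),
        "sasa_open": ser_sidechain_sasa(open_state, site, params),
        "sasa_closed": ser_sidechain_sasa(closed_state, site, params),
        "loop_shift_vector": shift.tolist(),
        "site": "toy",
    }
    return Ensemble(frames, [f.id for f in frames]), truth


def sample_gaussian_mixture(
    n: int,
    means: Sequence[float],
    sigmas: Sequence[float],
    weights: Sequence[float],
    seed: int,
) -> np.ndarray:
    """Draw n values from a univariate Gaussian mixture (fixed seed)."""
    means = np.asarray(means, float)
    sigmas = np.asarray(sigmas, float)
    weights = np.asarray(weights, float)
    if not (len(means) == len(sigmas) == len(weights)):
        raise ValidationError("means, sigmas, weights must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n, p=weights)
    return rng.normal(means[comp], sigmas[comp])


# ---------------------------------------------------------------------------
# Geometry validation and file output
# ---------------------------------------------------------------------------

_BONDS = {
    "common": [("N", "CA"), ("CA", "C"), ("C", "O")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "HIS": [("CA", "CB")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
}


def _bond_pairs(chain: Chain) -> set[frozenset[tuple[int, str]]]:
    pairs: set[frozenset] = set()
    prev = None
    for res in chain:
        if res.ref.res_name == LIGAND_RES_NAME:
            continue
        bonds = _BONDS["common"] + _BONDS.get(res.ref.res_name, [])
        for a, b in bonds:
            if res.get(a) is not None and res.get(b) is not None:
                pairs.add(frozenset({(res.ref.seq_num, a), (res.ref.seq_num, b)}))
        if prev is not None and prev.ref.seq_num == res.ref.seq_num - 1:
            if prev.get("C") is not None and res.get("N") is not None:
                pairs.add(frozenset({(prev.ref.seq_num, "C"), (res.ref.seq_num, "N")}))
        prev = res
    return pairs


def validate_toy_geometry(model: StructureModel) -> None:
    """Assert chemical plausibility: bonds 1.2-1.6 Å, non-bonded >= 2.0 Å.

    Pairs that are bonded or share a bonded neighbor (1-3 pairs) are exempt
    from the clash criterion, as in any molecular geometry check.
    """
    for chain in model.chains:
        pairs = _bond_pairs(chain)
        adjacency: dict[tuple[int, str], set[tuple[int, str]]] = {}
        for p in pairs:
            a, b = tuple(p)
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        atoms = [
            ((res.ref.seq_num, a.name), a.coords)
            for res in chain
            if res.ref.res_name != LIGAND_RES_NAME
            for a in res.atoms.values()
        ]
        for key in pairs:
            a, b = tuple(key)
            xa = chain.get(a[0]).get(a[1]).coords
            xb = chain.get(b[0]).get(b[1]).coords
            d = float(np.linalg.norm(xa - xb))
            if not 1.1 <= d <= 1.65:
                raise ValidationError(f"bond {a}-{b} has implausible length {d:.2f} Å")
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                ka, xa = atoms[i]
                kb, xb = atoms[j]
                if frozenset({ka, kb}) in pairs:
                    continue
                if adjacency.get(ka, set()) & adjacency.get(kb, set()):
                    continue  # 1-3 pair
                d = float(np.linalg.norm(xa - xb))
                if d < 2.0:
                    raise ValidationError(f"non-bonded clash {ka}-{kb}: {d:.2f} Å")


def write_fixture_pair(
    out_dir: str | Path, spec: FixtureSpec
) -> tuple[Path, Path, Path]:
    """Write apo.pdb, holo.pdb and truth.json for a planted apo/holo pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    apo, _site = make_toy_hydrolase(spec)
    holo, truth = make_holo_from_apo(apo, spec)
    apo_path, holo_path, truth_path = out / "apo.pdb", out / "holo.pdb", out / "truth.json"
    write_pdb(apo, apo_path)
    write_pdb(holo, holo_path)
    truth_path.write_text(json.dumps(truth, indent=2))
    return apo_path, holo_path, truth_path
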