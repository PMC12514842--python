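"""Site-definition configs, run manifests, and end-to-end report generation.

A site config is a YAML document describing one enzyme's catalytic
machinery (triad, oxyanion donors, loops, core segments, ligand key atoms)
plus measurement lists.  Curated configs ship under ``triadgeo/configs``.

Every JSON report embeds provenance: package version, config hash, and
SHA-256 checksums of the input coordinate files.  CSV outputs stay plain;
the run's ``provenance.json`` sits next to them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .ensemble import (
    ClusteringParams,
    Ensemble,
    fit_two_gaussians,
    gromos_cluster,
    pairwise_rmsd_matrix,
    sasa_series,
)
from .errors import FitError, TriadgeoError, ValidationError
from .sasa import SasaParams, shrake_rupley, ser_sidechain_sasa
from .site_metrics import (
    LigandSpec,
    SiteDefinition,
    atom_distance,
    delta_table,
    hbond_classify,
    loop_shift,
    triad_triangle,
)
from .structure_io import BACKBONE_ATOMS, ResidueSpec, SegmentSpec, parse_structure

__all__ = [
    "SiteConfig",
    "load_site_config",
    "builtin_config_path",
    "run_compare",
    "run_panel",
    "run_ensemble",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(config: "SiteConfig | None", inputs: Sequence[Path]) -> dict:
    return {
        "tool": "triadgeo",
        "version": __version__,
        "config_hash": config.digest if config is not None else None,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }


def _residue_spec(node: Mapping[str, Any], where: str) -> ResidueSpec:
    try:
        return ResidueSpec(
            res_name=str(node["res_name"]).upper(),
            seq_num=int(node["seq"]),
            icode=str(node.get("icode", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: malformed residue spec {node!r}: {exc}") from exc


def _segment(node: Mapping[str, Any], where: str, atoms=None) -> SegmentSpec:
    try:
        seg_atoms = node.get("atoms")
        return SegmentSpec(
            start=int(node["start"]),
            end=int(node["end"]),
            atoms=tuple(seg_atoms) if seg_atoms else (atoms or BACKBONE_ATOMS),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: malformed segment {node!r}: {exc}") from exc


@dataclass
class SiteConfig:
    """A parsed site-definition document plus its measurement lists."""

    site: SiteDefinition
    name: str
    accessions: list[str] = field(default_factory=list)
    measure_atoms: list[tuple[ResidueSpec, str]] = field(default_factory=list)
    contacts: list[dict] = field(default_factory=list)
    digest: str = ""
    source: Path | None = None


def load_site_config(path: str | Path) -> SiteConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"site config not found: {path}")
    raw = path.read_text()
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ValidationError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: site config must be a mapping")

    where = str(path)
    for key in ("name", "triad", "oxyanion_donors", "oxyanion_loop", "his_loop", "core"):
        if key not in doc:
            raise ValidationError(f"{where}: missing required key {key!r}")
    triad = doc["triad"]
    donors = [
        (_residue_spec(d, where), str(d["atom"]).upper()) for d in doc["oxyanion_donors"]
    ]
    ligand = None
    if doc.get("ligand"):
        lig = doc["ligand"]
        ligand = LigandSpec(
            res_name=str(lig["res_name"]).upper(),
            key_atoms=tuple(str(a).upper() for a in lig["atoms"]),
            seq_num=int(lig["seq"]) if lig.get("seq") is not None else None,
        )
    site = SiteDefinition(
        name=str(doc["name"]),
        ser=_residue_spec(triad["ser"], where),
        his=_residue_spec(triad["his"], where),
        asp=_residue_spec(triad["asp"], where),
        ser_og=str(doc.get("ser_og", "OG")).upper(),
        oxyanion_donors=donors,
        distal_donor_index=int(doc.get("distal_donor_index", 0)),
        oxyanion_loop=_segment(doc["oxyanion_loop"], where),
        his_loop=_segment(doc["his_loop"], where),
        core=[_segment(seg, where) for seg in doc["core"]],
        ligand=ligand,
    )
    measure = [
        (_residue_spec(m, where), str(m["atom"]).upper())
        for m in doc.get("measure_atoms", [])
    ]
    contacts = []
    for c in doc.get("contacts", []):
        contacts.append(
            {
                "label": str(c.get("label", "contact")),
                "a": (_residue_spec(c["a"], where), str(c["a"]["atom"]).upper()),
                "b": (_residue_spec(c["b"], where), str(c["b"]["atom"]).upper()),
            }
        )
    return SiteConfig(
        site=site,
        name=str(doc["name"]),
        accessions=[str(a) for a in doc.get("accessions", [])],
        measure_atoms=measure,
        contacts=contacts,
        digest=hashlib.sha256(raw.encode()).hexdigest(),
        source=path,
    )


def builtin_config_path(name: str) -> Path:
    """Path of a curated config shipped with the package (e.g. "apeh")."""
    root = resources.files("triadgeo") / "configs"
    path = Path(str(root / f"{name.lower()}.yaml"))
    if not path.exists():
        available = sorted(p.stem for p in Path(str(root)).glob("*.yaml"))
        raise ValidationError(f"no builtin config {name!r}; available: {available}")
    return path


# ---------------------------------------------------------------------------
# Headline runs
# ---------------------------------------------------------------------------


def run_compare(
    apo_path: str | Path,
    holo_path: str | Path,
    config: SiteConfig,
    out_dir: str | Path,
    *,
    chain_pairing: str | Mapping[str, str] = "by_id",
    lenient: bool = False,
    hbond_cutoff: float = 3.5,
) -> dict:
    """Apo-versus-holo measurement: shifts, triangles, contacts. Writes files."""
    apo_path, holo_path = Path(apo_path), Path(holo_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    apo = parse_structure(apo_path)
    holo = parse_structure(holo_path)
    site = config.site

    atoms = config.measure_atoms or [
        (ResidueSpec(site.distal_donor[0].res_name, site.distal_donor[0].seq_num), "N"),
        (ResidueSpec(site.distal_donor[0].res_name, site.distal_donor[0].seq_num), "CA"),
        (ResidueSpec(site.his.res_name, site.his.seq_num), "CA"),
    ]
    shifts = loop_shift(
        apo, holo, site, atoms, chain_pairing=chain_pairing, lenient_core=lenient
    )
    tri_apo = triad_triangle(apo, site)
    tri_holo = triad_triangle(holo, site)

    contact_rows = []
    for contact in config.contacts:
        (spec_a, atom_a), (spec_b, atom_b) = contact["a"], contact["b"]
        per_chain = {}
        for cid in holo.chain_ids:
            if holo.get_residue(spec_a.bind(cid)) is None:
                continue
            try:
                d = atom_distance(
                    holo, (spec_a.bind(cid), atom_a), (spec_b.bind(cid), atom_b)
                )
            except TriadgeoError:
                continue
            per_chain[cid] = d
        if per_chain:
            import numpy as np

            mean = float(np.mean(list(per_chain.values())))
            contact_rows.append(
                {
                    "label": contact["label"],
                    "per_chain": per_chain,
                    "mean": mean,
                    "hbond": hbond_classify(mean, hbond_cutoff),
                }
            )

    report = {
        "provenance": _provenance(config, [apo_path, holo_path]),
        "policies": {
            "altloc": "highest occupancy, ties to smallest altloc id",
            "core_segments": [
                {"start": s.start, "end": s.end, "atoms": list(s.atoms or ())}
                for s in site.core
            ],
            "display_rounding": "0.1 Å",
            "hbond_cutoff": hbond_cutoff,
            "chain_pairing": chain_pairing if isinstance(chain_pairing, str) else dict(chain_pairing),
        },
        "shift_report": shifts.to_dict(),
        "triangles": {"apo": tri_apo.to_dict(), "holo": tri_holo.to_dict()},
        "contacts": contact_rows,
    }
    (out / "compare.json").write_text(json.dumps(report, indent=2))
    shifts.to_frame().to_csv(out / "shifts.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(report["provenance"], indent=2))
    return report


def run_panel(manifest: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Cross-enzyme apo/holo delta table; per-row failures are isolated."""
    if not isinstance(manifest, Mapping):
        mpath = Path(manifest)
        manifest = yaml.safe_load(mpath.read_text())
        base = mpath.parent
    else:
        base = Path(".")
    entries = manifest.get("entries") or []
    if not entries:
        raise ValidationError("manifest has no entries")
    labels = [e.get("label") for e in entries]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate labels in manifest: {labels}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, failures = [], []
    input_paths = []
    for entry in entries:
        label = entry["label"]
        try:
            config = load_site_config(_resolve(base, entry["site"]))
            apo = parse_structure(_resolve(base, entry["apo"]))
            holo = parse_structure(_resolve(base, entry["holo"]))
            input_paths += [_resolve(base, entry["apo"]), _resolve(base, entry["holo"])]
            rows.append(
                (label, triad_triangle(apo, config.site), triad_triangle(holo, config.site))
            )
        except Exception as exc:  # isolate the row, keep the panel alive
            failures.append({"label": label, "error": f"{type(exc).__name__}: {exc}"})
    if rows:
        table = delta_table(rows)
        table.to_csv(out / "deltas.csv")
    summary = {
        "provenance": _provenance(None, [p for p in input_paths if Path(p).exists()]),
        "n_rows": len(rows),
        "failures": failures,
    }
    (out / "panel_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _resolve(base: Path, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def run_ensemble(
    path: str | Path,
    config: SiteConfig,
    out_dir: str | Path,
    *,
    cutoff: float = 1.0,
    sasa_params: SasaParams | None = None,
) -> dict:
    """Cluster an ensemble, trace Ser SASA, and fit the two-Gaussian mixture."""
    path = Path(path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ens = Ensemble.from_pdb(path)
    if len(ens) < 2:
        raise ValidationError(f"{path}: ensemble analysis needs at least 2 frames")
    sasa_params = sasa_params or SasaParams()

    matrix = pairwise_rmsd_matrix(ens, ClusteringParams(cutoff=cutoff))
    clusters = gromos_cluster(matrix, cutoff)
    series = sasa_series(ens, config.site, sasa_params)

    try:
        fit = fit_two_gaussians(series).to_dict()
    except (FitError, ValidationError) as exc:
        fit = {"error": str(exc), "degenerate": True}

    prov = _provenance(config, [path])
    cluster_doc = {"provenance": prov, **clusters.to_dict()}
    (out / "clusters.json").write_text(json.dumps(cluster_doc, indent=2))
    import pandas as pd

    pd.DataFrame({"frame": ens.labels, "ser_sasa": series}).to_csv(
        out / "sasa_series.csv", index=False
    )
    fit_doc = {"provenance": prov, "params": sasa_params.echo(), **fit}
    (out / "mixture_fit.json").write_text(json.dumps(fit_doc, indent=2))
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return {"clusters": cluster_doc, "fit": fit_doc, "n_frames": len(ens)}
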