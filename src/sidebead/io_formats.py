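"""File formats: PDB backbones and JSON containers for libraries/parameters.

PDB reading goes through gemmi (first model, first altloc); only N/CA/C are
consumed.  The rotamer library, Ramachandran table and parameter set are
stored as versioned JSON documents whose floats are written with full repr
precision, so every round trip is bit-exact; a SHA-256 checksum of the
payload is recorded on write and verified on read.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict

import numpy as np

from .geometry import AA3, BackboneChain, DerivedAtoms, PeptideGeometry
from .potential import (HBondCriteria, PairInteraction, ParameterSet,
                        PotentialConfig)
from .rotamer import (FineRotamerLibrary, PhiPsiGrid, RamachandranDensity,
                      ResidueFineStates)

__all__ = [
    "read_backbone_pdb", "write_backbone_pdb", "write_trajectory_pdb",
    "save_rotamer_library", "load_rotamer_library",
    "save_rama_density", "load_rama_density",
    "save_parameters", "load_parameters",
    "SchemaError",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Versioned parse error for the JSON containers."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_backbone_pdb(path, chain_id: str | None = None,
                      strict: bool = False) -> BackboneChain:
    """Extract the N/CA/C trace of one chain from a PDB file.

    Uses the first model and the first altloc.  Residues missing any of
    N/CA/C are skipped with a warning (or raise in strict mode).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError("no models in PDB file")
    model = st[0]
    chain = None
    for ch in model:
        if chain_id is None or ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")

    types, Ns, CAs, Cs = [], [], [], []
    for res in chain:
        atoms = {}
        for atom in res:
            if atom.name in ("N", "CA", "C") and atom.name not in atoms:
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y,
                                             atom.pos.z])
        if len(atoms) < 3:
            msg = (f"residue {res.seqid.num} {res.name}: missing backbone "
                   f"atoms {sorted({'N', 'CA', 'C'} - set(atoms))}")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        name = res.name if res.name in AA3 else "ALA"
        types.append(name)
        Ns.append(atoms["N"])
        CAs.append(atoms["CA"])
        Cs.append(atoms["C"])
    if not types:
        raise ValueError("no complete residues parsed from PDB")
    return BackboneChain(types, np.array(Ns), np.array(CAs), np.array(Cs),
                         chain_id=chain.name)


def _pdb_atom_line(serial, name, resname, chain_id, resseq, pos,
                   element) -> str:
    return (f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain_id}"
            f"{resseq:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"  1.00  0.00          {element:>2s}\n")


def _chain_records(chain: BackboneChain, derived: DerivedAtoms | None,
                   serial0: int = 1) -> str:
    lines = []
    serial = serial0
    for i, rt in enumerate(chain.residue_types):
        for name, pos, el in (("N", chain.N[i], "N"),
                              ("CA", chain.CA[i], "C"),
                              ("C", chain.C[i], "C")):
            lines.append(_pdb_atom_line(serial, name, rt, chain.chain_id,
                                        i + 1, pos, el))
            serial += 1
        if derived is not None:
            if derived.has_O[i]:
                lines.append(_pdb_atom_line(serial, "O", rt, chain.chain_id,
                                            i + 1, derived.O[i], "O"))
                serial += 1
            if derived.has_H[i]:
                lines.append(_pdb_atom_line(serial, "H", rt, chain.chain_id,
                                            i + 1, derived.H[i], "H"))
                serial += 1
    return "".join(lines)


def write_backbone_pdb(path, chain: BackboneChain,
                       derived: DerivedAtoms | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_chain_records(chain, derived))
        fh.write("END\n")


def write_trajectory_pdb(path, trajectory) -> None:
    """Multi-model PDB of a dynamics trajectory."""
    with open(path, "w") as fh:
        for m, coords in enumerate(trajectory.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            ch = BackboneChain.from_coords(trajectory.residue_types, coords)
            fh.write(_chain_records(ch, None))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_energy_log(path, trajectory) -> None:
    """Columnar TSV energy log of a trajectory."""
    keys = sorted(trajectory.energies[0])
    with open(path, "w") as fh:
        fh.write("frame\t" + "\t".join(keys) + "\n")
        for k, e in enumerate(trajectory.energies):
            fh.write(f"{k}\t" + "\t".join(repr(float(e[key]))
                                          for key in keys) + "\n")


# ---------------------------------------------------------------------------
# JSON containers
# ---------------------------------------------------------------------------

def _arr(a) -> list:
    return np.asarray(a).tolist()


def _dump(kind: str, body: dict, path) -> None:
    payload = json.dumps(body, sort_keys=True)
    doc = {"format": kind, "schema_version": SCHEMA_VERSION,
           "checksum": hashlib.sha256(payload.encode()).hexdigest(),
           "body": body}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def _load(kind: str, path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != kind:
        raise SchemaError(f"expected a {kind} file, got {doc.get('format')}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {doc.get('schema_version')}")
    body = doc["body"]
    payload = json.dumps(body, sort_keys=True)
    if hashlib.sha256(payload.encode()).hexdigest() != doc.get("checksum"):
        raise SchemaError("checksum mismatch; file corrupted")
    return body


def save_rotamer_library(path, library: FineRotamerLibrary) -> None:
    body = {
        "grid": {"n_phi": library.grid.n_phi, "n_psi": library.grid.n_psi},
        "residues": {
            rt: {
                "chi1_bin": _arr(e.chi1_bin), "chi2_bin": _arr(e.chi2_bin),
                "higher_bin": _arr(e.higher_bin), "probs": _arr(e.probs),
                "atoms": _arr(e.atoms), "atoms_gridded": e.atoms.ndim == 5,
                "n_chi1_bins": e.n_chi1_bins, "n_chi2_bins": e.n_chi2_bins,
            } for rt, e in library.residues.items()},
    }
    _dump("rotamer_library", body, path)


def load_rotamer_library(path) -> FineRotamerLibrary:
    body = _load("rotamer_library", path)
    grid = PhiPsiGrid(**body["grid"])
    residues = {}
    for rt, d in body["residues"].items():
        entry = ResidueFineStates(
            chi1_bin=np.array(d["chi1_bin"], dtype=int),
            chi2_bin=np.array(d["chi2_bin"], dtype=int),
            higher_bin=np.array(d["higher_bin"], dtype=int),
            probs=np.array(d["probs"], dtype=float),
            atoms=np.array(d["atoms"], dtype=float),
            n_chi1_bins=d["n_chi1_bins"], n_chi2_bins=d["n_chi2_bins"])
        residues[rt] = entry
    lib = FineRotamerLibrary(grid=grid, residues=residues)
    try:
        lib.validate(atol=1e-6)
    except ValueError as exc:
        raise SchemaError(f"invalid rotamer library: {exc}") from exc
    return lib


def save_rama_density(path, rama: RamachandranDensity) -> None:
    body = {"grid": {"n_phi": rama.grid.n_phi, "n_psi": rama.grid.n_psi},
            "density": _arr(rama.density)}
    _dump("rama_density", body, path)


def load_rama_density(path) -> RamachandranDensity:
    body = _load("rama_density", path)
    rama = RamachandranDensity(grid=PhiPsiGrid(**body["grid"]),
                               density=np.array(body["density"]))
    rama.validate()
    return rama


def save_parameters(path, params: ParameterSet) -> None:
    body = {
        "grid": {"n_phi": params.grid.n_phi, "n_psi": params.grid.n_psi},
        "pair": {f"{a}|{b}": {
            "r_cutoff": e.r_cutoff, "c_unif": _arr(e.c_unif),
            "c_dir": _arr(e.c_dir), "a1": _arr(e.a1), "a2": _arr(e.a2)}
            for (a, b), e in params.pair.items()},
        "bead_positions": {rt: _arr(v)
                           for rt, v in params.bead_positions.items()},
        "bead_directions": {rt: _arr(v)
                            for rt, v in params.bead_directions.items()},
        "rotamer_energy": {rt: _arr(v)
                           for rt, v in params.rotamer_energy.items()},
        "chi1_of_state": {rt: _arr(v)
                          for rt, v in params.chi1_of_state.items()},
        "backbone_bead_refs": _arr(params.backbone_bead_refs),
        "backbone_bead_dirs": _arr(params.backbone_bead_dirs),
        "geom": asdict(params.geom),
        "hbond": asdict(params.hbond),
        "config": asdict(params.config),
    }
    _dump("parameter_set", body, path)


def load_parameters(path) -> ParameterSet:
    body = _load("parameter_set", path)
    pair = {}
    for key, d in body["pair"].items():
        a, b = key.split("|")
        pair[(a, b)] = PairInteraction(
            r_cutoff=d["r_cutoff"], c_unif=np.array(d["c_unif"]),
            c_dir=np.array(d["c_dir"]), a1=np.array(d["a1"]),
            a2=np.array(d["a2"]))
    return ParameterSet(
        grid=PhiPsiGrid(**body["grid"]), pair=pair,
        bead_positions={rt: np.array(v)
                        for rt, v in body["bead_positions"].items()},
        bead_directions={rt: np.array(v)
                         for rt, v in body["bead_directions"].items()},
        rotamer_energy={rt: np.array(v)
                        for rt, v in body["rotamer_energy"].items()},
        chi1_of_state={rt: np.array(v, dtype=int)
                       for rt, v in body["chi1_of_state"].items()},
        backbone_bead_refs=np.array(body["backbone_bead_refs"]),
        backbone_bead_dirs=np.array(body["backbone_bead_dirs"]),
        geom=PeptideGeometry(**body["geom"]),
        hbond=HBondCriteria(**body["hbond"]),
        config=PotentialConfig(**body["config"]))
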