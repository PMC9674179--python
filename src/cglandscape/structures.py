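"""Coarse-grained structure data model and PDB/FASTA I/O.

One site per residue (CA for protein, a single C4'-like site per
nucleotide for RNA) is the default representation; every analysis in the
package depends only on one representative distance per residue pair.
Coordinates are stored in Angstrom throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from Bio import SeqIO

PROTEIN = "protein"
RNA = "rna"

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_RNA1 = {"A", "C", "G", "U"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class StructureError(ValueError):
    """Raised for malformed or inconsistent coarse-grained structures."""


@dataclass(frozen=True)
class CGSite:
    """A single coarse-grained site (one residue or nucleotide)."""

    chain_id: str
    residue_index: int          # 1-based, inherited from the source PDB
    residue_type: str           # 3-letter amino acid or 1-letter base
    molecule_class: str         # PROTEIN or RNA
    position: np.ndarray        # shape (3,), Angstrom
    site_role: str = "backbone_rep"

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"site {self.chain_id}/{self.residue_index}: position must be "
                "a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if self.molecule_class not in (PROTEIN, RNA):
            raise StructureError(
                f"unknown molecule class {self.molecule_class!r}"
            )


def _normalize_ranges(ranges):
    """Accept (chain, lo, hi) or a list of them; return tuple of tuples."""
    if (isinstance(ranges, (tuple, list)) and len(ranges) == 3
            and isinstance(ranges[0], str)):
        ranges = [ranges]
    return tuple((str(c), int(lo), int(hi)) for c, lo, hi in ranges)


class CGStructure:
    """An ordered list of CG sites with chain table and domain annotations.

    Parameters
    ----------
    sites : list of CGSite
        Sites in file order; residue indices must strictly increase within
        each chain and each chain must be of a single molecule class.
    domain_annotations : dict, optional
        Mapping ``name -> (chain_id, first_residue, last_residue)`` or a
        list of such ranges, naming functional regions (e.g. the two
        receptor lobes, a binding pocket lining both, a SIM-like peptide
        segment).
    """

    def __init__(self, sites, domain_annotations=None):
        if not sites:
            raise StructureError("structure must contain at least one site")
        self.sites = list(sites)
        self.chain_table = {}
        for idx, s in enumerate(self.sites):
            if s.chain_id not in self.chain_table:
                self.chain_table[s.chain_id] = {
                    "molecule_class": s.molecule_class,
                    "span": [idx, idx],
                    "_last_res": s.residue_index,
                }
            else:
                entry = self.chain_table[s.chain_id]
                if entry["span"][1] != idx - 1:
                    raise StructureError(
                        f"chain {s.chain_id} is not contiguous in site list"
                    )
                if s.molecule_class != entry["molecule_class"]:
                    raise StructureError(
                        f"chain {s.chain_id} mixes molecule classes"
                    )
                if s.residue_index <= entry["_last_res"]:
                    raise StructureError(
                        f"chain {s.chain_id}: residue indices must strictly "
                        f"increase (got {s.residue_index} after "
                        f"{entry['_last_res']})"
                    )
                entry["span"][1] = idx
                entry["_last_res"] = s.residue_index
        for entry in self.chain_table.values():
            entry.pop("_last_res")
            entry["span"] = tuple(entry["span"])
        self.domain_annotations = {}
        for name, ranges in (domain_annotations or {}).items():
            self.domain_annotations[name] = _normalize_ranges(ranges)
            for cid, lo, hi in self.domain_annotations[name]:
                self._check_annotation(name, cid, lo, hi)

    def _check_annotation(self, name, cid, lo, hi):
        if cid not in self.chain_table:
            raise StructureError(f"annotation {name!r}: no chain {cid!r}")
        res = [s.residue_index for s in self.chain_sites(cid)]
        if lo < res[0] or hi > res[-1] or lo > hi:
            raise StructureError(
                f"annotation {name!r}: range ({lo}, {hi}) outside chain "
                f"{cid} span ({res[0]}, {res[-1]})"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sites(self):
        return len(self.sites)

    @property
    def coords(self):
        """Site coordinates as an (n_sites, 3) array, Angstrom."""
        return np.array([s.position for s in self.sites])

    def chain_sites(self, chain_id):
        lo, hi = self.chain_table[chain_id]["span"]
        return self.sites[lo:hi + 1]

    def chain_indices(self, chain_id):
        """Flat site indices belonging to a chain."""
        lo, hi = self.chain_table[chain_id]["span"]
        return np.arange(lo, hi + 1)

    def annotation_indices(self, name):
        """Flat site indices covered by a domain annotation."""
        if name not in self.domain_annotations:
            raise StructureError(f"no annotation named {name!r}")
        out = []
        for cid, lo, hi in self.domain_annotations[name]:
            out.extend(
                i for i in self.chain_indices(cid)
                if lo <= self.sites[i].residue_index <= hi
            )
        return np.array(sorted(set(out)), dtype=int)

    def annotate(self, name, ranges):
        """Attach an annotation: one (chain, lo, hi) range or a list."""
        ranges = _normalize_ranges(ranges)
        for cid, lo, hi in ranges:
            self._check_annotation(name, cid, lo, hi)
        self.domain_annotations[name] = ranges

    def with_coords(self, coords):
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_sites, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.n_sites} sites"
            )
        sites = [
            CGSite(s.chain_id, s.residue_index, s.residue_type,
                   s.molecule_class, coords[i], s.site_role)
            for i, s in enumerate(self.sites)
        ]
        return CGStructure(sites, self.domain_annotations)

    def same_topology(self, other):
        if self.n_sites != other.n_sites:
            return False
        return all(
            a.chain_id == b.chain_id
            and a.residue_index == b.residue_index
            and a.residue_type == b.residue_type
            and a.molecule_class == b.molecule_class
            for a, b in zip(self.sites, other.sites)
        )

    def molecule_class_array(self):
        return np.array([s.molecule_class for s in self.sites])

    def __repr__(self):
        chains = ", ".join(
            f"{cid}:{e['molecule_class']}[{e['span'][1] - e['span'][0] + 1}]"
            for cid, e in self.chain_table.items()
        )
        return f"<CGStructure {self.n_sites} sites | {chains}>"


class Ensemble:
    """A set of conformations sharing one topology.

    ``topology`` provides chain/annotation bookkeeping; ``frames`` is an
    (n_frames, n_sites, 3) coordinate array.
    """

    def __init__(self, topology, frames, frame_labels=None):
        self.topology = topology
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (topology.n_sites, 3):
            raise StructureError(
                f"frames array shape {frames.shape} incompatible with "
                f"{topology.n_sites} topology sites"
            )
        self.frames = frames
        if frame_labels is not None and len(frame_labels) != len(frames):
            raise StructureError("frame_labels length mismatch")
        self.frame_labels = frame_labels

    @property
    def n_frames(self):
        return len(self.frames)

    def structure(self, i):
        """Frame ``i`` as a CGStructure."""
        return self.topology.with_coords(self.frames[i])

    def __iter__(self):
        return (self.structure(i) for i in range(self.n_frames))

    def __repr__(self):
        return (f"<Ensemble {self.n_frames} frames x "
                f"{self.topology.n_sites} sites>")


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_DEFAULT_SELECTION = {PROTEIN: ("CA",), RNA: ("C4'", "C4*", "P", "C1'")}


def _classify_residue(res_name):
    name = res_name.strip().upper()
    if name in _AA3:
        return PROTEIN, name
    if name in _RNA1 or name in {"RA", "RC", "RG", "RU"}:
        return RNA, name[-1]
    raise StructureError(f"unrecognized residue name {res_name!r}")


def _sites_from_atom_array(arr, site_selection):
    selection = dict(_DEFAULT_SELECTION)
    if site_selection:
        selection.update(site_selection)
    sites = []
    for chain_id in np.unique(arr.chain_id).tolist():
        mask = arr.chain_id == chain_id
        sub = arr[mask]
        for res_id in np.unique(sub.res_id).tolist():
            res = sub[sub.res_id == res_id]
            mclass, rtype = _classify_residue(res.res_name[0])
            atom_names = list(res.atom_name)
            rep = None
            for cand in selection[mclass]:
                if cand in atom_names:
                    rep = atom_names.index(cand)
                    break
            if rep is None:
                raise StructureError(
                    f"residue {chain_id}/{int(res_id)} has no representative "
                    f"atom among {selection[mclass]}"
                )
            sites.append(CGSite(
                chain_id=str(chain_id),
                residue_index=int(res_id),
                residue_type=rtype,
                molecule_class=mclass,
                position=np.asarray(res.coord[rep], dtype=float),
            ))
    return sites


def read_pdb_cg(path, site_selection=None, as_ensemble=False):
    """Read a PDB file into a coarse-grained structure.

    Parameters
    ----------
    path : str or Path
        PDB file; each residue must contain the representative atom
        (CA for protein, C4'/P for RNA unless overridden).
    site_selection : dict, optional
        Mapping molecule class -> tuple of candidate atom names, tried in
        order, overriding the defaults.
    as_ensemble : bool
        If True, a multi-MODEL file is returned as an :class:`Ensemble`.

    Returns
    -------
    CGStructure or Ensemble
    """
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path}: no models in PDB file")
    first = pdb_file.get_structure(model=1)
    if first.array_length() == 0:
        raise StructureError(f"{path}: no atoms in PDB file")
    sites = _sites_from_atom_array(first, site_selection)
    topo = CGStructure(sites, _read_sidecar(path))
    if not as_ensemble:
        return topo
    frames = [topo.coords]
    for m in range(2, n_models + 1):
        arr = pdb_file.get_structure(model=m)
        frame_sites = _sites_from_atom_array(arr, site_selection)
        frames.append(np.array([s.position for s in frame_sites]))
    return Ensemble(topo, np.array(frames))


def _atom_array_from(structure, coords=None):
    n = structure.n_sites
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(
        coords if coords is not None else structure.coords, dtype=np.float32
    )
    for i, s in enumerate(structure.sites):
        arr.chain_id[i] = s.chain_id
        arr.res_id[i] = s.residue_index
        if s.molecule_class == PROTEIN:
            arr.res_name[i] = s.residue_type
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
        else:
            arr.res_name[i] = s.residue_type
            arr.atom_name[i] = "C4'"
            arr.element[i] = "C"
        arr.hetero[i] = False
    return arr


def write_pdb_cg(obj, path):
    """Write a CGStructure (single model) or Ensemble (multi-MODEL) to PDB.

    Domain annotations go to a JSON sidecar next to the PDB file, since the
    PDB format has no standard field for them.
    """
    if isinstance(obj, Ensemble):
        topo = obj.topology
        stack = struc.stack([
            _atom_array_from(topo, obj.frames[i]) for i in range(obj.n_frames)
        ])
        to_write = stack
    else:
        topo = obj
        to_write = _atom_array_from(obj)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(to_write)
    pdb_file.write(str(path))
    _write_sidecar(topo, path)


def _sidecar_path(path):
    return Path(str(path) + ".annotations.json")


def _write_sidecar(structure, path):
    if structure.domain_annotations:
        _sidecar_path(path).write_text(json.dumps(
            {k: [list(r) for r in v]
             for k, v in structure.domain_annotations.items()},
            indent=1,
        ))


def _read_sidecar(path):
    sc = _sidecar_path(path)
    if sc.exists():
        raw = json.loads(sc.read_text())
        return {k: [tuple(r) for r in v] for k, v in raw.items()}
    return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_LEGAL_SEQ = set("ACDEFGHIKLMNPQRSTVWYU")


def read_fasta(path):
    """Read a FASTA file into a list of (id, uppercased sequence).

    Empty records and sequences with characters outside the amino-acid /
    RNA alphabet are rejected; the error names the offending position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise StructureError(f"empty FASTA record {rec.id!r}")
        for pos, ch in enumerate(seq, start=1):
            if ch not in _LEGAL_SEQ:
                raise StructureError(
                    f"record {rec.id!r}: illegal character {ch!r} at "
                    f"position {pos}"
                )
        records.append((rec.id, seq))
    if not records:
        raise StructureError(f"{path}: no FASTA records")
    return records
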