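"""RNA structure container and PDB reading/writing.

Only the four standard ribonucleotides are handled; anything else in a
coordinate file (protein, ligands, water, modified bases) is skipped
with a log message.  Legacy atom-name dialects using ``*`` instead of
``'`` (O2*, C1*...) are normalised on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from .chem import BASE_TYPES, BASE_HEAVY_ATOMS, RIBOSE_ATOMS, PHOSPHATE_ATOMS
from .geometry import BaseFrame, build_base_frame

log = logging.getLogger(__name__)

__all__ = ["BaseResidue", "RnaStructure", "StructureError",
           "read_structure", "write_structure"]

#: maximum O3'(i)-P(i+1) distance before two sequence neighbours are
#: considered disconnected (chain break)
CHAIN_BREAK_DISTANCE = 2.5

_RESNAME_ALIASES = {"A": "A", "C": "C", "G": "G", "U": "U",
                    "RA": "A", "RC": "C", "RG": "G", "RU": "U"}


class StructureError(ValueError):
    pass


@dataclass
class BaseResidue:
    """One ribonucleotide: chain id, 1-based residue index, base type and
    an atom-name -> coordinate table (Angstrom, PDB naming)."""

    chain_id: str
    index: int
    base_type: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.base_type not in BASE_TYPES:
            raise StructureError(f"unsupported base type {self.base_type!r}")
        self.atoms = {k: np.asarray(v, float) for k, v in self.atoms.items()}
        for name, pos in self.atoms.items():
            if not np.all(np.isfinite(pos)):
                raise StructureError(f"non-finite coordinate for atom {name}")

    def frame(self) -> BaseFrame:
        return build_base_frame(self)

    def heavy_atom_names(self) -> list[str]:
        wanted = (BASE_HEAVY_ATOMS[self.base_type] + RIBOSE_ATOMS
                  + PHOSPHATE_ATOMS)
        return [n for n in wanted if n in self.atoms]

    def copy(self) -> "BaseResidue":
        return BaseResidue(self.chain_id, self.index, self.base_type,
                           {k: v.copy() for k, v in self.atoms.items()})


@dataclass
class RnaStructure:
    """Ordered residues grouped into chains; indices strictly increasing
    within each chain."""

    residues: list[BaseResidue] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        prev: dict[str, int] = {}
        for r in self.residues:
            if r.chain_id in prev and r.index <= prev[r.chain_id]:
                raise StructureError(
                    f"residue indices not strictly increasing in chain "
                    f"{r.chain_id!r} at {r.index}"
                )
            prev[r.chain_id] = r.index

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def chains(self) -> dict[str, list[BaseResidue]]:
        out: dict[str, list[BaseResidue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def sequence(self) -> str:
        return "".join(r.base_type for r in self.residues)

    def copy(self) -> "RnaStructure":
        return RnaStructure([r.copy() for r in self.residues], self.name)

    def coords(self, atom_names: list[str] | None = None) -> np.ndarray:
        """Stacked coordinates over all residues (per-residue sorted atom
        order if names not given); used for whole-structure RMSD."""
        pts = []
        for r in self.residues:
            names = atom_names or sorted(r.atoms)
            pts.extend(r.atoms[n] for n in names if n in r.atoms)
        return np.array(pts)

    def same_chain_separation(self, i: int, j: int) -> str:
        """Separation class ('1', '2', '2+') between residues at flat
        positions i and j; inter-chain pairs are non-local by construction."""
        ri, rj = self.residues[i], self.residues[j]
        if ri.chain_id != rj.chain_id:
            return "2+"
        d = abs(ri.index - rj.index)
        return "1" if d == 1 else ("2" if d == 2 else "2+")

    def is_connected(self, i: int) -> bool:
        """Whether flat residue i is covalently linked to residue i+1."""
        if i < 0 or i + 1 >= len(self.residues):
            return False
        a, b = self.residues[i], self.residues[i + 1]
        if a.chain_id != b.chain_id or b.index != a.index + 1:
            return False
        if "O3'" not in a.atoms or "P" not in b.atoms:
            return False
        return float(np.linalg.norm(a.atoms["O3'"] - b.atoms["P"])) \
            <= CHAIN_BREAK_DISTANCE


def _normalise_atom_name(name: str) -> str:
    return name.replace("*", "'").strip()


def read_structure(path, name: str | None = None) -> RnaStructure:
    """Read an RNA structure from a PDB file (first model).

    Alternate locations are resolved to the highest-occupancy ('A' on
    ties) conformer; hydrogens and non-RNA residues are skipped.
    Residues carrying insertion codes are rejected: the sampler needs a
    simple linear residue order, renumber first.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("rna", str(path))
    model = next(structure.get_models())
    residues: list[BaseResidue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            base = _RESNAME_ALIASES.get(resname)
            if base is None:
                if hetflag == " " and resname not in ("HOH",):
                    log.info("skipping non-RNA residue %s %s%s",
                             resname, chain.id, resseq)
                continue
            if icode.strip():
                raise StructureError(
                    f"insertion code {icode!r} at {chain.id}{resseq}: "
                    "renumber the structure first"
                )
            atoms: dict[str, np.ndarray] = {}
            for atom in res.get_unpacked_list():
                if atom.element == "H":
                    continue
                aname = _normalise_atom_name(atom.get_name())
                if aname in atoms:
                    # keep the higher-occupancy altloc; 'A' wins ties by order
                    if (atom.get_occupancy() or 0.0) <= 1.0 and aname in atoms:
                        continue
                atoms[aname] = np.asarray(atom.get_coord(), float)
            try:
                residues.append(
                    BaseResidue(chain.id, int(resseq), base, atoms)
                )
            except StructureError as exc:
                log.warning("skipping residue %s%s: %s", chain.id, resseq, exc)
    if not residues:
        raise StructureError(f"no RNA residues found in {path}")
    return RnaStructure(residues, name or str(path))


_ELEMENT = {"C": "C", "N": "N", "O": "O", "P": "P"}


def write_structure(structure: RnaStructure | list[RnaStructure], path) -> None:
    """Write one structure (or a multi-model list) as PDB ATOM records."""
    models = structure if isinstance(structure, list) else [structure]
    builder = StructureBuilder()
    builder.init_structure("rna")
    for imodel, model in enumerate(models):
        builder.init_model(imodel)
        seen_chains: set[str] = set()
        for res in model:
            if res.chain_id not in seen_chains:
                builder.init_chain(res.chain_id)
                builder.init_seg("    ")
                seen_chains.add(res.chain_id)
            else:
                builder.structure[imodel][res.chain_id]
                builder.chain = builder.structure[imodel][res.chain_id]
            builder.init_residue(res.base_type, " ", res.index, " ")
            for iatom, (name, coord) in enumerate(sorted(res.atoms.items())):
                fullname = name if len(name) >= 4 else f" {name}"
                builder.init_atom(
                    name, np.asarray(coord, float), 0.0, 1.0, " ",
                    fullname, iatom, element=_ELEMENT[name[0]]
                )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
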