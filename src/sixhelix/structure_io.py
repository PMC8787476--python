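"""Macromolecular coordinate and sequence I/O.

Thin domain model over gemmi-parsed mmCIF/PDB files. Author residue numbering
(the numbering of the full-length envelope precursor, e.g. C549) is preserved
everywhere; downstream modules never renumber.

Conventions
-----------
- Alternate conformers: the highest-occupancy conformer is used for geometry;
  atom counts can be taken over all records or unique (name, altloc-collapsed)
  atoms, matching the two conventions refinement tables may use.
- Polymer vs hetero: a residue is polymer when its chemical component is a
  tabulated amino acid; everything else (waters, ions, ligands) is hetero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class EmptyModelError(ValueError):
    """Raised when a coordinate file contains no polymer residues."""


@dataclass
class AtomRecord:
    """One atom site: name, element, optional alternate-conformer id, position (A),
    occupancy and isotropic B-factor (A^2)."""

    name: str
    element: str
    pos: np.ndarray
    altloc: str | None = None
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class Residue:
    """A residue keyed by (chain id, author number, insertion code)."""

    chain_id: str
    number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str | None = None

    def get_atom(self, name: str) -> AtomRecord | None:
        """Highest-occupancy atom record with the given name, or None."""
        best = None
        for a in self.atoms:
            if a.name == name and (best is None or a.occupancy > best.occupancy):
                best = a
        return best

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> tuple[np.ndarray, list[int]]:
        """(n, 3) CA coordinates and matching author numbers; residues lacking
        a CA are skipped."""
        coords, numbers = [], []
        for res in self.residues:
            ca = res.get_atom("CA")
            if ca is not None:
                coords.append(ca.pos)
                numbers.append(res.number)
        return np.asarray(coords, dtype=float).reshape(-1, 3), numbers


@dataclass
class StructureModel:
    """Parsed coordinates: polymer chains, hetero components, resolution metadata."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)
    resolution: float | None = None

    def get_chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no such chain: {chain_id!r}")

    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def atom_count(self, conformers: str = "all") -> int:
        """Number of polymer atom records.

        conformers="all" counts every record (alternate conformers separately);
        "unique" collapses alternate conformers of the same atom name.
        """
        if conformers not in ("all", "unique"):
            raise ValueError("conformers must be 'all' or 'unique'")
        total = 0
        for ch in self.chains:
            for res in ch.residues:
                if conformers == "all":
                    total += len(res.atoms)
                else:
                    total += len({a.name for a in res.atoms})
        return total


@dataclass
class Assembly:
    """A connected component of the chain-contact graph."""

    members: frozenset[str]
    contacts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        return info.is_amino_acid()
    return name in THREE_TO_ONE


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    The format is taken from the extension unless ``fmt`` ("mmcif" or "pdb")
    is given. Raises :class:`EmptyModelError` if no polymer residues are found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        fmt_map = {"mmcif": gemmi.CoorFormat.Mmcif, "pdb": gemmi.CoorFormat.Pdb}
        key = fmt.lower().replace("cif", "mmcif").replace("mmmmcif", "mmcif")
        if key not in fmt_map:
            raise ValueError(f"unknown format {fmt!r}")
        st = gemmi.read_structure(str(path), format=fmt_map[key])
    st.setup_entities()

    model = StructureModel(id=st.name or path.stem)
    if st.resolution and st.resolution > 0:
        model.resolution = float(st.resolution)

    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    gmodel = st[0]
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                name=gres.name,
                icode=gres.seqid.icode.strip() or None,
            )
            for gatom in gres:
                res.atoms.append(
                    AtomRecord(
                        name=gatom.name,
                        element=gatom.element.name,
                        pos=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        altloc=gatom.altloc or None,
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        b_factor=gatom.b_iso,
                    )
                )
            if _is_amino_acid(res.name):
                chain.residues.append(res)
            else:
                model.hetero.append(res)
        if chain.residues:
            model.chains.append(chain)

    if not model.chains:
        raise EmptyModelError(f"{path}: no polymer residues")
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB (.pdb) or mmCIF (.cif) chosen by extension."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")

    def add_res(gchain: gemmi.Chain, res: Residue, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        gchain.add_residue(gres)

    het_by_chain: dict[str, list[Residue]] = {}
    for res in model.hetero:
        het_by_chain.setdefault(res.chain_id, []).append(res)

    seen_chains = set()
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            add_res(gchain, res, het=False)
        for res in het_by_chain.pop(chain.chain_id, []):
            add_res(gchain, res, het=True)
        gmodel.add_chain(gchain)
        seen_chains.add(chain.chain_id)
    for cid, residues in het_by_chain.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            add_res(gchain, res, het=True)
        gmodel.add_chain(gchain)

    st.add_model(gmodel)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def extract_sequence(
    model: StructureModel, chain_id: str
) -> tuple[str, dict[int, int]]:
    """One-letter sequence of a chain plus a 1-based index -> author-number map.

    Nonstandard residues (e.g. MSE) are emitted as ``X``.
    """
    chain = model.get_chain(chain_id)
    seq = []
    num_map: dict[int, int] = {}
    for i, res in enumerate(chain.residues, start=1):
        seq.append(res.one_letter)
        num_map[i] = res.number
    return "".join(seq), num_map


def detect_assemblies(
    model: StructureModel,
    cutoff: float = 4.5,
    min_pairs: int = 10,
) -> list[Assembly]:
    """Connected components of the chain-contact graph.

    Two chains are adjacent when at least ``min_pairs`` heavy-atom pairs lie
    within ``cutoff`` angstroms. All-atom structures resolve interfaces at the
    default 4.5 A; reduced (CA/CB pseudo-atom) models should use a residue-level
    cutoff around 8 A.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not model.chains:
        raise EmptyModelError("model has no chains")

    trees = {}
    for ch in model.chains:
        pts = np.array(
            [a.pos for res in ch.residues for a in res.atoms if a.element != "H"]
        ).reshape(-1, 3)
        trees[ch.chain_id] = cKDTree(pts) if len(pts) else None

    graph = nx.Graph()
    ids = [ch.chain_id for ch in model.chains]
    graph.add_nodes_from(ids)
    contacts: dict[tuple[str, str], int] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ta, tb = trees[a], trees[b]
            if ta is None or tb is None:
                continue
            n = int(ta.count_neighbors(tb, cutoff))
            if n >= min_pairs:
                graph.add_edge(a, b)
                contacts[(a, b)] = n

    assemblies = []
    for comp in nx.connected_components(graph):
        comp = frozenset(comp)
        sub = {k: v for k, v in contacts.items() if k[0] in comp and k[1] in comp}
        assemblies.append(Assembly(members=comp, contacts=sub))
    assemblies.sort(key=lambda a: sorted(a.members))
    return assemblies


def count_hetero(model: StructureModel, what: str) -> int:
    """Count hetero atoms matching an element symbol (e.g. "Cl") or a residue
    name (e.g. "HOH")."""
    n = 0
    for res in model.hetero:
        if res.name.upper() == what.upper():
            n += len(res.atoms)
        else:
            n += sum(1 for a in res.atoms if a.element.upper() == what.upper())
    return n


def write_fasta(sequences: Mapping[str, str], path: str | Path | None = None) -> str:
    """Serialize id -> sequence pairs as 60-column-wrapped FASTA.

    Returns the FASTA text; also writes it to ``path`` when given.
    """
    ids = list(sequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    lines = []
    for sid in ids:
        seq = sequences[sid]
        if not sid or not seq:
            raise ValueError("empty id or sequence")
        lines.append(f">{sid}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_fasta(source: str | Path) -> dict[str, str]:
    """Read FASTA from a path or from literal FASTA text."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    out: dict[str, str] = {}
    sid = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            sid = line[1:].split()[0]
            if sid in out:
                raise ValueError(f"duplicate id {sid!r}")
            out[sid] = ""
        elif sid is not None:
            out[sid] += line
    return out
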