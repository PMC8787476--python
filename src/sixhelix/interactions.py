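"""Electrostatic architecture of a six-helix bundle.

Maps three features of the postfusion fold: inter- and intrachain salt bridges
(side-chain N-O pairs within a cutoff), the axial "anion stripe" (a band of
acidic side chains around the bundle midsection, flanked by basic-enriched
bands), and core-coordinated ions sitting on the trimer axis.

Charge conventions: Asp/Glu -1, Arg/Lys +1, His +0.5 (partially protonated at
the pH range of interest). Salt-bridge criterion: minimum side-chain
carboxylate-O to side-chain-N distance <= 4.0 A, the common literature
convention; His counts as basic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

ACID_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASE_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
CHARGE = {"ASP": -1.0, "GLU": -1.0, "ARG": 1.0, "LYS": 1.0, "HIS": 0.5}
BACKBONE = {"N", "CA", "C", "O", "OXT"}

ResidueKey = tuple[str, int, str]  # (chain id, author number, 3-letter name)


@dataclass(frozen=True)
class SaltBridge:
    acid: ResidueKey
    base: ResidueKey
    distance: float
    interchain: bool


@dataclass
class BridgeNetwork:
    """Connected component of the residue graph induced by salt bridges."""

    residues: frozenset[ResidueKey]
    bridges: list[SaltBridge]

    @property
    def is_triad(self) -> bool:
        """One acid cross-linking two bases (or vice versa) in a 3-residue unit."""
        if len(self.residues) != 3:
            return False
        degree: dict[ResidueKey, int] = {}
        for b in self.bridges:
            degree[b.acid] = degree.get(b.acid, 0) + 1
            degree[b.base] = degree.get(b.base, 0) + 1
        return max(degree.values()) == 2


def _charged_atoms(res, table) -> list:
    names = table.get(res.name, ())
    return [a for name in names if (a := res.get_atom(name)) is not None]


def detect_salt_bridges(model, cutoff: float = 4.0) -> list[SaltBridge]:
    """All Asp/Glu-to-Arg/Lys/His side-chain N-O pairs with minimum distance
    <= cutoff, one bridge per residue pair, classified inter/intrachain."""
    acids, bases = [], []
    for chain in model.chains:
        for res in chain.residues:
            if res.name in ACID_ATOMS:
                atoms = _charged_atoms(res, ACID_ATOMS)
                if atoms:
                    acids.append(((chain.chain_id, res.number, res.name), atoms))
            elif res.name in BASE_ATOMS:
                atoms = _charged_atoms(res, BASE_ATOMS)
                if atoms:
                    bases.append(((chain.chain_id, res.number, res.name), atoms))
    bridges = []
    for akey, aatoms in acids:
        apos = np.array([a.pos for a in aatoms])
        for bkey, batoms in bases:
            bpos = np.array([a.pos for a in batoms])
            dmin = float(np.min(np.linalg.norm(apos[:, None] - bpos[None], axis=2)))
            if dmin <= cutoff:
                bridges.append(
                    SaltBridge(acid=akey, base=bkey, distance=dmin,
                               interchain=akey[0] != bkey[0])
                )
    bridges.sort(key=lambda b: (b.acid, b.base))
    return bridges


def bridge_networks(bridges: list[SaltBridge]) -> list[BridgeNetwork]:
    """Connected components over residues sharing salt bridges."""
    graph = nx.Graph()
    for b in bridges:
        graph.add_edge(b.acid, b.base)
    out = []
    for comp in nx.connected_components(graph):
        comp = frozenset(comp)
        out.append(BridgeNetwork(
            residues=comp,
            bridges=[b for b in bridges if b.acid in comp and b.base in comp],
        ))
    out.sort(key=lambda n: sorted(n.residues))
    return out


@dataclass
class ChargeBin:
    index: int
    z_center: float
    net: float
    acidic: list[ResidueKey] = field(default_factory=list)
    basic: list[ResidueKey] = field(default_factory=list)
    chains: set[str] = field(default_factory=set)

    @property
    def members(self) -> list[ResidueKey]:
        return self.acidic + self.basic


@dataclass
class AxialChargeProfile:
    bin_width: float
    bins: list[ChargeBin]

    def get(self, index: int) -> ChargeBin | None:
        for b in self.bins:
            if b.index == index:
                return b
        return None


def _sidechain_centroid(res) -> np.ndarray | None:
    atoms = _charged_atoms(res, ACID_ATOMS) or _charged_atoms(res, BASE_ATOMS)
    if not atoms:
        atoms = [a for a in res.atoms if a.name not in BACKBONE and a.element != "H"]
    if not atoms:
        ca = res.get_atom("CA")
        atoms = [ca] if ca else []
    if not atoms:
        return None
    return np.mean([a.pos for a in atoms], axis=0)


def axial_charge_profile(model, axis, bin_width: float = 4.0) -> AxialChargeProfile:
    """Charged residues binned by the axial coordinate of their side-chain
    centroid, with per-bin net charge."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[int, ChargeBin] = {}
    for chain in model.chains:
        for res in chain.residues:
            q = CHARGE.get(res.name)
            if q is None:
                continue
            centroid = _sidechain_centroid(res)
            if centroid is None:
                continue
            z = float(axis.axial(centroid))
            idx = int(np.floor(z / bin_width))
            b = bins.setdefault(
                idx, ChargeBin(index=idx, z_center=(idx + 0.5) * bin_width, net=0.0)
            )
            b.net += q
            b.chains.add(chain.chain_id)
            key = (chain.chain_id, res.number, res.name)
            (b.acidic if q < 0 else b.basic).append(key)
    return AxialChargeProfile(bin_width=bin_width,
                              bins=sorted(bins.values(), key=lambda b: b.index))


@dataclass
class AnionStripe:
    bins: list[ChargeBin]
    members: list[ResidueKey]            # acidic residues in the stripe
    flank_above: list[ChargeBin]
    flank_below: list[ChargeBin]

    @property
    def total_net(self) -> float:
        return sum(b.net for b in self.bins)


def detect_anion_stripe(
    profile: AxialChargeProfile,
    stripe_net: float = -2.0,
    flank_net: float = 2.0,
    min_chains: int = 2,
    flank_window: int = 6,
) -> AnionStripe | None:
    """Most negative maximal contiguous bin run with net <= ``stripe_net``
    contributed by >= ``min_chains`` chains, plus basic-enriched flanking runs
    (net >= ``flank_net``) found within ``flank_window`` bins of each edge."""
    by_index = {b.index: b for b in profile.bins}
    runs: list[list[ChargeBin]] = []
    current: list[ChargeBin] = []
    for b in profile.bins:
        if b.net <= stripe_net:
            if current and b.index != current[-1].index + 1:
                runs.append(current)
                current = []
            current.append(b)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    runs = [r for r in runs if len({c for b in r for c in b.chains}) >= min_chains]
    if not runs:
        return None
    stripe = min(runs, key=lambda r: sum(b.net for b in r))

    def find_flank(start: int, step: int) -> list[ChargeBin]:
        for offset in range(1, flank_window + 1):
            b = by_index.get(start + step * offset)
            if b is not None and b.net >= flank_net:
                flank = [b]
                idx = b.index + step
                while (nb := by_index.get(idx)) is not None and nb.net >= flank_net:
                    flank.append(nb)
                    idx += step
                return flank
        return []

    return AnionStripe(
        bins=stripe,
        members=[key for b in stripe for key in b.acidic],
        flank_above=find_flank(stripe[-1].index, +1),
        flank_below=find_flank(stripe[0].index, -1),
    )


@dataclass
class IonSite:
    element: str
    pos: np.ndarray
    donors: list[tuple[str, int, str, str, float]]  # chain, number, resname, atom, A
    axial_offset: float | None = None               # radial distance to bundle axis

    @property
    def n_donors(self) -> int:
        return len(self.donors)


def detect_ion_coordination(
    model,
    element: str = "Cl",
    cutoff: float = 3.5,
    min_donors: int = 3,
    axis=None,
) -> list[IonSite]:
    """Hetero ions of an element coordinated by >= ``min_donors`` protein N/O
    atoms within ``cutoff``; reports the radial offset from the bundle axis
    when one is supplied."""
    donors_pool = []
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                if a.element in ("N", "O"):
                    donors_pool.append((chain.chain_id, res.number, res.name, a))
    sites = []
    for res in model.hetero:
        for atom in res.atoms:
            if atom.element.upper() != element.upper():
                continue
            donors = []
            for cid, num, rname, a in donors_pool:
                d = float(np.linalg.norm(a.pos - atom.pos))
                if d <= cutoff:
                    donors.append((cid, num, rname, a.name, d))
            if len(donors) >= min_donors:
                offset = float(axis.radial(atom.pos)) if axis is not None else None
                sites.append(IonSite(element=atom.element, pos=atom.pos,
                                     donors=sorted(donors, key=lambda t: t[4]),
                                     axial_offset=offset))
    return sites
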