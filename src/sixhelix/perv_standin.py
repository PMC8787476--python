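"""Synthetic stand-in for the PERV-A TM ectodomain construct (residues 493-587).

This module does NOT contain the deposited crystal structure or the GenPept
record; it is a synthetic reference object that realizes the published
residue-level facts of the postfusion PERV TM six-helix bundle so the pipeline
can be exercised end to end:

- construct span 493-587 in envelope (author) numbering,
- the CX6CC chain-reversal motif with cysteines 549/556/557 (C557S in the
  crystallized construct; the cysteine is kept here so the motif is intact),
- the heptad stutter 506-VTED-509 in HR1 (leucines at a, valines at d
  elsewhere), and the QNRR motif 533-536 whose N534 ring coordinates an axial
  chloride,
- the six reported salt bridges: interchain D509-R576, D509-R580, E522-H562,
  E554-R536 and intrachain E514-R574, E521-R567,
- an anion stripe (E521, E522, D561 from all chains) flanked by basic bands
  (K572/R574/R576 on one side, R535/R536 on the other),
- two trimers per model by default (six chains, two chlorides), mirroring the
  crystal's asymmetric unit content.

Backbone geometry is a schematic Crick bundle; charged functional groups are
placed at engineered positions that realize the interaction list exactly, so
every analysis result on this object has known ground truth.
"""

from __future__ import annotations

import numpy as np

from .structure_io import AtomRecord, Chain, Residue, StructureModel
from .synthetic_data import BundleSpec, make_coiled_coil

CONSTRUCT_START = 493
CONSTRUCT_END = 587

# residue-level ground truth (all in author numbering)
STUTTER_SPAN = (506, 509)
CX6CC = (549, 557)
CR_REGION = (543, 557)
ISD_REGION = (532, 548)
TETHER_REGION = (558, 563)
HR2_REGION = (564, 587)
CHLORIDE_DONOR = 534
STRIPE_MEMBERS = frozenset({521, 522, 561})
FLANK_BASIC_HR2 = frozenset({572, 574, 576})
FLANK_BASIC_HR1 = frozenset({535, 536})
#: (acid number, base number, interchain) - unique residue pairs
SALT_BRIDGES = (
    (509, 576, True),
    (509, 580, True),
    (522, 562, True),
    (554, 536, True),
    (514, 574, False),
    (521, 567, False),
)

# 95-mer consistent with every published residue assignment above; filler
# positions are helix-favoring neutral residues. Synthetic - not the accession.
STANDIN_SEQUENCE = (
    "ASVNASLAQVTSSVTEDLQS"   # 493-512 (506-VTED-509 stutter)
    "VESQLTSVEESLTSVSQALT"   # 513-532 (E514, E521, E522)
    "QNRRGLTSVSNLTSPGCWLS"   # 533-552 (QNRR, N534; C549)
    "QEQCCFYADHTSLIRNLQAK"   # 553-572 (E554, C556/C557, D561, H562, R567, K572)
    "IRQRLAIRQANLSTS"        # 573-587 (R574, R576, R580)
)

HR1_LEN = 541 - CONSTRUCT_START + 1   # residues 493-541 threaded on the core
_RISE = 1.51
_ACID_RADIUS = 11.0

# engineered charged-group placements: number -> (atom, z (A), azimuth offset deg)
_ACID_SITES = {
    508: [("OE1", 49.4, 0.0)],
    509: [("OD1", 39.7, 0.0), ("OD2", 39.0, 15.0)],
    514: [("OE1", 39.7, 40.0)],
    521: [("OE1", 30.0, 0.0)],
    522: [("OE1", 29.0, -40.0)],
    554: [("OE1", 13.2, 0.0)],
    561: [("OD1", 29.5, 40.0)],
}
_FREE_BASES = {  # number -> (atom, z, azimuth offset)
    572: ("NZ", 37.0, 70.0),
    535: ("NH1", 13.5, 60.0),
}
#: base number -> (atom, partner acid number, partner acid atom, distance A,
#:                 neighbor chain?)
_PARTNER_BASES = {
    576: ("NH1", 509, "OD1", 3.3, True),
    580: ("NH1", 509, "OD2", 3.3, True),
    562: ("NE2", 522, "OE1", 3.4, True),
    536: ("NH1", 554, "OE1", 3.4, True),
    574: ("NH1", 514, "OE1", 3.5, False),
    567: ("NH1", 521, "OE1", 3.5, False),
}
_ION_Z = 20.0
_ION_DONOR_DIST = 3.2


def standin_sequence() -> str:
    return STANDIN_SEQUENCE


def _acid_pos(number: int, atom: str, chain_index: int) -> np.ndarray:
    for name, z, off in _ACID_SITES[number]:
        if name == atom:
            theta = 2.0 * np.pi * chain_index / 3.0 + np.radians(off)
            return np.array([_ACID_RADIUS * np.cos(theta),
                             _ACID_RADIUS * np.sin(theta), z])
    raise KeyError((number, atom))


def _seq_at(number: int) -> str:
    return STANDIN_SEQUENCE[number - CONSTRUCT_START]


def build_standin(n_trimers: int = 2, separation: float = 120.0,
                  noise: float = 0.0, seed: int = 0) -> StructureModel:
    """Build the synthetic PERV-TM-like six-helix bundle model.

    ``n_trimers`` trimers are placed ``separation`` A apart along x; each
    carries one axial chloride coordinated by the N534 ring. Gaussian
    coordinate noise (sigma in A) perturbs backbone atoms only, never the
    engineered functional groups.
    """
    rng = np.random.default_rng(seed)
    model = StructureModel(id="perv_tm_standin")
    chain_ids = "ABCDEF"

    for t in range(n_trimers):
        shift = np.array([t * separation, 0.0, 0.0])
        # HR1 core trimer, residues 493-541, stutter at 506 (index 13)
        spec = BundleSpec(
            n_chains=3, n_residues=HR1_LEN, stutter_positions=(13,),
            sequence=STANDIN_SEQUENCE[:HR1_LEN], start_letter="b",
            start_number=CONSTRUCT_START, noise=0.0, seed=seed + t,
        )
        core, _ = make_coiled_coil(spec)

        for c in range(3):
            cid = chain_ids[t * 3 + c]
            chain = Chain(chain_id=cid)
            for res in core.chains[c].residues:
                res.chain_id = cid
                chain.residues.append(res)

            # HR2: antiparallel outer helix, residues 564-587, descending z
            theta_g = 2.0 * np.pi * c / 3.0 + np.pi / 3.0
            axis_xy = np.array([10.5 * np.cos(theta_g), 10.5 * np.sin(theta_g)])
            step = 2.0 * np.pi / 3.6
            hr2 = []
            for j, num in enumerate(range(HR2_REGION[0], CONSTRUCT_END + 1)):
                pos = np.array([
                    axis_xy[0] + 2.3 * np.cos(-step * j),
                    axis_xy[1] + 2.3 * np.sin(-step * j),
                    66.0 - 1.5 * j,
                ])
                hr2.append((num, pos))

            # CR + tether loop 542-563: schematic path from the HR1 top to the
            # HR2 N terminus
            start_pos = chain.residues[-1].get_atom("CA").pos
            end_pos = hr2[0][1]
            loop_numbers = list(range(542, HR2_REGION[0]))
            for j, num in enumerate(loop_numbers):
                frac = (j + 1) / (len(loop_numbers) + 1)
                pos = start_pos + frac * (end_pos - start_pos)
                pos = pos + np.array([1.5 * np.sin(2 * np.pi * frac), 0.0, 0.0])
                res = Residue(chain_id=cid, number=num,
                              name=_three(_seq_at(num)))
                res.atoms.append(AtomRecord("CA", "C", pos))
                chain.residues.append(res)
            for num, pos in hr2:
                res = Residue(chain_id=cid, number=num,
                              name=_three(_seq_at(num)))
                res.atoms.append(AtomRecord("CA", "C", pos))
                chain.residues.append(res)

            _place_charged_groups(chain, c)
            if noise > 0:
                for res in chain.residues:
                    for a in res.atoms:
                        if a.name in ("CA", "CB"):
                            a.pos = a.pos + rng.normal(0.0, noise, 3)
            for res in chain.residues:
                for a in res.atoms:
                    a.pos = a.pos + shift
            model.chains.append(chain)

        ion = Residue(chain_id="X", number=901 + t, name="CL")
        ion.atoms.append(AtomRecord("Cl", "Cl",
                                    np.array([0.0, 0.0, _ION_Z]) + shift))
        model.hetero.append(ion)
    model.resolution = 2.0
    return model


def _three(aa: str) -> str:
    from .structure_io import ONE_TO_THREE

    return ONE_TO_THREE[aa]


def _place_charged_groups(chain: Chain, chain_index: int) -> None:
    """Replace default charged pseudo-atoms with the engineered layout."""
    by_number = {res.number: res for res in chain.residues}

    def reset(res: Residue, keep: set[str]) -> None:
        res.atoms = [a for a in res.atoms if a.name in keep]

    for number, sites in _ACID_SITES.items():
        res = by_number[number]
        reset(res, {"CA", "CB"})
        for atom, _, _ in sites:
            res.atoms.append(AtomRecord(atom, "O",
                                        _acid_pos(number, atom, chain_index)))
    for number, (atom, z, off) in _FREE_BASES.items():
        res = by_number[number]
        reset(res, {"CA", "CB"})
        theta = 2.0 * np.pi * chain_index / 3.0 + np.radians(off)
        res.atoms.append(AtomRecord(atom, "N",
                                    np.array([_ACID_RADIUS * np.cos(theta),
                                              _ACID_RADIUS * np.sin(theta), z])))
    for number, (atom, acid_num, acid_atom, dist, neighbor) in _PARTNER_BASES.items():
        res = by_number[number]
        reset(res, {"CA", "CB"})
        donor_chain = (chain_index - 1) % 3 if neighbor else chain_index
        acid = _acid_pos(acid_num, acid_atom, donor_chain)
        outward = acid.copy()
        outward[2] = 0.0
        outward /= np.linalg.norm(outward)
        res.atoms.append(AtomRecord(atom, "N", acid + dist * outward))

    # N534 ring coordinating the axial chloride
    res = by_number[CHLORIDE_DONOR]
    reset(res, {"CA", "CB"})
    theta = 2.0 * np.pi * chain_index / 3.0
    dz = np.sqrt(_ION_DONOR_DIST**2 - 3.0**2)
    res.atoms.append(AtomRecord("ND2", "N",
                                np.array([3.0 * np.cos(theta),
                                          3.0 * np.sin(theta), _ION_Z + dz])))
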