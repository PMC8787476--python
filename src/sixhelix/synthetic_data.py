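"""Ground-truth generators for every pipeline input.

Coordinates follow the Crick parameterization of an n-stranded coiled coil:
helix centers wind on a superhelix of radius R0 (default 6.5 A) about the
bundle (z) axis with a long left-handed pitch, and each CA sits at helix
radius R1 (default 2.26 A) at a Crick phase that advances 720/7 deg per
residue; phase 0 points at the bundle core. A stutter at position k repeats
the previous four register letters, implemented as a linear 51.43 deg phase
slip over the four-residue span (local 11/3 periodicity) - exactly the model
the register analyzer fits, so the generator's register string is recoverable
ground truth.

Residues carry a CA atom, a CB pseudo-atom 1.5 A further from the helix axis
(enough to resolve knob packing and interchain contacts at a residue-level
cutoff), and, for charged residues, a single functional-group pseudo-atom
(Asp OD1, Glu OE1, Arg NH1, Lys NZ, His NE2, Asn ND2) at a canonical offset.
No backbone N/C/O atoms are emitted: these are schematic CA-trace models, not
physically relaxed structures.

The biophysics generators encode the study conditions: SEC standards on the
calibration line Kav = -0.33 log10(MW) + 1.68 with Vo = 8 mL, Vc = 24 mL and
the Methods standard set (gamma-globulin marks the void volume and is not a
calibration point), and thermal melts on the 15-95 degC, 5 degC grid
(17 points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .biophysics import MeltCurve, SecStandard
from .coiled_coil import IDEAL_PHASE, LETTERS, PHASE_STEP, SLIP
from .conservation import AA20, Msa
from .structure_io import AtomRecord, Chain, ONE_TO_THREE, Residue, StructureModel

# study-condition defaults
SEC_SLOPE = -0.33
SEC_INTERCEPT = 1.68
VOID_VOLUME_ML = 8.0
COLUMN_VOLUME_ML = 24.0
#: calibration standards (gamma-globulin, 158 kDa, defines Vo instead)
SEC_STANDARDS_DA = {
    "bovine serum albumin": 66500.0,
    "ovalbumin": 44000.0,
    "carbonic anhydrase": 30000.0,
    "myoglobin": 17000.0,
}
MELT_GRID_C = np.arange(15.0, 96.0, 5.0)          # 15-95 degC in 5 degC steps
TRIMER_MW_DA = 39900.0
MONOMER_MW_DA = TRIMER_MW_DA / 3.0

CHARGED_ATOM = {"ASP": "OD1", "GLU": "OE1", "ARG": "NH1", "LYS": "NZ",
                "HIS": "NE2", "ASN": "ND2"}
_ELEMENT = {"O": "O", "N": "N"}


@dataclass
class BundleSpec:
    """Parameters of a symmetric n-helix coiled coil."""

    n_chains: int = 3
    n_residues: int = 35
    r0: float = 6.5                  # superhelix radius, A
    r1: float = 2.26                 # helix radius, A
    rise: float = 1.51               # axial rise per residue, A
    pitch: float = 175.0             # left-handed supercoil pitch, A
    stutter_positions: tuple[int, ...] = ()   # 0-based chain indices
    sequence: str | None = None      # one-letter; defaults to poly-Ala
    start_letter: str = "a"
    start_number: int = 1
    noise: float = 0.0               # Gaussian sigma on coordinates, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_residues < 7:
            raise ValueError("need >= 1 chain and >= 7 residues")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        for k in self.stutter_positions:
            # the span needs flanking helix on both sides to define the register
            if not 6 <= k <= self.n_residues - 10:
                raise ValueError(f"stutter position {k} too close to a chain end")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def register_string(n: int, stutters: tuple[int, ...], start_letter: str = "a") -> str:
    """Ground-truth register: canonical letters with the previous four letters
    repeated at each stutter position."""
    base = LETTERS.index(start_letter)
    out = []
    for i in range(n):
        shift = 4 * sum(1 for k in stutters if i >= k)
        out.append(LETTERS[(base + i - shift) % 7])
    return "".join(out)


def _phases(n: int, stutters: tuple[int, ...], start_letter: str) -> np.ndarray:
    """Unwrapped Crick phase track: canonical line minus a 4-residue slip ramp
    per stutter (matches the analyzer's model)."""
    from .coiled_coil import _slip_ramp

    i = np.arange(n, dtype=float)
    phi = IDEAL_PHASE[start_letter] + PHASE_STEP * i
    for k in stutters:
        phi -= _slip_ramp(n, k)
    return phi


def _chain_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def make_coiled_coil(spec: BundleSpec) -> tuple[StructureModel, str]:
    """Symmetric coiled-coil bundle; returns (model, true register string)."""
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or "A" * spec.n_residues
    phases = np.radians(_phases(spec.n_residues, spec.stutter_positions,
                                spec.start_letter))
    # a stutter unwinds the supercoil locally: the inward reference frame gains
    # the slip the Crick phase loses, keeping local helix geometry canonical
    from .coiled_coil import _slip_ramp

    unwind = np.zeros(spec.n_residues)
    for k in spec.stutter_positions:
        unwind += np.radians(_slip_ramp(spec.n_residues, k))
    omega0 = -2.0 * np.pi * spec.rise / spec.pitch    # left-handed supercoil
    model = StructureModel(id=f"cc{spec.seed}")
    for c, cid in enumerate(_chain_ids(spec.n_chains)):
        theta0 = 2.0 * np.pi * c / spec.n_chains
        chain = Chain(chain_id=cid)
        for i in range(spec.n_residues):
            ang = theta0 + omega0 * i + unwind[i]
            center = np.array([spec.r0 * np.cos(ang), spec.r0 * np.sin(ang),
                               spec.rise * i])
            tangent = np.array([-spec.r0 * omega0 * np.sin(ang),
                                spec.r0 * omega0 * np.cos(ang), spec.rise])
            tangent /= np.linalg.norm(tangent)
            inward = np.array([-np.cos(ang), -np.sin(ang), 0.0])
            inward -= (inward @ tangent) * tangent
            inward /= np.linalg.norm(inward)
            binorm = np.cross(tangent, inward)
            radial = np.cos(phases[i]) * inward + np.sin(phases[i]) * binorm
            aa = seq[i]
            name = ONE_TO_THREE.get(aa, "ALA")
            res = Residue(chain_id=cid, number=spec.start_number + i, name=name)
            res.atoms.append(AtomRecord("CA", "C", center + spec.r1 * radial))
            res.atoms.append(AtomRecord("CB", "C", center + (spec.r1 + 1.5) * radial))
            if name in CHARGED_ATOM:
                aname = CHARGED_ATOM[name]
                res.atoms.append(
                    AtomRecord(aname, aname[0], center + (spec.r1 + 3.2) * radial)
                )
            chain.residues.append(res)
        model.chains.append(chain)
    if spec.noise > 0:
        for chain in model.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.pos = a.pos + rng.normal(0.0, spec.noise, size=3)
    return model, register_string(spec.n_residues, spec.stutter_positions,
                                  spec.start_letter)


def rotate_model(model: StructureModel, rotation: np.ndarray,
                 translation: np.ndarray | None = None) -> StructureModel:
    """Rigidly transformed deep copy of a model."""
    rotation = np.asarray(rotation, float)
    if abs(np.linalg.det(rotation) - 1.0) > 1e-6:
        raise ValueError("rotation must be proper (det = +1)")
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    out = StructureModel(id=model.id, resolution=model.resolution)
    for chain in model.chains:
        new = Chain(chain_id=chain.chain_id)
        for res in chain.residues:
            nr = Residue(chain_id=res.chain_id, number=res.number, name=res.name,
                         icode=res.icode)
            for a in res.atoms:
                nr.atoms.append(AtomRecord(a.name, a.element, rotation @ a.pos + t,
                                           a.altloc, a.occupancy, a.b_factor))
            new.residues.append(nr)
        out.chains.append(new)
    for res in model.hetero:
        nr = Residue(chain_id=res.chain_id, number=res.number, name=res.name,
                     icode=res.icode)
        for a in res.atoms:
            nr.atoms.append(AtomRecord(a.name, a.element, rotation @ a.pos + t,
                                       a.altloc, a.occupancy, a.b_factor))
        out.hetero.append(nr)
    return out


def make_ideal_helix(n: int = 30, radius: float = 2.3, rise: float = 1.5,
                     per_turn: float = 3.6, start_number: int = 1,
                     chain_id: str = "A", noise: float = 0.0,
                     seed: int = 0) -> StructureModel:
    """Single straight alpha-helix (CA only)."""
    rng = np.random.default_rng(seed)
    step = 2.0 * np.pi / per_turn
    chain = Chain(chain_id=chain_id)
    for i in range(n):
        pos = np.array([radius * np.cos(step * i), radius * np.sin(step * i),
                        rise * i])
        if noise > 0:
            pos = pos + rng.normal(0, noise, 3)
        res = Residue(chain_id=chain_id, number=start_number + i, name="ALA")
        res.atoms.append(AtomRecord("CA", "C", pos))
        chain.residues.append(res)
    return StructureModel(id="helix", chains=[chain])


def make_strand(n: int = 12, spacing: float = 3.4) -> StructureModel:
    """Extended (non-helical) CA trace with a slight zigzag."""
    chain = Chain(chain_id="A")
    for i in range(n):
        pos = np.array([spacing * i, 0.9 * (-1) ** i, 0.0])
        res = Residue(chain_id="A", number=i + 1, name="ALA")
        res.atoms.append(AtomRecord("CA", "C", pos))
        chain.residues.append(res)
    return StructureModel(id="strand", chains=[chain])


def make_hairpin(helix_len: int = 15, loop_len: int = 6) -> StructureModel:
    """Helix-loop-helix single chain: two detectable segments."""
    h1 = make_ideal_helix(helix_len)
    chain = Chain(chain_id="A")
    chain.residues = list(h1.chains[0].residues)
    top = chain.residues[-1].get_atom("CA").pos
    target = top + np.array([10.0, 0.0, 0.0])
    for j in range(loop_len):
        frac = (j + 1) / (loop_len + 1)
        pos = top + frac * (target - top) + np.array([0, 2.5 * np.sin(np.pi * frac), 0])
        res = Residue(chain_id="A", number=helix_len + j + 1, name="GLY")
        res.atoms.append(AtomRecord("CA", "C", pos))
        chain.residues.append(res)
    h2 = make_ideal_helix(helix_len, start_number=helix_len + loop_len + 1)
    for res in h2.chains[0].residues:
        for a in res.atoms:
            a.pos = np.array([10.0 + a.pos[0], a.pos[1],
                              top[2] - (a.pos[2] - 0.0)])   # descend: antiparallel
        chain.residues.append(res)
    return StructureModel(id="hairpin", chains=[chain])


def make_protomer(protomer_id: str, cr_len: int, h1_len: int = 24,
                  h2_len: int = 16, noise: float = 0.3, seed: int = 0):
    """Single-chain fusion-protein protomer: HR1 helix, a chain-reversal loop
    whose length is the lineage driver, and an antiparallel HR2 helix.

    Returns a stutter-anchored domain (the chain conceptually starts at the
    HR1 stutter).
    """
    from .struct_phylo import StutterAnchoredDomain

    rng = np.random.default_rng(seed)
    coords = []
    step = 2.0 * np.pi / 3.6
    for i in range(h1_len):
        coords.append([2.3 * np.cos(step * i), 2.3 * np.sin(step * i), 1.5 * i])
    top = np.array(coords[-1])
    # chain-reversal arc out to the HR2 track at x ~ +10 A
    arc_r = 4.0 + 0.35 * cr_len
    for j in range(cr_len):
        ang = np.pi * (j + 1) / (cr_len + 1)
        coords.append([5.0 + -arc_r * np.cos(ang), 2.0 * np.sin(2 * ang),
                       top[2] + arc_r * np.sin(ang) * 0.6])
    for i in range(h2_len):
        coords.append([10.0 + 2.3 * np.cos(-step * i), 2.3 * np.sin(-step * i),
                       top[2] - 1.5 * i])
    coords = np.asarray(coords, float)
    if noise > 0:
        coords = coords + rng.normal(0.0, noise, coords.shape)
    return StutterAnchoredDomain(
        id=protomer_id, chain_id="A",
        numbers=list(range(1, len(coords) + 1)), coords=coords,
    )


# ---------------------------------------------------------------------------
# MSA generator


def region_rates(length: int, blocks: list[tuple[int, int, float]],
                 default: float = 0.5) -> np.ndarray:
    """Per-position substitution probabilities from (start, end, prob) blocks
    given in 0-based, inclusive coordinates."""
    rates = np.full(length, default, dtype=float)
    for start, end, prob in blocks:
        if not 0 <= start <= end < length:
            raise ValueError("block outside sequence")
        rates[start : end + 1] = prob
    return rates


def make_msa(reference: str, rates: np.ndarray, n: int, gap_rate: float = 0.0,
             seed: int = 0, reference_id: str = "ref") -> Msa:
    """Tree-free block-model MSA: each of n rows mutates the reference
    independently, position-wise, with the given substitution probabilities
    (replacement uniform over the 20 amino acids); the ungapped reference is
    row 0."""
    rates = np.asarray(rates, float)
    if rates.shape != (len(reference),):
        raise ValueError("rates must match reference length")
    if np.any((rates < 0) | (rates > 1)) or not 0 <= gap_rate <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [reference_id]
    rows = [reference]
    for s in range(n):
        chars = list(reference)
        mutate = rng.random(len(reference)) < rates
        for j in np.nonzero(mutate)[0]:
            chars[j] = AA20[rng.integers(len(AA20))]
        if gap_rate > 0:
            gaps = rng.random(len(reference)) < gap_rate
            for j in np.nonzero(gaps)[0]:
                chars[j] = "-"
        ids.append(f"s{s + 1}")
        rows.append("".join(chars))
    return Msa(ids=ids, rows=rows, reference=reference_id)


# ---------------------------------------------------------------------------
# melt curves and SEC standards


def make_melt(tms: list[float], amplitudes: list[float] | None = None,
              slopes: list[float] | None = None, noise: float = 0.0,
              t_grid: np.ndarray | None = None, seed: int = 0,
              ph: float | None = None) -> MeltCurve:
    """Logistic-sum melt curve plus Gaussian noise on the temperature grid."""
    tms = list(tms)
    amplitudes = list(amplitudes) if amplitudes is not None else [1.0 / len(tms)] * len(tms)
    slopes = list(slopes) if slopes is not None else [2.0] * len(tms)
    if not np.isclose(sum(amplitudes), 1.0):
        raise ValueError("amplitudes must sum to 1")
    t = MELT_GRID_C.copy() if t_grid is None else np.asarray(t_grid, float)
    y = np.zeros_like(t)
    for tm, k, f in zip(tms, slopes, amplitudes):
        y += f / (1.0 + np.exp((tm - t) / k))
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, size=len(t))
    return MeltCurve(temperatures=t, signal=y, ph=ph)


def make_sec_standards(
    slope: float = SEC_SLOPE,
    intercept: float = SEC_INTERCEPT,
    vo: float = VOID_VOLUME_ML,
    vc: float = COLUMN_VOLUME_ML,
    mws: dict[str, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> list[SecStandard]:
    """Standards whose elution volumes invert the Kav line, plus optional
    Gaussian noise on Kav (resampled with a warning if Ve leaves (Vo, Vc])."""
    mws = dict(mws) if mws is not None else dict(SEC_STANDARDS_DA)
    rng = np.random.default_rng(seed)
    out = []
    for name, mw in mws.items():
        if mw <= 0:
            raise ValueError("MW must be positive")
        kav_true = intercept + slope * np.log10(mw)
        for _ in range(100):
            kav = kav_true + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            ve = vo + kav * (vc - vo)
            if vo < ve <= vc:
                break
            warnings.warn(f"{name}: Ve outside (Vo, Vc], resampling")
            if noise == 0.0:
                break
        # a species at/over the exclusion limit elutes at the void volume
        ve = min(max(ve, vo + 1e-6), vc)
        out.append(SecStandard(name=name, mw=mw, ve=float(ve)))
    return out


# ---------------------------------------------------------------------------
# six-helix bundles


def make_6hb(
    n_chains: int = 3,
    core_len: int = 40,
    outer_len: int = 18,
    r0_core: float = 6.5,
    r0_outer: float = 10.5,
    stutter_positions: tuple[int, ...] = (),
    glu_ring: int | None = None,
    arg_rings: tuple[int, ...] = (),
    ion_donor: int | None = None,
    ion_element: str = "CL",
    noise: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Schematic six-helix bundle: an n-chain core coiled coil with one
    antiparallel outer helix per chain packed in the grooves; each chain holds
    its core (HR1-like) and outer (HR2-like) residues.

    Optional engineered features, all on the core helix by 0-based residue
    index: a Glu ring (``glu_ring``), Arg rings (``arg_rings``), and an axial
    ion coordinated by an Asn ring (``ion_donor``) with N-to-ion distance
    3.2 A.
    """
    if r0_outer <= r0_core:
        raise ValueError("outer radius must exceed core radius (clashing helices)")
    core_seq = list("A" * core_len)
    if glu_ring is not None:
        core_seq[glu_ring] = "E"
    for k in arg_rings:
        core_seq[k] = "R"
    if ion_donor is not None:
        core_seq[ion_donor] = "N"
    spec = BundleSpec(
        n_chains=n_chains, n_residues=core_len, r0=r0_core,
        stutter_positions=stutter_positions, sequence="".join(core_seq),
        noise=0.0, seed=seed,
    )
    model, _ = make_coiled_coil(spec)
    rng = np.random.default_rng(seed + 1)

    z_top = spec.rise * (core_len - 1)
    step = 2.0 * np.pi / 3.6
    for c, chain in enumerate(model.chains):
        theta = 2.0 * np.pi * (c + 0.5) / n_chains     # groove azimuth
        axis_xy = np.array([r0_outer * np.cos(theta), r0_outer * np.sin(theta)])
        for j in range(outer_len):
            pos = np.array([
                axis_xy[0] + 2.3 * np.cos(-step * j),
                axis_xy[1] + 2.3 * np.sin(-step * j),
                z_top - 1.5 * j,                        # antiparallel: descending
            ])
            res = Residue(chain_id=chain.chain_id,
                          number=core_len + 20 + j + 1, name="ALA")
            res.atoms.append(AtomRecord("CA", "C", pos))
            chain.residues.append(res)

    if ion_donor is not None:
        z_ion = spec.rise * ion_donor
        ion = Residue(chain_id="X", number=901, name=ion_element.upper())
        ion.atoms.append(AtomRecord(ion_element.capitalize(),
                                    ion_element.capitalize(),
                                    np.array([0.0, 0.0, z_ion])))
        model.hetero.append(ion)
        for c, chain in enumerate(model.chains):
            theta = 2.0 * np.pi * c / n_chains
            res = chain.residues[ion_donor]
            nd2 = res.get_atom("ND2")
            target = np.array([3.0 * np.cos(theta), 3.0 * np.sin(theta),
                               z_ion + np.sqrt(3.2**2 - 3.0**2)])
            if nd2 is not None:
                nd2.pos = target
            else:
                res.atoms.append(AtomRecord("ND2", "N", target))

    if noise > 0:
        for chain in model.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.pos = a.pos + rng.normal(0.0, noise, size=3)
    model.id = f"6hb{seed}"
    return model
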