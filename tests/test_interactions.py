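"""Salt bridges, bridge networks, axial charge profile, stripe and ion sites."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sixhelix import interactions as ia
from sixhelix.coiled_coil import BundleAxis
from sixhelix.structure_io import AtomRecord, Chain, Residue, StructureModel
from sixhelix.synthetic_data import BundleSpec, make_6hb, make_coiled_coil, rotate_model

Z_AXIS = BundleAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


def pair_model(distance: float, same_chain: bool = False) -> StructureModel:
    asp = Residue(chain_id="A", number=10, name="ASP")
    asp.atoms.append(AtomRecord("CA", "C", np.array([0.0, 0.0, 0.0])))
    asp.atoms.append(AtomRecord("OD1", "O", np.array([2.0, 0.0, 0.0])))
    arg = Residue(chain_id="A" if same_chain else "B", number=50, name="ARG")
    arg.atoms.append(AtomRecord("CA", "C", np.array([2.0 + distance + 2, 0.0, 0.0])))
    arg.atoms.append(AtomRecord("NH1", "N", np.array([2.0 + distance, 0.0, 0.0])))
    chains = ([Chain("A", [asp, arg])] if same_chain
              else [Chain("A", [asp]), Chain("B", [arg])])
    return StructureModel(id="pair", chains=chains)


class TestSaltBridges:
    def test_pair_at_cutoff_distance(self):
        bridges = ia.detect_salt_bridges(pair_model(3.5))
        assert len(bridges) == 1
        b = bridges[0]
        assert b.distance == pytest.approx(3.5)
        assert b.interchain is True
        assert b.acid[2] == "ASP" and b.base[2] == "ARG"

    def test_pair_beyond_cutoff(self):
        assert ia.detect_salt_bridges(pair_model(8.0)) == []

    def test_intrachain_classification(self):
        b = ia.detect_salt_bridges(pair_model(3.0, same_chain=True))[0]
        assert b.interchain is False

    def test_count_monotone_in_cutoff(self, standin_model):
        counts = [len(ia.detect_salt_bridges(standin_model, cutoff=c))
                  for c in (3.0, 4.0, 6.0)]
        assert counts == sorted(counts)

    def test_rigid_motion_invariance(self, standin_model):
        rot = Rotation.from_euler("xyz", [25, -80, 60], degrees=True).as_matrix()
        moved = rotate_model(standin_model, rot, np.array([7.0, 1.0, -9.0]))
        key = lambda bs: sorted((b.acid, b.base) for b in bs)
        assert key(ia.detect_salt_bridges(moved)) == key(
            ia.detect_salt_bridges(standin_model))


class TestNetworks:
    def _bridge(self, acid_num, base_num):
        return ia.SaltBridge(acid=("A", acid_num, "ASP"),
                             base=("B", base_num, "ARG"),
                             distance=3.0, interchain=True)

    def test_shared_acid_forms_triad(self):
        nets = ia.bridge_networks([self._bridge(1, 2), self._bridge(1, 3)])
        assert len(nets) == 1
        assert nets[0].is_triad

    def test_disjoint_pairs_stay_separate(self):
        nets = ia.bridge_networks([self._bridge(1, 2), self._bridge(5, 6)])
        assert len(nets) == 2
        assert not any(n.is_triad for n in nets)


class TestChargeProfile:
    def test_neutral_bundle_empty(self):
        model, _ = make_coiled_coil(BundleSpec(n_residues=21))
        profile = ia.axial_charge_profile(model, Z_AXIS)
        assert profile.bins == []

    def test_glu_ring_single_negative_bin(self):
        model = make_6hb(core_len=40, glu_ring=20)
        profile = ia.axial_charge_profile(model, Z_AXIS)
        hot = [b for b in profile.bins if b.net < 0]
        assert len(hot) == 1
        assert hot[0].net == -3.0
        assert {m[1] for m in hot[0].acidic} == {21}

    def test_every_charge_in_exactly_one_bin(self, standin_trimer, standin_axis):
        profile = ia.axial_charge_profile(standin_trimer, standin_axis)
        seen = [m for b in profile.bins for m in b.members]
        assert len(seen) == len(set(seen))
        n_charged = sum(1 for ch in standin_trimer.chains for r in ch.residues
                        if r.name in ia.CHARGE)
        assert len(seen) == n_charged


class TestStripe:
    def test_no_stripe_on_neutral_bundle(self):
        model, _ = make_coiled_coil(BundleSpec(n_residues=21))
        profile = ia.axial_charge_profile(model, Z_AXIS)
        assert ia.detect_anion_stripe(profile) is None

    def test_engineered_rings_recovered_exactly(self):
        """Precision = recall = 1 for Glu rings flanked by Arg rings over 20
        random geometries."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            core_len = int(rng.integers(34, 46))
            # keep the ring mid-bin so bin edges cannot split it
            g = int(rng.integers(16, core_len - 16))
            while not 1.0 < (1.51 * g) % 4.0 < 3.0:
                g += 1
            model = make_6hb(core_len=core_len, glu_ring=g,
                             arg_rings=(g - 8, g + 8), seed=int(rng.integers(1e6)))
            profile = ia.axial_charge_profile(model, Z_AXIS)
            stripe = ia.detect_anion_stripe(profile)
            assert stripe is not None
            assert {m[1] for m in stripe.members} == {g + 1}
            assert {m[1] for b in stripe.flank_above for m in b.basic} == {g + 9}
            assert {m[1] for b in stripe.flank_below for m in b.basic} == {g - 7}


class TestIons:
    def test_engineered_chloride_three_donors(self):
        model = make_6hb(core_len=40, ion_donor=20)
        sites = ia.detect_ion_coordination(model, "Cl", axis=Z_AXIS)
        assert len(sites) == 1
        site = sites[0]
        assert site.n_donors == 3
        assert all(d[2] == "ASN" and d[3] == "ND2" for d in site.donors)
        assert all(abs(d[4] - 3.2) < 1e-6 for d in site.donors)
        assert site.axial_offset < 1.0

    def test_undercoordinated_ion_excluded(self):
        model = make_6hb(core_len=40, ion_donor=20)
        # strip two of the three donors
        for chain in model.chains[1:]:
            res = chain.residues[20]
            res.atoms = [a for a in res.atoms if a.name != "ND2"]
        assert ia.detect_ion_coordination(model, "Cl") == []
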