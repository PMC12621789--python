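"""Hydrogen-bond detection and counting, Kabsch/pTyr RMSD, design gates."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from micurate.filters import (
    FilterThresholds,
    apply_filters,
    count_peptide_hbonds,
    count_phosphate_hbonds,
    detect_hbonds,
    kabsch_superpose,
    ptyr_rmsd,
)
from micurate.structure import ComplexStructure, StructureError
from micurate.fixtures import FixtureSpec, assemble_complex, build_phosphopeptide

from conftest import mk_atom, mk_res, random_rigid


def donor_acceptor_pair(distance, donor_chain="A", acceptor_is_phosphate=True):
    """Binder backbone-N donor at ``distance`` from a PTR terminal
    phosphate oxygen (antecedent P placed for a 180 deg approach)."""
    o1p = np.array([0.0, 0.0, 0.0])
    p = np.array([-1.5, 0.0, 0.0])
    acceptor = mk_res("B", 1, "PTR", {
        "N": (-6, 2, 0), "CA": (-5, 1, 0), "C": (-4, 2, 0), "O": (-4, 3, 0),
        "P": p, "O1P": o1p, "O2P": (-2.0, 1.3, 0.5), "O3P": (-2.0, -1.3, 0.5),
        "OH": (-2.2, 0.0, -1.2),
    })
    donor = mk_res(donor_chain, 1, "ALA", {
        "N": (distance, 0.0, 0.0),
        "CA": (distance + 1.4, 0.6, 0.0),
        "C": (distance + 2.6, -0.3, 0.0),
        "O": (distance + 3.7, 0.2, 0.0),
    })
    roles = {donor_chain: "binder", "B": "target"}
    return ComplexStructure([donor, acceptor], roles)


class TestDetectHbonds:
    def test_valid_geometry_detected(self):
        st = donor_acceptor_pair(3.2)
        bonds = detect_hbonds(st)
        phos = [b for b in bonds if b.acceptor_is_phosphate_oxygen]
        assert len(phos) == 1
        assert phos[0].distance == pytest.approx(3.2)

    def test_beyond_cutoff_rejected(self):
        st = donor_acceptor_pair(3.8)
        assert not [
            b for b in detect_hbonds(st) if b.acceptor_is_phosphate_oxygen
        ]

    def test_intra_residue_excluded(self):
        res = mk_res("A", 1, "SER", {
            "N": (0, 0, 0), "CA": (1.4, 0.4, 0), "C": (2.6, -0.4, 0),
            "O": (2.8, -1.6, 0), "OG": (1.5, 1.9, 0),
        })
        st = ComplexStructure([res], {"A": "binder"})
        assert detect_hbonds(st) == []

    def test_antecedent_angle_gate(self):
        # stripped PTR: only P + O1P in acceptor range, backbone far away
        def build(donor_xyz):
            acceptor = mk_res("B", 1, "PTR", {
                "N": (-6, 40, 0), "CA": (-5, 41, 0), "C": (-4, 40, 0),
                "O": (-4, 39, 0), "P": (-1.5, 0.0, 0.0),
                "O1P": (0.0, 0.0, 0.0),
            })
            donor = mk_res("A", 1, "ALA", {
                "N": donor_xyz, "CA": (-8, -8, 8), "C": (-9, -9, 8),
                "O": (-10, -10, 8),
            })
            return ComplexStructure(
                [donor, acceptor], {"A": "binder", "B": "target"}
            )

        # P-O1P-D angle 45 deg (donor leaning over the antecedent): vetoed
        bad = build((-2.0, 0.0, 2.0))
        assert not [
            b for b in detect_hbonds(bad) if b.acceptor_is_phosphate_oxygen
        ]
        # same distance on the far side (angle 135 deg): accepted
        good = build((2.0, 0.0, 2.0))
        assert [
            b for b in detect_hbonds(good) if b.acceptor_is_phosphate_oxygen
        ]

    def test_explicit_hydrogen_angle_gate(self):
        st_good = donor_acceptor_pair(3.2)
        donor = st_good.residues[0]
        # H between donor N and acceptor: near-linear D-H-A, accepted
        donor.atoms.append(mk_atom("H", (2.2, 0.0, 0.0), element="H"))
        assert [
            b for b in detect_hbonds(st_good) if b.acceptor_is_phosphate_oxygen
        ]
        st_bad = donor_acceptor_pair(3.2)
        donor = st_bad.residues[0]
        # H pointing away: D-H-A angle < 120, bond vetoed
        donor.atoms.append(mk_atom("H", (4.2, 0.0, 0.0), element="H"))
        assert not [
            b for b in detect_hbonds(st_bad) if b.acceptor_is_phosphate_oxygen
        ]

    def test_rigid_motion_invariant_counts(self, default_complex):
        n0 = len(detect_hbonds(default_complex))
        rot, t = random_rigid(np.random.default_rng(3))
        assert len(detect_hbonds(default_complex.transformed(rot, t))) == n0


class TestCounting:
    def test_three_donors_counted(self):
        st = assemble_complex(
            FixtureSpec(phosphate_donor_distances=(2.9, 2.9, 2.9))
        )
        bonds = detect_hbonds(st)
        assert count_phosphate_hbonds(bonds, st) == 3

    def test_no_donor_in_range(self):
        st = assemble_complex(FixtureSpec(phosphate_donor_distances=()))
        bonds = detect_hbonds(st)
        assert count_phosphate_hbonds(bonds, st) == 0

    def test_target_chain_donor_not_counted(self):
        st = donor_acceptor_pair(3.0, donor_chain="C")
        st.role_of_chain["C"] = "target"
        # keep a nominal binder so role bookkeeping stays valid
        st.residues.append(mk_res("D", 1, "ALA", {"CA": (50, 50, 50)}))
        st.role_of_chain["D"] = "binder"
        bonds = detect_hbonds(st)
        assert count_phosphate_hbonds(bonds, st) == 0

    def test_no_ptr_is_error(self):
        st = ComplexStructure(
            [
                mk_res("A", 1, "ALA", {"CA": (0, 0, 0)}),
                mk_res("B", 1, "ALA", {"CA": (5, 0, 0)}),
            ],
            {"A": "binder", "B": "target"},
        )
        with pytest.raises(StructureError, match="phosphotyrosine"):
            count_phosphate_hbonds([], st)

    def test_peptide_totals_include_phosphate_bonds(self):
        st = assemble_complex(FixtureSpec())
        bonds = detect_hbonds(st)
        n_phos = count_phosphate_hbonds(bonds, st)
        total, sc = count_peptide_hbonds(bonds, st)
        assert n_phos <= total
        assert sc <= total

    def test_cross_chain_only(self):
        st = assemble_complex(FixtureSpec())
        bonds = detect_hbonds(st)
        total, _ = count_peptide_hbonds(bonds, st)
        cross = [
            b for b in bonds
            if {st.role(b.donor_residue[0]), st.role(b.acceptor_residue[0])}
            == {"binder", "target"}
        ]
        assert total == len(cross)


def brute_force_min_rmsd(mobile, reference):
    """Independent oracle: optimize RMSD over rotations directly."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def cost(euler):
        r = Rotation.from_euler("xyz", euler).as_matrix()
        return np.sqrt(np.mean(np.sum(((r @ mobile.T).T - reference) ** 2, axis=1)))

    best = np.inf
    for start in itertools.product((-2.0, 0.0, 2.0), repeat=3):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3)) * 5
        rot, t = random_rigid(rng)
        moved = (rot @ pts.T).T + t
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_swap_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-9
        )

    def test_matches_bruteforce_oracle(self):
        a = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1, 1, 0.0]])
        b = 2.0 * a  # stretched: nonzero optimal rmsd
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(brute_force_min_rmsd(a, b), abs=1e-3)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 3)) * 4
        b = rng.normal(size=(10, 3)) * 4
        rot, _, rmsd = kabsch_superpose(a, b)
        r_sp, rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        assert np.allclose(rot, r_sp.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line * 2)


class TestPtyrRmsd:
    def test_self_is_zero(self, default_complex):
        assert ptyr_rmsd(default_complex, default_complex) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_displaced_ptr_measures_displacement(self, default_complex):
        moved = default_complex.transformed(np.eye(3), np.zeros(3))
        for r in moved.residues:
            if r.name == "PTR":
                for a in r.atoms:
                    a.coord = a.coord + np.array([6.0, 0.0, 0.0])
        assert ptyr_rmsd(default_complex, moved) == pytest.approx(6.0, abs=0.01)

    def test_rigid_motion_of_prediction_ignored(self, default_complex):
        rot, t = random_rigid(np.random.default_rng(9))
        moved = default_complex.transformed(rot, t)
        assert ptyr_rmsd(default_complex, moved) == pytest.approx(0.0, abs=1e-6)

    def test_shared_subset_when_atoms_missing(self, default_complex, caplog):
        pred = default_complex.transformed(np.eye(3), np.zeros(3))
        for r in pred.residues:
            if r.name == "PTR":
                r.atoms = [a for a in r.atoms if a.name not in ("O2P", "O3P")]
        with caplog.at_level("WARNING"):
            val = ptyr_rmsd(default_complex, pred)
        assert val == pytest.approx(0.0, abs=1e-9)
        assert "O2P" in caplog.text

    def test_phosphate_only_selection(self, default_complex):
        assert ptyr_rmsd(
            default_complex, default_complex, atoms="phosphate"
        ) == pytest.approx(0.0, abs=1e-9)

    def test_missing_ptr_errors(self, default_complex):
        plain = ComplexStructure(
            [r.copy() for r in default_complex.residues if r.name != "PTR"],
            dict(default_complex.role_of_chain),
        )
        with pytest.raises(StructureError):
            ptyr_rmsd(plain, default_complex)


class TestApplyFilters:
    @pytest.mark.parametrize(
        "n_phos,total,rmsd",
        list(itertools.product((1, 2), (12, 13), (4.9, 5.2))),
    )
    def test_gate_truth_table(self, n_phos, total, rmsd):
        rep = apply_filters(
            n_phosphate_hbonds=n_phos,
            n_peptide_hbonds_total=total,
            ptyr_rmsd_value=rmsd,
            binder_length=120,
        )
        expect_pass = n_phos >= 2 and total <= 12 and rmsd < 5.0
        assert (rep.verdict == "pass") == expect_pass
        assert ("insufficient_phosphate_hbonds" in rep.fail_reasons) == (
            n_phos < 2
        )
        assert ("excess_peptide_hbonds" in rep.fail_reasons) == (total > 12)
        assert ("ptyr_rmsd" in rep.fail_reasons) == (rmsd >= 5.0)

    def test_binder_length_gate(self):
        rep = apply_filters(3, 8, ptyr_rmsd_value=1.0, binder_length=160)
        assert "binder_too_long" in rep.fail_reasons
        assert apply_filters(3, 8, ptyr_rmsd_value=1.0, binder_length=159).verdict == "pass"

    def test_confidence_gates_explicit_only(self, caplog):
        thr = FilterThresholds(min_plddt=80.0, max_ipae=10.0)
        rep = apply_filters(
            3, 8, confidence={"plddt": 70.0, "ipae": 5.0}, thresholds=thr
        )
        assert rep.fail_reasons == ["low_plddt"]
        with caplog.at_level("WARNING"):
            rep2 = apply_filters(3, 8, confidence={}, thresholds=thr)
        assert rep2.verdict == "pass"  # missing metrics skip their gates
        assert "skipped" in caplog.text

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_phos = int(rng.integers(0, 5))
            total = int(rng.integers(0, 20))
            rmsd = float(rng.uniform(0, 8))
            strict = FilterThresholds()
            lax = FilterThresholds(
                min_phosphate_hbonds=1, max_peptide_hbonds=15, max_ptyr_rmsd=7.0
            )
            r_strict = apply_filters(n_phos, total, ptyr_rmsd_value=rmsd,
                                     thresholds=strict)
            r_lax = apply_filters(n_phos, total, ptyr_rmsd_value=rmsd,
                                  thresholds=lax)
            if r_strict.verdict == "pass":
                assert r_lax.verdict == "pass"
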