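import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixbind.errors import (
    CollisionError,
    NoFeasibleRegisterError,
    RegisterError,
    SelectionError,
)
from helixbind.graft import (
    BindingSite,
    GraftSpec,
    HelixAnnotation,
    HelixSegment,
    TernaryComplex,
    apply_graft,
    assess_graft_sites,
    inter_tmd_spacing,
    map_pseudosymmetric_positions,
    optimize_register,
)
from helixbind.structio import AtomRecord, Structure, kabsch_superpose
from helixbind.synthdata import make_toy_complex

from .conftest import random_rotation
from .oracles import direct_rmsd_after_superposition, nearest_neighbor_assignment

SITE_POSITIONS = (19, 20, 21, 22, 35, 36, 37, 38)  # spans H2 and H3


def _site(positions=SITE_POSITIONS, aa="W"):
    return BindingSite(role="secondary", entries=tuple((p, aa) for p in positions))


class TestMapping:
    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_bijection(self, ideal_bundle, orientation):
        structure, ann = ideal_bundle
        pm = map_pseudosymmetric_positions(structure, ann, orientation)
        inv = pm.inverse()
        for src, dst in pm.mapping:
            assert inv[dst] == src
        assert len(inv) == len(pm.mapping)

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_pairs_close_and_match_exhaustive_oracle(self, ideal_bundle, orientation):
        structure, ann = ideal_bundle
        pm = map_pseudosymmetric_positions(structure, ann, orientation)
        sup = pm.superposition
        dst_keys = []
        dst_xyz = []
        for seg in (ann.h1, ann.h4):
            for r in seg.residues:
                dst_keys.append((seg.chain, r))
                dst_xyz.append(structure.atom(seg.chain, r, "CA").position)
        dst_xyz = np.stack(dst_xyz)
        moved = np.stack(
            [sup.apply(structure.atom(c, r, "CA").position)[0] for (c, r), _ in pm.mapping]
        )
        # every mapped pair within 2 A after superposition
        dists = [
            np.linalg.norm(m - structure.atom(c, r, "CA").position)
            for m, (_, (c, r)) in zip(moved, pm.mapping)
        ]
        assert max(dists) < 2.0
        # agrees with brute-force nearest-neighbor assignment
        oracle_idx = nearest_neighbor_assignment(moved, dst_xyz)
        assert [dst_keys[i] for i in oracle_idx] == [dst for _, dst in pm.mapping]

    def test_orientations_differ(self, ideal_bundle):
        structure, ann = ideal_bundle
        par = set(map_pseudosymmetric_positions(structure, ann, "parallel").mapping)
        anti = set(map_pseudosymmetric_positions(structure, ann, "antiparallel").mapping)
        assert par != anti

    def test_register_offset_out_of_range(self, ideal_bundle):
        structure, ann = ideal_bundle
        with pytest.raises(RegisterError):
            map_pseudosymmetric_positions(structure, ann, "parallel", register_offset=99)

    def test_positions_must_be_on_source_face(self, ideal_bundle):
        structure, ann = ideal_bundle
        with pytest.raises(SelectionError):
            map_pseudosymmetric_positions(
                structure, ann, "parallel", positions=[("A", ann.h1.start)]
            )


class TestOptimizeRegister:
    def test_prealigned_ideal_case(self, ideal_bundle):
        structure, ann = ideal_bundle
        offset, rmsd = optimize_register(structure, ann, _site(), "parallel")
        assert offset == 0
        assert rmsd < 1e-5

    def test_shifted_site_recovers_inverse_offset(self, ideal_bundle):
        structure, ann = ideal_bundle
        reference = np.stack(
            [structure.atom("A", p, "CA").position for p in SITE_POSITIONS]
        )
        shifted = _site(tuple(p + 2 for p in SITE_POSITIONS))
        offset, _ = optimize_register(
            structure, ann, shifted, "parallel", reference_coords=reference
        )
        assert offset == -2

    @pytest.mark.parametrize("orientation", ["parallel", "antiparallel"])
    def test_argmin_against_independent_scan(self, ideal_bundle, orientation):
        structure, ann = ideal_bundle
        site = _site()
        reference = np.stack(
            [structure.atom("A", p, "CA").position for p in site.positions]
        )
        best_offset, best_rmsd = optimize_register(structure, ann, site, orientation)
        # independently coded exhaustive re-scan
        scanned = {}
        for offset in range(-4, 5):
            try:
                pm = map_pseudosymmetric_positions(
                    structure, ann, orientation, register_offset=offset,
                    positions=[("A", p) for p in site.positions],
                )
            except (RegisterError, SelectionError, CollisionError):
                continue
            dst = np.stack(
                [structure.atom(c, r, "CA").position for _, (c, r) in pm.mapping]
            )
            scanned[offset] = kabsch_superpose(reference, dst).rmsd
        assert best_rmsd <= min(scanned.values()) + 1e-12
        assert scanned[best_offset] == pytest.approx(best_rmsd, abs=1e-12)

    def test_no_feasible_register(self, ideal_bundle):
        structure, ann = ideal_bundle
        # break the destination face (move H1 only): no nearest-CA within cutoff
        far = Structure(
            [
                AtomRecord(
                    a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                    a.position + (np.array([500.0, 0, 0])
                                  if a.residue_number <= ann.h1.end else 0.0),
                )
                for a in structure
            ]
        )
        with pytest.raises(NoFeasibleRegisterError):
            optimize_register(far, ann, _site(), "parallel")


class TestApplyGraft:
    def test_empty_entries_identity(self):
        assert apply_graft("MKLV", ()) == "MKLV"

    def test_hamming_distance_three(self, rng):
        template = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        positions = rng.choice(np.arange(1, 41), size=3, replace=False)
        entries = []
        for p in positions:
            current = template[p - 1]
            new = "W" if current != "W" else "Y"
            entries.append((int(p), new))
        mutated = apply_graft(template, entries)
        assert sum(a != b for a, b in zip(template, mutated)) == 3
        assert len(mutated) == len(template)

    def test_idempotent(self):
        entries = ((2, "W"), (5, "Y"))
        once = apply_graft("AAAAAA", entries)
        twice = apply_graft(once, entries)
        assert once == twice

    def test_collision(self):
        with pytest.raises(CollisionError):
            apply_graft("AAAA", ((2, "W"), (2, "Y")))

    def test_out_of_range(self):
        with pytest.raises(SelectionError):
            apply_graft("AAAA", ((9, "W"),))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_unmapped_positions_untouched(self, seed):
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
        k = int(rng.integers(0, 6))
        positions = rng.choice(np.arange(1, 26), size=k, replace=False)
        entries = tuple((int(p), "W") for p in positions)
        mutated = apply_graft(template, entries)
        touched = {int(p) for p in positions}
        for i, (a, b) in enumerate(zip(template, mutated), start=1):
            if i not in touched:
                assert a == b


class TestGraftSpec:
    def test_valid(self):
        GraftSpec(orientation="parallel", patch_size=12)

    def test_invalid_patch(self):
        with pytest.raises(ValueError):
            GraftSpec(orientation="parallel", patch_size=13)

    def test_invalid_orientation(self):
        with pytest.raises(ValueError):
            GraftSpec(orientation="diagonal", patch_size=12)


class TestAssessSites:
    def test_self_zero(self, ideal_bundle):
        structure, ann = ideal_bundle
        primary = [(("A", r), ("A", r)) for r in SITE_POSITIONS]
        secondary = [(("A", r), ("A", r)) for r in range(ann.h1.start, ann.h1.start + 8)]
        got = assess_graft_sites(structure, structure, primary, secondary)
        assert got == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_matches_direct_formula(self, ideal_bundle):
        structure, ann = ideal_bundle
        rng = np.random.default_rng(11)
        noised = Structure(
            [
                AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                           a.position + rng.normal(0.0, 0.3, 3))
                for a in structure
            ]
        )
        primary = [(("A", r), ("A", r)) for r in SITE_POSITIONS]
        secondary = [(("A", r), ("A", r)) for r in range(ann.h1.start, ann.h1.start + 8)]
        got = assess_graft_sites(structure, noised, primary, secondary)
        from helixbind.structio import gather_paired_coords

        for value, sel in zip(got, (primary, secondary)):
            pa, pb = gather_paired_coords(structure, noised, sel, ("CA",))
            assert value == pytest.approx(direct_rmsd_after_superposition(pa, pb), abs=1e-12)


class TestSpacing:
    def _ligand(self):
        return Structure(
            [AtomRecord("A", i + 1, "GLY", "CA", np.array([0.0, 0.0, float(i)]))
             for i in range(5)]
        )

    def test_single_model_exact_distance(self):
        complex_ = make_toy_complex(self._ligand(), 100.0)
        est = inter_tmd_spacing([complex_])
        assert est.mean == pytest.approx(100.0, abs=1e-6)
        assert est.sd == 0.0

    def test_hand_computed_ensemble(self):
        distances = [80.0, 84.0, 84.0, 86.0, 86.0]
        models = [make_toy_complex(self._ligand(), d) for d in distances]
        est = inter_tmd_spacing(models)
        assert est.mean == pytest.approx(84.0, abs=1e-6)
        assert est.sd == pytest.approx(np.std(distances, ddof=1), abs=1e-6)
        np.testing.assert_allclose(est.distances, distances, atol=1e-6)

    def test_rigid_transform_invariance(self, rng):
        models = [make_toy_complex(self._ligand(), d) for d in (80.0, 90.0, 100.0)]
        base = inter_tmd_spacing(models)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 50.0
        moved_models = []
        for m in models:
            moved = Structure(
                [
                    AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                               rot @ a.position + shift)
                    for a in m.structure
                ]
            )
            moved_models.append(
                TernaryComplex(structure=moved, ligand_chain=m.ligand_chain,
                               receptor_chains=m.receptor_chains)
            )
        est = inter_tmd_spacing(moved_models)
        assert est.mean == pytest.approx(base.mean, abs=1e-9)
        assert est.sd == pytest.approx(base.sd, abs=1e-9)

    def test_missing_receptor_chain(self):
        complex_ = TernaryComplex(
            structure=self._ligand(), ligand_chain="A", receptor_chains=("R", "S")
        )
        with pytest.raises(SelectionError):
            inter_tmd_spacing([complex_])

    def test_empty_ensemble(self):
        with pytest.raises(ValueError):
            inter_tmd_spacing([])


class TestAnnotationTypes:
    def test_short_helix_rejected(self):
        with pytest.raises(ValueError):
            HelixSegment("A", 1, 4, "up")

    def test_overlap_rejected(self):
        segs = [
            HelixSegment("A", 1, 10, "up"),
            HelixSegment("A", 8, 18, "down"),
            HelixSegment("A", 19, 28, "up"),
            HelixSegment("A", 29, 38, "down"),
        ]
        with pytest.raises(ValueError):
            HelixAnnotation(*segs)

    def test_binding_site_duplicate_positions(self):
        with pytest.raises(ValueError):
            BindingSite(role="primary", entries=((1, "A"), (1, "C")))

    def test_binding_site_bad_alphabet(self):
        with pytest.raises(ValueError):
            BindingSite(role="primary", entries=((1, "B"),))
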