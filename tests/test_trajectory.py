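"""Trajectory geometry: virtual oxygen, frame classification, contacts."""

import math

import numpy as np
import pytest

from cypsom import (
    ClassificationThresholds,
    ContactTable,
    HemeGeometry,
    TrajectorySpec,
    build_virtual_oxygen,
    classify_frame,
    contact_counts,
    contact_differential,
    distance_histogram,
    generate_toy_trajectory,
    scan_trajectory,
)
from cypsom.model import InputError
from cypsom.trajectory import GeometryError, SelectionError, summarize


def ideal_heme():
    return HemeGeometry(
        fe=[0.0, 0.0, 0.0],
        pyrrole_n=[[2, 0, 0], [0, 2, 0], [-2, 0, 0], [0, -2, 0]],
        axial_s=[0.0, 0.0, -2.3],
    )


def random_rigid_transform(rng):
    # random rotation via QR of a Gaussian matrix, plus random translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-50, 50, 3)
    return q, t


class TestVirtualOxygen:
    def test_idealized_planar_heme(self):
        o = build_virtual_oxygen(ideal_heme())
        assert o == pytest.approx([0.0, 0.0, 1.65], abs=1e-12)

    def test_custom_ferryl_distance(self):
        o = build_virtual_oxygen(ideal_heme(), fe_o_distance=2.0)
        assert o == pytest.approx([0.0, 0.0, 2.0], abs=1e-12)

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(7)
        heme = ideal_heme()
        o_ref = build_virtual_oxygen(heme)
        for _ in range(20):
            q, t = random_rigid_transform(rng)
            moved = HemeGeometry(
                fe=q @ heme.fe + t,
                pyrrole_n=(q @ heme.pyrrole_n.T).T + t,
                axial_s=q @ heme.axial_s + t,
            )
            o_moved = build_virtual_oxygen(moved)
            assert np.linalg.norm(o_moved - (q @ o_ref + t)) < 1e-9

    def test_collinear_nitrogens_rejected(self):
        heme = HemeGeometry(
            fe=[0, 0, 0],
            pyrrole_n=[[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]],
            axial_s=[0, 0, -2.3],
        )
        with pytest.raises(GeometryError):
            build_virtual_oxygen(heme)

    def test_in_plane_axial_sulfur_rejected(self):
        heme = HemeGeometry(
            fe=[0, 0, 0],
            pyrrole_n=[[2, 0, 0], [0, 2, 0], [-2, 0, 0], [0, -2, 0]],
            axial_s=[3.0, 3.0, 0.0],
        )
        with pytest.raises(GeometryError):
            build_virtual_oxygen(heme)


class TestClassifyFrame:
    O = np.zeros(3)

    def place(self, d):
        return np.array([d, 0.0, 0.0])

    @pytest.mark.parametrize("d1,expected", [(4.4, True), (4.5, True),
                                             (4.6, False)])
    def test_productive_boundary_inclusive(self, d1, expected):
        fc = classify_frame(self.place(d1), self.place(9.0), self.O)
        assert fc.productive is expected
        if not expected:
            assert fc.selective is None

    @pytest.mark.parametrize("d4,expected", [(5.6, True), (5.5, False),
                                             (5.4, False)])
    def test_selective_boundary_strict(self, d4, expected):
        fc = classify_frame(self.place(4.0), self.place(d4), self.O)
        assert fc.productive
        assert fc.selective is expected

    def test_agrees_with_brute_force_on_random_frames(self):
        rng = np.random.default_rng(123)
        thr = ClassificationThresholds()
        for _ in range(10_000):
            c1, c4, o = rng.uniform(-10, 10, (3, 3))
            fc = classify_frame(c1, c4, o, thr)
            d1 = math.dist(c1, o)
            d4 = math.dist(c4, o)
            assert fc.productive == (d1 <= 4.5)
            if fc.productive:
                assert fc.selective == (d4 > 5.5)
            assert fc.d_c1_o == pytest.approx(d1, abs=1e-12)
            assert fc.d_c4_o == pytest.approx(d4, abs=1e-12)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(InputError):
            ClassificationThresholds(productive_cutoff=6.0,
                                     selective_cutoff=5.0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InputError):
            classify_frame([np.nan, 0, 0], self.place(5.0), self.O)


class TestScanTrajectory:
    def test_label_round_trip_exact(self, toy_trajectory):
        cls, summary = scan_trajectory(toy_trajectory["topology"],
                                       toy_trajectory["trajectory"])
        labels = toy_trajectory["labels"]
        recovered = np.array([c.productive for c in cls])
        assert (recovered == labels["productive"].to_numpy()).all()
        sel_truth = labels.loc[labels["productive"], "selective"].astype(bool)
        sel_rec = np.array([c.selective for c in cls if c.productive],
                           dtype=bool)
        assert (sel_rec == sel_truth.to_numpy()).all()
        assert summary.n_productive == labels["productive"].sum()

    def test_summary_consistent_with_frame_list(self, toy_trajectory):
        cls, summary = scan_trajectory(toy_trajectory["topology"],
                                       toy_trajectory["trajectory"])
        assert summary == summarize(cls)
        assert summary.n_selective + summary.n_nonselective == \
            summary.n_productive

    def test_stride_classifies_every_second_frame(self, toy_trajectory):
        cls1, _ = scan_trajectory(toy_trajectory["topology"],
                                  toy_trajectory["trajectory"])
        cls2, s2 = scan_trajectory(toy_trajectory["topology"],
                                   toy_trajectory["trajectory"], stride=2)
        assert s2.n_total == math.ceil(len(cls1) / 2)
        assert [c.frame_index for c in cls2] == \
            [c.frame_index for c in cls1][::2]

    def test_bad_selection_raises(self, toy_trajectory):
        with pytest.raises(SelectionError):
            scan_trajectory(toy_trajectory["topology"],
                            toy_trajectory["trajectory"],
                            selections={"c1": "name DOESNOTEXIST"})


class TestDistanceHistogram:
    def test_counts_match_brute_force(self, toy_trajectory):
        cls, _ = scan_trajectory(toy_trajectory["topology"],
                                 toy_trajectory["trajectory"])
        edges = np.arange(2.0, 10.5, 0.5)
        hist = distance_histogram(cls, which="c1", bin_edges=edges)
        naive = np.zeros(len(edges) - 1, int)
        for c in cls:
            d = min(max(c.d_c1_o, edges[0]), edges[-1] - 1e-12)
            naive[np.searchsorted(edges, d, side="right") - 1] += 1
        assert (hist["count"].to_numpy() == naive).all()
        assert hist["count"].sum() == len(cls)

    def test_single_bin_holds_everything(self, toy_trajectory):
        cls, _ = scan_trajectory(toy_trajectory["topology"],
                                 toy_trajectory["trajectory"])
        hist = distance_histogram(cls, which="c4", bin_edges=[0.0, 100.0])
        assert hist["count"].iloc[0] == len(cls)

    def test_productive_only_filter(self, toy_trajectory):
        cls, summary = scan_trajectory(toy_trajectory["topology"],
                                       toy_trajectory["trajectory"])
        hist = distance_histogram(cls, which="c4", bin_edges=[0.0, 100.0],
                                  productive_only=True)
        assert hist["count"].sum() == summary.n_productive

    def test_empty_selection_warns_not_errors(self):
        with pytest.warns(UserWarning):
            hist = distance_histogram([], which="c1", bin_edges=[0, 1, 2])
        assert (hist["count"] == 0).all()

    def test_unsorted_edges_rejected(self):
        with pytest.raises(InputError):
            distance_histogram([], bin_edges=[3.0, 1.0, 2.0])


class TestContacts:
    def test_counts_match_ground_truth_labels(self, toy_trajectory):
        labels = toy_trajectory["labels"]
        spec = toy_trajectory["spec"]
        cls, _ = scan_trajectory(toy_trajectory["topology"],
                                 toy_trajectory["trajectory"])
        mask = [c.productive for c in cls]
        table = contact_counts(
            toy_trajectory["topology"], toy_trajectory["trajectory"],
            residue_ids=sorted(spec.contact_probabilities),
            productive_mask=mask, condition="toy")
        prod = labels["productive"].to_numpy()
        for rid in table.counts:
            assert table.counts[rid] == labels.loc[prod, f"contact_{rid}"].sum()

    def test_zero_cutoff_yields_zero_counts(self, toy_trajectory):
        table = contact_counts(
            toy_trajectory["topology"], toy_trajectory["trajectory"],
            residue_ids=[106, 108], contact_cutoff=0.0)
        assert all(c == 0 for c in table.counts.values())

    def test_counts_monotone_in_cutoff(self, toy_trajectory):
        rids = [106, 215, 304]
        prev = None
        for cutoff in (2.0, 4.0, 8.0, 50.0):
            table = contact_counts(
                toy_trajectory["topology"], toy_trajectory["trajectory"],
                residue_ids=rids, contact_cutoff=cutoff)
            if prev is not None:
                assert all(table.counts[r] >= prev.counts[r] for r in rids)
            prev = table

    def test_frequency_converges_to_generator_probability(self, tmp_path):
        # 10,000 frames, p = 0.3: count within the 99% binomial interval
        from scipy.stats import binom

        spec = TrajectorySpec(n_frames=10_000, productive_probability=1.0,
                              selective_probability=0.5,
                              contact_probabilities={106: 0.3}, seed=99)
        top, trj = tmp_path / "t.pdb", tmp_path / "t.dcd"
        generate_toy_trajectory(spec, top, trj)
        table = contact_counts(top, trj, residue_ids=[106])
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.3)
        assert lo <= table.counts[106] <= hi

    def test_unknown_residue_rejected(self, toy_trajectory):
        with pytest.raises(InputError):
            contact_counts(toy_trajectory["topology"],
                           toy_trajectory["trajectory"], residue_ids=[9999])

    def test_mask_length_mismatch_rejected(self, toy_trajectory):
        with pytest.raises(InputError):
            contact_counts(toy_trajectory["topology"],
                           toy_trajectory["trajectory"], residue_ids=[106],
                           productive_mask=[True] * 3)


class TestContactDifferential:
    @staticmethod
    def table(counts, n=1000, label="a", cutoff=4.0):
        return ContactTable(condition=label, n_frames=n, counts=dict(counts),
                            cutoff=cutoff)

    def test_identical_tables_no_flags(self):
        t = self.table({106: 100, 108: 50})
        diff = contact_differential(t, self.table({106: 100, 108: 50},
                                                  label="b"))
        assert (diff.table["rel_change"] == 0).all()
        assert not diff.table["flag_major_loss"].any()
        assert not diff.table["flag_major_gain"].any()

    def test_sixty_percent_loss_flagged(self):
        a = self.table({106: 100})
        b = self.table({106: 40}, label="b")
        diff = contact_differential(a, b)
        row = diff.table.iloc[0]
        assert row["rel_change"] == pytest.approx(-0.6)
        assert row["flag_major_loss"]
        assert diff.major_losses == [106]

    def test_swap_negates_changes(self):
        a = self.table({106: 100, 108: 80, 215: 0})
        b = self.table({106: 40, 108: 90, 215: 10}, label="b")
        fwd = contact_differential(a, b).table.set_index("resid")
        rev = contact_differential(b, a).table.set_index("resid")
        for rid in (106, 108):
            fa, fb = fwd.loc[rid, "rel_change"], rev.loc[rid, "rel_change"]
            # antisymmetry in frequency space: (fb-fa) = -(fa-fb)
            assert fa * fb < 0

    def test_new_contact_category_not_division_by_zero(self):
        a = self.table({215: 0})
        b = self.table({215: 10}, label="b")
        diff = contact_differential(a, b)
        row = diff.table.iloc[0]
        assert row["category"] == "new-contact"
        assert math.isnan(row["rel_change"])
        assert 215 in diff.major_gains

    def test_mismatched_tables_rejected(self):
        with pytest.raises(InputError):
            contact_differential(self.table({106: 1}),
                                 self.table({108: 1}, label="b"))
        with pytest.raises(InputError):
            contact_differential(self.table({106: 1}),
                                 self.table({106: 1}, cutoff=5.0, label="b"))
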