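import numpy as np
import pytest
from scipy.spatial.distance import cdist

from valvekit.chordae_gen import (
    CdtClass,
    ChordParams,
    assign_papillary,
    build_chordae,
    chordae_summary,
    layout_branch_tips,
    sample_primary_insertions,
    sample_secondary_insertions,
)
from valvekit.valve_geometry import BODY, make_stereotypical_mv, surface_regions

from conftest import make_flat_patch


def straight_strip(length=50.0, ny=4, nx=100):
    """Flat strip whose free edge is an analytic straight line of known length."""
    return make_flat_patch(nx, ny, lx=length, ly=8.0)


class TestChordParams:
    def test_valid(self):
        p = ChordParams(CdtClass.PRIMARY, density=2.0)
        assert p.branch_length == 3.5 and p.n_branches == 3

    @pytest.mark.parametrize("kw", [
        dict(density=-1.0), dict(density=2.0, n_branches=0),
        dict(density=2.0, csa=0.0), dict(density=2.0, branch_radius=-1.0),
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ChordParams(CdtClass.PRIMARY, **kw)

    def test_out_of_tool_range(self):
        with pytest.raises(ValueError, match="range"):
            ChordParams(CdtClass.PRIMARY, density=5.0)
        ChordParams(CdtClass.PRIMARY, density=5.0, allow_out_of_range=True)


class TestPrimaryInsertions:
    def test_count_density_times_length(self):
        model = straight_strip(length=50.0)
        centers = sample_primary_insertions(model, density=2.0)
        assert len(centers) == 10  # round(2 * 5 cm)

    def test_equal_arclength_spacing(self):
        model = straight_strip(length=50.0)
        centers = sample_primary_insertions(model, density=2.0)
        xs = np.sort(centers[:, 0])
        gaps = np.diff(xs)
        assert np.allclose(gaps, 5.0, atol=1e-6)

    def test_deterministic_per_seed(self):
        model = make_stereotypical_mv(mesh_target_elems=600)
        a = sample_primary_insertions(model, 2.0, seed=3)
        b = sample_primary_insertions(model, 2.0, seed=3)
        assert np.array_equal(a, b)
        c = sample_primary_insertions(model, 2.0, seed=4)
        assert not np.array_equal(a, c)

    def test_at_least_one_per_leaflet(self):
        model = make_stereotypical_mv(mesh_target_elems=600)
        centers = sample_primary_insertions(model, 1.0)
        fe = [model.nodes[p] for p in model.free_edge_paths]
        owners = np.argmin(np.stack([cdist(centers, f).min(axis=1) for f in fe]), axis=0)
        assert set(owners.tolist()) == {0, 1}

    def test_density_range_enforced(self):
        model = straight_strip()
        with pytest.raises(ValueError):
            sample_primary_insertions(model, 0.5)
        sample_primary_insertions(model, 0.5, allow_out_of_range=True)

    def test_baseline_insertion_count_near_114(self):
        """Paper-parameter configuration on the default stereotypical MV."""
        model = make_stereotypical_mv(mesh_target_elems=3000)
        params = [
            ChordParams(CdtClass.PRIMARY, 2.0, 3.5, 3, 1.0, 1.0),
            ChordParams(CdtClass.SECONDARY, 3.0, 3.5, 4, 1.0, 1.0),
        ]
        ch = build_chordae(model, params)
        n = chordae_summary(ch)["n_insertion_points"]
        assert abs(n - 114) <= 0.15 * 114


class TestSecondaryInsertions:
    def test_count_density_times_area(self):
        # strip 20 x 30 mm = 6 cm^2; body band (0,1) covers every node
        model = make_flat_patch(20, 30, lx=20.0, ly=30.0)
        region = np.ones(model.n_nodes, dtype=bool)
        centers = sample_secondary_insertions(model, density=3.0, region=region)
        assert len(centers) == 18

    def test_density_doubling_doubles_count(self):
        model = make_flat_patch(20, 30, lx=20.0, ly=30.0)
        region = np.ones(model.n_nodes, dtype=bool)
        n1 = len(sample_secondary_insertions(model, 2.0, region))
        n2 = len(sample_secondary_insertions(model, 4.0, region))
        assert n2 == 2 * n1

    def test_blue_noise_beats_uniform_random(self):
        """Oracle: min pairwise distance >= best of 100 seeded uniform draws."""
        model = make_flat_patch(25, 25, lx=25.0, ly=25.0)
        region = np.ones(model.n_nodes, dtype=bool)
        centers = sample_secondary_insertions(model, 3.0, region, seed=0)
        k = len(centers)

        def min_pairwise(pts):
            d = cdist(pts, pts)
            np.fill_diagonal(d, np.inf)
            return d.min()

        ours = min_pairwise(centers)
        rng = np.random.default_rng(123)
        best = max(
            min_pairwise(model.nodes[rng.choice(model.n_nodes, size=k, replace=False)])
            for _ in range(100)
        )
        assert ours >= best

    def test_deterministic(self):
        model = make_flat_patch(10, 10)
        region = np.ones(model.n_nodes, dtype=bool)
        a = sample_secondary_insertions(model, 3.0, region, seed=9)
        b = sample_secondary_insertions(model, 3.0, region, seed=9)
        assert np.array_equal(a, b)

    def test_count_exceeding_region_rejected(self):
        model = make_flat_patch(3, 3, lx=30.0, ly=30.0)  # 16 nodes, 9 cm^2
        region = np.ones(model.n_nodes, dtype=bool)
        with pytest.raises(ValueError, match="region"):
            sample_secondary_insertions(model, 10.0, region)

    def test_empty_region_rejected(self):
        model = make_flat_patch(5, 5)
        with pytest.raises(ValueError):
            sample_secondary_insertions(model, 3.0, np.zeros(model.n_nodes, dtype=bool))


class TestAssignPapillary:
    def test_nearer_tip_wins(self):
        model = make_flat_patch(4, 4)
        model.papillary_tips = np.array([[10.0, 0, -20.0], [-10.0, 0, -20.0]])
        lab = assign_papillary(np.array([[3.0, 0, 0]]), model)
        assert lab[0] == 0

    def test_tie_breaks_to_lower_label(self):
        model = make_flat_patch(4, 4)
        model.papillary_tips = np.array([[10.0, 0, -20.0], [-10.0, 0, -20.0]])
        lab = assign_papillary(np.array([[0.0, 5.0, 1.0]]), model)
        assert lab[0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        model = make_flat_patch(4, 4)
        model.papillary_tips = rng.uniform(-20, 20, size=(4, 3))
        centers = rng.uniform(-20, 20, size=(50, 3))
        got = assign_papillary(centers, model)
        bf = np.array([int(np.argmin([np.linalg.norm(c - t)
                                      for t in model.papillary_tips]))
                       for c in centers])
        assert np.array_equal(got, bf)


class TestLayoutBranchTips:
    def test_regular_polygon_on_fine_flat_patch(self):
        model = make_flat_patch(100, 100, lx=20.0, ly=20.0)
        center = np.array([10.0, 10.0, 0.0])
        tips = layout_branch_tips(model, center, n_branches=4, branch_radius=1.0)
        pts = model.nodes[tips]
        r = np.linalg.norm(pts - center, axis=1)
        assert len(tips) == 4
        assert np.all(np.abs(r - 1.0) < 0.1)
        ang = np.unwrap(np.arctan2(pts[:, 1] - 10.0, pts[:, 0] - 10.0))
        diffs = np.abs(np.diff(ang)) % (2 * np.pi)
        assert np.allclose(diffs, np.pi / 2, atol=np.deg2rad(5))

    def test_single_branch_snaps_to_nearest_node(self):
        model = make_flat_patch(10, 10)
        center = np.array([3.3, 4.2, 0.0])
        tips = layout_branch_tips(model, center, 1, 1.0)
        expected = int(np.argmin(np.linalg.norm(model.nodes - center, axis=1)))
        assert tips.tolist() == [expected]

    def test_coarse_mesh_dedup(self):
        model = make_flat_patch(2, 2, lx=20.0, ly=20.0)  # nodes 10mm apart
        center = np.array([10.0, 10.0, 0.0])
        tips = layout_branch_tips(model, center, n_branches=5, branch_radius=0.5)
        assert len(tips) < 5
        assert len(set(tips.tolist())) == len(tips)


class TestBuildChordae:
    def patch_params(self, **kw):
        defaults = dict(density=2.0, branch_length=3.0, n_branches=3,
                        branch_radius=1.0, csa=1.0, seed=0)
        defaults.update(kw)
        return ChordParams(CdtClass.PRIMARY, **defaults)

    def test_segment_count_one_center(self):
        model = make_flat_patch(30, 30, lx=30.0, ly=8.0)
        params = self.patch_params(density=1.0, allow_out_of_range=True)
        ch = build_chordae(model, params)
        trunk_per_chord = 1
        for cid in range(ch.n_chords):
            n_seg = int(np.sum(ch.chord_id == cid))
            assert n_seg >= trunk_per_chord + 2  # trunk + >=2 deduped branches
            assert n_seg <= 4

    def test_single_branch_single_segment(self):
        model = make_flat_patch(30, 30, lx=30.0, ly=8.0)
        ch = build_chordae(model, self.patch_params(n_branches=1))
        counts = np.bincount(ch.chord_id)
        assert np.all(counts == 1)
        for seg in ch.segments:
            assert seg[0] in ch.papillary_node_index
            assert seg[1] < ch.n_valve_nodes

    def test_junction_distance_baseline(self):
        """Every junction sits exactly branch_length from its insertion
        center along the tip→center line."""
        model = make_stereotypical_mv(mesh_target_elems=900)
        params = [
            ChordParams(CdtClass.PRIMARY, 2.0, 3.5, 3, 1.0, 1.0),
            ChordParams(CdtClass.SECONDARY, 3.0, 3.5, 4, 1.0, 1.0),
        ]
        ch = build_chordae(model, params)
        allx = ch.all_nodes(model.nodes)
        n_pap = len(ch.papillary_node_index)
        for cid in range(ch.n_chords):
            segs = ch.segments[ch.chord_id == cid]
            trunk = segs[0]
            junction_idx = trunk[1]
            if junction_idx < ch.n_valve_nodes + n_pap:
                continue  # unbranched chord
            j = allx[junction_idx]
            center = ch.insertion_centers[cid]
            tip = model.papillary_tips[ch.papillary_label[cid]]
            assert np.linalg.norm(j - center) == pytest.approx(3.5, abs=1e-9)
            # collinearity with tip->center
            u = (tip - center) / np.linalg.norm(tip - center)
            assert np.linalg.norm((j - center) - np.dot(j - center, u) * u) < 1e-9

    def test_branch_length_clamped_with_warning(self, caplog):
        model = make_flat_patch(30, 30, lx=30.0, ly=8.0)
        model.papillary_tips = np.array([[15.0, 4.0, -2.0]])  # very close tip
        params = self.patch_params(branch_length=100.0)
        with caplog.at_level("WARNING", logger="valvekit.chordae_gen"):
            ch = build_chordae(model, params)
        assert "clamping" in caplog.text
        assert ch.n_segments > 0

    def test_forest_one_papillary_root_per_component(self):
        """Graph audit by traversal: each connected component contains
        exactly one papillary tip node."""
        import networkx as nx
        model = make_stereotypical_mv(mesh_target_elems=900)
        params = [
            ChordParams(CdtClass.PRIMARY, 2.0, 3.5, 3, 1.0, 1.0),
            ChordParams(CdtClass.SECONDARY, 3.0, 3.5, 4, 1.0, 1.0),
        ]
        ch = build_chordae(model, params)
        g = nx.Graph()
        g.add_edges_from(map(tuple, ch.segments))
        pap = set(ch.papillary_node_index.tolist())
        for comp in nx.connected_components(g):
            assert len(comp & pap) == 1

    def test_determinism_bit_identical(self):
        model = make_stereotypical_mv(mesh_target_elems=600)
        params = [ChordParams(CdtClass.PRIMARY, 2.0, 3.5, 3, 1.0, 1.0, seed=7)]
        a = build_chordae(model, params)
        b = build_chordae(model, params)
        assert np.array_equal(a.extra_nodes, b.extra_nodes)
        assert np.array_equal(a.segments, b.segments)
        assert np.array_equal(a.segment_csa, b.segment_csa)

    def test_no_zero_length_segments(self, mv_model, mv_chordae):
        allx = mv_chordae.all_nodes(mv_model.nodes)
        L = np.linalg.norm(allx[mv_chordae.segments[:, 1]]
                           - allx[mv_chordae.segments[:, 0]], axis=1)
        assert np.all(L > 1e-9)

    def test_insertions_are_valve_nodes(self, mv_chordae):
        idx = mv_chordae.insertion_node_indices()
        assert len(idx) > 0
        assert np.all(idx < mv_chordae.n_valve_nodes)


class TestChordaeSummary:
    def test_counting_no_dedup(self):
        """10 chords x 3 branches, no snapping collisions."""
        model = make_flat_patch(60, 20, lx=60.0, ly=20.0)
        region = np.zeros(model.n_nodes, dtype=np.int64)
        region[:] = BODY
        params = ChordParams(CdtClass.SECONDARY, density=10.0 / 12.0, branch_length=3.0,
                             n_branches=3, branch_radius=2.0, csa=1.0,
                             allow_out_of_range=True)
        ch = build_chordae(model, [params], body_band_bounds=(0.01, 0.99),
                          edge_band=0.5)
        s = chordae_summary(ch)
        # every insertion-adjacent segment contributes its csa
        assert s["total_csa"] == pytest.approx(s["n_insertion_points"] * 1.0)

    def test_empty_set(self):
        from valvekit.chordae_gen import ChordaeSet
        empty = ChordaeSet(
            n_valve_nodes=0, extra_nodes=np.empty((0, 3)),
            segments=np.empty((0, 2), dtype=np.int64), segment_csa=np.empty(0),
            chord_id=np.empty(0, dtype=np.int64), chord_class=np.empty(0, dtype=np.int64),
            insertion_centers=np.empty((0, 3)), papillary_label=np.empty(0, dtype=np.int64))
        s = chordae_summary(empty)
        assert s == {"n_insertion_points": 0, "total_csa": 0.0,
                     "n_chords": 0, "n_segments": 0}

    def test_matches_brute_force_recount(self, mv_chordae):
        s = chordae_summary(mv_chordae)
        # brute force over the segment list
        ins_nodes = set()
        total = 0.0
        for seg, csa in zip(mv_chordae.segments, mv_chordae.segment_csa):
            touching = [e for e in seg if e < mv_chordae.n_valve_nodes]
            ins_nodes.update(int(e) for e in touching)
            if touching:
                total += csa
        assert s["n_insertion_points"] == len(ins_nodes)
        assert s["total_csa"] == pytest.approx(total)

    def test_total_csa_linear_in_csa_param(self):
        model = make_stereotypical_mv(mesh_target_elems=600)
        for scale in (0.5, 2.0):
            a = build_chordae(model, [ChordParams(CdtClass.PRIMARY, 2.0, csa=1.0)])
            b = build_chordae(model, [ChordParams(CdtClass.PRIMARY, 2.0, csa=scale)])
            assert (chordae_summary(b)["total_csa"]
                    == pytest.approx(scale * chordae_summary(a)["total_csa"]))

    def test_insertion_points_monotone_in_density(self):
        model = make_stereotypical_mv(mesh_target_elems=1200)
        counts = []
        for d in (1.0, 2.0, 3.0):
            ch = build_chordae(model, [ChordParams(CdtClass.PRIMARY, d, 3.5, 3, 1.0)])
            counts.append(chordae_summary(ch)["n_insertion_points"])
        assert counts[0] <= counts[1] <= counts[2]
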