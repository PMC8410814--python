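"""Contact rule against brute-force adjacency enumeration, plus aggregation."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from nodeglia.contacts import (
    aggregate_mean_of_means,
    call_contact,
    classify_contacting_cells,
    percent_contacted,
)
from nodeglia.masks import binarize, label_nodes
from nodeglia.synthetic_microscopy import (
    CHANNEL_MICROGLIA,
    CHANNEL_NODES,
    generate_scene,
    high_snr_params,
    render,
)


def brute_force_contact(microglia, node, diagonals: bool) -> bool:
    """Independent oracle: scan every (node px, microglia px) pair."""
    node_px = np.argwhere(node)
    mg_px = np.argwhere(microglia)
    for (ny, nx), (my, mx) in itertools.product(node_px, mg_px):
        dy, dx = abs(int(ny) - int(my)), abs(int(nx) - int(mx))
        if dy == 0 and dx == 0:
            return True
        if diagonals and max(dy, dx) <= 1:
            return True
        if not diagonals and dy + dx <= 1:
            return True
    return False


class TestCallContact:
    def test_node_inside_microglia(self):
        mg = np.ones((5, 5), dtype=bool)
        node = np.zeros((5, 5), dtype=bool)
        node[2, 2] = True
        assert call_contact(mg, node)

    def test_empty_microglia(self):
        node = np.zeros((5, 5), dtype=bool)
        node[2, 2] = True
        assert not call_contact(np.zeros((5, 5), dtype=bool), node)

    def test_diagonal_one_gap(self):
        """Node and microglia separated by one diagonal background pixel."""
        node = np.zeros((5, 5), dtype=bool)
        mg = np.zeros((5, 5), dtype=bool)
        node[1, 1] = True
        mg[2, 2] = True  # diagonal neighbour: adjacent only with diagonals
        assert not call_contact(mg, node, adjacency="face")
        assert call_contact(mg, node, adjacency="full")
        mg[:] = False
        mg[3, 3] = True  # two diagonal steps away: never adjacent
        assert not call_contact(mg, node, adjacency="face")
        assert not call_contact(mg, node, adjacency="full")

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            call_contact(np.zeros((4, 4), dtype=bool), np.zeros((5, 5), dtype=bool))

    @pytest.mark.parametrize("adjacency,diagonals", [("face", False), ("full", True)])
    def test_all_512_neighborhood_configurations(self, adjacency, diagonals):
        """Exhaustive oracle: every 3x3 microglia pattern around a node px."""
        node = np.zeros((3, 3), dtype=bool)
        node[1, 1] = True
        for bits in range(512):
            mg = np.array(
                [(bits >> k) & 1 for k in range(9)], dtype=bool
            ).reshape(3, 3)
            assert call_contact(mg, node, adjacency=adjacency) == brute_force_contact(
                mg, node, diagonals
            ), f"bits={bits} adjacency={adjacency}"

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.random((6, 6)) > 0.7
            b = rng.random((6, 6)) > 0.7
            for adj in ("face", "full"):
                assert call_contact(a, b, adj) == call_contact(b, a, adj)

    def test_dilation_monotonicity(self):
        """Dilating microglia never turns a contacted node non-contacted."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            mg = rng.random((8, 8)) > 0.8
            node = rng.random((8, 8)) > 0.9
            if not node.any():
                continue
            grown = ndimage.binary_dilation(mg)
            if call_contact(mg, node):
                assert call_contact(grown, node)

    def test_3d_adjacency(self):
        node = np.zeros((3, 3, 3), dtype=bool)
        mg = np.zeros((3, 3, 3), dtype=bool)
        node[1, 1, 1] = True
        mg[0, 0, 0] = True  # corner neighbour in 3D
        assert call_contact(mg, node, adjacency="full")
        assert not call_contact(mg, node, adjacency="face")


class TestPercentContacted:
    def test_synthetic_field_recovery(self, high_snr_field):
        _, truth, stacks = high_snr_field
        mg = binarize(stacks[CHANNEL_MICROGLIA])
        nodes = binarize(stacks[CHANNEL_NODES])
        result = percent_contacted(mg, nodes, plane_mode="full_stack")
        assert result.n_nodes == 20
        assert result.percent_contacted == pytest.approx(40.0)

    def test_all_contacted(self):
        mg = np.ones((10, 10), dtype=bool)
        nodes = np.zeros((10, 10), dtype=bool)
        nodes[2, 2] = nodes[7, 7] = True
        assert percent_contacted(mg, nodes).percent_contacted == 100.0

    def test_no_microglia(self):
        nodes = np.zeros((10, 10), dtype=bool)
        nodes[2, 2] = nodes[7, 7] = True
        res = percent_contacted(np.zeros((10, 10), dtype=bool), nodes)
        assert res.percent_contacted == 0.0

    def test_zero_nodes_flagged_excluded(self):
        with pytest.warns(UserWarning, match="zero nodal structures"):
            res = percent_contacted(
                np.ones((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool)
            )
        assert res.excluded and res.percent_contacted is None

    def test_middle_plane_vs_full_stack(self):
        """A contact present only off the central plane counts in 3D only."""
        mg = np.zeros((3, 5, 5), dtype=bool)
        nodes = np.zeros((3, 5, 5), dtype=bool)
        nodes[:, 2, 2] = True
        mg[0, 2, 3] = True  # adjacent, but on the first z-plane
        mid = percent_contacted(mg, nodes, plane_mode="middle_plane")
        full = percent_contacted(mg, nodes, plane_mode="full_stack")
        assert mid.percent_contacted == 0.0
        assert full.percent_contacted == 100.0


class TestAggregation:
    def _field(self, pct, animal, cond="c"):
        from nodeglia.contacts import FieldResult

        return FieldResult("f", animal, cond, 10, int(pct / 10), pct)

    def test_mean_of_means_worked_example(self):
        """Animal A {10, 20}, animal B {30} -> 22.5, not the field mean 20."""
        fields = [self._field(10, "A"), self._field(20, "A"), self._field(30, "B")]
        out = aggregate_mean_of_means(fields)
        assert out.loc[0, "mean_percent"] == pytest.approx(22.5)
        assert out.loc[0, "n_animals"] == 2

    def test_single_animal_single_field(self):
        out = aggregate_mean_of_means([self._field(50, "A")])
        assert out.loc[0, "mean_percent"] == 50.0
        assert out.loc[0, "sem_percent"] == 0.0
        assert bool(out.loc[0, "n1_flag"])

    def test_excluded_fields_skipped(self):
        from nodeglia.contacts import FieldResult

        fields = [
            self._field(40, "A"),
            FieldResult("f2", "A", "c", 0, 0, None, excluded=True),
        ]
        out = aggregate_mean_of_means(fields)
        assert out.loc[0, "mean_percent"] == 40.0

    def test_no_usable_fields_raises(self):
        from nodeglia.contacts import FieldResult

        with pytest.raises(ValueError):
            aggregate_mean_of_means(
                [FieldResult("f", "A", "c", 0, 0, None, excluded=True)]
            )

    def test_simulated_cohort_recovery(self):
        """Per-animal planted fractions {.2,.25,.3,.35} -> condition mean 27.5."""
        params = high_snr_params()
        fields = []
        for i, frac in enumerate((0.2, 0.25, 0.3, 0.35)):
            for fld in range(2):
                seed = 100 + 10 * i + fld
                scene, truth = generate_scene(
                    seed=seed, n_nodes=20, params=params, contacted_fraction=frac
                )
                stacks = render(scene, truth, seed=seed)
                fields.append(
                    percent_contacted(
                        binarize(stacks[CHANNEL_MICROGLIA]),
                        binarize(stacks[CHANNEL_NODES]),
                        field_id=f"f{i}{fld}",
                        animal_id=f"a{i}",
                        condition="ctrl",
                    )
                )
        out = aggregate_mean_of_means(fields)
        assert out.loc[0, "mean_percent"] == pytest.approx(27.5, abs=2.0)


class TestClassifyContactingCells:
    def test_cell_overlapping_node(self):
        cells = np.zeros((8, 8), dtype=int)
        cells[1:4, 1:4] = 1
        cells[5:8, 5:8] = 2
        nodes = np.zeros((8, 8), dtype=bool)
        nodes[2, 2] = True
        df = classify_contacting_cells(cells, nodes)
        assert bool(df.set_index("cell_id").loc[1, "contacting"])
        assert not bool(df.set_index("cell_id").loc[2, "contacting"])

    def test_empty_node_field(self):
        cells = np.zeros((6, 6), dtype=int)
        cells[1:3, 1:3] = 1
        df = classify_contacting_cells(cells, np.zeros((6, 6), dtype=bool))
        assert not df["contacting"].any()

    def test_synthetic_flags_match_truth(self, high_snr_field):
        scene, truth, stacks = high_snr_field
        mg = binarize(stacks[CHANNEL_MICROGLIA])
        nodes = binarize(stacks[CHANNEL_NODES])
        labels = label_nodes(mg).labels
        df = classify_contacting_cells(labels, nodes)
        # the largest cell is the planted microglia: contacting iff any
        # node is in contact at frame 0 (truth has 8 contacted nodes)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        main_cell = int(sizes.argmax())
        assert bool(df.set_index("cell_id").loc[main_cell, "contacting"])
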