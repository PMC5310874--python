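import numpy as np
import pytest

from gapc.data_model import (
    AdjacencyGraph,
    MortalityDataset,
    StudyDimensions,
    esp2013_standard,
    load_counts,
    load_graph,
    load_standard_population,
    table1_fixture,
    write_counts,
)
from gapc.errors import DataValidationError, GraphError, SchemaError
from gapc.simulate import lattice_graph
from gapc.data_model import write_graph


def _write_tiny_counts(path, drop_last=False, dup=False, sep=","):
    rows = ["gender,area,age_group,year,deaths,population".replace(",", sep)]
    for g in ("female", "male"):
        for age in ("[25-30)", "[30-35)"):
            for year in (1990, 1991):
                rows.append(sep.join([g, "A", age, str(year), "3", "1000"]))
    if dup:
        rows.append(rows[-1])
    if drop_last:
        rows.pop()
    path.write_text("\n".join(rows) + "\n")
    return path


class TestLoadCounts:
    def test_complete_tiny_grid(self, tmp_path):
        ds = load_counts(_write_tiny_counts(tmp_path / "c.csv"))
        assert ds.dims.shape == (2, 1, 2, 2)
        assert ds.dims.K == 5 * 1 + 2  # M=5 default
        assert ds.deaths.sum() == 8 * 3

    def test_tab_delimited_autodetect(self, tmp_path):
        ds = load_counts(_write_tiny_counts(tmp_path / "c.tsv", sep="\t"))
        assert ds.dims.shape == (2, 1, 2, 2)

    def test_missing_cell_is_named(self, tmp_path):
        with pytest.raises(DataValidationError, match=r"male.*\[30-35\).*1991"):
            load_counts(_write_tiny_counts(tmp_path / "c.csv", drop_last=True))

    def test_fill_zero_deaths_never_fills_population(self, tmp_path):
        # the missing row removes the only population source for that cell
        with pytest.raises(DataValidationError, match="population"):
            load_counts(_write_tiny_counts(tmp_path / "c.csv", drop_last=True),
                        fill_zero_deaths=True)

    def test_duplicate_cell_rejected(self, tmp_path):
        with pytest.raises(DataValidationError, match="duplicate"):
            load_counts(_write_tiny_counts(tmp_path / "c.csv", dup=True))

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("gender,area,age_group,year,deaths\nf,A,[25-30),1990,1\n")
        with pytest.raises(SchemaError, match="population"):
            load_counts(p)

    def test_negative_deaths_rejected_with_rows(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "gender,area,age_group,year,deaths,population\n"
            "f,A,[25-30),1990,-1,1000\n"
        )
        with pytest.raises(DataValidationError, match="-1"):
            load_counts(p)

    def test_round_trip_preserves_grid(self, tmp_path, tiny_setup):
        _, _, dataset, _ = tiny_setup
        p = tmp_path / "out.csv"
        write_counts(dataset, p)
        back = load_counts(p)
        np.testing.assert_array_equal(back.deaths, dataset.deaths)
        np.testing.assert_allclose(back.population, dataset.population)


class TestGraph:
    def test_edge_list_path_graph(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("1 2\n2 3\n")
        g = load_graph(p)
        assert g.n_nodes == 3 and g.n_components == 1
        assert g.edges == [(0, 1), (1, 2)]

    def test_disconnected_components_counted(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("1 2\n3 4\n")
        g = load_graph(p)
        assert g.n_nodes == 4 and g.n_components == 2

    def test_region_dialect_round_structure(self, tmp_path):
        p = tmp_path / "g.graph"
        p.write_text("3\n1 1 2\n2 2 1 3\n3 1 2\n")
        g = load_graph(p)
        assert g.edges == [(0, 1), (1, 2)]

    def test_rook_lattice_edge_count(self, tmp_path):
        # a 5x10 rook lattice has 2rc - r - c = 85 edges
        g = lattice_graph(5, 10)
        assert g.n_nodes == 50 and len(g.edges) == 85
        p = tmp_path / "l.edges"
        write_graph(g, p)
        assert len(load_graph(p).edges) == 85

    def test_self_loop_rejected(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("1 1\n")
        with pytest.raises(GraphError, match="self-loop"):
            load_graph(p)

    def test_unknown_region_id_rejected(self, tmp_path):
        p = tmp_path / "g.graph"
        p.write_text("2\n1 1 5\n2 0\n")
        with pytest.raises(GraphError, match="out of range"):
            load_graph(p)

    def test_neighbor_relation_symmetric(self):
        g = lattice_graph(3, 4)
        for u in range(g.n_nodes):
            for v in g.neighbors(u):
                assert u in g.neighbors(v)


class TestTable1Fixture:
    def test_printed_marginals(self):
        ds = table1_fixture()
        assert ds.dims.shape == (2, 1, 13, 1)
        # female cases for [25,30) and male population for [85,+)
        assert ds.deaths[0, 0, 0, 0] == 29
        assert ds.population[1, 0, 12, 0] == 5_711_393

    def test_column_totals_match_printed_total_row(self):
        ds = table1_fixture()
        assert ds.deaths[0].sum() == 48_346
        assert ds.deaths[1].sum() == 54_652
        assert ds.population[0].sum() == 369_126_507
        assert ds.population[1].sum() == 343_698_536
        assert ds.deaths.sum() == 102_998


class TestValidation:
    def test_zero_population_cell_rejected(self):
        dims = StudyDimensions(G=1, A=1, I=2, T=1)
        with pytest.raises(DataValidationError, match="population"):
            MortalityDataset(dims=dims, deaths=np.zeros(dims.shape, int),
                             population=np.zeros(dims.shape))

    def test_overlapping_age_groups_rejected(self):
        dims = StudyDimensions(G=1, A=1, I=2, T=1)
        with pytest.raises(DataValidationError, match="overlap|ordered"):
            MortalityDataset(
                dims=dims,
                deaths=np.zeros(dims.shape, int),
                population=np.ones(dims.shape),
                age_groups=["[25-35)", "[30-40)"],
            )

    def test_cohort_count_identity(self):
        dims = StudyDimensions(G=2, A=50, I=13, T=24, M=5)
        assert dims.K == 84

    def test_standard_population_normalizes(self):
        std = esp2013_standard()
        assert len(std.age_groups) == 13
        assert std.normalized.sum() == pytest.approx(1.0)
        # the open-ended group carries the 85-89 plus 90+ weights
        assert std.weights[-1] == 2500

    def test_standard_population_reader(self, tmp_path):
        p = tmp_path / "std.csv"
        p.write_text("age_group,weight\n[25-30),1\n[30-35),3\n")
        std = load_standard_population(p)
        np.testing.assert_allclose(std.normalized, [0.25, 0.75])
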