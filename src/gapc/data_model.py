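"""Core data containers and readers for spatio-temporal mortality analysis.

The central object is :class:`MortalityDataset`, a complete
gender x area x age-group x period grid of death counts and person-years,
indexed by :class:`StudyDimensions`.  Spatial neighbourhood structure lives
in :class:`AdjacencyGraph` (a thin wrapper over :mod:`networkx`), and
external standard-population weights in :class:`StandardPopulation`.

Index conventions follow the age-period-cohort literature: indices
``g, a, i, t, k`` are 1-based in documentation; ``i = 1`` is the youngest
age group and ``i = I`` the oldest, the orientation required for the cohort
map ``k = M (I - i) + t`` to assign the earliest birth cohorts to the
oldest age group.  Internal arrays are 0-based with axis order
``(g, a, i, t)``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataValidationError, GraphError, SchemaError

__all__ = [
    "StudyDimensions",
    "MortalityDataset",
    "AdjacencyGraph",
    "StandardPopulation",
    "load_counts",
    "write_counts",
    "load_graph",
    "write_graph",
    "load_standard_population",
    "table1_fixture",
    "esp2013_standard",
]

REQUIRED_COLUMNS = ("gender", "area", "age_group", "year", "deaths", "population")


@dataclass(frozen=True)
class StudyDimensions:
    """Grid dimensions of a gender-area-age-period study.

    ``M`` is the ratio of the age-interval width to the period-interval
    width (5 for five-year age groups on annual data).  The number of birth
    cohorts is determined: ``K = M * (I - 1) + T``.
    """

    G: int
    A: int
    I: int
    T: int
    M: int = 5

    def __post_init__(self) -> None:
        if self.G < 1 or self.A < 1 or self.I < 2 or self.T < 1 or self.M < 1:
            raise DataValidationError(
                f"invalid study dimensions G={self.G}, A={self.A}, I={self.I}, "
                f"T={self.T}, M={self.M} (need G,A,M >= 1, I >= 2, T >= 1)"
            )

    @property
    def K(self) -> int:
        """Number of birth cohorts spanned by the grid."""
        return self.M * (self.I - 1) + self.T

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.G, self.A, self.I, self.T)


_AGE_RE = re.compile(r"^\[(\d+)[-,]\s*(\d+|\+)\)?$")


def _age_lower_bound(label: str) -> float:
    """Sort key for an age-group label such as '[25-30)' or '[85-+)'."""
    m = _AGE_RE.match(str(label).strip())
    if m:
        return float(m.group(1))
    try:
        return float(label)
    except ValueError:
        return np.inf


def _age_bounds(label: str) -> tuple[float, float] | None:
    m = _AGE_RE.match(str(label).strip())
    if not m:
        return None
    lo = float(m.group(1))
    hi = np.inf if m.group(2) == "+" else float(m.group(2))
    return lo, hi


@dataclass
class MortalityDataset:
    """Complete G x A x I x T grid of deaths and person-years at risk.

    ``deaths[g, a, i, t]`` is the death count C_gait and
    ``population[g, a, i, t]`` the person-years n_gait used as the Poisson
    offset; population must be strictly positive in every cell.
    """

    dims: StudyDimensions
    deaths: np.ndarray
    population: np.ndarray
    genders: list[str] = field(default_factory=list)
    areas: list[str] = field(default_factory=list)
    age_groups: list[str] = field(default_factory=list)
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.population = np.asarray(self.population, dtype=float)
        shape = self.dims.shape
        if self.deaths.shape != shape or self.population.shape != shape:
            raise DataValidationError(
                f"grid shapes {self.deaths.shape}/{self.population.shape} do not "
                f"match dims {shape}"
            )
        if not self.genders:
            self.genders = [f"g{j + 1}" for j in range(self.dims.G)]
        if not self.areas:
            self.areas = [f"area{j + 1}" for j in range(self.dims.A)]
        if not self.age_groups:
            self.age_groups = [f"age{j + 1}" for j in range(self.dims.I)]
        if not self.years:
            self.years = list(range(1, self.dims.T + 1))
        if np.any(self.deaths < 0):
            bad = np.argwhere(self.deaths < 0)[:5].tolist()
            raise DataValidationError(f"negative death counts at cells {bad}")
        if np.any(~(self.population > 0)):
            bad = np.argwhere(~(self.population > 0))[:5].tolist()
            raise DataValidationError(
                f"nonpositive population at cells {bad}; the model offset is "
                "log(population), so every cell needs person-years > 0"
            )
        self._check_age_intervals()

    def _check_age_intervals(self) -> None:
        bounds = [_age_bounds(lab) for lab in self.age_groups]
        if any(b is None for b in bounds):
            return  # opaque labels: ordering not checkable
        for (lo1, hi1), (lo2, _hi2) in zip(bounds, bounds[1:]):
            if not (lo1 < lo2 and hi1 <= lo2):
                raise DataValidationError(
                    f"age groups {self.age_groups} are not ordered, "
                    "non-overlapping intervals"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with one row per (gender, area, age_group, year) cell."""
        G, A, I, T = self.dims.shape
        idx = pd.MultiIndex.from_product(
            [self.genders, self.areas, self.age_groups, self.years],
            names=["gender", "area", "age_group", "year"],
        )
        return pd.DataFrame(
            {
                "deaths": self.deaths.reshape(-1),
                "population": self.population.reshape(-1),
            },
            index=idx,
        ).reset_index()


@dataclass
class AdjacencyGraph:
    """Undirected area neighbourhood graph for the intrinsic CAR prior."""

    n_nodes: int
    edges: list[tuple[int, int]]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise GraphError("graph needs at least one node")
        seen: set[tuple[int, int]] = set()
        clean: list[tuple[int, int]] = []
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop at node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise GraphError(f"edge ({u},{v}) references an unknown node")
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                clean.append(key)
        self.edges = sorted(clean)
        if not self.node_labels:
            self.node_labels = [str(j + 1) for j in range(self.n_nodes)]
        if len(self.node_labels) != self.n_nodes:
            raise GraphError("node_labels length does not match n_nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def adjacency_matrix(self) -> np.ndarray:
        W = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            W[u, v] = W[v, u] = 1.0
        return W

    def neighbors(self, node: int) -> list[int]:
        return sorted(
            {v for u, v in self.edges if u == node} | {u for u, v in self.edges if v == node}
        )


@dataclass
class StandardPopulation:
    """Age-group weights for direct standardization (e.g. ESP 2013)."""

    age_groups: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.age_groups) != self.weights.size:
            raise DataValidationError("age-group labels and weights differ in length")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise DataValidationError("standard-population weights must be >= 0 with positive sum")

    @property
    def normalized(self) -> np.ndarray:
        """Weights rescaled to sum to one."""
        return self.weights / self.weights.sum()


def _read_table(path_or_buf) -> pd.DataFrame:
    """Delimited text with comma/tab autodetection and a required header row."""
    return pd.read_csv(path_or_buf, sep=None, engine="python")


def load_counts(
    path,
    schema: dict[str, str] | None = None,
    fill_zero_deaths: bool = False,
) -> MortalityDataset:
    """Read a long-format count table into a complete grid.

    Parameters
    ----------
    path
        Delimited text file (comma or tab, autodetected) with a header row
        and columns gender, area, age_group, year, deaths, population.
    schema
        Optional mapping from the canonical column names to the names used
        in the file.
    fill_zero_deaths
        If true, (g,a,i,t) combinations absent from the file are filled
        with zero deaths -- but only when the population for that cell can
        be found in another row is NOT required; population itself is never
        imputed, so a missing cell is only fillable if some row supplies
        its population.  In practice registry extracts omit zero-death rows
        but always carry population; with this flag missing cells take
        deaths = 0 and population must come from a matching row, else the
        load fails.
    """
    df = _read_table(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    bad = df[(df["deaths"] < 0) | ~(df["population"] > 0)]
    if not bad.empty:
        raise DataValidationError(
            "rows with negative deaths or nonpositive population:\n"
            + bad.head(10).to_string(index=False)
        )
    keys = ["gender", "area", "age_group", "year"]
    dup = df[df.duplicated(keys, keep=False)]
    if not dup.empty:
        raise DataValidationError(
            "duplicate (gender, area, age_group, year) cells:\n"
            + dup.head(10).to_string(index=False)
        )

    genders = sorted(df["gender"].astype(str).unique())
    areas = sorted(df["area"].astype(str).unique())
    age_groups = sorted(df["age_group"].astype(str).unique(), key=_age_lower_bound)
    years = sorted(df["year"].unique())
    dims = StudyDimensions(G=len(genders), A=len(areas), I=len(age_groups), T=len(years))

    gi = {v: j for j, v in enumerate(genders)}
    ai = {v: j for j, v in enumerate(areas)}
    ii = {v: j for j, v in enumerate(age_groups)}
    ti = {v: j for j, v in enumerate(years)}

    deaths = np.full(dims.shape, -1.0)
    pop = np.full(dims.shape, np.nan)
    for row in df.itertuples(index=False):
        c = (gi[str(row.gender)], ai[str(row.area)], ii[str(row.age_group)], ti[row.year])
        deaths[c] = row.deaths
        pop[c] = row.population

    holes = np.argwhere(deaths < 0)
    if holes.size:
        if not fill_zero_deaths:
            g, a, i, t = holes[0]
            raise DataValidationError(
                f"incomplete grid: missing cell (gender={genders[g]}, "
                f"area={areas[a]}, age_group={age_groups[i]}, year={years[t]}) "
                f"and {len(holes) - 1} more; pass fill_zero_deaths=True only if "
                "absent rows mean zero deaths"
            )
        for g, a, i, t in holes:
            deaths[g, a, i, t] = 0.0
        # population is never imputed: any cell still lacking person-years fails
        if np.isnan(pop).any():
            g, a, i, t = np.argwhere(np.isnan(pop))[0]
            raise DataValidationError(
                f"cell (gender={genders[g]}, area={areas[a]}, "
                f"age_group={age_groups[i]}, year={years[t]}) has no population "
                "row; person-years cannot be filled"
            )

    return MortalityDataset(
        dims=dims,
        deaths=deaths.astype(np.int64),
        population=pop,
        genders=[str(g) for g in genders],
        areas=[str(a) for a in areas],
        age_groups=[str(i) for i in age_groups],
        years=[int(y) for y in years],
    )


def write_counts(dataset: MortalityDataset, path, sep: str = ",") -> None:
    """Write the long-format count table (inverse of :func:`load_counts`)."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def load_graph(path, n_nodes: int | None = None) -> AdjacencyGraph:
    """Read an adjacency graph in edge-list or region-neighbour dialect.

    Edge list (``.edges``): one ``u v`` pair per line, 1-based or arbitrary
    string identifiers.  Region file (``.graph``): first line the node
    count, then one line per region ``region n_neighbours neighbour...``
    with 1-based integer ids.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GraphError(f"empty graph file {path}")

    first = lines[0].split()
    if len(first) == 1:
        return _parse_region_lines(lines)
    return _parse_edge_lines(lines, n_nodes)


def _parse_edge_lines(lines: list[str], n_nodes: int | None) -> AdjacencyGraph:
    raw_edges: list[tuple[str, str]] = []
    for ln in lines:
        parts = ln.split()
        if len(parts) != 2:
            raise GraphError(f"malformed edge line {ln!r}")
        raw_edges.append((parts[0], parts[1]))
    ids = {u for e in raw_edges for u in e}
    all_int = all(re.fullmatch(r"\d+", u) for u in ids)
    if all_int:
        count = n_nodes if n_nodes is not None else max(int(u) for u in ids)
        labels = [str(j + 1) for j in range(count)]
        index = {str(j + 1): j for j in range(count)}
    else:
        labels = sorted(ids)
        if n_nodes is not None and n_nodes != len(labels):
            raise GraphError(
                f"declared n_nodes={n_nodes} but {len(labels)} labelled nodes found"
            )
        index = {lab: j for j, lab in enumerate(labels)}
    edges = []
    for u, v in raw_edges:
        if u not in index or v not in index:
            raise GraphError(f"edge ({u},{v}) references an unknown node id")
        edges.append((index[u], index[v]))
    return AdjacencyGraph(n_nodes=len(labels), edges=edges, node_labels=labels)


def _parse_region_lines(lines: list[str]) -> AdjacencyGraph:
    n = int(lines[0])
    if len(lines) - 1 != n:
        raise GraphError(f"region file declares {n} regions but lists {len(lines) - 1}")
    edges: list[tuple[int, int]] = []
    for ln in lines[1:]:
        parts = [int(x) for x in ln.split()]
        region, n_nb, nbs = parts[0], parts[1], parts[2:]
        if len(nbs) != n_nb:
            raise GraphError(f"region {region} declares {n_nb} neighbours, lists {len(nbs)}")
        if not (1 <= region <= n):
            raise GraphError(f"region id {region} out of range 1..{n}")
        for v in nbs:
            if not (1 <= v <= n):
                raise GraphError(f"neighbour id {v} of region {region} out of range 1..{n}")
            edges.append((region - 1, v - 1))
    return AdjacencyGraph(n_nodes=n, edges=edges)


def write_graph(graph: AdjacencyGraph, path) -> None:
    """Write the edge-list dialect (1-based integer ids)."""
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u + 1} {v + 1}\n")


def load_standard_population(path) -> StandardPopulation:
    """Two-column delimited text: age_group, weight."""
    df = _read_table(path)
    cols = list(df.columns)
    if "age_group" not in cols or "weight" not in cols:
        raise SchemaError(f"standard population file needs columns age_group, weight; got {cols}")
    return StandardPopulation(
        age_groups=[str(x) for x in df["age_group"]],
        weights=df["weight"].to_numpy(float),
    )


def _packaged(name: str) -> io.StringIO:
    text = resources.files("gapc.data").joinpath(name).read_text()
    return io.StringIO(text)


def table1_fixture() -> MortalityDataset:
    """National Spain 1990-2013 aggregate: 13 age groups x 2 genders.

    Deaths from pancreatic cancer (ICD-9 157 / ICD-10 C25) and aggregate
    person-years over the whole 24-year window, as published by the Spanish
    National Statistical Institute.  Periods are collapsed to a single
    totals column (T = 1), areas to the national level (A = 1).
    """
    df = pd.read_csv(_packaged("table1.csv"))
    I = len(df)
    dims = StudyDimensions(G=2, A=1, I=I, T=1)
    deaths = np.zeros(dims.shape, dtype=np.int64)
    pop = np.zeros(dims.shape)
    deaths[0, 0, :, 0] = df["female_cases"]
    deaths[1, 0, :, 0] = df["male_cases"]
    pop[0, 0, :, 0] = df["female_population"]
    pop[1, 0, :, 0] = df["male_population"]
    return MortalityDataset(
        dims=dims,
        deaths=deaths,
        population=pop,
        genders=["female", "male"],
        areas=["Spain"],
        age_groups=list(df["age_group"]),
        years=[1990],
    )


def esp2013_standard() -> StandardPopulation:
    """Revised European Standard Population 2013, truncated to ages 25+.

    The open-ended [85,+) group carries the sum of the ESP 85-89 and 90+
    weights.  Weights are renormalized over these 13 groups when used, so
    standardized rates are per 100,000 aged-25+ standard population.
    """
    df = pd.read_csv(_packaged("esp2013.csv"))
    return StandardPopulation(
        age_groups=list(df["age_group"]), weights=df["weight"].to_numpy(float)
    )
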