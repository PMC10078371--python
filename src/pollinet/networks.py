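"""Weekly, annual, combined and metaweb bipartite networks.

A :class:`BipartiteNetwork` is a plants x insects weighted incidence matrix
for one focal period. Visit weights are the number of observed visit events;
pollen-transport evidence adds at most one unit per link per period (an
insect carrying a plant's pollen must have visited it at least once, but the
load says nothing about how many times). The metaweb counts, for each link,
the number of weekly networks in which it appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import TaxonomyMap

__all__ = [
    "BipartiteNetwork",
    "NetworkSeries",
    "EmptyPeriodError",
    "build_network",
    "build_weekly_series",
    "merge_pollen_links",
    "aggregate_plants_to_genus",
    "sum_networks",
    "build_metaweb",
    "pollen_transport_network",
    "to_edgelist",
    "from_edgelist",
    "write_edgelist",
    "read_edgelist",
    "write_matrix",
    "read_matrix",
]


class EmptyPeriodError(ValueError):
    """No records fall in the requested period (caller may skip the week)."""


@dataclass
class BipartiteNetwork:
    plants: list[str]
    insects: list[str]
    weights: np.ndarray  # plants x insects, non-negative
    period: str = ""
    provenance: str = "visitation"  # visitation | pollen | combined

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.plants), len(self.insects)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match species lists "
                f"({len(self.plants)} plants, {len(self.insects)} insects)"
            )
        if len(set(self.plants)) != len(self.plants) or len(set(self.insects)) != len(
            self.insects
        ):
            raise ValueError("species lists contain duplicates")
        if (self.weights < 0).any():
            raise ValueError("negative interaction weights")

    # -- basic views --------------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_insects(self) -> int:
        return len(self.insects)

    @property
    def n_links(self) -> int:
        return int((self.weights > 0).sum())

    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    def weight_of(self, plant: str, insect: str) -> float:
        return float(self.weights[self.plants.index(plant), self.insects.index(insect)])

    def link_set(self) -> set[tuple[str, str]]:
        p, i = np.nonzero(self.weights > 0)
        return {(self.plants[a], self.insects[b]) for a, b in zip(p, i)}

    def pruned(self) -> "BipartiteNetwork":
        """Drop species with no links (every listed species must interact)."""
        rows = np.flatnonzero(self.weights.sum(axis=1) > 0)
        cols = np.flatnonzero(self.weights.sum(axis=0) > 0)
        return replace(
            self,
            plants=[self.plants[r] for r in rows],
            insects=[self.insects[c] for c in cols],
            weights=self.weights[np.ix_(rows, cols)],
        )

    def is_pruned(self) -> bool:
        return bool(
            (self.weights.sum(axis=1) > 0).all() and (self.weights.sum(axis=0) > 0).all()
        )


@dataclass
class NetworkSeries:
    """Chronologically ordered weekly networks keyed by (year, week)."""

    networks: dict[tuple[int, int], BipartiteNetwork] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.networks = dict(sorted(self.networks.items()))

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(sorted(self.networks.items()))

    def __getitem__(self, key: tuple[int, int]) -> BipartiteNetwork:
        return self.networks[key]

    def __contains__(self, key) -> bool:
        return key in self.networks

    def add(self, year: int, week: int, net: BipartiteNetwork) -> None:
        if (year, week) in self.networks:
            raise KeyError(f"duplicate period key {(year, week)}")
        self.networks[(year, week)] = net
        self.networks = dict(sorted(self.networks.items()))

    def years(self) -> list[int]:
        return sorted({y for y, _ in self.networks})

    def for_year(self, year: int) -> "NetworkSeries":
        return NetworkSeries({k: v for k, v in self.networks.items() if k[0] == year})


# ---------------------------------------------------------------------------
# construction

def build_network(
    records: pd.DataFrame,
    year: int | None = None,
    week: int | None = None,
    provenance: str = "visitation",
    period: str | None = None,
) -> BipartiteNetwork:
    """Aggregate interaction records of one focal period into a network.

    ``weight(p, i)`` is the summed visit count for the pair within the
    period; species never observed interacting in the period are absent
    (phenologically forbidden links are excluded from the species pool).
    """
    sel = records
    if year is not None:
        sel = sel[sel["year"] == year]
    if week is not None:
        sel = sel[sel["week"] == week]
    if sel.empty:
        raise EmptyPeriodError(f"no records for year={year} week={week}")
    tab = sel.pivot_table(
        index="plant_taxon", columns="insect_taxon", values="count", aggfunc="sum", fill_value=0
    )
    if period is None:
        period = f"{year if year is not None else 'all'}" + (
            f"-w{week}" if week is not None else ""
        )
    net = BipartiteNetwork(
        plants=list(tab.index),
        insects=list(tab.columns),
        weights=tab.to_numpy(dtype=float),
        period=period,
        provenance=provenance,
    )
    return net.pruned()


def build_weekly_series(records: pd.DataFrame, provenance: str = "visitation") -> NetworkSeries:
    """One network per (year, week) having at least one record."""
    series = NetworkSeries()
    for (year, week), _ in records.groupby(["year", "week"], sort=True):
        series.add(
            int(year),
            int(week),
            build_network(records, year=int(year), week=int(week), provenance=provenance),
        )
    return series


def merge_pollen_links(
    visit_net: BipartiteNetwork,
    pollen: pd.DataFrame,
    year: int | None = None,
    week: int | None = None,
    genus_map: TaxonomyMap | None = None,
) -> BipartiteNetwork:
    """Add pollen-transport evidence to a visitation network (+1 per link).

    Each distinct (insect, plant genus) pair carried by at least one captured
    individual with grains > 0 in the period increments the link weight by
    exactly one, regardless of how many individuals carried it or how many
    grains; pairs unseen in the visit data are appended. Pollen links are
    dated by capture week, so ``pollen`` must already carry year/week columns
    (see :func:`pollinet.records.pollen_assign_weeks`).
    """
    sel = pollen[pollen["grains"] > 0]
    if year is not None:
        sel = sel[sel["year"] == year]
    if week is not None:
        sel = sel[sel["week"] == week]
    pairs = sel[["insect", "plant_genus"]].drop_duplicates()
    plants = list(visit_net.plants)
    insects = list(visit_net.insects)
    p_idx = {p: k for k, p in enumerate(plants)}
    i_idx = {i: k for k, i in enumerate(insects)}
    increments: list[tuple[str, str]] = []
    for insect, genus in pairs.itertuples(index=False):
        plant = genus_map.canonical(genus) if genus_map is not None else genus
        increments.append((plant, insect))
        if plant not in p_idx:
            p_idx[plant] = len(plants)
            plants.append(plant)
        if insect not in i_idx:
            i_idx[insect] = len(insects)
            insects.append(insect)
    weights = np.zeros((len(plants), len(insects)))
    weights[: visit_net.n_plants, : visit_net.n_insects] = visit_net.weights
    for plant, insect in increments:
        weights[p_idx[plant], i_idx[insect]] += 1.0
    return BipartiteNetwork(
        plants=plants,
        insects=insects,
        weights=weights,
        period=visit_net.period,
        provenance="combined",
    )


def aggregate_plants_to_genus(net: BipartiteNetwork, taxmap: TaxonomyMap) -> BipartiteNetwork:
    """Collapse plant rows to genus level (pollen loads are genus-resolved,
    so combined networks are reconciled on the plant side at genus rank)."""
    genera: list[str] = []
    idx: dict[str, int] = {}
    rows = []
    for p in net.plants:
        g = taxmap.genus_of(p)
        if g not in idx:
            idx[g] = len(genera)
            genera.append(g)
        rows.append(idx[g])
    weights = np.zeros((len(genera), net.n_insects))
    for r_old, r_new in enumerate(rows):
        weights[r_new] += net.weights[r_old]
    return BipartiteNetwork(
        plants=genera,
        insects=list(net.insects),
        weights=weights,
        period=net.period,
        provenance=net.provenance,
    )


def sum_networks(
    nets: list[BipartiteNetwork], period: str, provenance: str | None = None
) -> BipartiteNetwork:
    """Sum link weights across networks (e.g. weekly -> annual)."""
    if not nets:
        raise EmptyPeriodError("no networks to sum")
    plants = sorted({p for n in nets for p in n.plants})
    insects = sorted({i for n in nets for i in n.insects})
    p_idx = {p: k for k, p in enumerate(plants)}
    i_idx = {i: k for k, i in enumerate(insects)}
    weights = np.zeros((len(plants), len(insects)))
    for n in nets:
        rows = [p_idx[p] for p in n.plants]
        cols = [i_idx[i] for i in n.insects]
        weights[np.ix_(rows, cols)] += n.weights
    return BipartiteNetwork(
        plants=plants,
        insects=insects,
        weights=weights,
        period=period,
        provenance=provenance or nets[0].provenance,
    )


def build_metaweb(series: NetworkSeries, period: str = "metaweb") -> BipartiteNetwork:
    """Union of all weekly networks; weight = number of weekly networks in
    which the link appears (its temporal frequency)."""
    if len(series) == 0:
        raise EmptyPeriodError("empty network series")
    nets = [net for _, net in series]
    plants = sorted({p for n in nets for p in n.plants})
    insects = sorted({i for n in nets for i in n.insects})
    p_idx = {p: k for k, p in enumerate(plants)}
    i_idx = {i: k for k, i in enumerate(insects)}
    weights = np.zeros((len(plants), len(insects)))
    for n in nets:
        rows = [p_idx[p] for p in n.plants]
        cols = [i_idx[i] for i in n.insects]
        weights[np.ix_(rows, cols)] += (n.weights > 0).astype(float)
    return BipartiteNetwork(
        plants=plants,
        insects=insects,
        weights=weights,
        period=period,
        provenance=nets[0].provenance,
    )


def pollen_transport_network(
    pollen: pd.DataFrame,
    year: int | None = None,
    week: int | None = None,
    period: str | None = None,
) -> BipartiteNetwork:
    """Pollen-transport web: weight = number of individuals of the insect
    taxon carrying the plant genus's pollen in the period (analysed with
    binary metrics only; the count is kept for bookkeeping)."""
    sel = pollen[pollen["grains"] > 0]
    if year is not None:
        sel = sel[sel["year"] == year]
    if week is not None:
        sel = sel[sel["week"] == week]
    if sel.empty:
        raise EmptyPeriodError(f"no pollen records for year={year} week={week}")
    tab = sel.pivot_table(
        index="plant_genus", columns="insect", values="individual", aggfunc="nunique", fill_value=0
    )
    if period is None:
        period = f"{year if year is not None else 'all'}" + (
            f"-w{week}" if week is not None else ""
        )
    net = BipartiteNetwork(
        plants=list(tab.index),
        insects=list(tab.columns),
        weights=tab.to_numpy(dtype=float),
        period=period,
        provenance="pollen",
    )
    return net.pruned()


# ---------------------------------------------------------------------------
# lossless text export

def to_edgelist(net: BipartiteNetwork) -> pd.DataFrame:
    p, i = np.nonzero(net.weights > 0)
    return pd.DataFrame(
        {
            "plant": [net.plants[a] for a in p],
            "insect": [net.insects[b] for b in i],
            "weight": net.weights[p, i],
        }
    )


def from_edgelist(
    edges: pd.DataFrame, period: str = "", provenance: str = "visitation"
) -> BipartiteNetwork:
    plants = sorted(edges["plant"].unique())
    insects = sorted(edges["insect"].unique())
    weights = np.zeros((len(plants), len(insects)))
    p_idx = {p: k for k, p in enumerate(plants)}
    i_idx = {i: k for k, i in enumerate(insects)}
    for plant, insect, w in edges.itertuples(index=False):
        weights[p_idx[plant], i_idx[insect]] = w
    return BipartiteNetwork(plants, insects, weights, period=period, provenance=provenance)


def write_edgelist(net: BipartiteNetwork, path, delimiter: str = ",") -> None:
    to_edgelist(net).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_edgelist(path, period: str = "", provenance: str = "visitation") -> BipartiteNetwork:
    edges = pd.read_csv(path)
    return from_edgelist(edges, period=period, provenance=provenance)


def write_matrix(net: BipartiteNetwork, path, delimiter: str = ",") -> None:
    pd.DataFrame(net.weights, index=net.plants, columns=net.insects).to_csv(
        path, sep=delimiter, float_format="%.17g"
    )


def read_matrix(path, period: str = "", provenance: str = "visitation") -> BipartiteNetwork:
    df = pd.read_csv(path, index_col=0)
    return BipartiteNetwork(
        plants=list(df.index),
        insects=list(df.columns),
        weights=df.to_numpy(dtype=float),
        period=period,
        provenance=provenance,
    )
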