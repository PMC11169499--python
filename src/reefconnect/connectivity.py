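"""Connectivity matrices and source/sink network analysis.

The connectivity (transfer-probability) matrix for one spawning night has
one row per source site and one column per sink site; entry M[i, j] is
the proportion of the larvae released at site i that settled at site j.
Row sums are therefore at most 1 (a site cannot export more larvae than
it released) while column sums may exceed 1 (a site can receive from many
sources).  From per-night matrices the analysis derives:

* the percentage of released larvae that settled and the percentage of
  sites acting as sinks (settling sites), per night and velocity mode;
* link counts, where a link is any strictly positive entry, the diagonal
  (self-recruitment) included;
* per-site source strength (row sum) and sink strength (column sum);
* consistency classification: a site is a consistent source (sink) if its
  source (sink) strength is positive on every analysed spawning night;
* pairwise comparisons of 2-D versus 3-D velocity scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ConnectivityMatrix:
    """Per-night site-by-site settlement proportions."""

    night_id: str
    sites: list[str]
    released: np.ndarray  # per source site
    matrix: np.ndarray  # (n_sites, n_sites)

    def __post_init__(self) -> None:
        n = len(self.sites)
        self.released = np.asarray(self.released, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (n, n) or self.released.shape != (n,):
            raise ValueError("matrix must be n_sites x n_sites, released length n_sites")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("entries must be proportions in [0, 1]")
        rows = self.matrix.sum(axis=1)
        if np.any(rows > 1 + 1e-9):
            raise ValueError("row sums must not exceed 1")

    @property
    def row_sums(self) -> np.ndarray:
        """Source strength: proportion of each site's larvae that settled."""
        return self.matrix.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """Sink strength: summed settling fractions received by each site."""
        return self.matrix.sum(axis=0)

    @property
    def self_recruitment(self) -> np.ndarray:
        return np.diag(self.matrix)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sites, columns=self.sites)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.insert(0, "released", self.released)
        df.to_csv(path, index_label="site_id")

    @classmethod
    def from_csv(cls, path: str | Path, night_id: str = "") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col="site_id")
        released = df.pop("released").to_numpy()
        return cls(
            night_id=night_id,
            sites=[str(s) for s in df.index],
            released=released,
            matrix=df.to_numpy(),
        )


def build_matrix(
    records: pd.DataFrame,
    released: Mapping[str, int],
    site_order: Sequence[str],
    night_id: str = "",
) -> ConnectivityMatrix:
    """Connectivity matrix from settlement records and release counts.

    ``records`` needs columns source_site and sink_site (one row per
    settled larva).  Sites without settlers give all-zero rows.
    """
    sites = list(site_order)
    pos = {s: k for k, s in enumerate(sites)}
    rel = np.array([float(released[s]) for s in sites])
    if np.any(rel <= 0):
        raise ValueError("every site needs a positive release count")
    counts = np.zeros((len(sites), len(sites)))
    for src, snk in zip(records["source_site"], records["sink_site"]):
        if src not in pos or snk not in pos:
            raise ValueError(f"settlement record references unknown site {src}->{snk}")
        counts[pos[src], pos[snk]] += 1
    return ConnectivityMatrix(
        night_id=night_id, sites=sites, released=rel, matrix=counts / rel[:, None]
    )


def pct_settled(matrix: ConnectivityMatrix) -> float:
    """Percentage of all released larvae that settled anywhere."""
    total_released = matrix.released.sum()
    if total_released <= 0:
        raise ValueError("no larvae released")
    settled = (matrix.matrix * matrix.released[:, None]).sum()
    return 100.0 * settled / total_released


def pct_sink_sites(matrix: ConnectivityMatrix) -> float:
    """Percentage of sites that received at least one settler."""
    return 100.0 * float((matrix.col_sums > 0).sum()) / len(matrix.sites)


def count_links(matrix: ConnectivityMatrix) -> int:
    """Number of strictly positive entries; self-loops count as links."""
    return int((matrix.matrix > 0).sum())


@dataclass
class ScenarioComparisonEntry:
    night_id: str
    reference_mode: str
    alternative_mode: str
    pct_more_links: float | None
    pct_more_sinks: float | None


def compare_dimensions(
    reference: ConnectivityMatrix, alternative: ConnectivityMatrix
) -> ScenarioComparisonEntry:
    """Relative link/sink surplus of one velocity scenario over another.

    Typically ``reference`` is a 2-D matrix and ``alternative`` the 3-D
    one; a positive percentage means the alternative has more.  When the
    reference count is zero the comparison is undefined (None).
    """
    if reference.sites != alternative.sites:
        raise ValueError("matrices must share the same site set and order")
    links_ref, links_alt = count_links(reference), count_links(alternative)
    sinks_ref = int((reference.col_sums > 0).sum())
    sinks_alt = int((alternative.col_sums > 0).sum())
    more_links = 100.0 * (links_alt - links_ref) / links_ref if links_ref else None
    more_sinks = 100.0 * (sinks_alt - sinks_ref) / sinks_ref if sinks_ref else None
    return ScenarioComparisonEntry(
        night_id=reference.night_id,
        reference_mode="reference",
        alternative_mode="alternative",
        pct_more_links=more_links,
        pct_more_sinks=more_sinks,
    )


def source_sink_summary(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Per-site source strength, sink strength and self-recruitment."""
    return pd.DataFrame(
        {
            "site_id": matrix.sites,
            "source_strength": matrix.row_sums,
            "sink_strength": matrix.col_sums,
            "self_recruitment": matrix.self_recruitment,
        }
    )


def consistency(matrices: Sequence[ConnectivityMatrix]) -> pd.DataFrame:
    """Nights-as-source/sink counts and consistency flags per site.

    A consistent source (sink) exports (receives) larvae on every night
    analysed.
    """
    if not matrices:
        raise ValueError("need at least one nightly matrix")
    sites = matrices[0].sites
    for m in matrices[1:]:
        if m.sites != sites:
            raise ValueError("all matrices must share the same site set and order")
    n_nights = len(matrices)
    src_nights = np.sum([m.row_sums > 0 for m in matrices], axis=0)
    snk_nights = np.sum([m.col_sums > 0 for m in matrices], axis=0)
    return pd.DataFrame(
        {
            "site_id": sites,
            "nights_as_source": src_nights.astype(int),
            "nights_as_sink": snk_nights.astype(int),
            "consistent_source": src_nights == n_nights,
            "consistent_sink": snk_nights == n_nights,
        }
    )


def scenario_table(
    matrices: Mapping[tuple[str, str], ConnectivityMatrix]
) -> pd.DataFrame:
    """Summary metrics per (mode, night): settled %, sink-site %, links.

    Percentages are rounded to two decimals in the output table.
    """
    rows = []
    for (mode, night), m in sorted(matrices.items()):
        rows.append(
            (
                mode,
                night,
                round(pct_settled(m), 2),
                round(pct_sink_sites(m), 2),
                count_links(m),
            )
        )
    return pd.DataFrame(
        rows, columns=["mode", "night_id", "pct_settled", "pct_sink_sites", "n_links"]
    )


def export_network(
    matrix: ConnectivityMatrix,
    centroids: Mapping[str, tuple[float, float]],
) -> nx.DiGraph:
    """Directed larval-exchange network with site centroids on the nodes.

    One weighted edge per positive matrix entry (self-loops included).
    """
    g = nx.DiGraph(night_id=matrix.night_id)
    for s in matrix.sites:
        cx, cy = centroids[s]
        g.add_node(s, x=float(cx), y=float(cy))
    n = len(matrix.sites)
    for i in range(n):
        for j in range(n):
            if matrix.matrix[i, j] > 0:
                g.add_edge(
                    matrix.sites[i], matrix.sites[j], weight=float(matrix.matrix[i, j])
                )
    return g


def network_to_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def edge_list(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Edge-list form of the matrix (positive entries only)."""
    rows = []
    for i, src in enumerate(matrix.sites):
        for j, snk in enumerate(matrix.sites):
            if matrix.matrix[i, j] > 0:
                rows.append((src, snk, matrix.matrix[i, j]))
    return pd.DataFrame(rows, columns=["source_site", "sink_site", "proportion"])


def matrix_from_edge_list(
    edges: pd.DataFrame,
    released: Mapping[str, int],
    site_order: Sequence[str],
    night_id: str = "",
) -> ConnectivityMatrix:
    """Inverse of :func:`edge_list` given the release counts."""
    sites = list(site_order)
    pos = {s: k for k, s in enumerate(sites)}
    m = np.zeros((len(sites), len(sites)))
    for _, row in edges.iterrows():
        m[pos[row["source_site"]], pos[row["sink_site"]]] = row["proportion"]
    rel = np.array([float(released[s]) for s in sites])
    return ConnectivityMatrix(night_id=night_id, sites=sites, released=rel, matrix=m)
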