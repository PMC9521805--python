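"""Domain types, file I/O and network-derived generalism metrics.

The central objects are :class:`PairedSample` (two paired species-level
measurements, e.g. generalism and abundance), :class:`BipartiteNetwork`
(a binary interaction matrix between two guilds, from which degree and
normalized degree are computed) and :class:`CommunityDataset` (a network
plus per-guild abundance tables and external covariates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

Direction = Literal["x_causes_y", "y_causes_x", "inconclusive"]

#: default column mapping for species tables
DEFAULT_COLUMN_MAP = {"id": "species", "x": "generalism", "y": "abundance"}


@dataclass
class PairedSample:
    """Two equal-length numeric vectors with species identifiers.

    ``x`` is the putative cause (generalism by convention) and ``y`` the
    putative effect (abundance). Both must be finite, of length >= 3 and
    contain at least two distinct values each.
    """

    ids: list
    x: np.ndarray
    y: np.ndarray
    x_name: str = "generalism"
    y_name: str = "abundance"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if not (len(self.x) == len(self.y) == n):
            raise DataError("ids, x and y must have equal length")
        if n < 3:
            raise DataError(f"need at least 3 species, got {n}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise DataError("x and y must be finite")
        if np.unique(self.x).size < 2 or np.unique(self.y).size < 2:
            raise DataError("x and y must each contain at least 2 distinct values")

    def __len__(self) -> int:
        return len(self.ids)

    def swapped(self) -> "PairedSample":
        """The same data with the roles of x and y exchanged."""
        return PairedSample(self.ids, self.y.copy(), self.x.copy(),
                            x_name=self.y_name, y_name=self.x_name)


@dataclass
class BipartiteNetwork:
    """Binary interaction matrix between two guilds (rows x cols)."""

    row_labels: list
    col_labels: list
    adjacency: np.ndarray

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.ndim != 2:
            raise DataError("adjacency must be a 2-d matrix")
        if self.adjacency.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("adjacency shape does not match label lists")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise DataError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise DataError("duplicate column labels")
        vals = np.unique(self.adjacency)
        if not np.isin(vals, [0, 1]).all():
            raise DataError("adjacency entries must be 0/1 (binarize counts first)")
        self.adjacency = self.adjacency.astype(np.int8)
        if self.adjacency.sum() == 0:
            raise DataError("all-zero interaction matrix")


@dataclass
class CommunityDataset:
    """A local community: optional network, per-guild abundances, covariates."""

    network: BipartiteNetwork | None
    abundance: dict  # {"rows": {species: value}, "cols": {...}}
    metadata: dict = field(default_factory=dict)

    def covariate(self, name: str) -> float:
        return float(self.metadata.get("covariates", {})[name])


@dataclass
class CausalVerdict:
    """Unified output of every discovery method."""

    method: str
    direction: Direction
    statistics: dict
    p_values: dict = field(default_factory=dict)
    diagnostics: str = ""


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_species_table(path, column_map: Mapping[str, str] | None = None) -> PairedSample:
    """Read a species-level CSV/TSV into a :class:`PairedSample`.

    ``column_map`` maps the roles ``id``, ``x``, ``y`` to the column names
    present in the file. Rows with missing values in any mapped column are
    dropped (and logged); row order is preserved otherwise.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    missing = [c for c in (cmap["id"], cmap["x"], cmap["y"]) if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"columns {missing} not found in {path}; available: {list(df.columns)}")
    sub = df[[cmap["id"], cmap["x"], cmap["y"]]].copy()
    sub.columns = ["id", "x", "y"]
    sub["x"] = pd.to_numeric(sub["x"], errors="coerce")
    sub["y"] = pd.to_numeric(sub["y"], errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("dropped %d incomplete rows while reading %s", n_dropped, path)
    if len(complete) < 3:
        raise DataError(f"fewer than 3 complete rows in {path}")
    return PairedSample(complete["id"].tolist(),
                        complete["x"].to_numpy(), complete["y"].to_numpy(),
                        x_name=cmap["x"], y_name=cmap["y"])


def read_bipartite_network(path, format: str = "adjacency") -> BipartiteNetwork:
    """Read a bipartite network from an adjacency CSV or 2-column edge list TSV.

    Visitation counts are binarized at > 0; duplicate edges collapse.
    """
    path = Path(path)
    if format == "adjacency":
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",",
                         index_col=0)
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise DataError(f"non-numeric adjacency cell in {path}: {exc}") from exc
        if not np.isfinite(mat).all():
            raise DataError(f"non-numeric adjacency cell in {path}")
        return BipartiteNetwork(list(df.index.astype(str)),
                                list(df.columns.astype(str)),
                                (mat > 0).astype(np.int8))
    if format == "edge_list":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise DataError(f"empty edge list in {path}") from exc
        df = df.dropna()
        if df.empty:
            raise DataError(f"empty edge list in {path}")
        if df.shape[1] < 2:
            raise DataError("edge list must have two columns")
        rows = list(dict.fromkeys(df[0].astype(str)))
        cols = list(dict.fromkeys(df[1].astype(str)))
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: i for i, c in enumerate(cols)}
        adj = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for a, b in zip(df[0].astype(str), df[1].astype(str)):
            adj[ri[a], ci[b]] = 1
        return BipartiteNetwork(rows, cols, adj)
    raise ConfigurationError(f"unknown network format {format!r}")


def write_bipartite_network(network: BipartiteNetwork, path, format: str = "adjacency") -> None:
    """Write a network back to disk (round-trips with :func:`read_bipartite_network`)."""
    path = Path(path)
    if format == "adjacency":
        df = pd.DataFrame(network.adjacency, index=network.row_labels,
                          columns=network.col_labels)
        df.to_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
    elif format == "edge_list":
        r, c = np.nonzero(network.adjacency)
        with open(path, "w") as fh:
            for i, j in zip(r, c):
                fh.write(f"{network.row_labels[i]}\t{network.col_labels[j]}\n")
    else:
        raise ConfigurationError(f"unknown network format {format!r}")


def write_species_table(sample: PairedSample, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"species": sample.ids, sample.x_name: sample.x,
                       sample.y_name: sample.y})
    df.to_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",", index=False)


# ---------------------------------------------------------------------------
# generalism metrics


def degree(network: BipartiteNetwork, side: str = "rows") -> pd.Series:
    """Number of interacting partners per species on the given side."""
    if side == "rows":
        vals = network.adjacency.sum(axis=1)
        labels = network.row_labels
    elif side == "cols":
        vals = network.adjacency.sum(axis=0)
        labels = network.col_labels
    else:
        raise ConfigurationError("side must be 'rows' or 'cols'")
    s = pd.Series(np.asarray(vals, dtype=int), index=labels, name="degree")
    n_zero = int((s == 0).sum())
    if n_zero:
        logger.warning("%d species with zero degree on side %r "
                       "(excluded from causal analyses downstream)", n_zero, side)
    return s


def normalized_degree(network: BipartiteNetwork, side: str = "rows") -> pd.Series:
    """Degree divided by the number of locally available partners."""
    deg = degree(network, side)
    opposite = len(network.col_labels) if side == "rows" else len(network.row_labels)
    out = deg / float(opposite)
    out.name = "normalized_degree"
    return out


def paired_sample_from_community(dataset: CommunityDataset, guild: str = "rows",
                                 metric: str = "degree") -> PairedSample:
    """Build (generalism, abundance) pairs for one guild of a community.

    Species missing from either the network or the abundance table, and
    zero-degree species, are dropped with a log message.
    """
    if dataset.network is None:
        raise DataError("community has no interaction network")
    if metric == "degree":
        gen = degree(dataset.network, guild)
    elif metric == "normalized_degree":
        gen = normalized_degree(dataset.network, guild)
    else:
        raise ConfigurationError("metric must be 'degree' or 'normalized_degree'")
    abund = dataset.abundance.get(guild, {})
    ids, xs, ys = [], [], []
    n_skipped = 0
    for sp, g in gen.items():
        if g <= 0 or sp not in abund:
            n_skipped += 1
            continue
        ids.append(sp)
        xs.append(float(g))
        ys.append(float(abund[sp]))
    if n_skipped:
        logger.info("skipped %d species without usable (generalism, abundance) pairs",
                    n_skipped)
    if len(ids) < 3:
        raise DataError("fewer than 3 usable species in guild")
    return PairedSample(ids, np.array(xs), np.array(ys),
                        x_name=metric, y_name="abundance")
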