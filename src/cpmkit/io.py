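"""Core data containers and text I/O for connectomes, atlases, and behavior.

A *connectome* here is a per-subject symmetric parcel-by-parcel functional
connectivity (FC) matrix; modeling operates on its vectorized strict upper
triangle (the "edges"). A *network atlas* assigns every parcel to one of the
twelve canonical Gordon resting-state networks (or leaves it unassigned),
which defines the edge sets removed by virtual lesioning.

All file formats are delimited text:

* connectomes — either a directory of one P×P matrix file per subject
  (filename stem = subject id) or a single edge table (rows = subjects,
  columns headed ``i_j`` with 0-based parcel pairs, i < j);
* atlas — two columns, ``parcel_id`` and ``network_label``;
* behavior — a header row with a mandatory ``subject_id`` column, outcomes
  and covariates as named columns, missing values as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The twelve canonical Gordon-network labels used for lesioning.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "AUD", "CO", "CP", "DAN", "DMN", "FPN", "RSP", "SAL", "SM", "SML", "VAN", "VIS",
)

#: Label for parcels not assigned to any canonical network.
UNASSIGNED = "UNASSIGNED"

DEFAULT_SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """Raised when an input artifact violates its declared format."""


class JoinError(ValueError):
    """Raised when connectome and behavior subject ids do not align."""


# ---------------------------------------------------------------------------
# Edge vectorization
# ---------------------------------------------------------------------------

def n_edges(n_parcels: int) -> int:
    """Number of unordered parcel pairs, P(P-1)/2."""
    return n_parcels * (n_parcels - 1) // 2


def n_parcels_from_edges(n_edge: int) -> int:
    """Invert E = P(P-1)/2; raises if E is not a triangular number."""
    p = int(round((1 + np.sqrt(1 + 8 * n_edge)) / 2))
    if n_edges(p) != n_edge:
        raise FormatError(f"{n_edge} is not P(P-1)/2 for any integer P")
    return p


def edge_pairs(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Parcel index pairs (i, j), i < j, in row-major upper-triangle order.

    This is the edge-index bijection used everywhere in the package: edge
    ``e`` connects parcels ``edge_pairs(P)[0][e]`` and ``edge_pairs(P)[1][e]``.
    """
    return np.triu_indices(n_parcels, k=1)


def vectorize_upper(matrix: np.ndarray, tol: float = DEFAULT_SYMMETRY_TOL) -> np.ndarray:
    """Vectorize a symmetric matrix's strict upper triangle, row-major.

    The diagonal is ignored. Asymmetry beyond ``tol`` (absolute) is a
    :class:`FormatError` naming the worst offending entry.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError(f"expected a square matrix, got shape {matrix.shape}")
    asym = np.abs(matrix - matrix.T)
    if asym.size and asym.max() > tol:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise FormatError(
            f"matrix not symmetric within tol={tol:g}: "
            f"|M[{i},{j}] - M[{j},{i}]| = {asym[i, j]:g}"
        )
    iu, ju = edge_pairs(matrix.shape[0])
    return matrix[iu, ju].copy()


def devectorize(edges: np.ndarray, n_parcels: int | None = None) -> np.ndarray:
    """Rebuild a symmetric matrix (zero diagonal) from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    if n_parcels is None:
        n_parcels = n_parcels_from_edges(edges.size)
    elif edges.size != n_edges(n_parcels):
        raise FormatError(
            f"edge vector length {edges.size} != P(P-1)/2 = {n_edges(n_parcels)}"
        )
    out = np.zeros((n_parcels, n_parcels))
    iu, ju = edge_pairs(n_parcels)
    out[iu, ju] = edges
    out[ju, iu] = edges
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkAtlas:
    """Parcel → resting-state-network assignment.

    Parameters
    ----------
    labels
        One label per parcel (0-based parcel index = array position), each a
        canonical network name or :data:`UNASSIGNED`.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        allowed = set(CANONICAL_NETWORKS) | {UNASSIGNED}
        bad = sorted({str(x) for x in labels} - allowed)
        if bad:
            raise FormatError(f"unknown network label(s): {bad}")
        object.__setattr__(self, "labels", labels)

    @property
    def n_parcels(self) -> int:
        return self.labels.size

    def parcels_of(self, label: str) -> np.ndarray:
        """0-based indices of parcels carrying ``label``."""
        return np.flatnonzero(self.labels == label)

    def networks_present(self) -> list[str]:
        return [n for n in CANONICAL_NETWORKS if (self.labels == n).any()]


def edges_of_network(
    atlas: NetworkAtlas, label: str, within_only: bool = False
) -> np.ndarray:
    """Edge indices belonging to one network.

    By default uses the *incidence* rule: an edge belongs to network L if
    either endpoint parcel is labeled L, so removing these edges severs the
    network entirely. ``within_only=True`` restricts to edges with both
    endpoints in L.
    """
    if label not in CANONICAL_NETWORKS:
        raise ValueError(
            f"{label!r} is not one of the 12 lesionable networks "
            f"{CANONICAL_NETWORKS}"
        )
    member = atlas.labels == label
    if not member.any():
        raise ValueError(f"atlas has no parcel labeled {label!r}; cannot lesion it")
    iu, ju = edge_pairs(atlas.n_parcels)
    if within_only:
        mask = member[iu] & member[ju]
    else:
        mask = member[iu] | member[ju]
    return np.flatnonzero(mask)


@dataclass
class ConnectomeSet:
    """N subjects × E edges, vectorized from symmetric FC matrices."""

    subject_ids: list[str]
    edges: np.ndarray
    n_parcels: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != len(set(self.subject_ids)):
            dup = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise FormatError(f"duplicated subject id(s): {dup}")
        if self.edges.ndim != 2 or self.edges.shape[0] != len(self.subject_ids):
            raise FormatError(
                f"edges shape {self.edges.shape} does not match "
                f"{len(self.subject_ids)} subjects"
            )
        if self.edges.shape[1] != n_edges(self.n_parcels):
            raise FormatError(
                f"E={self.edges.shape[1]} != P(P-1)/2 for P={self.n_parcels}"
            )
        if not np.isfinite(self.edges).all():
            raise FormatError("connectome edges contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def matrix(self, subject: str | int) -> np.ndarray:
        """Recover one subject's full symmetric matrix (zero diagonal)."""
        idx = subject if isinstance(subject, int) else self.subject_ids.index(subject)
        return devectorize(self.edges[idx], self.n_parcels)


@dataclass
class BehavioralTable:
    """Outcome and covariate columns indexed by subject id."""

    data: pd.DataFrame
    outcomes: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise FormatError(f"duplicated subject id(s) in behavior table: {dup}")
        missing = [c for c in (*self.outcomes, *self.covariates) if c not in self.data]
        if missing:
            raise FormatError(f"behavior table lacks column(s): {missing}")

    def outcome(self, name: str, subjects: Sequence[str] | None = None) -> np.ndarray:
        """Outcome column as a float vector; missing values are an error."""
        col = self.data[name]
        if subjects is not None:
            col = col.loc[list(subjects)]
        vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = list(col.index[np.isnan(vals)])
            raise FormatError(f"outcome {name!r} missing/non-numeric for subjects {bad}")
        return vals

    def covariate(self, name: str, subjects: Sequence[str] | None = None) -> pd.Series:
        col = self.data[name]
        if subjects is not None:
            col = col.loc[list(subjects)]
        return col


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path, sep: str = "\t") -> NetworkAtlas:
    """Read a two-column (parcel_id, network_label) table.

    Parcel ids must be 0..P-1, each exactly once.
    """
    df = pd.read_csv(path, sep=sep)
    if not {"parcel_id", "network_label"} <= set(df.columns):
        raise FormatError(
            f"atlas file {path} must have columns parcel_id, network_label"
        )
    ids = df["parcel_id"].to_numpy(dtype=int)
    order = np.argsort(ids)
    ids = ids[order]
    if not np.array_equal(ids, np.arange(len(ids))):
        raise FormatError(f"atlas parcel ids must be 0..P-1 exactly once (file {path})")
    return NetworkAtlas(df["network_label"].to_numpy(dtype=object)[order])


def write_atlas(atlas: NetworkAtlas, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"parcel_id": np.arange(atlas.n_parcels), "network_label": atlas.labels}
    ).to_csv(path, sep=sep, index=False)


def read_behavior(
    path: str | Path,
    outcomes: Sequence[str] = (),
    covariates: Sequence[str] = (),
    sep: str = "\t",
) -> BehavioralTable:
    """Read a behavior/covariate table; ``NA`` is the missing-value token."""
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    if "subject_id" not in df.columns:
        raise FormatError(f"behavior file {path} lacks a subject_id column")
    df["subject_id"] = df["subject_id"].astype(str)
    df = df.set_index("subject_id")
    return BehavioralTable(df, tuple(outcomes), tuple(covariates))


def write_behavior(table: BehavioralTable, path: str | Path, sep: str = "\t") -> None:
    out = table.data.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def _read_matrix_dir(
    directory: Path, tol: float, sep: str
) -> tuple[list[str], np.ndarray, int]:
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix in {".tsv", ".csv", ".txt"}
    )
    if not files:
        raise FormatError(f"no matrix files (*.tsv/*.csv/*.txt) in {directory}")
    ids, rows, n_parcels = [], [], None
    for f in files:
        mat = pd.read_csv(f, sep=sep if f.suffix != ".csv" else ",", header=None).to_numpy(dtype=float)
        try:
            vec = vectorize_upper(mat, tol=tol)
        except FormatError as err:
            raise FormatError(f"{f.name}: {err}") from err
        if n_parcels is None:
            n_parcels = mat.shape[0]
        elif mat.shape[0] != n_parcels:
            raise FormatError(
                f"{f.name}: {mat.shape[0]} parcels, expected {n_parcels}"
            )
        ids.append(f.stem)
        rows.append(vec)
    return ids, np.vstack(rows), int(n_parcels)


def _read_edge_table(path: Path, sep: str) -> tuple[list[str], np.ndarray, int]:
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "subject_id":
        raise FormatError(f"edge table {path} must start with a subject_id column")
    pairs = []
    for col in df.columns[1:]:
        try:
            i, j = (int(x) for x in col.split("_"))
        except ValueError as err:
            raise FormatError(f"edge column {col!r} is not of the form 'i_j'") from err
        if i >= j:
            raise FormatError(f"edge column {col!r} must have i < j")
        pairs.append((i, j))
    p = max(j for _, j in pairs) + 1
    iu, ju = edge_pairs(p)
    expected = list(zip(iu.tolist(), ju.tolist()))
    if pairs != expected:
        raise FormatError(
            f"edge table {path} columns are not the full row-major upper "
            f"triangle for P={p}"
        )
    ids = df["subject_id"].astype(str).tolist()
    return ids, df.iloc[:, 1:].to_numpy(dtype=float), p


def read_connectomes(
    source: str | Path, tol: float = DEFAULT_SYMMETRY_TOL, sep: str = "\t"
) -> ConnectomeSet:
    """Read connectomes from a matrix directory or a single edge-table file."""
    source = Path(source)
    if source.is_dir():
        ids, edges, p = _read_matrix_dir(source, tol, sep)
    elif source.is_file():
        ids, edges, p = _read_edge_table(source, sep)
    else:
        raise FileNotFoundError(source)
    return ConnectomeSet(ids, edges, p)


def write_connectomes(
    conn: ConnectomeSet,
    target: str | Path,
    fmt: str = "matrices",
    sep: str = "\t",
    float_fmt: str = "%.10g",
) -> None:
    """Write connectomes as per-subject matrix files or one edge table."""
    target = Path(target)
    if fmt == "matrices":
        target.mkdir(parents=True, exist_ok=True)
        for k, sid in enumerate(conn.subject_ids):
            np.savetxt(
                target / f"{sid}.tsv",
                conn.matrix(k),
                delimiter=sep,
                fmt=float_fmt,
            )
    elif fmt == "edge_table":
        iu, ju = edge_pairs(conn.n_parcels)
        cols = [f"{i}_{j}" for i, j in zip(iu.tolist(), ju.tolist())]
        df = pd.DataFrame(conn.edges, columns=cols)
        df.insert(0, "subject_id", conn.subject_ids)
        df.to_csv(target, sep=sep, index=False, float_format=float_fmt)
    else:
        raise ValueError(f"unknown connectome format {fmt!r}")


def join_subjects(
    conn: ConnectomeSet, behavior: BehavioralTable
) -> tuple[ConnectomeSet, BehavioralTable]:
    """Align behavior rows to connectome subject order; mismatches are errors."""
    conn_ids = set(conn.subject_ids)
    behav_ids = set(behavior.data.index)
    only_conn = sorted(conn_ids - behav_ids)
    only_behav = sorted(behav_ids - conn_ids)
    if only_conn or only_behav:
        raise JoinError(
            "subject ids do not align: "
            f"in connectomes only {only_conn}; in behavior only {only_behav}"
        )
    aligned = BehavioralTable(
        behavior.data.loc[conn.subject_ids], behavior.outcomes, behavior.covariates
    )
    return conn, aligned


def read_inputs(
    connectome_source: str | Path,
    atlas_path: str | Path,
    behavior_path: str | Path,
    outcomes: Sequence[str] = (),
    covariates: Sequence[str] = (),
    tol: float = DEFAULT_SYMMETRY_TOL,
    sep: str = "\t",
) -> tuple[ConnectomeSet, NetworkAtlas, BehavioralTable]:
    """Read and join the three input artifacts.

    The atlas must cover exactly the parcel indices appearing in the
    connectome matrices; the behavior table must contain exactly the
    connectome subjects.
    """
    conn = read_connectomes(connectome_source, tol=tol, sep=sep)
    atlas = read_atlas(atlas_path, sep=sep)
    if atlas.n_parcels != conn.n_parcels:
        raise FormatError(
            f"atlas covers {atlas.n_parcels} parcels but connectomes have "
            f"{conn.n_parcels}"
        )
    behavior = read_behavior(behavior_path, outcomes, covariates, sep=sep)
    conn, behavior = join_subjects(conn, behavior)
    logger.info(
        "loaded N=%d subjects, P=%d parcels, E=%d edges, outcomes=%s",
        conn.n_subjects, conn.n_parcels, conn.n_edges, list(behavior.outcomes),
    )
    return conn, atlas, behavior
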