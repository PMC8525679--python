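"""Similarity-network construction.

Metabolites are represented by numeric chemical-descriptor vectors (one row
per metabolite, e.g. a PaDEL-Descriptor export).  The metabolite network is
the dense matrix of pairwise cosine similarities between those vectors.  The
disease network is assembled from a precomputed disease-disease similarity
table (e.g. SemFunSim scores) around a focal disease: its nodes are the focal
disease plus every disease paired with it, edge weights are the given scores,
and unlisted pairs get weight zero.

Both networks are plain symmetric matrices with an ordered node-id list;
downstream modules treat them as weighted adjacency matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from ._errors import DataError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-10


@dataclass
class DescriptorMatrix:
    """Dense metabolite-by-descriptor feature matrix.

    Parameters
    ----------
    metabolite_ids : list of str
        Unique row identifiers, order matches ``values``.
    values : ndarray of shape (n_metabolites, n_descriptors)
        Numeric descriptor values; no NaN; every row has nonzero norm.
    """

    metabolite_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("descriptor values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise DataError("need at least 2 metabolites")
        if d < 1:
            raise DataError("need at least 1 descriptor column")
        if len(self.metabolite_ids) != n:
            raise DataError(
                f"{len(self.metabolite_ids)} ids for {n} descriptor rows"
            )
        if len(set(self.metabolite_ids)) != n:
            dupes = _duplicates(self.metabolite_ids)
            raise DataError(f"duplicate metabolite ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = [self.metabolite_ids[i]
                   for i in np.unique(np.nonzero(~np.isfinite(self.values))[0])]
            raise DataError(f"non-finite descriptor values for: {bad[:5]}")
        norms = np.linalg.norm(self.values, axis=1)
        if np.any(norms == 0):
            bad = [self.metabolite_ids[i] for i in np.nonzero(norms == 0)[0]]
            raise DataError(f"zero-norm descriptor vector for metabolite(s): {bad[:5]}")

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityNetwork:
    """Symmetric weighted similarity graph stored as a dense matrix."""

    node_ids: list[str]
    adjacency: np.ndarray
    kind: str = "metabolite"  # {"metabolite", "disease"}

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise DataError("duplicate node ids in network")
        if self.adjacency.shape != (n, n):
            raise DataError(
                f"adjacency shape {self.adjacency.shape} != ({n}, {n})"
            )
        if not np.all(np.isfinite(self.adjacency)):
            raise DataError("non-finite adjacency entries")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=_SYMMETRY_TOL):
            raise DataError("adjacency not symmetric within 1e-10")
        if self.kind not in ("metabolite", "disease"):
            raise DataError(f"unknown network kind {self.kind!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise DataError(f"node {node_id!r} not in network") from None


def cosine_similarity(u, v, id_u: str = "u", id_v: str = "v") -> float:
    """Cosine of the angle between two descriptor vectors.

    Returns sum(u_k v_k) / (||u|| ||v||), in [-1, 1].  Raises ``DataError``
    naming the offending metabolite if either vector has zero norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0:
        raise DataError(f"zero-norm descriptor vector for metabolite {id_u!r}")
    if nv == 0:
        raise DataError(f"zero-norm descriptor vector for metabolite {id_v!r}")
    return float(np.dot(u, v) / (nu * nv))


def clean_descriptors(
    df: pd.DataFrame,
    impute_missing: bool = False,
    drop_zero_variance: bool = True,
) -> pd.DataFrame:
    """Apply the configured cleaning policy to a raw descriptor table.

    Missing values are rejected by default; with ``impute_missing`` they are
    replaced by the column mean.  Columns constant across all metabolites
    carry no pairwise information and can dominate norms, so they are dropped
    (and logged) unless ``drop_zero_variance`` is off.
    """
    if df.isna().any().any():
        if not impute_missing:
            bad = df.columns[df.isna().any()].tolist()
            raise DataError(
                f"missing descriptor values in columns {bad[:5]}; "
                "enable column-mean imputation or clean the input"
            )
        df = df.fillna(df.mean())
    if drop_zero_variance:
        variances = df.var(axis=0, ddof=0)
        constant = variances[variances == 0].index
        if len(constant):
            logger.info("dropping %d zero-variance descriptor columns", len(constant))
            df = df.drop(columns=constant)
        if df.shape[1] == 0:
            raise DataError("all descriptor columns have zero variance")
    return df


def build_metabolite_network(
    desc: DescriptorMatrix,
    min_similarity: float | None = None,
    clamp_negative: bool = False,
) -> SimilarityNetwork:
    """Dense cosine-similarity network over all metabolite pairs.

    Entry (i, j) is the cosine similarity of descriptor rows i and j; the
    diagonal is exactly 1.  No edge threshold is applied by default; pass
    ``min_similarity`` to zero out weaker edges, or ``clamp_negative`` to
    floor negative cosines at 0.
    """
    adj = _sk_cosine(desc.values)
    adj = (adj + adj.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(adj, 1.0)
    if clamp_negative:
        adj = np.maximum(adj, 0.0)
    if min_similarity is not None:
        mask = adj < min_similarity
        np.fill_diagonal(mask, False)
        adj[mask] = 0.0
    return SimilarityNetwork(list(desc.metabolite_ids), adj, kind="metabolite")


def build_disease_network(
    sim_table: Iterable[tuple[str, str, float]],
    focal: str,
) -> SimilarityNetwork:
    """Disease similarity network centered on ``focal``.

    Nodes are the focal disease plus every disease paired with it in the
    table.  Any table entry between two included nodes contributes an edge
    (so a pure focal-vs-others table yields a star, while a full table yields
    a complete weighted graph); absent pairs get weight 0 and the diagonal is
    set to 1.  Conflicting duplicate scores for the same pair raise.
    """
    scores: dict[frozenset[str], float] = {}
    partners: set[str] = set()
    seen_focal = False
    for a, b, s in sim_table:
        a, b = str(a), str(b)
        s = float(s)
        if not np.isfinite(s):
            raise DataError(f"non-finite similarity for pair ({a}, {b})")
        key = frozenset((a, b))
        if key in scores and scores[key] != s:
            raise DataError(
                f"conflicting similarity scores for pair ({a}, {b}): "
                f"{scores[key]} vs {s}"
            )
        scores[key] = s
        if focal in (a, b):
            seen_focal = True
            partners.add(b if a == focal else a)
    if not seen_focal:
        raise DataError(f"focal disease {focal!r} absent from similarity table")
    partners.discard(focal)
    node_ids = [focal] + sorted(partners)
    n = len(node_ids)
    adj = np.zeros((n, n))
    index = {d: i for i, d in enumerate(node_ids)}
    for key, s in scores.items():
        pair = tuple(key)
        if len(pair) == 1:  # self-pair in the table; diagonal is forced to 1 below
            continue
        a, b = pair
        if a in index and b in index:
            adj[index[a], index[b]] = s
            adj[index[b], index[a]] = s
    np.fill_diagonal(adj, 1.0)
    return SimilarityNetwork(node_ids, adj, kind="disease")


# ---------------------------------------------------------------------------
# external interfaces (TSV/CSV)

def read_descriptor_matrix(
    path,
    impute_missing: bool = False,
    drop_zero_variance: bool = True,
    sep: str | None = None,
) -> DescriptorMatrix:
    """Read a descriptor table: first column metabolite id, header row of
    descriptor names (PaDEL-Descriptor export layout)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise DataError(f"no descriptor columns in {path}")
    df = clean_descriptors(df, impute_missing, drop_zero_variance)
    return DescriptorMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def read_disease_similarity(path, sep: str | None = None) -> list[tuple[str, str, float]]:
    """Read a 3-column (disease_a, disease_b, score) table with header."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise DataError(f"disease similarity table needs 3 columns, got {df.shape[1]}")
    return [
        (str(a), str(b), float(s))
        for a, b, s in df.iloc[:, :3].itertuples(index=False)
    ]


def write_network(net: SimilarityNetwork, path) -> None:
    """Serialize as a TSV matrix with id header row and column."""
    pd.DataFrame(net.adjacency, index=net.node_ids, columns=net.node_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_network(path, kind: str = "metabolite") -> SimilarityNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise DataError(f"network file {path} row/column ids disagree")
    return SimilarityNetwork(ids, df.to_numpy(dtype=float), kind=kind)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup
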