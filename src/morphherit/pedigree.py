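"""Pedigrees and the numerator relationship matrix.

A :class:`Pedigree` holds individual/dam/sire records, validated for
uniqueness and acyclicity and stored in topological (parents-first) order.
:func:`relationship_matrix` builds the additive (numerator) relationship
matrix A by the tabular method: for individual ``i`` with parents ``d, s``,

    a(i, i) = 1 + a(d, s) / 2
    a(i, j) = (a(d, j) + a(s, j)) / 2      for j earlier than i,

with unknown parents contributing zero and founders unrelated and
non-inbred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Pedigree", "RelationshipMatrix", "read_pedigree", "relationship_matrix"]

log = logging.getLogger(__name__)

_UNKNOWN = {"", "0", "NA", "NAN", "NONE", "<NA>"}


def _is_unknown(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip().upper() in _UNKNOWN


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree.

    ``ids`` lists individuals parents-first; ``dam_idx``/``sire_idx`` give
    the positional index of each individual's parents (-1 when unknown).
    """

    ids: list[str]
    dam_idx: np.ndarray
    sire_idx: np.ndarray

    def __post_init__(self) -> None:
        self.dam_idx = np.asarray(self.dam_idx, dtype=int)
        self.sire_idx = np.asarray(self.sire_idx, dtype=int)
        self.index = {ind: i for i, ind in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate ids in pedigree")

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (individual, dam, sire) triples; order-independent.

        Unknown parents may be ``None``/empty/``0``/``NA``.  Parents that
        are named but lack their own record are appended as founders (with
        a warning in the log).
        """
        seen: dict[str, tuple] = {}
        order: list[str] = []
        for ind, dam, sire in records:
            ind = str(ind).strip()
            if not ind or _is_unknown(ind):
                raise ValueError("blank individual id in pedigree")
            if ind in seen:
                raise ValueError(f"duplicate pedigree id {ind!r}")
            dam = None if _is_unknown(dam) else str(dam).strip()
            sire = None if _is_unknown(sire) else str(sire).strip()
            seen[ind] = (dam, sire)
            order.append(ind)
        for ind in order:
            for parent in seen[ind]:
                if parent is not None and parent not in seen:
                    log.warning(
                        "pedigree: parent %r of %r has no record; added as founder",
                        parent, ind,
                    )
                    seen[parent] = (None, None)
        graph = nx.DiGraph()
        graph.add_nodes_from(seen)
        for ind, (dam, sire) in seen.items():
            for parent in (dam, sire):
                if parent is not None:
                    graph.add_edge(parent, ind)
        try:
            topo = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"pedigree contains a cycle: {path}") from None
        idx = {ind: i for i, ind in enumerate(topo)}
        dam_idx = np.array(
            [idx[seen[i][0]] if seen[i][0] is not None else -1 for i in topo]
        )
        sire_idx = np.array(
            [idx[seen[i][1]] if seen[i][1] is not None else -1 for i in topo]
        )
        return cls(ids=topo, dam_idx=dam_idx, sire_idx=sire_idx)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> set[str]:
        mask = (self.dam_idx < 0) & (self.sire_idx < 0)
        return {self.ids[i] for i in np.nonzero(mask)[0]}

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F (diagonal of A minus one)."""
        return np.diag(relationship_matrix(self).A) - 1.0

    def to_dataframe(self) -> pd.DataFrame:
        dam = [self.ids[i] if i >= 0 else "" for i in self.dam_idx]
        sire = [self.ids[i] if i >= 0 else "" for i in self.sire_idx]
        return pd.DataFrame({"id": self.ids, "dam": dam, "sire": sire})


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with its id-to-row map."""

    A: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.index = {ind: i for i, ind in enumerate(self.ids)}

    def submatrix(self, ids) -> np.ndarray:
        rows = np.array([self.index[i] for i in ids])
        return self.A[np.ix_(rows, rows)]


def read_pedigree(path, sep=None) -> Pedigree:
    """Read a delimited pedigree table with columns id, dam, sire.

    Column names are case-insensitive; ``individual`` and ``animal`` are
    accepted aliases for ``id``.  Unknown parents: empty, ``0`` or ``NA``.
    Extra columns (sex, family, ...) are ignored here; use pandas directly
    to retrieve them.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, skipinitialspace=True)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next((cols[a] for a in ("id", "individual", "animal") if a in cols), None)
    if id_col is None or "dam" not in cols or "sire" not in cols:
        raise ValueError(
            f"pedigree file needs columns id/individual, dam, sire; got {list(df.columns)}"
        )
    records = zip(df[id_col], df[cols["dam"]], df[cols["sire"]])
    return Pedigree.from_records(records)


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix A by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    dam, sire = ped.dam_idx, ped.sire_idx
    for i in range(n):
        d, s = dam[i], sire[i]
        if d >= 0 and s >= 0:
            row = 0.5 * (A[d, :i] + A[s, :i])
            aii = 1.0 + 0.5 * A[d, s]
        elif d >= 0:
            row = 0.5 * A[d, :i]
            aii = 1.0
        elif s >= 0:
            row = 0.5 * A[s, :i]
            aii = 1.0
        else:
            row = np.zeros(i)
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return RelationshipMatrix(A=A, ids=list(ped.ids))
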