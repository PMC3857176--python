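"""Half-weight association indices and the social network of resighted whales.

Associations are tallied at the level of the encounter: for a dyad (a, b),
X is the number of encounters containing both, Ya the number containing a
without b, and Yb the number containing b without a.  With the encounter as
sampling unit the "seen in the same sample but not together" term of the
classic half-weight index cannot arise and is omitted, giving

    HWI(a, b) = X / (X + 0.5 * (Ya + Yb))        in [0, 1].

Only *eligible* individuals enter the matrix: resighted whales that were in
at least one group with at least one other resighted whale.  Per-individual
mean HWI averages over all other eligible whales (zero dyads included);
same-day repeat encounters each count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .encounter_store import EncounterStore, resighting_status

__all__ = [
    "DyadCounts",
    "AssociationMatrix",
    "eligible_individuals",
    "hwi",
    "half_weight_index",
    "association_matrix",
    "association_summaries",
    "export_network",
    "sightings_vs_associates",
    "round_to_tenth",
]


@dataclass(frozen=True)
class DyadCounts:
    id_a: str
    id_b: str
    x: int  # encounters containing both
    y_a: int  # encounters containing a without b
    y_b: int  # encounters containing b without a

    def __post_init__(self) -> None:
        if min(self.x, self.y_a, self.y_b) < 0:
            raise ValueError("dyad counts must be nonnegative")


def half_weight_index(x: int, y_a: int, y_b: int) -> float:
    if x + y_a + y_b == 0:
        raise ValueError("undefined HWI: dyad never observed")
    return x / (x + 0.5 * (y_a + y_b))


def hwi(d: DyadCounts) -> float:
    """Half-weight association index of a dyad."""
    return half_weight_index(d.x, d.y_a, d.y_b)


def round_to_tenth(x: float) -> float:
    """Round to the nearest 0.1, halves away from zero (0.25 -> 0.3)."""
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -round_to_tenth(-x)


def eligible_individuals(store: EncounterStore) -> set[str]:
    """Resighted whales seen with at least one other resighted whale.

    Individuals only ever resighted alone or with non-resighted whales are
    excluded from the social-structure analysis.
    """
    status = resighting_status(store)
    eligible: set[str] = set()
    for enc in store.encounters.values():
        rs = [m for m in enc.member_ids if status[m] == "resighted"]
        if len(rs) >= 2:
            eligible.update(rs)
    return eligible


@dataclass
class AssociationMatrix:
    """Symmetric HWI matrix over an ordered id list, with dyad tallies."""

    ids: list[str]
    matrix: np.ndarray  # HWI values, zero diagonal (diagonal is ignored)
    x_counts: np.ndarray  # joint-encounter counts per dyad
    encounter_counts: np.ndarray  # total encounters per individual

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.index_of(a), self.index_of(b)])

    def associate_counts(self) -> np.ndarray:
        """Number of partners each individual was ever grouped with (X >= 1)."""
        return (self.x_counts > 0).sum(axis=1)

    def mean_hwi(self) -> np.ndarray:
        """Mean over all other eligible individuals, zero dyads included."""
        if self.n < 2:
            return np.zeros(self.n)
        return self.matrix.sum(axis=1) / (self.n - 1)

    def max_hwi(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros(self.n)
        return self.matrix.max(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def association_matrix(store: EncounterStore, ids: set[str] | None = None) -> AssociationMatrix:
    """Tally dyad counts over all encounters and build the HWI matrix.

    ``ids`` defaults to the eligible individuals; it must be a subset of
    them when given.  Same-day multiple encounters are counted separately.
    """
    if ids is None:
        id_list = sorted(eligible_individuals(store))
    else:
        extra = set(ids) - eligible_individuals(store)
        if extra:
            raise ValueError(f"ids not eligible for association analysis: {sorted(extra)}")
        id_list = sorted(ids)
    index = {iid: i for i, iid in enumerate(id_list)}
    n = len(id_list)
    x = np.zeros((n, n), dtype=int)
    totals = np.zeros(n, dtype=int)
    for enc in store.encounters.values():
        members = [index[m] for m in enc.member_ids if m in index]
        for i in members:
            totals[i] += 1
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                x[i, j] += 1
                x[j, i] += 1
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = x[i, j] + 0.5 * ((totals[i] - x[i, j]) + (totals[j] - x[i, j]))
            if denom > 0:
                matrix[i, j] = matrix[j, i] = x[i, j] / denom
    return AssociationMatrix(id_list, matrix, x, totals)


def association_summaries(m: AssociationMatrix) -> dict[str, pd.Series]:
    """Frequency distributions of associate count, mean HWI, and max HWI.

    Max HWI is rounded to the nearest 0.1; mean HWI values are an order of
    magnitude smaller and are binned at 0.01.
    """
    assoc = pd.Series(m.associate_counts()).value_counts().sort_index()
    mean_binned = pd.Series([math.floor(v * 100 + 0.5) / 100 for v in m.mean_hwi()])
    max_binned = pd.Series([round_to_tenth(v) for v in m.max_hwi()])
    return {
        "associates": assoc,
        "mean_hwi": mean_binned.value_counts().sort_index(),
        "max_hwi": max_binned.value_counts().sort_index(),
    }


def export_network(
    m: AssociationMatrix,
    store: EncounterStore | None = None,
    threshold: float = 0.3,
    path=None,
    nodes_path=None,
    graphml_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list and node table for social-network display.

    Edges carry the exact HWI, the HWI rounded to the nearest 0.1, and a
    ``displayable`` flag marking associations at or above ``threshold``
    (default 0.3, the conventional display cut-off).  Node attributes record
    sex, cow status (has a known calf) and calf status.
    """
    edges = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            v = float(m.matrix[i, j])
            if m.x_counts[i, j] > 0:
                edges.append(
                    {
                        "source": m.ids[i],
                        "target": m.ids[j],
                        "hwi": v,
                        "hwi_rounded": round_to_tenth(v),
                        "displayable": v >= threshold,
                    }
                )
    edges_df = pd.DataFrame(edges, columns=["source", "target", "hwi", "hwi_rounded", "displayable"])

    mothers: set[str] = set()
    if store is not None:
        mothers = {i.mother_id for i in store.individuals.values() if i.mother_id}
    nodes = []
    for iid in m.ids:
        ind = store.individuals[iid] if store is not None else None
        nodes.append(
            {
                "individual_id": iid,
                "sex": ind.sex if ind else "unknown",
                "is_cow": iid in mothers,
                "is_calf": bool(ind and ind.age_class in ("calf_of_year", "yearling")),
            }
        )
    nodes_df = pd.DataFrame(nodes, columns=["individual_id", "sex", "is_cow", "is_calf"])

    if path is not None:
        edges_df.to_csv(path, index=False)
    if nodes_path is not None:
        nodes_df.to_csv(nodes_path, index=False)
    if graphml_path is not None:
        g = nx.Graph()
        for row in nodes_df.itertuples(index=False):
            g.add_node(row.individual_id, sex=row.sex, is_cow=bool(row.is_cow), is_calf=bool(row.is_calf))
        for row in edges_df.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                hwi=float(row.hwi),
                hwi_rounded=float(row.hwi_rounded),
                displayable=bool(row.displayable),
            )
        nx.write_graphml(g, graphml_path)
    return edges_df, nodes_df


def sightings_vs_associates(m: AssociationMatrix, store: EncounterStore) -> tuple[float, int, float]:
    """Pearson correlation between encounter count and associate count.

    Tests whether whales seen more often accumulate more associates.
    Returns ``(r, n, p)``.
    """
    if m.n < 3:
        raise ValueError("need at least 3 eligible individuals")
    x = m.encounter_counts.astype(float)
    y = m.associate_counts().astype(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), m.n, float(p)
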