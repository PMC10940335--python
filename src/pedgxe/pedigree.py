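"""Pedigree ingestion, kinship computation, and family-block structure.

A pedigree is a set of individuals with optional father/mother links, a sex
code, and an optional household id.  The additive relationship matrix (2x the
kinship coefficient) is computed by the classic recursive tabular method, so
inbreeding loops are handled naturally (diagonal 1 + F).  Family blocks are
the connected components of the union of the parent-offspring graph and the
same-household graph: the phenotypic likelihood factorizes exactly over these
blocks because both the genetic and the household covariance terms vanish
between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "Individual",
    "Pedigree",
    "read_pedigree",
    "compute_kinship",
    "household_matrix",
    "family_blocks",
    "write_kinship_csv",
]

#: tokens in pedigree/phenotype files that mean "no parent" / "no household"
MISSING_TOKENS = {"", "0", "NA", "na", "None", "nan"}

_SEX_MAP_DEFAULT = {
    "M": "male", "F": "female", "m": "male", "f": "female",
    "1": "male", "2": "female", 1: "male", 2: "female",
    "male": "male", "female": "female",
}


class PedigreeError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female"
    household: str | None


@dataclass
class Pedigree:
    """Validated pedigree.

    Invariants (enforced at construction): unique ids; named parents exist;
    zero or two named parents per individual; the parent graph is acyclic.
    """

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        seen: set[str] = set()
        for iid in ids:
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            seen.add(iid)
        self._index = {iid: k for k, iid in enumerate(ids)}
        for ind in self.individuals:
            named = [p for p in (ind.father, ind.mother) if p is not None]
            if len(named) == 1:
                raise PedigreeError(
                    f"individual {ind.iid!r} has exactly one named parent; "
                    "expected zero or two"
                )
            for p in named:
                if p not in self._index:
                    raise PedigreeError(
                        f"individual {ind.iid!r} names unknown parent {p!r}"
                    )
        g = self.parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains an ancestry cycle: {cyc}")

    # -- structure ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def is_founder(self, iid: str) -> bool:
        ind = self[iid]
        return ind.father is None and ind.mother is None

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals if i.father is None]

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> offspring."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for ind in self.individuals:
            if ind.father is not None:
                g.add_edge(ind.father, ind.iid)
                g.add_edge(ind.mother, ind.iid)
        return g

    def topological_order(self) -> list[str]:
        """Ids sorted so every parent precedes its offspring."""
        return list(nx.topological_sort(self.parent_graph()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "father": [i.father for i in self.individuals],
                "mother": [i.mother for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "household": [i.household for i in self.individuals],
            }
        )

    def write(self, path) -> None:
        df = self.to_frame()
        df["sex"] = df["sex"].map({"male": "M", "female": "F"})
        df = df.fillna("NA")
        df.to_csv(path, index=False)


def _norm_token(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in MISSING_TOKENS:
        return None
    # pandas reads integer-coded ids as floats when NAs are present
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    sex_map: Mapping | None = None,
) -> Pedigree:
    """Read a delimited pedigree file (header: id,father,mother,sex[,household]).

    ``dialect`` maps the canonical column names to the file's column names,
    e.g. ``{"id": "IID", "father": "PAT"}``.  Missing-parent tokens "", "0"
    and "NA" are normalized to missing.  The delimiter (comma or tab) is
    sniffed by pandas.
    """
    dialect = dict(dialect or {})
    sex_map = dict(sex_map or _SEX_MAP_DEFAULT)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {key: dialect.get(key, key) for key in ("id", "father", "mother", "sex", "household")}
    for key in ("id", "father", "mother", "sex"):
        if cols[key] not in df.columns:
            raise PedigreeError(f"pedigree file lacks required column {cols[key]!r}")
    has_household = cols["household"] in df.columns
    individuals = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        iid = _norm_token(rec[cols["id"]])
        if iid is None:
            raise PedigreeError(f"row {row_no}: missing individual id")
        sex_raw = _norm_token(rec[cols["sex"]])
        if sex_raw not in sex_map:
            raise PedigreeError(f"row {row_no}: unknown sex code {sex_raw!r}")
        individuals.append(
            Individual(
                iid=iid,
                father=_norm_token(rec[cols["father"]]),
                mother=_norm_token(rec[cols["mother"]]),
                sex=sex_map[sex_raw],
                household=_norm_token(rec[cols["household"]]) if has_household else None,
            )
        )
    return Pedigree(individuals)


def compute_kinship(ped: Pedigree) -> pd.DataFrame:
    """Additive relationship matrix 2*phi, indexed by individual id.

    Recursive tabular method over a parent-before-offspring ordering:

        phi_ii = 1/2 * (1 + phi_fm)           (f, m the parents of i)
        phi_ij = 1/2 * (phi_jf + phi_jm)      (j not a descendant of i)

    with phi terms involving absent parents equal to 0.  Returned entries are
    2*phi (so parent-offspring = 0.5, MZ-free diagonal = 1 + F).
    """
    order = ped.topological_order()
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        f = pos[ind.father] if ind.father is not None else None
        m = pos[ind.mother] if ind.mother is not None else None
        # cross terms with all previously placed individuals
        if f is None:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            phi[i, :i] = 0.5 * (phi[f, :i] + phi[m, :i])
            phi[:i, i] = phi[i, :i]
    two_phi = 2.0 * phi
    # return in the pedigree's own id order
    perm = [pos[iid] for iid in ped.ids]
    return pd.DataFrame(two_phi[np.ix_(perm, perm)], index=ped.ids, columns=ped.ids)


def household_matrix(ped: Pedigree) -> pd.DataFrame:
    """Binary same-household indicator H (diagonal 1 where household known).

    Individuals with a missing household id get an all-zero row and column,
    including the diagonal: they contribute no household variance.
    """
    ids = ped.ids
    hh = np.array([ped[i].household for i in ids], dtype=object)
    h = np.zeros((len(ids), len(ids)))
    for label in set(x for x in hh if x is not None):
        members = np.flatnonzero(hh == label)
        h[np.ix_(members, members)] = 1.0
    return pd.DataFrame(h, index=ids, columns=ids)


def family_blocks(ped: Pedigree) -> list[set[str]]:
    """Disjoint id sets over which the likelihood factorizes.

    Connected components of the union of the parent-offspring graph and the
    same-household graph; a shared household merges otherwise unrelated
    nuclear families because the household covariance links their members.
    """
    g = nx.Graph()
    g.add_nodes_from(ped.ids)
    for ind in ped.individuals:
        if ind.father is not None:
            g.add_edge(ind.father, ind.iid)
            g.add_edge(ind.mother, ind.iid)
    by_household: dict[str, list[str]] = {}
    for ind in ped.individuals:
        if ind.household is not None:
            by_household.setdefault(ind.household, []).append(ind.iid)
    for members in by_household.values():
        for other in members[1:]:
            g.add_edge(members[0], other)
    return [set(c) for c in nx.connected_components(g)]


def write_kinship_csv(kin: pd.DataFrame, path) -> None:
    """Long-format export of nonzero additive relationships (id1,id2,k2)."""
    ids = list(kin.index)
    rows = []
    values = kin.to_numpy()
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            if values[a, b] != 0.0:
                rows.append((ids[a], ids[b], values[a, b]))
    pd.DataFrame(rows, columns=["id1", "id2", "k2"]).to_csv(path, index=False)
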