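"""Pedigrees and the numerator relationship matrix A.

A pedigree is a list of (animal, sire, dam) triples.  The additive
(numerator) relationship matrix A collects the expected additive genetic
relationships implied by those triples; its diagonal is 1 + F, with F the
inbreeding coefficient.  The mixed-model machinery never needs A itself,
only its sparse inverse, which Henderson's rules assemble directly from the
pedigree once per-animal inbreeding coefficients are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

MISSING = -1

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "write_pedigree",
    "truncate_generations",
    "inbreeding",
    "build_A",
    "build_A_inverse",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, conflicting rows)."""


@dataclass
class Pedigree:
    """Completed, topologically sorted pedigree with dense integer coding.

    Attributes
    ----------
    ids : pandas.Index
        Original identifiers, in topological order (parents before
        offspring).  Position in this index is the internal code.
    sire, dam : ndarray of int
        Parent codes per animal, ``-1`` for unknown.  Phantom parents
        (identifiers that appear only as parents) are completed as founder
        rows.
    """

    ids: pd.Index
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.sire) != len(self.ids) or len(self.dam) != len(self.ids):
            raise PedigreeError("parent arrays and id index disagree in length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == MISSING) & (self.dam == MISSING)))

    def indices_of(self, ids) -> np.ndarray:
        """Map external identifiers to internal codes; raise on unknowns."""
        idx = self.ids.get_indexer(pd.Index(ids))
        if np.any(idx < 0):
            missing = list(pd.Index(ids)[idx < 0][:10])
            raise KeyError(f"identifiers not in pedigree: {missing}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Original-identifier view; unknown parents become ``pd.NA``."""
        ids = np.asarray(self.ids)
        sire = np.where(self.sire >= 0, ids[np.maximum(self.sire, 0)], None)
        dam = np.where(self.dam >= 0, ids[np.maximum(self.dam, 0)], None)
        return pd.DataFrame({"animal": ids, "sire": sire, "dam": dam})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, missing_codes=("0", "", "NA", ".")) -> "Pedigree":
        """Build a completed pedigree from an (animal, sire, dam) frame.

        Parents never listed as animals are appended as unknown-parent
        founder rows.  Rows are re-sorted so that parents precede offspring;
        a cycle (an animal that is its own ancestor) is a hard error.
        """
        cols = list(frame.columns[:3])
        raw = frame[cols].astype(object).copy()
        raw.columns = ["animal", "sire", "dam"]
        miss = set(missing_codes) | {None}
        for c in ("sire", "dam"):
            raw[c] = [None if (pd.isna(v) or v in miss) else v for v in raw[c]]
        raw["animal"] = [v for v in raw["animal"]]
        if any(pd.isna(v) or v in miss for v in raw["animal"]):
            raise PedigreeError("missing animal identifier in pedigree row")

        dup = raw.duplicated("animal", keep=False)
        if dup.any():
            conflict = raw[dup].groupby("animal").nunique()
            if (conflict[["sire", "dam"]] > 1).any().any():
                bad = conflict[(conflict[["sire", "dam"]] > 1).any(axis=1)].index[:5]
                raise PedigreeError(f"conflicting duplicate rows for animals {list(bad)}")
            raw = raw.drop_duplicates("animal")

        listed = pd.Index(raw["animal"])
        parents = {v for v in raw["sire"] if v is not None}
        parents |= {v for v in raw["dam"] if v is not None}
        phantoms = sorted(parents - set(listed), key=str)
        if phantoms:
            raw = pd.concat(
                [raw, pd.DataFrame({"animal": phantoms, "sire": None, "dam": None})],
                ignore_index=True,
            )

        ids = pd.Index(raw["animal"])
        pos = {v: i for i, v in enumerate(ids)}
        sire = np.array([MISSING if v is None else pos[v] for v in raw["sire"]], dtype=np.int64)
        dam = np.array([MISSING if v is None else pos[v] for v in raw["dam"]], dtype=np.int64)
        order = _toposort(sire, dam, ids)
        rank = np.empty(len(order), dtype=np.int64)
        rank[order] = np.arange(len(order))
        new_sire = np.where(sire >= 0, rank[np.maximum(sire, 0)], MISSING)[order]
        new_dam = np.where(dam >= 0, rank[np.maximum(dam, 0)], MISSING)[order]
        return cls(ids=ids[order], sire=new_sire, dam=new_dam)


def _toposort(sire: np.ndarray, dam: np.ndarray, ids: pd.Index) -> np.ndarray:
    """Kahn topological order (parents first); names the cycle on failure."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    order = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        v = stack.pop()
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) < n:
        cyc = [str(ids[i]) for i in range(n) if indeg[i] > 0][:10]
        raise PedigreeError(f"pedigree contains a cycle involving {cyc}")
    return np.asarray(order, dtype=np.int64)


def read_pedigree(
    path,
    id_columns=("animal", "sire", "dam"),
    missing_codes=("0", "", "NA", "."),
    sep=None,
) -> Pedigree:
    """Read a 3-column delimited pedigree file (comma or whitespace).

    ``sep=None`` sniffs: comma if the first line contains one, else any
    whitespace.  Identifiers are read as strings.
    """
    with open(path) as fh:
        first = fh.readline()
    if sep is None:
        sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = [c for c in id_columns if c in df.columns]
    if len(cols) < 3:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, header=None)
        cols = list(df.columns[:3])
    return Pedigree.from_frame(df[cols], missing_codes=missing_codes)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the recoded pedigree (topological order, '0' = unknown)."""
    df = ped.to_frame().fillna("0")
    df.to_csv(path, index=False)


def truncate_generations(ped: Pedigree, phenotyped, depth: int) -> Pedigree:
    """Keep phenotyped animals plus ancestors within ``depth`` parent-hops.

    Parents falling beyond the cut are set to unknown, so truncated
    boundary animals become founders.  ``depth=0`` keeps the phenotyped
    animals only.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    keep_ids = ped.indices_of(phenotyped)
    hops = np.full(len(ped), -1, dtype=np.int64)  # -1: dropped
    hops[keep_ids] = 0
    # descending code order visits offspring before parents
    for i in range(len(ped) - 1, -1, -1):
        if hops[i] < 0 or hops[i] >= depth:
            continue
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                h = hops[i] + 1
                if hops[p] < 0 or h < hops[p]:
                    hops[p] = h
    keep = hops >= 0
    frame = ped.to_frame()[keep].copy()
    boundary = keep & np.array(
        [
            (ped.sire[i] >= 0 and not keep[ped.sire[i]])
            or (ped.dam[i] >= 0 and not keep[ped.dam[i]])
            for i in range(len(ped))
        ]
    )
    for col, parent in (("sire", ped.sire), ("dam", ped.dam)):
        bad = [i for i in np.flatnonzero(boundary) if parent[i] >= 0 and not keep[parent[i]]]
        frame.loc[frame.index.intersection(bad), col] = None
    return Pedigree.from_frame(frame)


# ---------------------------------------------------------------------------
# numeric kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inbreeding_ml(sire, dam):
    """Meuwissen & Luo recursion for inbreeding coefficients.

    Works animal by animal on the topologically sorted pedigree, tracing
    the ancestor list with accumulated path coefficients; O(n * d^2) where
    d is pedigree depth.
    """
    n = sire.shape[0]
    F = np.zeros(n)
    # point = linked list over ancestor codes, L = path coefficients
    point = np.zeros(n, dtype=np.int64)
    L = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        point[i] = -1
        top = i
        while top >= 0:
            j = top
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                # insert sj into the sorted (descending) list
                k = top
                prev = -2
                while k > sj:
                    prev = k
                    k = point[k]
                if k != sj:
                    if prev == -2:
                        top = sj
                        point[sj] = k
                    else:
                        point[prev] = sj
                        point[sj] = k
                    L[sj] = 0.0
                L[sj] += 0.5 * L[j]
            if dj >= 0:
                k = top
                prev = -2
                while k > dj:
                    prev = k
                    k = point[k]
                if k != dj:
                    if prev == -2:
                        top = dj
                        point[dj] = k
                    else:
                        point[prev] = dj
                        point[dj] = k
                    L[dj] = 0.0
                L[dj] += 0.5 * L[j]
            fi += L[j] * L[j] * D[j]
            L[j] = 0.0
            nxt = point[j]
            point[j] = -1
            top = nxt if nxt != j else -1
        F[i] = fi
        D[i] = 0.5 - 0.25 * (Fs + Fd)
    return F


@njit(cache=True)
def _tabular_A(sire, dam):
    n = sire.shape[0]
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        if s >= 0 and d >= 0:
            A[j, j] = 1.0 + 0.5 * A[s, d]
        else:
            A[j, j] = 1.0
        for i in range(j):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[i, s]
            if d >= 0:
                aij += 0.5 * A[i, d]
            A[i, j] = aij
            A[j, i] = aij
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen–Luo recursion)."""
    return _inbreeding_ml(ped.sire, ped.dam)


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its id order and F."""

    entries: np.ndarray
    order: pd.Index
    inbreeding: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.inbreeding is None:
            self.inbreeding = np.diag(self.entries) - 1.0


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular method (small/medium pedigrees).

    a_jj = 1 + 0.5 a_{sire(j),dam(j)};  a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)}).
    """
    A = _tabular_A(ped.sire, ped.dam)
    return RelationshipMatrix(entries=A, order=ped.ids, inbreeding=np.diag(A) - 1.0)


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding adjustment.

    The contribution of animal i with Mendelian sampling variance
    delta_i = a_ii - 0.25 (a_ss + a_dd) over known parents is
    (1/delta_i) * outer(k, k) with k = (+1 at i, -1/2 at each known parent).
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    rows, cols, vals = _ainv_triplets(ped.sire, ped.dam, F)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv


@njit(cache=True)
def _ainv_triplets(sire, dam, F):
    n = sire.shape[0]
    cap = 9 * n
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap)
    m = 0
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            delta = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            delta = 0.75 - 0.25 * F[s]
        elif d >= 0:
            delta = 0.75 - 0.25 * F[d]
        else:
            delta = 1.0
        w = 1.0 / delta
        rows[m] = i; cols[m] = i; vals[m] = w; m += 1
        for p in (s, d):
            if p >= 0:
                rows[m] = i; cols[m] = p; vals[m] = -0.5 * w; m += 1
                rows[m] = p; cols[m] = i; vals[m] = -0.5 * w; m += 1
                rows[m] = p; cols[m] = p; vals[m] = 0.25 * w; m += 1
        if s >= 0 and d >= 0:
            rows[m] = s; cols[m] = d; vals[m] = 0.25 * w; m += 1
            rows[m] = d; cols[m] = s; vals[m] = 0.25 * w; m += 1
    return rows[:m], cols[:m], vals[:m]
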