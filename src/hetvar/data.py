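"""Phenotype tables: reading, quality-control filters, design structures.

Records are subjective conformation scores (1-9 integer scale, 5 ideal)
with a contemporary-group (CG) identifier and age in days.  Quality
control keeps CGs that are large enough and show score variation, ages
inside a fixed window, and a single record per animal; the filters
interact (dropping records shrinks CGs), so they are iterated to a fixed
point, which also makes the result independent of filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree

__all__ = [
    "read_phenotypes",
    "apply_cleaning_filters",
    "select_single_record",
    "build_design",
    "summarize",
    "CleaningReport",
    "DesignBundle",
]

REQUIRED_COLUMNS = ("animal", "score", "cg", "age")


def read_phenotypes(path, column_map: dict | None = None, sep=None) -> pd.DataFrame:
    """Read a delimited phenotype file with header.

    Expected logical columns: animal, score, cg, age, and optionally date.
    ``column_map`` maps logical names to file column names.
    """
    with open(path) as fh:
        first = fh.readline()
    if sep is None:
        sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns {missing}")
    df["animal"] = df["animal"].astype(str)
    df["score"] = df["score"].astype(float)
    df["age"] = df["age"].astype(float)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


@dataclass
class CleaningReport:
    records_in: int
    records_out: int
    dropped_by_rule: dict = field(default_factory=dict)
    cg_retained: int = 0
    n_passes: int = 1

    def __post_init__(self):
        total = self.records_out + sum(self.dropped_by_rule.values())
        if total != self.records_in:
            raise ValueError(
                f"cleaning counts not conserved: in={self.records_in}, "
                f"out + dropped = {total}"
            )

    def to_text(self) -> str:
        lines = [
            f"records_in\t{self.records_in}",
            f"records_out\t{self.records_out}",
            f"cg_retained\t{self.cg_retained}",
            f"passes\t{self.n_passes}",
        ]
        for rule, k in sorted(self.dropped_by_rule.items()):
            lines.append(f"dropped.{rule}\t{k}")
        return "\n".join(lines) + "\n"


def select_single_record(
    tab: pd.DataFrame, policy: str = "first_by_date", seed: int | None = None
) -> pd.DataFrame:
    """Reduce to one record per animal.

    ``first_by_date`` keeps the earliest record (requires a date column);
    ``random`` keeps a uniformly chosen record, reproducible by ``seed``.
    """
    if policy == "first_by_date":
        if "date" not in tab.columns or tab["date"].isna().any():
            raise ValueError("first_by_date policy requires complete record dates")
        idx = tab.sort_values(["animal", "date"], kind="stable").groupby("animal").head(1).index
    elif policy == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(tab))
        idx = tab.iloc[perm].groupby("animal").head(1).index
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return tab.loc[tab.index.isin(idx)].sort_index()


def apply_cleaning_filters(
    tab: pd.DataFrame,
    min_cg_size: int = 150,
    min_score_categories: int = 2,
    age_range: tuple[int, int] = (321, 7796),
    one_record_per_animal: bool = True,
    single_record_policy: str = "first_by_date",
    seed: int | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Quality-control filters, iterated to a fixed point.

    Rules: age inside ``age_range`` (inclusive); one record per animal;
    each CG with at least ``min_cg_size`` records and at least
    ``min_score_categories`` distinct scores.  CG membership changes as
    records are dropped, so the CG rules are re-applied until stable.
    """
    n_in = len(tab)
    dropped = {"age": 0, "duplicate_record": 0, "cg_size": 0, "cg_variation": 0}
    cur = tab

    in_window = (cur["age"] >= age_range[0]) & (cur["age"] <= age_range[1])
    dropped["age"] += int((~in_window).sum())
    cur = cur[in_window]

    if one_record_per_animal and len(cur):
        before = len(cur)
        if single_record_policy == "first_by_date" and "date" not in cur.columns:
            single_record_policy = "random"
            seed = 0 if seed is None else seed  # keep the fallback deterministic
        cur = select_single_record(cur, policy=single_record_policy, seed=seed)
        dropped["duplicate_record"] += before - len(cur)

    n_pass = 0
    while True:
        n_pass += 1
        sizes = cur.groupby("cg")["score"].transform("size")
        ncat = cur.groupby("cg")["score"].transform("nunique")
        small = sizes < min_cg_size
        uniform = (~small) & (ncat < min_score_categories)
        dropped["cg_size"] += int(small.sum())
        dropped["cg_variation"] += int(uniform.sum())
        nxt = cur[~(small | uniform)]
        if len(nxt) == len(cur):
            cur = nxt
            break
        cur = nxt

    report = CleaningReport(
        records_in=n_in,
        records_out=len(cur),
        dropped_by_rule=dropped,
        cg_retained=int(cur["cg"].nunique()),
        n_passes=n_pass,
    )
    return cur.copy(), report


@dataclass
class DesignBundle:
    """Response and incidence structures for one model fit.

    ``X`` holds CG class indicators (all levels, no intercept: CG absorbs
    the intercept) plus a centred age covariate in the last column.
    ``animal_index`` maps each record to the pedigree code of its animal.
    """

    y: np.ndarray
    X: sparse.csr_matrix
    animal_index: np.ndarray
    n_pedigree: int
    cg_levels: pd.Index
    weights: np.ndarray
    column_names: list
    age_mean: float = 0.0

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def Z(self) -> sparse.csr_matrix:
        n = self.n_records
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), self.animal_index)), shape=(n, self.n_pedigree)
        )


def build_design(tab: pd.DataFrame, ped: Pedigree, center_age: bool = True) -> DesignBundle:
    """Fixed and random incidence structures for the animal models.

    CG enters as a full set of class indicators without an intercept
    (equivalent to dropping a reference level in an intercept model);
    age enters as a linear covariate, centred by default.
    """
    animal_index = ped.indices_of(tab["animal"])
    cg = pd.Categorical(tab["cg"])
    n = len(tab)
    Xcg = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), cg.codes)), shape=(n, len(cg.categories))
    )
    age = tab["age"].to_numpy(dtype=float)
    age_mean = float(age.mean()) if center_age else 0.0
    Xage = sparse.csr_matrix((age - age_mean).reshape(-1, 1))
    X = sparse.hstack([Xcg, Xage]).tocsr()
    names = [f"cg:{c}" for c in cg.categories] + ["age"]
    return DesignBundle(
        y=tab["score"].to_numpy(dtype=float),
        X=X,
        animal_index=np.asarray(animal_index),
        n_pedigree=len(ped),
        cg_levels=pd.Index(cg.categories),
        weights=np.ones(n),
        column_names=names,
        age_mean=age_mean,
    )


def summarize(tab: pd.DataFrame, ddof: int = 1, excess_kurtosis: bool = True) -> dict:
    """Descriptive statistics of the score distribution and data structure.

    Skewness is m3/m2^1.5 and kurtosis m4/m2^2 (minus 3 when
    ``excess_kurtosis``), i.e. moment definitions.
    """
    y = tab["score"].to_numpy(dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two records to summarize")
    m = y.mean()
    d = y - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("constant scores: SD is 0 and skewness undefined")
    out = {
        "n_records": n,
        "n_animals": int(tab["animal"].nunique()),
        "n_cg": int(tab["cg"].nunique()),
        "mean_cg_size": float(n / tab["cg"].nunique()),
        "min": float(y.min()),
        "max": float(y.max()),
        "mean": float(m),
        "sd": float(np.sqrt(np.sum(d**2) / (n - ddof))),
        "skewness": float(np.mean(d**3) / m2**1.5),
        "kurtosis": float(np.mean(d**4) / m2**2 - (3.0 if excess_kurtosis else 0.0)),
    }
    return out
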