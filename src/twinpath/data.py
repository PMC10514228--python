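"""Pair-structured binary twin phenotype data: containers, I/O, validation.

Canonical storage is one row per *pair* with a (n_pairs, 2, p) value array
(NaN = missing), because every downstream moment is pair-level.  Only the four
same-sex zygosity groups MZM/MZF/DZM/DZF are supported; a pair whose second
member is entirely unobserved is retained as an incomplete pair.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "PhenotypeCodebook",
    "TwinDataset",
    "read_codebook",
    "read_twin_table",
    "write_twin_table",
    "summarize_prevalence",
    "pair_completeness",
]

GROUPS = ("MZM", "MZF", "DZM", "DZF")
_CLASS_TAGS = ("prescription", "illicit")
_MISSING_TOKENS = ("", "NA")


def group_zygosity(group: str) -> str:
    return group[:2]


def group_sex(group: str) -> str:
    return group[2]


@dataclass(frozen=True)
class PhenotypeCodebook:
    """Ordered phenotype identifiers with display labels and drug-class tags.

    ``class_tags`` ('prescription' or 'illicit') drive the two-factor loading
    pattern of the pathway models.
    """

    names: tuple
    labels: tuple
    class_tags: tuple

    def __init__(self, names: Sequence[str], labels: Sequence[str] | None = None,
                 class_tags: Sequence[str] | None = None):
        names = tuple(names)
        if labels is None:
            labels = names
        if class_tags is None:
            class_tags = ("illicit",) * len(names)
        labels = tuple(labels)
        class_tags = tuple(class_tags)
        if len(names) == 0 or len(set(names)) != len(names):
            raise ValueError("phenotype names must be unique and non-empty")
        if any(not n for n in names):
            raise ValueError("phenotype names must be non-empty strings")
        if len(labels) != len(names) or len(class_tags) != len(names):
            raise ValueError("labels and class_tags must match names in length")
        for t in class_tags:
            if t not in _CLASS_TAGS:
                raise ValueError(f"class_tag {t!r} not in {_CLASS_TAGS}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_tags", class_tags)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def class_mask(self, tag: str) -> np.ndarray:
        """Boolean mask of phenotypes carrying ``tag``."""
        if tag not in _CLASS_TAGS:
            raise ValueError(f"unknown class tag {tag!r}")
        return np.array([t == tag for t in self.class_tags])

    def subset(self, names: Sequence[str]) -> "PhenotypeCodebook":
        idx = [self.index(n) for n in names]
        return PhenotypeCodebook(
            [self.names[i] for i in idx],
            [self.labels[i] for i in idx],
            [self.class_tags[i] for i in idx],
        )


def read_codebook(path) -> PhenotypeCodebook:
    """Read a codebook from YAML or JSON: a list of {name, label, class_tag}."""
    text = open(path, "r", encoding="utf-8").read()
    try:
        entries = json.loads(text)
    except json.JSONDecodeError:
        entries = yaml.safe_load(text)
    return PhenotypeCodebook(
        [e["name"] for e in entries],
        [e.get("label", e["name"]) for e in entries],
        [e.get("class_tag", "illicit") for e in entries],
    )


@dataclass
class TwinDataset:
    """Binary twin-pair phenotype data for the classical twin design.

    values[i, t, j] is twin t's (0/1, NaN missing) value on phenotype j for
    pair i.  ``groups`` holds one of MZM/MZF/DZM/DZF per pair.
    """

    codebook: PhenotypeCodebook
    pair_ids: np.ndarray
    groups: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.pair_ids = np.asarray(self.pair_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n, two, p = self.values.shape
        if two != 2 or p != len(self.codebook):
            raise ValueError("values must have shape (n_pairs, 2, n_phenotypes)")
        if len(self.pair_ids) != n or len(self.groups) != n:
            raise ValueError("pair_ids/groups length mismatch")
        if len(set(self.pair_ids)) != n:
            raise ValueError("pair_id values must be unique")
        for g in set(self.groups):
            if g not in GROUPS:
                raise ValueError(f"unknown zygosity-sex group {g!r}")
        obs = np.isfinite(self.values)
        bad = obs & ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, t, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary phenotype value {self.values[i, t, j]!r} for pair "
                f"{self.pair_ids[i]!r} twin {t + 1} phenotype {self.codebook.names[j]!r}"
            )
        # twin1 must carry at least one observation; swap if only twin2 does
        t1_empty = ~obs[:, 0, :].any(axis=1)
        t2_any = obs[:, 1, :].any(axis=1)
        swap = t1_empty & t2_any
        if swap.any():
            self.values[swap] = self.values[swap][:, ::-1, :]
        keep = obs.any(axis=(1, 2))
        if not keep.all():
            self.pair_ids = self.pair_ids[keep]
            self.groups = self.groups[keep]
            self.values = self.values[keep]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def phenotypes(self) -> tuple:
        return self.codebook.names

    def complete_mask(self) -> np.ndarray:
        """True for pairs with both members at least partially observed."""
        obs = np.isfinite(self.values)
        return obs[:, 0, :].any(axis=1) & obs[:, 1, :].any(axis=1)

    def group_arrays(self, group: str):
        """(twin1, twin2) value arrays for one zygosity-sex group."""
        m = self.groups == group
        return self.values[m, 0, :], self.values[m, 1, :]

    def select_phenotypes(self, names: Sequence[str]) -> "TwinDataset":
        idx = [self.codebook.index(n) for n in names]
        return TwinDataset(self.codebook.subset(names), self.pair_ids.copy(),
                           self.groups.copy(), self.values[:, :, idx].copy())

    def subset_pairs(self, mask_or_index) -> "TwinDataset":
        """Row subset / resample.  Values are already validated, so this
        bypasses __post_init__ (it is the bootstrap hot path); resampled
        duplicates get fresh synthetic pair ids."""
        idx = np.asarray(mask_or_index)
        ids = self.pair_ids[idx]
        if len(set(ids)) != len(ids):  # bootstrap resamples reuse ids
            ids = np.arange(len(ids)).astype(object)
        out = object.__new__(TwinDataset)
        out.codebook = self.codebook
        out.pair_ids = ids
        out.groups = self.groups[idx]
        out.values = self.values[idx].copy()
        return out

    def swap_twins(self) -> "TwinDataset":
        return TwinDataset(self.codebook, self.pair_ids.copy(), self.groups.copy(),
                           self.values[:, ::-1, :].copy())

    def to_wide_frame(self) -> pd.DataFrame:
        cols = {"pair_id": self.pair_ids, "group": self.groups}
        for j, name in enumerate(self.phenotypes):
            for t in (0, 1):
                v = self.values[:, t, j]
                cols[f"{name}_t{t + 1}"] = ["" if not np.isfinite(x) else str(int(x)) for x in v]
        return pd.DataFrame(cols)


def _parse_cell(token, pair_id, column):
    token = str(token).strip()
    if token in _MISSING_TOKENS:
        return np.nan
    if token in ("0", "1", "0.0", "1.0"):
        return float(float(token))
    raise ValueError(
        f"non-binary phenotype value {token!r} at pair {pair_id!r}, column {column!r}"
    )


def read_twin_table(path, codebook: PhenotypeCodebook, layout: str = "wide") -> TwinDataset:
    """Read a twin-pair CSV in wide or long layout into a TwinDataset.

    Wide layout: pair_id, group, then ``<phen>_t1`` / ``<phen>_t2`` columns.
    Long layout: pair_id, group, twin_index (1/2), then one column per
    phenotype; a pair present with only one twin_index is kept as incomplete.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if layout not in ("wide", "long"):
        raise ValueError("layout must be 'wide' or 'long'")
    p = len(codebook)
    for g in df["group"].unique():
        if g not in GROUPS:
            raise ValueError(f"unknown zygosity-sex group {g!r}")
    if layout == "wide":
        if df["pair_id"].duplicated().any():
            dup = df["pair_id"][df["pair_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate pair_id {dup!r}")
        n = len(df)
        values = np.full((n, 2, p), np.nan)
        for j, name in enumerate(codebook.names):
            for t in (0, 1):
                col = f"{name}_t{t + 1}"
                if col not in df.columns:
                    raise ValueError(f"missing column {col!r}")
                values[:, t, j] = [
                    _parse_cell(v, pid, col) for v, pid in zip(df[col], df["pair_id"])
                ]
        return TwinDataset(codebook, df["pair_id"].to_numpy(object),
                           df["group"].to_numpy(object), values)
    # long
    if "twin_index" not in df.columns:
        raise ValueError("long layout requires a twin_index column")
    key = list(zip(df["pair_id"], df["twin_index"]))
    if len(set(key)) != len(key):
        dups = pd.Series(key)[pd.Series(key).duplicated()].iloc[0]
        raise ValueError(f"duplicate (pair_id, twin_index) {dups!r}")
    pair_order = list(dict.fromkeys(df["pair_id"]))
    pos = {pid: i for i, pid in enumerate(pair_order)}
    values = np.full((len(pair_order), 2, p), np.nan)
    groups = np.empty(len(pair_order), dtype=object)
    for _, row in df.iterrows():
        ti = int(row["twin_index"])
        if ti not in (1, 2):
            raise ValueError(f"twin_index must be 1 or 2, got {ti}")
        i = pos[row["pair_id"]]
        prev = groups[i]
        if prev is not None and prev != row["group"]:
            raise ValueError(f"pair {row['pair_id']!r} has conflicting group labels")
        groups[i] = row["group"]
        for j, name in enumerate(codebook.names):
            values[i, ti - 1, j] = _parse_cell(row[name], row["pair_id"], name)
    return TwinDataset(codebook, np.array(pair_order, dtype=object), groups, values)


def write_twin_table(ds: TwinDataset, path, layout: str = "wide") -> None:
    """Write a TwinDataset back to CSV (wide layout)."""
    if layout != "wide":
        raise ValueError("only wide output is supported")
    ds.to_wide_frame().to_csv(path, index=False)


def pair_completeness(ds: TwinDataset) -> float:
    """Share of individuals who belong to a complete pair (both twins observed)."""
    complete = int(ds.complete_mask().sum())
    singles = ds.n_pairs - complete
    individuals = 2 * complete + singles
    return 2 * complete / individuals


def summarize_prevalence(ds: TwinDataset) -> pd.DataFrame:
    """Per-phenotype endorsement proportions, overall and by zygosity-sex group.

    Proportions are computed over individuals with an observed value; a
    phenotype with no observed values in a cell is reported as NaN (undefined),
    never 0.  The individual-level pair-completeness rate is attached as
    ``df.attrs['completeness']``.
    """
    if ds.n_pairs == 0:
        raise ValueError("dataset is empty")
    persons = np.concatenate([ds.values[:, 0, :], ds.values[:, 1, :]])
    person_groups = np.concatenate([ds.groups, ds.groups])
    rows = {}
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        rows["overall"] = np.nanmean(persons, axis=0)
        for g in GROUPS:
            m = person_groups == g
            rows[g] = np.nanmean(persons[m], axis=0) if m.any() else np.full(len(ds.codebook), np.nan)
    out = pd.DataFrame(rows, index=list(ds.phenotypes))
    out.attrs["completeness"] = pair_completeness(ds)
    return out
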