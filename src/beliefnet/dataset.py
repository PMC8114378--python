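"""Tabular container for belief-questionnaire responses.

A :class:`BeliefDataset` is an n x p numeric table of questionnaire
responses in which each variable is declared ordinal (Likert-type),
binary, or continuous, with an optional binary group label per
respondent (e.g. registered vs. not registered as an organ donor).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_KINDS = ("ordinal", "binary", "continuous")

#: Columns with at most this many distinct integer levels are inferred ordinal.
MAX_ORDINAL_LEVELS = 9


@dataclass
class BeliefDataset:
    """n x p response table with per-variable kind and optional group labels.

    Parameters
    ----------
    values
        DataFrame of shape (n, p); all cells numeric, no missing values.
    var_kinds
        Mapping variable name -> one of ``"ordinal"``, ``"binary"``,
        ``"continuous"``.
    group
        Optional length-n integer array of 0/1 group labels.
    """

    values: pd.DataFrame
    var_kinds: dict[str, str]
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.isna().any().any():
            raise ValueError("BeliefDataset must not contain missing values")
        missing = set(self.values.columns) - set(self.var_kinds)
        if missing:
            raise ValueError(f"var_kinds missing for columns: {sorted(missing)}")
        for name, kind in self.var_kinds.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"invalid kind {kind!r} for variable {name!r}")
        for name in self.values.columns:
            if self.var_kinds[name] == "binary":
                vals = set(np.unique(self.values[name].to_numpy()))
                if not vals <= {0, 1}:
                    raise ValueError(f"binary column {name!r} has values outside {{0,1}}")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(self.values):
                raise ValueError("group length does not match number of rows")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def var_names(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_rows(self, index: np.ndarray) -> "BeliefDataset":
        """Row subset (bootstrap resample / case-drop subsample)."""
        group = self.group[index] if self.group is not None else None
        return BeliefDataset(
            self.values.iloc[index].reset_index(drop=True),
            dict(self.var_kinds),
            group,
        )

    def drop_column(self, name: str) -> "BeliefDataset":
        kinds = {k: v for k, v in self.var_kinds.items() if k != name}
        return BeliefDataset(self.values.drop(columns=[name]), kinds, self.group)

    def split_by(self, name: str) -> tuple["BeliefDataset", "BeliefDataset"]:
        """Split rows on a binary column, removing it from both halves.

        Returns the (column == 0, column == 1) halves; each half carries no
        group labels of its own.
        """
        if name not in self.values.columns:
            raise KeyError(f"no such variable: {name!r}")
        col = self.values[name].to_numpy()
        uniq = set(np.unique(col))
        if not uniq <= {0, 1}:
            raise ValueError(f"split variable {name!r} is not binary")
        rest = self.values.drop(columns=[name])
        kinds = {k: v for k, v in self.var_kinds.items() if k != name}
        d0 = BeliefDataset(rest[col == 0].reset_index(drop=True), dict(kinds))
        d1 = BeliefDataset(rest[col == 1].reset_index(drop=True), dict(kinds))
        return d0, d1

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write as CSV with header; variable kinds go to a sidecar JSON."""
        path = Path(path)
        frame = self.values.copy()
        if self.group is not None:
            frame = frame.assign(group=self.group)
        frame.to_csv(path, index=False)
        if sidecar:
            meta = {"var_kinds": self.var_kinds, "has_group": self.group is not None}
            path.with_suffix(".kinds.json").write_text(json.dumps(meta, indent=2))


def infer_kind(col: pd.Series) -> str:
    vals = col.to_numpy()
    uniq = np.unique(vals)
    if len(uniq) <= 2 and set(uniq) <= {0, 1}:
        return "binary"
    if np.allclose(vals, np.round(vals)) and len(uniq) <= MAX_ORDINAL_LEVELS:
        return "ordinal"
    return "continuous"


def read_dataset(path: str | Path, kinds: dict[str, str] | None = None) -> BeliefDataset:
    """Read a BeliefDataset from CSV.

    Kinds are inferred per column (<=2 unique values in {0,1} -> binary;
    <= 9 integer levels -> ordinal; otherwise continuous) unless a sidecar
    mapping overrides them. Rows with missing values are dropped with a
    logged count; a column literally named ``group`` becomes the group
    labels rather than a variable.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty dataset file: {path}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            raise ValueError(
                f"non-numeric cells in column {col!r} (e.g. row {bad[0] if len(bad) else '?'})"
            )
    n_before = len(frame)
    frame = frame.dropna().reset_index(drop=True)
    if len(frame) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(frame))

    group = None
    if "group" in frame.columns:
        group = frame["group"].to_numpy(dtype=int)
        frame = frame.drop(columns=["group"])

    sidecar = path.with_suffix(".kinds.json")
    file_kinds: dict[str, str] = {}
    if sidecar.exists():
        file_kinds = json.loads(sidecar.read_text()).get("var_kinds", {})
    inferred = {c: infer_kind(frame[c]) for c in frame.columns}
    inferred.update(file_kinds)
    if kinds:
        inferred.update(kinds)
    inferred = {c: k for c, k in inferred.items() if c in frame.columns}
    return BeliefDataset(frame, inferred, group)
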