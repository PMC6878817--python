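"""Readers and writers for alteration matrices, clinical tables and results.

File dialects are deliberately plain: tab-separated text with a header for
the tabular inputs, JSON for structured results, GraphML plus an edge-list
TSV for the exclusivity network.  Feature labels follow the convention of
gene symbol plus an optional suffix — ``(A)`` amplification, ``(D)``
deletion, bare symbol a nonsynonymous SNV; several comma-joined symbols
sharing one suffix denote a metagene.  The labels are opaque to every
statistic downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationMatrix",
    "ClinicalTable",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "align",
    "write_results",
    "write_network",
]


@dataclass
class AlterationMatrix:
    """Binary patients x alteration-features matrix.

    ``values[i, k]`` is 1 if patient ``i`` carries alteration ``k``.
    """

    patient_ids: list[str]
    feature_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"matrix must be at least 2x2, got {n}x{m}")
        if len(self.patient_ids) != n or len(self.feature_labels) != m:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if len(set(self.feature_labels)) != m:
            raise ValueError("duplicate feature labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        zero = [lab for lab, s in zip(self.feature_labels, self.values.sum(axis=0)) if s == 0]
        if zero:
            logger.info("retaining %d all-zero features: %s", len(zero), ", ".join(zero[:5]))

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns(self, labels: list[str]) -> np.ndarray:
        """Submatrix of the named features, in the given order."""
        idx = []
        for lab in labels:
            try:
                idx.append(self.feature_labels.index(lab))
            except ValueError:
                raise KeyError(f"unknown feature label: {lab!r}") from None
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids,
                            columns=self.feature_labels)


@dataclass
class ClinicalTable:
    """Per-patient survival outcome and covariates.

    ``time`` is months to death or censoring, ``event`` is 1 for death
    within follow-up and 0 for censoring.  ``gender`` is coded male=1 /
    female=0 so a positive Cox coefficient reads male-vs-female.  Extra
    numeric covariates live in ``extra``.
    """

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    age: np.ndarray | None = None
    gender: np.ndarray | None = None
    extra: pd.DataFrame | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event lengths do not match patient ids")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
        if self.gender is not None:
            self.gender = np.asarray(self.gender, dtype=float)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event},
                          index=self.patient_ids)
        if self.age is not None:
            df["age"] = self.age
        if self.gender is not None:
            df["gender"] = self.gender
        if self.extra is not None:
            for c in self.extra.columns:
                df[c] = self.extra[c].to_numpy()
        return df

    def subset(self, mask_or_index) -> "ClinicalTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ClinicalTable(
            patient_ids=[self.patient_ids[i] for i in idx],
            time=self.time[idx],
            event=self.event[idx],
            age=None if self.age is None else self.age[idx],
            gender=None if self.gender is None else self.gender[idx],
            extra=None if self.extra is None else self.extra.iloc[idx].reset_index(drop=True),
        )


def read_matrix(path, dialect: str = "patients_as_rows") -> AlterationMatrix:
    """Read a binary alteration matrix from TSV.

    ``dialect`` says what the file rows are; in memory the layout is always
    patients-as-rows.  Any cell other than 0/1 raises a parse error naming
    the offending row and column.
    """
    if dialect not in ("patients_as_rows", "features_as_rows"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if dialect == "features_as_rows":
        df = df.T
    vals = np.empty(df.shape, dtype=np.int8)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(arr[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}")
            vals[i, j] = int(cell)
    return AlterationMatrix(
        patient_ids=[str(x) for x in df.index],
        feature_labels=[str(x) for x in df.columns],
        values=vals,
    )


def write_matrix(matrix: AlterationMatrix, path, dialect: str = "patients_as_rows") -> None:
    df = matrix.to_frame()
    if dialect == "features_as_rows":
        df = df.T
    elif dialect != "patients_as_rows":
        raise ValueError(f"unknown dialect: {dialect!r}")
    df.to_csv(path, sep="\t", index_label="id")


DEFAULT_COLUMN_MAP = {
    "id": "patient_id", "time": "time", "event": "event",
    "age": "age", "gender": "gender",
}


def read_clinical(path, column_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read the clinical TSV, dropping and counting rows with missing time/event."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    for key in ("id", "time", "event"):
        if cmap[key] not in df.columns:
            raise ValueError(f"clinical table missing required column {cmap[key]!r}")
    time = pd.to_numeric(df[cmap["time"]], errors="coerce")
    event = pd.to_numeric(df[cmap["event"]], errors="coerce")
    usable = time.notna() & event.notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropped %d rows with incomplete survival information", n_dropped)
    df = df[usable]
    if df.empty:
        raise ValueError("no usable rows after dropping incomplete survival data")
    known = {cmap[k] for k in cmap}
    extra_cols = [c for c in df.columns if c not in known]
    return ClinicalTable(
        patient_ids=[str(x) for x in df[cmap["id"]]],
        time=time[usable].to_numpy(),
        event=event[usable].to_numpy(dtype=int),
        age=(pd.to_numeric(df[cmap["age"]], errors="coerce").to_numpy()
             if cmap["age"] in df.columns else None),
        gender=(pd.to_numeric(df[cmap["gender"]], errors="coerce").to_numpy()
                if cmap["gender"] in df.columns else None),
        extra=df[extra_cols].apply(pd.to_numeric, errors="coerce").reset_index(drop=True)
        if extra_cols else None,
        n_dropped=n_dropped,
    )


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.to_frame().to_csv(path, sep="\t", index_label="patient_id")


def align(matrix: AlterationMatrix, clinical: ClinicalTable):
    """Restrict both objects to their common patients, in matrix order."""
    common = [pid for pid in matrix.patient_ids if pid in set(clinical.patient_ids)]
    if not common:
        raise ValueError("no patients shared between matrix and clinical table")
    logger.info("aligned on %d shared patients", len(common))
    m_idx = [matrix.patient_ids.index(p) for p in common]
    pos = {p: i for i, p in enumerate(clinical.patient_ids)}
    c_idx = [pos[p] for p in common]
    new_matrix = AlterationMatrix(
        patient_ids=common,
        feature_labels=list(matrix.feature_labels),
        values=matrix.values[m_idx],
    )
    return new_matrix, clinical.subset(c_idx)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, path) -> None:
    """Serialize any result object (dataclass, dict, list) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=1, allow_nan=False, default=str)
        fh.write("\n")


def read_results(path):
    with open(path) as fh:
        return json.load(fh)


def write_network(graph: nx.Graph, graphml_path, edgelist_path=None) -> None:
    """Write the exclusivity network as GraphML plus a 3-column edge list."""
    nx.write_graphml(graph, graphml_path)
    if edgelist_path is not None:
        rows = [{"gene1": u, "gene2": v, "edge_weight": d.get("weight", 1)}
                for u, v, d in graph.edges(data=True)]
        pd.DataFrame(rows, columns=["gene1", "gene2", "edge_weight"]).to_csv(
            edgelist_path, sep="\t", index=False)
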