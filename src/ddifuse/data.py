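"""Domain types and file I/O shared by every pipeline stage.

The drug catalog fixes the row/column order of every matrix in the pipeline;
drug identity is always the string id, never a bare index. All delimited files
are UTF-8, comma- or tab-separated (sniffed), with a header row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ddifuse")

#: the four binary-descriptor feature spaces, in canonical order
FEATURE_SOURCES = ("struct", "target", "pathway", "enzyme")

#: WHO ATC code: letter, two digits, two letters, two digits (e.g. B01AC06)
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table with a sniffed comma/tab separator."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


@dataclass(frozen=True)
class DrugCatalog:
    """Ordered set of drug identifiers; the single source of matrix indexing."""

    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.drug_ids) == 0:
            raise ValueError("catalog must contain at least one drug")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug ids must be unique")
        if any(not d for d in self.drug_ids):
            raise ValueError("drug ids must be nonempty strings")
        object.__setattr__(self, "_index", {d: i for i, d in enumerate(self.drug_ids)})

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    def index_of(self, drug_id: str) -> int:
        try:
            return self._index[drug_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"drug id {drug_id!r} not in catalog") from None

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return self.m


@dataclass
class FeatureMatrix:
    """Binary drugs x descriptors matrix for one feature source."""

    source_name: str
    values: np.ndarray  # (m, w) of {0,1}
    descriptor_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {self.values[i, j]!r} at drug "
                f"{self.drug_ids[i]!r}, descriptor {self.descriptor_ids[j]!r}"
            )
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.drug_ids), len(self.descriptor_ids)):
            raise ValueError("feature matrix shape does not match its labels")


@dataclass
class ATCTable:
    """Mapping drug id -> set of 7-character ATC codes (possibly empty)."""

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for drug, codes in self.entries.items():
            for code in codes:
                if not ATC_PATTERN.match(code):
                    raise ValueError(f"malformed ATC code {code!r} for drug {drug!r}")

    def codes_for(self, drug_id: str) -> frozenset[str]:
        return self.entries.get(drug_id, frozenset())


@dataclass
class DDITable:
    """Labeled unordered drug pairs with contiguous integer type labels."""

    pairs: list[tuple[str, str, int]]
    type_names: tuple[str, ...]

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def as_arrays(self, catalog: DrugCatalog) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (index_a, index_b, label) arrays aligned to the catalog."""
        ia = np.array([catalog.index_of(a) for a, _, _ in self.pairs], dtype=np.int64)
        ib = np.array([catalog.index_of(b) for _, b, _ in self.pairs], dtype=np.int64)
        y = np.array([t for _, _, t in self.pairs], dtype=np.int64)
        return ia, ib, y

    def pair_keys(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.pairs}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MDAConfig:
    """Hyperparameters of the multimodal-autoencoder feature extractor."""

    lr: float = 0.01
    epochs: int = 80
    dropout: float = 0.0
    batch_size: int = 64
    embed_dim: int = 256          # per-network encoder width d_j
    unified_dim: int = 640        # bottleneck width d_u
    integration_layers: int = 1   # L: shared layers on each side of the bottleneck


@dataclass
class DNNConfig:
    """Hyperparameters of the softmax interaction-type classifier."""

    lr: float = 0.001
    epochs: int = 100
    dropout: float = 0.2
    batch_size: int = 128
    hidden_dims: tuple[int, ...] = (640, 320, 160)
    patience: int = 10
    val_fraction: float = 0.1


@dataclass
class CVConfig:
    folds: int = 5
    scene: str = "S1"
    seed: int = 0


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults are the published optimum."""

    alpha: float = 0.8      # RWR restart probability
    epsilon: float = 1e-9   # RWR L1 convergence tolerance
    mda: MDAConfig = field(default_factory=MDAConfig)
    dnn: DNNConfig = field(default_factory=DNNConfig)
    operator: str = "concat"
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for dim in (self.mda.embed_dim, self.mda.unified_dim, *self.dnn.hidden_dims):
            if dim <= 0:
                raise ValueError("layer dimensions must be positive")
        if self.cv.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")

    @classmethod
    def test_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Small-network configuration sized for the bundled synthetic benchmark."""
        return cls(
            mda=MDAConfig(embed_dim=16, unified_dim=32, batch_size=32),
            dnn=DNNConfig(hidden_dims=(64, 32)),
            cv=CVConfig(seed=seed),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        mda = MDAConfig(**d.pop("mda", {}))
        dnn_d = dict(d.pop("dnn", {}))
        if "hidden_dims" in dnn_d:
            dnn_d["hidden_dims"] = tuple(dnn_d["hidden_dims"])
        dnn = DNNConfig(**dnn_d)
        cv = CVConfig(**d.pop("cv", {}))
        return cls(mda=mda, dnn=dnn, cv=cv, **d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# readers


def load_catalog(path: str | Path) -> DrugCatalog:
    """Read a one-column drug-id file (header row required)."""
    df = _read_table(path)
    return DrugCatalog(tuple(df.iloc[:, 0].astype(str)))


def load_drug_features(
    path: str | Path, source_name: str, catalog: DrugCatalog
) -> FeatureMatrix:
    """Load one binary feature space, aligned to the catalog order.

    Accepts either a dense table (first column drug_id, remaining columns 0/1)
    or a sparse two-column (drug_id, descriptor_id) pair list. Catalog drugs
    absent from the file get all-zero rows with a logged warning.
    """
    df = _read_table(path)
    # a two-column file whose second column holds no 0/1 values is a pair list
    sparse = df.shape[1] == 2 and not set(df.iloc[:, 1].unique()) & {"0", "1"}
    if sparse:
        descriptor_ids = tuple(sorted(set(df.iloc[:, 1])))
        col = {s: j for j, s in enumerate(descriptor_ids)}
        values = np.zeros((catalog.m, len(descriptor_ids)), dtype=np.int8)
        seen = set()
        for drug, desc in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if drug not in catalog:
                raise ValueError(f"unknown drug id {drug!r} in {path}")
            values[catalog.index_of(drug), col[desc]] = 1
            seen.add(drug)
    else:
        drugs = df.iloc[:, 0].astype(str)
        dup = drugs[drugs.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate drug rows in {path}: {sorted(set(dup))}")
        descriptor_ids = tuple(df.columns[1:])
        values = np.zeros((catalog.m, len(descriptor_ids)), dtype=np.int8)
        seen = set()
        for _, row in df.iterrows():
            drug = row.iloc[0]
            if drug not in catalog:
                raise ValueError(f"unknown drug id {drug!r} in {path}")
            for j, cell in enumerate(row.iloc[1:]):
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"non-binary cell {cell!r} at drug {drug!r}, "
                        f"column {descriptor_ids[j]!r} in {path}"
                    )
                values[catalog.index_of(drug), j] = int(cell)
            seen.add(drug)
    missing = [d for d in catalog.drug_ids if d not in seen]
    if missing:
        logger.warning(
            "%s: %d catalog drugs have no %s annotations (all-zero rows): %s",
            path, len(missing), source_name, missing[:10],
        )
    return FeatureMatrix(source_name, values, descriptor_ids, catalog.drug_ids)


def load_atc_codes(path: str | Path) -> ATCTable:
    """Read a (drug_id, atc_code) pair list."""
    df = _read_table(path)
    entries: dict[str, set[str]] = {}
    for drug, code in zip(df.iloc[:, 0], df.iloc[:, 1]):
        entries.setdefault(str(drug), set()).add(str(code))
    return ATCTable({d: frozenset(c) for d, c in entries.items()})


def load_ddi_table(path: str | Path, catalog: DrugCatalog) -> DDITable:
    """Read a (drug_a, drug_b, type_name) table.

    Type names are mapped to contiguous integers in first-appearance order,
    unless a ``<path>.labels.json`` sidecar (written by ``save_ddi_table``)
    pins the mapping, which keeps labels stable across save/load round
    trips. Self-interactions and unordered pairs carrying two distinct types
    are rejected; exact duplicates collapse to one entry.
    """
    df = _read_table(path)
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    type_ids: dict[str, int] = {}
    if sidecar.exists():
        type_ids = {str(k): int(v) for k, v in json.loads(sidecar.read_text()).items()}
    seen: dict[frozenset[str], tuple[str, str, int]] = {}
    for a, b, name in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        a, b, name = str(a), str(b), str(name)
        if a == b:
            raise ValueError(f"self-interaction ({a!r}, {b!r}) is not allowed")
        for d in (a, b):
            if d not in catalog:
                raise ValueError(f"unknown drug id {d!r} in {path}")
        t = type_ids.setdefault(name, len(type_ids))
        key = frozenset((a, b))
        if key in seen and seen[key][2] != t:
            raise ValueError(
                f"conflicting type for unordered pair ({a!r}, {b!r}): "
                f"label {seen[key][2]} vs {name!r}"
            )
        seen.setdefault(key, (a, b, t))
    names = tuple(sorted(type_ids, key=type_ids.get))
    return DDITable(list(seen.values()), names)


def save_ddi_table(ddis: DDITable, path: str | Path) -> None:
    """Write pairs with type names; the label map goes to a JSON sidecar."""
    path = Path(path)
    rows = [(a, b, ddis.type_names[t]) for a, b, t in ddis.pairs]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "type"]).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    sidecar.write_text(json.dumps({n: i for i, n in enumerate(ddis.type_names)}, indent=2))


# ---------------------------------------------------------------------------
# labeled-matrix round trip


def save_matrix(values: np.ndarray, drug_ids: Sequence[str], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write an m x k real matrix with drug-id row labels as CSV."""
    if columns is None:
        n = np.asarray(values).shape[1]
        columns = list(drug_ids) if n == len(drug_ids) else [f"c{i}" for i in range(n)]
    df = pd.DataFrame(np.asarray(values), index=list(drug_ids), columns=list(columns))
    df.to_csv(path, index_label="drug_id")


def load_matrix(path: str | Path, catalog: DrugCatalog) -> np.ndarray:
    """Read a labeled matrix and reorder its rows to the catalog order.

    If the columns are also drug ids (a square drug-drug matrix), columns are
    reordered too. Missing catalog drugs are an error.
    """
    df = pd.read_csv(path, index_col="drug_id")
    df.index = df.index.astype(str)
    missing = [d for d in catalog.drug_ids if d not in df.index]
    if missing:
        raise ValueError(f"{path} is missing catalog drugs: {missing}")
    df = df.loc[list(catalog.drug_ids)]
    if set(df.columns) == set(catalog.drug_ids):
        df = df[list(catalog.drug_ids)]
    return df.to_numpy(dtype=float)


def save_catalog(catalog: DrugCatalog, path: str | Path) -> None:
    pd.DataFrame({"drug_id": list(catalog.drug_ids)}).to_csv(path, index=False)
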