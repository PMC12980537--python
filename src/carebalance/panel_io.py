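"""District-year panel data model, tabular readers/writers and spatial weights I/O.

The panel holds one record per (district, year): land area, aging indicators
(older-population coefficient in percent, older-population density in
persons/km²), optional per-capita disposable income, per-thousand care-resource
indicators, and optional pre-computed composite demand/resource scores in [0, 1].

Spatial weights are read from GAL files (GeoDa/PySAL dialect) or from a
3-column edge list; both produce the same matrix for the same graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DistrictRecord",
    "DistrictPanel",
    "SpatialWeights",
    "SchemaError",
    "PanelValidationError",
    "WeightsParseError",
    "read_panel",
    "write_panel",
    "read_weights_gal",
    "read_weights_edgelist",
    "load_fixture",
    "load_fixture_frame",
    "FIXTURE_TABLES",
]


class SchemaError(ValueError):
    """A mandatory column is missing or a config cannot be interpreted."""


class PanelValidationError(ValueError):
    """A record or panel violates a data-model invariant."""


class WeightsParseError(ValueError):
    """A spatial weights file cannot be parsed against the given labels."""


# Canonical field names accepted by read_panel; anything else that is numeric
# is routed into resource_indicators.
_SCALAR_FIELDS = (
    "aging_coefficient",
    "aging_density",
    "income_per_capita",
    "demand_score",
    "resource_score",
)
_MANDATORY = ("district", "year", "area_km2")


def _canon(label: str) -> str:
    """Case-insensitive, trimmed district-label key."""
    return str(label).strip().casefold()


@dataclass
class DistrictRecord:
    """One district-year observation.

    Optional numerics are ``None`` when absent — never 0 — so that downstream
    share computations are not silently distorted.
    """

    district: str
    year: int
    area_km2: float
    aging_coefficient: float | None = None
    aging_density: float | None = None
    income_per_capita: float | None = None
    resource_indicators: dict[str, float] = field(default_factory=dict)
    demand_score: float | None = None
    resource_score: float | None = None

    def __post_init__(self) -> None:
        self.district = str(self.district).strip()
        self.year = int(self.year)
        ctx = f"district={self.district!r}, year={self.year}"
        if not np.isfinite(self.area_km2) or self.area_km2 <= 0:
            raise PanelValidationError(f"area_km2 must be positive ({ctx})")
        if self.aging_coefficient is not None and not (
            0 <= self.aging_coefficient <= 100
        ):
            raise PanelValidationError(
                f"aging_coefficient must lie in [0, 100] ({ctx})"
            )
        if self.aging_density is not None and self.aging_density < 0:
            raise PanelValidationError(f"aging_density must be >= 0 ({ctx})")
        if self.income_per_capita is not None and self.income_per_capita <= 0:
            raise PanelValidationError(f"income_per_capita must be > 0 ({ctx})")
        for name in ("demand_score", "resource_score"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise PanelValidationError(f"{name} must lie in [0, 1] ({ctx})")
        for code, v in self.resource_indicators.items():
            if v < 0:
                raise PanelValidationError(
                    f"resource indicator {code!r} must be >= 0 ({ctx})"
                )


@dataclass
class DistrictPanel:
    """Ordered collection of district-year records with a canonical district order."""

    records: list[DistrictRecord]
    district_order: list[str]

    def __post_init__(self) -> None:
        seen = set()
        order_keys = {_canon(d) for d in self.district_order}
        for r in self.records:
            key = (_canon(r.district), r.year)
            if key in seen:
                raise PanelValidationError(
                    f"duplicate (district, year) pair: ({r.district}, {r.year})"
                )
            seen.add(key)
            if _canon(r.district) not in order_keys:
                raise PanelValidationError(
                    f"district {r.district!r} missing from district_order"
                )
        for year in self.years():
            if len(self.year_slice(year)) < 2:
                raise PanelValidationError(
                    f"year {year} has fewer than 2 districts"
                )

    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def year_slice(self, year: int) -> list[DistrictRecord]:
        """Records for one year, in canonical district order."""
        by_key = {_canon(r.district): r for r in self.records if r.year == year}
        return [by_key[_canon(d)] for d in self.district_order if _canon(d) in by_key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "district": r.district,
                "year": r.year,
                "area_km2": r.area_km2,
            }
            for name in _SCALAR_FIELDS:
                v = getattr(r, name)
                if v is not None:
                    row[name] = v
            row.update(r.resource_indicators)
            rows.append(row)
        df = pd.DataFrame(rows)
        key = df["district"].map(_canon)
        pos = {_canon(d): i for i, d in enumerate(self.district_order)}
        return (
            df.assign(_pos=key.map(pos))
            .sort_values(["year", "_pos"], kind="stable")
            .drop(columns="_pos")
            .reset_index(drop=True)
        )


def _load_schema(schema) -> dict[str, str]:
    """Column mapping: file column -> canonical field name."""
    if schema is None:
        return {}
    if isinstance(schema, Mapping):
        return dict(schema)
    path = Path(schema)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _frame_to_panel(df: pd.DataFrame, district_order: Sequence[str] | None = None) -> DistrictPanel:
    known = set(_MANDATORY) | set(_SCALAR_FIELDS)
    indicator_cols = [c for c in df.columns if c not in known]
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _SCALAR_FIELDS:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        indicators = {
            c: float(row[c]) for c in indicator_cols if pd.notna(row[c])
        }
        records.append(
            DistrictRecord(
                district=row["district"],
                year=int(row["year"]),
                area_km2=float(row["area_km2"]),
                resource_indicators=indicators,
                **kwargs,
            )
        )
    if district_order is None:
        district_order = list(dict.fromkeys(r.district for r in records))
    return DistrictPanel(records=records, district_order=list(district_order))


def read_panel(source, schema=None) -> DistrictPanel:
    """Read a district panel from CSV (header row) or JSON records.

    ``schema`` maps file column names to canonical field names
    (``district``, ``year``, ``area_km2``, ``aging_coefficient``,
    ``aging_density``, ``income_per_capita``, ``demand_score``,
    ``resource_score``); it may be a mapping or a path to a YAML/JSON file.
    Unmapped extra numeric columns become per-thousand resource indicators.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = _load_schema(schema)
    try:
        if path.suffix.lower() == ".json":
            df = pd.read_json(path, orient="records", precise_float=True)
        else:
            df = pd.read_csv(path)
    except (ValueError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"{path} contains no records")
    df = df.rename(columns=mapping)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            "missing mandatory column(s): " + ", ".join(missing)
        )
    return _frame_to_panel(df)


def write_panel(panel: DistrictPanel, dest) -> Path:
    """Write a panel to CSV or JSON (by extension); round-trips numerics."""
    path = Path(dest)
    df = panel.to_frame()
    if path.suffix.lower() == ".json":
        records = [
            {k: v for k, v in rec.items() if not (isinstance(v, float) and pd.isna(v))}
            for rec in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(records))  # repr floats: exact round-trip
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Spatial weights


@dataclass
class SpatialWeights:
    """Nonnegative weight matrix over labelled districts, zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if W.shape != (n, n):
            raise WeightsParseError(
                f"weight matrix shape {W.shape} does not match {n} labels"
            )
        if np.any(np.diag(W) != 0):
            raise WeightsParseError("weight matrix must have a zero diagonal")
        if np.any(W < 0):
            raise WeightsParseError("weights must be nonnegative")
        if W.sum() <= 0:
            raise WeightsParseError("weight matrix must have positive total weight")
        self.matrix = W

    @property
    def n(self) -> int:
        return len(self.labels)

    def row_standardized(self) -> "SpatialWeights":
        """Each row divided by its row sum (rows with no neighbors left zero)."""
        W = self.matrix.copy()
        rs = W.sum(axis=1, keepdims=True)
        np.divide(W, rs, out=W, where=rs > 0)
        return SpatialWeights(labels=list(self.labels), matrix=W)

    def align(self, labels: Iterable[str]) -> "SpatialWeights":
        """Reorder to the given label sequence (case-insensitive match)."""
        pos = {_canon(l): i for i, l in enumerate(self.labels)}
        try:
            idx = [pos[_canon(l)] for l in labels]
        except KeyError as exc:
            raise WeightsParseError(f"label {exc.args[0]!r} not in weights") from exc
        return SpatialWeights(
            labels=[self.labels[i] for i in idx],
            matrix=self.matrix[np.ix_(idx, idx)],
        )


def read_weights_gal(source, labels: Sequence[str] | None = None) -> SpatialWeights:
    """Read a GAL contiguity file (header count, then 'label k' + neighbor lines).

    Both the bare-count header and GeoDa's 4-token header are accepted. If
    ``labels`` is given, every node and neighbor must resolve to it
    (case-insensitively) and the output follows that ordering.
    """
    lines = [
        ln.strip()
        for ln in Path(source).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("!")
    ]
    if not lines:
        raise WeightsParseError("empty GAL file")
    header = lines[0].split()
    # "n" or GeoDa "0 n shapefile idvar"
    n_declared = int(header[1] if len(header) >= 2 else header[0])
    body = lines[1:]
    if len(body) % 2 != 0:
        raise WeightsParseError("GAL body must alternate node and neighbor lines")
    names: list[str] = []
    neighbor_lists: list[list[str]] = []
    for i in range(0, len(body), 2):
        head = body[i].split()
        name, k = " ".join(head[:-1]), int(head[-1])
        nbrs = body[i + 1].split() if k > 0 else []
        if len(nbrs) != k:
            raise WeightsParseError(
                f"node {name!r} declares {k} neighbors, lists {len(nbrs)}"
            )
        names.append(name)
        neighbor_lists.append(nbrs)
    if len(names) != n_declared:
        raise WeightsParseError(
            f"GAL header declares {n_declared} nodes, body has {len(names)}"
        )
    if labels is None:
        labels = names
    elif len(labels) != n_declared:
        raise WeightsParseError(
            f"GAL header count {n_declared} does not match {len(labels)} labels"
        )
    pos = {_canon(l): i for i, l in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for name, nbrs in zip(names, neighbor_lists):
        if _canon(name) not in pos:
            raise WeightsParseError(f"GAL node {name!r} not in labels")
        i = pos[_canon(name)]
        for nb in nbrs:
            if _canon(nb) not in pos:
                raise WeightsParseError(f"GAL neighbor {nb!r} not in labels")
            j = pos[_canon(nb)]
            if i == j:
                raise WeightsParseError(f"self-neighbor for node {name!r}")
            W[i, j] = 1.0
    return SpatialWeights(labels=list(labels), matrix=W)


def read_weights_edgelist(source, labels: Sequence[str] | None = None) -> SpatialWeights:
    """Read an undirected 3-column (i, j, w) CSV edge list.

    Each edge is applied in both directions, so a one-line-per-edge file
    yields the same symmetric matrix as the equivalent GAL file.
    """
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise WeightsParseError("edge list needs at least 2 columns (i, j[, w])")
    cols = list(df.columns)
    i_col, j_col = cols[0], cols[1]
    w_col = cols[2] if len(cols) > 2 else None
    if labels is None:
        labels = list(
            dict.fromkeys(
                [str(v).strip() for v in pd.concat([df[i_col], df[j_col]])]
            )
        )
    pos = {_canon(l): i for i, l in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for _, row in df.iterrows():
        a, b = str(row[i_col]).strip(), str(row[j_col]).strip()
        if _canon(a) not in pos or _canon(b) not in pos:
            missing = a if _canon(a) not in pos else b
            raise WeightsParseError(f"edge-list label {missing!r} not in labels")
        i, j = pos[_canon(a)], pos[_canon(b)]
        if i == j:
            raise WeightsParseError(f"self-edge for {a!r}")
        w = float(row[w_col]) if w_col is not None else 1.0
        W[i, j] = w
        W[j, i] = w
    return SpatialWeights(labels=list(labels), matrix=W)


# ---------------------------------------------------------------------------
# Packaged fixture tables (printed district tables, 4-decimal fidelity)

FIXTURE_TABLES = {
    "T3": "t3_aging.csv",
    "T5": "t5_demand_scores.csv",
    "T6": "t6_resource_scores.csv",
    "T7": "t7_concentration.csv",
}

#: Canonical printed district order shared by all fixture tables.
DISTRICT_ORDER = [
    "Liwan", "Yuexiu", "Haizhu", "Tianhe", "Baiyun", "Huangpu",
    "Panyu", "Huadu", "Nansha", "Conghua", "Zengcheng",
]


def load_fixture_frame(table_id: str) -> pd.DataFrame:
    """Raw fixture table as a DataFrame with every printed column."""
    key = table_id.upper().strip()
    if key not in FIXTURE_TABLES:
        raise KeyError(
            f"unknown fixture table {table_id!r}; available: {sorted(FIXTURE_TABLES)}"
        )
    ref = resources.files("carebalance.fixtures") / FIXTURE_TABLES[key]
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_fixture(table_id: str) -> DistrictPanel:
    """Packaged fixture table as a validated district panel.

    T3 → aging coefficient/density panel (2015, 2019, 2023).
    T5 → demand composite scores per year.
    T6 → resource composite scores (2023) with sub-dimension indicators.
    T7 → demand/resource scores and areas (2023); the printed concentration
    columns are available through :func:`load_fixture_frame`.
    """
    df = load_fixture_frame(table_id)
    key = table_id.upper().strip()
    areas = dict(
        zip(load_fixture_frame("T7")["district"], load_fixture_frame("T7")["area_km2"])
    )
    if key == "T3":
        return _frame_to_panel(df, district_order=DISTRICT_ORDER)
    if key == "T5":
        long = df.melt(
            id_vars=["district"],
            value_vars=["score_2015", "score_2019", "score_2023"],
            var_name="year",
            value_name="demand_score",
        )
        long["year"] = long["year"].str.removeprefix("score_").astype(int)
        long["area_km2"] = long["district"].map(areas)
        return _frame_to_panel(
            long[["district", "year", "area_km2", "demand_score"]],
            district_order=DISTRICT_ORDER,
        )
    if key == "T6":
        out = df.rename(columns={"composite": "resource_score"}).drop(columns="rank")
        out["year"] = 2023
        out["area_km2"] = out["district"].map(areas)
        return _frame_to_panel(out, district_order=DISTRICT_ORDER)
    # T7
    out = df[["district", "demand_score", "resource_score", "area_km2"]].copy()
    out["year"] = 2023
    return _frame_to_panel(out, district_order=DISTRICT_ORDER)
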