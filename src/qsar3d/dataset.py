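"""Compound registry, endpoint tables and log transforms.

The package ships three toxicity endpoint tables for a set of phthalate
diesters (PAEs):

* ``LD50`` — acute oral rat LD50 in mg/kg, modeled as lg(LD50),
* ``IC50_72h`` — 72-hour HepG2 IC50 in uM, modeled as lg(IC50),
* ``Nrf2`` — relative Nrf2 protein content (dimensionless), modeled as-is.

Each table carries the raw value, the transformed modeling value, the
train/test role, and the published model predictions/residuals used by the
regression-test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CompoundRecord",
    "EndpointTable",
    "PAEDataset",
    "DatasetError",
    "ENDPOINTS",
    "load_registry",
    "load_endpoint_table",
    "load_pae_dataset",
    "load_printed_predictions",
    "inconsistent_residual_rows",
    "lg_transform",
    "residual",
]

#: endpoint name -> (data file, transform)
ENDPOINTS: Mapping[str, tuple[str, str]] = {
    "LD50": ("ld50.csv", "log10"),
    "IC50_72h": ("ic50_72h.csv", "log10"),
    "Nrf2": ("nrf2.csv", "identity"),
}

_REGISTRY_FILE = "compounds.tsv"


class DatasetError(RuntimeError):
    """Raised when packaged data files are missing or malformed."""


@dataclass(frozen=True)
class CompoundRecord:
    """One phthalate ester: identity, structure and endpoint values."""

    abbrev: str
    full_name: str
    smiles: str
    endpoints: dict[str, float] = field(default_factory=dict)


@dataclass
class EndpointTable:
    """Per-compound endpoint values with the modeling transform applied.

    ``frame`` columns: ``abbrev``, ``raw_value``, ``transformed_value``,
    ``role`` (``train`` | ``test``).
    """

    endpoint: str
    transform: str  # "log10" | "identity"
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"abbrev", "raw_value", "transformed_value", "role"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DatasetError(f"endpoint table missing columns: {sorted(missing)}")
        roles = set(self.frame["role"])
        if not roles <= {"train", "test"}:
            raise DatasetError(f"unknown roles in endpoint table: {roles}")

    @property
    def train(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "train"].reset_index(drop=True)

    @property
    def test(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "test"].reset_index(drop=True)

    def values_for(self, abbrevs: list[str]) -> pd.Series:
        indexed = self.frame.set_index("abbrev")["transformed_value"]
        return indexed.loc[abbrevs]

    def to_csv(self, path: str | Path) -> None:
        cols = ["abbrev", "raw_value", "transformed_value", "role"]
        self.frame[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str, transform: str) -> "EndpointTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls(endpoint=endpoint, transform=transform, frame=frame)


@dataclass
class PAEDataset:
    """Registry of compounds plus the three endpoint tables."""

    registry: dict[str, CompoundRecord]
    tables: dict[str, EndpointTable]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "compounds": {
                a: {"full_name": c.full_name, "smiles": c.smiles, "endpoints": c.endpoints}
                for a, c in self.registry.items()
            },
            "tables": {
                name: t.frame.to_dict(orient="records") for name, t in self.tables.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def lg_transform(raw: float) -> float:
    """Base-10 log of a positive raw endpoint value.

    Raises ``ValueError`` for non-positive input. Full precision is
    returned; round to 4 decimals for display.
    """
    if not math.isfinite(raw) or raw <= 0:
        raise ValueError(f"lg transform requires a positive finite value, got {raw!r}")
    return math.log10(raw)


def residual(exp: float, pred: float) -> float:
    """Signed residual: experimental minus predicted value."""
    if not (math.isfinite(exp) and math.isfinite(pred)):
        raise ValueError("residual requires finite values")
    return exp - pred


def _data_path(name: str):
    ref = resources.files("qsar3d.data").joinpath(name)
    if not ref.is_file():
        raise DatasetError(f"packaged data file not found: {name}")
    return ref


def load_registry() -> dict[str, CompoundRecord]:
    """Load the compound registry (abbrev, full name, SMILES)."""
    with resources.as_file(_data_path(_REGISTRY_FILE)) as path:
        frame = pd.read_csv(path, sep="\t")
    records: dict[str, CompoundRecord] = {}
    for row in frame.itertuples(index=False):
        if row.abbrev in records:
            raise DatasetError(f"duplicate abbrev in registry: {row.abbrev}")
        records[row.abbrev] = CompoundRecord(
            abbrev=row.abbrev, full_name=row.full_name, smiles=row.smiles
        )
    return records


def _read_endpoint_file(endpoint: str) -> pd.DataFrame:
    try:
        fname, _ = ENDPOINTS[endpoint]
    except KeyError:
        raise DatasetError(f"unknown endpoint {endpoint!r}; expected one of {list(ENDPOINTS)}")
    with resources.as_file(_data_path(fname)) as path:
        return pd.read_csv(path, dtype={"exp_printed": str})


def load_endpoint_table(endpoint: str) -> EndpointTable:
    """Build an :class:`EndpointTable` for one endpoint from packaged data."""
    raw = _read_endpoint_file(endpoint)
    _, transform = ENDPOINTS[endpoint]
    if transform == "log10":
        transformed = raw["raw_value"].map(lg_transform)
    else:
        transformed = raw["raw_value"].astype(float)
    frame = pd.DataFrame(
        {
            "abbrev": raw["abbrev"],
            "raw_value": raw["raw_value"].astype(float),
            "transformed_value": transformed,
            "role": raw["role"],
        }
    )
    return EndpointTable(endpoint=endpoint, transform=transform, frame=frame)


def load_printed_predictions(endpoint: str) -> pd.DataFrame:
    """Published prediction table for one endpoint.

    Columns: ``abbrev``, ``raw_value``, ``exp`` (printed transformed value),
    ``exp_decimals`` (precision of the printed value), ``role`` and, per
    published model, ``<model>_pred`` / ``<model>_res``.
    """
    raw = _read_endpoint_file(endpoint)
    printed = raw["exp_printed"]
    out = pd.DataFrame(
        {
            "abbrev": raw["abbrev"],
            "raw_value": raw["raw_value"].astype(float),
            "exp": printed.astype(float),
            "exp_decimals": printed.map(lambda s: len(s.split(".")[1]) if "." in s else 0),
            "role": raw["role"],
        }
    )
    for model in ("comfa", "comsia"):
        if f"{model}_pred" in raw.columns:
            out[f"{model}_pred"] = raw[f"{model}_pred"].astype(float)
            out[f"{model}_res"] = raw[f"{model}_res"].astype(float)
    return out


def inconsistent_residual_rows(
    predictions: pd.DataFrame, tol: float = 1e-4
) -> list[tuple[str, str]]:
    """Rows of a printed prediction table where exp - pred != printed residual.

    Returns ``(model, abbrev)`` pairs whose recomputed residual deviates from
    the printed one by more than ``tol``. These are data-quality flags on the
    published tables; no correction is applied.
    """
    flagged: list[tuple[str, str]] = []
    for model in ("comfa", "comsia"):
        if f"{model}_pred" not in predictions.columns:
            continue
        for row in predictions.itertuples(index=False):
            recomputed = residual(row.exp, getattr(row, f"{model}_pred"))
            printed = getattr(row, f"{model}_res")
            if abs(recomputed - printed) > tol + 1e-12:
                flagged.append((model, row.abbrev))
    return flagged


def load_pae_dataset() -> PAEDataset:
    """Load the full packaged dataset: registry + all three endpoint tables.

    Every compound referenced by an endpoint table must exist in the
    registry; endpoint values are attached to the compound records.
    """
    registry = load_registry()
    tables: dict[str, EndpointTable] = {}
    endpoints_by_compound: dict[str, dict[str, float]] = {a: {} for a in registry}
    for endpoint in ENDPOINTS:
        table = load_endpoint_table(endpoint)
        for row in table.frame.itertuples(index=False):
            if row.abbrev not in registry:
                raise DatasetError(
                    f"compound {row.abbrev!r} in {endpoint} table missing from registry"
                )
            endpoints_by_compound[row.abbrev][endpoint] = float(row.raw_value)
        tables[endpoint] = table
    enriched = {
        a: CompoundRecord(a, rec.full_name, rec.smiles, endpoints_by_compound[a])
        for a, rec in registry.items()
    }
    return PAEDataset(registry=enriched, tables=tables)
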