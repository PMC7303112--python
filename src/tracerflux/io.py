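"""CSV schemas, validated dataset loading and pipeline configuration.

Dialect is fixed: comma separator, header row, UTF-8, period decimal
separator, empty string = missing.  Units are encoded in column-name
suffixes (_um, _l, _h, _mol, _ml, _g, _d); no unit inference is performed.
Output files carry a provenance header of '#'-prefixed comment lines
(package version, config hash, constants in force) and are read back with
``comment='#'``.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constants import IsotopeConstants
from .errors import ConfigError, LinkError, SchemaError

SPECIMEN_COLUMNS = [
    "id", "taxon", "volume_ml", "tissue_oc_mol", "dry_mass_g",
    "tissue_delta13c", "background_delta13c", "is_background",
    "substrate_batch_id", "feeding_hours",
]
BATCH_COLUMNS = ["id", "kind", "carbon_concentration_um", "atom_fraction"]
INCUBATION_COLUMNS = [
    "chamber_id", "specimen_id", "role", "group", "chamber_volume_l",
    "duration_h", "dic_start_um", "dic_end_um", "dic_d13c_start",
    "dic_d13c_end", "doc_start_um", "doc_end_um", "poc_start_um",
    "poc_end_um", "poc_d13c_start", "poc_d13c_end", "start_strategy",
    "refill_volume_l", "refill_dic_um", "refill_doc_um", "refill_poc_um",
]
O2_COLUMNS = ["chamber_id", "time_h", "o2_um"]
FOODCHAIN_COLUMNS = ["cycle", "pool", "organism_ids", "excess_13c_umol", "period_d"]

_SCHEMAS = {
    "specimens": SPECIMEN_COLUMNS,
    "batches": BATCH_COLUMNS,
    "incubations": INCUBATION_COLUMNS,
    "o2_series": O2_COLUMNS,
    "foodchain": FOODCHAIN_COLUMNS,
}


@dataclass
class PipelineConfig:
    """Configuration in force for one pipeline run.

    ``background_strategy`` selects the isotopic background of the DIC/POC
    tracer fluxes: "chamber_start" (the chamber's own start sample, which
    controls for enrichment carried over from feeding; default) or
    "unfed_background" (taxon-level unfed-conspecific background).
    """

    constants: IsotopeConstants = field(default_factory=IsotopeConstants)
    log_base: str = "10"
    background_strategy: str = "chamber_start"
    dunn_adjust: str = "holm"
    alpha: float = 0.05
    o2_saturation_min: float | None = None
    feeding_volume_l: float = 4.8

    def __post_init__(self) -> None:
        if self.log_base not in ("10", "e"):
            raise ConfigError(f"log_base must be '10' or 'e', got {self.log_base!r}")
        if self.background_strategy not in ("chamber_start", "unfed_background"):
            raise ConfigError(
                f"unknown background_strategy {self.background_strategy!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {
            "constants", "log_base", "background_strategy", "dunn_adjust",
            "alpha", "o2_saturation_min", "feeding_volume_l",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        kwargs["constants"] = IsotopeConstants.from_mapping(raw.get("constants"))
        return cls(**kwargs)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> list[str]:
        c = self.constants
        return [
            f"tracerflux {__version__}",
            f"config_hash={self.digest()}",
            f"r_vpdb={c.r_vpdb} respiratory_quotient={c.respiratory_quotient}",
            f"log_base={self.log_base} background_strategy={self.background_strategy} "
            f"dunn_adjust={self.dunn_adjust}",
        ]


def write_table(
    frame: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> Path:
    """Write a CSV with a '#'-comment provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (config or PipelineConfig()).provenance()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (or a plain CSV)."""
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


@dataclass
class Dataset:
    """Validated input tables for one analysis."""

    specimens: pd.DataFrame
    batches: pd.DataFrame
    incubations: pd.DataFrame
    o2_series: pd.DataFrame
    foodchain: pd.DataFrame | None = None
    validation_report: list[str] = field(default_factory=list)


def _require_columns(frame: pd.DataFrame, name: str, path: str) -> None:
    missing = [c for c in _SCHEMAS[name] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} in table '{name}'")


def _as_str(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip()


def validate_dataset(
    specimens: pd.DataFrame,
    batches: pd.DataFrame,
    incubations: pd.DataFrame,
    o2_series: pd.DataFrame,
    foodchain: pd.DataFrame | None = None,
    paths: dict[str, str] | None = None,
) -> Dataset:
    """Cross-validate the input tables and resolve references.

    Raises :class:`SchemaError` for malformed rows (file, row and column
    named) and :class:`LinkError` for dangling references; collects
    non-fatal observations in ``validation_report``.
    """
    paths = paths or {}
    report: list[str] = []
    for name, frame in (
        ("specimens", specimens), ("batches", batches),
        ("incubations", incubations), ("o2_series", o2_series),
    ):
        _require_columns(frame, name, paths.get(name, name))
    if foodchain is not None:
        _require_columns(foodchain, "foodchain", paths.get("foodchain", "foodchain"))

    specimens = specimens.copy()
    specimens["is_background"] = specimens["is_background"].astype(bool)
    specimens["substrate_batch_id"] = _as_str(specimens["substrate_batch_id"])
    spec_ids = set(_as_str(specimens["id"]))
    batch_ids = set(_as_str(batches["id"]))

    spath = paths.get("specimens", "specimens")
    for idx, row in specimens.iterrows():
        if row["is_background"]:
            if row["substrate_batch_id"]:
                raise SchemaError(
                    f"{spath}, row {idx}, column substrate_batch_id: background "
                    f"specimen {row['id']} must not reference a batch"
                )
        else:
            if not row["substrate_batch_id"]:
                raise LinkError(
                    f"{spath}, row {idx}: fed specimen {row['id']} has no "
                    "substrate_batch_id"
                )
            if row["substrate_batch_id"] not in batch_ids:
                raise LinkError(
                    f"{spath}, row {idx}: substrate_batch_id "
                    f"{row['substrate_batch_id']!r} not found in batches"
                )

    incubations = incubations.copy()
    incubations["specimen_id"] = _as_str(incubations["specimen_id"])
    ipath = paths.get("incubations", "incubations")
    for idx, row in incubations.iterrows():
        role = str(row["role"]).strip()
        if role not in ("animal", "control"):
            raise SchemaError(
                f"{ipath}, row {idx}, column role: expected 'animal' or "
                f"'control', got {role!r}"
            )
        if role == "control" and row["specimen_id"]:
            raise SchemaError(
                f"{ipath}, row {idx}, column specimen_id: control chamber "
                f"{row['chamber_id']} must not name a specimen"
            )
        if role == "animal":
            if not row["specimen_id"]:
                raise LinkError(
                    f"{ipath}, row {idx}: animal chamber {row['chamber_id']} "
                    "has no specimen_id"
                )
            if row["specimen_id"] not in spec_ids:
                raise LinkError(
                    f"{ipath}, row {idx}: specimen_id {row['specimen_id']!r} "
                    "not found in specimens"
                )
        if row["chamber_volume_l"] <= 0 or row["duration_h"] <= 0:
            raise SchemaError(
                f"{ipath}, row {idx}: chamber_volume_l and duration_h must be > 0"
            )

    known_chambers = set(_as_str(incubations["chamber_id"]))
    orphan = set(_as_str(o2_series["chamber_id"])) - known_chambers
    if orphan:
        raise LinkError(
            f"{paths.get('o2_series', 'o2_series')}: O2 series reference "
            f"unknown chambers {sorted(orphan)}"
        )
    no_o2 = known_chambers - set(_as_str(o2_series["chamber_id"]))
    if no_o2:
        report.append(f"chambers without O2 series: {sorted(no_o2)}")
    n_controls = int((incubations["role"] == "control").sum())
    if n_controls == 0:
        report.append("no control chambers: rates will be uncorrected")

    return Dataset(
        specimens=specimens,
        batches=batches,
        incubations=incubations,
        o2_series=o2_series,
        foodchain=foodchain,
        validation_report=report,
    )


def read_tables(
    specimens: str | Path,
    batches: str | Path,
    incubations: str | Path,
    o2_series: str | Path,
    foodchain: str | Path | None = None,
) -> Dataset:
    """Load and cross-validate the pipeline input CSVs."""
    frames = {
        "specimens": read_table(specimens),
        "batches": read_table(batches),
        "incubations": read_table(incubations),
        "o2_series": read_table(o2_series),
    }
    fc = read_table(foodchain) if foodchain is not None else None
    paths = {
        "specimens": str(specimens), "batches": str(batches),
        "incubations": str(incubations), "o2_series": str(o2_series),
    }
    if foodchain is not None:
        paths["foodchain"] = str(foodchain)
    return validate_dataset(**frames, foodchain=fc, paths=paths)
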