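"""Reading, validating and writing long-format per-well qPCR tables.

The canonical input is a long-format CSV with one well per row and columns
``replicate, sample_type, gene, role, plate, well, efficiency, cq``.
Instrument-specific headers (``Ct``, ``Well Position``, ...) are handled by a
schema mapping, never by guessing.  Efficiency ``E`` is the fold-amplification
per cycle, nominally in ``(1, 2]`` (e.g. 1.844 for 84.4% efficiency); values
given as percent (92) or as ``E − 1`` (0.92) are rejected outright rather
than silently converted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

#: Canonical column names of the long format.
CANONICAL_COLUMNS = (
    "replicate",
    "sample_type",
    "gene",
    "role",
    "plate",
    "well",
    "efficiency",
    "cq",
)

#: Columns that must be present (possibly via schema remapping).
REQUIRED_COLUMNS = ("replicate", "sample_type", "gene", "role", "efficiency", "cq")

#: Label used when the input carries no plate column (single-plate experiment).
DEFAULT_PLATE = "plate1"

#: Efficiencies above this are flagged as likely unit mistakes (percent or
#: raw slope values); the theoretical maximum fold-amplification is 2.
MAX_EFFICIENCY = 2.2

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"


class SchemaError(ValueError):
    """A required column could not be resolved in the input header."""


class ValidationError(ValueError):
    """A data row violates a well-record invariant; messages carry 1-based
    data-row numbers (the header row is not counted)."""


@dataclasses.dataclass(frozen=True)
class WellRecord:
    """One qPCR well: identifiers plus the measured pair (E, Cq)."""

    replicate_id: str
    sample_type: str
    gene: str
    role: str
    efficiency: float
    cq: float
    plate_id: str = DEFAULT_PLATE
    well_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_TARGET, ROLE_REFERENCE):
            raise ValidationError(
                f"role must be {ROLE_TARGET!r} or {ROLE_REFERENCE!r}, got {self.role!r}"
            )
        if not (math.isfinite(self.efficiency) and self.efficiency > 1.0):
            raise ValidationError(
                f"efficiency must be finite and > 1 (fold-amplification per "
                f"cycle), got {self.efficiency!r}"
            )
        if not (math.isfinite(self.cq) and self.cq > 0.0):
            raise ValidationError(f"cq must be finite and > 0, got {self.cq!r}")


@dataclasses.dataclass(frozen=True)
class ExperimentTable:
    """A validated collection of wells for one gene of interest.

    Attributes
    ----------
    data:
        Long-format DataFrame with the canonical columns, row order as read.
    goi:
        Label of the gene of interest (role ``target``).
    refs:
        Labels of the reference genes (role ``reference``), non-empty.
    """

    data: pd.DataFrame
    goi: str
    refs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValidationError("at least one reference gene is required")
        genes = set(self.data["gene"])
        allowed = {self.goi, *self.refs}
        stray = genes - allowed
        if stray:
            raise ValidationError(
                f"genes {sorted(stray)} are neither the gene of interest "
                f"({self.goi!r}) nor a reference gene"
            )
        # every biological sample must carry the GOI and every reference
        for (rep, styp), sub in self.data.groupby(
            ["replicate", "sample_type"], sort=False
        ):
            present = set(sub["gene"])
            missing = allowed - present
            if missing:
                raise ValidationError(
                    f"sample (replicate={rep!r}, sample_type={styp!r}) has no "
                    f"wells for gene(s) {sorted(missing)}"
                )

    @property
    def records(self) -> list[WellRecord]:
        return [
            WellRecord(
                replicate_id=row.replicate,
                sample_type=row.sample_type,
                gene=row.gene,
                role=row.role,
                efficiency=row.efficiency,
                cq=row.cq,
                plate_id=row.plate,
                well_id=None if pd.isna(row.well) else row.well,
            )
            for row in self.data.itertuples(index=False)
        ]

    @classmethod
    def from_records(cls, records: Sequence[WellRecord]) -> "ExperimentTable":
        data = pd.DataFrame(
            {
                "replicate": [r.replicate_id for r in records],
                "sample_type": [r.sample_type for r in records],
                "gene": [r.gene for r in records],
                "role": [r.role for r in records],
                "plate": [r.plate_id for r in records],
                "well": [r.well_id for r in records],
                "efficiency": [r.efficiency for r in records],
                "cq": [r.cq for r in records],
            }
        )
        goi, refs = _infer_roles(data)
        return cls(data=data, goi=goi, refs=refs)


def _load_schema(schema: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    """Schema maps input header names to canonical names; accepts a dict or a
    YAML/JSON file path."""
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        text = Path(schema).read_text(encoding="utf-8")
        if str(schema).endswith(".json"):
            loaded = json.loads(text)
        else:
            loaded = yaml.safe_load(text)
        if not isinstance(loaded, Mapping):
            raise SchemaError(f"schema file {schema} must contain a mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    return {str(k): str(v) for k, v in schema.items()}


def _infer_roles(data: pd.DataFrame) -> tuple[str, tuple[str, ...]]:
    roles = data.groupby("gene", sort=False)["role"].agg(lambda s: set(s))
    mixed = [g for g, r in roles.items() if len(r) > 1]
    if mixed:
        raise ValidationError(f"gene(s) {mixed} appear with more than one role")
    targets = [g for g, r in roles.items() if r == {ROLE_TARGET}]
    refs = tuple(g for g, r in roles.items() if r == {ROLE_REFERENCE})
    if len(targets) != 1:
        raise ValidationError(
            f"expected exactly one gene with role {ROLE_TARGET!r}, found "
            f"{sorted(targets)}"
        )
    if not refs:
        raise ValidationError("no reference genes (role 'reference') found")
    return targets[0], refs


def read_plate_csv(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    *,
    goi: str | None = None,
    refs: Sequence[str] | None = None,
    max_efficiency: float = MAX_EFFICIENCY,
) -> ExperimentTable:
    """Read and validate a long-format per-well qPCR CSV.

    Parameters
    ----------
    path:
        CSV file (RFC 4180, UTF-8, decimal point) with a header row.
    schema:
        Optional mapping from the file's header names to the canonical
        column names (dict, or path to a YAML/JSON file), e.g. ``{"Ct": "cq"}``.
    goi, refs:
        Explicit gene-of-interest / reference-gene labels.  When both are
        given the ``role`` column becomes optional (it is synthesized from
        the gene labels) and, if present, is checked for consistency.
    max_efficiency:
        Efficiencies above this raise a :class:`ValidationError` — values
        like 92 (percent) or 2.5 are almost always a unit mistake.  Pass
        ``math.inf`` to disable the check.

    Returns
    -------
    ExperimentTable
        Validated table; the gene of interest and reference genes are taken
        from the ``role`` column.

    Raises
    ------
    SchemaError
        If a required column is missing after applying the schema.
    ValidationError
        For non-numeric or out-of-range ``efficiency``/``cq`` values; the
        message names the offending 1-based data row.
    """
    if (goi is None) != (refs is None):
        raise ValueError("goi and refs must be given together")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True, encoding="utf-8")
    mapping = _load_schema(schema)
    raw = raw.rename(columns={k.strip(): v for k, v in mapping.items()})
    raw.columns = [c.strip() for c in raw.columns]

    required = list(REQUIRED_COLUMNS)
    if goi is not None:
        required.remove("role")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing} in {path.name} "
            f"(header: {list(raw.columns)}); use a schema mapping to rename "
            f"instrument-specific headers"
        )
    if goi is not None and "role" not in raw.columns:
        raw["role"] = [
            ROLE_TARGET if g.strip() == goi else ROLE_REFERENCE
            for g in raw["gene"].astype(str)
        ]
    if "plate" not in raw.columns:
        raw["plate"] = DEFAULT_PLATE
    if "well" not in raw.columns:
        raw["well"] = pd.NA

    for col in ("replicate", "sample_type", "gene", "role", "plate"):
        raw[col] = raw[col].astype(str).str.strip()
    raw["plate"] = raw["plate"].replace({"": DEFAULT_PLATE, "nan": DEFAULT_PLATE})

    for col in ("efficiency", "cq"):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"column {col!r}: non-numeric value {raw[col][bad.idxmax()]!r} "
                f"in data row {row}"
            )
        raw[col] = numeric.astype(float)

    bad_e = ~(raw["efficiency"] > 1.0) | ~raw["efficiency"].apply(math.isfinite)
    if bad_e.any():
        row = int(bad_e.idxmax()) + 1
        raise ValidationError(
            f"efficiency must be > 1 (fold-amplification per cycle, e.g. "
            f"1.844); got {raw['efficiency'][bad_e.idxmax()]} in data row {row}. "
            f"Percent (92) or E-1 (0.92) conventions are not converted."
        )
    high_e = raw["efficiency"] > max_efficiency
    if high_e.any():
        row = int(high_e.idxmax()) + 1
        raise ValidationError(
            f"efficiency {raw['efficiency'][high_e.idxmax()]} in data row {row} "
            f"exceeds {max_efficiency} — likely a unit mistake (percent "
            f"efficiency?); raise max_efficiency to override"
        )
    bad_cq = ~(raw["cq"] > 0.0) | ~raw["cq"].apply(math.isfinite)
    if bad_cq.any():
        row = int(bad_cq.idxmax()) + 1
        raise ValidationError(
            f"cq must be finite and > 0; got {raw['cq'][bad_cq.idxmax()]} "
            f"in data row {row}"
        )

    has_well = raw["well"].notna() & (raw["well"].astype(str).str.strip() != "")
    keyed = raw[has_well]
    if len(keyed):
        dup = keyed.duplicated(
            subset=["replicate", "sample_type", "gene", "well"], keep=False
        )
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise ValidationError(
                f"duplicate (replicate, sample_type, gene, well) key at data "
                f"row {row}"
            )

    goi_inf, refs_inf = _infer_roles(raw)
    if goi is not None:
        if goi_inf != goi or set(refs_inf) != set(refs):
            raise ValidationError(
                f"role column implies goi={goi_inf!r}, refs={sorted(refs_inf)}; "
                f"conflicting goi={goi!r}, refs={sorted(refs)} were requested"
            )
    return ExperimentTable(
        data=raw[list(CANONICAL_COLUMNS)], goi=goi_inf, refs=refs_inf
    )


def _result_frame(result) -> pd.DataFrame:
    """Flatten an InferenceResult or AnovaResult into a tidy DataFrame."""
    from cbqpcr.inference import AnovaResult, InferenceResult

    if isinstance(result, InferenceResult):
        return pd.DataFrame(
            [
                {
                    "kind": "test",
                    "mode": result.mode,
                    "estimate_log": result.estimate,
                    "se_log": result.se,
                    "df": result.df,
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "ci_log_lower": result.ci_log[0],
                    "ci_log_upper": result.ci_log[1],
                    "ratio": result.ratio,
                    "ratio_ci_lower": result.ratio_ci[0],
                    "ratio_ci_upper": result.ratio_ci[1],
                    "n_a": result.n_a,
                    "n_b": result.n_b,
                    "confidence": result.confidence,
                    "base": result.base,
                }
            ]
        )
    if isinstance(result, AnovaResult):
        rows = [
            {
                "kind": "source",
                "name": s.name,
                "df": s.df,
                "ss": s.ss,
                "ms": s.ms,
                "f": s.f,
                "p_value": s.p,
            }
            for s in result.sources
        ]
        rows += [
            {
                "kind": "comparison",
                "name": f"{c.pair[0]} vs {c.pair[1]}",
                "estimate_log": c.diff,
                "ci_log_lower": c.ci_log[0],
                "ci_log_upper": c.ci_log[1],
                "ratio": c.ratio,
                "ratio_ci_lower": c.ratio_ci[0],
                "ratio_ci_upper": c.ratio_ci[1],
                "p_value": c.p_adjusted,
            }
            for c in result.posthoc
        ]
        return pd.DataFrame(rows)
    raise TypeError(f"cannot serialise result of type {type(result).__name__}")


def write_results(result, path: str | Path) -> None:
    """Write an InferenceResult or AnovaResult as a flat CSV.

    Log-scale and ratio-scale quantities occupy separate, explicitly named
    columns; floats are written with 17 significant digits, so
    ``read_results(write_results(x))`` is lossless.
    """
    frame = _result_frame(result)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result CSV written by :func:`write_results`."""
    return pd.read_csv(path, float_precision="round_trip")
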