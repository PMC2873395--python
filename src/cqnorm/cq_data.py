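"""Data model and I/O for replicate-level Cq tables, sample sheets and assay panels.

The canonical on-disk format is a long (tidy) CSV with one row per
(sample, assay, replicate) measurement.  Undetected reactions — reported by
qPCR instruments as "Undetermined" — are a distinct state, carried in memory
as NaN and never conflated with a numeric ceiling such as Cq 40.  Wide
sample-by-assay matrices can be imported as a convenience; they are melted to
replicate-level records with replicate index 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

SCHEMA_VERSION = "cqnorm-cq-v1"

#: Cell values (case-insensitive) interpreted as "no detection" on import.
UNDETECTED_TOKENS = {"undetermined", "undetected", "na", "n/a", "nan", ""}

#: Fixed column order of the canonical long CSV.
MEASUREMENT_COLUMNS = ["sample_id", "assay_id", "replicate", "plate_id", "cq"]

VALID_ROLES = {"reference_candidate", "target", "control"}
VALID_RNA_CLASSES = {"miRNA", "snoRNA", "other"}


@dataclass
class SampleSheet:
    """Sample annotations: one row per sample with a group label.

    Required columns: ``sample_id``, ``group``.  Optional: ``patient_id``,
    ``stage``.  Group labels are free categorical text (e.g. tumour/normal).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "group"):
            if col not in f.columns:
                raise ValidationError(f"sample sheet missing required column {col!r}")
        if f["sample_id"].duplicated().any():
            dups = sorted(f.loc[f["sample_id"].duplicated(), "sample_id"].unique())
            raise ValidationError(f"duplicate sample_ids in sample sheet: {dups}")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def groups(self) -> pd.Series:
        """Group label per sample, indexed by sample_id."""
        return self.frame.set_index("sample_id")["group"]

    def group_levels(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def require_two_groups(self) -> None:
        levels = self.group_levels()
        if len(levels) < 2:
            raise ValidationError(
                f"group-wise analysis needs >= 2 groups, found {levels}"
            )


@dataclass
class AssayPanel:
    """Assay annotations: RNA class, panel role and optional efficiency.

    Required columns: ``assay_id``, ``role``.  Optional: ``rna_class``,
    ``efficiency_percent`` (E, in percent; amplification factor is 1 + E/100).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        for col in ("assay_id", "role"):
            if col not in f.columns:
                raise ValidationError(f"assay panel missing required column {col!r}")
        if f["assay_id"].duplicated().any():
            dups = sorted(f.loc[f["assay_id"].duplicated(), "assay_id"].unique())
            raise ValidationError(f"duplicate assay_ids in panel: {dups}")
        bad_roles = set(f["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(
                f"unknown roles {sorted(bad_roles)}; valid: {sorted(VALID_ROLES)}"
            )
        if "rna_class" not in f.columns:
            f["rna_class"] = "miRNA"
        if "efficiency_percent" in f.columns:
            eff = pd.to_numeric(f["efficiency_percent"], errors="coerce")
            out_of_range = eff.notna() & ~eff.between(50, 150, inclusive="neither")
            if out_of_range.any():
                bad = f.loc[out_of_range, "assay_id"].tolist()
                raise ValidationError(
                    f"efficiency_percent outside (50, 150) for assays {bad}"
                )
            f["efficiency_percent"] = eff
        else:
            f["efficiency_percent"] = np.nan
        self.frame = f.reset_index(drop=True)

    @property
    def assay_ids(self) -> list[str]:
        return self.frame["assay_id"].tolist()

    def assays_with_role(self, role: str) -> list[str]:
        return self.frame.loc[self.frame["role"] == role, "assay_id"].tolist()

    def amplification_factors(self, default: float = 2.0) -> pd.Series:
        """Per-assay amplification factor: 1 + E/100, or ``default`` when E is absent."""
        eff = self.frame.set_index("assay_id")["efficiency_percent"]
        af = 1.0 + eff / 100.0
        return af.fillna(default)


@dataclass
class CqDataset:
    """Replicate-level Cq measurements plus sample sheet and assay panel.

    ``measurements`` columns: sample_id, assay_id, replicate, plate_id, cq —
    with cq as float and NaN marking undetected reactions.
    """

    measurements: pd.DataFrame
    samples: SampleSheet
    panel: AssayPanel
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        m = self.measurements.copy()
        missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
        if missing:
            raise ValidationError(f"measurements missing columns {missing}")
        m = m[MEASUREMENT_COLUMNS]
        m["replicate"] = m["replicate"].astype(int)
        m["cq"] = pd.to_numeric(m["cq"], errors="coerce").astype(float)
        self.measurements = m.reset_index(drop=True)
        if self.validate_on_init:
            self.validate()

    def validate(self) -> None:
        m = self.measurements
        if (m["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        present = m["cq"].notna()
        if (m.loc[present, "cq"] <= 0).any():
            bad = m.loc[present & (m["cq"] <= 0)]
            raise ValidationError(
                f"non-positive Cq values at rows {bad.index.tolist()}"
            )
        unknown_samples = set(m["sample_id"]) - set(self.samples.sample_ids)
        if unknown_samples:
            raise ValidationError(
                f"measurements reference unknown samples: {sorted(unknown_samples)}"
            )
        unknown_assays = set(m["assay_id"]) - set(self.panel.assay_ids)
        if unknown_assays:
            raise ValidationError(
                f"measurements reference unknown assays: {sorted(unknown_assays)}"
            )
        key = m[["sample_id", "assay_id", "replicate"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].drop_duplicates().values.tolist()
            raise ValidationError(f"duplicate (sample, assay, replicate) keys: {dups}")

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)


def _parse_cq_column(raw: pd.Series) -> pd.Series:
    """Map undetected tokens to NaN and parse the rest as float.

    Raises ValidationError naming the offending 1-based data row on failure.
    """
    as_str = raw.astype(str).str.strip()
    undetected = as_str.str.lower().isin(UNDETECTED_TOKENS) | raw.isna()
    parsed = pd.to_numeric(as_str.where(~undetected), errors="coerce")
    bad = parsed.isna() & ~undetected
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 1
        raise ValidationError(
            f"unparseable Cq value {as_str[bad].iloc[0]!r} at data row {row}"
        )
    return parsed.astype(float)


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, keep_default_na=False, **kw)


def load_dataset(
    cq_path: str | Path,
    samples_path: str | Path,
    panel_path: str | Path,
    dialect: dict | None = None,
) -> CqDataset:
    """Read a Cq table, sample sheet and assay panel into a validated CqDataset.

    Parameters
    ----------
    cq_path, samples_path, panel_path
        CSV files.  The Cq table is either long format (columns sample_id,
        assay_id, replicate, plate_id, cq) or, with ``dialect={"format":
        "wide"}``, a sample-by-assay matrix whose first column holds sample
        ids.  "Undetermined"/"Undetected"/empty cells map to the undetected
        marker.
    dialect
        Format options: ``format`` ("long", default, or "wide"),
        ``separator`` (default ",").
    """
    dialect = dialect or {}
    sep = dialect.get("separator", ",")
    fmt = dialect.get("format", "long")

    cq_raw = _read_csv(cq_path, sep=sep)
    if fmt == "wide":
        long = cq_raw.melt(
            id_vars=cq_raw.columns[0], var_name="assay_id", value_name="cq"
        )
        long = long.rename(columns={cq_raw.columns[0]: "sample_id"})
        long["replicate"] = 1
        long["plate_id"] = dialect.get("plate_id", "plate1")
    elif fmt == "long":
        missing = [c for c in MEASUREMENT_COLUMNS if c not in cq_raw.columns]
        if missing:
            raise ValidationError(f"Cq table missing columns {missing}")
        long = cq_raw
    else:
        raise ValidationError(f"unknown dialect format {fmt!r}")

    long = long.copy()
    long["cq"] = _parse_cq_column(long["cq"])

    samples = SampleSheet(_read_csv(samples_path, sep=sep))
    panel = AssayPanel(_read_csv(panel_path, sep=sep))
    return CqDataset(long, samples, panel)


def save_dataset(dataset: CqDataset, out_path: str | Path) -> Path:
    """Write the canonical long-format CSV (undetected cells as "Undetermined").

    The first line is a comment carrying the schema version; column order is
    fixed so that save → load is the identity on validated datasets.
    """
    out_path = Path(out_path)
    m = dataset.measurements.copy()
    m["cq"] = m["cq"].map(lambda v: "Undetermined" if pd.isna(v) else repr(float(v)))
    buf = io.StringIO()
    buf.write(f"# {SCHEMA_VERSION}\n")
    m[MEASUREMENT_COLUMNS].to_csv(buf, index=False)
    out_path.write_text(buf.getvalue(), encoding="utf-8")
    return out_path


def save_samples(samples: SampleSheet, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    samples.frame.to_csv(out_path, index=False)
    return out_path


def save_panel(panel: AssayPanel, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    panel.frame.to_csv(out_path, index=False)
    return out_path
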