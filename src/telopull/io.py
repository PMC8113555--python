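"""Protein-group tables and sample sheets.

Reads MaxQuant-style ``proteinGroups``-like TSV files into a
:class:`ProteinGroupTable` — a protein x sample intensity (or ratio)
matrix with per-protein quality flags — and applies the row-filtering
rules shared by every quantitative proteomics stage: drop known
contaminants, reverse-database hits, and groups identified only by a
modification site.

The sample sheet is authoritative for which columns are read and what
they mean; column-name prefixes ("LFQ intensity ", "Ratio H/L
normalized ", ...) are only a fallback to tolerate dialect drift
across MaxQuant versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: flag-column aliases, in lookup order
FLAG_COLUMNS = {
    "contaminant": ("Potential contaminant", "Contaminant"),
    "reverse": ("Reverse",),
    "only_by_site": ("Only identified by site",),
}

#: intensity-column prefixes tried when the sheet's bare name is absent
COLUMN_PREFIXES = (
    "LFQ intensity ",
    "Intensity ",
    "Ratio H/L normalized ",
    "Ratio M/L normalized ",
    "Ratio H/L ",
    "Ratio M/L ",
)


@dataclass(frozen=True)
class SampleInfo:
    """One intensity/ratio column of the table.

    For dimethyl-labeling (DML) ratio columns, ``dml_channel`` records
    which isotope channel carried the *bait* pulldown in that set and
    ``dml_set`` whether the set is the forward or the label-switched
    reverse experiment. Stored ratios are assumed medium/light.
    """

    name: str
    condition: str  # "bait" | "control"
    replicate: int
    quant_mode: str = "lfq"  # "lfq" | "dml"
    dml_channel: Optional[str] = None  # "light" | "medium"
    dml_set: Optional[str] = None  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.condition not in ("bait", "control"):
            raise ValueError(f"condition must be bait|control, got {self.condition!r}")
        if self.quant_mode not in ("lfq", "dml"):
            raise ValueError(f"quant_mode must be lfq|dml, got {self.quant_mode!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        has_dml = self.dml_channel is not None or self.dml_set is not None
        if self.quant_mode == "dml":
            if self.dml_channel not in ("light", "medium"):
                raise ValueError("dml columns need dml_channel in {light, medium}")
            if self.dml_set not in ("forward", "reverse"):
                raise ValueError("dml columns need dml_set in {forward, reverse}")
        elif has_dml:
            raise ValueError("dml_channel/dml_set only allowed when quant_mode=dml")


@dataclass
class ProteinGroupTable:
    """Protein x sample quantification matrix with quality flags.

    ``intensities`` uses NaN for missing (explicitly distinct from 0);
    ``flags`` holds the three boolean columns ``contaminant``,
    ``reverse`` and ``only_by_site`` indexed like ``intensities``.
    ``imputed`` (optional) marks cells filled by imputation.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    sample_sheet: list[SampleInfo]
    imputed: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sample_sheet) != self.intensities.shape[1]:
            raise ValueError(
                f"sample sheet has {len(self.sample_sheet)} entries but table has "
                f"{self.intensities.shape[1]} intensity columns"
            )
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate protein ids: {sorted(set(dupes))}")
        for col in FLAG_COLUMNS:
            if col not in self.flags.columns:
                raise ValueError(f"flags missing column {col!r}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    def columns_for(self, **query: object) -> list[str]:
        """Names of sample columns whose SampleInfo matches all keywords."""
        return [
            s.name
            for s in self.sample_sheet
            if all(getattr(s, k) == v for k, v in query.items())
        ]

    def sample(self, name: str) -> SampleInfo:
        for s in self.sample_sheet:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_intensities(
        self, values: pd.DataFrame, imputed: Optional[pd.DataFrame] = None
    ) -> "ProteinGroupTable":
        return ProteinGroupTable(
            intensities=values,
            flags=self.flags,
            sample_sheet=list(self.sample_sheet),
            imputed=imputed if imputed is not None else self.imputed,
        )


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read a sample sheet TSV (columns: name, condition, replicate,
    quant_mode[, dml_channel, dml_set])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = []
    for _, row in df.iterrows():
        sheet.append(
            SampleInfo(
                name=row["name"],
                condition=row["condition"],
                replicate=int(row["replicate"]),
                quant_mode=row.get("quant_mode", "lfq") or "lfq",
                dml_channel=row.get("dml_channel", "") or None,
                dml_set=row.get("dml_set", "") or None,
            )
        )
    return sheet


def write_sample_sheet(sheet: Sequence[SampleInfo], path: str | Path) -> None:
    rows = [
        {
            "name": s.name,
            "condition": s.condition,
            "replicate": s.replicate,
            "quant_mode": s.quant_mode,
            "dml_channel": s.dml_channel or "",
            "dml_set": s.dml_set or "",
        }
        for s in sheet
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _resolve_column(name: str, columns: Sequence[str]) -> Optional[str]:
    if name in columns:
        return name
    for prefix in COLUMN_PREFIXES:
        if prefix + name in columns:
            return prefix + name
    return None


def read_protein_groups(
    path: str | Path,
    sheet: str | Path | Sequence[SampleInfo],
    id_column: str = "Majority protein IDs",
    zero_is_missing: bool = True,
) -> ProteinGroupTable:
    """Read a protein-groups TSV plus its sample sheet.

    ``zero_is_missing`` treats literal 0 in quantification columns as
    missing (MaxQuant emits 0 for unquantified proteins). Flag marks
    are "+"; an absent flag column is taken as all-false with a
    logged warning.
    """
    sample_sheet = (
        read_sample_sheet(sheet) if isinstance(sheet, (str, Path)) else list(sheet)
    )
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in raw.columns:
        # fall back to the first column as the id
        id_column = raw.columns[0]
    ids = raw[id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"duplicate protein_id values: {dupes}")

    resolved: dict[str, str] = {}
    missing_cols: list[str] = []
    for s in sample_sheet:
        col = _resolve_column(s.name, raw.columns)
        if col is None:
            missing_cols.append(s.name)
        else:
            resolved[s.name] = col
    if missing_cols:
        raise ValueError(f"intensity columns named in sheet absent from table: {missing_cols}")

    mat = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    for s in sample_sheet:
        vals = pd.to_numeric(raw[resolved[s.name]].values, errors="coerce")
        mat[s.name] = vals
    if zero_is_missing:
        mat = mat.mask(mat == 0.0)

    flags = pd.DataFrame(index=mat.index)
    for flag, aliases in FLAG_COLUMNS.items():
        col = next((a for a in aliases if a in raw.columns), None)
        if col is None:
            logger.warning("flag column for %r absent; treating as all-false", flag)
            flags[flag] = False
        else:
            flags[flag] = (raw[col].fillna("").str.strip() == "+").values

    return ProteinGroupTable(intensities=mat, flags=flags, sample_sheet=sample_sheet)


def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    id_column: str = "Majority protein IDs",
) -> None:
    """Write a table back to the TSV dialect ``read_protein_groups`` reads."""
    out = pd.DataFrame({id_column: table.protein_ids.astype(str)})
    for s in table.sample_sheet:
        out[s.name] = table.intensities[s.name].values
    out["Potential contaminant"] = np.where(table.flags["contaminant"], "+", "")
    out["Reverse"] = np.where(table.flags["reverse"], "+", "")
    out["Only identified by site"] = np.where(table.flags["only_by_site"], "+", "")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def filter_protein_groups(table: ProteinGroupTable) -> ProteinGroupTable:
    """Drop contaminants, reverse hits, and only-by-site groups.

    Row order is preserved; per-category removal counts are logged.
    Idempotent.
    """
    f = table.flags
    for cat in FLAG_COLUMNS:
        n = int(f[cat].sum())
        if n:
            logger.info("filtering %d protein groups flagged %s", n, cat)
    keep = ~(f["contaminant"] | f["reverse"] | f["only_by_site"])
    return ProteinGroupTable(
        intensities=table.intensities.loc[keep.values],
        flags=table.flags.loc[keep.values],
        sample_sheet=list(table.sample_sheet),
        imputed=None if table.imputed is None else table.imputed.loc[keep.values],
    )
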