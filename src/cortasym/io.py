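"""Readers and writers for the tabular formats the pipeline touches.

Thickness comes in two dialects:

* ``aparcstats2table_lh_rh_merged`` — the tab-separated wide layout FreeSurfer's
  ``aparcstats2table`` emits, one row per participant-visit with columns
  ``lh_<region>_thickness`` and ``rh_<region>_thickness`` (68 columns), plus
  ``participant_id`` and optionally ``visit``.
* ``long_csv`` — a tidy comma-separated layout with columns
  ``participant_id, visit, hemisphere, region, thickness_mm``.

Metadata is a comma-separated table with one row per participant-visit.
The merged "analysis table" (metadata + a ``cai`` column) is the hand-off
format every downstream analysis consumes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .atlas import DESIKAN_KILLIANY_REGIONS
from .cohort import (
    CohortTable,
    ParticipantRecord,
    RegionalThicknessProfile,
    ValidationError,
)

_HEMI_PREFIX = {"lh": "left", "rh": "right"}
_PREFIX_OF = {"left": "lh", "right": "rh"}

_OPTIONAL_FLOAT_FIELDS = (
    "parent_onset_age_years",
    "eyo_years",
    "csf_nfl_pg_ml",
    "plasma_nfl_pg_ml",
    "hippocampal_volume_mm3",
)

METADATA_COLUMNS = (
    "participant_id", "visit", "cohort", "group", "smc_subgroup", "mutation_gene",
    "apoe_genotype", "apoe_e4_carrier", "sex", "age_years",
    "parent_onset_age_years", "eyo_years", "cdr", "mmse",
    "csf_nfl_pg_ml", "plasma_nfl_pg_ml", "hippocampal_volume_mm3",
)


def _wide_row_to_profiles(row: pd.Series, row_locator: str) -> list[RegionalThicknessProfile]:
    pid = str(row["participant_id"])
    visit = int(row.get("visit", 0))
    out = []
    for prefix, hemi in _HEMI_PREFIX.items():
        values = {}
        for region in DESIKAN_KILLIANY_REGIONS:
            col = f"{prefix}_{region}_thickness"
            if col not in row.index:
                raise ValidationError(f"missing thickness column for region {region!r} ({col})")
            raw = row[col]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric thickness {raw!r} in column {col} at {row_locator}"
                ) from None
            if not np.isfinite(val) or val <= 0:
                raise ValidationError(
                    f"non-positive thickness {val!r} in column {col} at {row_locator}"
                )
            values[region] = val
        out.append(RegionalThicknessProfile.from_mapping(pid, visit, hemi, values))
    return out


def read_thickness_wide(
    path: str | Path, dialect: str = "aparcstats2table_lh_rh_merged"
) -> list[RegionalThicknessProfile]:
    """Read regional thickness tables in either supported dialect.

    Returns one left and one right profile per participant-visit, regions
    normalized to the canonical atlas order.
    """
    path = Path(path)
    if dialect == "aparcstats2table_lh_rh_merged":
        df = pd.read_csv(path, sep="\t")
        if "participant_id" not in df.columns:
            # aparcstats2table names its index column after the stats table
            first = df.columns[0]
            if first.endswith(".aparc.thickness") or first in ("lh.aparc.thickness",
                                                               "rh.aparc.thickness", "subject"):
                df = df.rename(columns={first: "participant_id"})
            else:
                raise ValidationError("wide table needs a 'participant_id' column")
        unknown = [
            c for c in df.columns
            if c.endswith("_thickness")
            and c.split("_", 1)[0] in _HEMI_PREFIX
            and c.split("_", 1)[1].rsplit("_thickness", 1)[0] not in DESIKAN_KILLIANY_REGIONS
        ]
        if unknown:
            raise ValidationError(f"unrecognized region column(s): {unknown}")
        profiles: list[RegionalThicknessProfile] = []
        for i, row in df.iterrows():
            profiles.extend(_wide_row_to_profiles(row, row_locator=f"row {i}"))
    elif dialect == "long_csv":
        df = pd.read_csv(path)
        required = {"participant_id", "visit", "hemisphere", "region", "thickness_mm"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long table must have columns {sorted(required)}")
        profiles = []
        for (pid, visit, hemi), grp in df.groupby(
            ["participant_id", "visit", "hemisphere"], sort=True
        ):
            dup = grp["region"].duplicated()
            if dup.any():
                raise ValidationError(
                    f"duplicate region rows for ({pid}, {visit}, {hemi}): "
                    f"{sorted(grp.loc[dup, 'region'].unique())}"
                )
            bad = grp[~(pd.to_numeric(grp["thickness_mm"], errors="coerce") > 0)]
            if len(bad):
                raise ValidationError(
                    f"non-positive or non-numeric thickness for ({pid}, {visit}, {hemi}), "
                    f"region {bad['region'].iloc[0]!r}"
                )
            mapping = dict(zip(grp["region"], grp["thickness_mm"].astype(float)))
            profiles.append(
                RegionalThicknessProfile.from_mapping(str(pid), int(visit), str(hemi), mapping)
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    keys = [(p.participant_id, p.visit, p.hemisphere) for p in profiles]
    if len(keys) != len(set(keys)):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (participant, visit, hemisphere): {dup[:5]}")
    return profiles


def write_thickness(
    profiles: Iterable[RegionalThicknessProfile],
    path: str | Path,
    dialect: str = "long_csv",
) -> None:
    """Write profiles in either dialect (inverse of :func:`read_thickness_wide`)."""
    profiles = list(profiles)
    path = Path(path)
    if dialect == "long_csv":
        rows = [
            (p.participant_id, p.visit, p.hemisphere, region, val)
            for p in profiles
            for region, val in zip(p.regions, p.values_mm)
        ]
        pd.DataFrame(
            rows, columns=["participant_id", "visit", "hemisphere", "region", "thickness_mm"]
        ).to_csv(path, index=False, float_format="%.9f")
    elif dialect == "aparcstats2table_lh_rh_merged":
        by_key: dict[tuple[str, int], dict] = {}
        for p in profiles:
            row = by_key.setdefault(
                (p.participant_id, p.visit),
                {"participant_id": p.participant_id, "visit": p.visit},
            )
            prefix = _PREFIX_OF[p.hemisphere]
            for region, val in zip(p.regions, p.values_mm):
                row[f"{prefix}_{region}_thickness"] = val
        df = pd.DataFrame(list(by_key.values()))
        cols = ["participant_id", "visit"] + [
            f"{pre}_{r}_thickness" for pre in ("lh", "rh") for r in DESIKAN_KILLIANY_REGIONS
        ]
        df[cols].to_csv(path, sep="\t", index=False, float_format="%.9f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _opt(row: pd.Series, col: str, cast):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and v.strip() == ""):
        return None
    return cast(v)


def read_metadata(path: str | Path) -> list[ParticipantRecord]:
    """Read the participant metadata CSV into validated records.

    Derived fields (``smc_subgroup``, ``apoe_e4_carrier``, ``eyo_years``) are
    filled from CDR / APOE genotype / parent onset age when absent.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "group", "sex", "age_years", "visit"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata is missing required column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        e4 = _opt(row, "apoe_e4_carrier", lambda v: str(v).strip().lower() in ("true", "1", "yes"))
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                visit=int(row["visit"]),
                cohort=_opt(row, "cohort", str) or "barcelona_like",
                group=str(row["group"]),
                smc_subgroup=_opt(row, "smc_subgroup", str),
                mutation_gene=_opt(row, "mutation_gene", str) or "none",
                apoe_genotype=_opt(row, "apoe_genotype", str),
                apoe_e4_carrier=e4,
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                cdr=_opt(row, "cdr", float) or 0.0,
                mmse=_opt(row, "mmse", lambda v: int(round(float(v)))),
                **{f: _opt(row, f, float) for f in _OPTIONAL_FLOAT_FIELDS},
            )
        )
    return records


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in METADATA_COLUMNS})
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    return df


def write_metadata(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.9f")


def build_analysis_table(cohort: CohortTable, cai_frame: pd.DataFrame) -> pd.DataFrame:
    """Merge metadata with CAI values into the one-row-per-participant-visit table.

    ``cai_frame`` must carry columns ``participant_id, visit, cai`` (the output
    of :func:`cortasym.cai.compute_cai_table`).
    """
    meta = records_to_frame(cohort.records)
    merged = meta.merge(cai_frame[["participant_id", "visit", "cai"]],
                        on=["participant_id", "visit"], how="left", validate="one_to_one")
    if merged["cai"].isna().any():
        missing = merged.loc[merged["cai"].isna(), ["participant_id", "visit"]]
        raise ValidationError(
            f"missing CAI for participant-visits: {missing.values.tolist()[:5]}"
        )
    return merged
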