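"""Reading and writing the tabular peak/sample formats.

Peak table (TSV default, CSV accepted, UTF-8, header mandatory):
``compound_id  name  mass  metabolite  is_contaminant  <sample_1> ... <sample_n>``

Sample table: ``sample_id  group  [cohort]  [covariate columns]``.

Empty cells, ``NA`` and ``0`` in the abundance block all map to abundance 0:
undetected compounds are encoded as exact zeros.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CASE, CompoundRecord, ProfileMatrix, canonical_group

META_COLUMNS = ["compound_id", "name", "mass", "metabolite", "is_contaminant"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _parse_bool(value, context: str) -> bool:
    key = str(value).strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE or key == "nan":
        return False
    raise ValueError(f"{context}: cannot parse boolean {value!r}")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by ``sample_id``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample table is missing column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated sample id {dup.iloc[0]!r}")
    df = df.set_index("sample_id")
    df["group"] = [canonical_group(g) for g in df["group"]]
    return df


def load_profile_table(
    peak_table_path: str | Path, sample_table_path: str | Path
) -> ProfileMatrix:
    """Load and validate a profile from a peak table and a sample table.

    Every empty/NA abundance cell is imputed to 0 ("not detected"); the
    imputation never changes a non-missing value.  Sample columns of the
    peak table must match the sample table exactly, by id.
    """
    peak_table_path = Path(peak_table_path)
    samples = read_sample_table(sample_table_path)
    peaks = pd.read_csv(peak_table_path, sep=_sep_for(peak_table_path), dtype=str)

    missing_meta = [c for c in META_COLUMNS if c not in peaks.columns]
    if missing_meta:
        raise ValueError(
            f"{peak_table_path}: peak table is missing metadata column(s) {missing_meta}"
        )
    sample_cols = [c for c in peaks.columns if c not in META_COLUMNS]
    unknown = [c for c in sample_cols if c not in samples.index]
    if unknown:
        raise ValueError(
            f"{peak_table_path}: sample column {unknown[0]!r} is absent "
            f"from the sample table"
        )
    absent = [s for s in samples.index if s not in sample_cols]
    if absent:
        raise ValueError(
            f"{sample_table_path}: sample id {absent[0]!r} has no column "
            f"in the peak table"
        )

    compounds = []
    for _, row in peaks.iterrows():
        compounds.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(row["name"]),
                mass=int(float(row["mass"])),
                metabolite=str(row["metabolite"]),
                is_contaminant=_parse_bool(
                    row["is_contaminant"], f"compound {row['compound_id']!r}"
                ),
            )
        )

    raw = peaks[sample_cols]
    block = raw.apply(pd.to_numeric, errors="coerce")

    def _is_missing(col: pd.Series) -> pd.Series:
        s = col.astype(str).str.strip().str.upper()
        return col.isna() | s.eq("") | s.eq("NA") | s.eq("NAN")

    na_but_not_missing = block.isna() & ~raw.apply(_is_missing)
    if na_but_not_missing.any().any():
        j = na_but_not_missing.any(axis=0).idxmax()
        i = na_but_not_missing[j].idxmax()
        raise ValueError(
            f"{peak_table_path}: non-numeric abundance "
            f"{peaks.loc[i, j]!r} for compound {peaks.loc[i, 'compound_id']!r}, "
            f"sample {j!r}"
        )
    # re-parse through float() for correctly-rounded values (pandas' fast
    # string parser can be one ulp off)
    cleaned = raw.apply(lambda col: col.astype(str).str.strip()).where(
        ~raw.apply(_is_missing), "0"
    )
    abundance = cleaned.astype(float).to_numpy()
    if np.any(abundance < 0):
        i, j = np.argwhere(abundance < 0)[0]
        raise ValueError(
            f"{peak_table_path}: negative abundance for compound "
            f"{compounds[i].compound_id!r}, sample {sample_cols[j]!r}"
        )
    groups = [samples.loc[s, "group"] for s in sample_cols]
    return ProfileMatrix(compounds, sample_cols, groups, abundance)


def write_profile_table(
    pm: ProfileMatrix,
    peak_table_path: str | Path,
    sample_table_path: str | Path,
) -> None:
    """Write a profile back to the two-table on-disk format (round-trip safe)."""
    peak_table_path = Path(peak_table_path)
    sample_table_path = Path(sample_table_path)
    meta = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in pm.compounds],
            "name": [c.name for c in pm.compounds],
            "mass": [c.mass for c in pm.compounds],
            "metabolite": [c.metabolite for c in pm.compounds],
            "is_contaminant": [str(c.is_contaminant).lower() for c in pm.compounds],
        }
    )
    block = pd.DataFrame(pm.abundance, columns=pm.sample_ids)
    pd.concat([meta, block], axis=1).to_csv(
        peak_table_path, sep=_sep_for(peak_table_path), index=False,
        float_format="%.17g",  # bit-exact round trip
    )
    pd.DataFrame({"sample_id": pm.sample_ids, "group": list(pm.groups)}).to_csv(
        sample_table_path, sep=_sep_for(sample_table_path), index=False
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
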