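"""Taxon-grouped aggregation of per-genome globin inventories.

The census table has one row per genome: species, taxonomy ranks
(phylum / subphylum / class), one count column per architecture class
label, and a genome-completeness flag.  Summaries roll the rows up to a
taxonomic rank: genomes total, genomes with at least one globin, their
ratio, and per-label totals.  Taxonomy is supplied as columns of the
input table and never queried online.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Union
from pathlib import Path

import numpy as np
import pandas as pd

#: Architecture labels counted in census tables.
LABEL_COLUMNS = (
    "FHb", "FHb_incomplete", "Fgb", "Sgb", "SensorChimera", "T1", "T1Chimera",
)

TAXONOMY_COLUMNS = ("phylum", "subphylum", "class")
REQUIRED_COLUMNS = ("species",) + TAXONOMY_COLUMNS + LABEL_COLUMNS


class CensusFormatError(ValueError):
    pass


def load_census(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    """Load and validate a census TSV (or pass through a DataFrame).

    Requires the species, taxonomy and per-label count columns; counts
    must be non-negative integers.  An empty table is returned as an
    empty frame with a warning.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source, sep="\t")
        except pd.errors.EmptyDataError:
            warnings.warn(f"census file {source} is empty")
            return pd.DataFrame(columns=list(REQUIRED_COLUMNS) + ["genome_complete"])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"missing required columns: {missing}")
    if df.empty:
        warnings.warn("census table has no rows")
        return df
    for col in LABEL_COLUMNS:
        values = pd.to_numeric(df[col], errors="raise")
        if (values < 0).any():
            raise CensusFormatError(f"negative counts in column {col}")
        df[col] = values.astype(int)
    if "genome_complete" not in df.columns:
        df["genome_complete"] = True
    for col in TAXONOMY_COLUMNS:
        df[col] = df[col].fillna("")
    return df


def _with_globins(df: pd.DataFrame) -> pd.Series:
    return df[list(LABEL_COLUMNS)].sum(axis=1) > 0


def summarize(
    rows: pd.DataFrame,
    group_by: Optional[str] = "phylum",
) -> pd.DataFrame:
    """Taxon-level presence counts and ratios.

    Groups the table by the requested rank (``None`` for a single
    overall row).  A genome counts as "with globins" iff any label count
    is positive.  The ratio is NaN for taxa with zero genomes rather
    than dropped.
    """
    if rows.empty:
        raise ValueError("cannot summarize an empty census")
    if group_by is not None and group_by not in rows.columns:
        raise KeyError(f"no such rank column: {group_by!r}")
    df = rows.copy()
    df["_with"] = _with_globins(df)
    keys = [group_by] if group_by is not None else []

    def _agg(g: pd.DataFrame) -> pd.Series:
        total = len(g)
        with_g = int(g["_with"].sum())
        out = {
            "genomes_total": total,
            "genomes_with_globins": with_g,
            "ratio": with_g / total if total else np.nan,
        }
        for label in LABEL_COLUMNS:
            out[label] = int(g[label].sum())
        return pd.Series(out)

    if keys:
        grouped = df.groupby(keys[0], sort=True, dropna=False)
        summary = grouped.apply(_agg, include_groups=False).reset_index()
    else:
        summary = _agg(df).to_frame().T
        summary.insert(0, "taxon", "all")
    for col in ("genomes_total", "genomes_with_globins") + LABEL_COLUMNS:
        summary[col] = summary[col].astype(int)
    summary["percent"] = (summary["ratio"] * 100).round().astype("Int64")
    return summary


def incomplete_fhb_report(
    rows: pd.DataFrame,
    group_by: str = "subphylum",
) -> pd.DataFrame:
    """Genomes carrying incomplete flavohemoglobins, per taxon.

    Counts genomes with at least one FHb_incomplete, grouped by the
    requested rank, alongside the taxon genome totals.
    """
    if rows.empty:
        return pd.DataFrame(columns=[group_by, "genomes_total", "genomes_with_incomplete_fhb"])
    df = rows.copy()
    df["_inc"] = df["FHb_incomplete"] > 0
    out = (
        df.groupby(group_by, sort=True)
        .agg(genomes_total=("species", "size"), genomes_with_incomplete_fhb=("_inc", "sum"))
        .reset_index()
    )
    out["genomes_with_incomplete_fhb"] = out["genomes_with_incomplete_fhb"].astype(int)
    return out


def census_from_calls(calls: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Build a census table from per-protein architecture calls.

    ``calls`` needs columns ``species`` and ``label``; ``taxonomy`` maps
    species to rank columns.  Genomes listed in the taxonomy sidecar but
    absent from the calls appear with all-zero counts, so globin-free
    genomes stay in the denominator.
    """
    tax = taxonomy.drop_duplicates("species").set_index("species")
    rows: List[dict] = []
    counts = (
        calls[calls["label"].isin(LABEL_COLUMNS)]
        .groupby(["species", "label"]).size().unstack(fill_value=0)
        if not calls.empty else pd.DataFrame()
    )
    for species, trow in tax.iterrows():
        row = {"species": species}
        for col in TAXONOMY_COLUMNS:
            row[col] = trow.get(col, "")
        for label in LABEL_COLUMNS:
            row[label] = int(counts.loc[species, label]) if (
                species in counts.index and label in counts.columns
            ) else 0
        row["genome_complete"] = bool(trow.get("genome_complete", True))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["genome_complete"])
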