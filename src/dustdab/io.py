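"""Reading and writing count tables, sample metadata, and result tables.

All on-disk formats are plain TSV.  The canonical count-table orientation
is taxa as rows with a leading ``lineage`` column (the shape most
classifier exports use); the samples-as-rows orientation is accepted via a
flag.  Metadata accepts a ``<LOD`` sentinel for below-detection FeNO
values, which is converted to a NaN value plus a ``feno_below_lod`` flag.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CATEGORICAL_LEVELS, CountTable, FormatError,
                         ResultTable, SampleFrame)

log = logging.getLogger("dustdab")

LOD_SENTINELS = {"<LOD", "<lod", "LOD", "BLOD"}


def read_count_table(path: str | Path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path
        TSV file.  In ``taxa_rows`` orientation the first column is the
        taxon id, an optional second column named ``lineage`` carries the
        taxonomy string, and remaining columns are samples.  In
        ``samples_rows`` orientation rows are samples and columns taxa
        (lineages then default to the bare taxon id).
    orientation
        ``"taxa_rows"`` (default) or ``"samples_rows"``.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if orientation == "samples_rows":
        df = df.T
        if df.index.name is None:
            df.index.name = "taxon_id"
    if "lineage" in df.columns:
        lineages = df["lineage"].fillna("").tolist()
        body = df.drop(columns=["lineage"])
    else:
        lineages = [str(t) for t in df.index]
        body = df
    taxon_ids = [str(t) for t in df.index]
    sample_ids = [str(c) for c in body.columns]
    counts = np.empty((len(sample_ids), len(taxon_ids)), dtype=np.int64)
    for j, (tid, row) in enumerate(body.iterrows()):
        for i, raw in enumerate(row):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                raise FormatError(f"missing count for taxon {tid!r}")
            try:
                val = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric count {raw!r} for taxon {tid!r}") from exc
            if val < 0:
                raise FormatError(f"negative count {raw!r} for taxon {tid!r}")
            if val != int(val):
                raise FormatError(f"non-integer count {raw!r} for taxon {tid!r}")
            counts[i, j] = int(val)
    table = CountTable(counts=counts, taxon_ids=taxon_ids,
                       lineages=lineages, sample_ids=sample_ids)
    log.info("read_count_table: %d samples x %d taxa from %s",
             table.n_samples, table.n_taxa, path)
    return table


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the canonical taxa-as-rows TSV layout."""
    table.to_dataframe().to_csv(path, sep="\t")
    log.info("write_count_table: %d samples x %d taxa to %s",
             table.n_samples, table.n_taxa, path)


def read_metadata(path: str | Path) -> SampleFrame:
    """Read a sample metadata TSV into a typed :class:`SampleFrame`.

    A mandatory ``sample_id`` column indexes the frame.  FeNO entries equal
    to a ``<LOD`` sentinel are flagged in ``feno_below_lod`` and left unset;
    they are imputed only by the FeNO transform downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")

    if "feno" in df.columns:
        sentinel = df["feno"].isin(LOD_SENTINELS)
        if "feno_below_lod" in df.columns:
            flagged = df["feno_below_lod"].str.lower().isin(
                {"true", "1", "yes"})
            sentinel = sentinel | flagged
        df.loc[sentinel, "feno"] = np.nan
        df["feno_below_lod"] = sentinel

    numeric = ["fev1", "fvc", "fev1_fvc", "feno", "age", "height", "weight",
               "pack_years"]
    for col in numeric:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in CATEGORICAL_LEVELS:
        if col in df.columns:
            df[col] = df[col].astype(object)
    frame = SampleFrame(df)
    log.info("read_metadata: %d samples, columns %s from %s",
             len(frame.sample_ids), list(df.columns), path)
    return frame


def write_metadata(frame: SampleFrame, path: str | Path) -> None:
    frame.data.to_csv(path, sep="\t")


def format_p(p: float) -> str:
    """Render a p-value with 3 significant figures.

    Values below 10^-3 use scientific notation (``2.1e-04``); larger ones
    plain decimal (``0.012``).
    """
    if p != p:  # NaN
        return "NA"
    if p == 0:
        return "0"
    if p < 1e-3:
        return f"{p:.1e}"
    return f"{p:.3g}"


def write_results(results: ResultTable, path: str | Path) -> None:
    """Write a result TSV sorted by (phylum, family, genus).

    Coefficients are printed with 3 decimals (the precision of the headline
    tables), p-values per :func:`format_p`.
    """
    df = results.sorted_by_taxonomy().copy()
    out = pd.DataFrame({
        "phylum": df["phylum"],
        "family": df["family"],
        "genus": df["genus"],
        "coefficient": [("NA" if c != c else f"{c:.3f}") for c in df["coefficient"]],
        "se": [("NA" if s != s else f"{s:.4f}") for s in df["se"]],
        "z": [("NA" if z != z else f"{z:.3f}") for z in df["z"]],
        "p_value": [format_p(p) for p in df["p_value"]],
        "significant": [bool(s) if s == s else False for s in df["significant"]],
    })
    out.to_csv(path, sep="\t", index=False)
    log.info("write_results: %d taxa (%d significant) to %s",
             len(df), int(out["significant"].sum()), path)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV (as plain frame; formatting is lossy)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["significant"] = df["significant"].astype(bool)
    return df
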