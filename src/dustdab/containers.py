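"""Core in-memory containers: taxon count tables, sample metadata, result tables.

A :class:`CountTable` holds an integer taxon-by-sample abundance matrix
(stored samples x taxa) together with taxonomy lineage strings.  A
:class:`SampleFrame` wraps per-sample respiratory outcomes and covariates
and knows, for each outcome, which covariate roster its regression model
uses.  A :class:`ResultTable` carries per-taxon differential-abundance
inference results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_INDEX = {name: i for i, name in enumerate(RANK_NAMES)}

#: Continuous outcomes the analysis supports, with their measurement units.
OUTCOMES = {
    "fev1": "ml",
    "fvc": "ml",
    "fev1_fvc": "proportion",
    "feno": "ppb",
}

CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "smoking": ("never", "former", "current"),
    "asthma": ("no", "yes"),
    "state": ("IA", "NC"),
    "ancestry": ("european", "not"),
    "season": ("not_winter", "winter"),
}


class FormatError(ValueError):
    """A file or table violates the expected structure."""


class AlignmentError(ValueError):
    """Two containers do not share the sample universe they must share."""


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage into 7 ranks (kingdom..species).

    Accepts both ``k__Bacteria;p__Firmicutes;...`` prefixed strings and bare
    ``Bacteria;Firmicutes;...`` strings.  Missing trailing ranks are padded
    with empty strings; genus is always the 6th rank.
    """
    parts = [p.strip() for p in lineage.split(";")]
    out = []
    for i, part in enumerate(parts[:7]):
        for pref in RANK_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        out.append(part)
    out.extend([""] * (7 - len(out)))
    return tuple(out)


def format_lineage(ranks: Sequence[str]) -> str:
    """Render ranks back into the prefixed ``k__...;p__...`` convention."""
    padded = list(ranks) + [""] * (7 - len(ranks))
    return ";".join(pref + name for pref, name in zip(RANK_PREFIXES, padded))


@dataclass
class CountTable:
    """Integer taxon abundance matrix with taxonomy, samples as rows.

    Parameters
    ----------
    counts
        Integer array of shape ``(n_samples, n_taxa)``; reads per cell.
    taxon_ids, lineages
        One id and one rank-delimited lineage string per taxon.
    sample_ids
        One unique id per sample.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    lineages: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.taxon_ids = list(self.taxon_ids)
        self.lineages = list(self.lineages)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if len(self.sample_ids) != n:
            raise FormatError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows")
        if len(self.taxon_ids) != p or len(self.lineages) != p:
            raise FormatError(
                f"{len(self.taxon_ids)} taxon ids / {len(self.lineages)} "
                f"lineages for {p} matrix columns")
        if len(set(self.taxon_ids)) != p:
            raise FormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (length ``n_samples``)."""
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> np.ndarray:
        """Total reads per taxon across samples (length ``n_taxa``)."""
        return self.counts.sum(axis=0)

    def lineage_ranks(self) -> list[tuple[str, ...]]:
        return [parse_lineage(s) for s in self.lineages]

    # -- subsetting -----------------------------------------------------
    def select_samples(self, mask: np.ndarray) -> "CountTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountTable(
            counts=self.counts[idx, :],
            taxon_ids=self.taxon_ids,
            lineages=self.lineages,
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def select_taxa(self, mask: np.ndarray) -> "CountTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountTable(
            counts=self.counts[:, idx],
            taxon_ids=[self.taxon_ids[i] for i in idx],
            lineages=[self.lineages[i] for i in idx],
            sample_ids=self.sample_ids,
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise AlignmentError(f"samples absent from count table: {missing[:5]}")
        return self.select_samples(np.array([pos[s] for s in sample_ids]))

    def to_dataframe(self) -> pd.DataFrame:
        """Taxa-as-rows frame with a leading ``lineage`` column."""
        df = pd.DataFrame(
            self.counts.T, index=pd.Index(self.taxon_ids, name="taxon_id"),
            columns=self.sample_ids)
        df.insert(0, "lineage", self.lineages)
        return df


@dataclass
class SampleFrame:
    """Per-sample outcomes and covariates.

    Wraps a :class:`pandas.DataFrame` indexed by sample id.  Outcome
    columns: ``fev1`` (ml), ``fvc`` (ml), ``fev1_fvc`` (proportion in
    (0, 1]), ``feno`` (ppb) with a companion boolean ``feno_below_lod``.
    Covariates: ``age`` (years), ``sex``, ``height`` (cm), ``weight``
    (kg), ``smoking``, ``pack_years``, ``asthma``, ``state``,
    ``ancestry``, ``season``.  Missing values stay as NaN; they are never
    silently replaced.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.name != "sample_id":
            if "sample_id" in self.data.columns:
                self.data = self.data.set_index("sample_id")
            else:
                self.data = self.data.rename_axis("sample_id")
        self.data.index = self.data.index.astype(str)
        self.validate()

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        for col, levels in CATEGORICAL_LEVELS.items():
            if col in self.data.columns:
                vals = self.data[col].dropna().unique()
                unknown = set(vals) - set(levels)
                if unknown:
                    raise FormatError(
                        f"unknown levels for {col!r}: {sorted(unknown)}")
        if "fev1_fvc" in self.data.columns:
            r = self.data["fev1_fvc"].dropna()
            if ((r <= 0) | (r > 1)).any():
                raise FormatError("fev1_fvc must lie in (0, 1]")
        if {"fev1", "fvc"} <= set(self.data.columns):
            both = self.data[["fev1", "fvc"]].dropna()
            if (both["fev1"] > both["fvc"] + 1e-9).any():
                raise FormatError("FEV1 exceeds FVC for some samples")
        if "feno" in self.data.columns:
            f = self.data["feno"].dropna()
            if (f < 0).any():
                raise FormatError("negative FeNO measurement")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def reorder(self, sample_ids: Sequence[str]) -> "SampleFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"samples absent from metadata: {missing[:5]}")
        return SampleFrame(self.data.loc[list(sample_ids)].copy())


RESULT_COLUMNS = [
    "taxon_id", "phylum", "family", "genus", "coefficient", "se", "z",
    "p_value", "significant",
]


@dataclass
class ResultTable:
    """Per-taxon differential-abundance results for one outcome.

    One row per tested taxon with the debiased coefficient (standardized
    scale), its standard error, z statistic, two-sided p-value, and a
    significance flag at the fixed 0.05 convention.  Taxa dropped from the
    design (e.g. constant after preprocessing) appear with NaN statistics
    and ``significant == False``.
    """

    data: pd.DataFrame
    outcome: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"result table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        p = self.data["p_value"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise FormatError("p-values outside [0, 1]")
        tested = self.data["p_value"].notna()
        flag = self.data.loc[tested, "significant"].astype(bool)
        expect = self.data.loc[tested, "p_value"] < 0.05
        if not (flag == expect).all():
            raise FormatError("significance flag inconsistent with p < 0.05")

    def significant_taxa(self) -> list[str]:
        return list(self.data.loc[self.data["significant"].fillna(False).astype(bool),
                                  "taxon_id"])

    def sorted_by_taxonomy(self) -> pd.DataFrame:
        return self.data.sort_values(["phylum", "family", "genus"],
                                     kind="mergesort").reset_index(drop=True)
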