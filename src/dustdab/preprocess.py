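"""Preprocessing: filtering, winsorization, compositional transform,
outcome transforms, covariate design, and standardization.

The inference-ready design is produced by the fixed chain

    filter -> aggregate to rank -> winsorize -> relative abundance
           -> center/scale (predictors and response)

Relative abundances divide by the *winsorized* sample totals so the
composition stays internally consistent after outlier capping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (CountTable, FormatError, SampleFrame, format_lineage,
                         parse_lineage)

log = logging.getLogger("dustdab")


class EmptyResultError(ValueError):
    """Filtering removed every sample (or taxon)."""


@dataclass
class FilterSpec:
    """Thresholds for sample- and taxon-level filtering.

    ``min_sample_reads``: samples with total reads strictly below this are
    dropped (default 1000).  ``min_taxon_fraction``: taxa whose share of
    the retained grand total is strictly below this fraction are dropped
    (default 5e-6, i.e. 0.0005%); taxa exactly at the threshold are kept.
    ``excluded_kingdoms``: lineage kingdoms removed outright (reference
    databases for these are too sparse for reliable classification).
    """

    min_sample_reads: int = 1000
    min_taxon_fraction: float = 5e-6
    excluded_kingdoms: tuple[str, ...] = ("Eukaryota", "Viruses")

    def __post_init__(self) -> None:
        if self.min_sample_reads < 0 or self.min_taxon_fraction < 0:
            raise ValueError("filter thresholds must be >= 0")


def filter_table(table: CountTable, spec: FilterSpec | None = None) -> CountTable:
    """Drop low-depth samples, then rare taxa, then excluded kingdoms.

    Samples with fewer than ``min_sample_reads`` total reads are removed
    first; taxon totals and the grand total are then recomputed on the
    retained samples, and taxa holding strictly less than
    ``min_taxon_fraction`` of the grand total are removed.  Both
    boundaries are strict ``<``.
    """
    spec = spec or FilterSpec()
    totals = table.sample_totals()
    keep_samples = totals >= spec.min_sample_reads
    n_dropped = int((~keep_samples).sum())
    if not keep_samples.any():
        raise EmptyResultError("all samples below the read-depth threshold")
    out = table.select_samples(keep_samples)

    grand = out.counts.sum()
    taxon_totals = out.taxon_totals()
    keep_taxa = taxon_totals >= spec.min_taxon_fraction * grand
    kingdoms = np.array([parse_lineage(s)[0] for s in out.lineages])
    excluded = np.isin(kingdoms, list(spec.excluded_kingdoms))
    p_rare = int((~keep_taxa).sum())
    p_kingdom = int((keep_taxa & excluded).sum())
    out = out.select_taxa(keep_taxa & ~excluded)
    log.info("filter_table: dropped %d samples (<%d reads), %d rare taxa, "
             "%d excluded-kingdom taxa; %d samples x %d taxa retained",
             n_dropped, spec.min_sample_reads, p_rare, p_kingdom,
             out.n_samples, out.n_taxa)
    return out


def aggregate_rank(table: CountTable, rank: str = "genus") -> CountTable:
    """Sum counts over all taxa sharing the lineage down to ``rank``.

    Genus-level analysis sums all classified species within a genus, which
    tempers the sparsity seen at species level.  Taxa with an empty name at
    the requested rank are grouped by their full available lineage prefix.
    """
    depth = {"kingdom": 1, "phylum": 2, "class": 3, "order": 4,
             "family": 5, "genus": 6, "species": 7}.get(rank)
    if depth is None:
        raise ValueError(f"unknown rank {rank!r}")
    keys: list[tuple[str, ...]] = []
    for lin in table.lineages:
        keys.append(parse_lineage(lin)[:depth])
    order: dict[tuple[str, ...], int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    p_out = len(order)
    counts = np.zeros((table.n_samples, p_out), dtype=np.int64)
    for j, k in enumerate(keys):
        counts[:, order[k]] += table.counts[:, j]
    uniq = list(order)
    lineages = [format_lineage(k) for k in uniq]
    taxon_ids = [(k[depth - 1] or ";".join(k).rstrip(";")) for k in uniq]
    # disambiguate homonym names occurring under different higher ranks
    seen: dict[str, int] = {}
    for i, t in enumerate(taxon_ids):
        if t in seen:
            seen[t] += 1
            taxon_ids[i] = f"{t}_{seen[t]}"
        else:
            seen[t] = 0
    out = CountTable(counts=counts, taxon_ids=taxon_ids,
                     lineages=lineages, sample_ids=table.sample_ids)
    log.info("aggregate_rank: %d taxa -> %d %s-level taxa",
             table.n_taxa, out.n_taxa, rank)
    return out


def winsorize_counts(table: CountTable, k_top: int = 5) -> CountTable:
    """Cap each taxon's ``k_top`` largest per-sample counts.

    For each taxon the values in the ``k_top`` samples with the largest
    reads are replaced by the (``k_top``+1)-th largest value; ties with
    that value make the operation a no-op on the tied cells.  Never
    increases any cell and is idempotent.
    """
    if table.n_samples <= k_top + 1:
        raise ValueError(
            f"winsorization needs more than {k_top + 1} samples, "
            f"got {table.n_samples}")
    counts = table.counts.copy()
    # cap = (k_top+1)-th largest per column
    part = np.partition(counts, table.n_samples - k_top - 1, axis=0)
    cap = part[table.n_samples - k_top - 1, :]
    counts = np.minimum(counts, cap[None, :])
    return CountTable(counts=counts, taxon_ids=table.taxon_ids,
                      lineages=table.lineages, sample_ids=table.sample_ids)


def to_relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample relative abundances (rows sum to 1).

    Divides each sample's counts by that sample's total; totals of zero
    are an error naming the first offending sample.
    """
    totals = table.sample_totals().astype(float)
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ZeroDivisionError(
            f"zero-total sample(s) cannot be normalized: {bad[:5]}")
    return table.counts / totals[:, None]


def transform_feno(values: np.ndarray, below_lod: np.ndarray | None = None,
                   lod: float = 5.0) -> np.ndarray:
    """ln-transform FeNO after imputing below-LOD values at LOD/sqrt(2).

    The imputed value is rounded to one decimal (5/sqrt(2) -> 3.5 ppb)
    before the natural log is applied to every entry.
    """
    values = np.asarray(values, dtype=float).copy()
    if below_lod is None:
        below_lod = np.zeros(values.shape, dtype=bool)
    below_lod = np.asarray(below_lod, dtype=bool)
    measured = values[~below_lod]
    if np.any(measured[~np.isnan(measured)] < 0):
        raise ValueError("negative measured FeNO value")
    imputed = round(lod / np.sqrt(2.0), 1)
    values[below_lod] = imputed
    return np.log(values)


#: Covariate rosters per outcome.  Spirometric outcomes adjust for age,
#: age^2, sex, height, height^2, smoking, pack-years, asthma, state and
#: ancestry; FVC additionally for weight; FeNO drops the quadratic terms.
_BASE_COVARIATES = ["age", "age2", "sex_male", "height", "height2",
                    "smoking_former", "smoking_current", "pack_years",
                    "asthma_yes", "state_nc", "ancestry_not"]

COVARIATE_ROSTERS = {
    "fev1": list(_BASE_COVARIATES),
    "fev1_fvc": list(_BASE_COVARIATES),
    "fvc": _BASE_COVARIATES[:5] + ["weight"] + _BASE_COVARIATES[5:],
    "feno": [c for c in _BASE_COVARIATES if c not in ("age2", "height2")],
}


def build_covariates(frame: SampleFrame, outcome: str,
                     season_sensitivity: bool = False) -> pd.DataFrame:
    """Assemble the dummy-coded covariate matrix for one outcome's model.

    Reference levels: never-smoker, female, no asthma, Iowa, European
    ancestry, non-winter season.  Quadratic terms are raw squares of the
    (uncentered) continuous covariates.  Rows with any missing covariate
    keep their NaN so complete-case handling happens downstream, never
    silently.
    """
    if outcome not in COVARIATE_ROSTERS:
        raise ValueError(f"unknown outcome {outcome!r}; "
                         f"expected one of {sorted(COVARIATE_ROSTERS)}")
    d = frame.data
    cols: dict[str, pd.Series] = {}
    cols["age"] = pd.to_numeric(d["age"])
    cols["age2"] = cols["age"] ** 2
    cols["sex_male"] = (d["sex"] == "male").astype(float).where(d["sex"].notna())
    cols["height"] = pd.to_numeric(d["height"])
    cols["height2"] = cols["height"] ** 2
    if "weight" in d.columns:
        cols["weight"] = pd.to_numeric(d["weight"])
    cols["smoking_former"] = (d["smoking"] == "former").astype(float).where(
        d["smoking"].notna())
    cols["smoking_current"] = (d["smoking"] == "current").astype(float).where(
        d["smoking"].notna())
    cols["pack_years"] = pd.to_numeric(d["pack_years"])
    cols["asthma_yes"] = (d["asthma"] == "yes").astype(float).where(
        d["asthma"].notna())
    cols["state_nc"] = (d["state"] == "NC").astype(float).where(d["state"].notna())
    cols["ancestry_not"] = (d["ancestry"] == "not").astype(float).where(
        d["ancestry"].notna())
    roster = list(COVARIATE_ROSTERS[outcome])
    if season_sensitivity:
        cols["season_winter"] = (d["season"] == "winter").astype(float).where(
            d["season"].notna())
        roster = roster + ["season_winter"]
    missing_cols = [c for c in roster if c not in cols]
    if missing_cols:
        raise FormatError(f"metadata lacks covariates: {missing_cols}")
    return pd.DataFrame({c: cols[c] for c in roster}, index=d.index)


@dataclass
class StandardizedDesign:
    """Centered/scaled predictors and response plus the raw covariate block.

    ``X`` holds taxon relative abundances with each column centered to
    mean 0 and scaled to sample SD 1 (ddof=1); ``y`` likewise.  ``Z`` is
    the dummy-coded covariate matrix, left on its natural scale (it is
    never penalized, so its scale is immaterial).  ``column_means`` and
    ``column_sds`` allow back-transformation of coefficients.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    y_mean: float
    y_sd: float
    taxon_ids: list[str]
    sample_ids: list[str]
    covariate_names: list[str] = field(default_factory=list)
    dropped_taxa: list[str] = field(default_factory=list)
    lineages: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(X_rel: np.ndarray, y: np.ndarray, Z_raw: pd.DataFrame,
                taxon_ids: list[str], sample_ids: list[str],
                lineages: list[str] | None = None) -> StandardizedDesign:
    """Center and scale predictors and response; drop constant columns.

    Uses the sample SD (ddof=1) consistently for X and y.  Columns of
    ``X_rel`` with zero variance are dropped with a warning and recorded
    in ``dropped_taxa``.  All inputs must be complete cases.
    """
    X_rel = np.asarray(X_rel, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z_raw, dtype=float)
    if np.isnan(X_rel).any() or np.isnan(y).any() or np.isnan(Z).any():
        raise ValueError("standardize requires complete cases; drop missing "
                         "rows upstream")
    mu = X_rel.mean(axis=0)
    sd = X_rel.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [taxon_ids[j] for j in np.flatnonzero(~keep)]
    if dropped:
        log.warning("standardize: dropping %d constant taxa: %s",
                    len(dropped), dropped[:5])
    Xs = (X_rel[:, keep] - mu[keep]) / sd[keep]
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("outcome has zero variance")
    ys = (y - y_mean) / y_sd
    lineages = list(lineages) if lineages is not None else [""] * len(taxon_ids)
    kept_idx = np.flatnonzero(keep)
    return StandardizedDesign(
        X=Xs, Z=Z, y=ys,
        column_means=mu[keep], column_sds=sd[keep],
        y_mean=y_mean, y_sd=y_sd,
        taxon_ids=[taxon_ids[j] for j in kept_idx],
        sample_ids=list(sample_ids),
        covariate_names=list(Z_raw.columns),
        dropped_taxa=dropped,
        lineages=[lineages[j] for j in kept_idx],
    )


def complete_cases(frame: SampleFrame, outcome: str,
                   season_sensitivity: bool = False) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Return sample ids, outcome vector and covariates for complete cases.

    FeNO is ln-transformed here (with below-LOD imputation) so every
    downstream consumer sees the analysis-scale outcome.  The number of
    dropped incomplete rows is logged.
    """
    Z = build_covariates(frame, outcome, season_sensitivity)
    if outcome == "feno":
        flags = frame.data.get("feno_below_lod")
        flags = (np.zeros(len(frame.data), dtype=bool) if flags is None
                 else flags.fillna(False).astype(bool).to_numpy())
        raw = frame.data["feno"].to_numpy(dtype=float)
        filled = raw.copy()
        filled[flags] = 1.0  # placeholder; imputed inside transform
        with np.errstate(invalid="ignore"):
            yvec = transform_feno(filled, below_lod=flags)
        yvec[np.isnan(raw) & ~flags] = np.nan
        y = pd.Series(yvec, index=frame.data.index)
    else:
        y = pd.to_numeric(frame.data[outcome])
    ok = y.notna() & Z.notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("complete_cases[%s]: dropped %d incomplete samples, %d kept",
                 outcome, n_drop, int(ok.sum()))
    ids = list(frame.data.index[ok])
    return ids, y[ok].to_numpy(dtype=float), Z.loc[ok]


def build_design(table: CountTable, frame: SampleFrame, outcome: str,
                 rank: str = "genus", filter_spec: FilterSpec | None = None,
                 season_sensitivity: bool = False,
                 k_top: int = 5) -> StandardizedDesign:
    """Run the full preprocessing chain and return the standardized design.

    filter -> aggregate to ``rank`` -> winsorize -> relative abundance ->
    align with complete-case metadata -> center/scale.
    """
    filt = filter_table(table, filter_spec)
    agg = aggregate_rank(filt, rank)
    ids, y, Z = complete_cases(frame, outcome, season_sensitivity)
    shared = [s for s in agg.sample_ids if s in set(ids)]
    if not shared:
        raise EmptyResultError("no samples shared between counts and metadata")
    agg = agg.reorder_samples(shared)
    win = winsorize_counts(agg, k_top=k_top)
    X_rel = to_relative_abundance(win)
    pos = {s: i for i, s in enumerate(ids)}
    order = [pos[s] for s in shared]
    return standardize(X_rel, y[order], Z.iloc[order], win.taxon_ids,
                       shared, lineages=win.lineages)
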