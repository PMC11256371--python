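"""Synthetic dust-metagenome data with known ground truth.

Emulates a post-classification genus-level count table from household
dust: heavily skewed per-sample sequencing depths, a few dominant taxa,
and a substantial fraction of zero cells; plus participant covariates
with realistic marginals, and continuous respiratory outcomes generated
as linear functions of covariates and a sparse set of standardized taxon
relative abundances.

Counts follow a Dirichlet-multinomial with a heavy-tailed (harmonic-decay)
concentration vector: the decay sets the dominance of the top taxa while
the total concentration sets between-sample compositional variability and
hence the zero fraction.  Outcomes are planted on the *post-preprocessing*
standardized abundance scale, so the true coefficients live on the same
scale the downstream inference estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, SampleFrame, format_lineage
from .preprocess import (standardize, to_relative_abundance, winsorize_counts)

# per-operation RNG stream offsets (reproducible without coupling streams)
_OFFSET_COUNTS = 1
_OFFSET_COVARIATES = 2
_OFFSET_OUTCOMES = 3

#: Phylum pool with dust-like overall shares (four phyla predominate).
_PHYLA = [
    ("Proteobacteria", 0.36),
    ("Actinobacteria", 0.30),
    ("Firmicutes", 0.15),
    ("Bacteroidetes", 0.10),
    ("Cyanobacteria", 0.03),
    ("Acidobacteria", 0.02),
    ("Deinococcus-Thermus", 0.02),
    ("Planctomycetes", 0.01),
    ("Verrucomicrobia", 0.01),
]

#: Outcome storage maps: analysis-scale value eta is stored as
#: loc + scale * eta (FeNO is stored in ppb, exp of the ln-scale value).
_OUTCOME_MAPS = {
    "fev1": (2649.0, 853.0, "identity"),
    "fvc": (3620.0, 1036.0, "identity"),
    "fev1_fvc": (0.73, 0.05, "clip01"),
    "feno": (2.8, 0.7, "exp"),
}


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Simulation parameters.

    ``concentration`` may be a scalar (symmetric Dirichlet), a full vector
    of length ``n_taxa``, or ``None`` for the default heavy-tailed vector
    ``total_concentration * (1/rank) / H_p`` whose harmonic decay puts
    roughly 28% of the mass on the top three taxa.  Depths are log-normal
    in reads; the defaults give a minimum near 1000 and a mean near 2e5
    across several hundred samples.
    """

    n_samples: int = 779
    n_taxa: int = 389
    n_causal: int = 5
    effect_sizes: np.ndarray | None = None  # standardized slopes, len n_causal
    depth_log_mean: float = 11.2
    depth_log_sd: float = 1.43
    concentration: float | np.ndarray | None = None
    total_concentration: float = 300.0
    noise_sd: float = 1.0
    covariate_effects: np.ndarray | float | None = 0.2  # on z-scored covariates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_taxa <= 0:
            raise ConfigurationError("n_samples and n_taxa must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_taxa:
            raise ConfigurationError("need 0 <= n_causal <= n_taxa")
        if self.effect_sizes is None:
            signs = np.where(np.arange(self.n_causal) % 2 == 0, 1.0, -1.0)
            self.effect_sizes = 0.3 * signs
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if len(self.effect_sizes) != self.n_causal:
            raise ConfigurationError("effect_sizes length must equal n_causal")

    def concentration_vector(self) -> np.ndarray:
        if self.concentration is None:
            ranks = np.arange(1, self.n_taxa + 1, dtype=float)
            w = 1.0 / ranks
            return self.total_concentration * w / w.sum()
        conc = np.asarray(self.concentration, dtype=float)
        if conc.ndim == 0:
            return np.full(self.n_taxa, float(conc))
        if conc.shape != (self.n_taxa,):
            raise ConfigurationError("concentration vector length mismatch")
        return conc


@dataclass
class SimTruth:
    """Planted ground truth for one simulated outcome."""

    causal_taxon_ids: list[str]
    true_beta: np.ndarray  # length n_taxa, standardized (analysis) scale
    true_covariate_beta: np.ndarray
    outcome: str = "fev1"
    outcome_loc: float = 0.0
    outcome_scale: float = 1.0
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        support = {self.taxon_ids[j] for j in np.flatnonzero(self.true_beta)} \
            if self.taxon_ids else set(self.causal_taxon_ids)
        if support != set(self.causal_taxon_ids):
            raise ConfigurationError("support(true_beta) != causal_taxon_ids")


def _taxonomy(n_taxa: int, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    names, lineages = [], []
    phyla = [p for p, _ in _PHYLA]
    probs = np.array([w for _, w in _PHYLA])
    assignment = rng.choice(len(phyla), size=n_taxa, p=probs / probs.sum())
    fam_counter: dict[str, int] = {}
    for j in range(n_taxa):
        ph = phyla[assignment[j]]
        fam_idx = int(rng.integers(1, 7))
        family = f"{ph[:5]}aceae{fam_idx}"
        genus = f"Genus{j + 1:03d}"
        fam_counter[family] = fam_counter.get(family, 0) + 1
        names.append(genus)
        lineages.append(format_lineage(
            ["Bacteria", ph, f"{ph[:5]}ia", f"{ph[:5]}ales", family, genus]))
    return names, lineages


def simulate_counts(config: SimConfig) -> CountTable:
    """Draw a Dirichlet-multinomial count table at log-normal depths.

    Each sample gets its own Dirichlet composition draw; its reads are a
    multinomial sample of that composition at its depth.  Row sums equal
    the drawn depths exactly.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + _OFFSET_COUNTS)
    depths = rng.lognormal(config.depth_log_mean, config.depth_log_sd,
                           size=config.n_samples)
    depths = np.maximum(1, np.round(depths)).astype(np.int64)
    conc = config.concentration_vector()
    counts = np.empty((config.n_samples, config.n_taxa), dtype=np.int64)
    for i in range(config.n_samples):
        if np.isinf(conc).any():
            comp = np.full(config.n_taxa, 1.0 / config.n_taxa)
        else:
            comp = rng.dirichlet(conc)
        counts[i] = rng.multinomial(depths[i], comp)
    taxon_ids, lineages = _taxonomy(config.n_taxa, rng)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    return CountTable(counts=counts, taxon_ids=taxon_ids,
                      lineages=lineages, sample_ids=sample_ids)


def simulate_covariates(n: int, seed: int = 0) -> SampleFrame:
    """Draw participant covariates with cohort-like marginals.

    Age ~ N(62, 11) years, 60% male, height sex-dependent around 171 cm,
    weight ~ N(90, 21) kg, smoking never/former/current at 65/29/6%,
    pack-years positive only in ever-smokers (mean about 21), asthma 38%,
    state NC 32% / IA 68%, European ancestry 96%, winter collection 23%.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed + _OFFSET_COVARIATES)
    age = np.clip(rng.normal(62.0, 11.0, n), 25.0, 95.0)
    sex = np.where(rng.random(n) < 0.60, "male", "female")
    height = np.where(sex == "male",
                      rng.normal(176.0, 7.0, n), rng.normal(163.0, 6.0, n))
    weight = np.clip(rng.normal(90.0, 21.0, n), 40.0, None)
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=[0.65, 0.29, 0.06])
    pack_years = np.where(smoking == "never", 0.0,
                          np.abs(rng.normal(21.0, 23.0, n)))
    asthma = np.where(rng.random(n) < 0.38, "yes", "no")
    state = np.where(rng.random(n) < 0.32, "NC", "IA")
    ancestry = np.where(rng.random(n) < 0.96, "european", "not")
    season = np.where(rng.random(n) < 0.23, "winter", "not_winter")
    df = pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": np.round(age, 1), "sex": sex, "height": np.round(height, 1),
        "weight": np.round(weight, 1), "smoking": smoking,
        "pack_years": np.round(pack_years, 1), "asthma": asthma,
        "state": state, "ancestry": ancestry, "season": season,
    })
    return SampleFrame(df)


def _standardized_abundance(table: CountTable) -> tuple[np.ndarray, list[int]]:
    """Winsorize, convert to relative abundance, center/scale.

    Mirrors the preprocessing the inference applies, minus filtering.
    Returns the standardized matrix over non-constant taxa plus the kept
    column indices into the original table.
    """
    win = winsorize_counts(table) if table.n_samples > 6 else table
    rel = to_relative_abundance(win)
    sd = rel.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    mu = rel[:, keep].mean(axis=0)
    X = (rel[:, keep] - mu) / sd[keep]
    return X, list(keep)


def simulate_outcomes(table: CountTable, covars: SampleFrame,
                      config: SimConfig, outcome: str = "fev1",
                      ) -> tuple[SampleFrame, SimTruth]:
    """Generate an outcome column with a planted sparse taxon signal.

    On the analysis scale, eta = Z_std @ gamma + X_std @ beta + N(0,
    noise_sd^2), where X_std is the standardized relative-abundance matrix
    (same preprocessing the inference uses) and Z_std the z-scored
    covariate design for this outcome.  eta is then mapped to the
    outcome's storage scale (e.g. ml for spirometry, ppb for FeNO, where
    the map is exp so the analysis ln-transform recovers eta affinely).
    Causal taxa are drawn among the more abundant half so downstream
    rare-taxon filtering does not remove them.
    """
    from .preprocess import build_covariates  # local import avoids cycle

    if outcome not in _OUTCOME_MAPS:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    if list(table.sample_ids) != list(covars.sample_ids):
        try:
            covars = covars.reorder(table.sample_ids)
        except Exception as exc:
            raise ConfigurationError(
                "count table and covariates have mismatched sample ids"
            ) from exc
    rng = np.random.default_rng(config.seed + _OFFSET_OUTCOMES)
    n = table.n_samples
    X_std, kept = _standardized_abundance(table)

    # eligible causal taxa: non-constant and in the upper half by reads
    totals = table.taxon_totals()
    order = np.argsort(totals)[::-1]
    abundant = set(order[: max(config.n_causal, table.n_taxa // 2)])
    eligible = [j for j in kept if j in abundant]
    if len(eligible) < config.n_causal:
        eligible = list(kept)
    causal = sorted(rng.choice(eligible, size=config.n_causal, replace=False)) \
        if config.n_causal else []

    beta_full = np.zeros(table.n_taxa)
    for b, j in zip(config.effect_sizes, causal):
        beta_full[j] = b
    col_of = {j: c for c, j in enumerate(kept)}
    taxon_signal = X_std @ np.array([beta_full[j] for j in kept]) if kept else 0.0

    Z = build_covariates(covars, outcome).to_numpy(dtype=float)
    Zsd = Z.std(axis=0, ddof=1)
    Zsd[Zsd == 0] = 1.0
    Z_std = (Z - Z.mean(axis=0)) / Zsd
    q = Z.shape[1]
    gamma = config.covariate_effects
    if gamma is None:
        gamma = np.zeros(q)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (q,)).copy()

    eta = Z_std @ gamma + taxon_signal + rng.normal(0.0, config.noise_sd, n)

    loc, scale, link = _OUTCOME_MAPS[outcome]
    stored = loc + scale * eta
    if link == "exp":
        stored = np.exp(stored)
    elif link == "clip01":
        stored = np.clip(stored, 1e-3, 1.0)
    data = covars.data.copy()
    data[outcome] = np.asarray(stored)
    if outcome == "feno":
        data["feno_below_lod"] = False
    truth = SimTruth(
        causal_taxon_ids=[table.taxon_ids[j] for j in causal],
        true_beta=beta_full,
        true_covariate_beta=gamma,
        outcome=outcome, outcome_loc=loc, outcome_scale=scale,
        taxon_ids=list(table.taxon_ids),
    )
    return SampleFrame(data), truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Persist planted truth as a TSV sidecar."""
    df = pd.DataFrame({
        "taxon_id": truth.taxon_ids,
        "true_beta": truth.true_beta,
        "causal": [t in set(truth.causal_taxon_ids) for t in truth.taxon_ids],
    })
    with open(path, "w") as fh:
        fh.write(f"# outcome={truth.outcome} loc={truth.outcome_loc} "
                 f"scale={truth.outcome_scale}\n")
        df.to_csv(fh, sep="\t", index=False)
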