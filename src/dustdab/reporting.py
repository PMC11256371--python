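"""Presentation layer: composition summaries, coefficient heatmap,
cross-outcome overlap, and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import CountTable, ResultTable, parse_lineage  # noqa: E402

log = logging.getLogger("dustdab")

_RANK_DEPTH = {"kingdom": 0, "phylum": 1, "class": 2, "order": 3,
               "family": 4, "genus": 5, "species": 6}


def summarize_composition(table: CountTable, rank: str = "phylum",
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample relative abundance at a taxonomic rank.

    Returns a samples-by-rank frame whose rows sum to 1, plus the overall
    rank shares of all reads pooled.
    """
    if rank not in _RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    depth = _RANK_DEPTH[rank]
    labels = [parse_lineage(s)[depth] or "unclassified" for s in table.lineages]
    groups: dict[str, list[int]] = {}
    for j, lab in enumerate(labels):
        groups.setdefault(lab, []).append(j)
    agg = np.column_stack([table.counts[:, idx].sum(axis=1)
                           for idx in groups.values()])
    totals = agg.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    per_sample = pd.DataFrame(agg / totals, index=table.sample_ids,
                              columns=list(groups))
    overall = pd.Series(agg.sum(axis=0) / agg.sum(), index=list(groups))
    return per_sample, overall.sort_values(ascending=False)


def cross_outcome_overlap(results: dict[str, ResultTable]) -> pd.DataFrame:
    """Which outcomes each taxon is significant for, plus overlap counts.

    One row per taxon significant for at least one outcome, with a boolean
    column per outcome and ``n_outcomes`` counting memberships.
    """
    if len(results) < 2:
        raise ValueError("overlap needs results for at least 2 outcomes")
    sig = {out: set(rt.significant_taxa()) for out, rt in results.items()}
    taxa = sorted(set().union(*sig.values()))
    rows = {out: [t in s for t in taxa] for out, s in sig.items()}
    df = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"))
    df["n_outcomes"] = df.sum(axis=1)
    return df


def coefficient_heatmap(results: dict[str, ResultTable],
                        path: str | Path) -> Path | None:
    """Taxa-by-outcome heatmap of signed coefficients, starred at p < 0.05.

    Rows are taxa significant for at least one outcome, ordered by
    taxonomy (phylum, family, genus); stars copy the ``significant`` flag
    from the result tables, never recomputing p-values.  Written as SVG.
    """
    sig_union: list[str] = []
    meta: dict[str, tuple[str, str, str]] = {}
    for rt in results.values():
        for _, row in rt.data.iterrows():
            meta[row["taxon_id"]] = (row["phylum"], row["family"], row["genus"])
        sig_union.extend(rt.significant_taxa())
    taxa = sorted(set(sig_union), key=lambda t: meta.get(t, ("", "", t)))
    if not taxa:
        log.warning("coefficient_heatmap: no significant taxa; skipped")
        return None
    outcomes = list(results)
    coef = np.full((len(taxa), len(outcomes)), np.nan)
    starred = np.zeros_like(coef, dtype=bool)
    for k, out in enumerate(outcomes):
        d = results[out].data.set_index("taxon_id")
        for i, t in enumerate(taxa):
            if t in d.index:
                coef[i, k] = d.loc[t, "coefficient"]
                starred[i, k] = bool(d.loc[t, "significant"])
    fig, ax = plt.subplots(
        figsize=(2 + 1.2 * len(outcomes), 1 + 0.28 * len(taxa)))
    vmax = np.nanmax(np.abs(coef)) or 1.0
    im = ax.imshow(coef, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(outcomes)), outcomes)
    ax.set_yticks(range(len(taxa)),
                  [f"{meta.get(t, ('', '', t))[0]} | {t}" for t in taxa],
                  fontsize=7)
    for i in range(len(taxa)):
        for k in range(len(outcomes)):
            if starred[i, k]:
                ax.text(k, i, "*", ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax, label="debiased coefficient (standardized)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    log.info("coefficient_heatmap: %d taxa x %d outcomes -> %s",
             len(taxa), len(outcomes), path)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit.

    Records input content hashes, every stage's seed, filter thresholds,
    and the dimensions flowing through each stage.  Deliberately excludes
    wall-clock information so identical runs serialize identically.
    """

    command: str = ""
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    dimensions: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def add_input(self, name: str, path: str | Path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": file_sha256(path)}

    def to_json(self) -> str:
        payload = {
            "command": self.command, "version": self.version,
            "seeds": self.seeds, "inputs": self.inputs,
            "parameters": self.parameters, "dimensions": self.dimensions,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
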