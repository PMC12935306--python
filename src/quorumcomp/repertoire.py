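"""Toxin-repertoire comparison and differential-expression panel reports.

top_match_identity builds the reference-by-isolate matrix of best protein
identities among LXG-domain (type VII secretion substrate) proteins: for each
reference toxin, the highest global-alignment identity to any domain-flagged
protein of each isolate. The domain hits themselves (e.g. a PF04740 search)
are consumed as an input table, not recomputed.

toxin_panel_filter applies the differential-expression cut (FDR < 0.01 and
|logFC| > 1 by default, both strict) and restricts the report to a supplied
toxin gene list; operon_regulation_summary flags operons whose members all
move > 2-fold in the same direction (|logFC| >= 1 on the log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import protein_identity

HIT_COLUMNS = ("genome_id", "protein_id", "family", "evalue")
DE_COLUMNS = ("gene", "logFC", "FDR")


class SchemaError(ValueError):
    """Input table lacks a required column."""


@dataclass
class PanelConfig:
    fdr_max: float = 0.01
    abs_lfc_min: float = 1.0
    toxin_genes: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self):
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.abs_lfc_min < 0:
            raise ValueError("abs_lfc_min must be >= 0")


@dataclass
class PanelReport:
    toxin_rows: pd.DataFrame       # toxin-list rows that pass, with direction
    n_pass_total: int              # all passing transcripts in the table
    n_pass_toxin: int
    n_toxin_measured: int


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {missing}")


def top_match_identity(reference_proteins: Mapping[str, str],
                       isolate_proteomes: Mapping[str, Mapping[str, str]],
                       hits: pd.DataFrame,
                       family: str | None = None) -> pd.DataFrame:
    """Matrix (reference x isolate) of max % identity to any domain-flagged
    protein; isolates without hits get missing values."""
    _check_columns(hits, ("genome_id", "protein_id"), "hit table")
    sel = hits
    if family is not None and "family" in hits.columns:
        sel = hits[hits["family"] == family]

    flagged: dict[str, list[str]] = {iso: [] for iso in isolate_proteomes}
    for _, row in sel.iterrows():
        iso, pid = row["genome_id"], row["protein_id"]
        if iso not in isolate_proteomes:
            continue
        if pid not in isolate_proteomes[iso]:
            raise KeyError(
                f"protein id {pid!r} not present in proteome of {iso!r}")
        flagged[iso].append(pid)

    mat = pd.DataFrame(index=list(reference_proteins),
                       columns=list(isolate_proteomes), dtype=float)
    for ref_name, ref_seq in reference_proteins.items():
        for iso, pids in flagged.items():
            if not pids:
                mat.loc[ref_name, iso] = np.nan
                continue
            mat.loc[ref_name, iso] = max(
                protein_identity(ref_seq, isolate_proteomes[iso][p])
                for p in pids)
    return mat


def toxin_panel_filter(de_table: pd.DataFrame,
                       config: PanelConfig) -> PanelReport:
    """Strict-inequality panel filter restricted to the toxin gene list."""
    _check_columns(de_table, DE_COLUMNS, "DE table")
    passing = de_table[(de_table["FDR"] < config.fdr_max)
                       & (de_table["logFC"].abs() > config.abs_lfc_min)]
    toxins = set(config.toxin_genes)
    toxin_rows = passing[passing["gene"].isin(toxins)].copy()
    toxin_rows["direction"] = np.where(toxin_rows["logFC"] > 0, "up", "down")
    measured = int(de_table["gene"].isin(toxins).sum())
    return PanelReport(toxin_rows.reset_index(drop=True),
                       int(len(passing)), int(len(toxin_rows)), measured)


def operon_regulation_summary(de_table: pd.DataFrame,
                              operon_gene_sets: Mapping[str, Sequence[str]],
                              fold_lfc: float = 1.0) -> pd.DataFrame:
    """Per-operon uniform-regulation flags.

    An operon is 'uniformly down > 2-fold' iff every member has
    logFC <= -fold_lfc (and analogously up). Members absent from the table
    are flagged not-measured and block the operon flag.
    """
    _check_columns(de_table, DE_COLUMNS, "DE table")
    lfc = de_table.set_index("gene")["logFC"]
    rows = []
    for operon, members in operon_gene_sets.items():
        members = list(members)
        if not members:
            raise ValueError(f"operon {operon!r} has an empty gene set")
        missing = [m for m in members if m not in lfc.index]
        present = [m for m in members if m in lfc.index]
        vals = lfc.loc[present]
        down = not missing and bool((vals <= -fold_lfc).all())
        up = not missing and bool((vals >= fold_lfc).all())
        fail_down = [m for m in present if lfc[m] > -fold_lfc]
        fail_up = [m for m in present if lfc[m] < fold_lfc]
        rows.append({
            "operon": operon,
            "n_members": len(members),
            "uniform_down": down,
            "uniform_up": up,
            "not_measured": ",".join(missing),
            "members_failing_down": "" if down else ",".join(fail_down),
            "members_failing_up": "" if up else ",".join(fail_up),
        })
    return pd.DataFrame(rows)


def save_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Write the identity matrix as a heatmap image (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * matrix.shape[1]),
                                    max(3, 0.4 * matrix.shape[0])))
    im = ax.imshow(matrix.to_numpy(dtype=float), vmin=0, vmax=100,
                   cmap="viridis", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="% identity of top match")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
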