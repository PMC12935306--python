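"""Synthetic differential-expression tables with known pass/fail truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class DETable:
    """A gene/logFC/FDR table plus the set of genes that truly pass the
    panel filter (FDR < fdr_max strictly and |logFC| > abs_lfc_min strictly)."""

    table: pd.DataFrame
    truth_pass: set[str]
    fdr_max: float
    abs_lfc_min: float


def make_de_table(n_genes: int, toxin_ids: Sequence[str] = (),
                  effects: Mapping[str, tuple[float, float]] | None = None,
                  seed: int = 0, fdr_max: float = 0.01,
                  abs_lfc_min: float = 1.0) -> DETable:
    """Random DE table of n_genes rows; toxin_ids become the first gene ids;
    effects pins (logFC, FDR) for named genes. Duplicate ids are an error."""
    toxin_ids = list(toxin_ids)
    if len(set(toxin_ids)) != len(toxin_ids):
        raise ValueError("duplicate gene ids in toxin_ids")
    if len(toxin_ids) > n_genes:
        raise ValueError("more toxin ids than genes")
    genes = toxin_ids + [f"gene_{i:04d}" for i in range(n_genes - len(toxin_ids))]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")

    rng = np.random.default_rng(seed)
    lfc = rng.normal(0.0, 1.2, size=n_genes)
    fdr = rng.uniform(0.0, 1.0, size=n_genes)
    df = pd.DataFrame({"gene": genes, "logFC": lfc, "FDR": fdr})
    if effects:
        unknown = set(effects) - set(genes)
        if unknown:
            raise ValueError(f"effects name unknown genes: {sorted(unknown)}")
        for g, (l, f) in effects.items():
            df.loc[df["gene"] == g, ["logFC", "FDR"]] = (l, f)

    passing = set(df.loc[(df["FDR"] < fdr_max)
                         & (df["logFC"].abs() > abs_lfc_min), "gene"])
    return DETable(df, passing, fdr_max, abs_lfc_min)
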