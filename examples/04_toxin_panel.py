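"""Toxin-panel filtering of a differential-expression table and the
LXG-toxin top-match identity matrix.

Builds a synthetic DE table with a few pinned toxin effects, applies the
panel filter (FDR < 0.01 and |logFC| > 1, both strict), summarises operon-
level regulation, and computes a small reference-by-isolate identity matrix
for LXG-domain (type VII secretion substrate) proteins.
"""

import numpy as np
import pandas as pd

from quorumcomp.repertoire import (PanelConfig, operon_regulation_summary,
                                   top_match_identity, toxin_panel_filter)
from quorumcomp.tables import make_de_table

# DE table: the ywq operon uniformly down > 2-fold, one toxin just missing
# the cut, everything else random
toxins = ["ywqJ", "ywqK", "ywqL", "sdpC", "skfA", "wapA"]
de = make_de_table(500, toxin_ids=toxins, seed=3, fdr_max=0.01,
                   abs_lfc_min=1.0)
pinned = {"ywqJ": (-2.3, 1e-6), "ywqK": (-1.8, 1e-5), "ywqL": (-2.9, 1e-7),
          "sdpC": (-0.8, 1e-4), "wapA": (-1.4, 0.02)}
for gene, (lfc, fdr) in pinned.items():
    de.table.loc[de.table["gene"] == gene, ["logFC", "FDR"]] = (lfc, fdr)

report = toxin_panel_filter(de.table, PanelConfig(toxin_genes=toxins))
print(f"{report.n_pass_total} transcripts pass FDR < 0.01 and |logFC| > 1; "
      f"{report.n_pass_toxin} of {report.n_toxin_measured} toxin genes:")
print(report.toxin_rows.to_string(index=False))
print("(sdpC fails |logFC| > 1; wapA fails FDR < 0.01 — both cuts are strict)")

ops = operon_regulation_summary(de.table, {"ywq": ["ywqJ", "ywqK", "ywqL"]})
print("\noperon regulation:")
print(ops[["operon", "uniform_down", "uniform_up"]].to_string(index=False))

# top-match identity: one isolate carries a near-identical YwqJ homologue,
# the other only a distant LXG protein
ref = "MKLLAVTGSELLDKVKQWREANPNARSTELLQKLGLSEEQLEAVKNM" * 3
rng = np.random.default_rng(0)
near = "".join("A" if i in set(rng.choice(len(ref), 10, replace=False))
               and c != "A" else c for i, c in enumerate(ref))
far = "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                    for i in rng.integers(0, 20, len(ref) - 1))
proteomes = {"iso_coexists": {"p1": near}, "iso_excluded": {"q1": far}}
hits = pd.DataFrame([("iso_coexists", "p1", "PF04740", 1e-40),
                     ("iso_excluded", "q1", "PF04740", 1e-8)],
                    columns=["genome_id", "protein_id", "family", "evalue"])
mat = top_match_identity({"ywqJ": ref}, proteomes, hits)
print("\ntop-match % identity to the reference YwqJ:")
print(mat.round(1).to_string())
print("(similar repertoires accompany coexistence; divergent ones, exclusion)")
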