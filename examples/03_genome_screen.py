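"""Screening annotated genomes for quorum-sensing gene disruptions.

Generates a small panel of synthetic genomes carrying engineered comP
mutations of each screening class (plus rapP-phrP modules), writes them as
FASTA + GFF3, runs the directory screen, and prints the per-genome calls and
the census summary. The Delta633-649 in-frame deletion is the worked
example: the predicted variant protein is exactly 17 aa shorter than the
reference ComP.
"""

import tempfile
from pathlib import Path

from quorumcomp._io import write_genome
from quorumcomp.genomes import (MutationSpec, make_rapP_module,
                                make_reference_operon, mutate_comP)
from quorumcomp.operon import classify_comP, extract_comQXPA
from quorumcomp.pipeline import run_screen
from quorumcomp.references import default_references

refs = default_references()

# the worked example: excise ComP codons 633-649 (inclusive)
genome = make_reference_operon("3610", seed=1)
mutant = mutate_comP(genome, MutationSpec("inframe_3prime_deletion",
                                          position=633, size=17))
call = classify_comP(extract_comQXPA(mutant, refs), refs)
print(f"Delta633-649: status={call.status}, classes={sorted(call.classes)}, "
      f"predicted length {call.predicted_length_aa} aa "
      f"({refs.comP_length_aa - call.predicted_length_aa} aa shorter than "
      f"the {refs.comP_length_aa}-aa reference)")

# a mixed panel screened from files, exactly as real genomes would be
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    panel = {
        "intact": None,
        "stop_at_200": MutationSpec("nonsense", 200, 1),
        "slipped_polyT": MutationSpec("polyT_slip", size=1),
        "is_insertion": MutationSpec("insertion_element", 400, 4),
    }
    for name, spec in panel.items():
        g = make_reference_operon("3610", seed=len(name))
        if spec is not None:
            g = mutate_comP(g, spec)
        g.genome_id = name
        write_genome(g, tmp / f"{name}.fasta", tmp / f"{name}.gff3")
    rp = make_rapP_module("T", "complete", "plasmid", seed=5)
    rp.genome_id = "plasmid_rapP_T236"
    write_genome(rp, tmp / "plasmid_rapP_T236.fasta",
                 tmp / "plasmid_rapP_T236.gff3")

    report, summary = run_screen(tmp, tmp / "out")
    cols = ["genome_id", "comP_status", "comP_classes",
            "comP_predicted_length_aa", "hotspot_run_length",
            "rapP_presence", "rapP_residue_236", "rapP_replicon"]
    print("\nper-genome calls:")
    print(report[cols].to_string(index=False))
    print("\ncensus summary:", {k: v for k, v in summary.items()
                                if not isinstance(v, dict)})
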