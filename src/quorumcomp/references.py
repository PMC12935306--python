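"""Reference sequences and thresholds used by the screening modules.

The default reference set is derived from the packaged synthetic templates
(3610-like operon, pherotype ComQ panel, RapP/PhrP). For real screens users
construct a ReferenceSet from their own reference strain sequences; every
threshold is a field so the screen's operating point is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from . import genomes
from .genomes import translate


@dataclass
class ReferenceSet:
    """Everything the comP / rapP screens compare against.

    conserved_boundary_codon: first codon (1-based, reference numbering) of
    the conserved 3' region of comP; in-frame deletions at or beyond it are
    disruptive. hotspot_offset: 0-based nt offset of the poly-T tract start in
    the reference comP CDS; hotspot_run: its length (eight thymidines).
    """

    comP_cds: str
    comP_protein: str
    comQ_pherotypes: dict[str, str]
    rapP_protein: str
    phrP_protein: str
    hotspot_offset: int | None = None
    hotspot_run: int = 8
    conserved_boundary_codon: int = 300
    # comP classification thresholds
    truncation_fraction: float = 0.95      # stop before this fraction => nonsense
    insertion_element_min_nt: int = 100
    # pherotype assignment
    pherotype_min_identity: float = 90.0
    pherotype_min_margin: float = 5.0
    # gene identification fallback (annotation-name drift)
    gene_id_min_identity: float = 40.0
    gene_id_min_coverage: float = 0.70
    # rapP detection
    rapp_min_identity: float = 80.0
    rapp_min_coverage: float = 0.60
    rapp_complete_coverage: float = 0.95
    rapp_residue: int = 236
    phrp_min_identity: float = 60.0
    phrp_window_nt: int = 500
    reference_proteins: dict[str, str] = field(default_factory=dict)

    @property
    def comP_length_aa(self) -> int:
        return len(self.comP_protein)


@lru_cache(maxsize=1)
def default_references() -> ReferenceSet:
    t = genomes._templates()
    comp = t["comP"]["3610"]
    refs = ReferenceSet(
        comP_cds=comp,
        comP_protein=translate(comp),
        comQ_pherotypes={k: translate(v) for k, v in t["comQ"].items()},
        rapP_protein=translate(t["rapP"]["T"]),
        phrP_protein=translate(t["phrP"]),
        hotspot_offset=t["hotspot_offset"],
    )
    refs.reference_proteins = {
        "comQ": refs.comQ_pherotypes["3610"],
        "comX": translate(t["comX"]),
        "comP": refs.comP_protein,
        "comA": translate(t["comA"]),
    }
    return refs


def boundary_from_alignment(aligned_cds: list[str], window_codons: int = 10,
                            min_identity: float = 0.80) -> int:
    """Derive the conserved-3'-region boundary from a multi-pherotype comP
    alignment: the first reference codon where windowed column identity
    exceeds the cutoff from there on.

    aligned_cds: equal-length gapped nucleotide rows, first row = reference.
    Returns a 1-based reference codon index.
    """
    if len(aligned_cds) < 2:
        raise ValueError("need at least two aligned sequences")
    ref = aligned_cds[0]
    ncol = len(ref)
    col_ident = []
    for i in range(ncol):
        ref_c = ref[i]
        if ref_c == "-":
            col_ident.append(None)
            continue
        same = sum(1 for row in aligned_cds[1:] if row[i] == ref_c)
        col_ident.append(same / (len(aligned_cds) - 1))
    # windowed identity per codon start over reference positions, then the
    # first codon from which every downstream window clears the cutoff
    ref_cols = [c for c in col_ident if c is not None]
    w = 3 * window_codons
    n_windows = (len(ref_cols) - w) // 3 + 1
    if n_windows <= 0:
        raise ValueError("alignment shorter than one window")
    win_ident = [sum(ref_cols[3 * k: 3 * k + w]) / w for k in range(n_windows)]
    suffix_ok = len(win_ident)
    for k in range(len(win_ident) - 1, -1, -1):
        if win_ident[k] > min_identity:
            suffix_ok = k
        else:
            break
    return suffix_ok + 1
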