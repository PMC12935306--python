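"""comQXPA operon extraction and comP allele classification.

The screen locates the quorum-sensing cassette in an annotated genome,
extracts the operon span (comQ start to comA end on the operon strand), and
classifies the comP allele against a reference under four disruption
criteria: internal nonsense mutations causing premature truncation,
frameshift-inducing indels, in-frame deletions within the conserved 3'
region, and insertion-element (transposon-scale) insertions. Point
substitutions are deliberately not called disruptive. The predicted variant
protein length is computed by translating the variant allele in its own
frame(s) through any frameshift to the first stop, and the poly-T
slipped-strand hotspot is located by anchoring the reference tract locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .align import local_align_nt, nt_alignment, protein_identity
from .genomes import Feature, SyntheticGenome, revcomp, translate
from .references import ReferenceSet, default_references

OPERON_GENES = ("comQ", "comX", "comP", "comA")

#: nt of genomic context kept downstream of comP for read-through translation
_DOWNSTREAM_CONTEXT = 3000


@dataclass
class OperonRecord:
    genome_id: str
    genes: dict[str, Feature | None]
    gene_seqs: dict[str, str]
    strand: str | None
    operon_seq: str
    completeness: list[str] = field(default_factory=list)
    comP_context: str = ""          # comP CDS + downstream genomic sequence

    @property
    def complete(self) -> bool:
        return not self.completeness


@dataclass
class HotspotRecord:
    present: bool
    run_length: int = 0
    indel_in_run: bool = False


@dataclass
class ComPCall:
    status: str                     # intact | disrupted | undetermined
    classes: set[str] = field(default_factory=set)
    predicted_length_aa: int = 0
    runs_off: bool = False
    hotspot: HotspotRecord = field(default_factory=lambda: HotspotRecord(False))
    identity: float = 0.0
    reason: str = ""


@dataclass
class PherotypeCall:
    label: str                      # pherotype label or "unassigned"
    identity: float = 0.0
    runner_up: float = 0.0


class VariantLength(NamedTuple):
    length_aa: int
    runs_off: bool


def _identify_genes(genome: SyntheticGenome,
                    refs: ReferenceSet) -> dict[str, Feature | None]:
    """Locate operon genes by annotated symbol, falling back to protein
    similarity against the reference proteins (annotation-name drift)."""
    found: dict[str, Feature | None] = {g: None for g in OPERON_GENES}
    by_symbol = {g.lower(): g for g in OPERON_GENES}
    unnamed: list[Feature] = []
    for f in genome.features:
        key = f.gene.lower()
        if key in by_symbol and found[by_symbol[key]] is None:
            found[by_symbol[key]] = f
        elif key not in by_symbol:
            unnamed.append(f)
    missing = [g for g in OPERON_GENES if found[g] is None]
    if missing and unnamed:
        for g in missing:
            ref_prot = refs.reference_proteins.get(g, "")
            if not ref_prot:
                continue
            best, best_id = None, 0.0
            for f in unnamed:
                prot = translate(genome.feature_seq(f))
                if len(prot) < refs.gene_id_min_coverage * len(ref_prot):
                    continue
                ident = protein_identity(ref_prot, prot)
                if ident > best_id:
                    best, best_id = f, ident
            if best is not None and best_id >= refs.gene_id_min_identity:
                found[g] = best
    return found


def extract_comQXPA(genome: SyntheticGenome,
                    refs: ReferenceSet | None = None) -> OperonRecord:
    """Locate the comQXPA genes and extract the operon nucleotide sequence
    (comQ start to comA end, operon strand). Minus-strand operons are
    reverse-complemented; missing or fragmented genes are flagged, not fatal.
    """
    refs = refs or default_references()
    genes = _identify_genes(genome, refs)
    flags: list[str] = [f"{g} missing" for g in OPERON_GENES if genes[g] is None]

    present = {g: f for g, f in genes.items() if f is not None}
    gene_seqs = {g: genome.feature_seq(f) for g, f in present.items()}

    strand = None
    if present:
        strands = {f.strand for f in present.values()}
        contigs = {f.contig for f in present.values()}
        if len(contigs) > 1:
            flags.append("fragmented")
        elif len(strands) > 1:
            flags.append("mixed strand")
        else:
            strand = strands.pop()

    operon_seq = ""
    if strand is not None and genes["comQ"] and genes["comA"]:
        contig = genome.contigs[genes["comQ"].contig]
        lo = min(f.start for f in present.values())
        hi = max(f.end for f in present.values())
        span = contig[lo:hi]
        operon_seq = revcomp(span) if strand == "-" else span
        # syntenic order check along the operon strand
        order = sorted(present, key=lambda g: present[g].start,
                       reverse=(strand == "-"))
        if [g for g in order] != [g for g in OPERON_GENES if g in present]:
            flags.append("non-syntenic order")

    comp_context = ""
    if genes["comP"] is not None:
        f = genes["comP"]
        contig = genome.contigs[f.contig]
        if f.strand == "+":
            comp_context = contig[f.start:min(len(contig),
                                              f.end + _DOWNSTREAM_CONTEXT)]
        else:
            comp_context = revcomp(contig[max(0, f.start - _DOWNSTREAM_CONTEXT):f.end])

    return OperonRecord(genome.genome_id, genes, gene_seqs, strand,
                        operon_seq, flags, comp_context)


def predicted_variant_length(seq: str,
                             refs: ReferenceSet | None = None) -> VariantLength:
    """Length (aa) of the protein produced by translating from the annotated
    start in the variant's own frame(s) through frameshifts to the first
    stop; the stop is excluded. runs_off flags a missing stop, in which case
    the length is the translated span."""
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3].upper()
        if codon in ("TAA", "TAG", "TGA"):
            return VariantLength(i // 3, False)
    return VariantLength(len(seq) // 3, True)


def detect_polyT_hotspot(seq: str,
                         refs: ReferenceSet | None = None,
                         flank: int = 25) -> HotspotRecord:
    """Anchor the reference poly-T tract locus by local alignment and report
    the observed maximal T-run there plus whether an indel relative to the
    reference falls inside the run. Absent when the locus does not align
    (pherotypes whose divergent 5' region lacks the tract)."""
    refs = refs or default_references()
    if refs.hotspot_offset is None or not seq:
        return HotspotRecord(False)
    off, run = refs.hotspot_offset, refs.hotspot_run
    window = refs.comP_cds[max(0, off - flank): off + run + flank]
    aln = local_align_nt(window, seq.upper())
    if aln is None or aln.score < 0.6 * len(window):
        return HotspotRecord(False)
    r_row, q_row = str(aln[0]), str(aln[1])
    t_start = int(aln.coordinates[0][0])
    q_start = int(aln.coordinates[1][0])
    run_lo = (off - max(0, off - flank))        # run start within the window
    run_hi = run_lo + run
    # the run must actually be covered by the local alignment
    if not (t_start <= run_lo and t_start + sum(c != "-" for c in r_row) >= run_hi):
        return HotspotRecord(False)

    rpos, qpos = t_start, q_start
    indel = False
    q_span = [None, None]
    for rc, qc in zip(r_row, q_row):
        in_run = run_lo <= rpos < run_hi or (rc == "-" and run_lo <= rpos <= run_hi)
        if in_run and (rc == "-" or qc == "-"):
            indel = True
        if in_run and qc != "-":
            if q_span[0] is None:
                q_span[0] = qpos
            q_span[1] = qpos + 1
        if rc != "-":
            rpos += 1
        if qc != "-":
            qpos += 1
    if q_span[0] is None:
        return HotspotRecord(True, 0, True)
    # maximal T-run in the query overlapping the mapped tract
    lo = q_span[0]
    while lo > 0 and seq[lo - 1].upper() == "T":
        lo -= 1
    hi = q_span[1]
    while hi < len(seq) and seq[hi].upper() == "T":
        hi += 1
    best = cur = 0
    for c in seq[lo:hi].upper():
        cur = cur + 1 if c == "T" else 0
        best = max(best, cur)
    return HotspotRecord(True, best, indel)


def classify_comP(operon: OperonRecord,
                  refs: ReferenceSet | None = None) -> ComPCall:
    """Codon-aware comparison of the comP allele to the reference.

    Premature in-frame stop before ``truncation_fraction`` of the reference
    length => nonsense; net intra-CDS indel length not divisible by 3 (large
    insertion-element insertions excluded) => frameshift; in-frame deletion of
    >= 1 codon at or beyond the conserved-region boundary =>
    inframe_3prime_deletion; insertion >= ``insertion_element_min_nt`` within
    the CDS => insertion_element. Classes may co-occur; none => intact.
    """
    refs = refs or default_references()
    if operon.genes.get("comP") is None:
        return ComPCall("undetermined", reason="comP missing")
    cds = operon.gene_seqs["comP"].upper()
    ref = refs.comP_cds
    identity, blocks = nt_alignment(ref, cds)

    classes: set[str] = set()
    small_net = 0
    # stops downstream of a frameshift or inside an inserted element are
    # consequences of that indel, not independent nonsense mutations
    first_disrupt_qpos = math.inf
    for b in blocks:
        if b.kind == "ins" and b.length >= refs.insertion_element_min_nt:
            classes.add("insertion_element")
            first_disrupt_qpos = min(first_disrupt_qpos, b.qry_pos)
            continue
        if b.kind == "del" and b.length % 3 == 0:
            codon = b.ref_pos // 3 + 1
            if codon >= refs.conserved_boundary_codon:
                classes.add("inframe_3prime_deletion")
            continue
        if b.kind == "ins" and b.length % 3 == 0:
            continue  # short in-frame insertion: reported non-disruptive
        small_net += b.length if b.kind == "ins" else -b.length
        first_disrupt_qpos = min(first_disrupt_qpos, b.qry_pos)
    if small_net % 3 != 0:
        classes.add("frameshift")

    # nonsense: a premature stop at an in-frame position upstream of any
    # frameshifting or element-scale indel
    ref_aa = refs.comP_length_aa
    vl = predicted_variant_length(operon.comP_context or cds, refs)
    # the stop codon spans query nt [3*len, 3*len + 3); it is an independent
    # nonsense mutation only when it ends strictly upstream of the first
    # disruptive indel (a stop created at the indel is the indel's doing)
    stop_codon_end_nt = 3 * vl.length_aa + 3
    if (not vl.runs_off
            and vl.length_aa < refs.truncation_fraction * ref_aa
            and stop_codon_end_nt <= first_disrupt_qpos):
        classes.add("nonsense")

    hotspot = detect_polyT_hotspot(cds, refs)
    status = "disrupted" if classes else "intact"
    return ComPCall(status, classes, vl.length_aa, vl.runs_off, hotspot,
                    identity)


def assign_pherotype(comQ_protein: str,
                     refs: ReferenceSet | None = None) -> PherotypeCall:
    """Assign the pherotype whose reference ComQ is nearest by global
    alignment identity, when identity and margin clear the thresholds."""
    refs = refs or default_references()
    if not comQ_protein:
        return PherotypeCall("unassigned")
    scored = sorted(((protein_identity(ref, comQ_protein), label)
                     for label, ref in refs.comQ_pherotypes.items()),
                    reverse=True)
    best_id, best_label = scored[0]
    runner = scored[1][0] if len(scored) > 1 else 0.0
    if best_id >= refs.pherotype_min_identity and \
            best_id - runner >= refs.pherotype_min_margin:
        return PherotypeCall(best_label, best_id, runner)
    return PherotypeCall("unassigned", best_id, runner)
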