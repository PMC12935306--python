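"""rapP-phrP module detection, residue-236 typing, and replicon context.

RapP is one of many Rap-family phosphatases; the detector separates rapP
proper from paralogs by protein identity/coverage against a reference RapP
(paralogs sit well below the cutoff). The signal-responsiveness state is read
at residue 236 in reference numbering (alignment-based, so indels elsewhere
in the protein do not shift the call): asparagine = PhrP-responsive,
threonine = the 3610-type unresponsive allele.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import protein_align_rows, protein_identity
from .genomes import Feature, SyntheticGenome, translate
from .references import ReferenceSet, default_references


@dataclass
class RapPCall:
    presence: str                   # complete | five_prime_truncated | absent
    phrP_downstream: bool = False
    residue_236: str = "undetermined"   # N | T | other | undetermined
    replicon: str = "unknown"       # plasmid_like | chromosomal | unknown
    identity: float = 0.0
    feature: Feature | None = None
    protein: str = ""


def _coverage_stats(ref: str, qry: str) -> tuple[float, float, int]:
    """(identity over aligned reference positions, aligned fraction of the
    reference, count of unaligned N-terminal reference residues)."""
    r, q = protein_align_rows(ref, qry)
    matches = aligned = 0
    lead_gap = 0
    seen_qry = False
    rpos = 0
    for rc, qc in zip(r, q):
        if rc != "-" and qc != "-":
            aligned += 1
            seen_qry = True
            if rc == qc:
                matches += 1
        if rc != "-":
            if qc == "-" and not seen_qry:
                lead_gap += 1
            rpos += 1
    ident = 100.0 * matches / aligned if aligned else 0.0
    return ident, aligned / len(ref), lead_gap


def check_residue_236(rapP_protein: str,
                      refs: ReferenceSet | None = None) -> str:
    """Residue at reference position 236 (alignment-based numbering)."""
    refs = refs or default_references()
    r, q = protein_align_rows(refs.rapP_protein, rapP_protein)
    rpos = 0
    for rc, qc in zip(r, q):
        if rc != "-":
            rpos += 1
            if rpos == refs.rapp_residue:
                if qc == "-":
                    return "undetermined"
                return qc if qc in ("N", "T") else "other"
    return "undetermined"


def replicon_context(genome: SyntheticGenome, feature: Feature,
                     refs: ReferenceSet | None = None,
                     plasmid_reference: str | None = None) -> str:
    """plasmid_like / chromosomal / unknown for the contig carrying rapP.

    plasmid_like when the contig is annotated as plasmid, matches a supplied
    plasmid reference, or is < 20% the length of the largest contig in a
    small (<= 5 contig) assembly; chromosomal when rapP sits on the largest
    contig; otherwise unknown.
    """
    contig = feature.contig
    desc = genome.contig_descriptions.get(contig, "").lower()
    if "plasmid" in desc or "plasmid" in contig.lower():
        return "plasmid_like"
    if plasmid_reference:
        from .align import nt_identity, align_nt_global
        seq = genome.contigs[contig]
        probe = seq[: min(len(seq), len(plasmid_reference))]
        r, q = align_nt_global(plasmid_reference, probe)
        if nt_identity(r, q) >= 90.0 and \
                len(probe) >= 0.5 * len(genome.contigs[contig]):
            return "plasmid_like"
    sizes = {name: len(s) for name, s in genome.contigs.items()}
    largest = max(sizes, key=sizes.get)
    if contig == largest:
        return "chromosomal"
    if len(sizes) <= 5 and sizes[contig] < 0.20 * sizes[largest]:
        return "plasmid_like"
    return "unknown"


def detect_rapP_module(genome: SyntheticGenome,
                       refs: ReferenceSet | None = None) -> RapPCall:
    """Locate rapP (best protein match above identity/coverage cutoffs),
    classify completeness, type residue 236, check for phrP within the
    downstream window on the same strand, and infer replicon context.
    Absence is a valid result, not an error."""
    refs = refs or default_references()
    ref = refs.rapP_protein

    best: tuple[float, float, int, Feature, str] | None = None
    for f in genome.features:
        prot = translate(genome.feature_seq(f))
        if len(prot) < 0.4 * len(ref):
            continue
        ident, cov, lead = _coverage_stats(ref, prot)
        if ident >= refs.rapp_min_identity and cov >= refs.rapp_min_coverage:
            if best is None or ident * cov > best[0] * best[1]:
                best = (ident, cov, lead, f, prot)
    if best is None:
        return RapPCall("absent")
    ident, cov, lead, feat, prot = best

    has_start = prot.startswith("M")
    if cov >= refs.rapp_complete_coverage and has_start:
        presence = "complete"
    elif lead >= 0.05 * len(ref):
        presence = "five_prime_truncated"
    else:
        presence = "complete" if has_start else "five_prime_truncated"

    # phrP within the downstream window, same strand
    phr = False
    contig = genome.contigs[feat.contig]
    for f in genome.features:
        if f.contig != feat.contig or f.strand != feat.strand or f is feat:
            continue
        gap = (f.start - feat.end) if feat.strand == "+" else (feat.start - f.end)
        if 0 <= gap <= refs.phrp_window_nt:
            prot_f = translate(genome.feature_seq(f))
            if protein_identity(refs.phrP_protein, prot_f) >= refs.phrp_min_identity:
                phr = True
                break

    return RapPCall(
        presence=presence,
        phrP_downstream=phr,
        residue_236=check_residue_236(prot, refs),
        replicon=replicon_context(genome, feat, refs),
        identity=ident,
        feature=feat,
        protein=prot,
    )
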