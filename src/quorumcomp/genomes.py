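"""Synthetic annotated genomes carrying the comQXPA quorum-sensing operon.

Generates every genome-like input the screening modules consume, with the
applied edits recorded as ground truth: a syntenic comQ-comX-comP-comA operon
(per pherotype template), engineered comP disruptions of each screening class,
and rapP-phrP modules in chromosomal or plasmid-like context.

All template coding sequences are synthetic stand-ins generated from a fixed
internal seed; they are not real Bacillus subtilis sequence. Real annotated
genomes (FASTA + GFF3) remain fully supported inputs to the screens.

Coordinates are 0-based half-open internally; GFF3 I/O converts to 1-based
inclusive.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if a + b + c not in STOP_CODONS]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

MutationClass = Literal[
    "nonsense", "frameshift_indel", "inframe_3prime_deletion",
    "insertion_element", "polyT_slip", "none",
]

PHEROTYPE_LABELS = ("3610", "RO-E-2", "RS-D-2")

#: 1-based codon at which the 8-T tract starts in the 3610-like comP template.
HOTSPOT_CODON = 60


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, to_stop: bool = True) -> str:
    """Translate a nucleotide sequence codon by codon from position 0."""
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODON_TABLE.get(seq[i:i + 3].upper(), "X")
        if aa == "*" and to_stop:
            break
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class MutationSpec:
    """One engineered comP edit.

    position is a 1-based codon index in the reference comP CDS (for
    polyT_slip it is ignored: the edit lands inside the recorded 8-T tract).
    size is nt for indels/insertions and codons for in-frame deletions.
    deletion selects the removal direction for frameshift/polyT edits.
    """

    class_label: MutationClass
    position: int = 1
    size: int = 0
    seed: int = 0
    deletion: bool = False

    def __post_init__(self):
        if self.class_label == "none":
            return
        if self.size <= 0:
            raise ValueError("size must be > 0 for a real edit")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.class_label == "frameshift_indel" and self.size % 3 == 0:
            raise ValueError("frameshift indel size must not be divisible by 3")


@dataclass(frozen=True)
class Feature:
    """A CDS on a contig; start/end are 0-based half-open contig coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    gene: str
    product: str = ""
    feature_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.gene}: {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SyntheticGenome:
    """Contigs + CDS features + the ground truth of every applied edit."""

    genome_id: str
    contigs: dict[str, str]
    features: list[Feature]
    truth: dict = field(default_factory=dict)
    contig_descriptions: dict[str, str] = field(default_factory=dict)

    def feature_seq(self, feat: Feature) -> str:
        seq = self.contigs[feat.contig][feat.start:feat.end]
        return revcomp(seq) if feat.strand == "-" else seq

    def find_gene(self, gene: str) -> Feature | None:
        for f in self.features:
            if f.gene.lower() == gene.lower():
                return f
        return None

    def copy(self) -> "SyntheticGenome":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# template construction (fixed internal seed: the reference set must be stable)

def _no_long_t_run(seq: str, tail: str, limit: int = 4) -> bool:
    return "T" * (limit + 1) not in (tail[-limit:] + seq)


def _random_codons(rng: np.random.Generator, n: int, tail: str = "") -> str:
    out = []
    cur = tail
    for _ in range(n):
        while True:
            c = _SENSE[rng.integers(len(_SENSE))]
            if _no_long_t_run(c, cur):
                break
        out.append(c)
        cur = (cur + c)[-4:]
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) sense codons + TAA; no internal stops, no T-run > 4."""
    return "ATG" + _random_codons(rng, n_aa - 1, tail="ATG") + "TAA"


def _filler(rng: np.random.Generator, n: int) -> str:
    """Intergenic filler at ~43% GC without long T runs or chance start-less ORFs
    long enough to matter."""
    probs = np.array([0.285, 0.215, 0.215, 0.285])
    out = []
    tail = ""
    for _ in range(n):
        while True:
            b = _BASES[rng.choice(4, p=probs)]
            if b != "T" or not tail.endswith("TTTT"):
                break
        out.append(b)
        tail = (tail + b)[-4:]
    return "".join(out)


def _mutate_codons(rng: np.random.Generator, cds: str, frac: float,
                   lo: int = 1, hi: int | None = None) -> str:
    """Replace a fraction of codons (1-based codon indices lo..hi, start codon
    kept) with codons encoding a different amino acid; avoids stops and long
    T runs."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    hi = hi if hi is not None else len(codons) - 1  # exclude terminal stop
    idx = [i for i in range(max(lo, 1), hi) if codons[i] not in STOP_CODONS]
    n_mut = int(round(frac * len(idx)))
    chosen = rng.choice(idx, size=n_mut, replace=False)
    for i in sorted(chosen):
        old_aa = _CODON_TABLE[codons[i]]
        tail = "".join(codons[max(0, i - 2):i])
        while True:
            c = _SENSE[rng.integers(len(_SENSE))]
            if _CODON_TABLE[c] != old_aa and _no_long_t_run(c, tail):
                break
        codons[i] = c
    return "".join(codons)


@lru_cache(maxsize=1)
def _templates() -> dict:
    """Deterministic template CDS set shared by the generator and the screens."""
    rng = np.random.default_rng(160_493_027)

    comq = _random_cds(rng, 299)
    comx = _random_cds(rng, 55)
    comp = _random_cds(rng, 769)
    coma = _random_cds(rng, 214)

    # engineer the 8-T slipped-strand hotspot into the 3610-like comP:
    # codons HOTSPOT_CODON..+2 -> TTT TTT TTC, preceded by a codon not ending
    # in T, giving exactly one maximal run of eight thymidines.
    codons = [comp[i:i + 3] for i in range(0, len(comp), 3)]
    codons[HOTSPOT_CODON - 2] = "GCA"
    codons[HOTSPOT_CODON - 1] = "TTT"
    codons[HOTSPOT_CODON] = "TTT"
    codons[HOTSPOT_CODON + 1] = "TTC"
    comp_3610 = "".join(codons)
    assert comp_3610.count("T" * 8) == 1 and "T" * 9 not in comp_3610
    hotspot_offset = (HOTSPOT_CODON - 1) * 3

    # other-pherotype comP: the 5' third is recoded wholesale (polymorphic
    # region, no equivalent poly-T tract), the 3' two thirds are conserved.
    third = len(codons) // 3
    alt_codons = list(codons)
    alt_5p = _random_codons(rng, third - 1, tail="ATG")
    for i, j in enumerate(range(1, third)):
        alt_codons[j] = alt_5p[3 * i:3 * i + 3]
    comp_alt = "".join(alt_codons)
    assert "T" * 8 not in comp_alt[: len(comp_alt) // 3]

    # pherotype-defining ComQ divergence (~30% of residues changed)
    comq_roe2 = _mutate_codons(rng, comq, 0.30)
    comq_rsd2 = _mutate_codons(rng, comq, 0.30)

    rapp = _random_cds(rng, 381)
    # signal-responsive backbone carries N236; the 3610 allele carries T236
    rp = [rapp[i:i + 3] for i in range(0, len(rapp), 3)]
    rp[235] = "AAC"
    rapp_n = "".join(rp)
    rp[235] = "ACC"
    rapp_t = "".join(rp)
    phrp = _random_cds(rng, 44)
    # a non-rapP Rap-family paralog at ~45% protein identity
    rap_paralog = _mutate_codons(rng, rapp_n, 0.55)

    # IS-like cassette: 25-nt terminal inverted repeats around a random core;
    # 1196 nt so that cassette + 4-nt target-site duplication is a multiple of 3
    tir = _filler(rng, 25)
    cassette = tir + _filler(rng, 1196 - 50) + revcomp(tir)

    return {
        "comQ": {"3610": comq, "RO-E-2": comq_roe2, "RS-D-2": comq_rsd2},
        "comX": comx,
        "comP": {"3610": comp_3610, "RO-E-2": comp_alt, "RS-D-2": comp_alt},
        "comA": coma,
        "hotspot_offset": hotspot_offset,
        "rapP": {"N": rapp_n, "T": rapp_t},
        "phrP": phrp,
        "rap_paralog": rap_paralog,
        "is_cassette": cassette,
    }


def is_cassette() -> str:
    """The packaged IS-like insertion cassette (1,196 nt, 25-nt inverted repeats)."""
    return _templates()["is_cassette"]


# ---------------------------------------------------------------------------
# operon genomes

def make_reference_operon(pherotype_id: str, seed: int,
                          strand: str = "+") -> SyntheticGenome:
    """A genome with a syntenic comQ->comX->comP->comA operon on one strand,
    flanked by random filler.

    The 3610-like template's comP contains exactly one maximal run of eight
    thymidines at a recorded offset; other pherotype templates do not carry an
    equivalent tract in the polymorphic 5' region.
    """
    t = _templates()
    if pherotype_id not in PHEROTYPE_LABELS:
        raise ValueError(
            f"unknown pherotype {pherotype_id!r}; valid labels: {PHEROTYPE_LABELS}")
    rng = np.random.default_rng(seed)
    parts = {
        "comQ": t["comQ"][pherotype_id],
        "comX": t["comX"],
        "comP": t["comP"][pherotype_id],
        "comA": t["comA"],
    }
    gaps = {"comQ": 20, "comX": 25, "comP": 30}
    seq = _filler(rng, 600)
    feats = []
    for gene in ("comQ", "comX", "comP", "comA"):
        start = len(seq)
        seq += parts[gene]
        feats.append(Feature("chr1", start, len(seq), "+", gene,
                             product=f"quorum-sensing protein {gene[0].upper()}{gene[1:]}",
                             feature_id=f"{gene}_1"))
        if gene in gaps:
            seq += _filler(rng, gaps[gene])
    seq += _filler(rng, 600)

    if strand == "-":
        n = len(seq)
        seq = revcomp(seq)
        feats = [replace(f, start=n - f.end, end=n - f.start, strand="-")
                 for f in feats]

    comp_feat = next(f for f in feats if f.gene == "comP")
    truth = {
        "pherotype": pherotype_id,
        "comP_class": "none",
        "hotspot_offset": t["hotspot_offset"] if pherotype_id == "3610" else None,
        "operon_strand": strand,
        "operon_span": (min(f.start for f in feats), max(f.end for f in feats)),
    }
    gid = f"syn_{pherotype_id}_s{seed}_{'fwd' if strand == '+' else 'rev'}"
    return SyntheticGenome(gid, {"chr1": seq}, feats, truth,
                           {"chr1": "synthetic chromosome"})


def _edit_cds(cds: str, spec: MutationSpec, hotspot_offset: int | None) -> str:
    """Apply one MutationSpec to a comP CDS string."""
    n_codons = len(cds) // 3
    rng = np.random.default_rng(spec.seed)

    if spec.class_label == "none":
        return cds
    if spec.class_label == "nonsense":
        off = (spec.position - 1) * 3
        if off + 3 > len(cds):
            raise ValueError("nonsense codon beyond CDS")
        return cds[:off] + "TAA" + cds[off + 3:]
    if spec.class_label == "frameshift_indel":
        off = (spec.position - 1) * 3
        if spec.deletion:
            if off + spec.size > len(cds) - 3:
                raise ValueError("deletion extends beyond CDS")
            return cds[:off] + cds[off + spec.size:]
        if off > len(cds) - 3:
            raise ValueError("insertion beyond CDS")
        ins = "".join("ACG"[rng.integers(3)] for _ in range(spec.size))
        return cds[:off] + ins + cds[off:]
    if spec.class_label == "inframe_3prime_deletion":
        off = (spec.position - 1) * 3
        if spec.position - 1 + spec.size > n_codons - 1:
            raise ValueError("in-frame deletion extends beyond CDS")
        return cds[:off] + cds[off + 3 * spec.size:]
    if spec.class_label == "insertion_element":
        off = (spec.position - 1) * 3
        if off + 4 > len(cds) - 3:
            raise ValueError("insertion site beyond CDS")
        site = cds[off:off + 4]
        cassette = is_cassette()
        # target-site duplication: ...site [cassette site] ...
        return cds[:off + 4] + cassette + site + cds[off + 4:]
    if spec.class_label == "polyT_slip":
        if hotspot_offset is None:
            raise ValueError("genome template has no poly-T hotspot")
        run = cds.find("T" * 8)
        if run < 0:
            raise ValueError("8-T tract not found in comP")
        if spec.deletion:
            return cds[:run] + cds[run + spec.size:]
        return cds[:run] + "T" * spec.size + cds[run:]
    raise ValueError(f"unknown mutation class {spec.class_label!r}")


def mutate_comP(genome: SyntheticGenome, spec: MutationSpec) -> SyntheticGenome:
    """Return a copy with the edit applied to the comP CDS.

    Coordinates of features downstream (in contig coordinates) are shifted by
    the length change; the genome's truth record is updated.
    """
    g = genome.copy()
    feat = g.find_gene("comP")
    if feat is None:
        raise ValueError("genome contains no comP feature")
    cds = g.feature_seq(feat)
    new_cds = _edit_cds(cds, spec, g.truth.get("hotspot_offset"))
    delta = len(new_cds) - len(cds)

    contig = g.contigs[feat.contig]
    embedded = revcomp(new_cds) if feat.strand == "-" else new_cds
    g.contigs[feat.contig] = contig[:feat.start] + embedded + contig[feat.end:]

    new_feats = []
    for f in g.features:
        if f is feat or (f.contig == feat.contig and f.start == feat.start
                         and f.end == feat.end and f.gene == feat.gene):
            new_feats.append(replace(f, end=f.end + delta))
        elif f.contig == feat.contig and f.start >= feat.end:
            new_feats.append(replace(f, start=f.start + delta, end=f.end + delta))
        else:
            new_feats.append(f)
    g.features = new_feats
    g.truth["comP_class"] = spec.class_label
    g.truth["comP_edit"] = {
        "position": spec.position, "size": spec.size,
        "deletion": spec.deletion, "seed": spec.seed,
    }
    g.genome_id = f"{genome.genome_id}_{spec.class_label}_p{spec.position}_s{spec.seed}"
    return g


# ---------------------------------------------------------------------------
# rapP-phrP modules

def make_rapP_module(variant: str = "T",
                     completeness: str = "complete",
                     replicon: str = "plasmid",
                     seed: int = 0,
                     include_paralog: bool = True) -> SyntheticGenome:
    """A genome fragment carrying (or lacking) a rapP-phrP module.

    variant selects the residue-236 codon (N = signal responsive,
    T = 3610-like signal unresponsive); completeness is one of complete /
    five_prime_truncated / absent; replicon places the module on a small
    plasmid-like contig or on the chromosome. A ~45%-identity Rap-family
    paralog is included on the chromosome by default so that screens must
    discriminate it from rapP proper.
    """
    if variant not in ("N", "T"):
        raise ValueError("variant must be 'N' or 'T'")
    if completeness not in ("complete", "five_prime_truncated", "absent"):
        raise ValueError("completeness must be complete|five_prime_truncated|absent")
    if replicon not in ("plasmid", "chromosome"):
        raise ValueError("replicon must be 'plasmid' or 'chromosome'")

    t = _templates()
    rng = np.random.default_rng(seed)
    feats: list[Feature] = []
    contigs: dict[str, str] = {}
    desc: dict[str, str] = {}

    rapp_cds = t["rapP"][variant]
    if completeness == "five_prime_truncated":
        # the first 150 codons and the annotated start are gone
        rapp_cds = rapp_cds[150 * 3:]

    def _module(prefix: str) -> str:
        seq = _filler(rng, 400)
        if completeness != "absent":
            start = len(seq)
            seq += rapp_cds
            feats.append(Feature(prefix, start, len(seq), "+", "rapP",
                                 "response regulator aspartate phosphatase RapP",
                                 f"rapP_{prefix}"))
            seq += _filler(rng, 120)
            start = len(seq)
            seq += t["phrP"]
            feats.append(Feature(prefix, start, len(seq), "+", "phrP",
                                 "phosphatase regulator peptide PhrP",
                                 f"phrP_{prefix}"))
        seq += _filler(rng, 400)
        return seq

    chrom = _filler(rng, 3000)
    if include_paralog:
        start = len(chrom)
        chrom += t["rap_paralog"]
        feats.insert(0, Feature("chr1", start, len(chrom), "+", "rapD",
                                "response regulator aspartate phosphatase",
                                "rap_paralog_1"))
        chrom += _filler(rng, 1500)

    if replicon == "plasmid":
        chrom += _filler(rng, 6000)  # keep the plasmid contig < 20% of this
        contigs["chr1"] = chrom
        desc["chr1"] = "synthetic chromosome"
        contigs["p1"] = _module("p1")
        desc["p1"] = "plasmid pBS32-like replicon"
    else:
        contigs["chr1"] = chrom + _module("chr1")
        desc["chr1"] = "synthetic chromosome"
        # fix feature contig labels minted inside _module
        feats = [replace(f, contig="chr1") if f.contig == "chr1" else f
                 for f in feats]

    # _module minted features with contig == prefix; for the chromosome case
    # the prefix was "chr1" already, for plasmid it is "p1" -- but the
    # chromosome-case module coordinates are relative to the module start.
    if replicon == "chromosome":
        offset = len(chrom)
        fixed = []
        for f in feats:
            if f.gene in ("rapP", "phrP"):
                fixed.append(replace(f, start=f.start + offset, end=f.end + offset))
            else:
                fixed.append(f)
        feats = fixed

    gid = f"syn_rapP_{variant}_{completeness}_{replicon}_s{seed}"
    truth = {"rapP_variant": variant, "rapP_completeness": completeness,
             "rapP_replicon": replicon}
    return SyntheticGenome(gid, contigs, feats, truth, desc)
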