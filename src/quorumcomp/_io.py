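"""FASTA + GFF3 reading/writing for annotated genomes.

Reading goes through Biopython (FASTA) and gffutils (GFF3, in-memory sqlite
database). Writing GFF3 is a plain formatter: the records are created de novo
here, so there is no database to dump. Internal coordinates are 0-based
half-open; GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
from Bio import SeqIO

from .genomes import Feature, SyntheticGenome


class GenomeIOError(IOError):
    """Unparseable genome input; message carries the offending file."""


def write_genome(genome: SyntheticGenome, fasta_path: str | Path,
                 gff_path: str | Path) -> None:
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    with open(fasta_path, "w") as fh:
        for name, seq in genome.contigs.items():
            desc = genome.contig_descriptions.get(name, "")
            fh.write(f">{name} {desc}".rstrip() + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for i, f in enumerate(genome.features):
            fid = f.feature_id or f"cds{i}"
            attrs = f"ID={fid};gene={f.gene};product={f.product}"
            fh.write("\t".join([
                f.contig, "quorumcomp", "CDS", str(f.start + 1), str(f.end),
                ".", f.strand, "0", attrs]) + "\n")


def read_genome(fasta_path: str | Path, gff_path: str | Path,
                genome_id: str | None = None) -> SyntheticGenome:
    """Load an annotated genome into the in-memory representation the screens
    consume. Raises GenomeIOError naming the file on parse failure."""
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs: dict[str, str] = {}
    desc: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
            desc[rec.id] = rec.description.partition(" ")[2]
    except (ValueError, OSError) as e:
        raise GenomeIOError(f"cannot parse FASTA {fasta_path}: {e}") from e
    if not contigs:
        raise GenomeIOError(f"no sequences in FASTA {fasta_path}")

    features: list[Feature] = []
    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                force=True, keep_order=True,
                                merge_strategy="create_unique")
    except Exception as e:  # gffutils raises assorted concrete types
        raise GenomeIOError(f"cannot parse GFF3 {gff_path}: {e}") from e
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        if feat.featuretype == "gene" and any(
                db.children(feat, featuretype="CDS")):
            continue  # the CDS child carries the coordinates we need
        gene = (feat.attributes.get("gene") or feat.attributes.get("Name")
                or [""])[0]
        product = (feat.attributes.get("product") or [""])[0]
        if feat.seqid not in contigs:
            raise GenomeIOError(
                f"{gff_path}: feature on unknown contig {feat.seqid!r}")
        features.append(Feature(feat.seqid, feat.start - 1, feat.end,
                                feat.strand if feat.strand in "+-" else "+",
                                gene, product, feat.id or ""))
    gid = genome_id or os.path.splitext(fasta_path.name)[0]
    return SyntheticGenome(gid, contigs, features, {}, desc)
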