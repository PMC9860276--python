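"""Genome + annotation I/O and intron extraction.

A `GenomeBundle` holds chromosome sequences and protein-coding gene models
(CDS exon intervals in genomic 0-based half-open coordinates).  Introns are
reconstructed from the gaps between consecutive CDS exons of one isoform per
gene (the longest CDS when several mRNAs are annotated), and extracted in
transcription orientation together with up to 20 nt of flanking exonic
sequence on each side, requiring at least 10 nt.

GFF3 files are written and read 1-based inclusive; everything in memory is
0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._seq import revcomp

MAX_FLANK = 20
MIN_FLANK = 10


@dataclass
class GeneModel:
    """One protein-coding gene: CDS exon intervals on the genome."""

    id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]] = field(default_factory=list)  # genomic, ascending

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_sequence(self, sequences: dict[str, str]) -> str:
        seq = sequences[self.chrom]
        parts = [seq[s:e] for s, e in self.exons]
        cds = "".join(parts)
        return cds if self.strand == "+" else revcomp(cds)

    def protein(self, sequences: dict[str, str]) -> str:
        cds = self.cds_sequence(sequences)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass
class IntronRecord:
    """One annotated intron with exonic flanks, transcription orientation."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic 0-based half-open
    end: int
    seq: str  # transcription orientation
    up_flank: str  # upstream exonic flank (3' end of upstream exon)
    down_flank: str  # downstream exonic flank (5' end of downstream exon)
    ordinal: int  # position within gene, transcription order, 0-based


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    genes: list[GeneModel]

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def genic_bases(self) -> int:
        total = 0
        for chrom, ivs in self._gene_spans_by_chrom().items():
            total += sum(e - s for s, e in ivs)
        return total

    def _gene_spans_by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        """Merged gene spans (start..end incl. introns) per chromosome."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = [(s, e) for s, e in out]
        return merged

    def write_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gff3(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, seq in self.sequences.items():
                fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
            for g in self.genes:
                s1, e1 = g.start + 1, g.end
                base = f"{g.chrom}\tintronerkit\t"
                fh.write(
                    f"{base}gene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.id}\n"
                )
                mrna = f"{g.id}.t1"
                fh.write(
                    f"{base}mRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                    f"ID={mrna};Parent={g.id}\n"
                )
                # phase bookkeeping in transcription order
                phases = {}
                cum = 0
                for s, e in g.exons_transcription_order():
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s
                for k, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{base}exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mrna}.exon{k};Parent={mrna}\n"
                    )
                    fh.write(
                        f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                        f"{phases[(s, e)]}\tID={mrna}.cds;Parent={mrna}\n"
                    )


def read_bundle(fasta_path: str | os.PathLike, gff3_path: str | os.PathLike) -> GenomeBundle:
    """Load a genome FASTA and GFF3 annotation into a GenomeBundle.

    One isoform per gene is kept (longest summed CDS).  Raises ValueError if
    a feature references a chromosome absent from the FASTA.
    """
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return GenomeBundle(sequences=sequences, genes=[])
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in sequences:
            raise ValueError(
                f"GFF3 feature references unknown chromosome {gene.seqid!r}"
            )
        best: list[tuple[int, int]] | None = None
        best_len = -1
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        for mrna in mrnas:
            cds = sorted(
                (c.start - 1, c.end)
                for c in db.children(mrna, featuretype="CDS")
            )
            clen = sum(e - s for s, e in cds)
            if clen > best_len:
                best, best_len = cds, clen
        if not best:
            continue
        genes.append(
            GeneModel(id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=best)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GenomeBundle(sequences=sequences, genes=genes)


def extract_introns(
    bundle: GenomeBundle, max_flank: int = MAX_FLANK, min_flank: int = MIN_FLANK
) -> list[IntronRecord]:
    """Extract all CDS-defined introns with exonic flanks.

    An intron is skipped when either flanking exon provides fewer than
    `min_flank` exonic nucleotides; flanks never cross into a neighboring
    intron.
    """
    records: list[IntronRecord] = []
    for gene in bundle.genes:
        seq = bundle.sequences[gene.chrom]
        exons_t = gene.exons_transcription_order()
        for k in range(len(exons_t) - 1):
            up_exon, down_exon = exons_t[k], exons_t[k + 1]
            if gene.strand == "+":
                i0, i1 = up_exon[1], down_exon[0]
                intron = seq[i0:i1]
                up = seq[max(up_exon[0], i0 - max_flank) : i0]
                down = seq[i1 : min(down_exon[1], i1 + max_flank)]
            else:
                i0, i1 = down_exon[1], up_exon[0]
                intron = revcomp(seq[i0:i1])
                up = revcomp(seq[i1 : min(up_exon[1], i1 + max_flank)])
                down = revcomp(seq[max(down_exon[0], i0 - max_flank) : i0])
            if len(up) < min_flank or len(down) < min_flank:
                continue
            if len(intron) < 4:
                continue
            records.append(
                IntronRecord(
                    id=f"{gene.id}.i{k}",
                    gene_id=gene.id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=i0,
                    end=i1,
                    seq=intron.upper(),
                    up_flank=up.upper(),
                    down_flank=down.upper(),
                    ordinal=k,
                )
            )
    return records


def gene_density(bundle: GenomeBundle) -> float:
    """Fraction of the genome covered by gene bodies (merged spans)."""
    gl = bundle.genome_length
    return bundle.genic_bases / gl if gl else 0.0


def introns_to_table(records: list[IntronRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intron_id": [r.id for r in records],
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "strand": [r.strand for r in records],
            "seq": [r.seq for r in records],
            "up_flank": [r.up_flank for r in records],
            "down_flank": [r.down_flank for r in records],
            "ordinal": [r.ordinal for r in records],
        }
    )


def write_intron_table(records: list[IntronRecord], path: str | os.PathLike) -> None:
    introns_to_table(records).to_csv(path, sep="\t", index=False)
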