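"""Synthetic genomes with planted Introner families and known ground truth.

The generator produces multi-gene genomes (FASTA + GFF3-equivalent gene
models), plants families of intron-generating elements with configurable
copy number, target-site duplication (TSD) and terminal-inverted-repeat
(TIR) structure, and records a per-copy truth table.  Six insertion
mechanisms are supported, mirroring the range of splice-site recruitment
strategies observed in real Introner families:

  A  element carries both splice sites; no TSD, no TIR (direct insertion)
  B  TSD + TIR; element carries the 3' AG, co-opts its 5' GT from the TSD
  C  TSD, no TIR; element carries the 5' GT, co-opts its 3' AG from the TSD
  D  TIR >= 6 nt, no TSD; splice sites sit immediately outside the TIRs
  E  split TSD (T = P + S, P ends AG, S starts GT); the new intron is
     S + element + P, so both splice sites are co-opted from TSD copies
     and the mature mRNA is unchanged
  F  TSD whose two copies remain exonic plus 4 element bp left in the
     exons: the mRNA gains tsd_length + 4 nt (12 with the 8-bp default)

Insertions preserve the mRNA sequence (hence reading frame) for A-E.
Confounders — paralogous gene duplications, microsatellite introns, and
secondary transposon insertions strictly interior to preexisting introns —
exercise the false-positive filters of the detection pipeline.

All coordinates are 0-based half-open on the forward strand; intron and
element sequences are stored in transcription orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import gc_fraction, mutate, random_seq, revcomp
from .genome_io import GeneModel, GenomeBundle

_MARGIN = 20  # minimum exonic piece left on each side of a new intron
_STOPS = {"TAA", "TAG", "TGA"}

MECHANISMS = ("A", "B", "C", "D", "E", "F")


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class GenomeSimConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 400
    exons_per_gene: tuple[int, int] = (2, 6)
    background_intron_length: tuple[int, int] = (60, 120)
    genic_fraction: float = 0.4
    gc_genic: float = 0.5
    gc_intergenic: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.genic_fraction < 1.0:
            raise ValueError("genic_fraction must be in (0,1)")
        for gc in (self.gc_genic, self.gc_intergenic):
            if not 0.0 < gc < 1.0:
                raise ValueError("GC fractions must be in (0,1)")
        if min(self.n_chromosomes, self.chromosome_length) <= 0:
            raise ValueError("chromosome dimensions must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid exons_per_gene range")
        ilo, ihi = self.background_intron_length
        if ilo < 30 or ihi < ilo:
            raise ValueError("background introns must be >= 30 nt")


@dataclass
class FamilySpec:
    """Parameters of one planted Introner family."""

    copy_number: int = 20
    element_length: int = 200  # length of the created intron
    tsd_length: int = 4  # 0 = no TSD
    tir_length: int = 8  # 0 = no TIR
    mechanism: str = "B"
    genic_bias: float = 1.0  # probability an insertion targets a gene
    gc_site_bias: float | None = None  # target GC of 20-bp insertion windows
    divergence: float = 0.0  # per-site substitution prob, post insertion

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.element_length < 30:
            raise ValueError("element_length must be >= 30")
        m = self.mechanism
        if m == "A" and (self.tsd_length or self.tir_length):
            raise ValueError("mechanism A takes no TSD and no TIR")
        if m == "B" and (self.tsd_length < 2 or self.tir_length < 1):
            raise ValueError("mechanism B requires tsd_length >= 2 and a TIR")
        if m == "C" and (self.tsd_length < 2 or self.tir_length != 0):
            raise ValueError("mechanism C requires tsd_length >= 2, no TIR")
        if m == "D" and (self.tir_length < 6 or self.tsd_length != 0):
            raise ValueError("mechanism D requires tir_length >= 6, no TSD")
        if m == "E" and (self.tsd_length < 4 or self.tir_length != 0):
            raise ValueError("mechanism E requires tsd_length >= 4, no TIR")
        if m == "F" and self.tsd_length < 2:
            raise ValueError("mechanism F requires a TSD")
        if not 0.0 <= self.genic_bias <= 1.0:
            raise ValueError("genic_bias must be in [0,1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0,1]")


@dataclass
class CountSimConfig:
    reads_per_kb: float = 50.0
    introner_retention_rate: float = 0.01
    background_retention_rate: float = 0.10
    missplice_rate: float = 0.02
    dispersion: float = 0.3  # lognormal sigma on per-gene expression
    introner_expression_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for r in (
            self.introner_retention_rate,
            self.background_retention_rate,
            self.missplice_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.reads_per_kb < 0:
            raise ValueError("expression must be nonnegative")


# ---------------------------------------------------------------------------
# genome simulation


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random non-stop codons + TAA."""
    need = n_codons - 2
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = rng.choice(bases, size=(need, 3), p=p)
    t, a, g = ord("T"), ord("A"), ord("G")
    while True:
        is_stop = (arr[:, 0] == t) & (
            ((arr[:, 1] == a) & ((arr[:, 2] == a) | (arr[:, 2] == g)))
            | ((arr[:, 1] == g) & (arr[:, 2] == a))
        )
        n_bad = int(is_stop.sum())
        if n_bad == 0:
            break
        arr[is_stop] = rng.choice(bases, size=(n_bad, 3), p=p)
    return "ATG" + arr.tobytes().decode("ascii") + "TAA"


def _partition(rng: np.random.Generator, total: int, k: int, min_part: int) -> list[int]:
    """Split `total` into k parts each >= min_part."""
    free = total - k * min_part
    if free < 0:
        raise ValueError("cannot partition: total too small")
    cuts = np.sort(rng.integers(0, free + 1, size=k - 1)) if k > 1 else np.array([], int)
    parts = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(p) + min_part for p in parts]


def simulate_genome(config: GenomeSimConfig) -> GenomeBundle:
    """Simulate a genome of non-overlapping protein-coding genes.

    Genes carry canonical GT..AG background introns; the realized genic
    fraction tracks the requested one.  Deterministic for a fixed seed.
    Raises ValueError when the requested genes cannot fit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_length = config.n_chromosomes * config.chromosome_length
    budget = config.genic_fraction * genome_length

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.n_genes == 0:
        seqs = {
            name: random_seq(rng, config.chromosome_length, config.gc_intergenic)
            for name in chrom_names
        }
        return GenomeBundle(sequences=seqs, genes=[])

    span_target = budget / config.n_genes
    lo, hi = config.exons_per_gene
    ilo, ihi = config.background_intron_length

    # draw gene structures
    structures = []
    for gi in range(config.n_genes):
        k = int(rng.integers(lo, hi + 1))
        intron_lens = [int(x) for x in rng.integers(ilo, ihi + 1, size=k - 1)]
        cds_len = int(span_target) - sum(intron_lens)
        n_codons = max(60, _MARGIN * k, cds_len // 3)
        cds_len = 3 * n_codons
        exon_lens = _partition(rng, cds_len, k, min_part=3 * _MARGIN)
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((exon_lens, intron_lens, strand))

    spans = [sum(e) + sum(i) for e, i, _ in structures]
    per_chrom: list[list[int]] = [[] for _ in chrom_names]
    for gi in range(config.n_genes):
        per_chrom[gi % config.n_chromosomes].append(gi)

    min_gap = 100
    genes: list[GeneModel] = []
    seqs: dict[str, str] = {}
    for ci, name in enumerate(chrom_names):
        idxs = per_chrom[ci]
        used = sum(spans[i] for i in idxs)
        n_gaps = len(idxs) + 1
        free = config.chromosome_length - used - n_gaps * min_gap
        if free < 0:
            raise ValueError(
                f"genes cannot fit on {name}: need {used + n_gaps * min_gap} bp, "
                f"have {config.chromosome_length}"
            )
        w = rng.dirichlet(np.ones(n_gaps))
        gaps = [min_gap + int(x) for x in np.floor(w * free)]
        gaps[-1] += config.chromosome_length - used - sum(gaps)

        parts: list[str] = []
        pos = 0
        for slot, gidx in enumerate(idxs):
            parts.append(random_seq(rng, gaps[slot], config.gc_intergenic))
            pos += gaps[slot]
            exon_lens, intron_lens, strand = structures[gidx]
            cds = _random_cds(rng, sum(exon_lens) // 3, config.gc_genic)
            pieces = []
            off = 0
            t_exons = []  # transcription-order offsets within the gene string
            cursor = 0
            for k, el in enumerate(exon_lens):
                pieces.append(cds[off : off + el])
                t_exons.append((cursor, cursor + el))
                cursor += el
                off += el
                if k < len(intron_lens):
                    il = intron_lens[k]
                    pieces.append("GT" + random_seq(rng, il - 4, config.gc_genic) + "AG")
                    cursor += il
            gene_t = "".join(pieces)
            glen = len(gene_t)
            if strand == "+":
                gseq = gene_t
                exons = [(pos + a, pos + b) for a, b in t_exons]
            else:
                gseq = revcomp(gene_t)
                exons = sorted((pos + glen - b, pos + glen - a) for a, b in t_exons)
            genes.append(
                GeneModel(
                    id=f"g{gidx + 1:05d}", chrom=name, strand=strand, exons=exons
                )
            )
            parts.append(gseq)
            pos += glen
        parts.append(random_seq(rng, gaps[-1], config.gc_intergenic))
        seqs[name] = "".join(parts)
        assert len(seqs[name]) == config.chromosome_length
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GenomeBundle(sequences=seqs, genes=genes)


def gene_table(bundle: GenomeBundle) -> pd.DataFrame:
    rows = []
    for g in bundle.genes:
        cds_len = sum(e - s for s, e in g.exons)
        rows.append(
            {
                "gene_id": g.id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "n_exons": len(g.exons),
                "cds_length": cds_len,
                "span": g.end - g.start,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# insertion machinery


def _shift_coords(bundle: GenomeBundle, chrom: str, gpos: int, length: int,
                  skip: GeneModel | None = None) -> None:
    for g in bundle.genes:
        if g.chrom != chrom or g is skip:
            continue
        g.exons = [
            (s + length if s >= gpos else s, e + length if e > gpos else e)
            for s, e in g.exons
        ]


def _insert_into_exon(
    bundle: GenomeBundle,
    gene: GeneModel,
    exon_idx: int,
    t_off: int,
    y: str,
    intron_rel: tuple[int, int],
) -> tuple[int, int]:
    """Insert transcription-orientation string `y` at offset `t_off` of an exon.

    `intron_rel` is the span of the newly created intron within the modified
    exon's transcription string.  Returns the genomic intron interval and
    updates the chromosome sequence and every gene model on the chromosome.
    """
    s0, e0 = gene.exons[exon_idx]
    L = len(y)
    n_new = (e0 - s0) + L
    a, b = intron_rel
    if gene.strand == "+":
        g = s0 + t_off
        ins_g = y
        gi = (s0 + a, s0 + b)
    else:
        g = e0 - t_off
        ins_g = revcomp(y)
        gi = (s0 + (n_new - b), s0 + (n_new - a))
    seq = bundle.sequences[gene.chrom]
    bundle.sequences[gene.chrom] = seq[:g] + ins_g + seq[g:]
    _shift_coords(bundle, gene.chrom, g, L, skip=gene)
    new_exons = []
    for k, (s, e) in enumerate(gene.exons):
        if k == exon_idx:
            new_exons.append((s0, gi[0]))
            new_exons.append((gi[1], e0 + L))
        else:
            new_exons.append((s + L if s >= g else s, e + L if e > g else e))
    gene.exons = sorted(new_exons)
    return gi, g


def _insert_intergenic(bundle: GenomeBundle, chrom: str, gpos: int, ins_plus: str) -> None:
    seq = bundle.sequences[chrom]
    bundle.sequences[chrom] = seq[:gpos] + ins_plus + seq[gpos:]
    _shift_coords(bundle, chrom, gpos, len(ins_plus))


def _shift_truth(tables, chrom: str, gpos: int, length: int) -> None:
    """Propagate an insertion to previously recorded truth intervals."""
    for df in tables:
        if df is None or len(df) == 0:
            continue
        m = (df["chrom"] == chrom) & (df["start"] >= gpos)
        if m.any():
            df.loc[m, "start"] += length
            df.loc[m, "end"] += length


def _shift_rows(rows: list[dict], chrom: str, gpos: int, length: int) -> None:
    for r in rows:
        if r["chrom"] == chrom and r["start"] >= gpos:
            r["start"] += length
            r["end"] += length


def _inside_any(rows, tables, chrom: str, gpos: int, pad: int = 5) -> bool:
    """Does gpos fall inside (or within pad of) a recorded element interval?"""
    for r in rows:
        if r["chrom"] == chrom and r["start"] - pad < gpos < r["end"] + pad:
            return True
    for df in tables:
        if df is None or len(df) == 0:
            continue
        m = (df["chrom"] == chrom) & (df["start"] - pad < gpos) & (gpos < df["end"] + pad)
        if m.any():
            return True
    return False


def _intergenic_gaps(bundle: GenomeBundle) -> list[tuple[str, int, int]]:
    gaps = []
    spans = bundle._gene_spans_by_chrom()
    for chrom, seq in bundle.sequences.items():
        pos = 0
        for s, e in spans.get(chrom, []):
            if s - pos >= 2 * _MARGIN + 10:
                gaps.append((chrom, pos, s))
            pos = e
        if len(seq) - pos >= 2 * _MARGIN + 10:
            gaps.append((chrom, pos, len(seq)))
    return gaps


# ---------------------------------------------------------------------------
# family element construction


def _build_element(rng: np.random.Generator, spec: FamilySpec, gc: float = 0.45):
    """Draw the family's element sequence and per-mechanism geometry.

    Returns a dict with keys used by the per-copy builder: the element body,
    protected intron positions (splice sites and TSD-derived bases are not
    mutated by post-insertion divergence), and mechanism F's exonic remnant.
    """
    m = spec.mechanism
    ilen = spec.element_length
    tsd, tir = spec.tsd_length, spec.tir_length
    if m == "A":
        body = "GT" + random_seq(rng, ilen - 4, gc) + "AG"
        return {"element": body, "protect": {0, 1, ilen - 2, ilen - 1}}
    if m == "B":
        elen = ilen - tsd
        arm = "CT" + random_seq(rng, tir - 2, gc)
        core = random_seq(rng, elen - 2 * tir, gc)
        body = arm + core + revcomp(arm)  # ends "AG"
        protect = set(range(tsd)) | {ilen - 2, ilen - 1}
        return {"element": body, "protect": protect}
    if m == "C":
        elen = ilen - tsd
        for _ in range(100):
            body = "GT" + random_seq(rng, elen - 2, gc)
            if not _has_terminal_ir(body, min_len=6):
                break
        protect = {0, 1} | set(range(ilen - tsd, ilen))
        return {"element": body, "protect": protect}
    if m == "D":
        arm = random_seq(rng, tir, gc)
        core = arm + random_seq(rng, ilen - 4 - 2 * tir, gc) + revcomp(arm)
        return {"element": core, "protect": {0, 1, ilen - 2, ilen - 1}}
    if m == "E":
        p_len = max(2, tsd // 2)
        s_len = tsd - p_len
        body = random_seq(rng, ilen - tsd, gc)
        protect = set(range(s_len)) | set(range(ilen - p_len, ilen))
        return {"element": body, "protect": protect, "p_len": p_len, "s_len": s_len}
    if m == "F":
        body = "GT" + random_seq(rng, ilen - 4, gc) + "AG"
        u, v = random_seq(rng, 2, gc), random_seq(rng, 2, gc)
        return {"element": body, "protect": {0, 1, ilen - 2, ilen - 1}, "u": u, "v": v}
    raise AssertionError(m)


def _has_terminal_ir(seq: str, min_len: int = 6, window: int = 20) -> bool:
    head, tail = seq[:window], seq[-window:]
    rtail = revcomp(tail)
    for L in range(min_len, window + 1):
        for i in range(len(head) - L + 1):
            if head[i : i + L] in rtail:
                return True
    return False


def _genic_site_candidates(
    bundle: GenomeBundle,
    spec: FamilySpec,
    elem: dict,
    rng: np.random.Generator,
    n_genes_scan: int = 60,
    used_genes: set[str] | None = None,
):
    """Sample candidate genic insertion sites satisfying mechanism motifs.

    Yields tuples (gene, exon_idx, descriptor) where descriptor carries the
    motif offset needed by the per-copy builder.
    """
    m = spec.mechanism
    tsd = spec.tsd_length
    order = rng.permutation(len(bundle.genes))
    out = []
    scanned = 0
    for oi in order:
        gene = bundle.genes[int(oi)]
        if used_genes and gene.id in used_genes:
            continue
        scanned += 1
        if scanned > n_genes_scan and out:
            break
        seq = bundle.sequences[gene.chrom]
        for exon_idx, (s, e) in enumerate(gene.exons):
            exon_t = seq[s:e] if gene.strand == "+" else revcomp(seq[s:e])
            n = len(exon_t)
            if n < 2 * _MARGIN + tsd + 8:
                continue
            if m in ("A", "D"):
                positions = range(_MARGIN, n - _MARGIN)
                cands = [(gene, exon_idx, q) for q in positions]
            elif m == "B":
                cands = [
                    (gene, exon_idx, q)
                    for q in range(_MARGIN, n - _MARGIN - tsd)
                    if exon_t[q : q + 2] == "GT"
                ]
            elif m == "C":
                cands = [
                    (gene, exon_idx, q)
                    for q in range(_MARGIN, n - _MARGIN - tsd)
                    if exon_t[q + tsd - 2 : q + tsd] == "AG"
                ]
            elif m == "E":
                c = elem["p_len"]
                cands = [
                    (gene, exon_idx, q)
                    for q in range(_MARGIN, n - _MARGIN - tsd)
                    if exon_t[q + c - 2 : q + c + 2] == "AGGT"
                ]
            elif m == "F":
                cands = [
                    (gene, exon_idx, q)
                    for q in range(_MARGIN, n - _MARGIN - tsd)
                ]
            else:  # pragma: no cover
                cands = []
            if cands:
                take = min(len(cands), 8)
                pick = rng.choice(len(cands), size=take, replace=False)
                out.extend(cands[int(i)] for i in pick)
        if len(out) >= 300:
            break
    return out


def _site_window_gc(bundle: GenomeBundle, gene: GeneModel, q: int, exon_idx: int) -> float:
    s, e = gene.exons[exon_idx]
    seq = bundle.sequences[gene.chrom]
    exon_t = seq[s:e] if gene.strand == "+" else revcomp(seq[s:e])
    lo, hi = max(0, q - 10), min(len(exon_t), q + 10)
    return gc_fraction(exon_t[lo:hi])


def plant_family(
    bundle: GenomeBundle,
    spec: FamilySpec,
    seed: int,
    family_id: str = "fam1",
    prior_truth: tuple[pd.DataFrame, ...] = (),
) -> pd.DataFrame:
    """Plant one Introner family into the bundle (mutated in place).

    Returns the truth table: one row per planted copy with its genomic
    interval, TSD, element sequence, and splice-site provenance.  Truth
    tables from earlier plant_family calls passed via `prior_truth` have
    their coordinates updated in place as insertions shift the genome.
    Raises RuntimeError when eligible target sites run out.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    elem = _build_element(rng, spec)
    m = spec.mechanism
    tsd_len = spec.tsd_length
    rows = []
    used_genes: set[str] = set()

    for copy in range(spec.copy_number):
        genic = bool(rng.random() < spec.genic_bias)
        placed = False
        if genic:
            cands = _genic_site_candidates(bundle, spec, elem, rng, used_genes=None)
            if not cands:
                raise RuntimeError(
                    f"no eligible genic target sites for mechanism {m} "
                    f"(copy {copy + 1}/{spec.copy_number})"
                )
            if spec.gc_site_bias is not None:
                gcs = np.array(
                    [_site_window_gc(bundle, g, q, ei) for g, ei, q in cands]
                )
                w = np.exp(-((gcs - spec.gc_site_bias) ** 2) / (2 * 0.1**2))
                w = w / w.sum()
                choice = int(rng.choice(len(cands), p=w))
            else:
                choice = int(rng.integers(len(cands)))
            gene, exon_idx, q = cands[choice]
            s, e = gene.exons[exon_idx]
            seq = bundle.sequences[gene.chrom]
            exon_t = seq[s:e] if gene.strand == "+" else revcomp(seq[s:e])
            intron, y, t_off, rel, tsd_seq = _copy_strings(
                rng, spec, elem, exon_t, q
            )
            gi, gpos = _insert_into_exon(bundle, gene, exon_idx, t_off, y, rel)
            _shift_rows(rows, gene.chrom, gpos, len(y))
            _shift_truth(prior_truth, gene.chrom, gpos, len(y))
            rows.append(
                _truth_row(
                    family_id, copy, gene.chrom, gi, gene.strand, True,
                    gene.id, tsd_seq, elem, intron, m,
                )
            )
            used_genes.add(gene.id)
            placed = True
        else:
            gaps = _intergenic_gaps(bundle)
            gaps = [gaps[int(i)] for i in rng.permutation(len(gaps))]
            for chrom, g0, g1 in gaps:
                strand = "+" if rng.random() < 0.5 else "-"
                seg = bundle.sequences[chrom][g0:g1]
                seg_t = seg if strand == "+" else revcomp(seg)
                qs = _motif_offsets(seg_t, m, tsd_len, elem)
                qs = [int(x) for x in rng.permutation(qs)] if qs else []
                chosen = None
                for q in qs[:20]:
                    q = int(q)
                    gtest = (g0 + q) if strand == "+" else (g0 + len(seg_t) - q)
                    if not _inside_any(rows, prior_truth, chrom, gtest, pad=10):
                        chosen = q
                        break
                if chosen is None:
                    continue
                q = chosen
                intron, y, t_off, rel, tsd_seq = _copy_strings(
                    rng, spec, elem, seg_t, q
                )
                n_new = len(seg_t) + len(y)
                if strand == "+":
                    gpos = g0 + t_off
                    ins = y
                    gi = (g0 + rel[0], g0 + rel[1])
                else:
                    gpos = g0 + (len(seg_t) - t_off)
                    ins = revcomp(y)
                    gi = (g0 + n_new - rel[1], g0 + n_new - rel[0])
                _insert_intergenic(bundle, chrom, gpos, ins)
                _shift_rows(rows, chrom, gpos, len(ins))
                _shift_truth(prior_truth, chrom, gpos, len(ins))
                rows.append(
                    _truth_row(
                        family_id, copy, chrom, gi, strand, False,
                        "", tsd_seq, elem, intron, m,
                    )
                )
                placed = True
                break
            if not placed:
                raise RuntimeError("no eligible intergenic target sites")
    return pd.DataFrame(rows)


def _motif_offsets(seg_t: str, m: str, tsd: int, elem: dict) -> list[int]:
    n = len(seg_t)
    span = range(_MARGIN, max(_MARGIN, n - _MARGIN - tsd))
    if m in ("A", "D", "F"):
        return list(span)
    if m == "B":
        return [q for q in span if seg_t[q : q + 2] == "GT"]
    if m == "C":
        return [q for q in span if seg_t[q + tsd - 2 : q + tsd] == "AG"]
    if m == "E":
        c = elem["p_len"]
        return [q for q in span if seg_t[q + c - 2 : q + c + 2] == "AGGT"]
    return []


def _copy_strings(rng, spec: FamilySpec, elem: dict, exon_t: str, q: int):
    """Build the per-copy insert string and intron geometry.

    Returns (intron_seq, y, t_off, intron_rel, tsd_seq) where y is the string
    inserted at transcription offset t_off and intron_rel the intron span
    within the modified exon string.
    """
    m = spec.mechanism
    tsd = spec.tsd_length
    body = elem["element"]
    div = spec.divergence
    if m in ("A", "D"):
        intron = body if m == "A" else "GT" + body + "AG"
        intron = mutate(rng, intron, div, elem["protect"])
        return intron, intron, q, (q, q + len(intron)), ""
    if m == "B":
        t = exon_t[q : q + tsd]  # starts GT
        intron = t + mutate(rng, body, div)
        intron = _protect_fix(intron, elem["protect"], t + body)
        y = intron
        return intron, y, q, (q, q + len(intron)), t
    if m == "C":
        t = exon_t[q : q + tsd]  # ends AG
        e_div = mutate(rng, body, div, {0, 1})
        intron = e_div + t
        y = e_div + t
        return intron, y, q + tsd, (q + tsd, q + tsd + len(intron)), t
    if m == "E":
        c = elem["p_len"]
        t = exon_t[q : q + tsd]
        p_part, s_part = t[:c], t[c:]
        e_div = mutate(rng, body, div)
        intron = s_part + e_div + p_part
        y = e_div + t
        return intron, y, q + tsd, (q + c, q + c + len(intron)), t
    if m == "F":
        t = exon_t[q : q + tsd]
        i_div = mutate(rng, body, div, {0, 1, len(body) - 2, len(body) - 1})
        y = elem["u"] + i_div + elem["v"] + t
        o = q + tsd
        rel = (o + 2, o + 2 + len(i_div))
        return i_div, y, o, rel, t
    raise AssertionError(m)


def _protect_fix(seq: str, protect: set[int], original: str) -> str:
    out = list(seq)
    for i in protect:
        out[i] = original[i]
    return "".join(out)


def _truth_row(family_id, copy, chrom, gi, strand, genic, gene_id, tsd_seq, elem, intron, m):
    prov5 = "co-opted" if m in ("B", "E") else "carried"
    prov3 = "co-opted" if m in ("C", "E") else "carried"
    return {
        "family": family_id,
        "copy": copy,
        "chrom": chrom,
        "start": gi[0],
        "end": gi[1],
        "strand": strand,
        "genic": genic,
        "gene_id": gene_id,
        "tsd": tsd_seq,
        "element": elem["element"],
        "intron_seq": intron,
        "mechanism": m,
        "five_prime_source": prov5,
        "three_prime_source": prov3,
        "mrna_gain": (len(tsd_seq) + 4) if m == "F" else 0,
    }


# ---------------------------------------------------------------------------
# confounders


def _background_introns(bundle: GenomeBundle, exclude: set[str]):
    out = []
    for gene in bundle.genes:
        if gene.id in exclude:
            continue
        for k in range(len(gene.exons) - 1):
            i0, i1 = gene.exons[k][1], gene.exons[k + 1][0]
            out.append((gene, i0, i1))
    return out


def _replace_intron_interior(
    bundle: GenomeBundle, gene: GeneModel, i0: int, i1: int, motif: str, offset: int
) -> None:
    """Overwrite intron interior bases (transcription offsets offset..) with motif."""
    seq = bundle.sequences[gene.chrom]
    if gene.strand == "+":
        a = i0 + offset
        bundle.sequences[gene.chrom] = seq[:a] + motif + seq[a + len(motif):]
    else:
        b = i1 - offset
        bundle.sequences[gene.chrom] = seq[: b - len(motif)] + revcomp(motif) + seq[b:]


def add_confounders(
    bundle: GenomeBundle,
    n_paralog_pairs: int = 0,
    n_microsat_introns: int = 0,
    n_secondary_te: int = 0,
    seed: int = 0,
    exclude_gene_ids: set[str] | None = None,
    prior_truth: tuple[pd.DataFrame, ...] = (),
) -> pd.DataFrame:
    """Plant false-positive generators for the detection pipeline.

    Paralog pairs are whole-gene duplications (introns similar because their
    flanks are too); microsatellite introns share a tandem repeat strictly
    interior to the intron; secondary-TE introns share a 50-nt motif placed
    >= 20 nt from each splice boundary.  Genes in `exclude_gene_ids` (for
    example Introner hosts) are never touched.
    """
    rng = np.random.default_rng(seed)
    exclude = set(exclude_gene_ids or ())
    rows = []

    # paralog pairs: duplicate a whole gene into an intergenic gap
    candidates = [g for g in bundle.genes if g.id not in exclude and len(g.exons) >= 2]
    candidates = [candidates[int(i)] for i in rng.permutation(len(candidates))]
    for k in range(n_paralog_pairs):
        if not candidates:
            raise RuntimeError("no genes available for paralog duplication")
        src = candidates.pop()
        exclude.add(src.id)
        seq = bundle.sequences[src.chrom]
        span = seq[src.start : src.end]
        gene_t = span if src.strand == "+" else revcomp(span)
        t_exons = []
        for s, e in src.exons_transcription_order():
            if src.strand == "+":
                t_exons.append((s - src.start, e - src.start))
            else:
                t_exons.append((src.end - e, src.end - s))
        t_exons.sort()
        mutated = _mutate_gene_copy(rng, gene_t, t_exons, rate=0.01)
        gaps = [g for g in _intergenic_gaps(bundle) if g[2] - g[1] > len(mutated) + 2 * _MARGIN]
        if not gaps:
            raise RuntimeError("no intergenic room for paralog copy")
        chrom, g0, g1 = gaps[int(rng.integers(len(gaps)))]
        gpos = g0 + _MARGIN
        if _inside_any([], prior_truth, chrom, gpos, pad=10):
            gpos = g1 - _MARGIN - len(mutated)
        _insert_intergenic(bundle, chrom, gpos, mutated)
        _shift_truth(prior_truth, chrom, gpos, len(mutated))
        dup = GeneModel(
            id=f"{src.id}_dup",
            chrom=chrom,
            strand="+",
            exons=[(gpos + a, gpos + b) for a, b in t_exons],
        )
        bundle.genes.append(dup)
        bundle.genes.sort(key=lambda g: (g.chrom, g.start))
        exclude.add(dup.id)
        rows.append(
            {"type": "paralog", "id": f"paralog{k}", "gene_id": src.id,
             "partner": dup.id, "chrom": chrom, "start": gpos,
             "end": gpos + len(mutated)}
        )

    # microsatellite introns: shared tandem repeat interior
    if n_microsat_introns:
        unit = random_seq(rng, 5)
        motif = unit * 9  # 45 nt, 9 tandem copies
        pool = [x for x in _background_introns(bundle, exclude)
                if x[2] - x[1] >= len(motif) + 2 * _MARGIN]
        if len(pool) < n_microsat_introns:
            raise RuntimeError("not enough long background introns for microsatellites")
        picks = rng.choice(len(pool), size=n_microsat_introns, replace=False)
        for j, pi in enumerate(picks):
            gene, i0, i1 = pool[int(pi)]
            _replace_intron_interior(bundle, gene, i0, i1, motif, _MARGIN)
            exclude.add(gene.id)
            rows.append(
                {"type": "microsat", "id": f"ms{j}", "gene_id": gene.id,
                 "partner": "", "chrom": gene.chrom, "start": i0, "end": i1}
            )

    # secondary TE insertions strictly interior to preexisting introns
    if n_secondary_te:
        motif = random_seq(rng, 50)
        pool = [x for x in _background_introns(bundle, exclude)
                if x[2] - x[1] >= len(motif) + 2 * _MARGIN]
        if len(pool) < n_secondary_te:
            raise RuntimeError("not enough long background introns for secondary TEs")
        picks = rng.choice(len(pool), size=n_secondary_te, replace=False)
        for j, pi in enumerate(picks):
            gene, i0, i1 = pool[int(pi)]
            _replace_intron_interior(bundle, gene, i0, i1, motif, _MARGIN)
            exclude.add(gene.id)
            rows.append(
                {"type": "secondary_te", "id": f"te{j}", "gene_id": gene.id,
                 "partner": "", "chrom": gene.chrom, "start": i0, "end": i1}
            )

    return pd.DataFrame(
        rows, columns=["type", "id", "gene_id", "partner", "chrom", "start", "end"]
    )


def _mutate_gene_copy(rng, gene_t: str, t_exons: list[tuple[int, int]], rate: float) -> str:
    """Mutate a gene copy codon-aware: never creates stops or breaks splice sites."""
    out = list(gene_t)
    exonic = np.zeros(len(gene_t), bool)
    for a, b in t_exons:
        exonic[a:b] = True
    # introns: mutate interiors freely
    prev_end = None
    for a, b in t_exons:
        if prev_end is not None:
            for i in range(prev_end + 2, a - 2):
                if rng.random() < rate:
                    out[i] = "ACGT"[int(rng.integers(4))]
        prev_end = b
    # exons: codon-level substitutions avoiding stops
    cds_pos = [i for a, b in t_exons for i in range(a, b)]
    for c in range(1, len(cds_pos) // 3 - 1):  # skip start and stop codons
        if rng.random() < 3 * rate:
            idxs = cds_pos[3 * c : 3 * c + 3]
            for _ in range(20):
                codon = random_seq(rng, 3)
                if codon not in _STOPS:
                    break
            for i, ch in zip(idxs, codon):
                out[i] = ch
    return "".join(out)


# ---------------------------------------------------------------------------
# read-count and species-panel simulation


def simulate_counts(
    bundle: GenomeBundle,
    truth: pd.DataFrame | None,
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-intron splice-junction counts and per-gene read counts.

    Introns matching truth intervals use `introner_retention_rate`; all other
    introns use the background rate.  Expected reads per gene scale with
    expression times CDS length.  Returns (splice_counts, gene_counts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth_keys = set()
    truth_genes = set()
    if truth is not None and len(truth):
        truth_keys = set(zip(truth["chrom"], truth["start"], truth["end"]))
        truth_genes = set(truth.loc[truth["gene_id"] != "", "gene_id"])

    from .genome_io import extract_introns

    records = extract_introns(bundle)
    srows, grows = [], []
    for gene in bundle.genes:
        cds_len = sum(e - s for s, e in gene.exons)
        expr = config.reads_per_kb
        if config.dispersion > 0:
            expr *= float(rng.lognormal(0.0, config.dispersion))
        if gene.id in truth_genes:
            expr *= config.introner_expression_factor
        reads = int(rng.poisson(expr * cds_len / 1000.0)) if expr > 0 else 0
        depth = expr
        grows.append(
            {"gene_id": gene.id, "length": cds_len, "reads": reads,
             "has_introner": gene.id in truth_genes}
        )
        for rec in [r for r in records if r.gene_id == gene.id]:
            is_introner = (rec.chrom, rec.start, rec.end) in truth_keys
            rate = (
                config.introner_retention_rate
                if is_introner
                else config.background_retention_rate
            )
            total = int(rng.poisson(depth)) if depth > 0 else 0
            retained = int(rng.binomial(total, rate)) if total else 0
            spliced = total - retained
            miss = int(rng.binomial(spliced, config.missplice_rate)) if spliced else 0
            srows.append(
                {
                    "intron_id": rec.id,
                    "gene_id": rec.gene_id,
                    "is_introner": is_introner,
                    "proper_splices": spliced - miss,
                    "missplices": miss,
                    "retained": retained,
                    "depth": depth,
                    "length": rec.end - rec.start,
                }
            )
    return pd.DataFrame(srows), pd.DataFrame(grows)


def simulate_species_panel(
    n_aquatic: int,
    n_nonaquatic: int,
    p_introner_aquatic: float,
    p_introner_other: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli species panel: habitat flag and Introner presence flag."""
    if min(n_aquatic, n_nonaquatic) <= 0:
        raise ValueError("species counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_aquatic):
        rows.append(
            {"species": f"aq{i + 1:04d}", "habitat": "aquatic",
             "introner_present": bool(rng.random() < p_introner_aquatic)}
        )
    for i in range(n_nonaquatic):
        rows.append(
            {"species": f"na{i + 1:04d}", "habitat": "non-aquatic",
             "introner_present": bool(rng.random() < p_introner_other)}
        )
    return pd.DataFrame(rows)
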