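"""Genome-wide recovery of family copies and insertion-bias permutation tests.

Intergenic element copies are invisible to annotation-based intron
extraction, so each family consensus is searched against the whole genome
(both strands); hits overlapping an annotated member are marked as self and
deduplicated.  Insertional biases are then assessed by permutation:

* genic enrichment — observed genic site count versus sites dropped
  uniformly at random on the genome (gene density sets the null rate);
* GC enrichment — observed mean GC of the 20-bp concatenated flanks versus
  random 20-bp windows resampled from the same host genes, with element
  spans masked so the elements' own composition cannot leak into the null.

Permutation p-values use the +1 pseudo-count convention
p = (1 + #{null >= observed}) / (n_perm + 1), which is valid (never zero)
and super-uniform under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import gc_fraction, iter_kmers, revcomp
from .genome_io import GenomeBundle
from .similarity import SimilarityParams, local_align, significance


@dataclass
class InsertionSite:
    family: str
    chrom: str
    start: int
    end: int
    strand: str
    genic: bool
    flank_gc: float
    source: str  # "annotated_intron" | "consensus_scan"
    gene_id: str = ""


@dataclass
class EnrichmentResult:
    name: str
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float
    direction: str


# ---------------------------------------------------------------------------
# consensus-to-genome scan


def _gene_lookup(bundle: GenomeBundle):
    spans = bundle._gene_spans_by_chrom()
    starts = {c: np.array([s for s, _ in iv]) for c, iv in spans.items()}
    ends = {c: np.array([e for _, e in iv]) for c, iv in spans.items()}
    genes_sorted = {}
    for g in bundle.genes:
        genes_sorted.setdefault(g.chrom, []).append(g)

    def lookup(chrom: str, pos: int) -> bool:
        if chrom not in starts or len(starts[chrom]) == 0:
            return False
        i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        return i >= 0 and pos < ends[chrom][i]

    def gene_at(chrom: str, pos: int):
        for g in genes_sorted.get(chrom, []):
            if g.start <= pos < g.end:
                return g
        return None

    return lookup, gene_at


def scan_genome(
    consensus: str,
    family_id: str,
    bundle: GenomeBundle,
    annotated: list[tuple[str, int, int]] | None = None,
    params: SimilarityParams = SimilarityParams(),
    flank: int = 10,
) -> list[InsertionSite]:
    """Significant occurrences of a family consensus across the genome.

    Seeded on exact 11-mers, extended by local alignment on a window around
    each seed cluster, filtered at the e-value threshold, deduplicated at
    50% reciprocal overlap.  Hits reciprocally overlapping an annotated
    member interval by >= 50% are dropped (self hits).  Requires a consensus
    of at least 20 nt.
    """
    if len(consensus) < 20:
        raise ValueError("consensus too short to scan (< 20 nt)")
    k = params.seed_k
    annotated = annotated or []
    lookup, gene_at = _gene_lookup(bundle)
    genome_total = float(bundle.genome_length)

    hits: list[tuple[str, int, int, str, float]] = []
    for chrom, seq in bundle.sequences.items():
        index: dict[str, list[int]] = {}
        for pos, km in iter_kmers(seq, k):
            index.setdefault(km, []).append(pos)
        for strand, cons in (("+", consensus), ("-", revcomp(consensus))):
            diag_pos: set[int] = set()
            for off, km in iter_kmers(cons, k):
                for pos in index.get(km, ()):
                    diag_pos.add(pos - off)
            # cluster candidate start positions within one consensus length
            starts = sorted(diag_pos)
            clusters: list[list[int]] = []
            for s in starts:
                if clusters and s - clusters[-1][-1] <= len(cons) // 2:
                    clusters[-1].append(s)
                else:
                    clusters.append([s])
            for cl in clusters:
                w0 = max(0, min(cl) - 20)
                w1 = min(len(seq), max(cl) + len(cons) + 20)
                aln = local_align(cons, seq[w0:w1], params)
                ev = significance(
                    aln.score, len(cons), w1 - w0, 2 * genome_total * len(cons), params
                )
                if ev <= params.evalue:
                    hits.append((chrom, w0 + aln.y_start, w0 + aln.y_end, strand, aln.score))

    # deduplicate overlapping hits, best score first
    hits.sort(key=lambda h: (-h[4], h[0], h[1]))
    kept: list[tuple[str, int, int, str, float]] = []
    for h in hits:
        if not any(_reciprocal_overlap(h, other) >= 0.5 for other in kept if other[0] == h[0]):
            kept.append(h)

    sites = []
    for chrom, s, e, strand, _score in sorted(kept, key=lambda h: (h[0], h[1])):
        if any(
            c == chrom and _reciprocal_overlap((chrom, s, e), (c, a, b)) >= 0.5
            for c, a, b in annotated
        ):
            continue
        mid = (s + e) // 2
        genic = lookup(chrom, mid)
        gene = gene_at(chrom, mid) if genic else None
        seq = bundle.sequences[chrom]
        fl = seq[max(0, s - flank) : s] + seq[e : e + flank]
        sites.append(
            InsertionSite(
                family=family_id,
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                genic=genic,
                flank_gc=gc_fraction(fl),
                source="consensus_scan",
                gene_id=gene.id if gene else "",
            )
        )
    return sites


def _reciprocal_overlap(a, b) -> float:
    _, s1, e1 = a[0], a[1], a[2]
    _, s2, e2 = b[0], b[1], b[2]
    ov = max(0, min(e1, e2) - max(s1, s2))
    if ov == 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def sites_from_annotation(
    family_id: str,
    member_intervals: list[tuple[str, int, int, str]],
    bundle: GenomeBundle,
    flank: int = 10,
) -> list[InsertionSite]:
    """InsertionSite records for a family's annotated (intronic) members."""
    lookup, gene_at = _gene_lookup(bundle)
    out = []
    for chrom, s, e, strand in member_intervals:
        seq = bundle.sequences[chrom]
        mid = (s + e) // 2
        gene = gene_at(chrom, mid)
        fl = seq[max(0, s - flank) : s] + seq[e : e + flank]
        out.append(
            InsertionSite(
                family=family_id,
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                genic=lookup(chrom, mid),
                flank_gc=gc_fraction(fl),
                source="annotated_intron",
                gene_id=gene.id if gene else "",
            )
        )
    return out


# ---------------------------------------------------------------------------
# permutation tests


def genic_enrichment(
    sites: list[InsertionSite],
    bundle: GenomeBundle,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for insertion bias into genes.

    Each permutation drops len(sites) positions uniformly on the genome and
    counts genic landings; one-sided p for enrichment with the +1 convention.
    """
    if not sites:
        raise ValueError("need at least one insertion site")
    rng = np.random.default_rng(seed)
    observed = sum(1 for s in sites if s.genic)
    chroms = list(bundle.sequences)
    lengths = np.array([len(bundle.sequences[c]) for c in chroms], dtype=float)
    pchrom = lengths / lengths.sum()
    spans = bundle._gene_spans_by_chrom()
    starts = {c: np.array([s for s, _ in spans.get(c, [])]) for c in chroms}
    ends = {c: np.array([e for _, e in spans.get(c, [])]) for c in chroms}
    n = len(sites)
    ci = rng.choice(len(chroms), size=(n_perm, n), p=pchrom)
    pos = rng.random((n_perm, n))
    genic = np.zeros((n_perm, n), dtype=bool)
    for k, c in enumerate(chroms):
        mask = ci == k
        if not mask.any() or len(starts[c]) == 0:
            continue
        p_k = (pos[mask] * lengths[k]).astype(np.int64)
        idx = np.searchsorted(starts[c], p_k, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(p_k.shape, dtype=bool)
        hit[ok] = p_k[ok] < ends[c][idx[ok]]
        genic[mask] = hit
    null = genic.sum(axis=1)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return EnrichmentResult(
        name="genic_enrichment",
        observed=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_perm=n_perm,
        p_value=p,
        direction="enriched" if observed > null.mean() else "depleted",
    )


def gc_enrichment(
    sites: list[InsertionSite],
    bundle: GenomeBundle,
    flank: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for insertion bias into GC-rich sites.

    Observed statistic: mean GC of the concatenated `flank` bp upstream and
    downstream of each genic site (2*flank total, element excluded).  Null:
    for each site, a random 2*flank window from the same host gene with all
    element spans masked.  One-sided for enrichment.
    """
    rng = np.random.default_rng(seed)
    genes = {g.id: g for g in bundle.genes}
    window = 2 * flank

    masked: dict[str, tuple[str, np.ndarray]] = {}
    spans_by_gene: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        if s.gene_id:
            spans_by_gene.setdefault(s.gene_id, []).append((s.start, s.end))

    usable_sites = []
    obs_vals = []
    for s in sites:
        gene = genes.get(s.gene_id)
        if gene is None:
            continue
        seq = bundle.sequences[gene.chrom]
        fl = seq[max(0, s.start - flank) : s.start] + seq[s.end : s.end + flank]
        if gene.id not in masked:
            gseq = seq[gene.start : gene.end]
            ok = np.ones(len(gseq), dtype=bool)
            for a, b in spans_by_gene.get(gene.id, []):
                ok[max(0, a - gene.start) : max(0, b - gene.start)] = False
            masked[gene.id] = (gseq, ok)
        gseq, ok = masked[gene.id]
        starts = [
            i for i in range(len(gseq) - window + 1) if ok[i : i + window].all()
        ]
        if not starts:
            warnings.warn(f"gene {gene.id} too short for GC null sampling; site skipped")
            continue
        usable_sites.append((gene.id, starts))
        obs_vals.append(gc_fraction(fl))
    if not usable_sites:
        raise ValueError("no usable genic sites for GC enrichment")
    observed = float(np.mean(obs_vals))

    null = np.empty(n_perm)
    for b in range(n_perm):
        vals = []
        for gid, starts in usable_sites:
            gseq, _ = masked[gid]
            i = starts[int(rng.integers(len(starts)))]
            vals.append(gc_fraction(gseq[i : i + window]))
        null[b] = np.mean(vals)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return EnrichmentResult(
        name="gc_enrichment",
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_perm=n_perm,
        p_value=p,
        direction="enriched" if observed > null.mean() else "depleted",
    )


def cross_species_binomial(per_species_flags: list[bool]) -> float:
    """One-sided exact binomial tail P(X >= successes | n, 0.5)."""
    if not per_species_flags:
        raise ValueError("need at least one species")
    n = len(per_species_flags)
    k = sum(bool(f) for f in per_species_flags)
    return float(stats.binom.sf(k - 1, n, 0.5))


def sites_to_table(sites: list[InsertionSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [s.family for s in sites],
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "strand": [s.strand for s in sites],
            "genic": [s.genic for s in sites],
            "flank_gc": [s.flank_gc for s in sites],
            "source": [s.source for s in sites],
            "gene_id": [s.gene_id for s in sites],
        }
    )
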