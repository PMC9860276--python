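"""Family assembly: paralog and low-complexity filters, clustering, consensus.

Surviving intron pairs are clustered into families as connected components of
the pair graph (single linkage); families need at least four members.  A
majority-rule consensus (>50% per column) is built from a center-star
multiple alignment of the members, which is adequate at the high identities
of recently expanded element families and fully deterministic.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import gc_fraction, kmer_entropy, max_tandem_coverage, revcomp
from .genome_io import GenomeBundle, IntronRecord
from .similarity import IntronPair, SimilarityParams, local_align, significance

MIN_FAMILY_SIZE = 4

# standard gapped Karlin-Altschul constants for BLOSUM62 (open 11, extend 1)
_PROT_LAMBDA = 0.267
_PROT_K = 0.041


@dataclass
class ConsensusModel:
    """Majority-rule consensus of an Introner family."""

    sequence: str
    frequencies: pd.DataFrame  # per emitted position, columns A C G T -
    n_members: int
    flanked: str  # flank5 + sequence + flank3 (N where no majority)
    flank5_len: int
    flank3_len: int

    @property
    def boundaries(self) -> tuple[int, int]:
        """(5' boundary, 3' boundary) positions within `flanked`."""
        return self.flank5_len, self.flank5_len + len(self.sequence)


@dataclass
class IntronerFamily:
    id: str
    members: list[str]  # intron ids
    orientations: dict[str, int]  # +1 / -1 relative to family reference
    consensus: ConsensusModel | None = None
    low_complexity: bool = False
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# paralog filter


@lru_cache(maxsize=2)
def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _protein_evalue(p1: str, p2: str) -> float:
    al = _protein_aligner()
    score = al.score(p1, p2)
    if score <= 0:
        return math.inf
    return _PROT_K * len(p1) * len(p2) * math.exp(-_PROT_LAMBDA * score)


def paralog_filter(
    pairs: list[IntronPair],
    bundle: GenomeBundle,
    records: list[IntronRecord],
    protein_sig_threshold: float = 1e-20,
) -> list[IntronPair]:
    """Drop pairs whose host genes encode significantly similar proteins.

    Recent gene duplications make introns similar for reasons unrelated to
    element mobilization; such pairs are detected at the protein level and
    removed.  Pairs of introns within one gene are exempt.  Genes whose CDS
    cannot be translated are skipped conservatively (their pairs retained).
    """
    gene_of = {r.id: r.gene_id for r in records}
    genes = {g.id: g for g in bundle.genes}
    prot_cache: dict[str, str | None] = {}

    def protein(gid: str) -> str | None:
        if gid not in prot_cache:
            gene = genes.get(gid)
            if gene is None:
                prot_cache[gid] = None
            else:
                try:
                    aa = gene.protein(bundle.sequences)
                    prot_cache[gid] = aa.replace("*", "X") if aa else None
                except Exception:
                    warnings.warn(f"untranslatable CDS for gene {gid}; pairs retained")
                    prot_cache[gid] = None
        return prot_cache[gid]

    evalue_cache: dict[tuple[str, str], float] = {}
    kept = []
    for p in pairs:
        g1, g2 = gene_of[p.x_id], gene_of[p.y_id]
        if g1 == g2:
            kept.append(p)
            continue
        key = (min(g1, g2), max(g1, g2))
        if key not in evalue_cache:
            p1, p2 = protein(g1), protein(g2)
            if p1 is None or p2 is None:
                evalue_cache[key] = math.inf
            else:
                evalue_cache[key] = _protein_evalue(p1, p2)
        if evalue_cache[key] > protein_sig_threshold:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# low-complexity screen


def low_complexity_filter(seq: str, tandem_threshold: float = 0.5, entropy_bits: float = 2.0) -> bool:
    """Flag a sequence dominated by short repeats.

    True when one <=6-mer tandem run covers more than half the sequence or
    the 3-mer Shannon entropy falls below `entropy_bits`.
    """
    if not seq:
        return True
    if max_tandem_coverage(seq, max_unit=6) > tandem_threshold:
        return True
    return kmer_entropy(seq, k=3) < entropy_bits


# ---------------------------------------------------------------------------
# clustering


def cluster_families(
    pairs: list[IntronPair], min_size: int = MIN_FAMILY_SIZE
) -> list[IntronerFamily]:
    """Group introns into families: connected components of the pair graph.

    Components smaller than `min_size` are discarded.  Member orientations
    are propagated breadth-first from an arbitrary reference; an inconsistent
    (odd inversion) cycle triggers a warning and keeps the first-assigned
    orientation for the conflicting member.
    """
    adj: dict[str, list[tuple[str, int]]] = {}
    for p in pairs:
        flip = -1 if p.orientation == "opposite" else 1
        adj.setdefault(p.x_id, []).append((p.y_id, flip))
        adj.setdefault(p.y_id, []).append((p.x_id, flip))

    seen: set[str] = set()
    families: list[IntronerFamily] = []
    for root in sorted(adj):
        if root in seen:
            continue
        orient = {root: 1}
        seen.add(root)
        queue = deque([root])
        conflict = False
        while queue:
            u = queue.popleft()
            for v, flip in adj[u]:
                want = orient[u] * flip
                if v not in orient:
                    orient[v] = want
                    seen.add(v)
                    queue.append(v)
                elif orient[v] != want:
                    conflict = True
        if conflict:
            warnings.warn(f"orientation conflict in component containing {root}")
        if len(orient) >= min_size:
            members = sorted(orient)
            families.append(
                IntronerFamily(
                    id=f"family{len(families) + 1}",
                    members=members,
                    orientations=orient,
                )
            )
    return families


# ---------------------------------------------------------------------------
# consensus building (center-star MSA, majority rule)


@lru_cache(maxsize=2)
def _global_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -2.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    return al


def _project_onto_star(star: str, member: str) -> tuple[list[str], dict[int, str]]:
    """Align member to star; return per-star-position chars and insertions.

    Insertions are keyed by the star position they precede.
    """
    al = _global_aligner()
    aln = al.align(star, member)[0]
    bx, by = aln.aligned
    cols = ["-"] * len(star)
    inserts: dict[int, str] = {}
    prev_y = 0
    for (ax, ex), (ay, ey) in zip(bx, by):
        if ay > prev_y:  # member bases not matched to star: insertion before ax
            inserts[ax] = member[prev_y:ay]
        for k in range(ex - ax):
            cols[ax + k] = member[ay + k]
        prev_y = ey
    if prev_y < len(member):
        inserts[len(star)] = member[prev_y:]
    return cols, inserts


def build_consensus(
    family: IntronerFamily, records_by_id: dict[str, IntronRecord]
) -> ConsensusModel:
    """Majority-rule consensus from a center-star multiple alignment.

    The star is the member minimizing summed pairwise distance (ties broken
    by id).  Columns whose most frequent symbol (gap included) does not
    exceed 50% are dropped, as are gap-majority columns.
    """
    seqs = {}
    for mid in family.members:
        rec = records_by_id[mid]
        s = rec.seq
        seqs[mid] = s if family.orientations.get(mid, 1) == 1 else revcomp(s)
    ids = sorted(seqs)
    n = len(ids)
    if n < 2:
        raise ValueError("consensus needs >= 2 members")

    al = _global_aligner()
    dist = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = -al.score(seqs[ids[i]], seqs[ids[j]])
            dist[i] += d
            dist[j] += d
    star_id = ids[int(np.argmin(dist))]
    star = seqs[star_id]

    projections = {mid: _project_onto_star(star, seqs[mid]) for mid in ids}
    max_ins = {p: 0 for p in range(len(star) + 1)}
    for _, inserts in projections.values():
        for p, s in inserts.items():
            max_ins[p] = max(max_ins[p], len(s))

    # column layout: [insertions before p] + star position p, for each p
    columns: list[list[str]] = []
    for p in range(len(star) + 1):
        for k in range(max_ins[p]):
            col = []
            for mid in ids:
                ins = projections[mid][1].get(p, "")
                col.append(ins[k] if k < len(ins) else "-")
            columns.append(col)
        if p < len(star):
            columns.append([projections[mid][0][p] for mid in ids])

    consensus_chars = []
    freq_rows = []
    for col in columns:
        counts = Counter(col)
        sym, cnt = counts.most_common(1)[0]
        if cnt / n <= 0.5 or sym == "-":
            continue
        consensus_chars.append(sym)
        freq_rows.append({b: counts.get(b, 0) / n for b in "ACGT-"})
    sequence = "".join(consensus_chars)

    flank5 = _flank_consensus([records_by_id[m] for m in ids], family.orientations, end=5)
    flank3 = _flank_consensus([records_by_id[m] for m in ids], family.orientations, end=3)
    model = ConsensusModel(
        sequence=sequence,
        frequencies=pd.DataFrame(freq_rows),
        n_members=n,
        flanked=flank5 + sequence + flank3,
        flank5_len=len(flank5),
        flank3_len=len(flank3),
    )
    family.consensus = model
    family.low_complexity = low_complexity_filter(sequence)
    lengths = [len(s) for s in seqs.values()]
    family.summary = {
        "copy_number": n,
        "median_length": float(np.median(lengths)),
        "gc": float(np.mean([gc_fraction(s) for s in seqs.values()])),
        "five_prime_dinucleotides": dict(Counter(s[:2] for s in seqs.values())),
    }
    return model


def _flank_consensus(records: list[IntronRecord], orientations: dict[str, int], end: int) -> str:
    """Columnwise majority of exonic flanks, aligned at the splice boundary.

    In family orientation the 5' flank of a flipped member is the reverse
    complement of its 3' flank.  Columns without a >50% majority emit N.
    """
    flanks = []
    for rec in records:
        fwd = orientations.get(rec.id, 1) == 1
        if end == 5:
            flanks.append(rec.up_flank if fwd else revcomp(rec.down_flank))
        else:
            flanks.append(rec.down_flank if fwd else revcomp(rec.up_flank))
    width = min(len(f) for f in flanks)
    out = []
    for k in range(width):
        if end == 5:  # right-aligned at the boundary
            col = [f[len(f) - width + k] for f in flanks]
        else:  # left-aligned at the boundary
            col = [f[k] for f in flanks]
        sym, cnt = Counter(col).most_common(1)[0]
        out.append(sym if cnt / len(col) > 0.5 else "N")
    return "".join(out)


def compare_consensi(
    consensi: dict[str, ConsensusModel],
    params: SimilarityParams = SimilarityParams(),
) -> pd.DataFrame:
    """All-vs-all local-alignment significance among family consensi."""
    ids = sorted(consensi)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = consensi[ids[i]].sequence, consensi[ids[j]].sequence
            if not a or not b:
                continue
            best = None
            for query in (b, revcomp(b)):
                aln = local_align(a, query, params)
                if best is None or aln.score > best.score:
                    best = aln
            ev = significance(best.score, len(a), len(b), params=params)
            rows.append(
                {
                    "family_x": ids[i],
                    "family_y": ids[j],
                    "score": best.score,
                    "evalue": ev,
                    "significant": ev <= params.evalue,
                }
            )
    return pd.DataFrame(
        rows, columns=["family_x", "family_y", "score", "evalue", "significant"]
    )


def family_summary_table(families: list[IntronerFamily]) -> pd.DataFrame:
    rows = []
    for f in families:
        row = {"family": f.id, "low_complexity": f.low_complexity}
        row.update(f.summary)
        if f.consensus:
            row["consensus_length"] = len(f.consensus.sequence)
        rows.append(row)
    return pd.DataFrame(rows)
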