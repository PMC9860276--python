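"""Boundary-anchored intron pair detection.

Two introns are accepted as a candidate Introner pair when their 5' ends
align to each other and their 3' ends align to each other (or 5' with 3' for
opposite-orientation insertions), each end alignment is significant under a
Karlin-Altschul e-value analogue, and every aligned region reaches to within
a 15-base window around the splice boundary of both introns (5 exonic or 10
intronic bases).  The boundary requirement distinguishes introns created by
the same insertion event from introns that merely share interior repeats
(microsatellites, secondary transposon insertions).

Alignments are computed on end windows only — up to 100 intronic nucleotides
plus the full exonic flank per end — which tolerates secondary indels in the
element interior.  Candidate pairs are seeded by shared exact 11-mers on
either strand; an exhaustive mode aligns every pair and is used as the
seeding oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from ._seq import iter_kmers, revcomp
from .genome_io import IntronRecord


@dataclass(frozen=True)
class SimilarityParams:
    seed_k: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    evalue: float = 1e-5  # significance threshold per end
    end_window: int = 100  # intronic nt assessed per end
    exonic_window: int = 5  # boundary window, exonic side
    intronic_window: int = 10  # boundary window, intronic side
    ka_k: float = 0.1  # Karlin-Altschul K, calibrated on shuffled introns
    # chance matches in the exonic flank can drag an otherwise boundary-
    # anchored alignment past the 5-base exonic window; overhangs up to this
    # many positions are trimmed back to the window edge, while the long
    # high-identity flank alignments typical of gene duplications still fail
    max_exonic_overhang: int = 10

    def __post_init__(self) -> None:
        if self.evalue <= 0 or self.end_window <= 0:
            raise ValueError("threshold and windows must be positive")


@dataclass
class LocalAlignment:
    score: float
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    identity: float


@dataclass
class EndAlignment:
    """Evidence for one intron pair: per-end scores and boundary offsets.

    Offsets are splice-site-relative: for each of the four boundaries the
    aligned region's boundary-proximal edge, with exonic positions negative
    and intronic positions >= 0 (5'-type) or <= 0 (3'-type).
    """

    query_id: str
    subject_id: str
    orientation: str  # "same" | "opposite"
    score5: float
    score3: float
    evalue5: float
    evalue3: float
    identity5: float
    identity3: float
    # boundary-proximal edge offsets, one per (intron, boundary)
    start_off_q5: int = 0
    start_off_s5: int = 0
    end_off_q3: int = 0
    end_off_s3: int = 0


@dataclass
class IntronPair:
    x_id: str
    y_id: str
    orientation: str
    evidence: EndAlignment
    combined_evalue: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.combined_evalue = max(self.evidence.evalue5, self.evidence.evalue3)


@lru_cache(maxsize=8)
def _dna_matrix(match: float, mismatch: float):
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == "N" or b == "N":
                m[a, b] = mismatch  # N matches nothing
            else:
                m[a, b] = match if a == b else mismatch
    return m


@lru_cache(maxsize=8)
def _aligner(params: SimilarityParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _dna_matrix(params.match, params.mismatch)
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    return al


@lru_cache(maxsize=8)
def karlin_lambda(match: float, mismatch: float) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch scheme, uniform bases."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 50.0))


def significance(
    score: float,
    len_x: int,
    len_y: int,
    total_search_space: float | None = None,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """Expected chance-hit count for a local alignment score.

    E = K * S * exp(-lambda * score) with S the total search space (defaults
    to len_x * len_y for a single comparison).  Monotone decreasing in score
    and linear in the search space.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    ss = float(total_search_space) if total_search_space is not None else float(len_x * len_y)
    lam = karlin_lambda(params.match, params.mismatch)
    return params.ka_k * ss * math.exp(-lam * score)


def local_align(x: str, y: str, params: SimilarityParams = SimilarityParams()) -> LocalAlignment:
    """Optimal local alignment of two ACGTN strings under affine scoring."""
    if not x or not y:
        raise ValueError("sequences must be non-empty")
    al = _aligner(params)
    score = al.score(x, y)
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0.0)
    aln = al.align(x, y)[0]
    blocks_x, blocks_y = aln.aligned
    x0, x1 = int(blocks_x[0][0]), int(blocks_x[-1][1])
    y0, y1 = int(blocks_y[0][0]), int(blocks_y[-1][1])
    matches = 0
    aligned = 0
    for (ax, bx), (ay, _by) in zip(blocks_x, blocks_y):
        seg_x = x[ax:bx]
        seg_y = y[ay : ay + (bx - ax)]
        aligned += bx - ax
        matches += sum(1 for c, d in zip(seg_x, seg_y) if c == d and c != "N")
    identity = matches / aligned if aligned else 0.0
    return LocalAlignment(float(score), x0, x1, y0, y1, identity)


# ---------------------------------------------------------------------------
# end windows and boundary geometry


@dataclass
class _Windows:
    """End windows of one intron: flank + up to `end_window` intronic nt."""

    w5: str
    f5: int  # exonic flank length inside w5
    ip5: int  # intronic length inside w5
    w3: str
    ip3: int
    f3: int


def _windows(rec: IntronRecord, params: SimilarityParams) -> _Windows:
    w = min(params.end_window, len(rec.seq))
    return _Windows(
        w5=rec.up_flank + rec.seq[:w],
        f5=len(rec.up_flank),
        ip5=w,
        w3=rec.seq[-w:] + rec.down_flank,
        ip3=w,
        f3=len(rec.down_flank),
    )


def _start_ok(off: int, params: SimilarityParams) -> bool:
    # 5'-type boundary: aligned region must begin within 5 exonic or 10
    # intronic bases of the splice site (offset 0 = first intronic base)
    return -params.exonic_window <= off < params.intronic_window


def _end_ok(off: int, params: SimilarityParams) -> bool:
    # 3'-type boundary, mirrored: off = aligned end - intronic window length
    return -params.intronic_window < off <= params.exonic_window


def boundary_anchored(alignment: EndAlignment, params: SimilarityParams = SimilarityParams()) -> bool:
    """True iff all four boundary-proximal edges lie inside the 15-base window."""
    return (
        _start_ok(alignment.start_off_q5, params)
        and _start_ok(alignment.start_off_s5, params)
        and _end_ok(alignment.end_off_q3, params)
        and _end_ok(alignment.end_off_s3, params)
    )


# ---------------------------------------------------------------------------
# all-vs-all candidate pair search


def _seed_pairs(
    records: list[IntronRecord], wins: list[_Windows], params: SimilarityParams
) -> dict[tuple[int, int], set[str]]:
    """Unordered index pairs sharing an exact k-mer, with orientation flags."""
    k = params.seed_k
    fulls = [r.up_flank + r.seq + r.down_flank for r in records]
    index: dict[str, list[int]] = {}
    for i, s in enumerate(fulls):
        seen = set()
        for _, km in iter_kmers(s, k):
            if km not in seen:
                seen.add(km)
                index.setdefault(km, []).append(i)
    pairs: dict[tuple[int, int], set[str]] = {}
    for bucket in index.values():
        if len(bucket) > 1:
            for ai in range(len(bucket)):
                for bi in range(ai + 1, len(bucket)):
                    key = (bucket[ai], bucket[bi])
                    pairs.setdefault(key, set()).add("same")
    for j, s in enumerate(fulls):
        seen = set()
        for _, km in iter_kmers(revcomp(s), k):
            if km in seen:
                continue
            seen.add(km)
            for i in index.get(km, ()):
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                pairs.setdefault(key, set()).add("opposite")
    return pairs


def _try_pair(
    ri: IntronRecord,
    rj: IntronRecord,
    wi: _Windows,
    wj: _Windows,
    orientation: str,
    db_total: float,
    params: SimilarityParams,
) -> IntronPair | None:
    al = _aligner(params)
    if orientation == "same":
        x5, y5 = wi.w5, wj.w5
        x3, y3 = wi.w3, wj.w3
    else:
        x5, y5 = wi.w5, revcomp(wj.w3)
        x3, y3 = wi.w3, revcomp(wj.w5)
    s5 = al.score(x5, y5)
    if s5 <= 0:
        return None
    e5 = significance(s5, len(x5), len(y5), len(x5) * db_total, params)
    if e5 > params.evalue:
        return None
    s3 = al.score(x3, y3)
    if s3 <= 0:
        return None
    e3 = significance(s3, len(x3), len(y3), len(x3) * db_total, params)
    if e3 > params.evalue:
        return None

    a5 = local_align(x5, y5, params)
    a3 = local_align(x3, y3, params)

    def clip_start(off: int) -> int:
        ov = -params.exonic_window - off
        if 0 < ov <= params.max_exonic_overhang:
            return -params.exonic_window
        return off

    def clip_end(off: int) -> int:
        ov = off - params.exonic_window
        if 0 < ov <= params.max_exonic_overhang:
            return params.exonic_window
        return off

    if orientation == "same":
        off_q5 = a5.x_start - wi.f5
        off_s5 = a5.y_start - wj.f5
        off_q3 = a3.x_end - wi.ip3
        off_s3 = a3.y_end - wj.ip3
    else:
        # y5 = revcomp(w3_j): flank-first window anchored at j's 3' boundary
        off_q5 = a5.x_start - wi.f5
        off_s5 = a5.y_start - wj.f3
        # y3 = revcomp(w5_j): intron-first window anchored at j's 5' boundary
        off_q3 = a3.x_end - wi.ip3
        off_s3 = a3.y_end - wj.ip5
    ev = EndAlignment(
        query_id=ri.id,
        subject_id=rj.id,
        orientation=orientation,
        score5=float(s5),
        score3=float(s3),
        evalue5=e5,
        evalue3=e3,
        identity5=a5.identity,
        identity3=a3.identity,
        start_off_q5=clip_start(off_q5),
        start_off_s5=clip_start(off_s5),
        end_off_q3=clip_end(off_q3),
        end_off_s3=clip_end(off_s3),
    )
    if not boundary_anchored(ev, params):
        return None
    return IntronPair(x_id=ri.id, y_id=rj.id, orientation=orientation, evidence=ev)


def candidate_pairs(
    records: list[IntronRecord],
    params: SimilarityParams = SimilarityParams(),
    exhaustive: bool = False,
) -> list[IntronPair]:
    """All accepted intron pairs among `records`.

    With `exhaustive=True` every unordered pair is aligned in both
    orientations (no k-mer seeding); results are otherwise identical given
    adequate seeding and this mode serves as the seeding oracle.
    """
    if len(records) < 2:
        return []
    order = sorted(range(len(records)), key=lambda i: records[i].id)
    records = [records[i] for i in order]
    wins = [_windows(r, params) for r in records]
    db_total = float(sum(len(w.w5) + len(w.w3) for w in wins))

    if exhaustive:
        cand: dict[tuple[int, int], set[str]] = {
            (i, j): {"same", "opposite"}
            for i in range(len(records))
            for j in range(i + 1, len(records))
        }
    else:
        cand = _seed_pairs(records, wins, params)

    out: list[IntronPair] = []
    for (i, j) in sorted(cand):
        orients = cand[(i, j)]
        pair = None
        if "same" in orients:
            pair = _try_pair(records[i], records[j], wins[i], wins[j], "same", db_total, params)
        if pair is None and "opposite" in orients:
            pair = _try_pair(
                records[i], records[j], wins[i], wins[j], "opposite", db_total, params
            )
        if pair is not None:
            out.append(pair)
    return out


def pairs_to_table(pairs: list[IntronPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intron_x": [p.x_id for p in pairs],
            "intron_y": [p.y_id for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "score5": [p.evidence.score5 for p in pairs],
            "score3": [p.evidence.score3 for p in pairs],
            "evalue5": [p.evidence.evalue5 for p in pairs],
            "evalue3": [p.evidence.evalue3 for p in pairs],
            "combined_evalue": [p.combined_evalue for p in pairs],
        }
    )
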