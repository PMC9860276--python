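"""Transposon signature calling: TSDs, TIRs, mechanisms, end PWMs.

A target site duplication (TSD) leaves the same host motif on both sides of
an insertion, so within each new intron the nucleotides at equal unsigned
distance from the 5' and the 3' splice site match — locus-specifically, not
across family members.  The TSD profile therefore records, per signed offset
k (negative = exonic side), the absolute within-intron match fraction A(k)
and the expected fraction E(k) from random cross-member 5'/3' re-pairings;
the relative match R(k) = A(k)/E(k) separates locus-specific duplications
(R >> 1) from motifs shared across members such as the obligatory splice
dinucleotides (A high, R ~ 1 — the degenerate "AGgt...ag" case, which is
called ambiguous).

Terminal inverted repeats (TIRs) are searched in the +-20 nt regions around
both boundaries of the flanked family consensus; a call of `present`
additionally requires the two arms to sit near-terminally and symmetrically
(offset from the respective boundary <= 6, offset difference <= 2), which
operationalizes a "clear extended TIR" and keeps chance inverted repeats in
random sequence rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .genome_io import GenomeBundle, IntronRecord
from .families import ConsensusModel, IntronerFamily

MIN_GENIC_MEMBERS = 15


@dataclass
class TSDProfile:
    family: str
    offsets: list[int]  # signed; negative = exonic side
    absolute: dict[int, float]  # A(k)
    expected: dict[int, float]  # E(k)
    relative: dict[int, float]  # R(k) = A/E
    n_members: int


@dataclass
class TSDCall:
    family: str
    status: str  # "present" | "absent" | "ambiguous"
    tsd_length: int = 0
    offsets: list[int] = field(default_factory=list)
    detail: dict = field(default_factory=dict)


@dataclass
class TIRCall:
    family: str
    status: str  # "present" | "absent" | "ambiguous"
    tir_length: int = 0
    arm5: str = ""
    arm3: str = ""
    offset5: int = 0
    offset3: int = 0


@dataclass
class EndPWM:
    end: str  # "five_prime" | "three_prime"
    matrix: np.ndarray  # length x 4, column-stochastic per position
    pseudo: float

    def __post_init__(self) -> None:
        assert np.allclose(self.matrix.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# TSD profile and call


def _side_base(rec: IntronRecord, side: int, k: int) -> str | None:
    """Base at signed offset k from the 5' (side=5) or 3' (side=3) splice site.

    Positive offsets run into the intron at the 5' site and into the
    downstream exon at the 3' site; negative offsets mirror that (upstream
    exon / intron end).  Offset 0 is not defined.
    """
    if k == 0:
        return None
    if side == 5:
        if k > 0:
            return rec.seq[k - 1] if k <= len(rec.seq) else None
        return rec.up_flank[k] if -k <= len(rec.up_flank) else None
    if k > 0:
        return rec.down_flank[k - 1] if k <= len(rec.down_flank) else None
    return rec.seq[k] if -k <= len(rec.seq) else None


def tsd_profile(
    family: IntronerFamily,
    records_by_id: dict[str, IntronRecord],
    max_offset: int = 10,
    n_pairings: int = 1000,
    seed: int = 0,
    min_members: int = MIN_GENIC_MEMBERS,
) -> TSDProfile:
    """Absolute and relative 5'/3' match fractions per signed offset."""
    members = [records_by_id[m] for m in family.members if m in records_by_id]
    members = [
        m
        for m in members
        if len(m.up_flank) >= max_offset
        and len(m.down_flank) >= max_offset
        and len(m.seq) >= 2 * max_offset
    ]
    if len(members) < min_members:
        raise ValueError(
            f"TSD profiling requires >= {min_members} genic members with "
            f"adequate flanks; family {family.id} has {len(members)}"
        )
    rng = np.random.default_rng(seed)
    offsets = [k for k in range(-max_offset, max_offset + 1) if k != 0]
    n = len(members)
    absolute, expected, relative = {}, {}, {}
    for k in offsets:
        five = [_side_base(m, 5, k) for m in members]
        three = [_side_base(m, 3, k) for m in members]
        a = float(np.mean([f == t for f, t in zip(five, three)]))
        hits = 0
        for _ in range(n_pairings):
            i, j = rng.integers(n), rng.integers(n)
            while j == i:
                j = int(rng.integers(n))
            hits += five[int(i)] == three[int(j)]
        e = hits / n_pairings
        absolute[k] = a
        expected[k] = e
        relative[k] = a / e if e > 0 else (np.inf if a > 0 else 1.0)
    return TSDProfile(
        family=family.id,
        offsets=offsets,
        absolute=absolute,
        expected=expected,
        relative=relative,
        n_members=n,
    )


def call_tsd(
    profile: TSDProfile,
    min_relative: float = 1.5,
    alpha: float = 0.01,
    min_absolute: float = 0.75,
) -> TSDCall:
    """Call TSD presence from a profile.

    `present` needs at least one locus-specific offset: R(k) >= min_relative
    with A(k) exceeding E(k) at exact-binomial p < alpha.  The inferred TSD
    spans the maximal contiguous high-A run on each side that contains such
    an offset and touches the boundary.  High-A runs without any
    locus-specific support at boundary-adjacent offsets (the shared-motif
    degeneracy) give `ambiguous`; otherwise `absent`.
    """
    n = profile.n_members
    locus_specific = {}
    for k in profile.offsets:
        a, e = profile.absolute[k], profile.expected[k]
        r = profile.relative[k]
        p = stats.binom.sf(int(round(a * n)) - 1, n, max(e, 1e-12))
        locus_specific[k] = (r >= min_relative) and (p < alpha)

    def runs(side: int):
        ks = [k for k in profile.offsets if (k > 0) == (side > 0)]
        ks.sort(key=abs)
        run: list[int] = []
        for k in ks:
            if profile.absolute[k] >= min_absolute:
                run.append(k)
            else:
                break  # runs must touch the boundary
        return run

    found_offsets: list[int] = []
    ambiguous_only = False
    for side in (+1, -1):
        run = runs(side)
        if not run:
            continue
        if any(locus_specific[k] for k in run):
            found_offsets.extend(run)
        elif abs(run[0]) <= 2:
            ambiguous_only = True
    if found_offsets:
        status = "present"
    elif ambiguous_only:
        status = "ambiguous"
    else:
        status = "absent"
    return TSDCall(
        family=profile.family,
        status=status,
        tsd_length=len(found_offsets),
        offsets=sorted(found_offsets),
        detail={
            "locus_specific_offsets": sorted(k for k, v in locus_specific.items() if v)
        },
    )


# ---------------------------------------------------------------------------
# TIR search


def find_tir(
    consensus: ConsensusModel,
    region: int = 20,
    min_len: int = 6,
    ambiguous_range: tuple[int, int] = (3, 5),
    max_mismatch_per_10: int = 1,
    max_arm_offset: int = 6,
    max_asymmetry: int = 2,
) -> TIRCall:
    """Longest inverted-repeat arm pair around the two element boundaries.

    Arms are searched within `region` nt on both sides of each boundary of
    the flanked consensus, allowing `max_mismatch_per_10` mismatches per
    10 nt (N never matches).  A `present` call needs arm length >= min_len
    plus near-terminal symmetric geometry; short exact symmetric arms in the
    ambiguous_range give `ambiguous`.
    """
    b5, b3 = consensus.boundaries
    flanked = consensus.flanked
    w5 = flanked[max(0, b5 - region) : b5 + region]
    w3 = flanked[max(0, b3 - region) : b3 + region]
    w5_origin = b5 - max(0, b5 - region)  # index of boundary within w5
    w3_origin = b3 - max(0, b3 - region)

    best = None  # (length, mism, d5, d3, arm5, arm3)
    rw3 = revcomp(w3)
    for L in range(min(len(w5), len(w3)), 2, -1):
        allowed = L // 10 * max_mismatch_per_10
        for i in range(len(w5) - L + 1):
            seg5 = w5[i : i + L]
            if "N" in seg5:
                continue
            for j in range(len(rw3) - L + 1):
                seg3r = rw3[j : j + L]
                if "N" in seg3r:
                    continue
                mism = sum(1 for a, b in zip(seg5, seg3r) if a != b)
                if mism > allowed:
                    continue
                # arm offsets from the boundaries: d5 = element-interior
                # distance of the 5' arm start, d3 = interior distance of the
                # 3' arm end (negative values = arm reaches into the flank)
                d5 = i - w5_origin
                arm3_end_in_w3 = len(w3) - j
                d3 = w3_origin - arm3_end_in_w3
                cand = (L, mism, d5, d3, seg5, revcomp(seg3r))
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
        if best is not None and best[0] == L:
            break  # longest found; lower L cannot beat it

    call = TIRCall(family="", status="absent")
    if best is None:
        return call
    L, mism, d5, d3, arm5, arm3 = best
    call.tir_length = L
    call.arm5, call.arm3 = arm5, arm3
    call.offset5, call.offset3 = d5, d3
    geometric = (
        abs(d5) <= max_arm_offset
        and abs(d3) <= max_arm_offset
        and abs(abs(d5) - abs(d3)) <= max_asymmetry
    )
    if L >= min_len and geometric:
        call.status = "present"
    elif (
        ambiguous_range[0] + 1 <= L <= ambiguous_range[1]
        and mism == 0
        and abs(d5) <= max_asymmetry
        and d5 == d3
    ):
        call.status = "ambiguous"
    return call


# ---------------------------------------------------------------------------
# mechanism classification


def classify_mechanism(
    family: IntronerFamily,
    tsd_call: TSDCall,
    tir_call: TIRCall,
    consensus: ConsensusModel,
    mrna_gain: int = 0,
) -> dict:
    """Label the splice-site recruitment mechanism of a family.

    Donor/acceptor provenance follows the TSD geometry: a splice dinucleotide
    covered by the locus-specific TSD run on its side is co-opted from the
    target site, otherwise it is carried within the element consensus.
    """
    seq = consensus.sequence
    donor_in_consensus = seq[:2] == "GT"
    acceptor_in_consensus = seq[-2:] == "AG"
    pos_run = [k for k in tsd_call.offsets if k > 0]
    neg_run = [k for k in tsd_call.offsets if k < 0]
    donor = "co-opted" if (tsd_call.status == "present" and (1 in pos_run or 2 in pos_run)) else "carried"
    acceptor = "co-opted" if (tsd_call.status == "present" and (-1 in neg_run or -2 in neg_run)) else "carried"

    tsd = tsd_call.status == "present"
    tir = tir_call.status == "present"
    if mrna_gain:
        label = "F"
    elif tsd and tir and donor == "co-opted" and acceptor == "carried":
        label = "B"
    elif tsd and not tir and donor == "carried" and acceptor == "co-opted":
        label = "C"
    elif tir and not tsd:
        label = "D"
    elif tsd and donor == "co-opted" and acceptor == "co-opted":
        label = "E"
    elif not tsd and not tir and donor_in_consensus and acceptor_in_consensus:
        label = "A"
    else:
        label = "undetermined"
    return {
        "family": family.id,
        "mechanism": label,
        "five_prime_site": donor,
        "three_prime_site": acceptor,
        "tsd_status": tsd_call.status,
        "tir_status": tir_call.status,
    }


# ---------------------------------------------------------------------------
# end PWMs and autonomous-element scan


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def end_pwm(
    family: IntronerFamily,
    records_by_id: dict[str, IntronRecord],
    length: int = 22,
    pseudo: float = 0.01,
    end: str = "five_prime",
) -> EndPWM:
    """Column-stochastic position weight matrix of member end sequences."""
    seqs = []
    for mid in family.members:
        rec = records_by_id[mid]
        s = rec.seq if family.orientations.get(mid, 1) == 1 else revcomp(rec.seq)
        if len(s) < length:
            continue
        seqs.append(s[:length] if end == "five_prime" else s[-length:])
    if len(seqs) < 4:
        raise ValueError("end PWM requires >= 4 members of adequate length")
    counts = np.full((length, 4), pseudo)
    for s in seqs:
        for i, b in enumerate(s):
            if b in _BASE_IDX:
                counts[i, _BASE_IDX[b]] += 1
    return EndPWM(end=end, matrix=counts / counts.sum(axis=1, keepdims=True), pseudo=pseudo)


def _pwm_scores(seq: str, pwm: EndPWM, background: np.ndarray) -> np.ndarray:
    """Log-odds score of the PWM at every start position of seq."""
    L = pwm.matrix.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    logodds = np.log(pwm.matrix) - np.log(background)[None, :]
    worst = logodds.min() - 1.0
    scores = np.zeros(n)
    for j in range(L):
        col = idx[j : j + n]
        vals = np.where(col >= 0, logodds[j][np.clip(col, 0, 3)], worst)
        scores += vals
    return scores


def pwm_score_threshold(
    pwm: EndPWM, bundle: GenomeBundle, quantile: float = 0.9999, seed: int = 0,
    sample: int = 200_000,
) -> float:
    """Score quantile of the PWM on randomly sampled genomic windows."""
    rng = np.random.default_rng(seed)
    bg = _background_freqs(bundle)
    chroms = list(bundle.sequences)
    L = pwm.matrix.shape[0]
    vals = []
    while len(vals) < sample:
        c = chroms[int(rng.integers(len(chroms)))]
        seq = bundle.sequences[c]
        if len(seq) <= L:
            continue
        n_take = min(sample - len(vals), 50_000)
        start = int(rng.integers(max(1, len(seq) - 60_000)))
        s = seq[start : start + n_take + L]
        sc = _pwm_scores(s, pwm, bg)
        vals.extend(sc.tolist())
    return float(np.quantile(np.array(vals[:sample]), quantile))


def _background_freqs(bundle: GenomeBundle) -> np.ndarray:
    counts = np.zeros(4)
    for seq in bundle.sequences.values():
        for b, i in _BASE_IDX.items():
            counts[i] += seq.count(b)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def _orfs_in(seq: str, min_codons: int = 100) -> list[tuple[int, int, str]]:
    """ATG..stop open reading frames of >= min_codons codons, forward frames."""
    out = []
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        i = frame
        start = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in stops:
                if (i + 3 - start) // 3 >= min_codons:
                    out.append((start, i + 3, seq[start : i + 3]))
                start = None
            i += 3
    return out


def scan_pwm_pairs(
    bundle: GenomeBundle,
    pwm5: EndPWM,
    pwm3: EndPWM,
    score_threshold: float,
    max_span: int = 10_000,
    min_orf_codons: int = 100,
) -> list[dict]:
    """Candidate autonomous elements: paired 5'/3' PWM matches with ORFs.

    Scans both strands; for each 5' match above threshold, 3' matches within
    `max_span` downstream define a candidate interval, and every contained
    ORF of >= min_orf_codons codons is reported.
    """
    bg = _background_freqs(bundle)
    L5, L3 = pwm5.matrix.shape[0], pwm3.matrix.shape[0]
    candidates = []
    for chrom, seq in bundle.sequences.items():
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            sc5 = _pwm_scores(s, pwm5, bg)
            sc3 = _pwm_scores(s, pwm3, bg)
            hits5 = np.nonzero(sc5 >= score_threshold)[0]
            hits3 = np.nonzero(sc3 >= score_threshold)[0]
            for h5 in hits5:
                lo, hi = h5 + L5, h5 + max_span
                sel = hits3[(hits3 >= lo) & (hits3 + L3 <= hi)]
                for h3 in sel:
                    elem = s[h5 : h3 + L3]
                    orfs = _orfs_in(elem, min_orf_codons)
                    if strand == "+":
                        start, end = int(h5), int(h3 + L3)
                    else:
                        start, end = len(seq) - int(h3 + L3), len(seq) - int(h5)
                    candidates.append(
                        {
                            "chrom": chrom,
                            "start": start,
                            "end": end,
                            "strand": strand,
                            "score5": float(sc5[h5]),
                            "score3": float(sc3[h3]),
                            "orfs": [
                                {"start": a, "end": b, "seq": o} for a, b, o in orfs
                            ],
                        }
                    )
    return candidates


def signature_table(calls: list[tuple[TSDCall, TIRCall]]) -> pd.DataFrame:
    rows = []
    for tsd, tir in calls:
        rows.append(
            {
                "family": tsd.family or tir.family,
                "tsd_status": tsd.status,
                "tsd_length": tsd.tsd_length,
                "tir_status": tir.status,
                "tir_length": tir.tir_length,
                "tir_arm5": tir.arm5,
                "tir_arm3": tir.arm3,
            }
        )
    return pd.DataFrame(rows)
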