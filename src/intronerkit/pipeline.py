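"""End-to-end Introner family detection on one genome bundle.

Chains intron extraction, boundary-anchored pair search, the paralog and
low-complexity filters, clustering, and consensus building; the stages stay
individually accessible through their own modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .families import (
    IntronerFamily,
    build_consensus,
    cluster_families,
    family_summary_table,
    paralog_filter,
)
from .genome_io import GenomeBundle, IntronRecord, extract_introns
from .similarity import IntronPair, SimilarityParams, candidate_pairs


@dataclass
class DetectionResult:
    records: list[IntronRecord]
    raw_pairs: list[IntronPair]
    pairs: list[IntronPair]  # post paralog filter
    families: list[IntronerFamily]  # consensus built, low-complexity flagged
    records_by_id: dict[str, IntronRecord] = field(default_factory=dict)

    @property
    def clean_families(self) -> list[IntronerFamily]:
        return [f for f in self.families if not f.low_complexity]

    def summary(self) -> pd.DataFrame:
        return family_summary_table(self.families)


def detect_families(
    bundle: GenomeBundle,
    params: SimilarityParams = SimilarityParams(),
    min_family_size: int = 4,
    protein_sig_threshold: float = 1e-20,
) -> DetectionResult:
    """Run the full detection pipeline on one genome."""
    records = extract_introns(bundle)
    raw_pairs = candidate_pairs(records, params)
    pairs = paralog_filter(raw_pairs, bundle, records, protein_sig_threshold)
    families = cluster_families(pairs, min_size=min_family_size)
    by_id = {r.id: r for r in records}
    for fam in families:
        build_consensus(fam, by_id)
    return DetectionResult(
        records=records,
        raw_pairs=raw_pairs,
        pairs=pairs,
        families=families,
        records_by_id=by_id,
    )


def member_intervals(
    family: IntronerFamily, records_by_id: dict[str, IntronRecord]
) -> list[tuple[str, int, int, str]]:
    out = []
    for mid in family.members:
        r = records_by_id[mid]
        out.append((r.chrom, r.start, r.end, r.strand))
    return out
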