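"""Shared fixtures: simulated genomes with planted families and confounders."""

from __future__ import annotations

import pandas as pd
import pytest

import intronerkit as ik


@pytest.fixture(scope="session")
def small_bundle():
    cfg = ik.GenomeSimConfig(
        n_chromosomes=1, chromosome_length=400_000, n_genes=150, seed=2
    )
    return ik.simulate_genome(cfg)


@pytest.fixture(scope="session")
def planted():
    """2-Mb genome, three planted families (B/D/E) plus all confounders.

    Returns (bundle, truth tables dict, confounder table).
    """
    cfg = ik.GenomeSimConfig(
        n_chromosomes=2, chromosome_length=1_000_000, n_genes=400, seed=1
    )
    bundle = ik.simulate_genome(cfg)
    tB = ik.plant_family(
        bundle,
        ik.FamilySpec(mechanism="B", copy_number=25, tsd_length=4, tir_length=8,
                      divergence=0.05),
        seed=7, family_id="famB",
    )
    tD = ik.plant_family(
        bundle,
        ik.FamilySpec(mechanism="D", copy_number=16, tsd_length=0, tir_length=8,
                      divergence=0.02),
        seed=8, family_id="famD", prior_truth=(tB,),
    )
    tE = ik.plant_family(
        bundle,
        ik.FamilySpec(mechanism="E", copy_number=20, tsd_length=6, tir_length=0,
                      divergence=0.02),
        seed=9, family_id="famE", prior_truth=(tB, tD),
    )
    truth = {"famB": tB, "famD": tD, "famE": tE}
    exclude = set(tB.gene_id) | set(tD.gene_id) | set(tE.gene_id)
    conf = ik.add_confounders(
        bundle, n_paralog_pairs=2, n_microsat_introns=5, n_secondary_te=5,
        seed=11, exclude_gene_ids=exclude, prior_truth=(tB, tD, tE),
    )
    return bundle, truth, conf


@pytest.fixture(scope="session")
def detection(planted):
    bundle, truth, conf = planted
    return ik.detect_families(bundle)


@pytest.fixture(scope="session")
def truth_map(planted):
    """(chrom, start, end) -> family name for every planted copy."""
    _, truth, _ = planted
    out = {}
    for name, df in truth.items():
        for _, r in df.iterrows():
            out[(r.chrom, r.start, r.end)] = name
    return out


@pytest.fixture(scope="session")
def all_truth(planted) -> pd.DataFrame:
    _, truth, _ = planted
    return pd.concat(truth.values(), ignore_index=True)
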