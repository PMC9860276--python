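"""Splicing efficiency and expression context of Introner introns.

Input is a per-intron junction-count table (the documented ingestion
boundary; any junction caller can produce it):

    intron_id  gene_id  is_introner  proper_splices  missplices  retained
    depth  length

`proper_splices` counts junction reads using the annotated donor+acceptor,
`missplices` junction reads using a non-canonical junction within 50 nt of
either annotated boundary, and `retained` reads mapping across the intron
unspliced.  Two binomial GLMs with logit link are fitted per genome:

    (proper, mis)     ~ introner + depth + length   (mis-splicing)
    (retained, spliced) ~ introner + depth + length   (retention / PSI)

each against the reduced model without the introner flag; the flag is
interpreted only when the full model is preferred by AIC.  A negative
retention coefficient means Introners are retained less, i.e. spliced more
efficiently, than other introns of the same genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SPLICE_COUNT_COLUMNS = [
    "intron_id",
    "gene_id",
    "is_introner",
    "proper_splices",
    "missplices",
    "retained",
    "depth",
    "length",
]


@dataclass
class GLMResult:
    label: str
    coef: float  # Introner-indicator coefficient (full model)
    se: float
    aic_full: float
    aic_reduced: float
    preferred: str  # "full" | "reduced"
    direction: str
    flagged: bool = False
    note: str = ""


def _fit_binomial(endog: np.ndarray, exog: np.ndarray):
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    return model.fit(tol=1e-8, maxiter=200)


def _binomial_glm(
    counts: pd.DataFrame,
    successes: str | pd.Series,
    failures: str | pd.Series,
    label: str,
    positive_means: str,
    negative_means: str,
) -> GLMResult:
    if counts["is_introner"].nunique() < 2 or len(counts) < 4:
        raise ValueError("need >= 2 introns in each class")
    succ = counts[successes] if isinstance(successes, str) else successes
    fail = counts[failures] if isinstance(failures, str) else failures
    succ = np.asarray(succ, dtype=float)
    fail = np.asarray(fail, dtype=float)
    if (succ + fail).sum() == 0:
        raise ValueError("no junction reads")
    endog = np.column_stack([succ, fail])
    x = np.column_stack(
        [
            counts["is_introner"].astype(float),
            counts["depth"].astype(float),
            counts["length"].astype(float),
        ]
    )
    exog_full = sm.add_constant(x, has_constant="add")
    exog_red = sm.add_constant(x[:, 1:], has_constant="add")

    flagged = False
    note = ""
    if succ.sum() == 0 or fail.sum() == 0:
        return GLMResult(
            label=label, coef=np.nan, se=np.nan, aic_full=np.nan,
            aic_reduced=np.nan, preferred="reduced", direction="undetermined",
            flagged=True, note="degenerate: all-zero successes or failures",
        )
    try:
        full = _fit_binomial(endog, exog_full)
        red = _fit_binomial(endog, exog_red)
    except Exception as exc:
        return GLMResult(
            label=label, coef=np.nan, se=np.nan, aic_full=np.nan,
            aic_reduced=np.nan, preferred="reduced", direction="undetermined",
            flagged=True, note=f"fit failed: {exc}",
        )
    coef = float(full.params[1])
    se = float(full.bse[1])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        flagged = True
        note = "separation suspected; coefficient not interpretable"
    preferred = "full" if full.aic < red.aic else "reduced"
    if flagged or preferred == "reduced":
        direction = "undetermined"
    else:
        direction = positive_means if coef > 0 else negative_means
    return GLMResult(
        label=label,
        coef=coef,
        se=se,
        aic_full=float(full.aic),
        aic_reduced=float(red.aic),
        preferred=preferred,
        direction=direction,
        flagged=flagged,
        note=note,
    )


def missplice_glm(counts: pd.DataFrame) -> GLMResult:
    """(proper, mis) ~ introner + depth + length vs the reduced model.

    A positive Introner coefficient means higher proper-splicing odds for
    Introners (fewer mis-splicing events).
    """
    return _binomial_glm(
        counts,
        "proper_splices",
        "missplices",
        label="(proper,mis) ~ introner + depth + length",
        positive_means="introners_spliced_more_accurately",
        negative_means="introners_missplice_more",
    )


def psi_glm(counts: pd.DataFrame) -> GLMResult:
    """(retained, spliced) ~ introner + depth + length vs the reduced model.

    A negative Introner coefficient means lower retention odds for
    Introners, i.e. they are spliced more efficiently.
    """
    spliced = counts["proper_splices"].astype(float) + counts["missplices"].astype(float)
    return _binomial_glm(
        counts,
        "retained",
        spliced,
        label="(retained,spliced) ~ introner + depth + length",
        positive_means="introners_retained_more",
        negative_means="introners_spliced_more_efficiently",
    )


def expression_permutation(
    gene_counts: pd.DataFrame,
    introner_gene_ids: set[str] | list[str],
    n_samples: int = 10_000,
    seed: int = 0,
) -> float:
    """Length-weighted permutation test for low expression of Introner genes.

    Observed: mean read count of Introner-containing genes.  Null: random
    gene sets of the same size, each gene sampled with probability
    proportional to its length.  Returns p_low, small when Introner genes
    are lowly expressed relative to length-matched expectation.
    """
    introner_gene_ids = set(introner_gene_ids)
    flags = gene_counts["gene_id"].isin(introner_gene_ids)
    k = int(flags.sum())
    if k == 0:
        raise ValueError("no Introner-containing genes in the table")
    rng = np.random.default_rng(seed)
    reads = gene_counts["reads"].to_numpy(dtype=float)
    lengths = gene_counts["length"].to_numpy(dtype=float)
    w = lengths / lengths.sum()
    observed = float(reads[flags.to_numpy()].mean())
    null = np.empty(n_samples)
    n = len(gene_counts)
    for b in range(n_samples):
        idx = rng.choice(n, size=k, replace=False, p=w)
        null[b] = reads[idx].mean()
    return float((1 + np.sum(null <= observed)) / (n_samples + 1))


def expression_mwu(
    rpkm_introner: np.ndarray | list[float],
    rpkm_other: np.ndarray | list[float],
    reads_introner: np.ndarray | None = None,
    reads_other: np.ndarray | None = None,
    min_reads: int = 10,
    alternative: str = "less",
) -> tuple[float, str]:
    """Rank-sum test on RPKM distributions, after a >=10-read filter.

    Exact null for small samples, normal approximation with tie correction
    otherwise.  Returns (p, direction).
    """
    x = np.asarray(rpkm_introner, dtype=float)
    y = np.asarray(rpkm_other, dtype=float)
    if reads_introner is not None:
        x = x[np.asarray(reads_introner) >= min_reads]
    if reads_other is not None:
        y = y[np.asarray(reads_other) >= min_reads]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is empty after the read filter")
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    direction = (
        "introner_genes_lower" if np.median(x) < np.median(y) else "introner_genes_higher"
    )
    return float(res.pvalue), direction


def read_splice_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPLICE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"splice-count table missing columns: {sorted(missing)}")
    return df
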