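"""Gene-signature scoring of expression matrices.

A signature score summarises a gene set's expression in each sample of
a cohort.  The workflow: log2-transform and per-gene median-centre the
matrix, take each sample's median over the signature genes, split the
cohort at the median score into high/low groups, and correlate two
signature scores (e.g. a substrate signature against the CIN70
chromosomal-instability signature) by Pearson product-moment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("degronscreen")


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    score: float
    group: str  # high | low


def preprocess_expression(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount), then subtract each gene row's median.

    Genes are rows, samples columns; input values must be nonnegative
    (e.g. RSEM estimates).  After centering every row has median 0.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative before log transform")
    logged = np.log2(matrix + pseudocount)
    return logged.sub(logged.median(axis=1), axis=0)


def score_samples(matrix: pd.DataFrame, signature_genes: Iterable[str]) -> pd.Series:
    """Per-sample median over the signature genes present in the matrix.

    Missing signature genes are reported; an entirely absent signature
    is an error.
    """
    genes = [str(g).upper() for g in signature_genes]
    idx = matrix.index.astype(str).str.upper()
    present = [g for g in genes if g in set(idx)]
    missing = [g for g in genes if g not in set(idx)]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if missing:
        logger.info("signature: %d/%d genes missing from matrix", len(missing), len(genes))
    sub = matrix.loc[idx.isin(present)]
    scores = sub.median(axis=0)
    scores.name = "score"
    return scores


def split_by_median(scores: pd.Series) -> pd.Series:
    """High/low grouping at the cohort median score.

    Samples scoring strictly above the median are ``high``; ties at the
    median go ``low`` (deterministic, so |high| ≤ |low|).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(scores.median())
    groups = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    groups.name = "group"
    return groups


def correlate_signatures(scores_a: pd.Series, scores_b: pd.Series) -> dict:
    """Pearson r, r² and two-sided p between two per-sample score vectors."""
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score vectors must share the same sample roster")
    if len(scores_a) < 3:
        raise ValueError("need at least 3 samples")
    b = scores_b.loc[scores_a.index]
    if float(np.std(scores_a)) == 0.0 or float(np.std(b)) == 0.0:
        raise ValueError("zero variance in a score vector")
    r, p = stats.pearsonr(scores_a.to_numpy(), b.to_numpy())
    return {"r": float(r), "r2": float(r) ** 2, "p_value": float(p)}


def companion_score(
    matrix: pd.DataFrame, gene_set: Iterable[str], method: str = "mean"
) -> pd.Series:
    """CIN70-style companion score: mean (default) or median over a gene set.

    The mean reading follows the common averaged-signature convention;
    the median option matches :func:`score_samples` exactly.
    """
    genes = [str(g).upper() for g in gene_set]
    idx = matrix.index.astype(str).str.upper()
    present = idx.isin(genes)
    if not present.any():
        raise ValueError("no companion genes present in the matrix")
    sub = matrix.loc[present]
    if method == "mean":
        scores = sub.mean(axis=0)
    elif method == "median":
        scores = sub.median(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    scores.name = "score"
    return scores


def group_difference(values: pd.Series, groups: pd.Series) -> dict:
    """Welch t-test of a per-sample covariate between high and low groups."""
    hi = values[groups == "high"].dropna()
    lo = values[groups == "low"].dropna()
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(hi, lo, equal_var=False)
    return {"t": float(t), "p_value": float(p),
            "mean_high": float(hi.mean()), "mean_low": float(lo.mean())}


def scores_to_frame(scores: pd.Series, groups: pd.Series | None = None) -> pd.DataFrame:
    out = pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy()})
    if groups is not None:
        out["group"] = groups.loc[scores.index].to_numpy()
    return out
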