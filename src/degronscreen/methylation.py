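"""Array-methylation downstream statistics.

Works on Infinium-style probe tables: per-probe β-values in [0, 1]
(fraction methylated signal) across samples.  The analysis chain is

1. QC — drop any probe whose detection p-value exceeds the threshold in
   *any one* sample,
2. transform β to M-values, M = log2(β / (1 − β)), the scale on which
   variances are comparable and two-sample testing behaves,
3. per-probe differential testing between sample groups with
   Benjamini–Hochberg adjustment; significant probes are classified
   hypermethylated (logFC > 0) or hypomethylated (logFC < 0),
4. genomic and replication-timing annotation of probe coordinates
   against BED-like interval files,
5. per-feature enrichment-bias statistics (delegated to
   :mod:`degronscreen.setstats`).

The default differential engine is a moderated two-sample t-test on
M-values: per-probe variances are shrunk toward a common prior fitted
across the array by empirical Bayes, which restores power at the
2-3 replicates typical of array designs.  The engine is pluggable
(the classification rule — direction by sign of the M-scale logFC,
significance by adjusted p ≤ α — is the fixed part, the per-probe
p-value machinery is not); a plain Welch t-test is available as
``engine="welch"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .setstats import EnrichmentBiasResult, enrichment_stats

logger = logging.getLogger("degronscreen")

BETA_EPSILON = 1e-6  # clamp before logit; β of exactly 0 or 1 is saturated signal

#: Single-label assignment order when a probe falls in several features.
FEATURE_PRIORITY = ["promoter-TSS", "TTS", "exon", "intron", "intergenic"]


# ---------------------------------------------------------------------------
# QC and transforms
# ---------------------------------------------------------------------------

def qc_filter(
    beta: pd.DataFrame, detection_p: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Keep probes whose detection p ≤ threshold in *every* sample.

    ``beta`` and ``detection_p`` are probe × sample frames sharing an
    index; a probe failing in any one sample is excluded.
    """
    if detection_p is None:
        raise ValueError("detection p-values required for QC filtering")
    missing = beta.index.difference(detection_p.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes lack detection p-values")
    ok = (detection_p.loc[beta.index] <= p_threshold).all(axis=1)
    removed = int((~ok).sum())
    if removed:
        logger.info("QC: removed %d/%d probes (detection p > %g in >=1 sample)",
                    removed, len(beta), p_threshold)
    return beta.loc[ok]


def beta_to_m(beta, epsilon: float = BETA_EPSILON):
    """Logit transform β to M: M = log2(β′/(1−β′)), β′ clamped to [ε, 1−ε]."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if arr.shape else float(m)


def m_to_beta(m):
    """Inverse logit: β = 2^M / (2^M + 1)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta if arr.shape else float(beta)


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------

def _welch_p(test: np.ndarray, ref: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(test, ref, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration solving psi'(x) = y for x > 0
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _moderated_p(test: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Moderated two-sample t-test with empirical-Bayes variance shrinkage.

    Per-probe pooled variances are modelled as draws from a scaled-F
    prior fitted across the array (method of moments on log s²); each
    probe's variance is shrunk toward the prior and the prior degrees
    of freedom are added to the residual ones, restoring power at few
    replicates per group.
    """
    n1, n2 = test.shape[1], ref.shape[1]
    df = n1 + n2 - 2
    delta = test.mean(axis=1) - ref.mean(axis=1)
    s2 = (test.var(axis=1, ddof=1) * (n1 - 1) + ref.var(axis=1, ddof=1) * (n2 - 1)) / df
    positive = s2 > 0
    if positive.sum() < 2:
        return _welch_p(test, ref)
    z = np.log(s2[positive])
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess > 1e-8:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0_sq = (
            float(np.mean(z))
            - float(special.digamma(df / 2.0))
            + float(special.digamma(d0 / 2.0))
            - np.log(d0 / df)
        )
        s2_post = (d0 * np.exp(log_s0_sq) + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        # log-variances no more dispersed than chi-square sampling noise:
        # the probes share one variance, so pool completely
        s2_post = np.full_like(s2, float(np.mean(s2[positive])))
        df_total = df * int(positive.sum())
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.where(np.isfinite(p), p, np.nan)


ENGINES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "moderated": _moderated_p,
    "welch": _welch_p,
    "student": lambda t, r: np.asarray(stats.ttest_ind(t, r, axis=1).pvalue),
}


def differential_test(
    m_values: pd.DataFrame,
    group_labels: dict[str, str] | pd.Series,
    test_group: str,
    ref_group: str,
    alpha: float = 0.05,
    engine: str | Callable[[np.ndarray, np.ndarray], np.ndarray] = "moderated",
) -> pd.DataFrame:
    """Per-probe differential methylation calls on the M scale.

    Returns a frame indexed by probe_id with columns ``logFC`` (mean M
    of the test group minus the reference group), ``p_value``, ``adj_p``
    (Benjamini–Hochberg over all tested probes), ``significant``
    (adj_p ≤ alpha) and ``direction`` (hyper / hypo / none).

    Probes that are constant across all samples get p = 1.
    """
    labels = pd.Series(group_labels)
    test_samples = labels.index[labels == test_group].tolist()
    ref_samples = labels.index[labels == ref_group].tolist()
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(test_samples) & set(ref_samples)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
    t = m_values[test_samples].to_numpy(dtype=float)
    r = m_values[ref_samples].to_numpy(dtype=float)
    logfc = t.mean(axis=1) - r.mean(axis=1)
    fn = ENGINES[engine] if isinstance(engine, str) else engine
    with np.errstate(invalid="ignore", divide="ignore"):
        p = fn(t, r)
    # zero within-group variance with equal means -> undefined t -> null call
    p = np.where(np.isnan(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    sig = adj <= alpha
    direction = np.where(~sig, "none", np.where(logfc > 0, "hyper", "hypo"))
    # significant probes with logFC exactly 0 have no direction
    direction = np.where(sig & (logfc == 0), "none", direction)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": p,
            "adj_p": adj,
            "significant": sig,
            "direction": direction,
        },
        index=m_values.index,
    )
    out.index.name = "probe_id"
    n_hyper = int((out["direction"] == "hyper").sum())
    n_hypo = int((out["direction"] == "hypo").sum())
    logger.info("differential: %d hyper, %d hypo of %d probes (alpha=%g)",
                n_hyper, n_hypo, len(out), alpha)
    return out


def overlap_analysis(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    direction: str,
    denominator: str = "union",
) -> dict:
    """Overlap of significant probes (given direction) between two call sets.

    ``denominator`` chooses the reference for ``overlap_percent``:
    ``union`` (default), ``a`` or ``b``.
    """
    set_a = set(calls_a.index[calls_a["direction"] == direction])
    set_b = set(calls_b.index[calls_b["direction"] == direction])
    common = set_a & set_b
    union = set_a | set_b
    if denominator == "union":
        denom = len(union)
    elif denominator == "a":
        denom = len(set_a)
    elif denominator == "b":
        denom = len(set_b)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = 100.0 * len(common) / denom if denom else 0.0
    return {
        "common": sorted(common),
        "unique_to_a": sorted(set_a - set_b),
        "unique_to_b": sorted(set_b - set_a),
        "overlap_percent": pct,
    }


# ---------------------------------------------------------------------------
# Interval annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    genomic_feature: str
    rt_class: str  # early | late | unassigned


def load_bed(path: str | Path, value_column: bool = False) -> list[tuple]:
    """Read a BED-like file: chrom, start, end, name-or-value.

    Coordinates are half-open 0-based.  Malformed intervals
    (end ≤ start) are fatal with the offending line number.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval (end <= start)")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, float(label) if value_column else label))
    return rows


def _build_trees(intervals: Sequence[tuple]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for order, (chrom, start, end, label) in enumerate(intervals):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, (order, label))
    return trees


def _feature_rank(name: str) -> int:
    try:
        return FEATURE_PRIORITY.index(name)
    except ValueError:
        return len(FEATURE_PRIORITY)


def annotate_probes(
    probes: pd.DataFrame,
    feature_intervals: Sequence[tuple] | None,
    rt_intervals: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Assign one genomic feature and one replication-timing class per probe.

    ``probes`` needs columns probe_id, chrom, pos (1-based single-base
    positions, converted internally to half-open [pos−1, pos)).
    Feature conflicts resolve by :data:`FEATURE_PRIORITY` (ties by file
    order); probes outside every interval are ``intergenic``.  The RT
    class is ``early`` if the overlapping replication-timing value is
    > 0, ``late`` if < 0, and ``unassigned`` at exactly 0 or with no
    overlap (ties by file order).
    """
    feat_trees = _build_trees(feature_intervals or [])
    rt_trees = _build_trees(rt_intervals or [])
    features = []
    rt_classes = []
    for chrom, pos in zip(probes["chrom"], probes["pos"]):
        point = int(pos) - 1
        overlaps = feat_trees.get(chrom, IntervalTree())[point]
        if overlaps:
            best = min(overlaps, key=lambda iv: (_feature_rank(iv.data[1]), iv.data[0]))
            features.append(best.data[1])
        else:
            features.append("intergenic")
        rt_over = rt_trees.get(chrom, IntervalTree())[point]
        if rt_over:
            first = min(rt_over, key=lambda iv: iv.data[0])
            value = float(first.data[1])
            rt_classes.append("early" if value > 0 else "late" if value < 0 else "unassigned")
        else:
            rt_classes.append("unassigned")
    out = pd.DataFrame(
        {"genomic_feature": features, "rt_class": rt_classes},
        index=pd.Index(probes["probe_id"], name="probe_id"),
    )
    return out


# ---------------------------------------------------------------------------
# Feature enrichment
# ---------------------------------------------------------------------------

def feature_enrichment(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    feature: str,
    direction: str = "hyper",
    column: str = "genomic_feature",
) -> EnrichmentBiasResult:
    """Enrichment bias of significant calls (given direction) in a feature.

    ``q`` = significant probes of the chosen direction inside the
    feature, ``m`` = array probes in the feature, ``n`` = array probes
    outside it, ``k`` = all significant probes of the direction;
    statistics from :func:`degronscreen.setstats.enrichment_stats`.
    """
    if set(calls.index) != set(annotations.index):
        raise ValueError("calls and annotations must cover the same probe universe")
    ann = annotations.loc[calls.index, column]
    if feature not in set(ann):
        raise ValueError(f"feature {feature!r} absent from annotations")
    in_feature = ann == feature
    sig = calls["direction"] == direction
    q = int((sig & in_feature).sum())
    m = int(in_feature.sum())
    n = int((~in_feature).sum())
    k = int(sig.sum())
    if k == 0:
        raise ValueError(f"no significant probes with direction {direction!r}")
    return enrichment_stats(q, m, n, k)


def enrichment_table(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    direction: str,
    columns: Iterable[str] = ("genomic_feature", "rt_class"),
) -> pd.DataFrame:
    """Enrichment bias for every feature level in the given annotation columns."""
    rows = []
    for col in columns:
        for feature in sorted(annotations[col].unique()):
            r = feature_enrichment(calls, annotations, feature, direction, column=col)
            rows.append(
                {
                    "annotation": col,
                    "feature": feature,
                    "direction": direction,
                    "q": r.q,
                    "m": r.m,
                    "n": r.n,
                    "k": r.k,
                    "expected": r.e,
                    "bias_percent": r.bias_percent,
                    "p_hyper": r.p_hyper,
                }
            )
    return pd.DataFrame(rows)
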