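"""Candidate substrate derivation: motif evidence x transcription evidence.

A candidate APC/C substrate is a gene that is both degron-motif positive
(protein level) and periodically transcribed (mRNA level).  The two
evidence streams are keyed by canonical gene symbol — the only
identifier the protein scan and the transcriptome lists share — so the
intersection is a plain set intersection on symbols, with the motif
hits and vote counts carried along for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import MotifHit, ProteomeScan
from .periodicity import PeriodicGene

logger = logging.getLogger("degronscreen")


@dataclass
class CandidateSubstrate:
    gene_symbol: str
    protein_ids: list[str] = field(default_factory=list)
    motif_hits: list[MotifHit] = field(default_factory=list)
    votes: int = 0
    annotations: dict[str, str] = field(default_factory=dict)


def intersect_candidates(
    motif_positive: Iterable[str],
    periodic: Iterable[str] | Sequence[PeriodicGene],
    scan: ProteomeScan | None = None,
    votes: Mapping[str, int] | None = None,
) -> list[CandidateSubstrate]:
    """Exact intersection of the two gene sets, sorted by symbol.

    ``scan`` (if given) supplies per-gene hits and supporting protein
    ids; ``votes`` (or PeriodicGene inputs) supply vote counts.
    """
    periodic = list(periodic)
    if periodic and isinstance(periodic[0], PeriodicGene):
        votes = {p.gene_symbol: p.votes for p in periodic}  # type: ignore[union-attr]
        periodic_set = set(votes)
    else:
        periodic_set = {str(g) for g in periodic}
    motif_set = {str(g) for g in motif_positive}
    common = sorted(motif_set & periodic_set)
    if not common:
        logger.warning("empty candidate intersection")
    hits_by_gene: dict[str, list[MotifHit]] = {}
    if scan is not None:
        gene_of = getattr(scan, "_gene_of", {})
        for h in scan.hits:
            g = gene_of.get(h.protein_id, h.protein_id)
            hits_by_gene.setdefault(g, []).append(h)
    out = []
    for g in common:
        hits = hits_by_gene.get(g, [])
        out.append(
            CandidateSubstrate(
                gene_symbol=g,
                protein_ids=sorted({h.protein_id for h in hits}),
                motif_hits=hits,
                votes=(votes or {}).get(g, 0),
            )
        )
    logger.info(
        "candidates: %d motif-positive x %d periodic -> %d candidates",
        len(motif_set),
        len(periodic_set),
        len(out),
    )
    return out


def annotate_candidates(
    candidates: Sequence[CandidateSubstrate], curation: pd.DataFrame
) -> list[CandidateSubstrate]:
    """Left-join curation annotations onto candidates by gene_symbol.

    Candidates without curation rows keep empty annotation fields;
    curation rows for non-candidate genes are ignored (count logged).
    """
    if curation.empty:
        return list(candidates)
    if "gene_symbol" not in curation.columns:
        raise ValueError("curation table must have a gene_symbol column")
    curation = curation.copy()
    curation["gene_symbol"] = curation["gene_symbol"].astype(str).str.upper()
    by_gene = {
        g: rows.iloc[0].drop("gene_symbol").to_dict()
        for g, rows in curation.groupby("gene_symbol")
    }
    cand_genes = {c.gene_symbol for c in candidates}
    unused = len(set(by_gene) - cand_genes)
    if unused:
        logger.info("ignored %d curation rows for non-candidate genes", unused)
    out = []
    for c in candidates:
        ann = {k: str(v) for k, v in by_gene.get(c.gene_symbol, {}).items()}
        out.append(
            CandidateSubstrate(
                c.gene_symbol, c.protein_ids, c.motif_hits, c.votes, ann
            )
        )
    return out


def candidates_to_frame(candidates: Sequence[CandidateSubstrate]) -> pd.DataFrame:
    """Candidate exchange table (one row per gene)."""
    ann_cols: list[str] = []
    for c in candidates:
        for k in c.annotations:
            if k not in ann_cols:
                ann_cols.append(k)
    rows = []
    for c in candidates:
        flanked = ";".join(
            f"{h.flank_left}[{h.matched}]{h.flank_right}" for h in c.motif_hits
        )
        row = {
            "gene_symbol": c.gene_symbol,
            "n_hits": len(c.motif_hits),
            "motif_positions": ";".join(
                f"{h.motif_name}:{h.start}-{h.end}" for h in c.motif_hits
            ),
            "flanked_motifs": flanked,
            "votes": c.votes,
        }
        for k in ann_cols:
            row[k] = c.annotations.get(k, "")
        rows.append(row)
    cols = ["gene_symbol", "n_hits", "motif_positions", "flanked_motifs", "votes"] + ann_cols
    return pd.DataFrame(rows, columns=cols)
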