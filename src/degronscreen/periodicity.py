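"""Cell-cycle periodicity voting across transcriptome studies.

A gene is called "periodic" when its mRNA abundance oscillates with the
cell cycle.  Individual profiling studies disagree substantially, so the
pipeline combines several published gene lists by a >=k-of-N vote
(default: at least 2 of 4 studies).  Identifiers are normalised through
a local alias table before voting so that studies using legacy symbols
(e.g. KIAA0101 for PCLAF) merge correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("degronscreen")


@dataclass(frozen=True)
class StudyCall:
    """One study's periodicity call for one (raw) gene symbol."""

    gene_symbol: str
    study_id: str
    periodic: bool = True


@dataclass(frozen=True)
class PeriodicGene:
    """A canonical gene symbol with its vote count out of ``n_studies``."""

    gene_symbol: str
    votes: int
    n_studies: int


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column raw->canonical alias TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"alias table {path} needs two columns")
    return {
        str(r).strip().upper(): str(c).strip().upper()
        for r, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def normalize_ids(
    raw_symbols: Iterable[str], alias_map: Mapping[str, str] | None = None
) -> tuple[list[str], list[str]]:
    """Uppercase, trim, and alias-map symbols.

    Returns (canonical symbols in input order, symbols that had no alias
    entry).  Unmapped symbols pass through unchanged (after case
    folding) rather than being dropped: downstream set operations on a
    partially-mapped list lose less than ones on a truncated list.
    """
    alias_map = alias_map or {}
    out: list[str] = []
    unmapped: list[str] = []
    for raw in raw_symbols:
        sym = str(raw).strip().upper()
        if sym in alias_map:
            out.append(alias_map[sym])
        else:
            out.append(sym)
            unmapped.append(sym)
    if alias_map and unmapped:
        logger.info(
            "identifier normalisation: %d/%d symbols had no alias entry",
            len(unmapped),
            len(out),
        )
    return out, unmapped


def load_study_list(path: str | Path) -> list[str]:
    """Read one study's periodic-gene list.

    Accepts a single-column file of symbols or a two-column (symbol,
    flag) file where truthy flags (1/true/yes) mark periodic genes.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 1:
        return [s.strip() for s in df.iloc[:, 0].astype(str)]
    truthy = {"1", "true", "yes", "periodic"}
    mask = df.iloc[:, 1].astype(str).str.strip().str.lower().isin(truthy)
    return [s.strip() for s in df.loc[mask].iloc[:, 0].astype(str)]


def vote_periodic(
    calls: Sequence[StudyCall],
    min_votes: int = 2,
    n_studies: int | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[PeriodicGene]:
    """Combine per-study calls into the periodic gene set.

    A gene's vote count is the number of *distinct* studies calling it
    periodic; duplicate (gene, study) rows collapse with a warning.
    Only genes with ``votes >= min_votes`` are returned, sorted by
    symbol.
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    voters: dict[str, set[str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    n_dup = 0
    study_ids: set[str] = set()
    for call in calls:
        study_ids.add(call.study_id)
        if not call.periodic:
            continue
        sym, _ = normalize_ids([call.gene_symbol], alias_map)
        key = (sym[0], call.study_id)
        if key in seen_pairs:
            n_dup += 1
            continue
        seen_pairs.add(key)
        voters.setdefault(sym[0], set()).add(call.study_id)
    if n_dup:
        logger.warning("collapsed %d duplicate (gene, study) rows", n_dup)
    roster = n_studies if n_studies is not None else len(study_ids)
    out = [
        PeriodicGene(g, len(s), roster)
        for g, s in voters.items()
        if len(s) >= min_votes
    ]
    out.sort(key=lambda p: p.gene_symbol)
    logger.info(
        "voting: %d genes with >=%d of %d study votes (from %d called genes)",
        len(out),
        min_votes,
        roster,
        len(voters),
    )
    return out


def vote_from_lists(
    study_lists: Mapping[str, Iterable[str]],
    min_votes: int = 2,
    alias_map: Mapping[str, str] | None = None,
) -> list[PeriodicGene]:
    """Voting convenience over {study_id: gene list} (list membership = call)."""
    calls = [
        StudyCall(g, sid)
        for sid, genes in study_lists.items()
        for g in genes
    ]
    return vote_periodic(calls, min_votes, n_studies=len(study_lists), alias_map=alias_map)


def periodic_to_frame(periodic: Sequence[PeriodicGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_symbol, p.votes, p.n_studies) for p in periodic],
        columns=["gene_symbol", "votes", "n_studies"],
    )
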