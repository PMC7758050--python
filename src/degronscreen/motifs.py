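"""Short linear degron motif scanning over protein sequences.

APC/C coactivators recognise substrates through short linear motifs
(SLiMs): the KEN-box (exact tripeptide K-E-N) and the minimal
destruction box (D-box, R-x-x-L, where ``x`` is any residue).  This
module reads a proteome from FASTA, locates every occurrence of such
motifs, and summarises hits at the gene level for downstream
intersection with cell-cycle transcription data.

Motif patterns are strings over the 20 standard amino-acid letters plus
the lowercase wildcard ``x`` which matches any residue.  The ambiguity
code ``X`` in a sequence matches only wildcard positions, never a fixed
pattern letter (a conservative call: an unknown residue is not evidence
for a degron).

Coordinates are 1-based inclusive throughout, matching the residue
numbering conventions of protein databases (a KEN-box "at amino acids
622-624" starts at residue 622 and ends at 624).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("degronscreen")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_FLANK = 10  # residues of context on each side of a hit

#: Canonical degron patterns by field name.
KNOWN_MOTIFS = {
    "KEN": "KEN",
    "Dbox": "RxxL",
}


class ProteomeError(ValueError):
    """Raised for unreadable or internally inconsistent proteome input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifiers.

    ``gene_symbol`` is the canonical uppercase symbol used as the join
    key across the pipeline; several isoform records may share it.
    """

    protein_id: str
    gene_symbol: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifSpec:
    """A degron pattern: fixed letters match themselves, ``x`` any residue."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"motif pattern {self.pattern!r} shorter than 3 residues")
        if not any(c != "x" for c in self.pattern):
            raise ValueError("motif pattern must contain at least one fixed residue")
        for c in self.pattern:
            if c != "x" and c not in AMINO_ACIDS:
                raise ValueError(f"invalid pattern character {c!r} in {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start``/``end`` are 1-based inclusive."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    matched: str
    flank_left: str = ""
    flank_right: str = ""


def parse_motif(expr: str, name: str | None = None) -> MotifSpec:
    """Build a :class:`MotifSpec` from a pattern expression.

    Accepts a bare pattern (``"KEN"``, ``"RxxL"``), a known motif name
    (``"Dbox"``), or a dash-separated form (``"R-x-x-L"``).
    """
    if expr in KNOWN_MOTIFS:
        return MotifSpec(expr, KNOWN_MOTIFS[expr])
    pattern = expr.replace("-", "")
    return MotifSpec(name or expr, pattern)


def _parse_header(header: str) -> tuple[str, str]:
    """Extract (protein_id, gene_symbol) from a FASTA description line.

    Supports ``>ID GENE=SYMBOL ...``, UniProt-style ``>sp|ID|NAME ...
    GN=SYMBOL``, and bare ``>ID`` (symbol falls back to the id).
    """
    tokens = header.split()
    first = tokens[0]
    if "|" in first:
        parts = first.split("|")
        protein_id = parts[1] if len(parts) >= 2 and parts[1] else first
    else:
        protein_id = first
    symbol = ""
    for tok in tokens[1:]:
        if tok.startswith("GENE=") or tok.startswith("GN="):
            symbol = tok.split("=", 1)[1]
            break
    if not symbol:
        symbol = protein_id
    return protein_id, symbol.upper()


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; non-amino-acid characters are replaced by
    ``X`` with a warning.  Duplicate protein ids and empty files are
    fatal.
    """
    path = Path(path)
    if not path.exists():
        raise ProteomeError(f"proteome file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_replaced = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        protein_id, symbol = _parse_header(entry.description)
        seq = str(entry.seq).upper()
        if not seq:
            logger.warning("skipping zero-length record %s", protein_id)
            continue
        cleaned = []
        for c in seq:
            if c in AMINO_ACIDS or c == "X":
                cleaned.append(c)
            else:
                cleaned.append("X")
                n_replaced += 1
        if protein_id in seen:
            raise ProteomeError(f"duplicate protein_id {protein_id!r} in {path}")
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id, symbol, "".join(cleaned)))
    if n_replaced:
        logger.warning("replaced %d non-amino-acid characters with X", n_replaced)
    if not records:
        raise ProteomeError(f"no records in {path}")
    return records


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    # X in the sequence never satisfies a fixed pattern letter
    for j, p in enumerate(pattern):
        c = seq[i + j]
        if p == "x":
            continue
        if c != p:
            return False
    return True


def scan_motif(protein: ProteinRecord, motif: MotifSpec) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``protein``, overlapping included.

    Hits are returned in ascending start order with 1-based inclusive
    coordinates.
    """
    seq = protein.sequence
    plen = len(motif.pattern)
    hits = []
    for i in range(len(seq) - plen + 1):
        if _matches_at(seq, motif.pattern, i):
            hits.append(
                MotifHit(
                    protein_id=protein.protein_id,
                    motif_name=motif.name,
                    start=i + 1,
                    end=i + plen,
                    matched=seq[i : i + plen],
                )
            )
    return hits


def extract_flanks(hit: MotifHit, protein: ProteinRecord, w: int = DEFAULT_FLANK) -> MotifHit:
    """Populate a hit's flanking context, clipped at sequence boundaries.

    ``flank_left`` holds up to ``w`` residues immediately preceding the
    hit, ``flank_right`` up to ``w`` residues following it; no padding.
    """
    if not (1 <= hit.start <= hit.end <= protein.length):
        raise ValueError(
            f"hit {hit.start}-{hit.end} outside protein {protein.protein_id} "
            f"of length {protein.length}"
        )
    left = protein.sequence[max(0, hit.start - 1 - w) : hit.start - 1]
    right = protein.sequence[hit.end : hit.end + w]
    return replace(hit, flank_left=left, flank_right=right)


@dataclass
class ProteomeScan:
    """Result of scanning a proteome: flat hit list plus gene summary."""

    hits: list[MotifHit]
    #: gene_symbol -> {motif_name: hit count summed over isoforms}
    gene_summary: dict[str, dict[str, int]]
    motif_names: list[str] = field(default_factory=list)

    def positive_genes(self, motif_name: str) -> set[str]:
        """Genes with at least one hit of the given motif (isoforms collapse)."""
        return {
            g for g, counts in self.gene_summary.items() if counts.get(motif_name, 0) > 0
        }

    def to_frame(self) -> pd.DataFrame:
        return hits_to_frame(self.hits)


def scan_proteome(
    proteins: Sequence[ProteinRecord],
    motifs: Iterable[MotifSpec],
    w: int = DEFAULT_FLANK,
) -> ProteomeScan:
    """Scan every protein for every motif and summarise per gene.

    A gene is motif-positive if any of its protein records (isoforms)
    carries at least one hit; hit counts in the summary are summed over
    isoforms.
    """
    if not proteins:
        raise ProteomeError("empty proteome")
    motifs = list(motifs)
    all_hits: list[MotifHit] = []
    summary: dict[str, dict[str, int]] = {}
    gene_of: dict[str, str] = {}
    for protein in proteins:
        gene_of[protein.protein_id] = protein.gene_symbol
        counts = summary.setdefault(protein.gene_symbol, {m.name: 0 for m in motifs})
        for motif in motifs:
            for hit in scan_motif(protein, motif):
                all_hits.append(extract_flanks(hit, protein, w))
                counts[motif.name] = counts.get(motif.name, 0) + 1
    scan = ProteomeScan(all_hits, summary, [m.name for m in motifs])
    scan._gene_of = gene_of  # type: ignore[attr-defined]
    for m in motifs:
        logger.info(
            "motif %s: %d hits, %d positive genes of %d",
            m.name,
            sum(c.get(m.name, 0) for c in summary.values()),
            len(scan.positive_genes(m.name)),
            len(summary),
        )
    return scan


def hits_to_frame(hits: Sequence[MotifHit], gene_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten hits into the tab-separated exchange table."""
    rows = [
        {
            "protein_id": h.protein_id,
            "gene_symbol": (gene_of or {}).get(h.protein_id, ""),
            "motif": h.motif_name,
            "start": h.start,
            "end": h.end,
            "matched": h.matched,
            "flank_left": h.flank_left,
            "flank_right": h.flank_right,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "gene_symbol",
            "motif",
            "start",
            "end",
            "matched",
            "flank_left",
            "flank_right",
        ],
    )


def write_hits(scan: ProteomeScan, path: str | Path) -> None:
    gene_of = getattr(scan, "_gene_of", {})
    hits_to_frame(scan.hits, gene_of).to_csv(path, sep="\t", index=False)
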