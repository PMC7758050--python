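"""Seeded synthetic-data generators with ground-truth manifests.

Every stage of the pipeline has a generator here that produces inputs
with the statistical structure the stage assumes, together with a
manifest recording every planted fact (motif placements, true periodic
genes, shifted probes, latent correlation).  Regeneration from the same
parameters and seed is bit-identical; no global random state is used.

The generators emulate structure, not biology: proteome backgrounds are
i.i.d. residues, methylation noise is Gaussian on the M scale, and
expression follows a single latent factor.  They exist so that
parameter-recovery tests have exact ground truth, not to imitate real
assay chemistry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import AMINO_ACIDS, ProteinRecord

# Default scales: sized so each generator runs in seconds on one CPU.
DEFAULT_N_PROTEINS = 2000
DEFAULT_PROTEIN_LENGTH = 500
DEFAULT_N_GENES = 1000
DEFAULT_N_PROBES = 5000
DEFAULT_N_SAMPLES = 500


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def uniform_residue_freqs() -> dict[str, float]:
    return {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def gen_proteome(
    n_proteins: int = DEFAULT_N_PROTEINS,
    length: int = DEFAULT_PROTEIN_LENGTH,
    residue_freqs: dict[str, float] | None = None,
    planted_motifs: Sequence[tuple[int, int, str]] = (),
    isoforms_per_gene: int = 1,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict]:
    """I.i.d.-residue proteins with motif strings planted at known positions.

    ``planted_motifs`` is a sequence of (protein_index, start, motif)
    with 0-based protein index and 1-based start; the motif string
    overwrites the background at that position.  Placements must fit
    inside the protein and not overlap within one protein.
    ``residue_freqs`` maps residues to background frequencies (uniform
    over the 20 standard letters by default; a residue's frequency may
    be 0 to make a motif impossible by chance).
    """
    freqs = residue_freqs or uniform_residue_freqs()
    letters = sorted(freqs)
    probs = np.array([freqs[c] for c in letters], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("residue frequencies must sum to 1")
    rng = _rng(seed)
    draws = rng.choice(len(letters), size=(n_proteins, length), p=probs)
    letter_arr = np.array(list(letters))
    records: list[ProteinRecord] = []
    seqs = ["".join(letter_arr[row]) for row in draws]
    occupied: dict[int, list[tuple[int, int]]] = {}
    for idx, start, motif in planted_motifs:
        if not (0 <= idx < n_proteins):
            raise ValueError(f"planted motif protein index {idx} out of range")
        end = start + len(motif) - 1
        if start < 1 or end > length:
            raise ValueError(f"planted motif at {start} exceeds protein length {length}")
        for s, e in occupied.get(idx, []):
            if not (end < s or start > e):
                raise ValueError(f"overlapping planted motifs in protein {idx}")
        occupied.setdefault(idx, []).append((start, end))
        seq = seqs[idx]
        seqs[idx] = seq[: start - 1] + motif + seq[end:]
    for i, seq in enumerate(seqs):
        gene = f"GENE{i // isoforms_per_gene:05d}"
        records.append(ProteinRecord(f"P{i:05d}", gene, seq))
    manifest = {
        "generator": "gen_proteome",
        "seed": seed,
        "n_proteins": n_proteins,
        "length": length,
        "isoforms_per_gene": isoforms_per_gene,
        "residue_freqs": freqs,
        "planted_motifs": [
            {
                "protein_id": records[idx].protein_id,
                "gene_symbol": records[idx].gene_symbol,
                "start": start,
                "end": start + len(motif) - 1,
                "motif": motif,
            }
            for idx, start, motif in planted_motifs
        ],
    }
    return records, manifest


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.protein_id} GENE={r.gene_symbol}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Periodicity studies
# ---------------------------------------------------------------------------

def gen_periodicity(
    n_genes: int = DEFAULT_N_GENES,
    true_set_size: int = 200,
    sensitivity: float = 0.8,
    fpr: float = 0.02,
    n_studies: int = 4,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict]:
    """Per-study periodic-gene lists with a planted true periodic set.

    Each study independently calls each truly periodic gene with
    probability ``sensitivity`` and every other gene with probability
    ``fpr``.
    """
    if true_set_size > n_genes:
        raise ValueError("true_set_size exceeds n_genes")
    if not (0 <= sensitivity <= 1 and 0 <= fpr <= 1):
        raise ValueError("sensitivity and fpr must lie in [0, 1]")
    rng = _rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    true_idx = rng.choice(n_genes, size=true_set_size, replace=False)
    is_true = np.zeros(n_genes, dtype=bool)
    is_true[true_idx] = True
    call_prob = np.where(is_true, sensitivity, fpr)
    studies: dict[str, list[str]] = {}
    for s in range(n_studies):
        called = rng.random(n_genes) < call_prob
        studies[f"study{s + 1}"] = [g for g, c in zip(genes, called) if c]
    manifest = {
        "generator": "gen_periodicity",
        "seed": seed,
        "n_genes": n_genes,
        "n_studies": n_studies,
        "sensitivity": sensitivity,
        "fpr": fpr,
        "true_periodic": sorted(genes[i] for i in true_idx),
    }
    return studies, manifest


# ---------------------------------------------------------------------------
# Gene-set pairs and the substrate benchmark
# ---------------------------------------------------------------------------

def gen_set_pair(
    universe_size: int,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int = 0,
    prefix: str = "GENE",
) -> tuple[list[str], set[str], set[str], dict]:
    """Two gene sets over a shared universe with an exact planted overlap."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds a set size")
    if size_a + size_b - overlap > universe_size:
        raise ValueError("sets do not fit in the universe")
    rng = _rng(seed)
    genes = [f"{prefix}{i:05d}" for i in range(universe_size)]
    picked = rng.choice(universe_size, size=size_a + size_b - overlap, replace=False)
    shared = picked[:overlap]
    only_a = picked[overlap:size_a]
    only_b = picked[size_a:]
    set_a = {genes[i] for i in np.concatenate([shared, only_a])}
    set_b = {genes[i] for i in np.concatenate([shared, only_b])}
    manifest = {
        "generator": "gen_set_pair",
        "seed": seed,
        "universe_size": universe_size,
        "overlap": sorted(genes[i] for i in shared),
    }
    return genes, set_a, set_b, manifest


def gen_substrate_benchmark(
    seed: int = 0,
    universe_size: int = 20263,
    motif_set_size: int = 2206,
    periodic_set_size: int = 651,
    candidate_overlap: int = 145,
    truth_large: int = 53,
    captured_large: int = 26,
    truth_small: int = 33,
    captured_small: int = 22,
    ipms_size: int = 100,
    union_captured_large: int = 31,
) -> dict:
    """Synthetic substrate-discovery benchmark with a planted funnel.

    A synthetic stand-in for curated substrate tables: gene sets over a
    shared universe constructed so that the degron-motif set and the
    periodic set overlap in exactly ``candidate_overlap`` genes, the
    candidates capture ``captured_large`` of the large truth set and
    ``captured_small`` of the small one, and the union of candidates
    with an affinity-proteomics (IP/MS) set captures
    ``union_captured_large`` of the large truth set.  The default sizes
    mirror a published substrate-discovery funnel so that recovery
    statistics computed on this benchmark land on a realistic scale.

    Returns a dict with keys ``universe``, ``motif_genes``,
    ``periodic_genes``, ``candidates_expected``, ``truth_large``,
    ``truth_small``, ``ipms_genes`` and a ``manifest``.
    """
    rng = _rng(seed)
    genes = np.array([f"GENE{i:05d}" for i in range(universe_size)])
    perm = rng.permutation(universe_size)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor : cursor + n]
        cursor += n
        return out

    shared = take(candidate_overlap)  # the planted candidates
    motif_only = take(motif_set_size - candidate_overlap)
    periodic_only = take(periodic_set_size - candidate_overlap)
    candidates = genes[shared]
    motif_genes = set(genes[shared]) | set(genes[motif_only])
    periodic_genes = set(genes[shared]) | set(genes[periodic_only])

    # large truth set: captured_large inside candidates, rest outside
    cap_large = rng.choice(shared, size=captured_large, replace=False)
    miss_large = take(truth_large - captured_large)
    truth_large_set = set(genes[cap_large]) | set(genes[miss_large])
    # small truth set: captured_small inside candidates, rest outside
    cap_small = rng.choice(shared, size=captured_small, replace=False)
    miss_small = take(truth_small - captured_small)
    truth_small_set = set(genes[cap_small]) | set(genes[miss_small])
    # IP/MS set: rescues exactly (union_captured_large - captured_large)
    # truth members the candidates missed; remainder away from the truth set
    n_rescue = union_captured_large - captured_large
    if n_rescue > len(miss_large):
        raise ValueError("union capture exceeds truth set size")
    rescue = rng.choice(miss_large, size=n_rescue, replace=False)
    filler = take(ipms_size - n_rescue)
    ipms = set(genes[rescue]) | set(genes[filler])

    return {
        "universe": [str(g) for g in genes],
        "motif_genes": {str(g) for g in motif_genes},
        "periodic_genes": {str(g) for g in periodic_genes},
        "candidates_expected": sorted(str(g) for g in candidates),
        "truth_large": {str(g) for g in truth_large_set},
        "truth_small": {str(g) for g in truth_small_set},
        "ipms_genes": {str(g) for g in ipms},
        "manifest": {
            "generator": "gen_substrate_benchmark",
            "seed": seed,
            "universe_size": universe_size,
            "planted": {
                "candidates": candidate_overlap,
                "captured_large": captured_large,
                "captured_small": captured_small,
                "union_captured_large": union_captured_large,
            },
        },
    }


# ---------------------------------------------------------------------------
# Methylation arrays
# ---------------------------------------------------------------------------

FEATURE_CYCLE = ["promoter-TSS", "exon", "intron", "TTS", "intergenic"]


def gen_beta(
    n_probes: int = DEFAULT_N_PROBES,
    group_sizes: tuple[int, int] = (3, 3),
    delta_m: float = 2.0,
    affected_feature: str = "exon",
    n_affected: int = 50,
    enrichment_ratio: float | None = None,
    noise: float = 0.5,
    block_size: int = 10_000,
    n_qc_fail: int = 0,
    detection_p_threshold: float = 0.05,
    seed: int = 0,
) -> dict:
    """β-value matrix with group-specific M-scale shifts planted in a feature.

    A single synthetic chromosome is tiled with fixed-size blocks
    cycling through genomic feature labels; replication-timing blocks
    alternate early (+) and late (−) values on a coarser grid.  Probes
    sit at distinct random positions.  Baseline probe M-values are
    Gaussian; every sample adds N(0, noise²) on the M scale; the test
    group adds ``delta_m`` at the affected probes.

    Affected probes are drawn entirely from ``affected_feature`` when
    ``enrichment_ratio`` is None; otherwise they are drawn from the
    whole array with in-feature probes weighted ``enrichment_ratio``
    times higher than the rest (3.0 emulates a 3× planted rate).
    ``n_qc_fail`` probes get one failing detection p-value each.

    Returns a dict with ``beta``, ``detection_p`` (probe × sample
    frames), ``probes`` (probe_id, chrom, pos), ``features`` and ``rt``
    (BED-like tuples), ``groups`` (sample -> label) and ``manifest``.
    """
    rng = _rng(seed)
    chrom = "chrS"
    chrom_len = max(block_size * len(FEATURE_CYCLE) * 4, n_probes * 40)
    n_blocks = chrom_len // block_size
    features = [
        (chrom, b * block_size, (b + 1) * block_size, FEATURE_CYCLE[b % len(FEATURE_CYCLE)])
        for b in range(n_blocks)
    ]
    rt_block = block_size * 3
    rt = []
    for b in range(chrom_len // rt_block):
        value = (1.0 if b % 2 == 0 else -1.0) * float(rng.uniform(0.2, 2.0))
        rt.append((chrom, b * rt_block, (b + 1) * rt_block, value))
    pos = np.sort(rng.choice(chrom_len, size=n_probes, replace=False)) + 1  # 1-based
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    feature_of = np.array(
        [FEATURE_CYCLE[((p - 1) // block_size) % len(FEATURE_CYCLE)] for p in pos]
    )
    in_feature = feature_of == affected_feature
    if enrichment_ratio is None:
        pool = np.flatnonzero(in_feature)
        if n_affected > len(pool):
            raise ValueError(
                f"n_affected={n_affected} exceeds capacity of {affected_feature} "
                f"({len(pool)} probes)"
            )
        affected = rng.choice(pool, size=n_affected, replace=False)
    else:
        weights = np.where(in_feature, enrichment_ratio, 1.0)
        weights = weights / weights.sum()
        affected = rng.choice(n_probes, size=n_affected, replace=False, p=weights)
    n_test, n_ref = group_sizes
    samples = [f"test{i + 1}" for i in range(n_test)] + [f"ref{i + 1}" for i in range(n_ref)]
    groups = {s: ("test" if s.startswith("test") else "ref") for s in samples}
    base_m = rng.normal(0.0, 2.0, size=n_probes)
    m = base_m[:, None] + rng.normal(0.0, noise, size=(n_probes, len(samples)))
    m[np.asarray(affected)[:, None], np.arange(n_test)[None, :]] += delta_m
    beta = 1.0 / (1.0 + np.exp2(-m))
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    det = pd.DataFrame(
        rng.uniform(0.0, detection_p_threshold * 0.5, size=(n_probes, len(samples))),
        index=beta_df.index,
        columns=samples,
    )
    fail_idx = rng.choice(n_probes, size=n_qc_fail, replace=False) if n_qc_fail else []
    for i in fail_idx:
        j = int(rng.integers(len(samples)))
        det.iloc[int(i), j] = detection_p_threshold * 2
    probes_df = pd.DataFrame({"probe_id": probe_ids, "chrom": chrom, "pos": pos})
    manifest = {
        "generator": "gen_beta",
        "seed": seed,
        "n_probes": n_probes,
        "delta_m": delta_m,
        "noise": noise,
        "affected_feature": affected_feature,
        "enrichment_ratio": enrichment_ratio,
        "affected_probes": sorted(probe_ids[int(i)] for i in affected),
        "qc_fail_probes": sorted(probe_ids[int(i)] for i in fail_idx),
        "probe_features": {pid: str(f) for pid, f in zip(probe_ids, feature_of)},
    }
    return {
        "beta": beta_df,
        "detection_p": det,
        "probes": probes_df,
        "features": features,
        "rt": rt,
        "groups": groups,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(
    n_genes: int = DEFAULT_N_GENES,
    n_samples: int = DEFAULT_N_SAMPLES,
    sig_a_size: int = 145,
    sig_b_size: int = 70,
    rho: float = 0.85,
    noise: float = 0.3,
    seed: int = 0,
) -> dict:
    """Expression matrix where two signatures share one latent factor.

    Per sample, latent factors f and g = ρf + √(1−ρ²)h (h independent)
    drive signature A and B genes respectively, so the two signature
    scores have population correlation ρ.  Values are emitted on the
    raw (2^log2) scale with per-gene baselines, ready for
    log2 + median-centering preprocessing.  Background genes carry
    noise only.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if sig_a_size + sig_b_size > n_genes:
        raise ValueError("signatures exceed gene count")
    rng = _rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    sig_a = genes[:sig_a_size]
    sig_b = genes[sig_a_size : sig_a_size + sig_b_size]
    f = rng.normal(size=n_samples)
    h = rng.normal(size=n_samples)
    g = rho * f + np.sqrt(max(0.0, 1.0 - rho**2)) * h
    baseline = rng.uniform(6.0, 10.0, size=n_genes)
    log2x = baseline[:, None] + rng.normal(0.0, noise, size=(n_genes, n_samples))
    log2x[:sig_a_size] += f[None, :]
    log2x[sig_a_size : sig_a_size + sig_b_size] += g[None, :]
    matrix = pd.DataFrame(
        np.exp2(log2x),
        index=pd.Index(genes, name="gene_symbol"),
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    manifest = {
        "generator": "gen_expression",
        "seed": seed,
        "rho": rho,
        "noise": noise,
        "sig_a": sig_a,
        "sig_b": sig_b,
    }
    return {"matrix": matrix, "sig_a": sig_a, "sig_b": sig_b, "manifest": manifest}


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
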