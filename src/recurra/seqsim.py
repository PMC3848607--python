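"""In-silico deep sequencing: error injection, filters, OTU clustering.

Deep 16S sequencing inflates OTU counts because rare per-base errors
generate novel unique sequences faster than clustering absorbs them.
This module reproduces that experiment at desk scale: draw reads from
reference sequences, substitute bases at a configurable rate, dereplicate,
optionally filter, and cluster greedily at a nucleotide-identity
threshold (default 97%).

The error model is substitution-only, so all reads share one length and
identity is 1 - hamming/L over the full read length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorSimConfig",
    "OtuClustering",
    "inject_errors",
    "dereplicate",
    "retention_filter",
    "contaminant_filter",
    "cluster_otus",
    "inflation_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Equal-length ACGT strings -> (n, L) uint8 array of ASCII codes."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
    joined = "".join(seqs).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(seqs), lengths.pop()).copy()


def decode_sequences(arr: np.ndarray) -> list[str]:
    return [row.tobytes().decode("ascii") for row in arr]


@dataclass
class ErrorSimConfig:
    """Configuration of one error-injection run.

    ``error_rate`` is the per-base substitution probability; each error
    replaces the base with one of the other three uniformly.  Reads are
    drawn from the references uniformly unless ``abundances`` is given.
    """

    references: SequenceSet
    read_length: int
    depth: int
    error_rate: float
    seed: int | np.random.Generator | None = None
    abundances: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error rate must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.references) == 0:
            raise ValueError("no reference sequences")
        short = [
            i for i, s in zip(self.references.ids, self.references.sequences)
            if len(s) < self.read_length
        ]
        if short:
            raise ValueError(f"references shorter than read length: {short}")


def inject_errors_array(cfg: ErrorSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: returns (reads as (depth, L) uint8, template indices)."""
    rng = np.random.default_rng(cfg.seed)
    refs = encode_sequences([s[: cfg.read_length] for s in cfg.references.sequences])
    if cfg.abundances is not None:
        p = np.asarray(cfg.abundances, dtype=float)
        p = p / p.sum()
    else:
        p = None
    templates = rng.choice(len(refs), size=cfg.depth, p=p)
    reads = refs[templates]
    if cfg.error_rate > 0:
        mask = rng.random(reads.shape) < cfg.error_rate
        n_err = int(mask.sum())
        if n_err:
            # shift each hit base by 1-3 positions in the ACGT alphabet
            base_idx = np.searchsorted(_BASES, reads[mask])
            shift = rng.integers(1, 4, size=n_err)
            reads[mask] = _BASES[(base_idx + shift) % 4]
    return reads, templates


def inject_errors(cfg: ErrorSimConfig) -> SequenceSet:
    """Draw ``depth`` reads from the references with per-base errors."""
    reads, templates = inject_errors_array(cfg)
    ids = [f"read{i:07d}" for i in range(cfg.depth)]
    return SequenceSet(ids, decode_sequences(reads))


def dereplicate(reads: SequenceSet) -> SequenceSet:
    """Collapse identical sequences at 100% identity, conserving counts."""
    arr = encode_sequences(reads.sequences)
    uniq, inverse, first = _unique_rows(arr)
    counts = np.bincount(inverse, weights=reads.counts.astype(float)).astype(np.int64)
    seqs = decode_sequences(uniq)
    ids = [f"uniq{i:06d}" for i in range(len(seqs))]
    return SequenceSet(ids, seqs, counts)


def _unique_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # void view makes row-unique a 1-D problem (much faster than axis=0)
    n, L = arr.shape
    packed = np.ascontiguousarray(arr).view(np.dtype((np.void, L))).ravel()
    _, first, inverse = np.unique(packed, return_index=True, return_inverse=True)
    return arr[first], inverse.ravel(), first


def dereplicate_by_sample(
    reads: SequenceSet,
) -> tuple[SequenceSet, pd.DataFrame]:
    """Dereplicate and tabulate per-sample counts (uniques x samples)."""
    if reads.sample_ids is None:
        raise ValueError("reads carry no sample ids")
    arr = encode_sequences(reads.sequences)
    uniq, inverse, _ = _unique_rows(arr)
    samples = sorted(set(reads.sample_ids))
    s_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(uniq), len(samples)), dtype=np.int64)
    cols = np.array([s_idx[s] for s in reads.sample_ids])
    np.add.at(counts, (inverse, cols), reads.counts)
    seqs = decode_sequences(uniq)
    ids = [f"uniq{i:06d}" for i in range(len(seqs))]
    table = pd.DataFrame(counts, index=ids, columns=samples)
    return SequenceSet(ids, seqs, counts.sum(axis=1)), table


def retention_filter(
    per_sample_counts: pd.DataFrame,
    min_samples: int = 2,
    min_total: int = 10,
) -> pd.DataFrame:
    """Keep reads present in >= ``min_samples`` samples with a combined
    count of >= ``min_total`` (both thresholds inclusive)."""
    n_samples = (per_sample_counts > 0).sum(axis=1)
    totals = per_sample_counts.sum(axis=1)
    keep = (n_samples >= min_samples) & (totals >= min_total)
    logger.info(
        "retention filter: kept %d of %d unique reads", int(keep.sum()), len(keep)
    )
    return per_sample_counts[keep]


def contaminant_filter(
    uniques: SequenceSet,
    contaminant_refs: SequenceSet,
    allowed_refs: SequenceSet,
) -> tuple[SequenceSet, float]:
    """Drop reads matching contaminant references but no allowed reference.

    A read is removed iff it occurs verbatim as a substring of any
    contaminant reference (e.g. human genomic DNA) AND occurs in no
    allowed reference (e.g. a ribosomal database).  Returns the filtered
    set and the removed fraction of total reads.
    """
    if len(contaminant_refs) == 0 or len(allowed_refs) == 0:
        raise ValueError("reference sets must be non-empty")
    sep = "N"
    contaminant_blob = sep.join(contaminant_refs.sequences)
    allowed_blob = sep.join(allowed_refs.sequences)
    keep_idx = []
    removed_reads = 0
    for i, seq in enumerate(uniques.sequences):
        in_contaminant = seq in contaminant_blob
        in_allowed = seq in allowed_blob
        if in_contaminant and not in_allowed:
            removed_reads += int(uniques.counts[i])
        else:
            keep_idx.append(i)
    total = uniques.total_reads()
    removed_fraction = removed_reads / total if total else 0.0
    logger.info(
        "contaminant filter: removed %.2f%% of reads", 100.0 * removed_fraction
    )
    filtered = SequenceSet(
        [uniques.ids[i] for i in keep_idx],
        [uniques.sequences[i] for i in keep_idx],
        uniques.counts[keep_idx],
    )
    return filtered, removed_fraction


@dataclass
class OtuClustering:
    """Result of greedy centroid clustering at an identity threshold."""

    threshold: float
    read_length: int
    centroid_sequences: list[str]
    assignments: np.ndarray         # cluster index per input unique
    member_counts: np.ndarray       # reads per cluster

    @property
    def n_otus(self) -> int:
        return len(self.centroid_sequences)

    def check_radius(self, sequences: Sequence[str]) -> bool:
        """Post-hoc invariant: every member within threshold of its centroid."""
        max_mm = int(np.floor((1.0 - self.threshold) * self.read_length + 1e-9))
        arr = encode_sequences(sequences)
        cents = encode_sequences(self.centroid_sequences)
        mism = (arr != cents[self.assignments]).sum(axis=1)
        return bool((mism <= max_mm).all())


def cluster_otus(uniques: SequenceSet, threshold: float = 0.97) -> OtuClustering:
    """Greedy abundance-ordered centroid clustering (uclust-style).

    Uniques are processed in decreasing abundance (ties broken
    lexicographically by sequence); each joins the first centroid, in
    creation order, with identity >= threshold (identity computed as
    1 - hamming/L over the full length), else opens a new centroid.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    arr = encode_sequences(uniques.sequences)
    n, L = arr.shape
    max_mm = int(np.floor((1.0 - threshold) * L + 1e-9))
    order = sorted(range(n), key=lambda i: (-int(uniques.counts[i]), uniques.sequences[i]))
    ordered = arr[order]
    # Equivalent batched form of per-unique greedy assignment: each not-yet
    # assigned unique (in order) opens a centroid and immediately claims every
    # later unassigned unique within the mismatch radius, i.e. every unique
    # joins the earliest-created centroid covering it.
    assign_ordered = np.full(n, -1, dtype=int)
    centroid_rows: list[int] = []
    for i in range(n):
        if assign_ordered[i] >= 0:
            continue
        c = len(centroid_rows)
        centroid_rows.append(i)
        assign_ordered[i] = c
        open_idx = np.nonzero(assign_ordered[i + 1:] < 0)[0] + i + 1
        if open_idx.size:
            mism = (ordered[open_idx] != ordered[i]).sum(axis=1)
            assign_ordered[open_idx[mism <= max_mm]] = c
    n_cent = len(centroid_rows)
    centroids = ordered[centroid_rows]
    assign = np.empty(n, dtype=int)
    assign[np.array(order)] = assign_ordered
    member_counts = np.zeros(n_cent, dtype=np.int64)
    np.add.at(member_counts, assign, uniques.counts)
    return OtuClustering(
        threshold=threshold,
        read_length=L,
        centroid_sequences=decode_sequences(centroids),
        assignments=assign,
        member_counts=member_counts,
    )


def inflation_experiment(
    references: SequenceSet,
    read_length: int,
    depths: Sequence[int],
    error_rates: Sequence[float],
    threshold: float = 0.97,
    seed: int = 0,
) -> pd.DataFrame:
    """OTU counts over an (error rate, depth) grid.

    Runs the full inject -> dereplicate -> cluster chain per grid cell
    and returns a table sorted by error rate then depth.  At zero error
    the OTU count equals the clustering of the references alone.
    """
    if not depths or not len(list(error_rates)):
        raise ValueError("empty grid")
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = [(e, d) for e in sorted(error_rates) for d in sorted(depths)]
    for (eps, depth), child in zip(cells, ss.spawn(len(cells))):
        cfg = ErrorSimConfig(
            references=references,
            read_length=read_length,
            depth=int(depth),
            error_rate=float(eps),
            seed=np.random.default_rng(child),
        )
        reads_arr, _ = inject_errors_array(cfg)
        uniq, inverse, _ = _unique_rows(reads_arr)
        counts = np.bincount(inverse).astype(np.int64)
        uniques = SequenceSet(
            [f"u{i:06d}" for i in range(len(uniq))],
            decode_sequences(uniq),
            counts,
        )
        clustering = cluster_otus(uniques, threshold=threshold)
        rows.append(
            {
                "error_rate": float(eps),
                "depth": int(depth),
                "n_unique": len(uniques),
                "n_otus": clustering.n_otus,
            }
        )
        logger.info(
            "inflation: eps=%g depth=%d -> %d uniques, %d OTUs",
            eps, depth, len(uniques), clustering.n_otus,
        )
    return pd.DataFrame(rows).sort_values(["error_rate", "depth"]).reset_index(drop=True)
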