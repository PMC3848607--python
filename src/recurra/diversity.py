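"""Alpha and beta diversity: weighted UniFrac, Chao1, Faith PD, rarefaction.

Weighted UniFrac compares two communities on a shared phylogeny: each
branch contributes its length times the absolute difference in the
fraction of each community's reads descending through it.  The
normalised variant divides by the abundance-weighted root-to-leaf depth
of both communities, bounding the distance in [0, 1].
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .data_model import CountTable, DistanceMatrix, PhyloTree

__all__ = [
    "weighted_unifrac",
    "unifrac_matrix",
    "chao1",
    "faith_pd",
    "rarefy_counts",
    "observed_richness",
    "expected_rarefied_richness",
]


def _leaf_proportions(tree: PhyloTree, counts: Mapping[str, int], label: str) -> np.ndarray:
    idx = tree.branch_index()
    taxa = [t for t, c in counts.items() if c > 0]
    vals = np.array([float(counts[t]) for t in taxa])
    if vals.sum() <= 0:
        raise ValueError(f"sample {label} has zero total count")
    try:
        pos = idx.leaf_positions(taxa)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    p = np.zeros(len(idx.leaf_names))
    p[pos] = vals / vals.sum()
    return p


def weighted_unifrac(
    tree: PhyloTree,
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two taxon->count communities.

    Raw value: sum over branches b of length(b) * |p_A(b) - p_B(b)|,
    where p_X(b) is the fraction of community X's reads on leaves below
    b.  Normalised value divides by sum over leaves j of
    depth(j) * (p_A(j) + p_B(j)).
    """
    idx = tree.branch_index()
    pa = _leaf_proportions(tree, counts_a, "A")
    pb = _leaf_proportions(tree, counts_b, "B")
    branch_pa = idx.membership @ pa
    branch_pb = idx.membership @ pb
    raw = float(idx.lengths @ np.abs(branch_pa - branch_pb))
    if not normalized:
        return raw
    denom = float(idx.depths @ (pa + pb))
    if denom == 0.0:
        return 0.0
    return raw / denom


def unifrac_matrix(
    tree: PhyloTree, table: CountTable, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over every sample pair in a count table.

    Vectorised: one samples-by-branches proportion matrix, then a
    branch-length-weighted L1 distance between its rows.
    """
    idx = tree.branch_index()
    taxa = table.taxon_ids
    pos = idx.leaf_positions(taxa)
    counts = table.df.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total samples: {bad}")
    n_leaves = len(idx.leaf_names)
    P = np.zeros((counts.shape[0], n_leaves))
    P[:, pos] = counts / totals[:, None]
    B = P @ idx.membership.T                      # samples x branches
    diffs = np.abs(B[:, None, :] - B[None, :, :])  # fine at cohort scale
    raw = diffs @ idx.lengths
    if normalized:
        depth_mass = P @ idx.depths               # per-sample weighted depth
        denom = depth_mass[:, None] + depth_mass[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(denom > 0, raw / denom, 0.0)
    np.fill_diagonal(raw, 0.0)
    return DistanceMatrix(table.sample_ids, raw, _validate=False)


def chao1(counts: Mapping[str, int] | np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from a single community's counts.

    Bias-corrected form S_obs + F1*(F1-1) / (2*(F2+1)) with F1/F2 the
    singleton/doubleton counts; the classic form F1^2/(2*F2) is kept
    behind ``bias_corrected=False`` and is undefined when F2 = 0.
    """
    vals = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts)
    if (vals < 0).any():
        raise ValueError("negative counts")
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("all-zero community")
    s_obs = float(vals.size)
    f1 = float((vals == 1).sum())
    f2 = float((vals == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined when there are no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def faith_pd(tree: PhyloTree, counts: Mapping[str, int]) -> float:
    """Faith phylogenetic diversity of the observed taxa.

    Total branch length of the minimal subtree connecting every observed
    leaf to the root (root-connecting branches included).  Empty
    observation sets score 0 by convention.
    """
    observed = [t for t, c in counts.items() if c > 0]
    if not observed:
        return 0.0
    idx = tree.branch_index()
    try:
        pos = idx.leaf_positions(observed)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    mask = np.zeros(len(idx.leaf_names), dtype=bool)
    mask[pos] = True
    used = idx.membership[:, mask].any(axis=1)
    return float(idx.lengths[used].sum())


def rarefy_counts(
    counts: Mapping[str, int], n: int, seed_or_rng
) -> dict[str, int]:
    """Subsample exactly ``n`` reads without replacement (one draw).

    Multivariate hypergeometric draw; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed_or_rng)
    taxa = list(counts.keys())
    vals = np.array([int(counts[t]) for t in taxa], dtype=np.int64)
    if (vals < 0).any():
        raise ValueError("negative counts")
    total = int(vals.sum())
    if n > total:
        raise ValueError(f"cannot draw {n} reads from a total of {total}")
    drawn = rng.multivariate_hypergeometric(vals, n)
    return {t: int(c) for t, c in zip(taxa, drawn)}


def observed_richness(counts: Mapping[str, int]) -> int:
    return sum(1 for c in counts.values() if c > 0)


def expected_rarefied_richness(counts: Mapping[str, int], n: int) -> float:
    """Analytic mean richness of a hypergeometric subsample of size n.

    E[S] = sum_i 1 - C(N - N_i, n) / C(N, n); used as the oracle for the
    single-draw rarefaction above.
    """
    from scipy.special import gammaln

    vals = np.array([c for c in counts.values() if c > 0], dtype=float)
    total = vals.sum()
    if n > total:
        raise ValueError("n exceeds total count")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_denom = log_comb(total, n)
    with np.errstate(invalid="ignore"):
        log_num = log_comb(total - vals, n)
    p_absent = np.where(total - vals >= n, np.exp(log_num - log_denom), 0.0)
    return float(np.sum(1.0 - p_absent))
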