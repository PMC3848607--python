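"""Group-level statistics on distances and taxon abundances.

Significance of distance differences uses a permutation (Monte-Carlo)
t-test: the Welch t statistic is recomputed under random relabelings of
the pooled values.  Small problems are enumerated exhaustively, so the
permutation p-value is exact there.  Per-taxon comparisons average
relative abundances within patient (per timepoint) before a Welch
two-sample t-test across patients.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountTable, DistanceMatrix, SampleMetadata
from .ordination import Ordination, collapse_to_centroids

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "mc_ttest",
    "welch_t",
    "distance_pool",
    "group_distance_summary",
    "taxon_group_comparison",
]


@dataclass
class GroupComparison:
    label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    replicates: int
    method: str = "permutation"


def welch_t(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Welch (unequal-variance) two-sample t statistic, vectorised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.shape[axis]
    ny = y.shape[axis]
    mx = x.mean(axis=axis)
    my = y.mean(axis=axis)
    vx = x.var(axis=axis, ddof=1)
    vy = y.var(axis=axis, ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mx - my) / denom


def _sem(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / np.sqrt(v.size))


def mc_ttest(
    x: Sequence[float],
    y: Sequence[float],
    reps: int = 1000,
    seed=None,
    label: str = "",
    method: str = "auto",
) -> GroupComparison:
    """Permutation two-sample t-test (Welch statistic under relabeling).

    ``method='auto'`` enumerates every label assignment when their number
    C(n, n_x) does not exceed ``reps`` (the p-value is then exact and
    includes the observed assignment); otherwise ``reps`` random
    relabelings are drawn and p = (1 + #extreme) / (reps + 1).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if pooled.var() == 0:
        raise ValueError("degenerate test: zero variance in pooled values")
    t_obs = float(welch_t(x, y))
    n, nx = pooled.size, x.size
    n_assign = comb(n, nx)
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = method == "exhaustive" or (method == "auto" and n_assign <= reps)
    tol = 1e-12
    if exhaustive:
        idx = np.array(list(itertools.combinations(range(n), nx)), dtype=int)
        xs = pooled[idx]                                    # (n_assign, nx)
        mask = np.ones((idx.shape[0], n), dtype=bool)
        rows = np.repeat(np.arange(idx.shape[0]), nx)
        mask[rows, idx.ravel()] = False
        ys = pooled[np.where(mask)[1]].reshape(idx.shape[0], n - nx)
        t_perm = welch_t(xs, ys)
        extreme = np.abs(t_perm) >= np.abs(t_obs) - tol
        p = float(extreme.sum()) / idx.shape[0]
        used = idx.shape[0]
        meth = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        # split sizes and pooled order are canonicalised (smaller group first,
        # values sorted) so p is invariant to swapping x and y
        k = min(nx, n - nx)
        canon = np.sort(pooled)
        order = np.argsort(rng.random((reps, n)), axis=1)
        perm = canon[order]
        t_perm = welch_t(perm[:, :k], perm[:, k:])
        extreme = np.abs(t_perm) >= np.abs(t_obs) - tol
        p = (1.0 + float(extreme.sum())) / (reps + 1.0)
        used = reps
        meth = "montecarlo"
    return GroupComparison(
        label=label,
        n_a=x.size,
        n_b=y.size,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        sem_a=_sem(x),
        sem_b=_sem(y),
        t=t_obs,
        p=p,
        replicates=used,
        method=meth,
    )


def distance_pool(
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    level: str,
    *,
    D: DistanceMatrix | None = None,
    ordn: Ordination | None = None,
    meta: SampleMetadata | None = None,
) -> np.ndarray:
    """Build a pool of distances for a labelled group comparison.

    level 'between-patient-centroids': samples are collapsed to one
    centroid per patient in ordination space; the pool is the pairwise
    centroid distances within the set (when the two id sets coincide) or
    across the two sets.

    level 'within-patient-pairs': for each patient with samples in both
    id sets, all cross pairwise distances are averaged to a single value
    (one number per individual enters the pool).
    """
    if level == "between-patient-centroids":
        if ordn is None or meta is None:
            raise ValueError("centroid level needs an ordination and metadata")
        sub_ids = sorted(set(ids_a) | set(ids_b))
        sub_meta = SampleMetadata(meta.df[meta.df["sample_id"].isin(sub_ids)])
        keep = [s for s in ordn.ids if s in set(sub_ids)]
        sub_ord = Ordination(
            keep,
            ordn.coords_for(keep),
            ordn.eigenvalues,
            ordn.proportion_explained,
            ordn.negative_fraction,
        )
        cents = collapse_to_centroids(sub_ord, sub_meta, key=("patient_id",))
        pat_of = meta.df.set_index("sample_id")["patient_id"]
        pats_a = sorted({pat_of[s] for s in ids_a})
        pats_b = sorted({pat_of[s] for s in ids_b})
        ca = np.array([cents.coords_for((p,)) for p in pats_a])
        cb = np.array([cents.coords_for((p,)) for p in pats_b])
        if pats_a == pats_b:
            iu = np.triu_indices(len(pats_a), k=1)
            diff = ca[:, None, :] - ca[None, :, :]
            return np.sqrt((diff ** 2).sum(-1))[iu]
        diff = ca[:, None, :] - cb[None, :, :]
        return np.sqrt((diff ** 2).sum(-1)).ravel()
    if level == "within-patient-pairs":
        if D is None or meta is None:
            raise ValueError("within-patient level needs a distance matrix and metadata")
        pat_of = meta.df.set_index("sample_id")["patient_id"]
        vals = []
        for pat in sorted(set(pat_of[s] for s in ids_a) & set(pat_of[s] for s in ids_b)):
            sa = [s for s in ids_a if pat_of[s] == pat]
            sb = [s for s in ids_b if pat_of[s] == pat]
            block = D.between(sa, sb)
            pairs = [
                block[i, j]
                for i in range(len(sa))
                for j in range(len(sb))
                if sa[i] != sb[j]
            ]
            if pairs:
                vals.append(float(np.mean(pairs)))
        return np.asarray(vals)
    raise ValueError(f"unknown comparison level {level!r}")


def group_distance_summary(
    comparisons: Sequence[tuple[str, np.ndarray, np.ndarray]],
    reps: int = 1000,
    seed: int = 0,
) -> list[GroupComparison]:
    """Permutation t-test for each labelled pair of distance pools."""
    out = []
    ss = np.random.SeedSequence(seed)
    for (label, pool_a, pool_b), child in zip(comparisons, ss.spawn(len(comparisons))):
        pool_a = np.asarray(pool_a, dtype=float)
        pool_b = np.asarray(pool_b, dtype=float)
        if pool_a.size < 2 or pool_b.size < 2:
            raise ValueError(f"comparison {label!r}: fewer than 2 units in a pool")
        out.append(mc_ttest(pool_a, pool_b, reps=reps, seed=child, label=label))
    return out


def taxon_group_comparison(
    table: CountTable,
    meta: SampleMetadata,
    patients_a: Sequence[str],
    patients_b: Sequence[str],
    timepoint: int,
) -> pd.DataFrame:
    """Per-taxon Welch t-test between two patient groups at one timepoint.

    Relative abundances are averaged per patient (over that patient's
    samples at the timepoint) so each patient contributes one value per
    taxon.  Raw p-values are primary; Benjamini-Hochberg q-values are
    reported alongside.
    """
    rel = table.relative_abundance()
    sub = meta.df[meta.df["timepoint"] == timepoint]

    def patient_means(patients):
        rows, kept = [], []
        for pat in patients:
            samples = sub.loc[sub["patient_id"] == pat, "sample_id"]
            samples = [s for s in samples if s in rel.index]
            if samples:
                rows.append(rel.loc[samples].mean(axis=0))
                kept.append(pat)
        return pd.DataFrame(rows, index=kept)

    ma = patient_means(patients_a)
    mb = patient_means(patients_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need >= 2 patients with samples in each group")
    present = (ma.sum(axis=0) + mb.sum(axis=0)) > 0
    skipped = [t for t, keep in present.items() if not keep]
    if skipped:
        logger.info("taxon comparison: skipping %d all-zero taxa", len(skipped))
    taxa = [t for t, keep in present.items() if keep]
    a = ma[taxa].to_numpy()
    b = mb[taxa].to_numpy()
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = _bh_adjust(pvals)
    return pd.DataFrame(
        {
            "taxon": taxa,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "t": np.asarray(res.statistic, dtype=float),
            "p": pvals,
            "q": qvals,
        }
    ).set_index("taxon")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
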