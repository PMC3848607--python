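"""Binned-likelihood recurrence prediction from UniFrac distances.

The predictive model is deliberately simple: pool the UniFrac distances
observed in patients who stayed in remission and in patients who
recurred, histogram each class in bins of width 0.1, and convert the two
per-bin frequencies into a per-bin probability of recurrence
P(rec | bin) = f_rec / (f_rec + f_rem).  A new patient's biopsies each
yield distances; each distance maps to its bin's probability and the
patient-level probability of recurrence is the arithmetic mean.
Validation is leave-one-patient-out: refit on the remaining patients,
predict the held-out one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import RECURRENCE, REMISSION, DistanceMatrix, SampleMetadata
from .ordination import Ordination, centroid_distance, collapse_to_centroids

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedLikelihoodModel",
    "PatientPrediction",
    "fit_binned_model",
    "predict_recurrence",
    "loocv",
    "single_biopsy_resampling",
    "combination_tests",
    "stability_through_time",
]

INDETERMINATE = "indeterminate"
_TIE_TOL = 1e-12

POOLS = ("surgical-controls", "all-controls", "through-time")


def patient_distance_pools(
    D: DistanceMatrix,
    meta: SampleMetadata,
    pool: str = "all-controls",
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Per-patient UniFrac distance pools feeding the binned model.

    'surgical-controls': each Crohn's surgical biopsy vs every surgical
    control biopsy.  'all-controls': vs every control biopsy regardless
    of procedure.  'through-time': all pairwise distances between a
    patient's surgical (timepoint 1) and post-operative (timepoint 2)
    biopsies.  Patients with unknown outcome are excluded.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}; choose from {POOLS}")
    df = meta.df
    outcomes = meta.outcomes()
    crohns_surg = df[
        (df["cohort"] == "crohns") & (df["timepoint"] == 1)
        & (df["procedure"] == "surgery")
    ]
    pools: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    sample_set = set(D.ids)
    for pat, rows in crohns_surg.groupby("patient_id"):
        pat = str(pat)
        if outcomes.get(pat) not in (REMISSION, RECURRENCE):
            continue
        surg_ids = [s for s in rows["sample_id"] if s in sample_set]
        if not surg_ids:
            continue
        if pool == "through-time":
            post = df[
                (df["patient_id"] == pat) & (df["timepoint"] == 2)
            ]["sample_id"]
            post_ids = [s for s in post if s in sample_set]
            if not post_ids:
                logger.info("pools: patient %s lacks timepoint-2 samples", pat)
                continue
            vals = D.between(surg_ids, post_ids).ravel()
        else:
            ctrl = df[df["cohort"] == "control"]
            if pool == "surgical-controls":
                ctrl = ctrl[ctrl["procedure"] == "surgery"]
            ctrl_ids = [s for s in ctrl["sample_id"] if s in sample_set]
            if not ctrl_ids:
                raise ValueError(f"no control samples for pool {pool!r}")
            vals = D.between(surg_ids, ctrl_ids).ravel()
        pools[pat] = np.asarray(vals, dtype=float)
        labels[pat] = outcomes[pat]
    return pools, labels


@dataclass
class BinnedLikelihoodModel:
    """Per-bin probability of recurrence over binned distances.

    ``p_recurrence[k]`` is NaN for bins empty in both classes
    (undefined); for every defined bin P(rec) + P(rem) = 1 by
    construction.  ``freq_*`` are class-normalised frequencies (each
    class sums to 1 over the bins), so unequal class sizes carry no
    weight; the raw-count pooling variant is kept behind a flag at fit
    time.
    """

    bin_width: float
    edges: np.ndarray               # n_bins + 1 edges, [0, ceiling]
    counts_remission: np.ndarray
    counts_recurrence: np.ndarray
    freq_remission: np.ndarray
    freq_recurrence: np.ndarray
    p_recurrence: np.ndarray        # NaN where undefined
    class_normalized: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, distance: float) -> int:
        """Half-open bins [k*w, (k+1)*w); values past the ceiling land in the last bin."""
        if distance < 0:
            raise ValueError(f"negative distance {distance}")
        k = int(np.floor(distance / self.bin_width + _TIE_TOL))
        return min(k, self.n_bins - 1)

    def prob_for(self, distance: float) -> float:
        """P(recurrence) for one distance; undefined bins fall back to 0.5."""
        p = self.p_recurrence[self.bin_of(distance)]
        return 0.5 if np.isnan(p) else float(p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.edges[:-1],
                "bin_high": self.edges[1:],
                "count_remission": self.counts_remission,
                "count_recurrence": self.counts_recurrence,
                "freq_remission": self.freq_remission,
                "freq_recurrence": self.freq_recurrence,
                "p_recurrence": self.p_recurrence,
            }
        )


@dataclass
class PatientPrediction:
    patient_id: str
    distances: np.ndarray
    probability: float              # averaged P(recurrence)
    predicted: str                  # remission / recurrence / indeterminate
    true_label: str | None = None
    note: str = ""

    @property
    def correct(self) -> bool | None:
        if self.true_label is None or self.predicted == INDETERMINATE:
            return None
        return self.predicted == self.true_label

    @property
    def winning_probability(self) -> float:
        """Probability assigned to the predicted outcome."""
        return max(self.probability, 1.0 - self.probability)


def fit_binned_model(
    dist_remission: Sequence[float],
    dist_recurrence: Sequence[float],
    bin_width: float = 0.1,
    class_normalized: bool = True,
) -> BinnedLikelihoodModel:
    """Fit the per-bin recurrence likelihood from two distance pools."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rem = np.asarray(list(dist_remission), dtype=float)
    rec = np.asarray(list(dist_recurrence), dtype=float)
    if rem.size == 0 or rec.size == 0:
        raise ValueError("both outcome classes need at least one distance")
    if (rem < 0).any() or (rec < 0).any():
        raise ValueError("distances must be non-negative")
    top = float(max(rem.max(), rec.max()))
    n_bins = max(1, int(np.floor(top / bin_width + _TIE_TOL)) + 1)
    edges = np.arange(n_bins + 1) * bin_width

    def hist(vals):
        idx = np.minimum(
            np.floor(vals / bin_width + _TIE_TOL).astype(int), n_bins - 1
        )
        return np.bincount(idx, minlength=n_bins).astype(float)

    c_rem, c_rec = hist(rem), hist(rec)
    f_rem = c_rem / c_rem.sum()
    f_rec = c_rec / c_rec.sum()
    num = f_rec if class_normalized else c_rec
    den = (f_rec + f_rem) if class_normalized else (c_rec + c_rem)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_rec = np.where(den > 0, num / den, np.nan)
    return BinnedLikelihoodModel(
        bin_width=bin_width,
        edges=edges,
        counts_remission=c_rem,
        counts_recurrence=c_rec,
        freq_remission=f_rem,
        freq_recurrence=f_rec,
        p_recurrence=p_rec,
        class_normalized=class_normalized,
    )


def predict_recurrence(
    model: BinnedLikelihoodModel,
    distances: Sequence[float],
    patient_id: str = "",
    true_label: str | None = None,
) -> PatientPrediction:
    """Average per-distance recurrence probabilities into one prediction."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("at least one distance is required")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    probs = np.array([model.prob_for(v) for v in d])
    prob = float(probs.mean())
    if abs(prob - 0.5) <= _TIE_TOL:
        predicted, note = INDETERMINATE, "tie at probability 0.5"
    elif prob > 0.5:
        predicted, note = RECURRENCE, ""
    else:
        predicted, note = REMISSION, ""
    return PatientPrediction(
        patient_id=patient_id,
        distances=d,
        probability=prob,
        predicted=predicted,
        true_label=true_label,
        note=note,
    )


def loocv(
    per_patient_distances: Mapping[str, Sequence[float]],
    labels: Mapping[str, str],
    bin_width: float = 0.1,
    class_normalized: bool = True,
) -> tuple[list[PatientPrediction], dict]:
    """Leave-one-patient-out cross-validation of the binned model.

    For each patient the model is refit on the aggregate distances of
    every other patient, then applied to the held-out patient's
    distances.  Returns the per-patient predictions and a summary with
    accuracy and the mean +/- s.d. of the winning-class probabilities.
    """
    patients = list(per_patient_distances)
    if set(patients) - set(labels):
        raise ValueError("every patient needs an outcome label")
    preds = []
    for held in patients:
        train_rem, train_rec = [], []
        for other in patients:
            if other == held:
                continue
            pool = train_rec if labels[other] == RECURRENCE else train_rem
            pool.extend(np.asarray(per_patient_distances[other], dtype=float))
        if not train_rem or not train_rec:
            raise ValueError(
                f"fold holding out {held!r} leaves an empty outcome class"
            )
        model = fit_binned_model(
            train_rem, train_rec, bin_width=bin_width, class_normalized=class_normalized
        )
        preds.append(
            predict_recurrence(
                model,
                per_patient_distances[held],
                patient_id=held,
                true_label=labels[held],
            )
        )
    decided = [p for p in preds if p.predicted != INDETERMINATE]
    n_correct = sum(1 for p in decided if p.correct)
    accuracy = n_correct / len(preds) if preds else float("nan")
    winners = np.array([p.winning_probability for p in preds])
    summary = {
        "n_patients": len(preds),
        "n_correct": n_correct,
        "n_indeterminate": len(preds) - len(decided),
        "accuracy": accuracy,
        "mean_confidence": float(winners.mean()),
        "sd_confidence": float(winners.std(ddof=1)) if winners.size > 1 else 0.0,
    }
    return preds, summary


def _welch_p_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values row-wise for (reps, n) arrays."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        df = se2 ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isnan(p), 1.0, p)


def single_biopsy_resampling(
    D: DistanceMatrix,
    crohns_biopsies: Mapping[str, Sequence[str]],
    labels: Mapping[str, str],
    control_ids: Sequence[str],
    reps: int = 10000,
    alpha: float = 0.05,
    seed=None,
) -> dict:
    """How often does a single biopsy per patient separate the outcomes?

    Each repetition draws one biopsy per Crohn's patient and, for each
    comparison, a different randomly chosen control biopsy; the UniFrac
    distances of the remission patients are compared with those of the
    recurrence patients by a Welch t-test.  Returns the fraction of
    repetitions significant at ``alpha``.
    """
    patients = list(crohns_biopsies)
    rem_idx = [i for i, p in enumerate(patients) if labels[p] == REMISSION]
    rec_idx = [i for i, p in enumerate(patients) if labels[p] == RECURRENCE]
    if len(rem_idx) < 2 or len(rec_idx) < 2:
        raise ValueError("need at least 2 patients per outcome class")
    controls = list(control_ids)
    if len(controls) < len(patients):
        raise ValueError("need at least one distinct control biopsy per patient")
    rng = np.random.default_rng(seed)
    # distance lookup: rows = all crohns biopsies, cols = controls
    all_biopsies = [b for p in patients for b in crohns_biopsies[p]]
    row_of = {b: i for i, b in enumerate(all_biopsies)}
    M = D.between(all_biopsies, controls)
    n_pat = len(patients)
    biopsy_rows = [
        np.array([row_of[b] for b in crohns_biopsies[p]]) for p in patients
    ]
    chosen_rows = np.column_stack(
        [rows[rng.integers(0, len(rows), size=reps)] for rows in biopsy_rows]
    )
    # distinct control per comparison within a repetition
    ctrl_cols = np.argsort(rng.random((reps, len(controls))), axis=1)[:, :n_pat]
    dists = M[chosen_rows, ctrl_cols]                     # (reps, n_pat)
    pvals = _welch_p_rows(dists[:, rem_idx], dists[:, rec_idx])
    frac = float((pvals < alpha).mean())
    return {
        "reps": reps,
        "alpha": alpha,
        "fraction_significant": frac,
        "p_values": pvals,
    }


def combination_tests(
    per_patient_coords: Mapping[str, np.ndarray],
    control_centroid: np.ndarray,
    labels: Mapping[str, str],
    alpha: float = 0.05,
) -> dict:
    """Exhaustively test every one-biopsy-per-patient selection.

    Each patient's surgical biopsies sit in ordination space; every
    combination chooses one biopsy per patient and compares the
    remission patients' distances to the control centroid against the
    recurrence patients' by a Welch t-test.  The number of combinations
    is the product of per-patient biopsy counts.
    """
    patients = list(per_patient_coords)
    control_centroid = np.asarray(control_centroid, dtype=float)
    per_patient_dists = []
    for p in patients:
        coords = np.atleast_2d(np.asarray(per_patient_coords[p], dtype=float))
        if coords.shape[1] != control_centroid.shape[0]:
            raise ValueError(f"coordinate dimension mismatch for patient {p!r}")
        per_patient_dists.append(
            np.sqrt(((coords - control_centroid) ** 2).sum(axis=1))
        )
    counts = [len(d) for d in per_patient_dists]
    n_comb = int(np.prod(counts))
    grid = np.array(
        list(itertools.product(*[range(c) for c in counts])), dtype=int
    )                                                     # (n_comb, n_pat)
    dists = np.column_stack(
        [per_patient_dists[j][grid[:, j]] for j in range(len(patients))]
    )
    rem_idx = [i for i, p in enumerate(patients) if labels[p] == REMISSION]
    rec_idx = [i for i, p in enumerate(patients) if labels[p] == RECURRENCE]
    if len(rem_idx) < 2 or len(rec_idx) < 2:
        raise ValueError("need at least 2 patients per outcome class")
    pvals = _welch_p_rows(dists[:, rem_idx], dists[:, rec_idx])
    return {
        "n_combinations": n_comb,
        "alpha": alpha,
        "fraction_significant": float((pvals < alpha).mean()),
        "p_values": pvals,
    }


def stability_through_time(
    meta: SampleMetadata,
    ordn: Ordination | None = None,
    D: DistanceMatrix | None = None,
    mode: str = "through-time",
) -> dict[str, float]:
    """Per-patient instability score.

    mode 'through-time': Euclidean distance between the centroid of a
    patient's timepoint-1 (surgical) biopsies and the centroid of the
    timepoint-2 (post-operative) biopsies, in ordination space.

    mode 'within-surgery': mean of all pairwise distances among the
    patient's surgical biopsies (consistency at a single timepoint).
    """
    out: dict[str, float] = {}
    if mode == "through-time":
        if ordn is None:
            raise ValueError("through-time mode needs an ordination")
        cents = collapse_to_centroids(ordn, meta, key=("patient_id", "timepoint"))
        by_patient: dict[str, dict[int, np.ndarray]] = {}
        for key, coord in zip(cents.keys, cents.coordinates):
            pat, tp = key
            by_patient.setdefault(pat, {})[int(tp)] = coord
        for pat, tps in sorted(by_patient.items()):
            if 1 in tps and 2 in tps:
                out[pat] = centroid_distance(tps[1], tps[2])
            else:
                logger.info("stability: patient %s lacks a timepoint, skipped", pat)
        return out
    if mode == "within-surgery":
        if D is None:
            raise ValueError("within-surgery mode needs a distance matrix")
        surg = meta.df[(meta.df["timepoint"] == 1)]
        for pat, rows in surg.groupby("patient_id"):
            ids = [s for s in rows["sample_id"] if s in set(D.ids)]
            if len(ids) < 2:
                logger.info("stability: patient %s has < 2 surgical samples, skipped", pat)
                continue
            out[str(pat)] = float(D.submatrix(ids).condensed().mean())
        return out
    raise ValueError(f"unknown mode {mode!r}")
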