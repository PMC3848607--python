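"""Synthetic cohort generator: trees, count tables, metadata, reads.

The cohort design being emulated: Crohn's patients undergoing ileocolic
resection are biopsied at surgery (timepoint 1) and at the first
post-operative colonoscopy (timepoint 2), where a Rutgeerts score labels
them remission (0-1) or recurrence (2-4); control patients contribute
biopsies at one procedure.  The generator plants the three structural
features the analysis is sensitive to:

* controls cluster tightly (small patient dispersion),
* Crohn's patients are dispersed, with recurrence patients additionally
  offset from the control centroid along a fixed direction,
* recurrence patients drift more between the two timepoints.

Mechanically each patient has a latent log-abundance vector
(baseline + group offset + patient noise); biopsies are multinomial
draws at a fixed depth from the softmax of that vector plus small
biopsy-level noise.  This is a harness for the analysis, not a model of
16S data generation: no chimeras, no batch effects, no sequence
evolution along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CountTable, PhyloTree, SampleMetadata, SequenceSet, parse_newick

__all__ = [
    "CohortSimConfig",
    "simulate_tree",
    "simulate_cohort",
    "simulate_reference_sequences",
    "simulate_reads",
]


@dataclass
class CohortSimConfig:
    """Defaults match the emulated cohort scale: 6 Crohn's surgical
    patients (3 remission / 3 recurrence) with biopsies at two
    timepoints, and a pool of control patients split between surgery
    and colonoscopy."""

    n_taxa: int = 64
    n_control_surgery: int = 4
    n_control_colonoscopy: int = 4
    n_remission: int = 3
    n_recurrence: int = 3
    biopsies_per_timepoint: int = 3
    depth: int = 2000
    sigma_control: float = 0.3       # patient-level log-abundance s.d.
    sigma_crohns: float = 0.6
    delta: float = 20.0              # recurrence offset from control centroid
    tau_remission: float = 0.3       # temporal drift s.d., timepoint 1 -> 2
    tau_recurrence: float = 1.5
    sigma_biopsy: float = 0.1        # biopsy-level log-abundance s.d.
    baseline_sd: float = 1.0
    per_patient_direction: bool = False

    def __post_init__(self):
        for name in ("sigma_control", "sigma_crohns", "tau_remission",
                     "tau_recurrence", "sigma_biopsy", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.biopsies_per_timepoint < 1:
            raise ValueError("biopsies_per_timepoint must be >= 1")


def simulate_tree(n_taxa: int, seed) -> PhyloTree:
    """Random bifurcating tree by sequential random joins.

    Branch lengths are i.i.d. exponential with mean 0.1 substitutions
    per site; leaves are named t0001, t0002, ...
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    subtrees = [f"t{i + 1:04d}" for i in range(n_taxa)]

    def edge() -> float:
        return float(rng.exponential(0.1))

    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a}:{edge():.6f},{b}:{edge():.6f})")
    return parse_newick(subtrees[0] + ";")


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def simulate_cohort(
    cfg: CohortSimConfig, tree: PhyloTree, seed
) -> tuple[CountTable, SampleMetadata]:
    """Generate counts and metadata for one synthetic cohort."""
    taxa = tree.leaf_names
    if len(taxa) != cfg.n_taxa:
        raise ValueError(
            f"tree has {len(taxa)} leaves but config expects {cfg.n_taxa} taxa"
        )
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_taxa)
    direction = rng.normal(size=cfg.n_taxa)
    direction /= np.linalg.norm(direction)

    sites = ["ileum", "colon"]
    counts_rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add_biopsies(sample_prefix, latent, patient, cohort, procedure, timepoint,
                     inflamed_first, rutgeerts):
        for b in range(cfg.biopsies_per_timepoint):
            noisy = latent + rng.normal(0.0, cfg.sigma_biopsy, size=cfg.n_taxa)
            probs = _softmax(noisy)
            counts = rng.multinomial(cfg.depth, probs)
            sid = f"{sample_prefix}.b{b + 1}"
            counts_rows[sid] = counts
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "cohort": cohort,
                    "procedure": procedure,
                    "timepoint": timepoint,
                    "site": sites[b % 2],
                    "inflamed": inflamed_first and b == 0,
                    "rutgeerts": rutgeerts,
                }
            )

    # controls: one procedure each, timepoint 1
    ctrl_specs = ["surgery"] * cfg.n_control_surgery + [
        "colonoscopy"
    ] * cfg.n_control_colonoscopy
    for k, procedure in enumerate(ctrl_specs):
        patient = f"ctrl{k + 1:02d}"
        latent = baseline + rng.normal(0.0, cfg.sigma_control, size=cfg.n_taxa)
        add_biopsies(f"{patient}.t1", latent, patient, "control", procedure, 1,
                     False, pd.NA)

    # Crohn's surgical patients: surgery (t1) + post-op colonoscopy (t2)
    crohn_specs = [("rem", i, "remission") for i in range(cfg.n_remission)] + [
        ("rec", i, "recurrence") for i in range(cfg.n_recurrence)
    ]
    for tag, i, outcome in crohn_specs:
        patient = f"{tag}{i + 1:02d}"
        u = direction
        if cfg.per_patient_direction:
            u = rng.normal(size=cfg.n_taxa)
            u /= np.linalg.norm(u)
        offset = cfg.delta * u if outcome == "recurrence" else 0.0
        latent1 = baseline + offset + rng.normal(
            0.0, cfg.sigma_crohns, size=cfg.n_taxa
        )
        tau = cfg.tau_recurrence if outcome == "recurrence" else cfg.tau_remission
        latent2 = latent1 + rng.normal(0.0, tau, size=cfg.n_taxa)
        score = int(rng.integers(2, 4)) if outcome == "recurrence" else int(
            rng.integers(0, 2)
        )
        add_biopsies(f"{patient}.t1", latent1, patient, "crohns", "surgery", 1,
                     True, pd.NA)
        add_biopsies(f"{patient}.t2", latent2, patient, "crohns", "colonoscopy", 2,
                     False, score)

    table = CountTable(
        pd.DataFrame.from_dict(counts_rows, orient="index", columns=taxa)
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return table, meta


def simulate_reference_sequences(
    taxon_ids, length: int, seed
) -> SequenceSet:
    """One random ACGT reference sequence per taxon."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = [
        bases[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for _ in taxon_ids
    ]
    return SequenceSet(list(taxon_ids), seqs)


def simulate_reads(
    community: Mapping[str, int],
    taxon_seqs: SequenceSet,
    read_length: int,
    depth: int,
    seed,
) -> SequenceSet:
    """Sample reads proportionally to community counts, truncated to L."""
    rng = np.random.default_rng(seed)
    taxa = [t for t, c in community.items() if c > 0]
    missing = [t for t in taxa if t not in set(taxon_seqs.ids)]
    if missing:
        raise ValueError(f"no reference sequence for taxa: {missing}")
    seq_of = dict(zip(taxon_seqs.ids, taxon_seqs.sequences))
    short = [t for t in taxa if len(seq_of[t]) < read_length]
    if short:
        raise ValueError(f"reference shorter than read length: {short}")
    if depth == 0:
        return SequenceSet([], [], np.array([], dtype=np.int64))
    weights = np.array([community[t] for t in taxa], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(taxa), size=depth, p=weights)
    seqs = [seq_of[taxa[k]][:read_length] for k in picks]
    ids = [f"read{i:07d}" for i in range(depth)]
    return SequenceSet(ids, seqs, sample_ids=None)
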