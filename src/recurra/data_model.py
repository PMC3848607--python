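"""Domain types and on-disk formats for the cohort analysis.

The analysis joins four artifacts on sample identifiers: a rooted
phylogeny of the observed taxa, a sample-by-taxon count table, per-sample
clinical metadata, and (downstream) distance matrices.  All of them are
plain text: newick for trees, TSV for tables and matrices, FASTA for
sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

__all__ = [
    "PhyloTree",
    "CountTable",
    "SampleMetadata",
    "DistanceMatrix",
    "SequenceSet",
    "parse_newick",
    "load_count_table",
    "derive_outcome",
    "COHORTS",
    "PROCEDURES",
    "SITES",
    "REMISSION",
    "RECURRENCE",
    "UNKNOWN",
]

COHORTS = frozenset({"crohns", "control"})
PROCEDURES = frozenset({"surgery", "colonoscopy"})
SITES = frozenset({"ileum", "colon", "stool"})

REMISSION = "remission"
RECURRENCE = "recurrence"
UNKNOWN = "unknown"


class PhyloTree:
    """Rooted phylogenetic tree with non-negative branch lengths.

    Thin wrapper around :class:`skbio.TreeNode` that enforces the
    invariants the diversity metrics rely on (unique leaf names,
    non-negative lengths, single root) and precomputes an indexed branch
    table for vectorised UniFrac / Faith PD.
    """

    def __init__(self, root: TreeNode):
        self._root = root
        self._validate()
        self._index = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            root = TreeNode.read(io.StringIO(text), format="newick")
        except Exception as exc:  # skbio raises format-specific errors
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(root)

    def _validate(self) -> None:
        names = [t.name for t in self._root.tips()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")
        if self._root.length is None:
            self._root.length = 0.0
        for node in self._root.traverse(include_self=False):
            if node.length is None:
                raise ValueError(
                    f"missing branch length on node {node.name!r}"
                )
            if node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} on node {node.name!r}"
                )

    # -- basic queries -------------------------------------------------

    @property
    def root(self) -> TreeNode:
        return self._root

    @property
    def leaf_names(self) -> list[str]:
        return list(self.branch_index().leaf_names)

    @property
    def n_leaves(self) -> int:
        return len(self.branch_index().leaf_names)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_index().lengths.sum())

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._root.write(buf, format="newick")
        return buf.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- branch table --------------------------------------------------

    def branch_index(self) -> "BranchIndex":
        """Indexed view of every non-root branch (lazy, cached)."""
        if self._index is None:
            self._index = BranchIndex.build(self._root)
        return self._index


@dataclass(frozen=True)
class BranchIndex:
    """Arrays describing the non-root branches of a tree.

    ``membership[b, j]`` is True when leaf *j* descends through branch
    *b*; ``depths[j]`` is the root-to-leaf path length.  Both UniFrac and
    Faith PD are linear scans over this table.
    """

    leaf_names: tuple[str, ...]
    lengths: np.ndarray          # (n_branches,)
    membership: np.ndarray       # (n_branches, n_leaves) bool
    depths: np.ndarray           # (n_leaves,)

    @classmethod
    def build(cls, root: TreeNode) -> "BranchIndex":
        leaves = list(root.tips())
        leaf_names = tuple(t.name for t in leaves)
        leaf_pos = {id(t): j for j, t in enumerate(leaves)}
        nodes = [n for n in root.postorder(include_self=False)]
        n_b, n_l = len(nodes), len(leaves)
        lengths = np.array([n.length for n in nodes], dtype=float)
        membership = np.zeros((n_b, n_l), dtype=bool)
        node_row = {id(n): b for b, n in enumerate(nodes)}
        for b, node in enumerate(nodes):
            if node.is_tip():
                membership[b, leaf_pos[id(node)]] = True
            else:
                for child in node.children:
                    membership[b] |= membership[node_row[id(child)]]
        depths = membership.T.astype(float) @ lengths
        return cls(leaf_names, lengths, membership, depths)

    def leaf_positions(self, taxa: Iterable[str]) -> np.ndarray:
        pos = {n: j for j, n in enumerate(self.leaf_names)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise KeyError(f"taxa absent from tree: {sorted(missing)}")
        return np.array([pos[t] for t in taxa], dtype=int)


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a validated :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


class CountTable:
    """Samples-by-taxa table of non-negative integer counts.

    Stored as a pandas DataFrame with sample ids on the index and taxon
    ids on the columns.  The on-disk layout is transposed (taxa as rows,
    one column per sample), the common format for OTU tables.
    """

    def __init__(self, counts: pd.DataFrame, require_nonzero_samples: bool = True):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts are not allowed")
        if require_nonzero_samples and (arr.sum(axis=1) == 0).any():
            empty = counts.index[arr.sum(axis=1) == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        self.df = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def counts_for(self, sample_id: str) -> pd.Series:
        return self.df.loc[sample_id]

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.df.sum(axis=1)
        return self.df.div(totals, axis=0)

    def total(self) -> int:
        return int(self.df.to_numpy().sum())

    def to_tsv(self, path) -> None:
        out = self.df.T
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    def subset(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.df.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)


def load_count_table(path) -> CountTable:
    """Read a taxa-by-samples TSV (first column taxon ids) into a CountTable."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids in header: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric counts in column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer counts in column {col!r}")
        if (vals < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    return CountTable(df.T.astype(np.int64))


_META_COLUMNS = [
    "sample_id",
    "patient_id",
    "cohort",
    "procedure",
    "timepoint",
    "site",
    "inflamed",
    "rutgeerts",
]


class SampleMetadata:
    """Clinical annotations, one row per sample.

    Vocabulary is closed: unknown cohort/procedure/site tokens are
    errors, so that synthetic and real runs cannot silently diverge.
    The Rutgeerts score (0-4, graded at post-operative colonoscopy;
    0-1 remission, 2-4 recurrence) may only be present for Crohn's
    patients with a colonoscopy timepoint.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _META_COLUMNS if c not in df.columns and c != "rutgeerts"]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if "rutgeerts" not in df.columns:
            df["rutgeerts"] = pd.array([pd.NA] * len(df), dtype="Int64")
        df["rutgeerts"] = df["rutgeerts"].astype("Int64")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        for col, vocab in (("cohort", COHORTS), ("procedure", PROCEDURES), ("site", SITES)):
            bad = set(df[col]) - vocab
            if bad:
                raise ValueError(f"unknown {col} tokens: {sorted(bad)}")
        if (df["timepoint"].astype(int) < 1).any():
            raise ValueError("timepoint must be >= 1")
        df["timepoint"] = df["timepoint"].astype(int)
        df["inflamed"] = df["inflamed"].astype(bool)
        scored = df["rutgeerts"].notna()
        vals = df.loc[scored, "rutgeerts"]
        if ((vals < 0) | (vals > 4)).any():
            raise ValueError("rutgeerts score outside 0-4")
        bad_rows = scored & (
            (df["cohort"] != "crohns") | (df["procedure"] != "colonoscopy")
        )
        if bad_rows.any():
            raise ValueError(
                "rutgeerts score only valid for crohns colonoscopy samples: "
                f"{df.loc[bad_rows, 'sample_id'].tolist()}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    def rows_for_patient(self, patient_id: str) -> pd.DataFrame:
        return self.df[self.df["patient_id"] == patient_id]

    def select(self, **conditions) -> pd.DataFrame:
        """Rows matching all equality conditions, e.g. cohort='crohns'."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            mask &= self.df[col] == val
        return self.df[mask]

    def outcome_for(self, patient_id: str) -> str:
        return derive_outcome(self.rows_for_patient(patient_id))

    def outcomes(self) -> dict[str, str]:
        return {p: self.outcome_for(p) for p in self.patient_ids}

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
        return cls(df)


def derive_outcome(rows: pd.DataFrame) -> str:
    """Post-operative outcome from the Rutgeerts scores of one patient.

    Remission when the maximum recorded score is 0-1, recurrence when it
    is 2-4, unknown when no score was recorded.
    """
    patients = set(rows["patient_id"])
    if len(patients) > 1:
        raise ValueError(f"rows span multiple patients: {sorted(patients)}")
    scores = rows["rutgeerts"].dropna()
    if scores.empty:
        return UNKNOWN
    if ((scores < 0) | (scores > 4)).any():
        raise ValueError("rutgeerts score outside 0-4")
    return RECURRENCE if int(scores.max()) >= 2 else REMISSION


class DistanceMatrix:
    """Symmetric, zero-diagonal matrix of pairwise sample distances."""

    def __init__(self, ids: Sequence[str], data: np.ndarray, *, _validate: bool = True):
        ids = list(ids)
        data = np.asarray(data, dtype=float)
        if _validate:
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids")
            if data.shape != (len(ids), len(ids)):
                raise ValueError("matrix shape does not match id count")
            if not np.allclose(data, data.T, atol=1e-12):
                raise ValueError("matrix is not symmetric")
            if not np.allclose(np.diag(data), 0.0, atol=1e-12):
                raise ValueError("diagonal is not zero")
            if (data < -1e-12).any():
                raise ValueError("negative distances")
        data = np.clip((data + data.T) / 2.0, 0.0, None)
        np.fill_diagonal(data, 0.0)
        self.ids = ids
        self.data = data
        self._pos = {s: i for i, s in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self._pos[a], self._pos[b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], _validate=False)

    def between(self, ids_a: Sequence[str], ids_b: Sequence[str]) -> np.ndarray:
        ia = [self._pos[s] for s in ids_a]
        ib = [self._pos[s] for s in ids_b]
        return self.data[np.ix_(ia, ib)]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


_DNA = frozenset("ACGT")


@dataclass
class SequenceSet:
    """Nucleotide records over {A,C,G,T} with optional abundances.

    ``counts`` defaults to one per record; ``sample_ids`` optionally maps
    each record to the sample it came from.
    """

    ids: list[str]
    sequences: list[str]
    counts: np.ndarray = None  # type: ignore[assignment]
    sample_ids: list[str] | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        for i, s in enumerate(self.sequences):
            if not s:
                raise ValueError(f"empty sequence at record {self.ids[i]!r}")
            if set(s) - _DNA:
                raise ValueError(f"non-ACGT characters in record {self.ids[i]!r}")
        if self.counts is None:
            self.counts = np.ones(len(self.ids), dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (len(self.ids),):
                raise ValueError("counts length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description=f"count={c}")
            for i, s, c in zip(self.ids, self.sequences, self.counts)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "SequenceSet":
        ids, seqs, counts = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
            c = 1
            for tok in rec.description.split():
                if tok.startswith("count="):
                    c = int(tok.split("=", 1)[1])
            counts.append(c)
        return cls(ids, seqs, np.array(counts, dtype=np.int64))


def check_sample_alignment(
    table: CountTable,
    meta: SampleMetadata,
    *,
    drop_unmatched: bool = False,
) -> tuple[CountTable, SampleMetadata]:
    """Ensure table and metadata cover the same samples (the join key).

    With ``drop_unmatched`` the intersection is kept; otherwise any
    discrepancy is an error at pipeline assembly time.
    """
    t_ids, m_ids = set(table.sample_ids), set(meta.sample_ids)
    if t_ids == m_ids:
        return table, meta
    if not drop_unmatched:
        raise ValueError(
            f"sample mismatch: only-in-table={sorted(t_ids - m_ids)}, "
            f"only-in-metadata={sorted(m_ids - t_ids)}"
        )
    keep = sorted(t_ids & m_ids)
    if not keep:
        raise ValueError("no samples in common")
    sub_meta = SampleMetadata(meta.df[meta.df["sample_id"].isin(keep)])
    return table.subset(keep), sub_meta
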