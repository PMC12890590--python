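"""Data model and I/O: OTU tables, sample metadata, taxonomy, QC.

The central container is :class:`OtuTable`: a sparse samples × OTUs count
matrix plus per-sample metadata (project id, raw environment keywords,
canonical environment set) and, at the fine identity level, a child→parent
map onto coarse OTUs.  Formats are plain TSV: a sparse triplet dialect
(``sample_id<TAB>otu_id<TAB>count``) and a dense dialect (samples as rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParseError, ValidationError
from .trees import PhyloTree
from .util import ENV_ORDER

logger = logging.getLogger("ccons.io")

#: Taxonomic ranks from coarsest to finest.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Default environment keyword lexicon: raw token → canonical label.
DEFAULT_LEXICON: dict[str, str] = {
    "sea": "marine", "ocean": "marine", "marine": "marine",
    "lake": "freshwater", "river": "freshwater", "freshwater": "freshwater",
    "animal": "animal", "plant": "plant", "soil": "soil",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    """One sequenced community sample (a read-only view onto an OtuTable row)."""

    sample_id: str
    project_id: str
    env_keywords: list[str]
    environments: frozenset[str]
    counts: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


class OtuTable:
    """Sparse sample × OTU count matrix at one identity level."""

    def __init__(
        self,
        counts: sp.spmatrix | np.ndarray,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
        level: str = "99",
        meta: pd.DataFrame | None = None,
        child_to_parent: Mapping[str, str] | None = None,
    ):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(sample_ids), len(otu_ids)):
            raise ValidationError("counts shape does not match id lists")
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("negative counts are not allowed")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(otu_ids)) != len(otu_ids):
            raise ValidationError("duplicate OTU ids")
        self.counts = counts
        self.counts.eliminate_zeros()
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)
        self.level = level
        self.child_to_parent = dict(child_to_parent) if child_to_parent else None
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._otu_index = {o: i for i, o in enumerate(self.otu_ids)}
        if meta is None:
            meta = pd.DataFrame(
                {
                    "project_id": ["" for _ in self.sample_ids],
                    "env_keywords": [[] for _ in self.sample_ids],
                    "environments": [frozenset() for _ in self.sample_ids],
                },
                index=pd.Index(self.sample_ids, name="sample_id"),
            )
        self.meta = meta.loc[self.sample_ids]

    # -- indexing ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def otu_index(self, otu_id: str) -> int:
        try:
            return self._otu_index[otu_id]
        except KeyError:
            raise KeyError(f"unknown OTU id: {otu_id!r}") from None

    def sample(self, sample_id: str) -> Sample:
        i = self.sample_index(sample_id)
        row = self.counts.getrow(i).tocoo()
        meta = self.meta.iloc[i]
        return Sample(
            sample_id=sample_id,
            project_id=str(meta["project_id"]),
            env_keywords=list(meta["env_keywords"]),
            environments=frozenset(meta["environments"]),
            counts={self.otu_ids[j]: int(v) for j, v in zip(row.col, row.data)},
        )

    # -- summaries ---------------------------------------------------------

    def totals(self) -> np.ndarray:
        """Total reads per sample."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def richness(self) -> np.ndarray:
        """Number of distinct OTUs (count > 0) per sample."""
        return np.diff(self.counts.indptr)

    def singletons(self) -> np.ndarray:
        """Number of OTUs observed exactly once, per sample."""
        ones = self.counts.copy()
        ones.data = (ones.data == 1).astype(np.int64)
        return np.asarray(ones.sum(axis=1)).ravel()

    def presence_samples(self, otu_id: str) -> np.ndarray:
        """Indices of samples containing the OTU (count > 0)."""
        col = self.counts.getcol(self.otu_index(otu_id)).tocoo()
        return np.sort(col.row)

    def relative_abundance(self) -> np.ndarray:
        """Dense relative-abundance matrix; all-zero samples stay all-zero."""
        dense = np.asarray(self.counts.todense(), dtype=float)
        tot = dense.sum(axis=1, keepdims=True)
        np.divide(dense, tot, out=dense, where=tot > 0)
        return dense

    def project_codes(self) -> np.ndarray:
        """Integer project code per sample; missing ids become singleton codes."""
        codes = np.empty(self.n_samples, dtype=np.intp)
        mapping: dict[str, int] = {}
        nxt = 0
        for i, pid in enumerate(self.meta["project_id"]):
            pid = str(pid)
            if pid == "" or pid.lower() == "nan":
                codes[i] = nxt  # singleton project: never excluded against others
                nxt += 1
            else:
                if pid not in mapping:
                    mapping[pid] = nxt
                    nxt += 1
                codes[i] = mapping[pid]
        return codes

    def subset_samples(self, keep: Sequence[int]) -> "OtuTable":
        keep = np.asarray(keep, dtype=np.intp)
        return OtuTable(
            self.counts[keep],
            [self.sample_ids[i] for i in keep],
            self.otu_ids,
            level=self.level,
            meta=self.meta.iloc[keep],
            child_to_parent=self.child_to_parent,
        )


@dataclass
class Taxonomy:
    """OTU → ranked lineage (domain..species); missing ranks are ``None``."""

    lineages: dict[str, tuple[str | None, ...]]

    def __post_init__(self):
        for otu, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise ValidationError(
                    f"lineage of {otu!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )
            seen_missing = False
            for entry in lin:
                if entry is None:
                    seen_missing = True
                elif seen_missing:
                    raise ValidationError(
                        f"lineage of {otu!r} fills a rank below a missing rank"
                    )

    def lineage(self, otu_id: str) -> tuple[str | None, ...]:
        try:
            return self.lineages[otu_id]
        except KeyError:
            raise KeyError(f"unknown OTU id in taxonomy: {otu_id!r}") from None

    def rank(self, otu_id: str, rank: str) -> str | None:
        return self.lineage(otu_id)[RANKS.index(rank)]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            {k: list(v) for k, v in self.lineages.items()},
            orient="index",
            columns=list(RANKS),
        ).rename_axis("otu_id")


@dataclass
class QcReport:
    """Per-sample quality-control outcome."""

    frame: pd.DataFrame  # total_reads, n_otus, coverage, pass_* flags, passed

    @property
    def n_passed(self) -> int:
        return int(self.frame["passed"].sum())

    @property
    def rejected(self) -> pd.DataFrame:
        return self.frame[~self.frame["passed"]]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, level: str = "99") -> OtuTable:
    """Read an OTU table from triplet or dense TSV (autodetected by header)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if cols[:3] == ["sample_id", "otu_id", "count"]:
        return _read_triplet(path, level)
    if cols and cols[0] == "sample_id":
        return _read_dense(path, level)
    raise ParseError(f"{path}: unrecognized header {header!r}")


def _read_triplet(path: Path, level: str) -> OtuTable:
    samples: list[str] = []
    otus: list[str] = []
    sample_pos: dict[str, int] = {}
    otu_pos: dict[str, int] = {}
    rows, cols, vals = [], [], []
    seen: set[tuple[int, int]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            sid, oid, raw = parts
            try:
                count = int(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: count {raw!r} is not an integer"
                ) from None
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {count}")
            si = sample_pos.setdefault(sid, len(samples))
            if si == len(samples):
                samples.append(sid)
            oi = otu_pos.setdefault(oid, len(otus))
            if oi == len(otus):
                otus.append(oid)
            if (si, oi) in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate entry for sample {sid!r}, OTU {oid!r}"
                )
            seen.add((si, oi))
            rows.append(si)
            cols.append(oi)
            vals.append(count)
    mat = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(samples), len(otus)), dtype=np.int64
    )
    return OtuTable(mat.tocsr(), samples, otus, level=level)


def _read_dense(path: Path, level: str) -> OtuTable:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    if frame.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample rows")
    if frame.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate OTU columns")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValidationError(f"{path}: non-integer counts in dense table")
        values = values.astype(np.int64)
    if values.size and values.min() < 0:
        raise ValidationError(f"{path}: negative counts in dense table")
    return OtuTable(
        sp.csr_matrix(values), list(frame.index), list(frame.columns), level=level
    )


def write_otu_table(table: OtuTable, path, dialect: str = "triplet") -> None:
    path = Path(path)
    if dialect == "triplet":
        coo = table.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\totu_id\tcount\n")
            for k in order:
                fh.write(
                    f"{table.sample_ids[coo.row[k]]}\t"
                    f"{table.otu_ids[coo.col[k]]}\t{int(coo.data[k])}\n"
                )
    elif dialect == "dense":
        frame = pd.DataFrame(
            np.asarray(table.counts.todense()),
            index=pd.Index(table.sample_ids, name="sample_id"),
            columns=table.otu_ids,
        )
        frame.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV: sample_id, project_id, env_keywords ('|'-separated)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "project_id", "env_keywords"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: metadata must have columns {sorted(required)}")
    frame = frame.set_index("sample_id")
    if frame.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in metadata")
    frame["env_keywords"] = [
        [k for k in kw.split("|") if k] for kw in frame["env_keywords"]
    ]
    return frame


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "project_id": meta["project_id"],
            "env_keywords": ["|".join(k) for k in meta["env_keywords"]],
        },
        index=meta.index,
    ).rename_axis("sample_id")
    out.to_csv(path, sep="\t")


def attach_metadata(
    table: OtuTable, meta: pd.DataFrame, lexicon: Mapping[str, str] | None = None
) -> OtuTable:
    """Attach project/environment metadata to a table (canonicalizing keywords)."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing for samples: {missing[:5]} ...")
    sub = meta.loc[table.sample_ids].copy()
    sub["environments"] = [
        canonicalize_environments(kw, lexicon) for kw in sub["env_keywords"]
    ]
    table.meta = sub
    return table


def read_taxonomy(path) -> Taxonomy:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in frame.columns:
        raise ParseError(f"{path}: taxonomy must have an otu_id column")
    lineages = {}
    for _, row in frame.iterrows():
        lin = tuple(
            (None if pd.isna(row.get(r)) or row.get(r) == "" else str(row[r]))
            for r in RANKS
        )
        lineages[str(row["otu_id"])] = lin
    return Taxonomy(lineages)


def write_taxonomy(tax: Taxonomy, path) -> None:
    tax.to_frame().fillna("").to_csv(path, sep="\t")


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree; polytomies are resolved deterministically."""
    return PhyloTree.from_newick_file(path)


def load_lexicon(path) -> dict[str, str]:
    """Read a keyword lexicon TSV (keyword<TAB>canonical)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["keyword", "canonical"])
    return {
        str(k).strip().lower(): str(v).strip().lower()
        for k, v in zip(frame["keyword"], frame["canonical"])
    }


# ---------------------------------------------------------------------------
# environment canonicalization
# ---------------------------------------------------------------------------

def canonicalize_environments(
    keywords: Iterable[str], lexicon: Mapping[str, str] | None = None
) -> frozenset[str]:
    """Map raw environment keywords onto the canonical five-label set.

    Compound annotations like ``"animal|soil"`` yield both labels; matching
    is case-insensitive on whole tokens; unknown tokens are dropped.
    """
    lexicon = DEFAULT_LEXICON if lexicon is None else lexicon
    out: set[str] = set()
    for kw in keywords:
        for token in str(kw).split("|"):
            token = token.strip().lower()
            if token in lexicon:
                out.add(lexicon[token])
    return frozenset(out)


# ---------------------------------------------------------------------------
# coverage and QC
# ---------------------------------------------------------------------------

def estimate_coverage(counts: Mapping[str, int], strategy: str = "good") -> float:
    """Estimated community coverage of a count vector.

    The default ``good`` strategy is the classic Good coverage 1 − F1/N,
    with F1 the number of OTUs observed exactly once and N the total reads.
    The strategy argument leaves room for improved Good–Turing variants.
    """
    if strategy != "good":
        raise ValueError(f"unknown coverage strategy {strategy!r}")
    values = [v for v in counts.values() if v > 0]
    if not values:
        raise ValidationError("cannot estimate coverage of an empty count vector")
    total = sum(values)
    f1 = sum(1 for v in values if v == 1)
    return 1.0 - f1 / total


def qc_filter_samples(
    table: OtuTable,
    min_reads: int = 1000,
    min_otus: int = 20,
    min_coverage: float = 0.90,
) -> tuple[OtuTable, QcReport]:
    """Retain samples with ≥ min_reads reads, ≥ min_otus OTUs and ≥ min_coverage.

    Coverage uses the Good estimator (1 − F1/N); empty samples fail all rules.
    """
    totals = table.totals()
    rich = table.richness()
    f1 = table.singletons()
    with np.errstate(divide="ignore", invalid="ignore"):
        coverage = np.where(totals > 0, 1.0 - f1 / np.maximum(totals, 1), 0.0)
    pass_reads = totals >= min_reads
    pass_otus = rich >= min_otus
    pass_cov = coverage >= min_coverage
    passed = pass_reads & pass_otus & pass_cov
    frame = pd.DataFrame(
        {
            "total_reads": totals,
            "n_otus": rich,
            "coverage": coverage,
            "pass_reads": pass_reads,
            "pass_otus": pass_otus,
            "pass_coverage": pass_cov,
            "passed": passed,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    kept = table.subset_samples(np.flatnonzero(passed))
    return kept, QcReport(frame)


# ---------------------------------------------------------------------------
# main-environment vote and level collapsing
# ---------------------------------------------------------------------------

def assign_main_environment(otu_id: str, table: OtuTable) -> str | None:
    """Majority-vote main environment of one OTU over the samples containing it.

    Each sample contributes one vote per environment label it carries; ties
    break by the fixed order animal, marine, freshwater, plant, soil.
    """
    return main_environments(table, [otu_id])[otu_id]


def main_environments(
    table: OtuTable, otu_ids: Sequence[str] | None = None
) -> dict[str, str | None]:
    """Vectorized majority-vote main environment for many OTUs at once."""
    if otu_ids is None:
        otu_ids = table.otu_ids
    env_mat = np.zeros((table.n_samples, len(ENV_ORDER)))
    for i, envs in enumerate(table.meta["environments"]):
        for e in envs:
            env_mat[i, ENV_ORDER.index(e)] = 1.0
    presence = table.counts.copy()
    presence.data = np.ones_like(presence.data)
    votes = np.asarray((presence.T @ env_mat))  # n_otus × n_env
    out: dict[str, str | None] = {}
    for otu in otu_ids:
        row = votes[table.otu_index(otu)]
        if row.sum() == 0:
            out[otu] = None
            continue
        best = int(np.argmax(row))  # argmax takes the first max: fixed-order tie-break
        if (row == row[best]).sum() > 1:
            logger.info("environment-vote tie for OTU %s, fixed-order tie-break", otu)
        out[otu] = ENV_ORDER[best]
    return out


def collapse_to_level(table: OtuTable, new_level: str | None = None) -> OtuTable:
    """Sum child OTU counts onto their coarse parents; per-sample totals unchanged."""
    if table.child_to_parent is None:
        raise ValidationError("table has no child_to_parent map")
    missing = [o for o in table.otu_ids if o not in table.child_to_parent]
    if missing:
        raise ValidationError(
            f"child_to_parent is missing entries for: {missing[:5]} ..."
        )
    parents: list[str] = []
    parent_pos: dict[str, int] = {}
    col_map = np.empty(table.n_otus, dtype=np.intp)
    for j, otu in enumerate(table.otu_ids):
        parent = table.child_to_parent[otu]
        k = parent_pos.setdefault(parent, len(parents))
        if k == len(parents):
            parents.append(parent)
        col_map[j] = k
    indicator = sp.csr_matrix(
        (np.ones(table.n_otus), (np.arange(table.n_otus), col_map)),
        shape=(table.n_otus, len(parents)),
    )
    collapsed = (table.counts @ indicator).astype(np.int64)
    return OtuTable(
        collapsed,
        table.sample_ids,
        parents,
        level=new_level or f"{table.level}-collapsed",
        meta=table.meta,
    )
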