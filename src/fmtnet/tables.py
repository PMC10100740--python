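"""ASV count tables, taxonomy, sample metadata: reading, writing, and basic views.

The central container is :class:`AsvTable`, a validated non-negative integer
matrix of amplicon sequence variant (ASV) counts, rows = ASVs, columns =
samples.  Tables round-trip through TSV and BIOM-JSON (v1.0).  Taxonomy is a
per-ASV ranked lineage (domain..species, SILVA-style semicolon strings with
optional ``g__`` prefixes); sample metadata carries the experimental group and
sampling day.

Rarefaction subsamples each sample's counts *without replacement* (multivariate
hypergeometric) to a common depth; samples below the depth are dropped with a
warning rather than raising, which is the common behaviour of amplicon
pipelines.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"

#: groups of the FMT study design: donor (P), conventional mice (CV),
#: antibiotic-treated (AT), antibiotic + multiple FMT (AM), germfree multiple
#: FMT (M), germfree single FMT (S)
DEFAULT_GROUPS = ("P", "CV", "AT", "AM", "M", "S")
DEFAULT_DAYS = (0, 3, 7, 14, 21)

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class AsvTable:
    """A features-by-samples matrix of non-negative integer ASV counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by ASV id, columns by sample id.  Values must be finite,
        integral, and >= 0; float columns holding whole numbers are accepted
        and cast.

    Raises
    ------
    ValueError
        On duplicate ids, or on any negative / non-integral cell (the error
        message names the offending ASV and sample).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if values.size:
            if not np.all(np.isfinite(values.astype(float))):
                raise ValueError("counts must be finite")
            bad = (values.astype(float) < 0) | (values.astype(float) % 1 != 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"invalid count {values[i, j]!r} at ASV "
                    f"{counts.index[i]!r}, sample {counts.columns[j]!r}: "
                    "counts must be non-negative integers"
                )
        self._df = counts.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        """The underlying integer DataFrame (ASV x sample)."""
        return self._df

    @property
    def asv_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_totals(self) -> pd.Series:
        return self._df.sum(axis=0)

    def subset(self, samples=None, asvs=None) -> "AsvTable":
        """Return a sub-table restricted to the given samples and/or ASVs."""
        df = self._df
        if samples is not None:
            df = df.loc[:, list(samples)]
        if asvs is not None:
            df = df.loc[list(asvs)]
        return AsvTable(df.copy())

    def drop_empty_asvs(self) -> "AsvTable":
        keep = self._df.sum(axis=1) > 0
        return AsvTable(self._df.loc[keep].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return (
            self.asv_ids == other.asv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self._df.to_numpy(), other._df.to_numpy())
        )

    def __repr__(self) -> str:
        return f"AsvTable({self.shape[0]} ASVs x {self.shape[1]} samples)"


@dataclass
class TaxonomyMap:
    """ASV id -> seven-rank lineage (domain..species), ``unassigned`` filled in."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.lineages = {a: _pad_lineage(l) for a, l in self.lineages.items()}

    def rank(self, asv_id: str, rank: str) -> str:
        """Label of ``asv_id`` at ``rank``; ``unassigned`` if unknown."""
        idx = RANKS.index(rank)
        lineage = self.lineages.get(asv_id)
        return lineage[idx] if lineage is not None else UNASSIGNED

    def genus(self, asv_id: str) -> str:
        return self.rank(asv_id, "genus")

    def phylum(self, asv_id: str) -> str:
        return self.rank(asv_id, "phylum")

    def __contains__(self, asv_id) -> bool:
        return asv_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample experimental annotation: group label and sampling day."""

    frame: pd.DataFrame  # index sample_id, columns: group, day
    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.frame["group"]) - set(self.groups)
        if bad:
            raise ValueError(
                f"metadata group(s) {sorted(bad)} outside declared set {self.groups}"
            )
        days = self.frame["day"].astype(int)
        odd = sorted(set(days) - set(DEFAULT_DAYS))
        if odd:
            logger.warning("metadata days outside the study design retained: %s", odd)
        self.frame = self.frame.assign(day=days)
        self.frame.index.name = "sample_id"

    def group_of(self, sample_id: str) -> str:
        return self.frame.loc[sample_id, "group"]

    def day_of(self, sample_id: str) -> int:
        return int(self.frame.loc[sample_id, "day"])

    def samples(self, group: str | None = None, day: int | None = None) -> list[str]:
        """Sample ids matching an optional (group, day) filter."""
        sel = pd.Series(True, index=self.frame.index)
        if group is not None:
            sel &= self.frame["group"] == group
        if day is not None:
            sel &= self.frame["day"] == day
        return list(self.frame.index[sel])

    def group_series(self, sample_ids) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing}")
        return self.frame.loc[list(sample_ids), "group"]


# ---------------------------------------------------------------------------
# readers / writers


def read_asv_table(path, format: str = "tsv") -> AsvTable:
    """Read an ASV count table from ``tsv`` or ``biom-json``."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return AsvTable(df)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _biom_to_table(doc)
    raise ValueError(f"unknown format {format!r}")


def write_asv_table(table: AsvTable, path, format: str = "tsv") -> None:
    """Write a table; ``read_asv_table`` of the result reproduces it exactly."""
    if format == "tsv":
        out = table.counts.copy()
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")
        return
    if format == "biom-json":
        with open(path, "w") as fh:
            json.dump(_table_to_biom(table), fh)
        return
    raise ValueError(f"unknown format {format!r}")


def _biom_to_table(doc: dict) -> AsvTable:
    n_rows, n_cols = doc["shape"]
    row_ids = [r["id"] for r in doc["rows"]]
    col_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return AsvTable(pd.DataFrame(mat, index=row_ids, columns=col_ids))


def _table_to_biom(table: AsvTable) -> dict:
    arr = table.counts.to_numpy()
    data = [[int(i), int(j), int(arr[i, j])] for i, j in zip(*np.nonzero(arr))]
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "fmtnet",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.shape[0], table.shape[1]],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon lineage string into a 7-rank tuple.

    Rank prefixes (``d__``, ``g__``, ...) are stripped; empty or missing
    trailing ranks become ``unassigned``.
    """
    parts = [(_RANK_PREFIX.sub("", p.strip()) or UNASSIGNED) for p in lineage.split(";")]
    return _pad_lineage(parts)


def _pad_lineage(parts) -> tuple[str, ...]:
    parts = list(parts)[: len(RANKS)]
    parts += [UNASSIGNED] * (len(RANKS) - len(parts))
    return tuple(p if p else UNASSIGNED for p in parts)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column (asv_id, lineage) TSV, header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0] in ("asv_id", "id", "ASV"):
        df = df.iloc[1:]
    lineages = {}
    for asv, lin in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if asv in lineages:
            raise ValueError(f"duplicate taxonomy entry for {asv!r}")
        lineages[str(asv)] = parse_lineage("" if pd.isna(lin) else str(lin))
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("asv_id\tlineage\n")
        for asv, lineage in taxonomy.lineages.items():
            fh.write(f"{asv}\t{';'.join(lineage)}\n")


def read_metadata(path, groups: tuple[str, ...] = DEFAULT_GROUPS) -> SampleMetadata:
    """Read a three-column (sample_id, group, day) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.columns = [c.lower() for c in df.columns]
    return SampleMetadata(df[["group", "day"]], groups=groups)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# rarefaction and abundance views


def rarefy(table: AsvTable, depth: int, seed: int | None = None) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged warning).
    Deterministic given ``seed``: each retained column sums to ``depth`` and no
    cell exceeds its original count (multivariate hypergeometric draw).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not keep:
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.asv_ids, columns=keep)
    return AsvTable(df)


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample fractions; every column sums to 1.  Zero-total samples error."""
    totals = table.sample_totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    return table.counts / totals


def collapse_taxa(
    abund: pd.DataFrame,
    taxonomy: TaxonomyMap,
    rank: str = "genus",
    min_frac: float = 0.01,
    others_label: str = "Others",
) -> pd.DataFrame:
    """Sum per-ASV fractions into taxa at ``rank``; pool rare taxa as Others.

    A taxon whose *mean* relative abundance across the displayed samples is
    below ``min_frac`` goes into the ``Others`` bucket (the display convention
    for <1% taxa).  Column sums are preserved.  ``min_frac=0`` disables the
    bucket.
    """
    if rank not in RANKS[1:]:
        raise ValueError(f"rank must be one of {RANKS[1:]}")
    labels = pd.Series({a: taxonomy.rank(a, rank) for a in abund.index})
    collapsed = abund.groupby(labels.reindex(abund.index)).sum()
    if min_frac > 0:
        rare = collapsed.index[collapsed.mean(axis=1) < min_frac]
        if len(rare):
            others = collapsed.loc[rare].sum(axis=0)
            collapsed = collapsed.drop(index=rare)
            collapsed.loc[others_label] = collapsed.loc[others_label] + others \
                if others_label in collapsed.index else others
    return collapsed
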