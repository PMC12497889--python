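"""Shared containers, I/O and elementary community statistics.

The universal community representation is :class:`AbundanceMatrix`:
integer read counts with samples as rows and taxa as columns, everywhere
in this package. Helpers here cover TSV/BIOM-v1 I/O, relative abundance,
Bray–Curtis dissimilarity, richness, occupancy/mean-abundance summaries,
functional-group assignment and sample aggregation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .exceptions import ConfigError, FormatError, InvalidInputError

FUNCTIONAL_GROUPS = (
    "autotroph",
    "mixotroph",
    "parasite",
    "osmotroph",
    "phagotroph",
    "unassigned",
)


@dataclass
class AbundanceMatrix:
    """Integer count matrix, samples x taxa, with unique string IDs.

    Parameters
    ----------
    counts : ndarray of int, shape (n_samples, n_taxa)
        Non-negative read counts.
    sample_ids, taxon_ids : sequences of str
        Unique identifiers for rows and columns respectively.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D samples x taxa matrix")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(self.counts < 0):
            s, t = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"taxon {self.taxon_ids[t]!r}"
            )
        self.counts = np.rint(self.counts).astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n, t = self.counts.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != t:
            raise FormatError("ID lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != t:
            raise FormatError("duplicate taxon IDs")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def drop_empty_samples(self) -> "AbundanceMatrix":
        keep = self.counts.sum(axis=1) > 0
        return AbundanceMatrix(
            self.counts[keep],
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.taxon_ids),
        )

    def sorted(self) -> "AbundanceMatrix":
        """Return a copy with rows and columns in lexicographic ID order."""
        df = self.to_dataframe().sort_index(axis=0).sort_index(axis=1)
        return AbundanceMatrix.from_dataframe(df)


def read_abundance(path, format: str = "tsv", orientation: str = "auto") -> AbundanceMatrix:
    """Read an abundance table from TSV or BIOM v1 JSON.

    ``orientation`` is one of ``samples_rows``, ``taxa_rows`` or ``auto``
    (TSV only; BIOM fixes observations=taxa as rows by its own convention).
    Auto-detection assumes the longer axis holds taxa, which is the common
    case for amplicon tables.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise FormatError(f"{path}: duplicate IDs in table")
        bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        arr = df.to_numpy()
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if orientation == "taxa_rows" or (
            orientation == "auto" and df.shape[0] > df.shape[1]
        ):
            df = df.T
        return AbundanceMatrix.from_dataframe(df)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") == "dense":
            data = np.asarray(doc["data"], dtype=float)
        else:  # sparse: list of [row, col, value]
            nrow, ncol = doc["shape"]
            data = np.zeros((nrow, ncol))
            for r, c, v in doc["data"]:
                data[int(r), int(c)] = v
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        # BIOM convention: rows are observations (taxa) -> transpose
        return AbundanceMatrix(data.T, samples, taxa)
    raise ConfigError(f"unknown abundance format {format!r}")


def write_abundance(m: AbundanceMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        m.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "lakeassembly",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [m.n_taxa, m.n_samples],
            "rows": [{"id": t, "metadata": None} for t in m.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in m.sample_ids],
            "data": m.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ConfigError(f"unknown abundance format {format!r}")


def relative_abundance(m: AbundanceMatrix) -> np.ndarray:
    """Row-normalized counts; every row sums to 1 within 1e-12."""
    totals = m.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = m.sample_ids[int(np.argmax(totals == 0))]
        raise InvalidInputError(f"sample {bad!r} has zero total count")
    return m.counts / totals[:, None]


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("negative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise InvalidInputError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def rarefy(m: AbundanceMatrix, depth: int, seed: int) -> AbundanceMatrix:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Off by default throughout the pipeline; exposed for sensitivity checks.
    """
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for i, sid in enumerate(m.sample_ids):
        row = m.counts[i]
        if row.sum() < depth:
            warnings.warn(f"sample {sid!r} has fewer than {depth} reads; dropped")
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth))
        ids.append(sid)
    if not rows:
        raise InvalidInputError("no sample reaches the rarefaction depth")
    return AbundanceMatrix(np.asarray(rows), ids, list(m.taxon_ids))


def occupancy_and_mean_abundance(m: AbundanceMatrix) -> pd.DataFrame:
    """Per-taxon detection frequency and mean relative abundance.

    ``frequency`` is the fraction of samples in which the taxon is
    detected; ``mean_relative_abundance`` is the arithmetic mean of its
    relative abundance across samples (the metacommunity abundance p used
    by the neutral model).
    """
    if m.n_samples < 2:
        raise InvalidInputError("occupancy requires at least 2 samples")
    rel = relative_abundance(m)
    return pd.DataFrame(
        {
            "frequency": (m.counts > 0).mean(axis=0),
            "mean_relative_abundance": rel.mean(axis=0),
        },
        index=pd.Index(m.taxon_ids, name="taxon_id"),
    )


def read_functional_map(path) -> dict:
    """Two-column TSV (taxonomy label, functional group) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "group"])
    return validate_functional_map(dict(zip(df["label"], df["group"])))


def validate_functional_map(fmap: dict) -> dict:
    for label, group in fmap.items():
        if group not in FUNCTIONAL_GROUPS:
            raise ConfigError(
                f"illegal functional group {group!r} for {label!r}; "
                f"allowed: {', '.join(FUNCTIONAL_GROUPS)}"
            )
    return fmap


def assign_functional_groups(taxonomy: pd.Series | dict, fmap: dict) -> pd.Series:
    """Map semicolon-separated taxonomy strings to functional groups.

    The most specific (deepest) rank with an entry in ``fmap`` wins;
    taxa with no matching rank are ``unassigned``.
    """
    validate_functional_map(fmap)
    taxonomy = pd.Series(taxonomy)
    out = {}
    for taxon, lineage in taxonomy.items():
        ranks = [r.strip() for r in str(lineage).split(";") if r.strip()]
        group = "unassigned"
        for rank in reversed(ranks):  # deepest first
            if rank in fmap:
                group = fmap[rank]
                break
        out[taxon] = group
    return pd.Series(out, name="functional_group")


def group_relative_abundances(m: AbundanceMatrix, taxon_groups: pd.Series) -> pd.DataFrame:
    """Per-sample relative abundance of each functional group.

    Rows sum to 1 over the groups present (including ``unassigned``).
    """
    rel = pd.DataFrame(relative_abundance(m), index=m.sample_ids, columns=m.taxon_ids)
    groups = taxon_groups.reindex(m.taxon_ids).fillna("unassigned")
    out = rel.T.groupby(groups.to_numpy()).sum().T
    out.index.name = "sample_id"
    return out


def aggregate_samples(m: AbundanceMatrix, metadata: pd.DataFrame, keys) -> AbundanceMatrix:
    """Sum counts over samples sharing the given metadata key values.

    ``metadata`` must carry a ``sample_id`` column (or index) covering
    every sample of ``m``. The aggregate sample ID is the ``|``-joined
    key values. A ``month`` key is derived from ``date`` when absent.
    Total counts are conserved.
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    keys = list(keys)
    if "month" in keys and "month" not in md.columns and "date" in md.columns:
        md["month"] = pd.to_datetime(md["date"]).dt.strftime("%Y-%m")
    missing = [s for s in m.sample_ids if s not in md.index]
    if missing:
        raise InvalidInputError(f"sample {missing[0]!r} has no metadata row")
    for k in keys:
        if k not in md.columns:
            raise InvalidInputError(f"metadata lacks aggregation key {k!r}")
    labels = md.loc[m.sample_ids, keys].astype(str).agg("|".join, axis=1)
    df = m.to_dataframe().groupby(labels.to_numpy()).sum()
    return AbundanceMatrix.from_dataframe(df.sort_index())
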