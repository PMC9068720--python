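"""Domain types, validation and on-disk formats shared by every analysis stage.

The universal in-memory containers are thin wrappers around pandas DataFrames
(samples x OTUs for counts, OTUs x functions for genome content) and a rooted
:class:`skbio.TreeNode` phylogeny.  On disk the count table follows the classic
QIIME orientation (OTUs as rows, samples as columns, first column the OTU id);
it is transposed to samples x OTUs in memory.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("assemblage")

__all__ = [
    "CountTable",
    "AlignedData",
    "read_count_table",
    "write_count_table",
    "read_tree",
    "read_taxonomy",
    "genus_of",
    "read_metadata",
    "read_functions",
    "read_category_map",
    "align_inputs",
    "to_relative",
    "patristic_distances",
    "branch_matrix",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Invariants: unique sample and OTU identifiers, integer counts >= 0, and
    every retained sample has a positive total (zero-total samples are dropped
    with a warning at validation time).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU identifiers: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        df = df.astype(np.int64).rename_axis(index=None, columns=None)
        zero = df.sum(axis=1) == 0
        if zero.any():
            dropped = df.index[zero].tolist()
            logger.warning("dropping %d zero-total sample(s): %s", len(dropped), dropped)
            df = df.loc[~zero]
        if df.shape[0] == 0:
            raise ValidationError("no samples with positive totals")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return to_relative(self)

    def select_otus(self, otu_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(otu_ids)])

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])


def to_relative(table: CountTable) -> pd.DataFrame:
    """Row-normalise a CountTable to per-sample fractions summing to 1."""
    totals = table.data.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("cannot normalise a sample with zero total")
    return table.data.div(totals, axis=0)


def read_count_table(path, format: str | None = None) -> CountTable:
    """Read a count table from TSV (QIIME classic: OTUs x samples) or BIOM.

    ``format`` is ``"tsv"`` or ``"biom"``; if omitted it is inferred from the
    file suffix (``.biom`` -> BIOM, else TSV).
    """
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "tsv":
        return _read_count_tsv(path)
    if format == "biom":
        return _read_count_biom(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_count_tsv(path: Path) -> CountTable:
    # QIIME classic convention: leading '#' lines are comments, except that
    # the last one before the data ('#OTU ID<TAB>...') is the header row
    lines = Path(path).read_text().splitlines()
    first_data = next((i for i, l in enumerate(lines)
                       if l.strip() and not l.startswith("#")), len(lines))
    header = None
    for line in lines[:first_data]:
        if "\t" in line:
            header = line.lstrip("#")
    body = [l for l in lines[first_data:] if l.strip() and not l.startswith("#")]
    if header is None and body:
        header, body = body[0], body[1:]
    if header is None or not body:
        raise FormatError(f"{path}: no tabular content found")
    import io as _io

    try:
        df = pd.read_csv(_io.StringIO("\n".join([header] + body)), sep="\t",
                         index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    try:
        num = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    # on disk: OTU rows x sample columns -> transpose to samples x OTUs
    return CountTable(num.T)


def _read_count_biom(path: Path) -> CountTable:
    from skbio.table import Table

    try:
        with open(path, "rb") as fh:
            head = fh.read(8)
        if head.startswith(b"\x89HDF"):
            import h5py

            with h5py.File(path, "r") as fh:
                tab = Table.from_hdf5(fh)
        else:
            with open(path) as fh:
                tab = Table.from_json(__import__("json").load(fh))
    except (OSError, ValueError, KeyError) as exc:
        raise FormatError(f"cannot parse {path} as BIOM: {exc}") from exc
    df = pd.DataFrame(
        tab.matrix_data.toarray().T,
        index=list(tab.ids("sample")),
        columns=list(tab.ids("observation")),
    )
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    """Write a CountTable as classic TSV (OTUs x samples)."""
    out = table.data.T.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted Newick phylogeny.

    Unrooted trees (basal polytomy with >2 children) are midpoint-rooted with
    a warning; missing branch lengths are set to 0 with a warning.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as Newick: {exc}") from exc
    missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing += 1
    if missing:
        logger.warning("%d branch(es) had no length; set to 0", missing)
    if len(tree.children) > 2:
        logger.warning("tree appears unrooted (basal polytomy); midpoint-rooting")
        tree = tree.root_at_midpoint()
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def patristic_distances(tree: TreeNode, otu_ids) -> np.ndarray:
    """Dense tip-to-tip (patristic) distance matrix in the given OTU order."""
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    order = [dm.index(o) for o in otu_ids]
    return dm.data[np.ix_(order, order)]


def branch_matrix(tree: TreeNode, otu_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip incidence for branch-wise phylogenetic metrics.

    Returns ``(lengths, incidence)`` where ``lengths`` has one entry per
    non-root branch and ``incidence[b, k]`` is True when OTU ``k`` descends
    from branch ``b``.  Multiplying ``incidence`` by a relative-abundance
    vector gives the abundance carried by each branch (UniFrac family), and
    any-tip incidence gives Faith's PD including the root path.
    """
    otu_index = {o: k for k, o in enumerate(otu_ids)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.traverse(include_self=False):
        inc = np.zeros(len(otu_index), dtype=bool)
        for tip in node.tips(include_self=True):
            k = otu_index.get(tip.name)
            if k is not None:
                inc[k] = True
        lengths.append(float(node.length or 0.0))
        rows.append(inc)
    return np.asarray(lengths), np.asarray(rows)


# ---------------------------------------------------------------------------
# Taxonomy, metadata, genome functions
# ---------------------------------------------------------------------------

_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIX = {"k": "domain", "d": "domain", "p": "phylum", "c": "class",
           "o": "order", "f": "family", "g": "genus", "s": "species"}


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited lineage like ``k__Bacteria; ...; g__Vibrio``."""
    out: dict[str, str] = {}
    fields = [f.strip() for f in lineage.split(";") if f.strip()]
    for pos, fld in enumerate(fields):
        m = re.match(r"^([a-zA-Z])__(.*)$", fld)
        if m:
            rank = _PREFIX.get(m.group(1).lower())
            name = m.group(2).strip()
        else:
            rank = _RANKS[pos] if pos < len(_RANKS) else None
            name = fld
        if rank and name:
            out[rank] = name
    return out


def read_taxonomy(path) -> dict[str, dict[str, str]]:
    """Read a taxonomy TSV: otu_id <TAB> semicolon-delimited ranked lineage."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy TSV needs two columns")
    # tolerate a header row
    if df.iloc[0, 0].lower() in {"otu", "otu_id", "#otu id", "feature id"}:
        df = df.iloc[1:]
    return {str(r[0]): parse_lineage(str(r[1])) for r in df.itertuples(index=False)}


def genus_of(taxonomy: dict[str, dict[str, str]], otu_id: str) -> str | None:
    lin = taxonomy.get(otu_id)
    return lin.get("genus") if lin else None


def _natural_key(label: str):
    return [int(tok) if tok.isdigit() else tok
            for tok in re.split(r"(\d+)", str(label))]


def read_metadata(path, time_order: list[str] | None = None) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, time_point, group.

    ``time_point`` becomes an ordered categorical; the order is ``time_order``
    when given, otherwise a natural sort of the labels (so W0 < W8 < W12).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample_id", "time_point", "group"):
        if required not in cols:
            raise FormatError(f"{path}: missing metadata column {required!r}")
    df = df.rename(columns={cols["sample_id"]: "sample_id",
                            cols["time_point"]: "time_point",
                            cols["group"]: "group"})
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    order = time_order or sorted(df["time_point"].unique(), key=_natural_key)
    df["time_point"] = pd.Categorical(df["time_point"], categories=order, ordered=True)
    if df["time_point"].isna().any():
        raise ValidationError("time_point outside the declared time order")
    return df


def read_functions(path) -> pd.DataFrame:
    """Read a genome function copy-number TSV (OTU rows x function columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative copy number")
    return df.astype(float)


def read_category_map(path) -> dict[str, str]:
    """Read function_id -> category TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: category TSV needs two columns")
    if df.iloc[0, 0].lower() in {"function", "function_id", "ko"}:
        df = df.iloc[1:]
    return {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Alignment of inputs to the common OTU set
# ---------------------------------------------------------------------------

@dataclass
class AlignedData:
    """Inputs restricted to a common OTU universe.

    ``table``/``tree``/``taxonomy`` share one OTU set; ``functions`` (when
    supplied) may cover fewer OTUs — robustness stages use
    ``table_for_functions``, the table restricted to OTUs with genome content.
    """

    table: CountTable
    tree: TreeNode | None = None
    taxonomy: dict[str, dict[str, str]] | None = None
    functions: pd.DataFrame | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def table_for_functions(self) -> CountTable:
        if self.functions is None:
            raise ValueError("no genome function table in this bundle")
        return self.table.select_otus(self.functions.index)


def align_inputs(table: CountTable,
                 tree: TreeNode | None = None,
                 tax: dict[str, dict[str, str]] | None = None,
                 funcs: pd.DataFrame | None = None) -> AlignedData:
    """Restrict all structures to the OTU set they share.

    The core universe is the intersection of table and tree OTUs (taxonomy may
    legitimately miss OTUs — lottery excludes them with a logged count).  A
    genome-function table smaller than the core universe restricts only the
    robustness view, with a warning.
    """
    otus = list(table.otu_ids)
    dropped: dict[str, int] = {}
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        common = [o for o in otus if o in tips]
        if not common:
            raise ValidationError("no OTUs shared between table and tree")
        dropped["table_vs_tree"] = len(otus) - len(common)
        dropped["tree_tips_pruned"] = len(tips) - len(common)
        if len(common) < len(tips):
            tree = tree.shear(common)
            for node in tree.traverse(include_self=False):
                if node.length is None:
                    node.length = 0.0
        otus = common
    new_table = table.select_otus(otus)
    if tax is not None:
        missing = sum(1 for o in otus if o not in tax)
        dropped["otus_without_taxonomy"] = missing
        if missing:
            logger.warning("%d OTU(s) lack taxonomy; excluded from clade analyses", missing)
        tax = {o: tax[o] for o in otus if o in tax}
    if funcs is not None:
        common_f = [o for o in otus if o in funcs.index]
        if not common_f:
            raise ValidationError("no OTUs shared between table and function table")
        dropped["otus_without_functions"] = len(otus) - len(common_f)
        if dropped["otus_without_functions"]:
            logger.warning(
                "%d OTU(s) lack genome functions; robustness restricted to %d OTUs",
                dropped["otus_without_functions"], len(common_f))
        funcs = funcs.loc[common_f]
        zero = funcs.sum(axis=1) == 0
        if zero.any():
            raise ValidationError(
                f"OTUs with all-zero function profiles: {funcs.index[zero].tolist()}")
    for key, n in dropped.items():
        if n:
            logger.info("align_inputs: %s = %d", key, n)
    return AlignedData(table=new_table, tree=tree, taxonomy=tax,
                       functions=funcs, dropped=dropped)
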