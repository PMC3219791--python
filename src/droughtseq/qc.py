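"""Count-matrix QC, transcriptional-activity calls, and quantile normalization.

The pipeline starts from lane-level per-gene read counts (genes x lanes)
plus a sample sheet mapping each lane to tissue, treatment and biological
replicate.  This module validates that input, reproduces the run-level
summary arithmetic (grand totals and mapping percentages), defines
transcriptionally active genes, computes per-gene sequencing depth in
coverage units (count * read_length / exonic length), and quantile
normalizes all lanes jointly so that downstream exact tests can condition
on equalized library sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from droughtseq.errors import ConfigError, DesignError, FormatError

SAMPLE_SHEET_COLUMNS = ("lane", "tissue", "treatment", "replicate")

#: Depth-bin edges used for the per-sample depth histograms: an exact-zero
#: bin followed by (0,1], (1,2], (2,5], (5,10], (10,50], (50, inf).
DEFAULT_DEPTH_EDGES = (0.0, 1.0, 2.0, 5.0, 10.0, 50.0)

DEPTH_BIN_LABELS = ("0x", "<=1x", "1-2x", "2-5x", "5-10x", "10-50x", ">50x")


@dataclass
class CountMatrix:
    """Genes x lanes raw counts with a sample sheet; normalized counts optional.

    Attributes
    ----------
    counts : pandas.DataFrame
        Raw counts, genes as index, lanes as columns, non-negative integers.
    samples : pandas.DataFrame
        One row per lane with columns ``lane, tissue, treatment, replicate``,
        indexed by lane in the same order as ``counts.columns``.
    normalized : pandas.DataFrame or None
        Quantile-normalized counts; ``None`` until normalization runs.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        validate_counts(self.counts)
        validate_sample_sheet(self.samples, self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def lanes(self) -> pd.Index:
        return self.counts.columns

    def working_counts(self) -> pd.DataFrame:
        """Normalized counts when available, raw counts otherwise."""
        return self.normalized if self.normalized is not None else self.counts

    def group_lanes(self, tissue: str, treatment: str) -> list[str]:
        """Lanes belonging to one tissue/treatment sample group."""
        sel = (self.samples["tissue"] == tissue) & (
            self.samples["treatment"] == treatment
        )
        return list(self.samples.loc[sel, "lane"])


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in count matrix: {dups[:5]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric values")
    if (values < 0).any():
        raise FormatError("count matrix contains negative values")
    if not np.allclose(values, np.round(values)):
        raise FormatError("raw counts must be integral")


def validate_sample_sheet(samples: pd.DataFrame, lanes) -> None:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet_lanes = set(samples["lane"])
    matrix_lanes = set(lanes)
    if samples["lane"].duplicated().any():
        raise DesignError("sample sheet lists a lane more than once")
    if sheet_lanes != matrix_lanes:
        only_matrix = sorted(matrix_lanes - sheet_lanes)
        only_sheet = sorted(sheet_lanes - matrix_lanes)
        raise DesignError(
            "lane/sheet mismatch: "
            f"in counts only {only_matrix[:5]}, in sheet only {only_sheet[:5]}"
        )


def read_counts(counts_path, sample_sheet_path) -> CountMatrix:
    """Load a counts TSV (gene id in first column) and its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype={"lane": str})
    counts.columns = counts.columns.astype(str)
    samples = samples.set_index("lane", drop=False).loc[list(counts.columns)]
    return CountMatrix(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# Run-level summary arithmetic
# ---------------------------------------------------------------------------

QC_CATEGORIES = (
    "total_reads",
    "purity_filtered",
    "repeat_masked",
    "unmatched",
    "uniquely_mapped",
    "mapped_to_genes",
)


def qc_summary(lane_totals: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-sample and grand totals of read-category counts, with percentages.

    Parameters
    ----------
    lane_totals : pandas.DataFrame
        One row per sample (or lane), one column per read category; must
        include every name in :data:`QC_CATEGORIES`.  Units are whatever the
        table uses (typically millions of reads); totals inherit them.
    decimals : int
        Rounding applied to the derived percentages (the published summary
        prints one decimal).

    Returns
    -------
    pandas.DataFrame
        Input rows plus a ``total`` row, with two extra columns:
        ``pct_uniquely_mapped_of_total`` and ``pct_uniquely_mapped_of_pf``.
        Percentages are NaN (undefined) where the denominator is zero.
    """
    missing = [c for c in QC_CATEGORIES if c not in lane_totals.columns]
    if missing:
        raise FormatError(f"qc summary table missing categories: {missing}")
    table = lane_totals.loc[:, list(QC_CATEGORIES)].astype(float).copy()
    total = table.sum(axis=0)
    total.name = "total"
    out = pd.concat([table, total.to_frame().T])

    def pct(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(den > 0, num / den * 100.0, np.nan)
        return np.round(frac, decimals)

    out["pct_uniquely_mapped_of_total"] = pct(
        out["uniquely_mapped"].to_numpy(), out["total_reads"].to_numpy()
    )
    out["pct_uniquely_mapped_of_pf"] = pct(
        out["uniquely_mapped"].to_numpy(), out["purity_filtered"].to_numpy()
    )
    return out


# ---------------------------------------------------------------------------
# Transcriptional activity
# ---------------------------------------------------------------------------


def call_expressed(
    matrix: CountMatrix,
    annotation: pd.DataFrame | None = None,
    min_raw: int = 2,
    evidence: str = "sum",
) -> tuple[set[str], pd.DataFrame]:
    """Call transcriptionally active genes from raw counts.

    A gene is active when its raw-count evidence reaches ``min_raw``
    uniquely mapped reads; by default evidence is summed across all lanes
    of all runs ("when considering all samples in all runs"), the
    ``any_lane`` mode instead requires one lane alone to reach the bar.

    Returns the expressed-gene set and a per-confidence-class breakdown
    (columns ``expressed, annotated, pct_of_annotated``).  Genes absent
    from the annotation are tallied under class ``unclassified``.
    """
    if evidence == "sum":
        score = matrix.counts.sum(axis=1)
    elif evidence == "any_lane":
        score = matrix.counts.max(axis=1)
    else:
        raise ConfigError(f"unknown evidence mode {evidence!r}")
    expressed = set(score.index[score >= min_raw])

    if annotation is None:
        classes = pd.Series("unclassified", index=matrix.genes)
    else:
        classes = annotation["confidence"].reindex(matrix.genes)
        n_missing = int(classes.isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} genes in the count matrix are missing from the "
                "annotation; counted as unclassified",
                stacklevel=2,
            )
        classes = classes.fillna("unclassified")

    rows = []
    for cls, genes in classes.groupby(classes).groups.items():
        n_annot = len(genes)
        n_expr = len(expressed.intersection(genes))
        rows.append(
            {
                "confidence": cls,
                "expressed": n_expr,
                "annotated": n_annot,
                "pct_of_annotated": round(100.0 * n_expr / n_annot, 1)
                if n_annot
                else np.nan,
            }
        )
    breakdown = pd.DataFrame(rows).set_index("confidence")
    return expressed, breakdown


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Quantile normalize all lanes jointly.

    Every lane's sorted value vector becomes the cross-lane mean of order
    statistics, so all per-lane distributions (and medians) coincide while
    each lane's rank order is preserved.  Tied entries within a lane are
    assigned the mean-order-statistic curve interpolated at their average
    rank, matching the behavior of the reference microarray-style
    implementation.  Normalization is performed once across all lanes.
    """
    if matrix.counts.shape[1] < 2:
        warnings.warn("fewer than 2 lanes; quantile normalization is a no-op",
                      stacklevel=2)
        matrix.normalized = matrix.counts.astype(float)
        return matrix
    values = matrix.counts.to_numpy(dtype=float)
    matrix.normalized = pd.DataFrame(
        quantile_normalize_array(values),
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    return matrix


def quantile_normalize_array(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D float array (see above)."""
    n_genes = values.shape[0]
    mean_order_stats = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_order_stats)
    return out


# ---------------------------------------------------------------------------
# Sequencing depth
# ---------------------------------------------------------------------------


def compute_depth(
    matrix: CountMatrix,
    gene_lengths: pd.Series,
    read_length: int = 50,
    depth_mode: str = "coverage",
    use_normalized: bool = True,
) -> pd.DataFrame:
    """Median per-gene sequencing depth for each tissue/treatment group.

    Depth of one replicate lane is ``count * read_length / exonic_length``
    ("coverage" mode, X units); ``raw_count`` mode uses the count itself.
    The median is taken across the biological replicates of each group.

    Returns a genes x groups DataFrame; group columns are ``tissue:treatment``.
    """
    if depth_mode not in ("coverage", "raw_count"):
        raise ConfigError(f"unknown depth_mode {depth_mode!r}")
    counts = matrix.working_counts() if use_normalized else matrix.counts
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise FormatError(f"genes missing exonic lengths: {missing}")
    if (lengths <= 0).any():
        raise FormatError("exonic gene lengths must be positive")

    groups = matrix.samples.groupby(["tissue", "treatment"], sort=True)
    cols = {}
    for (tissue, treatment), rows in groups:
        lanes = list(rows["lane"])
        block = counts.loc[:, lanes].to_numpy(dtype=float)
        if depth_mode == "coverage":
            block = block * read_length / lengths.to_numpy()[:, None]
        cols[f"{tissue}:{treatment}"] = np.median(block, axis=1)
    return pd.DataFrame(cols, index=counts.index)


def depth_bins(
    depth: pd.DataFrame, edges: tuple[float, ...] = DEFAULT_DEPTH_EDGES
) -> pd.DataFrame:
    """Bin genes by median depth per sample group.

    ``edges`` are the finite upper bounds after the exact-zero bin; the
    default reproduces the 0 / <=1 / 1-2 / 2-5 / 5-10 / 10-50 / >50 X
    histogram.  Bin counts partition the gene set, so each column sums to
    the number of genes.
    """
    edges = tuple(float(e) for e in edges)
    if list(edges) != sorted(set(edges)):
        raise ConfigError("depth bin edges must be strictly increasing")
    if edges[0] != 0.0:
        raise ConfigError("depth bin edges must start at 0 (the exact-zero bin)")
    labels = _edge_labels(edges)
    out = {}
    for col in depth.columns:
        d = depth[col].to_numpy(dtype=float)
        counts = [int((d == 0.0).sum())]
        lower = 0.0
        for upper in edges[1:]:
            counts.append(int(((d > lower) & (d <= upper)).sum()))
            lower = upper
        counts.append(int((d > edges[-1]).sum()))
        out[col] = counts
    return pd.DataFrame(out, index=labels)


def _edge_labels(edges: tuple[float, ...]) -> list[str]:
    if edges == DEFAULT_DEPTH_EDGES:
        return list(DEPTH_BIN_LABELS)
    labels = ["0x", f"<={edges[1]:g}x"]
    labels += [f"{lo:g}-{hi:g}x" for lo, hi in zip(edges[1:-1], edges[2:])]
    labels.append(f">{edges[-1]:g}x")
    return labels


def replicate_correlation(matrix: CountMatrix) -> pd.DataFrame:
    """Spearman and Pearson correlations between replicate lanes per group.

    Both coefficients are reported; published summaries of this design
    quote one or the other without distinguishing them.
    """
    counts = matrix.working_counts()
    rows = []
    for (tissue, treatment), grp in matrix.samples.groupby(["tissue", "treatment"]):
        lanes = list(grp["lane"])
        for i in range(len(lanes)):
            for j in range(i + 1, len(lanes)):
                a, b = counts[lanes[i]], counts[lanes[j]]
                rows.append(
                    {
                        "tissue": tissue,
                        "treatment": treatment,
                        "lane_a": lanes[i],
                        "lane_b": lanes[j],
                        "spearman": a.corr(b, method="spearman"),
                        "pearson": a.corr(b, method="pearson"),
                    }
                )
    return pd.DataFrame(rows)
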