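"""Common-dispersion negative-binomial exact-test differential expression.

Model: counts for gene *g*, lane *i* of group A or B are NB with mean
``mu_g`` (equal under the null after library-size equalization) and a
single dispersion ``phi`` shared by all genes, so ``Var = mu + phi mu^2``.
``phi = 0`` reduces to Poisson.

The dispersion is estimated by maximizing the conditional log-likelihood
of the within-group counts given each group's total, summed over genes —
conditioning removes the per-gene means from the likelihood.  The exact
test then conditions each gene on its total count across both groups:
with equalized library sizes and r = n_lanes/phi per group, the group-A
sum given the total follows a beta-binomial law, and the two-sided
p-value is the summed probability of all partitions of the total at most
as probable as the observed one.

Downstream, genes pass the three-part filter (median depth >= 2X in at
least one compared group, |log2FC| >= 1, BH-adjusted p < 0.05) to be
called differentially expressed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from droughtseq.errors import DesignError, EstimationError
from droughtseq.qc import CountMatrix

_POISSON_PHI = 1e-8  # below this the conditional law is treated as binomial


@dataclass(frozen=True)
class Contrast:
    """One treatment-vs-control comparison within a tissue."""

    name: str
    tissue: str
    treatment: str
    control: str

    def lanes(self, matrix: CountMatrix) -> tuple[list[str], list[str]]:
        group_a = matrix.group_lanes(self.tissue, self.treatment)
        group_b = matrix.group_lanes(self.tissue, self.control)
        if set(group_a) & set(group_b):
            raise DesignError(f"contrast {self.name}: groups share lanes")
        if len(group_a) < 2 or len(group_b) < 2:
            raise DesignError(
                f"contrast {self.name}: each group needs >= 2 replicates "
                f"(got {len(group_a)} vs {len(group_b)})"
            )
        return group_a, group_b


@dataclass(frozen=True)
class Dispersion:
    """Common NB dispersion phi >= 0; delta = phi/(1+phi) in [0,1)."""

    phi: float

    @property
    def delta(self) -> float:
        return self.phi / (1.0 + self.phi)

    @staticmethod
    def from_delta(delta: float) -> "Dispersion":
        return Dispersion(phi=delta / (1.0 - delta))


# ---------------------------------------------------------------------------
# Common-dispersion estimation (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _group_conditional_loglik(counts: np.ndarray, phi: float) -> float:
    """Summed log P(y_1..y_n | sum y) for NB(size r = 1/phi) lanes.

    ``counts`` is genes x lanes for one replicate group.  Means cancel
    under the conditioning, leaving a Dirichlet-multinomial-type term.
    """
    n_lanes = counts.shape[1]
    totals = counts.sum(axis=1)
    if phi < _POISSON_PHI:
        # Poisson limit: multinomial with equal cell probabilities.
        ll = (
            gammaln(totals + 1).sum()
            - gammaln(counts + 1).sum()
            - totals.sum() * np.log(n_lanes)
        )
        return float(ll)
    r = 1.0 / phi
    ll = (
        gammaln(counts + r).sum()
        - counts.size * gammaln(r)
        - gammaln(counts + 1).sum()
        - gammaln(totals + n_lanes * r).sum()
        + len(totals) * gammaln(n_lanes * r)
        + gammaln(totals + 1).sum()
    )
    return float(ll)


def estimate_common_dispersion(
    matrix: CountMatrix, contrast: Contrast, tol: float = 1e-6
) -> Dispersion:
    """Estimate the common dispersion for one contrast.

    Maximizes the summed conditional NB log-likelihood over genes with a
    bounded 1-D search on delta = phi/(1+phi).  Counts are the (rounded)
    normalized counts, whose library sizes the normalization equalized.
    """
    group_a, group_b = contrast.lanes(matrix)
    counts = np.round(matrix.working_counts().to_numpy(dtype=float))
    if counts.sum() == 0:
        raise EstimationError("all-zero count matrix")
    lanes = list(matrix.lanes)
    idx_a = [lanes.index(l) for l in group_a]
    idx_b = [lanes.index(l) for l in group_b]
    keep = counts[:, idx_a + idx_b].sum(axis=1) > 0
    block_a = counts[np.ix_(keep, idx_a)]
    block_b = counts[np.ix_(keep, idx_b)]
    if block_a.size == 0:
        raise EstimationError("no nonzero genes in contrast lanes")

    def neg_loglik(delta: float) -> float:
        phi = delta / (1.0 - delta)
        return -(
            _group_conditional_loglik(block_a, phi)
            + _group_conditional_loglik(block_b, phi)
        )

    res = minimize_scalar(
        neg_loglik, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": tol},
    )
    return Dispersion.from_delta(float(res.x))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def conditional_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """pmf of the group-A sum given the two-group total, y = 0..total.

    Equalized library sizes; group sums are NB with sizes n_a/phi and
    n_b/phi and a common success probability, so the conditional law is
    beta-binomial BB(total, n_a/phi, n_b/phi); phi -> 0 gives
    Binomial(total, n_a/(n_a+n_b)).
    """
    y = np.arange(total + 1)
    if phi < _POISSON_PHI:
        pmf = binom.pmf(y, total, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (
            gammaln(y + r_a)
            - gammaln(y + 1)
            + gammaln(total - y + r_b)
            - gammaln(total - y + 1)
        )
        pmf = np.exp(logw - logsumexp(logw))
    if n_a == n_b:
        # mirror atoms are exactly equal in exact arithmetic; enforce it so
        # the minimum-likelihood inclusion rule cannot split a mirror pair
        # on floating-point noise at large totals
        pmf = 0.5 * (pmf + pmf[::-1])
    return pmf


def exact_test_gene(
    y_a: int, y_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided exact p for one gene: summed probability of all
    partitions of the total at most as probable as the observed one."""
    total = y_a + y_b
    if total == 0:
        return 1.0
    pmf = conditional_pmf(total, n_a, n_b, phi)
    observed = pmf[y_a]
    # tolerance guards float ties (e.g. the symmetric partner partition);
    # genuinely distinct atoms near the threshold differ by far more
    p = float(pmf[pmf <= observed * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def exact_test(
    matrix: CountMatrix,
    contrast: Contrast,
    dispersion: Dispersion,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene exact-test p-values and log2 fold changes for a contrast.

    log2FC is ``log2((mean_A + c) / (mean_B + c))`` on normalized group
    means with pseudo-count ``c`` per group (avoids infinities when one
    group is all zero); genes with zero total get p = 1, log2FC = 0.
    """
    group_a, group_b = contrast.lanes(matrix)
    counts = matrix.working_counts()
    block_a = np.round(counts.loc[:, group_a].to_numpy(dtype=float)).astype(np.int64)
    block_b = np.round(counts.loc[:, group_b].to_numpy(dtype=float)).astype(np.int64)
    ya = block_a.sum(axis=1)
    yb = block_b.sum(axis=1)
    n_a, n_b = len(group_a), len(group_b)
    phi = dispersion.phi

    pvals = np.ones(len(ya))
    for i, (a, b) in enumerate(zip(ya, yb)):
        if a + b > 0:
            pvals[i] = exact_test_gene(int(a), int(b), n_a, n_b, phi)

    mean_a = counts.loc[:, group_a].mean(axis=1).to_numpy()
    mean_b = counts.loc[:, group_b].mean(axis=1).to_numpy()
    lfc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
    lfc[ya + yb == 0] = 0.0

    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": pvals,
            "sum_treatment": ya,
            "sum_control": yb,
        },
        index=counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def apply_de_filters(
    results: pd.DataFrame,
    depth: pd.DataFrame,
    contrast: Contrast,
    min_median_depth: float = 2.0,
    min_abs_lfc: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the three-part DE filter and assign directions.

    A gene is differentially expressed iff its median depth reaches
    ``min_median_depth`` X in at least one of the two compared groups,
    |log2FC| >= ``min_abs_lfc``, and BH-adjusted p < ``alpha``.
    """
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    col_a = f"{contrast.tissue}:{contrast.treatment}"
    col_b = f"{contrast.tissue}:{contrast.control}"
    depth_a = depth[col_a].reindex(out.index)
    depth_b = depth[col_b].reindex(out.index)
    out["depth_treatment"] = depth_a
    out["depth_control"] = depth_b
    out["depth_pass"] = (depth_a >= min_median_depth) | (depth_b >= min_median_depth)
    out["lfc_pass"] = out["log2fc"].abs() >= min_abs_lfc
    out["p_pass"] = out["padj"] < alpha
    out["de"] = out["depth_pass"] & out["lfc_pass"] & out["p_pass"]
    direction = np.where(
        out["de"] & (out["log2fc"] > 0),
        "up",
        np.where(out["de"] & (out["log2fc"] < 0), "down", "ns"),
    )
    out["direction"] = direction
    return out


def de_gene_sets(filtered: pd.DataFrame) -> dict[str, set[str]]:
    """Up/down/all DE gene-id sets from a filtered result table."""
    up = set(filtered.index[filtered["direction"] == "up"])
    down = set(filtered.index[filtered["direction"] == "down"])
    return {"up": up, "down": down, "all": up | down}


# ---------------------------------------------------------------------------
# Cross-contrast overlaps
# ---------------------------------------------------------------------------


def overlap_sets(
    de_lists: dict[str, set[str]],
    results: dict[str, pd.DataFrame] | None = None,
    top_k: int = 5,
) -> dict:
    """Exclusive/shared membership regions across >= 2 DE gene lists.

    Returns region counts keyed by the sorted tuple of list names sharing
    the region (a partition of the union), pairwise overlap percentages
    under both the union denominator and each per-list denominator, and
    optionally top-``top_k`` genes per region ranked by |log2FC| (largest
    |log2FC| across the contributing lists in ``results``).
    """
    names = sorted(de_lists)
    if len(names) < 2:
        raise DesignError("overlap_sets needs at least two DE lists")
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            members = set.intersection(*(de_lists[n] for n in combo))
            for other in names:
                if other not in combo:
                    members = members - de_lists[other]
            regions[combo] = members

    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        inter = de_lists[a] & de_lists[b]
        union = de_lists[a] | de_lists[b]
        pairwise[(a, b)] = {
            "shared": len(inter),
            "pct_of_union": 100.0 * len(inter) / len(union) if union else np.nan,
            f"pct_of_{a}": 100.0 * len(inter) / len(de_lists[a])
            if de_lists[a]
            else np.nan,
            f"pct_of_{b}": 100.0 * len(inter) / len(de_lists[b])
            if de_lists[b]
            else np.nan,
        }

    top = {}
    if results is not None:
        for combo, members in regions.items():
            if not members:
                continue
            scores = {}
            for g in members:
                best = 0.0
                for n in combo:
                    if n in results and g in results[n].index:
                        best = max(best, abs(float(results[n].loc[g, "log2fc"])))
                scores[g] = best
            ranked = sorted(scores, key=lambda g: (-scores[g], g))
            top[combo] = ranked[:top_k]

    return {
        "region_counts": {c: len(m) for c, m in regions.items()},
        "regions": regions,
        "pairwise": pairwise,
        "top_genes": top,
    }
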