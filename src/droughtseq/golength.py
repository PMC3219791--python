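"""Length-bias-corrected GO enrichment via the Wallenius distribution.

Long transcripts accumulate more reads, so at fixed expression change a
long gene is more likely to be called DE; naive hypergeometric tests then
overcall categories of long genes.  The correction fits a probability
weighting function (PWF) — a monotone map from exonic length to the
probability of being called DE — and scores each category with the
Wallenius noncentral hypergeometric distribution, an urn model where
category members are drawn with odds

    omega = mean PWF inside the category / mean PWF outside.

omega = 1 recovers the central hypergeometric.  The pmf is evaluated by
the exact recursive formulation of the sequential urn process (exact in
float arithmetic for the modest category sizes arising here, where the
classical integral representation gets numerically delicate at large
odds); an independent sequential-urn Monte-Carlo sampler serves as an
oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from droughtseq.errors import DesignError
from droughtseq.de import bh_adjust
from droughtseq.enrich import CategoryDB, is_scaffold_gene

_PWF_EPS = 1e-4


@dataclass
class PWF:
    """Monotone non-decreasing map length -> P(called DE).

    Piecewise-linear interpolation through isotonic-smoothed binned DE
    proportions; values clamped to (eps, 1-eps) so odds stay finite.
    """

    bin_lengths: np.ndarray
    bin_probs: np.ndarray

    def __call__(self, lengths) -> np.ndarray:
        vals = np.interp(
            np.asarray(lengths, dtype=float), self.bin_lengths, self.bin_probs
        )
        return np.clip(vals, _PWF_EPS, 1.0 - _PWF_EPS)


def fit_pwf(lengths, de_flags, n_bins: int = 20) -> PWF:
    """Fit the probability weighting function on (length, is_DE) pairs.

    Genes are split into ``n_bins`` equal-occupancy length bins; the
    per-bin DE proportion is smoothed by isotonic regression (weighted by
    bin occupancy) to enforce monotone non-decrease in length.
    """
    lengths = np.asarray(lengths, dtype=float)
    flags = np.asarray(de_flags, dtype=bool)
    if len(np.unique(lengths)) < 2:
        raise DesignError("PWF fit needs >= 2 distinct lengths")
    overall = flags.mean()
    if flags.all() or not flags.any():
        warnings.warn(
            "all-DE or no-DE input: degenerate constant PWF", stacklevel=2
        )
        const = np.clip(overall, _PWF_EPS, 1.0 - _PWF_EPS)
        return PWF(np.array([lengths.min(), lengths.max()]),
                   np.array([const, const]))

    n_bins = max(1, min(n_bins, len(np.unique(lengths))))
    quantiles = np.quantile(lengths, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1,
                  0, len(edges) - 2)
    xs, ys, ws = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(lengths[mask].mean())
        ys.append(flags[mask].mean())
        ws.append(mask.sum())
    if len(xs) == 1:
        const = np.clip(ys[0], _PWF_EPS, 1.0 - _PWF_EPS)
        return PWF(np.array([lengths.min(), lengths.max()]),
                   np.array([const, const]))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(xs, ys, sample_weight=ws)
    return PWF(np.asarray(xs), np.asarray(fitted))


# ---------------------------------------------------------------------------
# Wallenius noncentral hypergeometric
# ---------------------------------------------------------------------------


def _wallenius_distribution(
    n_universe: int, k_category: int, n_draws: int, omega: float
) -> np.ndarray:
    """Full pmf vector P(X = 0..K) by the exact urn recursion.

    The draw process is Markov in (reds drawn, total drawn): given x reds
    after j draws, the next ball is red with probability
    omega (K - x) / (omega (K - x) + (N - K) - (j - x)).  Propagating the
    state distribution over the n draws evaluates the pmf to float
    precision with no quadrature error (the integral representation gets
    numerically delicate at large odds).
    """
    whites = n_universe - k_category
    f = np.zeros(k_category + 1)
    f[0] = 1.0
    for j in range(n_draws):
        x = np.arange(k_category + 1)
        red_rem = (k_category - x).astype(float)
        white_rem = np.maximum(whites - (j - x), 0).astype(float)
        denom = omega * red_rem + white_rem
        with np.errstate(invalid="ignore", divide="ignore"):
            p_red = np.where(denom > 0, omega * red_rem / np.where(
                denom > 0, denom, 1.0), 0.0)
        nxt = f * (1.0 - p_red)
        nxt[1:] += (f * p_red)[:-1]
        f = nxt
    return f


def wallenius_pmf(
    k, n_universe: int, k_category: int, n_draws: int, omega: float
) -> np.ndarray | float:
    """Wallenius noncentral hypergeometric pmf.

    Parameters follow the urn convention: ``n_universe`` balls of which
    ``k_category`` are red, ``n_draws`` sequential draws with red odds
    ``omega``; returns P(X = k) for scalar or array ``k``.
    """
    if omega <= 0:
        raise DesignError("Wallenius odds ratio must be > 0")
    if n_draws > n_universe:
        raise DesignError("cannot draw more balls than the urn holds")
    dist = _wallenius_distribution(n_universe, k_category, n_draws, omega)
    scalar = np.isscalar(k)
    ks = np.atleast_1d(np.asarray(k, dtype=int))
    out = np.zeros(len(ks), dtype=float)
    valid = (ks >= 0) & (ks <= k_category)
    out[valid] = dist[ks[valid]]
    return float(out[0]) if scalar else out


def wallenius_sf(
    observed: int, n_universe: int, k_category: int, n_draws: int, omega: float
) -> float:
    """Upper tail P[X >= observed] by summing the pmf."""
    hi = min(n_draws, k_category)
    if observed <= max(0, n_draws - (n_universe - k_category)):
        return 1.0
    if observed > hi:
        return 0.0
    ks = np.arange(observed, hi + 1)
    return float(min(1.0, wallenius_pmf(ks, n_universe, k_category,
                                        n_draws, omega).sum()))


def wallenius_urn_sample(
    n_universe: int, k_category: int, n_draws: int, omega: float,
    size: int, rng: np.random.Generator,
) -> np.ndarray:
    """Sequential-urn Monte-Carlo draws from the Wallenius law.

    Independent oracle for the integral evaluation, and the fallback
    estimator when quadrature fails.
    """
    red = np.full(size, k_category, dtype=float)
    white = np.full(size, n_universe - k_category, dtype=float)
    drawn = np.zeros(size, dtype=np.int64)
    for _ in range(n_draws):
        p_red = omega * red / (omega * red + white)
        take = rng.random(size) < p_red
        red -= take
        white -= ~take
        drawn += take
    return drawn


# ---------------------------------------------------------------------------
# GO loading and enrichment
# ---------------------------------------------------------------------------


def load_go_pairs(path) -> CategoryDB:
    """Read (gene, term) pairs; collapse gene-model ``.N`` suffixes, drop
    scaffold-pattern ids, and keep only unique gene-term pairs."""
    df = pd.read_csv(path, sep="\t")
    gene_col, term_col = df.columns[:2]
    df[gene_col] = df[gene_col].astype(str).str.replace(
        r"\.\d+$", "", regex=True
    )
    df = df[~df[gene_col].map(is_scaffold_gene)].drop_duplicates()
    return CategoryDB.from_pairs(
        df.rename(columns={gene_col: "gene", term_col: "category"}), kind="go"
    )


def go_enrich(
    de_set: set,
    go_db: CategoryDB,
    gene_lengths: pd.Series,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-category Wallenius enrichment p-values with length-bias odds.

    The universe is the length-annotated gene set; categories entirely
    outside it are skipped with a warning.  Significance is called on the
    raw Wallenius p (p <= alpha); a BH-adjusted column is also reported.
    """
    universe = set(gene_lengths.index)
    de_in = de_set & universe
    if not de_in:
        raise DesignError("no DE genes in the length-annotated universe")
    pwf = fit_pwf(
        gene_lengths.to_numpy(),
        gene_lengths.index.isin(de_in),
        n_bins=n_bins,
    )
    weights = pd.Series(pwf(gene_lengths.to_numpy()), index=gene_lengths.index)
    n_total, n_draws = len(universe), len(de_in)

    rows = []
    for cat in sorted(go_db.categories):
        members = go_db.categories[cat] & universe
        if not members:
            warnings.warn(
                f"category {cat} has no length-annotated genes; skipped",
                stacklevel=2,
            )
            continue
        k = len(members)
        observed = len(de_in & members)
        inside = weights.loc[list(members)].mean()
        outside_idx = universe - members
        outside = weights.loc[list(outside_idx)].mean() if outside_idx else inside
        omega = inside / outside
        p = wallenius_sf(observed, n_total, k, n_draws, omega)
        rows.append(
            {
                "category": cat,
                "size": k,
                "observed": observed,
                "expected_central": n_draws * k / n_total,
                "omega": omega,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] <= alpha
    out.attrs["n_de_in_universe"] = n_draws
    out.attrs["n_universe"] = n_total
    return out
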