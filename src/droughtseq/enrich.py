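"""Z-score gene-set enrichment with an exact hypergeometric companion.

One engine serves metabolic pathways, transcription-factor families and
promoter cis-element presence sets.  For a DE list of size n (after
intersection with the category universe), a category of size K in a
universe of N genes has expected overlap E = nK/N; the Z-score is
(O - E)/sqrt(V) with V either the hypergeometric variance
n(K/N)(1-K/N)(N-n)/(N-1) (default) or the Poisson approximation V = E.
A category is significant when Z >= 2, p <= 0.05 and E > 1; for motif
enrichment the p entering the criterion is the BH-adjusted exact
hypergeometric upper tail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

from droughtseq.errors import DesignError, FormatError
from droughtseq.de import bh_adjust

#: Gene models on unplaced scaffolds (id shape like ``Sb0012s002010``)
#: are dropped from every category universe on load.
SCAFFOLD_RE = re.compile(r"^Sb\d+s\d+", re.IGNORECASE)


def is_scaffold_gene(gene_id: str) -> bool:
    return bool(SCAFFOLD_RE.match(gene_id))


@dataclass
class CategoryDB:
    """Gene-set database: category id -> member genes, plus a universe.

    The universe is the set of unique genes across all categories (never
    the sum of category sizes); genes may belong to several categories.
    Scaffold-pattern gene ids are removed when building from pairs.
    """

    categories: dict[str, set[str]]
    kind: str = "generic"
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe: set[str] = set().union(*self.categories.values()) \
            if self.categories else set()

    @classmethod
    def from_pairs(
        cls, pairs: pd.DataFrame, kind: str = "generic",
        gene_col: str = "gene", category_col: str = "category",
        drop_scaffolds: bool = True,
    ) -> "CategoryDB":
        if gene_col not in pairs.columns or category_col not in pairs.columns:
            raise FormatError(
                f"category table needs columns {gene_col!r} and {category_col!r}"
            )
        df = pairs[[gene_col, category_col]].dropna().drop_duplicates()
        if drop_scaffolds:
            df = df[~df[gene_col].map(is_scaffold_gene)]
        cats = {
            str(c): set(g)
            for c, g in df.groupby(category_col)[gene_col]
        }
        return cls(categories=cats, kind=kind)

    @classmethod
    def read_tsv(cls, path, kind: str = "generic") -> "CategoryDB":
        return cls.from_pairs(pd.read_csv(path, sep="\t"), kind=kind)

    def to_pairs(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "category": c}
            for c in sorted(self.categories)
            for g in sorted(self.categories[c])
        ]
        return pd.DataFrame(rows, columns=["gene", "category"])

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class EnrichmentCriteria:
    """Three-part significance rule: Z >= min_z, p <= max_p, E > min_expected."""

    min_z: float = 2.0
    max_p: float = 0.05
    min_expected: float = 1.0
    #: which p enters the rule: "normal" (one-sided Z p), "hypergeom",
    #: or their BH-adjusted variants "normal_adj" / "hypergeom_adj"
    p_source: str = "normal"


def expected_count(de_set: set, category: set, universe: set) -> float:
    """E = n * K / N with n = |DE ∩ universe|, K = |category|, N = |universe|."""
    n_universe = len(universe)
    if n_universe == 0:
        raise DesignError("empty universe")
    n = len(de_set & universe)
    k = len(category & universe)
    return n * k / n_universe


def zscore(
    observed: int, n: int, k: int, n_universe: int,
    variance_model: str = "hypergeometric",
) -> tuple[float, float]:
    """Z = (O - E)/sqrt(V) and its one-sided (enrichment) normal p.

    Degenerate configurations (V = 0: empty or whole-universe category,
    empty or whole-universe DE list) return (nan, 1.0).
    """
    expected = n * k / n_universe
    if variance_model == "hypergeometric":
        variance = (
            n * (k / n_universe) * (1.0 - k / n_universe)
            * (n_universe - n) / (n_universe - 1)
            if n_universe > 1
            else 0.0
        )
    elif variance_model == "poisson":
        variance = expected
    else:
        raise DesignError(f"unknown variance model {variance_model!r}")
    if variance <= 0:
        return float("nan"), 1.0
    z = (observed - expected) / np.sqrt(variance)
    return float(z), float(norm.sf(z))


def hypergeom_p(observed: int, n: int, k: int, n_universe: int) -> float:
    """Exact upper-tail P[X >= O] for overlap of an n-draw with a K-category."""
    if observed <= 0:
        return 1.0
    return float(hypergeom.sf(observed - 1, n_universe, k, n))


def enrich(
    de_set: set,
    db: CategoryDB,
    criteria: EnrichmentCriteria | None = None,
    variance_model: str = "hypergeometric",
) -> pd.DataFrame:
    """Score every category of ``db`` against a DE gene list.

    DE genes outside the database universe are dropped before computing n.
    Output columns: observed, expected, z, p_normal, p_hypergeom, their
    BH-adjusted versions, a ``degenerate`` flag (undefined Z) and the
    ``significant`` flag from the three-part criterion.
    """
    if criteria is None:
        criteria = EnrichmentCriteria()
    if not de_set:
        raise DesignError("empty DE set")
    if not db.universe:
        raise DesignError("empty category universe (after scaffold filtering)")
    universe = db.universe
    de_in = de_set & universe
    n, n_universe = len(de_in), len(universe)

    rows = []
    for cat in sorted(db.categories):
        members = db.categories[cat] & universe
        k = len(members)
        observed = len(de_in & members)
        expected = n * k / n_universe
        z, p_norm = zscore(observed, n, k, n_universe, variance_model)
        p_hyp = hypergeom_p(observed, n, k, n_universe)
        rows.append(
            {
                "category": cat,
                "size": k,
                "observed": observed,
                "expected": expected,
                "z": z,
                "p_normal": p_norm,
                "p_hypergeom": p_hyp,
                "degenerate": not np.isfinite(z),
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out["p_normal_adj"] = bh_adjust(out["p_normal"].to_numpy())
    out["p_hypergeom_adj"] = bh_adjust(out["p_hypergeom"].to_numpy())
    p_col = {
        "normal": "p_normal",
        "hypergeom": "p_hypergeom",
        "normal_adj": "p_normal_adj",
        "hypergeom_adj": "p_hypergeom_adj",
    }[criteria.p_source]
    out["significant"] = (
        ~out["degenerate"]
        & (out["z"] >= criteria.min_z)
        & (out[p_col] <= criteria.max_p)
        & (out["expected"] > criteria.min_expected)
    )
    out.attrs["n_de_in_universe"] = n
    out.attrs["n_universe"] = n_universe
    out.attrs["variance_model"] = variance_model
    out.attrs["p_source"] = criteria.p_source
    out.attrs["adjustment"] = "benjamini-hochberg"
    return out
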