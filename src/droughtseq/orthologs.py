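"""Cross-species triage of drought-responsive genes of unknown function.

Given the focal species' DE gene set, per-gene descriptions, a table of
putative ortholog pairs to other species, and per-species published
drought-responsive gene lists, the decision tree keeps a focal gene for a
species when:

  (a) the focal gene is DE and of unknown function (its description
      matches 'hypothetical', 'expressed', 'predicted' or
      'uncharacterized' as a whole word, case-insensitively);
  (b) it has at least one ortholog in that species and ALL its orthologs
      there are of unknown function; and
  (c) at least one of those orthologs is on the species' published
      drought-responsive list.

Direction of expression is deliberately ignored — drought severity and
platform differences make cross-species sign comparisons unreliable.
The per-species gene lists are then summarized as multi-species overlap
regions (which focal genes recur in 2, 3, ... species).
"""

from __future__ import annotations

import itertools
import re
import warnings

import pandas as pd

from droughtseq.errors import DesignError, FormatError

UNKNOWN_KEYWORDS = ("hypothetical", "expressed", "predicted", "uncharacterized")

ORTHOLOG_COLUMNS = ("focal_gene", "species", "ortholog_gene",
                    "ortholog_description")


def call_unknown(
    descriptions: pd.Series,
    keywords: tuple[str, ...] = UNKNOWN_KEYWORDS,
) -> pd.DataFrame:
    """Flag unknown-function genes by whole-word keyword match.

    Matching is case-insensitive and whole-word ('expressed' must not hit
    'overexpressed').  Returns a DataFrame indexed like ``descriptions``
    with ``is_unknown`` and the comma-joined ``matched`` keywords.
    """
    patterns = {
        kw: re.compile(rf"\b{re.escape(kw)}\b", re.IGNORECASE)
        for kw in keywords
    }
    rows = []
    for desc in descriptions.fillna(""):
        matched = [kw for kw, pat in patterns.items() if pat.search(desc)]
        rows.append({"is_unknown": bool(matched), "matched": ",".join(matched)})
    return pd.DataFrame(rows, index=descriptions.index)


def decision_tree(
    focal_de: set,
    descriptions: pd.Series,
    ortholog_table: pd.DataFrame,
    drought_lists: dict[str, set],
    keywords: tuple[str, ...] = UNKNOWN_KEYWORDS,
    require_all_species: bool = False,
) -> pd.DataFrame:
    """Run the conserved-unknown decision tree once per species.

    ``ortholog_table`` needs columns (focal_gene, species, ortholog_gene,
    ortholog_description).  Branch (b) is evaluated per species: the
    annotation status of a gene's orthologs in other species does not
    affect the call for the species under test, unless
    ``require_all_species`` is set, in which case a focal gene must have
    all-unknown orthologs in every species where it has any.

    Returns qualifying (focal_gene, species, ortholog_gene) pairs — the
    orthologs on the species' drought list — one row each.  Species
    without a drought list are skipped with a warning.
    """
    missing = [c for c in ORTHOLOG_COLUMNS if c not in ortholog_table.columns]
    if missing:
        raise FormatError(f"ortholog table missing columns: {missing}")
    unknown_focal = call_unknown(descriptions, keywords)
    candidates = focal_de & set(
        unknown_focal.index[unknown_focal["is_unknown"]]
    )
    table = ortholog_table.drop_duplicates(
        subset=["focal_gene", "species", "ortholog_gene"]
    )
    ortho_unknown = call_unknown(
        table["ortholog_description"], keywords
    )["is_unknown"].to_numpy()
    table = table.assign(ortholog_unknown=ortho_unknown)

    if require_all_species:
        ok = table.groupby("focal_gene")["ortholog_unknown"].all()
        globally_clean = set(ok.index[ok])

    rows = []
    for species, sub in table.groupby("species"):
        if species not in drought_lists:
            warnings.warn(f"no drought list for species {species!r}; skipped",
                          stacklevel=2)
            continue
        drought = drought_lists[species]
        for focal, genes in sub.groupby("focal_gene"):
            if focal not in candidates:
                continue
            if not genes["ortholog_unknown"].all():
                continue
            if require_all_species and focal not in globally_clean:
                continue
            responsive = [
                g for g in genes["ortholog_gene"] if g in drought
            ]
            for ortholog in sorted(responsive):
                rows.append(
                    {
                        "focal_gene": focal,
                        "species": species,
                        "ortholog_gene": ortholog,
                    }
                )
    return pd.DataFrame(rows, columns=["focal_gene", "species",
                                       "ortholog_gene"])


def pairs_to_gene_sets(pairs: pd.DataFrame) -> dict[str, set]:
    """Per-species sets of focal genes from a decision-tree pair table."""
    return {
        species: set(sub["focal_gene"])
        for species, sub in pairs.groupby("species")
    }


def species_overlap(gene_sets: dict[str, set]) -> dict:
    """Multi-species overlap regions of per-species focal-gene sets.

    Returns exclusive region counts (a partition of the union, keyed by
    the sorted species combination), the genes found in every species,
    and the genes found in at least two.
    """
    names = sorted(gene_sets)
    if len(names) < 2:
        raise DesignError("species_overlap needs >= 2 species lists")
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            members = set.intersection(*(gene_sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    members -= gene_sets[other]
            regions[combo] = members
    in_all = set.intersection(*(gene_sets[n] for n in names))
    union = set.union(*(gene_sets[n] for n in names))
    in_two_plus = {
        g for g in union
        if sum(g in gene_sets[n] for n in names) >= 2
    }
    return {
        "region_counts": {c: len(m) for c, m in regions.items()},
        "regions": regions,
        "in_all_species": in_all,
        "in_two_or_more": in_two_plus,
    }
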