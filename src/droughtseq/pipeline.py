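"""End-to-end orchestration: one config, deterministic runs, a manifest.

``run_all`` executes normalize -> differential expression -> pathway /
TF / GO / motif enrichment -> reaction coverage -> cross-talk network ->
ortholog triage, writing every stage's table under the output directory
and a manifest recording thresholds, input hashes and output files.
Inputs either come from flat files or are generated in place by the
synthetic-data module when the config carries a ``simulate`` block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from droughtseq import __version__
from droughtseq.de import (
    Contrast,
    apply_de_filters,
    de_gene_sets,
    estimate_common_dispersion,
    exact_test,
    overlap_sets,
)
from droughtseq.enrich import CategoryDB, EnrichmentCriteria, enrich
from droughtseq.errors import ConfigError
from droughtseq.golength import go_enrich, load_go_pairs
from droughtseq.orthologs import decision_tree, pairs_to_gene_sets, species_overlap
from droughtseq.pathnet import (
    PathwayDB,
    build_network,
    collapse,
    hormone_subnetwork,
    reaction_coverage,
    write_graphml,
    write_sif,
)
from droughtseq.promoters import (
    extract_upstream,
    load_motifs,
    motif_enrichment,
    scan_motifs,
)
from droughtseq.qc import (
    call_expressed,
    compute_depth,
    depth_bins,
    quantile_normalize,
    read_counts,
    replicate_correlation,
)
from droughtseq.simulate import SimulationConfig, simulate_annotations, simulate_counts

log = logging.getLogger("droughtseq")

INPUT_KEYS = (
    "counts", "sample_sheet", "annotation", "pathways", "collapse_map",
    "go", "tf", "motifs", "genome", "gff", "orthologs",
)


@dataclass
class RunConfig:
    """Paths, contrast definitions and thresholds for one pipeline run."""

    outdir: str = "droughtseq_out"
    seed: int = 0
    #: thresholds (defaults are the study's criteria)
    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    min_median_depth: float = 2.0
    min_z: float = 2.0
    min_expected: float = 1.0
    variance_model: str = "hypergeometric"
    top_k: int = 5
    read_length: int = 50
    min_raw: int = 2
    promoter_window: int = 1000
    #: list of {name, tissue, treatment, control}; empty = the standard four
    contrasts: list = field(default_factory=list)
    #: flat-file inputs keyed by INPUT_KEYS; drought lists keyed by species
    inputs: dict = field(default_factory=dict)
    drought_lists: dict = field(default_factory=dict)
    #: when present, inputs are generated with these SimulationConfig fields
    simulate: dict | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def contrast_objects(self) -> list[Contrast]:
        if not self.contrasts:
            from droughtseq.simulate import DEFAULT_CONTRASTS

            return list(DEFAULT_CONTRASTS)
        return [Contrast(**c) for c in self.contrasts]


def validate_config(config: RunConfig) -> list[str]:
    """Exhaustive report of config problems; empty means valid."""
    problems = []
    if not 0 < config.alpha <= 1:
        problems.append(f"alpha must be in (0, 1]: {config.alpha}")
    if config.min_abs_lfc < 0:
        problems.append("min_abs_lfc must be >= 0")
    if config.min_median_depth < 0:
        problems.append("min_median_depth must be >= 0")
    if config.variance_model not in ("hypergeometric", "poisson"):
        problems.append(f"unknown variance_model {config.variance_model!r}")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    for c in config.contrasts:
        missing = {"name", "tissue", "treatment", "control"} - set(c)
        if missing:
            problems.append(f"contrast {c}: missing fields {sorted(missing)}")
    if config.simulate is None:
        for key in ("counts", "sample_sheet", "annotation"):
            path = config.inputs.get(key)
            if path is None:
                problems.append(f"missing required input {key!r}")
            elif not Path(path).exists():
                problems.append(f"input file not found: {key} = {path}")
        sheet_path = config.inputs.get("sample_sheet")
        if sheet_path and Path(sheet_path).exists():
            sheet = pd.read_csv(sheet_path, sep="\t")
            for c in config.contrast_objects():
                for grp in (c.treatment, c.control):
                    n = int(
                        ((sheet["tissue"] == c.tissue)
                         & (sheet["treatment"] == grp)).sum()
                    )
                    if n < 2:
                        problems.append(
                            f"contrast {c.name}: group {grp} has {n} "
                            "replicates (needs >= 2)"
                        )
    else:
        try:
            SimulationConfig(**{**config.simulate, "seed": config.seed})
        except Exception as exc:  # surfaced as a report entry, not a raise
            problems.append(f"invalid simulate block: {exc}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        matrix, truth = simulate_counts(sim)
        annotations = simulate_annotations(sim, truth)
        indir = outdir / "inputs"
        indir.mkdir(parents=True, exist_ok=True)
        matrix.counts.to_csv(indir / "counts.tsv", sep="\t")
        matrix.samples.to_csv(indir / "sample_sheet.tsv", sep="\t",
                              index=False)
        annotations.write_all(indir)
        truth.to_json(indir / "ground_truth.json")
        matrix = read_counts(indir / "counts.tsv", indir / "sample_sheet.tsv")
        annotation = pd.read_csv(indir / "annotation.tsv", sep="\t",
                                 index_col=0)
        pathway_db = PathwayDB.read_tsv(indir / "pathways.tsv",
                                        indir / "collapse_map.tsv")
        go_db = load_go_pairs(indir / "go.tsv")
        tf_db = CategoryDB.read_tsv(indir / "tf.tsv", kind="tf_family")
        motifs = load_motifs(indir / "motifs.tsv")
        genome_path, gff_path = indir / "genome.fa", indir / "genes.gff3"
        ortho = pd.read_csv(indir / "orthologs.tsv", sep="\t")
        drought = {
            s: set(pd.read_csv(indir / f"drought_{s}.tsv", sep="\t")["gene"])
            for s in sorted(annotations.drought_lists)
        }
        return matrix, annotation, pathway_db, go_db, tf_db, motifs, \
            genome_path, gff_path, ortho, drought

    inp = config.inputs
    matrix = read_counts(inp["counts"], inp["sample_sheet"])
    annotation = pd.read_csv(inp["annotation"], sep="\t", index_col=0)
    pathway_db = (
        PathwayDB.read_tsv(inp["pathways"], inp.get("collapse_map"))
        if "pathways" in inp else None
    )
    go_db = load_go_pairs(inp["go"]) if "go" in inp else None
    tf_db = (
        CategoryDB.read_tsv(inp["tf"], kind="tf_family")
        if "tf" in inp else None
    )
    motifs = load_motifs(inp["motifs"]) if "motifs" in inp else None
    genome_path = inp.get("genome")
    gff_path = inp.get("gff")
    ortho = (
        pd.read_csv(inp["orthologs"], sep="\t") if "orthologs" in inp else None
    )
    drought = {
        s: set(pd.read_csv(p, sep="\t")["gene"])
        for s, p in sorted(config.drought_lists.items())
    }
    return matrix, annotation, pathway_db, go_db, tf_db, motifs, \
        genome_path, gff_path, ortho, drought


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to
    ``outdir/manifest.json``).  Any stage failure raises with a
    stage-tagged message; outputs written before the failure remain."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "load"

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs[name] = _sha256(path)
        return path

    try:
        (matrix, annotation, pathway_db, go_db, tf_db, motifs,
         genome_path, gff_path, ortho, drought) = _load_inputs(config, outdir)
        contrasts = config.contrast_objects()

        stage = "qc"
        expressed, breakdown = call_expressed(
            matrix, annotation, min_raw=config.min_raw
        )
        _emit("expressed_breakdown.tsv",
              lambda p: breakdown.to_csv(p, sep="\t"))
        log.info("qc: %d expressed genes", len(expressed))

        stage = "normalize"
        quantile_normalize(matrix)
        _emit("normalized_counts.tsv",
              lambda p: matrix.normalized.to_csv(p, sep="\t"))
        depth = compute_depth(
            matrix, annotation["length"], read_length=config.read_length
        )
        _emit("depth_bins.tsv",
              lambda p: depth_bins(depth).to_csv(p, sep="\t"))
        _emit("replicate_correlation.tsv",
              lambda p: replicate_correlation(matrix).to_csv(p, sep="\t",
                                                             index=False))

        stage = "de"
        de_tables: dict[str, pd.DataFrame] = {}
        de_sets: dict[str, set] = {}
        for contrast in contrasts:
            dispersion = estimate_common_dispersion(matrix, contrast)
            results = exact_test(matrix, contrast, dispersion)
            filtered = apply_de_filters(
                results, depth, contrast,
                min_median_depth=config.min_median_depth,
                min_abs_lfc=config.min_abs_lfc,
                alpha=config.alpha,
            )
            de_tables[contrast.name] = filtered
            de_sets[contrast.name] = de_gene_sets(filtered)["all"]
            _emit(f"de_{contrast.name}.tsv",
                  lambda p, t=filtered: t.to_csv(p, sep="\t"))
            log.info("de %s: phi=%.4f, %d DE genes", contrast.name,
                     dispersion.phi, len(de_sets[contrast.name]))
        overlaps = overlap_sets(de_sets, de_tables, top_k=config.top_k)
        _emit("de_overlaps.json", lambda p: _write_overlap_json(overlaps, p))

        de_union = set().union(*de_sets.values()) if de_sets else set()
        criteria = EnrichmentCriteria(
            min_z=config.min_z, max_p=config.alpha,
            min_expected=config.min_expected,
        )

        stage = "enrich-pathways"
        if pathway_db is not None and de_union:
            collapsed = collapse(pathway_db)
            pwy_db = CategoryDB(
                categories={p: collapsed.pathway_genes(p)
                            for p in collapsed.pathways()},
                kind="pathway",
            )
            _emit("enrich_pathways.tsv", lambda p: enrich(
                de_union, pwy_db, criteria, config.variance_model
            ).to_csv(p, sep="\t"))
            stage = "reaction-coverage"
            _emit("reaction_coverage.tsv", lambda p: reaction_coverage(
                collapsed, de_union
            ).to_csv(p, sep="\t"))

        stage = "enrich-tf"
        if tf_db is not None and de_union:
            _emit("enrich_tf.tsv", lambda p: enrich(
                de_union, tf_db, criteria, config.variance_model
            ).to_csv(p, sep="\t"))

        stage = "enrich-go"
        if go_db is not None and de_union:
            lengths = annotation["length"]
            _emit("enrich_go.tsv", lambda p: go_enrich(
                de_union, go_db, lengths, alpha=config.alpha
            ).to_csv(p, sep="\t"))

        stage = "scan-promoters"
        if motifs is not None and genome_path is not None:
            promoters = extract_upstream(
                genome_path, gff_path, window=config.promoter_window
            )
            hits = scan_motifs(promoters, motifs)
            _emit("motif_hits.tsv",
                  lambda p: hits.to_csv(p, sep="\t", index=False))
            stage = "enrich-motifs"
            if de_union:
                universe = set(promoters.sequences)
                _emit("enrich_motifs.tsv", lambda p: motif_enrichment(
                    hits, motifs, de_union, universe
                ).to_csv(p, sep="\t"))

        stage = "network"
        if pathway_db is not None:
            collapsed = collapse(pathway_db)
            for contrast in contrasts:
                graph = build_network(collapsed, de_tables[contrast.name])
                _emit(f"network_{contrast.name}.graphml",
                      lambda p, g=graph: write_graphml(g, p))
                hormones = {
                    n for n, d in graph.nodes(data=True) if d["is_hormone"]
                }
                if len(hormones) >= 2:
                    sub = hormone_subnetwork(graph, hormones)
                    _emit(
                        f"hormone_network_{contrast.name}.sif",
                        lambda p, g=sub: write_sif(
                            g, p,
                            node_attr_path=str(p) + ".nodes.tsv",
                            edge_attr_path=str(p) + ".edges.tsv",
                        ),
                    )

        stage = "orthologs"
        if ortho is not None and drought:
            pairs = decision_tree(
                de_union, annotation["description"], ortho, drought
            )
            _emit("ortholog_pairs.tsv",
                  lambda p: pairs.to_csv(p, sep="\t", index=False))
            sets_by_species = pairs_to_gene_sets(pairs)
            if len(sets_by_species) >= 2:
                overlap = species_overlap(sets_by_species)
                _emit("ortholog_overlap.json",
                      lambda p: _write_species_overlap_json(overlap, p))
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    stage = "manifest"
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "min_abs_lfc": config.min_abs_lfc,
            "min_median_depth": config.min_median_depth,
            "min_z": config.min_z,
            "min_expected": config.min_expected,
            "variance_model": config.variance_model,
        },
        "outputs": dict(sorted(outputs.items())),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _write_overlap_json(overlaps: dict, path) -> None:
    payload = {
        "region_counts": {
            "+".join(combo): n
            for combo, n in sorted(overlaps["region_counts"].items())
        },
        "pairwise": {
            f"{a}|{b}": stats
            for (a, b), stats in sorted(overlaps["pairwise"].items())
        },
        "top_genes": {
            "+".join(combo): genes
            for combo, genes in sorted(overlaps["top_genes"].items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _write_species_overlap_json(overlap: dict, path) -> None:
    payload = {
        "region_counts": {
            "+".join(combo): n
            for combo, n in sorted(overlap["region_counts"].items())
        },
        "in_all_species": sorted(overlap["in_all_species"]),
        "in_two_or_more": sorted(overlap["in_two_or_more"]),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
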