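"""Synthetic-data generator emulating the study design, with ground truth.

The generator emulates a 2-tissue (shoot, root) x 2 treatment/control
pair (ABA vs NaOH, PEG vs H2O) x 3-biological-replicate bulk RNA-seq
experiment at the gene-count level (alignment is out of scope; the
pipeline consumes per-gene counts).  It produces every input the
downstream stages consume — counts + sample sheet, gene annotation,
pathway/GO/TF databases, a motif set, a genome FASTA + GFF3 pair with
motif instances planted in promoter windows, and a cross-species
ortholog table — together with a :class:`GroundTruth` record of what was
planted, so recovery can be scored exactly.

Counts are negative binomial with a log-normal baseline mean per gene, a
common dispersion phi (Var = mu + phi mu^2; phi = 0 gives Poisson),
spiked log2 fold changes on a fraction of genes (each in one contrast),
a fraction of everywhere-silent genes, and a per-replicate library-size
scale factor (default: run 3 scaled x1.3, mimicking a base-caller
upgrade mid-study) that quantile normalization must remove.

Determinism: one global seed; every sub-generator derives a child seed
from it, so fixed seed means bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from droughtseq.de import Contrast
from droughtseq.errors import ConfigError, DesignError
from droughtseq.pathnet import PathwayDB
from droughtseq.promoters import IUPAC, Motif, PromoterSet, reverse_complement
from droughtseq.qc import CountMatrix
from droughtseq.enrich import CategoryDB

TISSUES = ("shoot", "root")
TREATMENT_PAIRS = (("ABA", "NaOH"), ("PEG", "H2O"))
SPECIES = ("rice", "maize", "arabidopsis")

DEFAULT_CONTRASTS = tuple(
    Contrast(name=f"{tissue}_{trt}", tissue=tissue, treatment=trt, control=ctl)
    for tissue in TISSUES
    for trt, ctl in TREATMENT_PAIRS
)

#: Cis-element set scanned by default: ABA-, dehydration- and
#: low-temperature-responsive elements plus common core promoter motifs,
#: several with IUPAC degeneracy.
DEFAULT_MOTIFS = (
    Motif("ABRE", "ACGTGKC", "synthetic"),
    Motif("DRE", "RCCGAC", "synthetic"),
    Motif("CGTCA-motif", "CGTCA", "synthetic"),
    Motif("LTRE", "CCGAAA", "synthetic"),
    Motif("MYB-core", "WAACCA", "synthetic"),
    Motif("GT1-box", "GRWAAW", "synthetic"),
    Motif("CCAAT-box", "CCAAT", "synthetic"),
    Motif("W-box", "TTGACY", "synthetic"),
)

_UNKNOWN_DESCRIPTIONS = (
    "putative uncharacterized protein",
    "hypothetical protein",
    "similar to expressed protein",
    "predicted protein",
    "uncharacterized conserved protein",
)

_KNOWN_DESCRIPTIONS = (
    "peroxidase 6",
    "late embryogenesis abundant protein",
    "dehydrin family protein",
    "aquaporin PIP2",
    "sucrose synthase 2",
    "heat shock protein 70",
    "chlorophyll a/b binding protein",
    "constitutively overexpressed reporter line marker",
    "9-cis-epoxycarotenoid dioxygenase",
    "sugar substrate transporter",
)


@dataclass
class SimulationConfig:
    """Study-design and generator parameters (defaults are the emulated
    study conditions; see the methods note for the rationale of values the
    design itself does not fix)."""

    n_genes: int = 10000
    n_replicates: int = 3
    #: log-normal baseline mean expression, calibrated to the study's
    #: reported read-count distribution: median ~200 counts/lane gives
    #: ~4800 total reads for the median gene over 24 lanes, ~40-50% of
    #: genes in the 5,001-50,000 total-read decade and >80% above 500
    mean_log_mu: float = math.log(200.0)
    mean_log_sigma: float = 1.0
    dispersion: float = 0.1
    spike_fraction: float = 0.05
    spike_lfc_values: tuple[float, ...] = (-2.0, -1.0, 1.0, 2.0)
    #: when set, every spiked gene perturbs this contrast; default spreads
    #: spikes uniformly over the four contrasts
    spike_contrast: str | None = None
    #: when set, spiked genes get this baseline mean instead of a
    #: log-normal draw (controlled spike-in experiments)
    spike_baseline_mean: float | None = None
    silent_fraction: float = 0.17
    read_length: int = 50
    #: log-normal exonic lengths, floored
    length_log_mu: float = math.log(1200.0)
    length_log_sigma: float = 0.6
    min_length: int = 200
    #: per-replicate library scale (replicate index -> factor)
    lane_scale: dict = field(default_factory=lambda: {3: 1.3})
    #: annotation-side sizes and planted-signal strength
    n_pathways: int = 40
    n_planted_pathways: int = 4
    n_go_terms: int = 60
    n_planted_go: int = 5
    n_tf_families: int = 20
    n_planted_tf: int = 3
    enrichment_odds: float = 5.0
    motif_background_prob: float = 0.15
    n_scaffold_decoys: int = 5
    promoter_window: int = 1000
    n_conserved_unknown: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_fraction + self.silent_fraction > 1.0:
            raise ConfigError("spike_fraction + silent_fraction must be <= 1")
        if self.n_replicates < 2:
            raise DesignError("tested contrasts need >= 2 replicates")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.min_length <= 0 or self.read_length <= 0:
            raise ConfigError("lengths must be positive")

    def contrasts(self) -> tuple[Contrast, ...]:
        return DEFAULT_CONTRASTS

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for tissue in TISSUES:
            for trt, ctl in TREATMENT_PAIRS:
                for treatment in (trt, ctl):
                    for rep in range(1, self.n_replicates + 1):
                        rows.append(
                            {
                                "lane": f"{tissue}_{treatment}_r{rep}",
                                "tissue": tissue,
                                "treatment": treatment,
                                "replicate": rep,
                            }
                        )
        sheet = pd.DataFrame(rows).drop_duplicates("lane")
        return sheet.set_index("lane", drop=False)


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact recovery scoring."""

    true_lfc: pd.DataFrame               # genes x contrasts
    spiked_genes: set
    silent_genes: set
    gene_means: pd.Series
    gene_lengths: pd.Series
    enriched_categories: dict = field(default_factory=dict)  # kind -> set
    motif_positions: dict = field(default_factory=dict)  # gene -> [(name,pos)]
    conserved_unknown: dict = field(default_factory=dict)  # species -> set
    conserved_pairs: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "spiked_genes": sorted(self.spiked_genes),
            "silent_genes": sorted(self.silent_genes),
            "true_lfc": {
                c: {
                    g: float(v)
                    for g, v in self.true_lfc[c].items()
                    if v != 0.0
                }
                for c in self.true_lfc.columns
            },
            "enriched_categories": {
                k: sorted(v) for k, v in self.enriched_categories.items()
            },
            "motif_positions": {
                g: [[name, int(pos)] for name, pos in hits]
                for g, hits in sorted(self.motif_positions.items())
            },
            "conserved_unknown": {
                s: sorted(v) for s, v in self.conserved_unknown.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_ids(n: int) -> list[str]:
    """Sorghum-style placed-gene ids Sb<chrom>g<number>."""
    ids = []
    for i in range(n):
        chrom = i % 10 + 1
        ids.append(f"Sb{chrom:02d}g{(i // 10 + 1) * 10:06d}")
    return sorted(ids)


def _child_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi == 0.0:
        out[pos] = rng.poisson(mu[pos])
        return out
    r = 1.0 / phi
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the lane-level count matrix and its ground truth."""
    rngs = _child_rngs(config.seed, ["means", "assign", "counts", "lengths"])
    genes = _gene_ids(config.n_genes)
    sheet = config.sample_sheet()
    contrasts = config.contrasts()
    for c in contrasts:
        if not (sheet["treatment"] == c.control).any():
            raise DesignError(f"contrast {c.name} has no control lanes")

    means = np.exp(
        rngs["means"].normal(config.mean_log_mu, config.mean_log_sigma,
                             config.n_genes)
    )
    lengths = np.maximum(
        np.exp(
            rngs["lengths"].normal(config.length_log_mu,
                                   config.length_log_sigma, config.n_genes)
        ).astype(int),
        config.min_length,
    )

    order = rngs["assign"].permutation(config.n_genes)
    n_silent = int(round(config.silent_fraction * config.n_genes))
    n_spiked = int(round(config.spike_fraction * config.n_genes))
    silent_idx = order[:n_silent]
    spiked_idx = order[n_silent : n_silent + n_spiked]
    means[silent_idx] = 0.0
    if config.spike_baseline_mean is not None:
        means[spiked_idx] = config.spike_baseline_mean

    true_lfc = pd.DataFrame(
        0.0, index=genes, columns=[c.name for c in contrasts]
    )
    if config.spike_contrast is not None:
        names = [c.name for c in contrasts]
        if config.spike_contrast not in names:
            raise DesignError(
                f"unknown spike_contrast {config.spike_contrast!r}"
            )
        spike_contrast = np.full(n_spiked, names.index(config.spike_contrast))
    else:
        spike_contrast = rngs["assign"].integers(0, len(contrasts), n_spiked)
    spike_lfc = rngs["assign"].choice(
        np.asarray(config.spike_lfc_values, dtype=float), size=n_spiked
    )
    for gi, ci, lfc in zip(spiked_idx, spike_contrast, spike_lfc):
        true_lfc.iloc[gi, ci] = lfc

    counts = {}
    for lane_row in sheet.itertuples(index=False):
        mu = means.copy()
        for ci, c in enumerate(contrasts):
            if lane_row.tissue == c.tissue and lane_row.treatment == c.treatment:
                mu = mu * np.power(2.0, true_lfc.iloc[:, ci].to_numpy())
        mu = mu * config.lane_scale.get(lane_row.replicate, 1.0)
        counts[lane_row.lane] = _nb_draw(rngs["counts"], mu, config.dispersion)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes), samples=sheet
    )
    truth = GroundTruth(
        true_lfc=true_lfc,
        spiked_genes={genes[i] for i in spiked_idx},
        silent_genes={genes[i] for i in silent_idx},
        gene_means=pd.Series(means, index=genes),
        gene_lengths=pd.Series(lengths, index=genes),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotation-side generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticAnnotations:
    """All annotation-side inputs for one simulated experiment."""

    annotation: pd.DataFrame
    pathway_db: PathwayDB
    go_db: CategoryDB
    tf_db: CategoryDB
    motifs: list
    genome: dict                      # contig -> sequence
    gff: pd.DataFrame
    promoters: PromoterSet
    ortholog_table: pd.DataFrame
    drought_lists: dict

    def write_all(self, outdir) -> dict[str, str]:
        """Write every flat-file input; returns {logical name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _save(name, fn):
            paths[name] = str(outdir / name)
            fn(outdir / name)

        _save("annotation.tsv",
              lambda p: self.annotation.to_csv(p, sep="\t"))
        _save("pathways.tsv",
              lambda p: self.pathway_db.to_table().to_csv(p, sep="\t",
                                                          index=False))
        _save("collapse_map.tsv", lambda p: pd.DataFrame(
            sorted(self.pathway_db.collapse_map.items()),
            columns=["pathway_id", "collapsed_id"],
        ).to_csv(p, sep="\t", index=False))
        _save("go.tsv",
              lambda p: self.go_db.to_pairs().to_csv(p, sep="\t", index=False))
        _save("tf.tsv",
              lambda p: self.tf_db.to_pairs().to_csv(p, sep="\t", index=False))
        _save("motifs.tsv", lambda p: pd.DataFrame(
            [{"name": m.name, "pattern": m.pattern, "source": m.source}
             for m in self.motifs]
        ).to_csv(p, sep="\t", index=False))
        _save("genome.fa", self._write_fasta)
        _save("genes.gff3", self._write_gff3)
        _save("orthologs.tsv", lambda p: self.ortholog_table.to_csv(
            p, sep="\t", index=False))
        for species, genes in sorted(self.drought_lists.items()):
            _save(f"drought_{species}.tsv", lambda p, g=genes: pd.Series(
                sorted(g), name="gene").to_csv(p, sep="\t", index=False))
        return paths

    def _write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.genome):
                fh.write(f">{contig}\n")
                seq = self.genome[contig]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def _write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.gff.itertuples(index=False):
                fh.write(
                    f"{row.seqid}\tdroughtseq\tgene\t{row.start}\t{row.end}\t."
                    f"\t{row.strand}\t.\tID={row.gene_id}\n"
                )


def _planted_category_db(
    rng: np.random.Generator,
    genes: list[str],
    de_genes: set,
    n_categories: int,
    n_planted: int,
    size_range: tuple[int, int],
    prefix: str,
    kind: str,
    odds: float,
    scaffold_decoys: list[str],
) -> tuple[CategoryDB, set]:
    """Draw categories; the first ``n_planted`` sample members with odds
    ``odds`` for truly-DE genes (odds 1 = membership independent of DE)."""
    lo, hi = size_range
    if hi > len(genes):
        raise ConfigError("requested category size exceeds n_genes")
    gene_arr = np.asarray(genes)
    is_de = np.isin(gene_arr, sorted(de_genes))
    cats: dict[str, set] = {}
    planted: set = set()
    for i in range(n_categories):
        planted_here = i < n_planted and odds != 1.0
        # planted categories sit in the upper half of the size range so the
        # expected-count gate (E > 1) cannot mask the planted signal
        size = int(rng.integers((lo + hi) // 2, hi + 1)) if planted_here \
            else int(rng.integers(lo, hi + 1))
        cat_id = f"{prefix}{i + 1:03d}"
        if planted_here:
            w = np.where(is_de, odds, 1.0)
            members = rng.choice(gene_arr, size=size, replace=False,
                                 p=w / w.sum())
            planted.add(cat_id)
        else:
            members = rng.choice(gene_arr, size=size, replace=False)
        cats[cat_id] = set(members.tolist())
    # scaffold-pattern decoys must be removed by the loaders
    for j, cat_id in enumerate(sorted(cats)):
        if j < len(scaffold_decoys):
            cats[cat_id].add(scaffold_decoys[j])
    pairs = pd.DataFrame(
        [{"gene": g, "category": c} for c in cats for g in cats[c]]
    )
    return CategoryDB.from_pairs(pairs, kind=kind), planted


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> SyntheticAnnotations:
    """Generate every annotation-side input consistent with the counts.

    Must run after :func:`simulate_counts` (gene ids and DE truth come
    from ``truth``).  Plants enriched pathway/GO/TF categories at
    ``config.enrichment_odds``, motif instances preferentially in DE-gene
    promoters at recorded window positions, and a conserved-unknown
    ortholog set that passes every branch of the cross-species decision
    tree, alongside decoys that each fail exactly one branch.
    """
    rngs = _child_rngs(
        config.seed + 1,
        ["annot", "pathway", "go", "tf", "motif", "genome", "ortho"],
    )
    genes = list(truth.true_lfc.index)
    de_genes = set(truth.spiked_genes)
    scaffold_decoys = [
        f"Sb{i + 1:04d}s{(i + 1) * 1010:06d}"
        for i in range(config.n_scaffold_decoys)
    ]

    # --- conserved-unknown planting decides which genes must look unknown
    ortho, drought_lists, conserved, forced_unknown, forced_known = (
        _plant_orthologs(rngs["ortho"], genes, de_genes,
                         config.n_conserved_unknown)
    )
    truth.conserved_unknown = {
        s: set(sub["focal_gene"]) for s, sub in conserved.groupby("species")
    }
    truth.conserved_pairs = conserved

    # --- annotation table
    rng = rngs["annot"]
    unknown_draw = rng.random(len(genes)) < 0.3
    desc = [
        _UNKNOWN_DESCRIPTIONS[i % len(_UNKNOWN_DESCRIPTIONS)]
        if u
        else _KNOWN_DESCRIPTIONS[i % len(_KNOWN_DESCRIPTIONS)]
        for i, u in enumerate(unknown_draw)
    ]
    annotation = pd.DataFrame(
        {
            "description": desc,
            "confidence": np.where(
                rng.random(len(genes)) < 0.92, "high", "low"
            ),
            "length": truth.gene_lengths.to_numpy(),
            "pericentromeric": rng.random(len(genes)) < 0.05,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    silent = sorted(truth.silent_genes)
    annotation.loc[silent, "confidence"] = np.where(
        rng.random(len(silent)) < 0.67, "low", "high"
    )
    annotation.loc[sorted(forced_unknown), "description"] = (
        "putative uncharacterized protein"
    )
    annotation.loc[sorted(forced_known), "description"] = "peroxidase 6"

    # --- category databases
    pathway_db, planted_pwy = _build_pathways(
        rngs["pathway"], genes, de_genes, config, scaffold_decoys
    )
    go_db, planted_go = _planted_category_db(
        rngs["go"], genes, de_genes, config.n_go_terms, config.n_planted_go,
        (5, 80), "GO:", "go", config.enrichment_odds, scaffold_decoys,
    )
    tf_db, planted_tf = _planted_category_db(
        rngs["tf"], genes, de_genes, config.n_tf_families,
        config.n_planted_tf, (10, 60), "TF_", "tf_family",
        config.enrichment_odds, scaffold_decoys,
    )
    truth.enriched_categories = {
        "pathway": planted_pwy, "go": planted_go, "tf": planted_tf
    }

    # --- promoters, genome, planted motifs
    motifs = list(DEFAULT_MOTIFS)
    genome, gff, promoters, motif_positions = _build_genome(
        rngs["motif"], rngs["genome"], genes, de_genes, motifs, config
    )
    truth.motif_positions = motif_positions

    return SyntheticAnnotations(
        annotation=annotation,
        pathway_db=pathway_db,
        go_db=go_db,
        tf_db=tf_db,
        motifs=motifs,
        genome=genome,
        gff=gff,
        promoters=promoters,
        ortholog_table=ortho,
        drought_lists=drought_lists,
    )


def _build_pathways(
    rng: np.random.Generator,
    genes: list[str],
    de_genes: set,
    config: SimulationConfig,
    scaffold_decoys: list[str],
) -> tuple[PathwayDB, set]:
    """Pathway -> reaction -> gene table with planted enrichment, a
    collapse map merging variant pathways, and hormone flags."""
    gene_arr = np.asarray(genes)
    is_de = np.isin(gene_arr, sorted(de_genes))
    rows = []
    planted = set()
    for i in range(config.n_pathways):
        pwy = f"PWY{i + 1:03d}"
        enriched = i < config.n_planted_pathways and config.enrichment_odds != 1
        # planted pathways sit at the large end so the E > 1 gate cannot
        # mask the planted signal
        n_rxn = int(rng.integers(6, 9)) if enriched else int(rng.integers(2, 9))
        if enriched:
            planted.add(pwy)
        for j in range(n_rxn):
            rxn = f"{pwy}-RXN{j + 1}"
            n_gene = int(rng.integers(2, 6)) if enriched \
                else int(rng.integers(1, 5))
            if enriched:
                w = np.where(is_de, config.enrichment_odds, 1.0)
                members = rng.choice(gene_arr, size=n_gene, replace=False,
                                     p=w / w.sum())
            else:
                members = rng.choice(gene_arr, size=n_gene, replace=False)
            for g in members:
                rows.append({"pathway_id": pwy, "reaction_id": rxn,
                             "gene_id": g, "is_hormone": False})
    for j, decoy in enumerate(scaffold_decoys):
        rows.append(
            {
                "pathway_id": f"PWY{j % config.n_pathways + 1:03d}",
                "reaction_id": f"PWY{j % config.n_pathways + 1:03d}-RXN1",
                "gene_id": decoy,
                "is_hormone": False,
            }
        )
    table = pd.DataFrame(rows)
    # merge variant pathway pairs (e.g. "... II" and "... III") and flag a
    # hormone-related subset of the collapsed ids
    collapse_map = {}
    n_merge = min(6, config.n_pathways - config.n_pathways % 2)
    for k in range(0, n_merge, 2):
        a, b = f"PWY{k + 1:03d}", f"PWY{k + 2:03d}"
        target = f"PWY-GRP{k // 2 + 1}"
        collapse_map[a] = target
        collapse_map[b] = target
    db = PathwayDB.from_table(table, collapse_map=collapse_map)
    collapsed_ids = sorted(
        {collapse_map.get(p, p) for p in db.reactions}
    )
    n_hormone = min(8, len(collapsed_ids))
    hormone_collapsed = set(
        rng.choice(np.asarray(collapsed_ids), size=n_hormone, replace=False)
    )
    db.hormone = {
        p for p in db.reactions
        if collapse_map.get(p, p) in hormone_collapsed
    }
    return db, planted


def _build_genome(
    rng_motif: np.random.Generator,
    rng_genome: np.random.Generator,
    genes: list[str],
    de_genes: set,
    motifs: list[Motif],
    config: SimulationConfig,
) -> tuple[dict, pd.DataFrame, PromoterSet, dict]:
    """Lay genes on 10 contigs with alternating strands; each gene body is
    preceded (in gene orientation) by its promoter window carrying planted
    motif instances, preferentially for DE genes."""
    window = config.promoter_window
    gene_body = 120
    spacer = 20
    planted_motifs = [m for m in motifs if m.name in ("ABRE", "DRE")]
    p_bg = config.motif_background_prob
    p_de = min(p_bg * config.enrichment_odds, 0.9)

    promoter_seqs: dict[str, str] = {}
    motif_positions: dict[str, list] = {}
    for gi, gene in enumerate(genes):
        seq = list(_random_seq(rng_genome, window))
        hits = []
        for motif in planted_motifs:
            prob = p_de if gene in de_genes else p_bg
            if rng_motif.random() < prob:
                instance = "".join(
                    rng_motif.choice(list(IUPAC[c])) for c in motif.pattern
                )
                pos0 = int(rng_motif.integers(0, window - len(instance) + 1))
                seq[pos0 : pos0 + len(instance)] = list(instance)
                hits.append((motif.name, pos0 + 1))
        promoter_seqs[gene] = "".join(seq)
        if hits:
            motif_positions[gene] = hits

    genome: dict[str, list] = {f"chr{c:02d}": [] for c in range(1, 11)}
    gff_rows = []
    cursors = {c: 0 for c in genome}
    for gi, gene in enumerate(genes):
        contig = f"chr{gi % 10 + 1:02d}"
        strand = "+" if (gi // 10) % 2 == 0 else "-"
        parts = genome[contig]
        cur = cursors[contig]
        body = _random_seq(rng_genome, gene_body)
        if strand == "+":
            parts.append(promoter_seqs[gene])
            parts.append(body)
            start = cur + window + 1
            end = start + gene_body - 1
        else:
            parts.append(body)
            parts.append(reverse_complement(promoter_seqs[gene]))
            start = cur + 1
            end = cur + gene_body
        parts.append(_random_seq(rng_genome, spacer))
        cursors[contig] = cur + window + gene_body + spacer
        gff_rows.append(
            {"gene_id": gene, "seqid": contig, "start": start, "end": end,
             "strand": strand}
        )
    genome_str = {c: "".join(parts) for c, parts in genome.items()}
    gff = pd.DataFrame(gff_rows).sort_values(["seqid", "start"])
    promoters = PromoterSet(sequences=promoter_seqs, window=window)
    return genome_str, gff, promoters, motif_positions


def _plant_orthologs(
    rng: np.random.Generator,
    genes: list[str],
    de_genes: set,
    n_conserved: int,
):
    """Plant a conserved-unknown ortholog set plus one decoy per branch.

    Returns (ortholog table, per-species drought lists, planted pair
    table, focal genes forced to unknown descriptions, focal genes forced
    to known descriptions).
    """
    de_sorted = sorted(de_genes)
    non_de = sorted(set(genes) - de_genes)
    need = n_conserved + 3  # planted set + decoys drawn from DE genes
    if len(de_sorted) < need or len(non_de) < 1:
        raise ConfigError("not enough genes to plant the ortholog truth set")
    picked = [
        str(g)
        for g in rng.choice(np.asarray(de_sorted), size=need, replace=False)
    ]
    planted = picked[:n_conserved]
    decoy_annotated_ortholog = picked[n_conserved]
    decoy_no_drought = picked[n_conserved + 1]
    decoy_known_focal = picked[n_conserved + 2]
    decoy_not_de = non_de[0]

    forced_unknown = set(planted) | {
        decoy_annotated_ortholog, decoy_no_drought, decoy_not_de
    }
    forced_known = {decoy_known_focal}

    rows = []
    drought_lists: dict[str, set] = {s: set() for s in SPECIES}
    conserved_rows = []

    def ortho_id(species: str, k: int) -> str:
        prefix = {"rice": "Os", "maize": "Zm", "arabidopsis": "AT"}[species]
        return f"{prefix}g{k:06d}"

    counter = 0
    for focal in planted:
        # each planted gene is conserved in a deterministic-random subset
        n_sp = int(rng.integers(1, len(SPECIES) + 1))
        species_subset = sorted(
            str(s) for s in rng.choice(np.asarray(SPECIES), size=n_sp,
                                       replace=False)
        )
        for species in species_subset:
            n_orth = int(rng.integers(1, 3))
            for _ in range(n_orth):
                counter += 1
                og = ortho_id(species, counter)
                rows.append(
                    {
                        "focal_gene": focal,
                        "species": species,
                        "ortholog_gene": og,
                        "ortholog_description": "hypothetical protein",
                    }
                )
                drought_lists[species].add(og)
                conserved_rows.append(
                    {"focal_gene": focal, "species": species,
                     "ortholog_gene": og}
                )

    def add_decoy(focal, species, desc, in_drought):
        nonlocal counter
        counter += 1
        og = ortho_id(species, counter)
        rows.append(
            {"focal_gene": focal, "species": species, "ortholog_gene": og,
             "ortholog_description": desc}
        )
        if in_drought:
            drought_lists[species].add(og)

    for species in SPECIES:
        # fails branch (b): one ortholog has a known function
        add_decoy(decoy_annotated_ortholog, species, "hypothetical protein",
                  True)
        add_decoy(decoy_annotated_ortholog, species, "catalase isozyme",
                  True)
        # fails branch (c): unknown orthologs, none drought-responsive
        add_decoy(decoy_no_drought, species, "predicted protein", False)
        # fails unknown-focal gate
        add_decoy(decoy_known_focal, species, "uncharacterized protein", True)
        # fails DE gate
        add_decoy(decoy_not_de, species, "hypothetical protein", True)
        # drought-list filler ids that belong to no ortholog pair
        for j in range(10):
            drought_lists[species].add(ortho_id(species, 900000 + j))

    ortho = pd.DataFrame(
        rows, columns=["focal_gene", "species", "ortholog_gene",
                       "ortholog_description"]
    )
    conserved = pd.DataFrame(
        conserved_rows, columns=["focal_gene", "species", "ortholog_gene"]
    )
    return ortho, drought_lists, conserved, forced_unknown, forced_known
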