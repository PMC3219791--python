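"""Upstream-region extraction and IUPAC degenerate cis-element scanning.

Promoter windows (default 1000 bp immediately upstream of the gene
feature start, strand-oriented 5'->3' toward the gene) are pulled from a
genome FASTA + GFF3 pair; cis-regulatory elements given as IUPAC
degenerate patterns are matched at every offset on both strands, and the
per-gene presence sets feed the Z-score/hypergeometric enrichment engine.

Coordinate conventions: GFF3 is 1-based inclusive; match positions are
reported 1-based from the window's 5' end, with the distance from the
match to the gene start as a derived column.  An ``N`` in the genome
never matches any motif symbol (masked sequence cannot generate hits).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from droughtseq.errors import FormatError
from droughtseq.enrich import CategoryDB, EnrichmentCriteria, enrich

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A named IUPAC degenerate pattern over {A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N}."""

    name: str
    pattern: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise FormatError(f"motif {self.name!r}: empty pattern")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise FormatError(
                f"motif {self.name!r}: invalid IUPAC symbols {bad}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def regex(self) -> str:
        """Equivalent character-class regex (N in the target never matches)."""
        return "".join(f"[{IUPAC[c]}]" for c in self.pattern)


def load_motifs(path) -> list[Motif]:
    """Read a motif TSV (name, pattern[, source]); identically-sequenced
    motifs are collapsed onto one record with joined names."""
    df = pd.read_csv(path, sep="\t")
    name_col, pat_col = df.columns[:2]
    src_col = df.columns[2] if len(df.columns) > 2 else None
    by_seq: dict[str, list] = {}
    for row in df.itertuples(index=False):
        pat = str(getattr(row, pat_col)).upper()
        by_seq.setdefault(pat, []).append(row)
    motifs = []
    for pat, rows in by_seq.items():
        names = sorted({str(getattr(r, name_col)) for r in rows})
        source = ";".join(
            sorted({str(getattr(r, src_col)) for r in rows})
        ) if src_col else ""
        motifs.append(Motif(name="/".join(names), pattern=pat, source=source))
    return sorted(motifs, key=lambda m: m.name)


@dataclass
class PromoterSet:
    """gene id -> upstream sequence (5'->3' toward the gene start)."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)
    window: int = 1000

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {g: len(s) for g, s in self.sequences.items()}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.sequences):
                fh.write(f">{gene}\n{self.sequences[gene]}\n")


def _parse_gff3_genes(gff3_path, feature_type: str):
    """GFF3 features of one type as (gene_id, seqid, start, end, strand)."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    for feat in db.features_of_type(feature_type, order_by="start"):
        yield feat.id, feat.seqid, feat.start, feat.end, feat.strand


def extract_upstream(
    fasta_path, gff3_path, window: int = 1000, feature_type: str = "gene"
) -> PromoterSet:
    """Extract up-to-``window``-bp upstream regions for every gene feature.

    Plus-strand genes take [start-window, start-1]; minus-strand genes the
    reverse complement of [end+1, end+window]; windows truncate at contig
    boundaries (possibly to length 0).  Genes on missing contigs or with
    strand '.' are skipped with a warning.
    """
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    sequences: dict[str, str] = {}
    for gene_id, seqid, start, end, strand in _parse_gff3_genes(
        gff3_path, feature_type
    ):
        if seqid not in genome:
            warnings.warn(f"gene {gene_id}: contig {seqid} not in FASTA; "
                          "skipped", stacklevel=2)
            continue
        contig_len = len(genome[seqid])
        if strand == "+":
            lo = max(start - 1 - window, 0)       # 0-based slice bounds
            hi = start - 1
            seq = str(genome[seqid][lo:hi]) if hi > lo else ""
        elif strand == "-":
            lo = end
            hi = min(end + window, contig_len)
            raw = str(genome[seqid][lo:hi]) if hi > lo else ""
            seq = reverse_complement(raw)
        else:
            warnings.warn(f"gene {gene_id}: strand {strand!r}; skipped",
                          stacklevel=2)
            continue
        sequences[gene_id] = seq
    return PromoterSet(sequences=sequences, window=window)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _match_table(pattern: str) -> np.ndarray:
    """(pattern_len x 5) boolean table; column 4 ('N' in target) all False."""
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, code in enumerate(pattern):
        for base in IUPAC[code]:
            table[j, _BASE_INDEX[base]] = True
    return table


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _scan_encoded(encoded: np.ndarray, table: np.ndarray) -> np.ndarray:
    """0-based start offsets of all (overlapping) matches."""
    m = len(table)
    n = len(encoded)
    if n < m:
        return np.empty(0, dtype=np.int64)
    acc = table[0][encoded[: n - m + 1]]
    for j in range(1, m):
        acc &= table[j][encoded[j : n - m + 1 + j]]
    return np.nonzero(acc)[0]


def scan_motifs(
    promoters: PromoterSet, motifs: list[Motif], both_strands: bool = True
) -> pd.DataFrame:
    """All (overlapping) IUPAC matches of each motif in each promoter.

    Returns rows (gene, motif, position, strand, dist_to_gene_start);
    ``position`` is the 1-based match start from the window's 5' end and
    ``strand`` is '+' for the given sequence, '-' for a reverse-complement
    pattern match.  Uppercase matching; genome N matches nothing.
    """
    rows = []
    for gene in sorted(promoters.sequences):
        seq = promoters.sequences[gene].upper()
        if not seq:
            continue
        encoded = _encode(seq)
        seq_len = len(seq)
        for motif in motifs:
            strands = [("+", motif.pattern)]
            rc = reverse_complement(motif.pattern)
            if both_strands and rc != motif.pattern:
                strands.append(("-", rc))
            for strand, pattern in strands:
                for pos0 in _scan_encoded(encoded, _match_table(pattern)):
                    rows.append(
                        {
                            "gene": gene,
                            "motif": motif.name,
                            "position": int(pos0) + 1,
                            "strand": strand,
                            "dist_to_gene_start": seq_len - int(pos0),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["gene", "motif", "position", "strand",
                       "dist_to_gene_start"]
    )


def scan_regex_oracle(
    promoters: PromoterSet, motifs: list[Motif], both_strands: bool = True
) -> pd.DataFrame:
    """Brute-force scanner: IUPAC codes expanded to regex character
    classes with overlap-permitting lookahead.  Independent reference for
    :func:`scan_motifs`."""
    rows = []
    for gene in sorted(promoters.sequences):
        seq = promoters.sequences[gene].upper()
        if not seq:
            continue
        for motif in motifs:
            strands = [("+", motif.pattern)]
            rc = reverse_complement(motif.pattern)
            if both_strands and rc != motif.pattern:
                strands.append(("-", rc))
            for strand, pattern in strands:
                regex = re.compile(
                    "(?=" + "".join(f"[{IUPAC[c]}]" for c in pattern) + ")"
                )
                for m in regex.finditer(seq):
                    rows.append(
                        {
                            "gene": gene,
                            "motif": motif.name,
                            "position": m.start() + 1,
                            "strand": strand,
                            "dist_to_gene_start": len(seq) - m.start(),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["gene", "motif", "position", "strand",
                       "dist_to_gene_start"]
    )


def presence_db(hits: pd.DataFrame, motifs: list[Motif]) -> CategoryDB:
    """Gene-level presence CategoryDB (one category per motif)."""
    cats = {m.name: set() for m in motifs}
    for row in hits.itertuples(index=False):
        cats[row.motif].add(row.gene)
    return CategoryDB(categories=cats, kind="motif")


def motif_enrichment(
    hits: pd.DataFrame,
    motifs: list[Motif],
    de_set: set,
    universe: set,
    criteria: EnrichmentCriteria | None = None,
) -> pd.DataFrame:
    """Motif presence enrichment among DE-gene promoters.

    The universe is every gene with an extracted promoter (hits must have
    been computed on the full universe, not only DE genes); duplicated
    hits within a promoter do not inflate the observed count.  The
    significance rule is Z >= 2, BH-adjusted hypergeometric p <= 0.05 and
    expected count > 1; motifs present in zero or all genes are flagged
    degenerate and never significant.
    """
    if criteria is None:
        criteria = EnrichmentCriteria(p_source="hypergeom_adj")
    db = presence_db(hits, motifs)
    db.categories = {
        name: members & universe for name, members in db.categories.items()
    }
    db.universe = set(universe)
    return enrich(de_set & universe, db, criteria=criteria)
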