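"""Variant effect classification, promoter extraction and cis-element scanning.

Variant categories follow the conventional gene-context breakdown: within a
gene the precedence is CDS > intron > upstream_1kb > downstream_1kb
(upstream/downstream measured strand-aware from the TSS/TES, positions -1 to
-1000 and +1 to +1000 exclusive of the gene body); a variant overlapping
several genes' contexts yields one record per gene; with no gene context it
is intergenic. Coding effects are evaluated by splicing the CDS, substituting
the alt base (complemented on minus-strand genes) and translating with the
standard genetic code.

Promoters are the 2,000 bp immediately 5' of the strand-aware TSS, returned
5'->3' relative to transcription (reverse-complemented for minus-strand
genes) and clipped at chromosome edges.

Cis-element matching is exact IUPAC consensus matching of a bundled,
user-replaceable motif table on both strands; an N in the scanned sequence
never matches. Variant-induced motif gains/losses are the set difference of
hits (motif, start, strand) between the reference and mutated promoter, with
positions left-aligned back to the reference frame after insertions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .io import GeneModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = (
    "upstream_1kb",
    "downstream_1kb",
    "intron",
    "exon_missense",
    "exon_synonymous",
    "exon_other",
    "intergenic",
)


class MotifTableError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str
    category: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifTableError(f"motif {self.name!r} has an empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise MotifTableError(
                f"motif {self.name!r}: invalid IUPAC letter(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int  # 1-based on the scanned sequence's 5'->3' orientation
    strand: str
    site: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.motif, self.start, self.strand)


@dataclass
class MotifDiff:
    gained: list[MotifHit] = field(default_factory=list)
    lost: list[MotifHit] = field(default_factory=list)


@dataclass
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    category: str
    detail: str = ""


def load_motif_table(path=None) -> list[Motif]:
    """Load motifs from a TSV (name, pattern, category, source); default bundled table."""
    if path is None:
        with resources.files("popsweep").joinpath("data/motifs.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        Motif(
            name=str(r["name"]),
            pattern=str(r["pattern"]).upper(),
            category=str(r.get("category", "")),
            source=str(r.get("source", "")),
        )
        for _, r in df.iterrows()
    ]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _match_at(seq: str, i: int, pattern: str) -> bool:
    for k, letter in enumerate(pattern):
        base = seq[i + k]
        if base not in IUPAC[letter]:  # sequence N never matches
            return False
    return True


def scan_motifs(
    sequence: str, motifs: Iterable[Motif], sequence_id: str = ""
) -> list[MotifHit]:
    """All IUPAC consensus matches of each motif on both strands of ``sequence``.

    Overlapping matches are all reported; minus-strand hits are positions
    where the reverse complement of the pattern occurs in the given
    sequence. Hits are sorted by start.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        for strand, pattern in (("+", motif.pattern), ("-", revcomp(motif.pattern))):
            m = len(pattern)
            for i in range(len(seq) - m + 1):
                if _match_at(seq, i, pattern):
                    hits.append(
                        MotifHit(
                            sequence_id=sequence_id,
                            motif=motif.name,
                            start=i + 1,
                            strand=strand,
                            site=seq[i : i + m],
                        )
                    )
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def motif_diff_for_variant(
    promoter_ref: str,
    offset: int,
    ref: str,
    alt: str,
    motifs: Iterable[Motif],
    sequence_id: str = "",
) -> MotifDiff:
    """Motif gains/losses caused by a substitution or insertion in a promoter.

    ``offset`` is the 1-based position of ``ref`` within ``promoter_ref``;
    for insertions ``ref`` is the anchor base and ``alt`` the anchor plus
    inserted bases (VCF-style). Hit identity is (motif, start, strand) with
    mutated-sequence positions shifted back (left-aligned) to the reference
    frame past the insertion point.
    """
    motifs = list(motifs)
    if promoter_ref[offset - 1 : offset - 1 + len(ref)].upper() != ref.upper():
        raise ReferenceMismatchError(
            f"reference allele {ref!r} not found at promoter offset {offset}"
        )
    promoter_alt = promoter_ref[: offset - 1] + alt + promoter_ref[offset - 1 + len(ref) :]
    shift = len(alt) - len(ref)
    hits_ref = scan_motifs(promoter_ref, motifs, sequence_id)
    hits_alt = scan_motifs(promoter_alt, motifs, sequence_id)

    def remap(h: MotifHit) -> MotifHit:
        if shift and h.start > offset:
            return MotifHit(h.sequence_id, h.motif, h.start - shift, h.strand, h.site)
        return h

    hits_alt = [remap(h) for h in hits_alt]
    ref_keys = {h.key for h in hits_ref}
    alt_keys = {h.key for h in hits_alt}
    gained = [h for h in hits_alt if h.key not in ref_keys]
    lost = [h for h in hits_ref if h.key not in alt_keys]
    return MotifDiff(gained=gained, lost=lost)


# ---------------------------------------------------------------------------
# promoters


def extract_promoter(
    gene: GeneModel, genome: dict[str, str], length: int = 2000
) -> tuple[str, bool]:
    """The ``length`` bp 5' of the strand-aware TSS, 5'->3' in transcription sense.

    Returns (sequence, clipped). Clipped is True when a chromosome edge
    truncated the promoter; a TSS at position 1 yields a zero-length
    promoter with a warning.
    """
    seq = genome[gene.chrom]
    if gene.strand == "+":
        start0 = max(0, gene.start - 1 - length)
        prom = seq[start0 : gene.start - 1]
        clipped = gene.start - 1 - length < 0
    else:
        end0 = min(len(seq), gene.end + length)
        prom = revcomp(seq[gene.end : end0])
        clipped = gene.end + length > len(seq)
    if not prom:
        warnings.warn(f"gene {gene.gene_id}: zero-length promoter (TSS at chromosome edge)")
    return prom, clipped


# ---------------------------------------------------------------------------
# variant effect classification


def _which_cds(gene: GeneModel, pos: int) -> int | None:
    for k, (s, e, _) in enumerate(gene.cds_intervals):
        if s <= pos <= e:
            return k
    return None


def _coding_effect(gene: GeneModel, pos: int, alt: str, genome: dict[str, str]) -> tuple[str, str]:
    from .simulate import spliced_cds

    cds = spliced_cds(gene, genome)
    # offset of pos within the spliced CDS (transcription order)
    offset = 0
    for s, e, _ in gene.cds_intervals:
        if s <= pos <= e:
            offset += (pos - s) if gene.strand == "+" else (e - pos)
            break
        offset += e - s + 1
    base = alt if gene.strand == "+" else revcomp(alt)
    cds_alt = cds[:offset] + base + cds[offset + 1 :]
    codon_i = offset // 3
    codon_ref = cds[3 * codon_i : 3 * codon_i + 3]
    codon_alt = cds_alt[3 * codon_i : 3 * codon_i + 3]
    if len(codon_ref) < 3:
        return "exon_other", f"incomplete codon {codon_ref}>{codon_alt}"
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    detail = f"codon {codon_ref}>{codon_alt}; p.{aa_ref}{codon_i + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return "exon_synonymous", detail
    if aa_alt == "*" or aa_ref == "*" or (codon_i == 0 and aa_alt != "M"):
        return "exon_other", detail
    return "exon_missense", detail


def classify_variant_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: list[GeneModel],
    genome: dict[str, str] | None = None,
) -> list[VariantEffect]:
    """Classify one SNP against every gene whose context contains it.

    Requires ``genome`` for coding evaluation and for the reference check;
    raises :class:`ReferenceMismatchError` when the VCF ref base disagrees
    with the genome FASTA.
    """
    if genome is not None and chrom in genome:
        g_base = genome[chrom][pos - 1].upper()
        if g_base != ref.upper():
            raise ReferenceMismatchError(
                f"{chrom}:{pos} VCF ref {ref!r} != genome base {g_base!r}"
            )
    effects: list[VariantEffect] = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        category = detail = None
        if gene.start <= pos <= gene.end:
            if gene.cds_intervals and _which_cds(gene, pos) is not None:
                if genome is None:
                    category, detail = "exon_other", "no genome sequence for coding evaluation"
                else:
                    category, detail = _coding_effect(gene, pos, alt, genome)
            else:
                category, detail = "intron", ""
        else:
            # strand-aware upstream/downstream within 1 kb of TSS/TES
            if gene.strand == "+":
                up = gene.start - pos
                down = pos - gene.end
            else:
                up = pos - gene.end
                down = gene.start - pos
            if 1 <= up <= 1000:
                category, detail = "upstream_1kb", f"{up} bp upstream of TSS"
            elif 1 <= down <= 1000:
                category, detail = "downstream_1kb", f"{down} bp downstream of TES"
        if category is not None:
            effects.append(VariantEffect(chrom, pos, ref, alt, gene.gene_id, category, detail))
    if not effects:
        effects.append(VariantEffect(chrom, pos, ref, alt, None, "intergenic", ""))
    return effects


def summarize_effect_counts(effects: list[VariantEffect]) -> pd.DataFrame:
    """Per-category record counts plus a deduplicated variant total.

    A variant in several genes' contexts counts once per context in the
    per-category rows, and once in the ``total_unique_variants`` row.
    """
    counts = {c: 0 for c in CATEGORIES}
    variants = set()
    for e in effects:
        counts[e.category] += 1
        variants.add((e.chrom, e.pos, e.ref, e.alt))
    rows = [{"category": c, "count": n} for c, n in counts.items()]
    rows.append({"category": "total_records", "count": len(effects)})
    rows.append({"category": "total_unique_variants", "count": len(variants)})
    return pd.DataFrame(rows)
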