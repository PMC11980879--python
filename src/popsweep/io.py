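"""Readers/writers for VCF, GFF3, FASTA and population maps, plus the genotype data model.

The central container is :class:`GenotypeMatrix`: diploid alt-allele dosages
(0/1/2, with ``MISSING = -1``) for ``n_samples x n_sites``, a per-site table
(chrom, 1-based pos, ref, alt alleles) and optional per-sample read depth.
Every statistic downstream operates on this container.

Coordinates are kept 1-based inclusive at the file boundary (VCF/GFF3
convention) and converted to 0-based half-open only inside interval
arithmetic; everything user-visible is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

MISSING: int = -1

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be interpreted (bad header, missing GT, ...)."""


class GffConsistencyError(ValueError):
    """Raised when GFF3 features contradict each other (e.g. CDS outside gene)."""


# ---------------------------------------------------------------------------
# data model


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages with per-site metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows of ``calls``).
    calls : ndarray of int, shape (n_samples, n_sites)
        Alt-allele dosage in {0, 1, 2} or ``MISSING`` (-1).
    sites : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``ref`` (str),
        ``alt`` (tuple of str). Sorted by (chrom, pos), no duplicates.
    depth : ndarray of int or None
        Per-call read depth, same shape as ``calls``; None if absent.
    """

    sample_ids: list[str]
    calls: np.ndarray
    sites: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (n_samples x n_sites)")
        if self.calls.shape[0] != len(self.sample_ids):
            raise ValueError("calls row count != number of samples")
        if self.calls.shape[1] != len(self.sites):
            raise ValueError("calls column count != number of sites")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        key = list(zip(self.sites["chrom"], self.sites["pos"]))
        if sorted(key) != key:
            raise ValueError("sites not sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) in sites")
        if self.depth is not None:
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape mismatch")
            if (self.depth < 0).any():
                raise ValueError("negative depth")

    # -- subsetting --------------------------------------------------------
    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            calls=self.calls[:, index].copy(),
            sites=self.sites.iloc[index].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            calls=self.calls[index, :].copy(),
            sites=self.sites.copy(),
            depth=None if self.depth is None else self.depth[index, :].copy(),
        )

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.sites["alt"]], dtype=bool)


@dataclass
class PopulationMap:
    """Mapping of sample id -> population label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.assignments.items():
            if not p:
                raise ValueError(f"empty population label for sample {s!r}")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    @classmethod
    def read(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t")
        if not {"sample", "population"} <= set(df.columns):
            raise ValueError("population map needs columns 'sample' and 'population'")
        return cls(dict(zip(df["sample"].astype(str), df["population"].astype(str))))

    def write(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignments), "population": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GeneModel:
    """A gene with its CDS/exon structure.

    ``cds_intervals`` are (start, end, frame) triples, 1-based inclusive,
    ordered 5'->3' in transcription direction (descending coordinates on
    the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e, _ in self.cds_intervals:
            if not (self.start <= s <= e <= self.end):
                raise GffConsistencyError(
                    f"gene {self.gene_id}: CDS [{s},{e}] outside gene span"
                )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (1-based)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Strand-aware transcription end site (1-based)."""
        return self.end if self.strand == "+" else self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_intervals)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes are collapsed to alt-allele dosage irrespective of phasing;
    any genotype with a missing allele (``./.``, ``.|.``, ``0/.``) becomes
    ``MISSING``. Multi-allelic SNP records are retained with all alt alleles
    (biallelic filtering happens downstream); indel records are dropped with
    a logged count.
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    calls_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    records: list[tuple[str, int, str, tuple[str, ...]]] = []
    any_depth = False
    n_indels = 0

    for var in vcf:
        alts = tuple(var.ALT)
        if len(var.REF) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts) or not alts:
            n_indels += 1
            continue
        if "GT" not in (var.FORMAT or []):
            raise VcfFormatError(
                f"record {var.CHROM}:{var.POS} has no GT field"
            )
        gts = np.array([g[:2] for g in var.genotypes], dtype=int)
        dosage = (gts > 0).sum(axis=1).astype(np.int8)
        dosage[(gts < 0).any(axis=1)] = MISSING
        calls_cols.append(dosage)
        dp = var.format("DP")
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = 0
            depth_cols.append(dp)
            any_depth = True
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int64))
        records.append((var.CHROM, var.POS, var.REF, alts))
    vcf.close()

    if n_indels:
        logger.info("read_vcf: dropped %d non-SNP records", n_indels)

    sites = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    n = len(records)
    calls = (
        np.stack(calls_cols, axis=1) if n else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = np.stack(depth_cols, axis=1) if (n and any_depth) else None
    gm = GenotypeMatrix(samples, calls, sites, depth)
    gm.validate()
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF v4.2 text file.

    Round-trips exactly through :func:`read_vcf` (calls, positions, alleles).
    """
    has_depth = gm.depth is not None
    fmt = "GT:DP" if has_depth else "GT"
    chroms = list(dict.fromkeys(gm.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            sub = gm.sites.loc[gm.sites["chrom"] == c, "pos"]
            fh.write(f"##contig=<ID={c},length={int(sub.max()) + 10000 if len(sub) else 10000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            rec = gm.sites.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                gt = _GT_STR[int(gm.calls[i, j])]
                if has_depth:
                    cells.append(f"{gt}:{int(gm.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t"
                f"{','.join(rec['alt'])}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / FASTA


def read_gff(path) -> list[GeneModel]:
    """Load gene models (gene -> mRNA -> CDS/exon) from a GFF3 file.

    One :class:`GeneModel` per gene; if a gene has several mRNAs the first
    one (file order) supplies the CDS/exon structure. CDS intervals are
    returned in transcription order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else g
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        exons = list(db.children(parent, featuretype="exon", order_by="start"))
        rev = g.strand == "-"
        cds_iv = [
            (c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
            for c in sorted(cds, key=lambda c: c.start, reverse=rev)
        ]
        exon_iv = [(e.start, e.end) for e in sorted(exons, key=lambda e: e.start, reverse=rev)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                cds_intervals=cds_iv,
                exon_intervals=exon_iv,
            )
        )
    return genes


def write_gff(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS/exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tpopsweep\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpopsweep\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in sorted(g.exon_intervals):
                fh.write(
                    f"{g.chrom}\tpopsweep\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            for s, e, frame in sorted(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\tpopsweep\tCDS\t{s}\t{e}\t.\t{g.strand}\t{frame}\t"
                    f"Parent={mrna}\n"
                )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{sequence_id: sequence}`` (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ts/tv


def ts_tv_summary(gm_or_counts) -> tuple[int, int, float | None]:
    """Transition/transversion counts and their ratio over biallelic SNP sites.

    Transitions are A<->G and C<->T; every other ref/alt base pair is a
    transversion. Accepts either a :class:`GenotypeMatrix` or a precomputed
    ``(n_ts, n_tv)`` pair. The ratio is ``None`` when ``n_tv == 0``.
    """
    if isinstance(gm_or_counts, GenotypeMatrix):
        gm = gm_or_counts
        n_ts = n_tv = 0
        for ref, alt in zip(gm.sites["ref"], gm.sites["alt"]):
            if len(alt) != 1:
                continue
            if (ref, alt[0]) in _TRANSITIONS:
                n_ts += 1
            else:
                n_tv += 1
    else:
        n_ts, n_tv = map(int, gm_or_counts)
    ratio = (n_ts / n_tv) if n_tv else None
    return n_ts, n_tv, ratio
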