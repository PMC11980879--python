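"""Synthetic multi-population genotype data with planted selective sweeps.

The generator follows the Balding–Nichols model: each site has an ancestral
alt-allele frequency p0 drawn from a Beta (or uniform) distribution, and each
population's frequency is drawn from

    Beta( p0 * (1 - F) / F,  (1 - p0) * (1 - F) / F )

where F is the per-population drift parameter; E[FST] between two populations
is then governed directly by F, which makes the simulator an independent
oracle for the FST estimators. Genotypes are Binomial(2, p_pop) per diploid
sample, i.e. sites are unlinked by default (an optional block-copy mode
replicates frequencies in blocks to create LD for exercising the pruner).

A planted sweep pulls the focal population's frequency toward the nearer
boundary of {0, 1} by a factor s (p' = p*(1-s) below 0.5, p' = p + s*(1-p)
above; ties at 0.5 go down), reducing within-population heterozygosity in the
sweep interval — the diversity signature the genome scan is designed to find.

Defaults emulate a four-population, 10-diploids-per-population resequencing
design at mean depth 12x with up to 30% missing genotypes per site and
background divergence in the FST ~ 0.05-0.15 range.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence.spawn``: child streams, in order, are
(0) site placement and ancestral frequencies, (1) population frequencies,
(2) genotype draws, (3) missingness, (4) depth, (5) gene/sequence fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    GenotypeMatrix,
    MISSING,
    PopulationMap,
    write_fasta,
    write_gff,
    write_vcf,
)

_DEFAULT_LABELS = ("DZG", "ZZ", "QZ", "WZ")

_BASES = np.array(list("ACGT"))
# codons that do not encode stop, as strings
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SweepSpec:
    population: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    s: float  # sweep strength in [0, 1]


@dataclass
class SimulationConfig:
    """Recipe for a synthetic dataset; fully determines it together with ``seed``."""

    n_pops: int = 4
    samples_per_pop: int = 10
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_sites: int = 20_000
    ancestral_beta: tuple[float, float] | None = None  # None -> Uniform(0.05, 0.95)
    divergence_F: float = 0.1
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.05
    mean_depth: float = 12.0
    ld_block: int = 1  # >1 copies allele frequencies in blocks (creates LD)
    pop_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.divergence_F < 1):
            raise ConfigError("divergence_F must lie in (0, 1)")
        if not (0 <= self.missing_rate <= 1):
            raise ConfigError("missing_rate must lie in [0, 1]")
        if self.ancestral_beta is not None and min(self.ancestral_beta) <= 0:
            raise ConfigError("Beta parameters must be positive")
        if self.pop_labels is None:
            if self.n_pops <= len(_DEFAULT_LABELS):
                self.pop_labels = _DEFAULT_LABELS[: self.n_pops]
            else:
                self.pop_labels = tuple(f"P{i + 1}" for i in range(self.n_pops))
        if len(self.pop_labels) != self.n_pops:
            raise ConfigError("pop_labels length != n_pops")
        for sw in self.sweep_specs:
            if not (0 <= sw.s <= 1):
                raise ConfigError("sweep strength s must lie in [0, 1]")
            if not (1 <= sw.start <= sw.end <= self.chrom_length):
                raise ConfigError("sweep interval outside chromosome")
            if sw.population not in self.pop_labels:
                raise ConfigError(f"sweep population {sw.population!r} unknown")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(6)
        return [np.random.default_rng(c) for c in children]

    def population_map(self) -> PopulationMap:
        out = {}
        for p, label in enumerate(self.pop_labels):
            for k in range(self.samples_per_pop):
                out[f"{label}_{k + 1:02d}"] = label
        return PopulationMap(out)


def _sweep_pull(p: np.ndarray, s: float) -> np.ndarray:
    """Pull frequencies toward the nearer boundary of {0,1} by factor s."""
    out = p.copy()
    low = p <= 0.5
    out[low] = p[low] * (1.0 - s)
    out[~low] = p[~low] + s * (1.0 - p[~low])
    return out


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a genotype matrix under the Balding–Nichols model.

    Returns the matrix (no missingness; apply
    :func:`apply_missingness_and_depth` afterwards) and a truth table with
    per-site, per-population allele frequencies and sweep labels.
    """
    rng_sites, rng_freq, rng_geno, *_ = cfg.streams()

    # site placement: evenly split across chromosomes, unique sorted positions
    per_chrom = np.full(cfg.n_chroms, cfg.n_sites // cfg.n_chroms)
    per_chrom[: cfg.n_sites % cfg.n_chroms] += 1
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for name, k in zip(cfg.chrom_names, per_chrom):
        if k > cfg.chrom_length:
            raise ConfigError("more sites than positions on a chromosome")
        pos = rng_sites.choice(cfg.chrom_length, size=k, replace=False) + 1
        pos.sort()
        positions.append(pos)
        chroms.extend([name] * int(k))
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)

    # ancestral frequencies
    n = cfg.n_sites
    n_blocks = (n + cfg.ld_block - 1) // cfg.ld_block
    if cfg.ancestral_beta is None:
        p0_blocks = rng_sites.uniform(0.05, 0.95, size=n_blocks)
    else:
        a, b = cfg.ancestral_beta
        p0_blocks = rng_sites.beta(a, b, size=n_blocks)
        p0_blocks = np.clip(p0_blocks, 1e-9, 1 - 1e-9)
    p0 = np.repeat(p0_blocks, cfg.ld_block)[:n]

    # per-population frequencies (Balding–Nichols)
    F = cfg.divergence_F
    alpha = p0 * (1 - F) / F
    beta = (1 - p0) * (1 - F) / F
    pop_freq = {}
    for label in cfg.pop_labels:
        pf_blocks = rng_freq.beta(alpha[::cfg.ld_block][:n_blocks], beta[::cfg.ld_block][:n_blocks])
        pop_freq[label] = np.repeat(pf_blocks, cfg.ld_block)[:n]

    # planted sweeps
    sweep_label = np.array([""] * n, dtype=object)
    chrom_arr = np.asarray(chroms)
    for sw in cfg.sweep_specs:
        in_iv = (chrom_arr == sw.chrom) & (pos_all >= sw.start) & (pos_all <= sw.end)
        pop_freq[sw.population][in_iv] = _sweep_pull(pop_freq[sw.population][in_iv], sw.s)
        sweep_label[in_iv] = np.where(
            sweep_label[in_iv] == "", sw.population, sweep_label[in_iv]
        )

    # genotypes
    popmap = cfg.population_map()
    sample_ids = list(popmap.assignments)
    calls = np.empty((len(sample_ids), n), dtype=np.int8)
    row = 0
    for label in cfg.pop_labels:
        n_samp = cfg.samples_per_pop
        draws = rng_geno.binomial(2, pop_freq[label][None, :], size=(n_samp, n))
        calls[row : row + n_samp] = draws
        row += n_samp

    # ref/alt alleles: random distinct bases, 2:1 ts:tv-ish mix not enforced
    ref_idx = rng_sites.integers(0, 4, size=n)
    alt_shift = rng_sites.integers(1, 4, size=n)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos_all,
            "ref": ref,
            "alt": [(a,) for a in alt],
        }
    )
    gm = GenotypeMatrix(sample_ids, calls, sites)

    truth = pd.DataFrame({"chrom": chroms, "pos": pos_all, "p_ancestral": p0})
    for label in cfg.pop_labels:
        truth[f"p_{label}"] = pop_freq[label]
    truth["sweep_population"] = sweep_label
    return gm, truth


def apply_missingness_and_depth(gm: GenotypeMatrix, cfg: SimulationConfig) -> GenotypeMatrix:
    """Knock out calls independently at ``missing_rate`` and attach Poisson depth.

    Missing calls get depth 0.
    """
    *_, rng_miss, rng_depth, _ = cfg.streams()
    calls = gm.calls.copy()
    miss = rng_miss.random(calls.shape) < cfg.missing_rate
    calls[miss] = MISSING
    depth = rng_depth.poisson(cfg.mean_depth, size=calls.shape).astype(np.int64)
    depth[calls == MISSING] = 0
    return GenotypeMatrix(list(gm.sample_ids), calls, gm.sites.copy(), depth)


# ---------------------------------------------------------------------------
# gene / genome fixtures


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)].copy()


def generate_gene_fixture(
    cfg: SimulationConfig,
    genes_per_chrom: int = 5,
    cds_exons: int = 2,
    codons_per_exon: int = 30,
    intron_length: int = 200,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Build a random genome FASTA plus non-overlapping multi-exon gene models.

    Each gene's spliced CDS starts with ATG, ends with a stop codon and has
    no internal stop; strands alternate. Genes keep >= 2,000 bp of upstream
    sequence except the first gene of chr1, which is placed deliberately
    close to the chromosome start to exercise promoter clipping.
    """
    rng = cfg.streams()[5]
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}

    n_codons_total = cds_exons * codons_per_exon
    cds_len = 3 * (n_codons_total + 2)  # ATG + codons + stop
    gene_len = cds_exons * 0  # computed below
    exon_lens = [3 * (n_codons_total + 2) // cds_exons] * cds_exons
    # make exon lengths sum to cds_len and each a multiple of 1 (frames handled)
    exon_lens[-1] += cds_len - sum(exon_lens)
    gene_len = sum(exon_lens) + (cds_exons - 1) * intron_length

    for ci, chrom in enumerate(cfg.chrom_names):
        seq = _random_seq(rng, cfg.chrom_length)
        spacing = cfg.chrom_length // (genes_per_chrom + 1)
        if spacing < gene_len + 2100:
            raise ConfigError("chromosome too short for the requested genes")
        for gi in range(genes_per_chrom):
            if ci == 0 and gi == 0:
                start = 500  # deliberately < 2000 bp from the edge
            else:
                start = (gi + 1) * spacing
            end = start + gene_len - 1
            strand = "+" if (gi % 2 == 0) else "-"
            gene_id = f"gene{ci + 1:02d}{gi + 1:03d}"

            codons = ["ATG"] + [
                _NONSTOP_CODONS[i]
                for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons_total)
            ] + ["TAA"]
            coding = "".join(codons)

            # carve exons separated by introns, in genomic order
            iv: list[tuple[int, int]] = []
            cur = start
            for L in exon_lens:
                iv.append((cur, cur + L - 1))
                cur += L + intron_length
            if strand == "-":
                # transcription runs right-to-left: 5' exon is the rightmost
                tx_order = iv[::-1]
            else:
                tx_order = iv

            # write coding sequence into the genome along transcription order
            offset = 0
            for s_, e_ in tx_order:
                L = e_ - s_ + 1
                chunk = coding[offset : offset + L]
                if strand == "-":
                    chunk = _revcomp(chunk)
                seq[s_ - 1 : e_] = list(chunk)
                offset += L

            # frames along transcription order
            cds_iv: list[tuple[int, int, int]] = []
            consumed = 0
            for s_, e_ in tx_order:
                frame = (3 - consumed % 3) % 3
                cds_iv.append((s_, e_, frame))
                consumed += e_ - s_ + 1

            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds_intervals=cds_iv,
                    exon_intervals=[(s_, e_) for s_, e_ in tx_order],
                )
            )
        genome[chrom] = "".join(seq)
    return genes, genome


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def spliced_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Return the gene's CDS spliced 5'->3' in transcription orientation."""
    seq = genome[gene.chrom]
    parts = []
    for s, e, _ in gene.cds_intervals:
        chunk = seq[s - 1 : e]
        if gene.strand == "-":
            chunk = _revcomp(chunk)
        parts.append(chunk)
    return "".join(parts)


# ---------------------------------------------------------------------------
# survival counts


def simulate_survival_counts(n_per_group: list[int], rates: list[float], seed: int):
    """Binomial survivor counts per group; returns a 2x2 contingency table."""
    from .phenotype import ContingencyTable2x2

    if len(n_per_group) != 2 or len(rates) != 2:
        raise ConfigError("exactly two groups expected")
    for r in rates:
        if not (0 <= r <= 1):
            raise ConfigError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    survived = [int(rng.binomial(n, r)) for n, r in zip(n_per_group, rates)]
    died = [n - s for n, s in zip(n_per_group, survived)]
    return ContingencyTable2x2(
        groups=("group1", "group2"), survived=tuple(survived), died=tuple(died)
    )


# ---------------------------------------------------------------------------
# fixture bundle


@dataclass
class FixtureBundle:
    vcf: Path
    gff: Path
    fasta: Path
    popmap: Path
    truth: Path


def write_fixture_bundle(
    cfg: SimulationConfig, outdir, genes_per_chrom: int = 5
) -> FixtureBundle:
    """Generate a mutually consistent VCF/GFF3/FASTA/popmap/truth-table set.

    The genome FASTA is patched so each SNP's reference base equals the VCF
    REF allele, which downstream annotation relies on.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, truth = simulate_genotypes(cfg)
    gm = apply_missingness_and_depth(gm, cfg)
    genes, genome = generate_gene_fixture(cfg, genes_per_chrom=genes_per_chrom)

    # make REF alleles consistent with the genome sequence
    patched = {c: list(s) for c, s in genome.items()}
    for chrom, pos, ref in zip(gm.sites["chrom"], gm.sites["pos"], gm.sites["ref"]):
        patched[chrom][pos - 1] = ref
    genome = {c: "".join(s) for c, s in patched.items()}

    b = FixtureBundle(
        vcf=outdir / "genotypes.vcf",
        gff=outdir / "genes.gff3",
        fasta=outdir / "genome.fasta",
        popmap=outdir / "popmap.tsv",
        truth=outdir / "truth.tsv",
    )
    write_vcf(gm, b.vcf)
    write_gff(genes, b.gff)
    write_fasta(genome, b.fasta)
    cfg.population_map().write(b.popmap)
    truth.to_csv(b.truth, sep="\t", index=False)
    return b
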