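"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here deliberately avoid the package's vectorised code paths:
pi is enumerated over explicit allele pairs with exact rational arithmetic,
the Weir-Cockerham components are a scalar transcription of the published
formulas, motif scanning goes through regex character classes, and
translation uses a literal codon table.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from popsweep import GenotypeMatrix, MISSING, PopulationMap


# ---------------------------------------------------------------------------
# builders


def make_matrix(calls, positions=None, chrom="chr1", ref="A", alt="G", depth=None,
                sample_prefix="S"):
    """GenotypeMatrix from a nested list (samples x sites) of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = list(range(1, n_sites + 1))
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": [ref] * n_sites,
            "alt": [(alt,)] * n_sites,
        }
    )
    depth_arr = None if depth is None else np.asarray(depth)
    return GenotypeMatrix(
        [f"{sample_prefix}{i + 1}" for i in range(n_samples)], calls, sites, depth_arr
    )


@pytest.fixture
def toy_vcf(tmp_path):
    """Hand-written 3-sample, 2-SNP VCF plus one indel and one multi-allelic record."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:10\t1|1:12\t./.:0
chr1\t250\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/0:9\t0/.:7\t0|1:11
chr1\t300\t.\tC\tCAT\t.\tPASS\t.\tGT:DP\t0/0:9\t0/0:7\t0/1:11
chr1\t400\t.\tG\tA,T\t.\tPASS\t.\tGT:DP\t1/2:9\t0/0:7\t0/1:11
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_gff(tmp_path):
    """Two genes, one per strand; minus-strand gene has two CDS chunks."""
    text = """##gff-version 3
chr1\ttest\tgene\t1001\t1600\t.\t+\t.\tID=gA
chr1\ttest\tmRNA\t1001\t1600\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\ttest\texon\t1001\t1200\t.\t+\t.\tParent=gA.t1
chr1\ttest\texon\t1401\t1600\t.\t+\t.\tParent=gA.t1
chr1\ttest\tCDS\t1001\t1200\t.\t+\t0\tParent=gA.t1
chr1\ttest\tCDS\t1401\t1600\t.\t+\t1\tParent=gA.t1
chr1\ttest\tgene\t5001\t5900\t.\t-\t.\tID=gB
chr1\ttest\tmRNA\t5001\t5900\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\ttest\tCDS\t5001\t5300\t.\t-\t0\tParent=gB.t1
chr1\ttest\tCDS\t5601\t5900\t.\t-\t0\tParent=gB.t1
"""
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


def two_pop_map(n_per=10, labels=("QZ", "WZ"), sample_ids=None):
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(2 * n_per)]
    return PopulationMap(
        {s: (labels[0] if i < n_per else labels[1]) for i, s in enumerate(sample_ids)}
    )


# ---------------------------------------------------------------------------
# oracles


def oracle_pi_window(calls: np.ndarray) -> Fraction:
    """Exact window pi: pooled pairwise differences / comparisons over sites.

    ``calls`` is samples x sites, complete or with MISSING.
    """
    n_diff = 0
    n_comp = 0
    for j in range(calls.shape[1]):
        alleles = []
        for dose in calls[:, j]:
            if dose == MISSING:
                continue
            alleles.extend([1] * int(dose) + [0] * (2 - int(dose)))
        for x, y in itertools.combinations(alleles, 2):
            n_comp += 1
            n_diff += int(x != y)
    if n_comp == 0:
        raise ZeroDivisionError("no comparisons")
    return Fraction(n_diff, n_comp)


def oracle_wc_site(callsA, callsB):
    """Scalar transcription of the Weir-Cockerham (1984) two-population
    variance components for one site; returns (a, b, c) or None if undefined."""
    stats = []
    for calls in (callsA, callsB):
        obs = [int(c) for c in calls if c != MISSING]
        n = len(obs)
        if n < 1:
            return None
        p = sum(obs) / (2 * n)
        h = sum(1 for c in obs if c == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def oracle_wc_fst(callsA, callsB):
    """Ratio-of-sums FST from the scalar per-site oracle; nan if undefined."""
    num = den = 0.0
    any_ok = False
    for j in range(callsA.shape[1]):
        comp = oracle_wc_site(callsA[:, j], callsB[:, j])
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
        any_ok = True
    if not any_ok or den == 0:
        return float("nan")
    return num / den


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def oracle_motif_hits(sequence: str, pattern: str):
    """Regex-based both-strand consensus scan; returns {(start_1based, strand)}."""
    seq = sequence.upper()
    hits = set()
    for strand, pat in (("+", pattern), ("-", pattern.translate(_COMP)[::-1])):
        regex = "".join(f"[{_IUPAC[ch]}]" for ch in pat.upper())
        for m in re.finditer(f"(?=({regex}))", seq):
            hits.add((m.start() + 1, strand))
    return hits


_CODON_TABLE = {}


def oracle_translate(cds: str) -> str:
    """Literal standard-genetic-code translation (independent of Biopython)."""
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        for i, (b1, b2, b3) in enumerate(itertools.product(bases, bases, bases)):
            _CODON_TABLE[b1 + b2 + b3] = aas[i]
    return "".join(
        _CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def oracle_r2(x, y):
    """Pairwise-complete squared Pearson correlation via numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    xv, yv = x[ok], y[ok]
    if len(xv) < 2 or xv.std() == 0 or yv.std() == 0:
        return float("nan")
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)
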