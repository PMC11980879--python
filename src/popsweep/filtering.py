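"""SNP site filters and LD pruning, applied in a fixed order with accounting.

The five steps, in order: (i) drop multi-allelic sites, (ii) drop sites with
mean depth < 4 across all samples, (iii) drop sites with minor allele
frequency < 0.05 (computed on non-missing alleles), (iv) keep sites genotyped
in at least 70% of samples, (v) prune SNPs in strong linkage disequilibrium
(sliding window, greedy removal of the later SNP of any pair with dosage
r^2 above the threshold). Boundaries are literal: MAF exactly 0.05 and call
rate exactly 0.70 are retained, mean depth exactly 4 is retained.

LD-pruning parameters default to common practice (window 50 SNPs, step 5,
r^2 > 0.2) and are fully configurable; r^2 is the squared Pearson correlation
of alt-allele dosages over pairwise-complete observations. Zero-variance
vectors leave r^2 undefined: the pair is skipped and both SNPs kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING


class FilterConfigError(ValueError):
    pass


@dataclass
class SiteFilterConfig:
    """Thresholds for the five filtering steps; ``None`` disables a step."""

    max_alleles: int | None = 2
    min_mean_depth: float | None = 4.0
    min_maf: float | None = 0.05
    min_call_rate: float | None = 0.70
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float | None = 0.2

    def __post_init__(self) -> None:
        if self.ld_step_snps > self.ld_window_snps:
            raise FilterConfigError("ld_step_snps must be <= ld_window_snps")
        for name in ("min_maf", "min_call_rate"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise FilterConfigError(f"{name} must lie in [0, 1]")


@dataclass
class FilterReport:
    """Telescoping per-step site accounting."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        self.steps.append(
            {"step": name, "sites_in": n_in, "sites_removed": n_removed, "sites_out": n_in - n_removed}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "sites_in", "sites_removed", "sites_out"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_biallelic(gm: GenotypeMatrix, max_alleles: int = 2) -> tuple[GenotypeMatrix, int]:
    """Keep sites with at most ``max_alleles`` alleles (ref + alts)."""
    keep = np.array([1 + len(a) <= max_alleles for a in gm.sites["alt"]], dtype=bool)
    return gm.take_sites(keep), int((~keep).sum())


def filter_mean_depth(gm: GenotypeMatrix, min_mean_depth: float = 4.0) -> tuple[GenotypeMatrix, int]:
    """Keep sites whose mean depth over ALL samples is >= the threshold.

    Missing genotypes contribute their recorded depth (0 when absent).
    """
    if gm.depth is None:
        raise FilterConfigError(
            "matrix has no per-sample depth; set min_mean_depth=None to disable this step"
        )
    keep = gm.depth.mean(axis=0) >= min_mean_depth
    return gm.take_sites(keep), int((~keep).sum())


def _maf(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site minor allele frequency on non-missing alleles; nan if all missing."""
    called = gm.calls != MISSING
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1 - p), n_alleles


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.05) -> tuple[GenotypeMatrix, int, int]:
    """Keep sites with MAF >= ``min_maf``.

    Returns (filtered matrix, n removed, n removed because all calls missing —
    a subset of n removed, counted separately).
    """
    maf, n_alleles = _maf(gm)
    all_missing = n_alleles == 0
    keep = ~all_missing & (maf >= min_maf)
    return gm.take_sites(keep), int((~keep).sum()), int(all_missing.sum())


def filter_call_rate(gm: GenotypeMatrix, min_call_rate: float = 0.70) -> tuple[GenotypeMatrix, int]:
    """Keep sites genotyped in at least ``min_call_rate`` of the samples."""
    rate = (gm.calls != MISSING).mean(axis=0)
    keep = rate >= min_call_rate
    return gm.take_sites(keep), int((~keep).sum())


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Returns nan when fewer than 2 complete pairs or either vector is constant.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, cfg: SiteFilterConfig) -> tuple[GenotypeMatrix, int]:
    """Greedy window-based LD pruning on dosage r^2.

    Windows of ``ld_window_snps`` SNPs advance by ``ld_step_snps`` within each
    chromosome; of any pair with r^2 > ``ld_r2_max`` the later SNP (position
    order) is removed. Pairs with undefined r^2 are skipped.
    """
    if cfg.ld_r2_max is None:
        return gm, 0
    removed = np.zeros(gm.n_sites, dtype=bool)
    chrom = gm.sites["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        n = len(idx)
        if n < 2:
            continue
        start = 0
        while True:
            window = idx[start : start + cfg.ld_window_snps]
            for a in range(len(window)):
                i = window[a]
                if removed[i]:
                    continue
                for b in range(a + 1, len(window)):
                    j = window[b]
                    if removed[j]:
                        continue
                    r2 = dosage_r2(gm.calls[:, i], gm.calls[:, j])
                    if np.isfinite(r2) and r2 > cfg.ld_r2_max:
                        removed[j] = True
            if start + cfg.ld_window_snps >= n:
                break
            start += cfg.ld_step_snps
    return gm.take_sites(~removed), int(removed.sum())


def apply_filters(
    gm: GenotypeMatrix, cfg: SiteFilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the five filters in order, returning the matrix and a telescoping report."""
    cfg = cfg or SiteFilterConfig()
    report = FilterReport()

    if cfg.max_alleles is not None:
        n_in = gm.n_sites
        gm, removed = filter_biallelic(gm, cfg.max_alleles)
        report.add("biallelic", n_in, removed)
    if cfg.min_mean_depth is not None:
        n_in = gm.n_sites
        gm, removed = filter_mean_depth(gm, cfg.min_mean_depth)
        report.add("mean_depth", n_in, removed)
    if cfg.min_maf is not None:
        n_in = gm.n_sites
        gm, removed, _ = filter_maf(gm, cfg.min_maf)
        report.add("maf", n_in, removed)
    if cfg.min_call_rate is not None:
        n_in = gm.n_sites
        gm, removed = filter_call_rate(gm, cfg.min_call_rate)
        report.add("call_rate", n_in, removed)
    if cfg.ld_r2_max is not None:
        n_in = gm.n_sites
        gm, removed = ld_prune(gm, cfg)
        report.add("ld_prune", n_in, removed)
    return gm, report
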