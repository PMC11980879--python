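"""Per-population diversity statistics and pairwise differentiation.

Statistics are computed per biallelic site on non-missing alleles only:

* nucleotide diversity pi in the missing-data-aware ("pixy") form — at a site
  with a alt and r ref allele copies among non-missing calls, the number of
  pairwise differences is a*r and the number of pairwise comparisons is
  C(a+r, 2); site pi = a*r / C(a+r,2), and multi-site (window) pi is the
  ratio of the summed numerators to the summed denominators;
* observed heterozygosity Ho = fraction of heterozygous calls;
* expected heterozygosity He = 2pq and its small-sample correction
  uHe = 2n/(2n-1) * He with n the number of non-missing diploid genotypes;
* polymorphic information content (Botstein) PIC = 1 - (p^2+q^2) - 2 p^2 q^2;
* Shannon information index I = -(p ln p + q ln q).

Between-population differentiation uses the Weir & Cockerham (1984)
variance-components FST estimator: per-site among- (a) and within-population
(b, c) components, combined across sites as sum(a) / sum(a+b+c). The raw
multi-site value may be negative; it is clamped to 0 for reporting and for
the qualitative differentiation bins (<0.05 very low, 0.05-0.15 moderate,
0.15-0.25 considerable, >=0.25 high).

Reported pi is averaged over variant sites only (the input VCF carries no
invariant sites), so it is not a per-bp diversity; see the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING, PopulationMap

FST_BINS = (
    (0.05, "very-low"),
    (0.15, "moderate"),
    (0.25, "considerable"),
)


def _pop_idx(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> np.ndarray:
    return gm.sample_indices(popmap.samples(pop))


def allele_frequencies(
    gm: GenotypeMatrix, sample_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt-allele frequency and non-missing allele count for a subset.

    Frequency is nan at sites where every call in the subset is missing.
    """
    if len(sample_index) == 0:
        raise ValueError("empty population")
    calls = gm.calls[sample_index]
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def pi_sites(
    gm: GenotypeMatrix, sample_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Missing-data-aware per-site pi plus its pooled numerators/denominators.

    Returns (pi, n_diff, n_comp); pi is nan where n_comp == 0 and such sites
    are excluded from any pooled sum downstream.
    """
    calls = gm.calls[sample_index]
    called = calls != MISSING
    a = np.where(called, calls, 0).sum(axis=0)  # alt allele copies
    n = 2 * called.sum(axis=0)
    r = n - a
    n_diff = (a * r).astype(float)
    n_comp = (n * (n - 1) / 2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
    return pi, n_diff, n_comp


def observed_heterozygosity(
    gm: GenotypeMatrix, sample_index: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-site Ho and its mean over sites with at least one call."""
    calls = gm.calls[sample_index]
    called = calls != MISSING
    n = called.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return ho, float(np.nanmean(ho)) if np.isfinite(ho).any() else float("nan")


def expected_heterozygosity(
    gm: GenotypeMatrix, sample_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site He = 2pq and unbiased uHe = (2n/(2n-1)) He."""
    p, n_alleles = allele_frequencies(gm, sample_index)
    he = 2 * p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n_alleles > 1, n_alleles / np.maximum(n_alleles - 1, 1), np.nan)
    return he, corr * he


def pic(gm: GenotypeMatrix, sample_index: np.ndarray) -> np.ndarray:
    """Botstein polymorphic information content, biallelic closed form."""
    p, _ = allele_frequencies(gm, sample_index)
    q = 1 - p
    return 1 - (p**2 + q**2) - 2 * p**2 * q**2


def shannon_index(gm: GenotypeMatrix, sample_index: np.ndarray) -> np.ndarray:
    """Shannon information index over the two allele frequencies."""
    p, _ = allele_frequencies(gm, sample_index)
    out = np.zeros_like(p)
    for freq in (p, 1 - p):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(freq > 0, freq * np.log(np.maximum(freq, 1e-300)), 0.0)
        out -= term
    out[np.isnan(p)] = np.nan
    return out


def diversity_summary(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population mean pi, Ho, He, uHe, PIC and Shannon index over variant sites."""
    rows = []
    for pop in popmap.populations:
        idx = _pop_idx(gm, popmap, pop)
        pi, _, _ = pi_sites(gm, idx)
        ho, ho_mean = observed_heterozygosity(gm, idx)
        he, uhe = expected_heterozygosity(gm, idx)
        rows.append(
            {
                "population": pop,
                "n_samples": len(idx),
                "pi": float(np.nanmean(pi)),
                "Ho": ho_mean,
                "He": float(np.nanmean(he)),
                "uHe": float(np.nanmean(uhe)),
                "PIC": float(np.nanmean(pic(gm, idx))),
                "shannon": float(np.nanmean(shannon_index(gm, idx))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) FST


def wc_components(
    callsA: np.ndarray, callsB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham variance components (a, b, c) for two populations.

    ``callsA``/``callsB`` are dosage matrices (samples x sites) with MISSING
    sentinels. Components are nan at sites where either population has fewer
    than one called genotype or the mean sample size is <= 1.
    """
    comps = []
    ns = []
    ps = []
    hs = []
    for calls in (callsA, callsB):
        called = calls != MISSING
        n_i = called.sum(axis=0).astype(float)  # diploid individuals
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / np.maximum(2 * n_i, 1), np.nan)
            h_i = np.where(n_i > 0, (calls == 1).sum(axis=0) / np.maximum(n_i, 1), np.nan)
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(
    gm: GenotypeMatrix,
    idxA: np.ndarray,
    idxB: np.ndarray,
    site_index: np.ndarray | None = None,
) -> float:
    """Multi-site Weir–Cockerham FST (ratio of sums); nan when undefined.

    The returned value is raw (may be negative); use :func:`clamp_fst` for
    reporting/classification.
    """
    callsA = gm.calls[idxA]
    callsB = gm.calls[idxB]
    if site_index is not None:
        callsA = callsA[:, site_index]
        callsB = callsB[:, site_index]
    a, b, c = wc_components(callsA, callsB)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def clamp_fst(fst: float) -> float:
    if np.isnan(fst):
        return fst
    return max(0.0, fst)


def classify_fst(fst: float) -> str:
    """Qualitative differentiation label for a (clamped) FST value."""
    v = clamp_fst(float(fst))
    if np.isnan(v):
        return "undefined"
    for upper, label in FST_BINS:
        if v < upper:
            return label
    return "high"


def fst_matrix(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """All pairwise multi-site FST values with classification labels."""
    pops = popmap.populations
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            raw = wc_fst(gm, _pop_idx(gm, popmap, pa), _pop_idx(gm, popmap, pb))
            rows.append(
                {
                    "pop_a": pa,
                    "pop_b": pb,
                    "fst_raw": raw,
                    "fst": clamp_fst(raw),
                    "classification": classify_fst(raw),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 2, scale: bool = False):
    """PCA of mean-imputed, centred genotype dosages.

    Returns (coordinates DataFrame indexed by sample, explained-variance
    fractions).
    """
    from sklearn.decomposition import PCA

    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = gm.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean[np.isnan(col_mean)] = 0.0
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X -= col_mean
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    k = min(n_components, gm.n_samples - 1, gm.n_sites)
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    df = pd.DataFrame(
        coords, index=gm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, model.explained_variance_ratio_
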