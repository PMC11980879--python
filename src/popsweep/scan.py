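"""Windowed FST / pi genome scan with a permutation null and joint sweep detection.

The scan tiles each chromosome into windows (default 10 kb, non-overlapping),
computes per-window Weir–Cockerham FST between a reference and a focal
population and missing-data-aware pi within each, and screens for selective
sweeps in the focal population with a joint criterion: a window is a
candidate iff its FST is in the top quantile (default 5%) of defined window
FSTs AND its log2(pi_ref / pi_focal) is in the top quantile of defined
ratios. Candidate windows touching or overlapping each other are merged into
sweep regions, which can then be associated with overlapping genes.

The significance baseline is a permutation null: population labels are
shuffled (group sizes preserved), the windowed FST scan recomputed, and all
permuted window values pooled into a single genome-wide null distribution
whose 95th percentile serves as the baseline FST expected under no
differentiation.

The statsmodels-style entry point is :class:`SweepScan` (model) whose
``fit()`` returns a :class:`SweepScanResults` carrying the window table,
thresholds, permutation null, merged regions and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import clamp_fst, wc_components
from .io import GeneModel, GenotypeMatrix, MISSING, PopulationMap


class ScanConfigError(ValueError):
    pass


@dataclass
class ScanConfig:
    """Geometry and thresholds of the genome scan."""

    window_size: int = 10_000
    step_size: int = 10_000
    top_quantile: float = 0.05
    n_permutations: int = 1_000
    permutation_seed: int = 0
    null_quantile: float = 0.95
    quantile_method: str = "linear"  # numpy interpolation convention

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ScanConfigError("window_size must be positive")
        if self.step_size > self.window_size:
            raise ScanConfigError("step_size must be <= window_size")
        if not (0 < self.top_quantile < 1):
            raise ScanConfigError("top_quantile must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ScanConfigError("n_permutations must be >= 1")


@dataclass
class PermutationNull:
    """Pooled permuted window-FST values and their upper percentile."""

    n_perm: int
    values: np.ndarray
    percentile95: float
    quantile: float = 0.95


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    window_index: list[int] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def make_windows(chrom_lengths: dict[str, int], cfg: ScanConfig) -> pd.DataFrame:
    """Tile chromosomes into windows; last partial window kept and flagged.

    Start/end are 1-based inclusive.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        for start0 in range(0, length, cfg.step_size):
            end0 = min(start0 + cfg.window_size, length)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start0 + 1,
                    "end": end0,
                    "partial": end0 - start0 < cfg.window_size,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def _window_sums(
    pos: np.ndarray, windows: pd.DataFrame, per_site: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Sum per-site arrays over windows of one chromosome via prefix sums.

    ``pos`` must be sorted ascending; nan entries contribute 0.
    """
    csums = {}
    counts_key = {}
    for name, arr in per_site.items():
        filled = np.nan_to_num(arr, nan=0.0)
        csums[name] = np.concatenate([[0.0], np.cumsum(filled)])
        counts_key[name] = np.concatenate(
            [[0], np.cumsum(np.isfinite(arr).astype(int))]
        )
    lo = np.searchsorted(pos, windows["start"].to_numpy(), side="left")
    hi = np.searchsorted(pos, windows["end"].to_numpy(), side="right")
    out = {}
    for name in per_site:
        out[name] = csums[name][hi] - csums[name][lo]
        out[name + "_n"] = counts_key[name][hi] - counts_key[name][lo]
    return out


def _per_site_arrays(
    calls: np.ndarray, maskA: np.ndarray, maskB: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-site WC components for A vs B and pi numerators/denominators per group."""
    a, b, c = wc_components(calls[maskA], calls[maskB])
    out = {"a": a, "abc": a + b + c}
    for tag, mask in (("A", maskA), ("B", maskB)):
        sub = calls[mask]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        ref = n - alt
        out[f"diff{tag}"] = (alt * ref).astype(float)
        out[f"comp{tag}"] = (n * (n - 1) / 2).astype(float)
    return out


def _windows_from_sites(
    gm: GenotypeMatrix, windows: pd.DataFrame, per_site: dict[str, np.ndarray]
) -> pd.DataFrame:
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()
    pieces = []
    for chrom in windows["chrom"].unique():
        wsub = windows[windows["chrom"] == chrom]
        site_sel = chrom_arr == chrom
        pos = pos_arr[site_sel]
        local = {k: v[site_sel] for k, v in per_site.items()}
        sums = _window_sums(pos, wsub, local)
        piece = wsub.copy()
        piece["n_sites"] = sums["a_n"]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst_raw = np.where(sums["abc"] != 0, sums["a"] / sums["abc"], np.nan)
            fst_raw = np.where(sums["a_n"] > 0, fst_raw, np.nan)
            piA = np.where(sums["compA"] > 0, sums["diffA"] / sums["compA"], np.nan)
            piB = np.where(sums["compB"] > 0, sums["diffB"] / sums["compB"], np.nan)
        piece["fst_raw"] = fst_raw
        piece["fst"] = np.where(np.isnan(fst_raw), np.nan, np.maximum(fst_raw, 0.0))
        piece["pi_ref"] = piA
        piece["pi_focal"] = piB
        with np.errstate(invalid="ignore", divide="ignore"):
            piece["log2_ratio"] = np.log2(piA / piB)
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def scan_windows(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    reference: str,
    focal: str,
    cfg: ScanConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window FST and per-population pi between a reference and focal population.

    Windows with no usable site carry nan statistics (excluded from
    quantiles downstream). ``log2_ratio`` is log2(pi_ref / pi_focal): +inf
    when the focal population has zero diversity but the reference does not.
    """
    for pop in (reference, focal):
        if pop not in popmap.populations:
            raise KeyError(f"population {pop!r} not in population map")
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(gm.sites.loc[gm.sites["chrom"] == c, "pos"].max())
            for c in pd.unique(gm.sites["chrom"])
        }
    windows = make_windows(chrom_lengths, cfg)
    maskA = np.zeros(gm.n_samples, dtype=bool)
    maskA[gm.sample_indices(popmap.samples(reference))] = True
    maskB = np.zeros(gm.n_samples, dtype=bool)
    maskB[gm.sample_indices(popmap.samples(focal))] = True
    per_site = _per_site_arrays(gm.calls, maskA, maskB)
    return _windows_from_sites(gm, windows, per_site)


def permute_fst_null(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    reference: str,
    focal: str,
    cfg: ScanConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> PermutationNull:
    """Pooled null distribution of window FST under shuffled population labels.

    Each permutation reassigns the combined reference+focal samples to two
    groups of the original sizes and recomputes the windowed FST exactly as
    :func:`scan_windows`; all defined permuted window values are pooled and
    the configured upper quantile (default 0.95) is the baseline.
    """
    idxA = gm.sample_indices(popmap.samples(reference))
    idxB = gm.sample_indices(popmap.samples(focal))
    if len(idxA) < 2 or len(idxB) < 2:
        raise ValueError("each group needs at least 2 samples for permutation")
    combined = np.concatenate([idxA, idxB])
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(gm.sites.loc[gm.sites["chrom"] == c, "pos"].max())
            for c in pd.unique(gm.sites["chrom"])
        }
    rng = np.random.default_rng(cfg.permutation_seed)
    pooled: list[np.ndarray] = []
    windows = make_windows(chrom_lengths, cfg)
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(combined)
        maskA = np.zeros(gm.n_samples, dtype=bool)
        maskA[perm[: len(idxA)]] = True
        maskB = np.zeros(gm.n_samples, dtype=bool)
        maskB[perm[len(idxA) :]] = True
        per_site = _per_site_arrays(gm.calls, maskA, maskB)
        wtab = _windows_from_sites(gm, windows, per_site)
        vals = wtab["fst_raw"].to_numpy()
        pooled.append(vals[np.isfinite(vals)])
    values = np.concatenate(pooled) if pooled else np.array([])
    pct = float(np.quantile(values, cfg.null_quantile, method=cfg.quantile_method))
    return PermutationNull(
        n_perm=cfg.n_permutations,
        values=values,
        percentile95=pct,
        quantile=cfg.null_quantile,
    )


def top_quantile_threshold(
    values: np.ndarray, q: float = 0.05, method: str = "linear"
) -> tuple[float, np.ndarray]:
    """(1-q) quantile of the defined values and the indices at/above it."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no defined values")
    thr = float(np.quantile(values[finite], 1 - q, method=method))
    idx = np.flatnonzero(finite & (values >= thr))
    return thr, idx


def detect_sweep_regions(
    windows: pd.DataFrame, cfg: ScanConfig
) -> tuple[list[SweepRegion], float, float]:
    """Joint FST + log2(pi-ratio) top-quantile screen, with region merging.

    A window is a candidate iff its FST is at/above the top-quantile FST
    threshold AND its log2 ratio is at/above the top-quantile ratio threshold
    (windows where the focal pi is 0 but the reference pi is positive count
    as above the ratio threshold; windows where both are 0 are excluded).
    Adjacent or overlapping candidate windows merge into regions. The input
    row order does not matter.

    Returns (regions, fst_threshold, ratio_threshold).
    """
    w = windows.sort_values(["chrom", "start"]).reset_index()
    fst = w["fst_raw"].to_numpy(dtype=float)
    ratio = w["log2_ratio"].to_numpy(dtype=float)
    pi_ref = w["pi_ref"].to_numpy(dtype=float)
    pi_focal = w["pi_focal"].to_numpy(dtype=float)

    fst_thr, _ = top_quantile_threshold(fst, cfg.top_quantile, cfg.quantile_method)
    finite_ratio = np.isfinite(ratio)
    ratio_thr = float(
        np.quantile(ratio[finite_ratio], 1 - cfg.top_quantile, method=cfg.quantile_method)
    )

    focal_zero = (pi_focal == 0) & (pi_ref > 0)
    both_zero = (pi_focal == 0) & (pi_ref == 0)
    ratio_pass = (finite_ratio & (ratio >= ratio_thr)) | focal_zero
    candidate = np.isfinite(fst) & (fst >= fst_thr) & ratio_pass & ~both_zero

    regions: list[SweepRegion] = []
    for i in np.flatnonzero(candidate):
        chrom = w.at[i, "chrom"]
        start, end = int(w.at[i, "start"]), int(w.at[i, "end"])
        orig = int(w.at[i, "index"])
        if regions and regions[-1].chrom == chrom and start <= regions[-1].end + 1:
            regions[-1].end = max(regions[-1].end, end)
            regions[-1].window_index.append(orig)
        else:
            regions.append(SweepRegion(chrom=chrom, start=start, end=end, window_index=[orig]))
    return regions, fst_thr, ratio_thr


def genes_in_regions(
    regions: list[SweepRegion], genes: list[GeneModel]
) -> tuple[dict[tuple[str, int, int], list[str]], list[str]]:
    """Associate genes overlapping each region by >= 1 bp.

    Returns (region-key -> gene ids, deduplicated flat list ordered by
    position). Raises if region and gene chromosome names share nothing.
    """
    if regions and genes:
        rchroms = {r.chrom for r in regions}
        gchroms = {g.chrom for g in genes}
        if not (rchroms & gchroms):
            raise ValueError(
                f"chromosome names do not match: regions use {sorted(rchroms)}, "
                f"genes use {sorted(gchroms)}"
            )
    table: dict[tuple[str, int, int], list[str]] = {}
    flat: list[tuple[str, int, str]] = []
    for r in regions:
        hits = [
            g for g in genes if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start
        ]
        hits.sort(key=lambda g: (g.chrom, g.start))
        table[(r.chrom, r.start, r.end)] = [g.gene_id for g in hits]
        r.gene_ids = [g.gene_id for g in hits]
        flat.extend((g.chrom, g.start, g.gene_id) for g in hits)
    seen: list[str] = []
    for _, _, gid in sorted(flat):
        if gid not in seen:
            seen.append(gid)
    return table, seen


def intersect_gene_sets(set_a, set_b) -> list[str]:
    """Set intersection with duplicates collapsed, ordered as in ``set_a``."""
    b = set(set_b)
    out: list[str] = []
    for g in set_a:
        if g in b and g not in out:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Model / Results


class SweepScan:
    """Genome-scan model for sweep detection in a focal population.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Filtered biallelic SNP matrix.
    popmap : PopulationMap
        Sample-to-population assignment.
    reference, focal : str
        Population labels; the pi ratio is pi_reference / pi_focal, so a
        sweep in the focal population raises the ratio.
    config : ScanConfig
    chrom_lengths : dict, optional
        Chromosome lengths; inferred from the site table when omitted.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        popmap: PopulationMap,
        reference: str,
        focal: str,
        config: ScanConfig | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.genotypes = genotypes
        self.popmap = popmap
        self.reference = reference
        self.focal = focal
        self.config = config or ScanConfig()
        self.chrom_lengths = chrom_lengths

    def fit(self, permute: bool = True, seed: int | None = None) -> "SweepScanResults":
        """Run the windowed scan, the permutation null and the joint screen."""
        cfg = self.config
        if seed is not None:
            cfg = ScanConfig(**{**cfg.__dict__, "permutation_seed": seed})
        windows = scan_windows(
            self.genotypes, self.popmap, self.reference, self.focal, cfg, self.chrom_lengths
        )
        null = None
        if permute:
            null = permute_fst_null(
                self.genotypes, self.popmap, self.reference, self.focal, cfg, self.chrom_lengths
            )
        regions, fst_thr, ratio_thr = detect_sweep_regions(windows, cfg)
        return SweepScanResults(self, cfg, windows, null, regions, fst_thr, ratio_thr)


class SweepScanResults:
    """Fitted genome scan: window table, thresholds, null and sweep regions."""

    def __init__(self, model, config, windows, null, regions, fst_threshold, ratio_threshold):
        self.model = model
        self.config = config
        self.windows = windows
        self.null = null
        self.regions = regions
        self.fst_threshold = fst_threshold
        self.ratio_threshold = ratio_threshold
        self.candidate_genes: list[str] = []

    def associate_genes(self, genes: list[GeneModel]) -> list[str]:
        """Attach overlapping genes to each region; returns the flat candidate list."""
        _, flat = genes_in_regions(self.regions, genes)
        self.candidate_genes = flat
        return flat

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_windows": len(r.window_index),
                    "genes": ",".join(r.gene_ids),
                }
                for r in self.regions
            ],
            columns=["chrom", "start", "end", "n_windows", "genes"],
        )

    def summary(self) -> str:
        w = self.windows
        defined = w["fst_raw"].notna().sum()
        obs_fst = w["fst_raw"].to_numpy(dtype=float)
        obs_fst = obs_fst[np.isfinite(obs_fst)]
        lines = [
            "Selective sweep scan (windowed Weir-Cockerham FST + pi ratio)",
            "=" * 62,
            f"reference population:      {self.model.reference}",
            f"focal population:          {self.model.focal}",
            f"window / step:             {self.config.window_size} / {self.config.step_size} bp",
            f"windows (defined FST):     {len(w)} ({defined})",
            f"mean window FST:           {obs_fst.mean():.4f}" if len(obs_fst) else "mean window FST: nan",
            f"top-{self.config.top_quantile:.0%} FST threshold:     {self.fst_threshold:.4f}",
            f"top-{self.config.top_quantile:.0%} log2-ratio threshold: {self.ratio_threshold:.4f}",
        ]
        if self.null is not None:
            lines.append(
                f"permutation null ({self.null.n_perm} perms), "
                f"{self.null.quantile:.0%} percentile: {self.null.percentile95:.4f}"
            )
        lines.append(f"sweep regions detected:    {len(self.regions)}")
        for r in self.regions:
            genes = f" [{', '.join(r.gene_ids)}]" if r.gene_ids else ""
            lines.append(f"  {r.chrom}:{r.start}-{r.end} ({len(r.window_index)} windows){genes}")
        if self.candidate_genes:
            lines.append(f"candidate genes:           {len(self.candidate_genes)}")
        return "\n".join(lines)

    # -- output ------------------------------------------------------------
    def windows_to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)

    def regions_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{','.join(r.gene_ids) or '.'}\n")

    def plot_manhattan(self, ax=None):
        """Manhattan-style plot of window FST with the joint-screen threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        ticks, labels = [], []
        for i, (chrom, sub) in enumerate(self.windows.groupby("chrom", sort=False)):
            mid = (sub["start"] + sub["end"]) / 2 + offset
            ax.scatter(mid, sub["fst"], s=4, color=["#4477AA", "#CCBB44"][i % 2])
            ticks.append(float(mid.mean()))
            labels.append(chrom)
            offset += float(sub["end"].max())
        ax.axhline(max(self.fst_threshold, 0.0), ls="--", color="red", lw=0.8)
        ax.set_xticks(ticks, labels)
        ax.set_ylabel(r"window $F_{ST}$")
        return ax
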