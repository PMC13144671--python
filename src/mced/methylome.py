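"""CpG-level methylation handling: site filtering, status classification,
region construction, AMF quantification and differential-region selection.

The central quantity is the average methylation fraction (AMF) of a region:
the unweighted mean, over the region's covered CpG sites, of the per-site
methylated-read fraction ``C / (C + T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CpGCountTable",
    "MethylRegion",
    "STATUS_METHYLATED",
    "STATUS_UNMETHYLATED",
    "STATUS_NEUTRAL",
    "filter_sites",
    "classify_cpg_status",
    "build_regions",
    "compute_amf",
    "bh_fdr",
    "select_dmrs",
    "concordance_filter",
]

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_NEUTRAL = "neutral"

DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class CpGCountTable:
    """Per-sample cytosine/thymine counts on a shared CpG site grid.

    ``sites`` holds one row per CpG (columns ``chrom``, ``pos0``, ``strand``),
    sorted by (chrom, pos0); ``C`` and ``T`` are (n_sites, n_samples) integer
    arrays aligned to ``samples``.
    """

    sites: pd.DataFrame
    C: np.ndarray
    T: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C)
        self.T = np.asarray(self.T)
        if self.C.shape != self.T.shape:
            raise ValueError("C and T shapes differ")
        if self.C.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays not aligned with sites/samples")
        if (self.C < 0).any() or (self.T < 0).any():
            raise ValueError("negative counts")
        key = self.sites[["chrom", "pos0"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos0) sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def coverage(self) -> np.ndarray:
        return self.C + self.T

    def beta(self) -> np.ndarray:
        """Per-site, per-sample methylation level C/(C+T); NaN where uncovered."""
        cov = self.coverage()
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(cov > 0, self.C / np.where(cov > 0, cov, 1), np.nan)
        return b

    def sample_index(self, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return np.array([pos[s] for s in ids], dtype=int)

    def subset_sites(self, mask: np.ndarray) -> "CpGCountTable":
        mask = np.asarray(mask, dtype=bool)
        return CpGCountTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.C[mask], self.T[mask], list(self.samples),
        )

    def subset_samples(self, ids: list[str]) -> "CpGCountTable":
        idx = self.sample_index(ids)
        return CpGCountTable(self.sites.copy(), self.C[:, idx], self.T[:, idx], list(ids))

    # Wide TSV: chrom, pos0, strand, then <sample>:C / <sample>:T column pairs.
    def to_tsv(self, path) -> None:
        cols = {}
        for i, s in enumerate(self.samples):
            cols[f"{s}:C"] = self.C[:, i]
            cols[f"{s}:T"] = self.T[:, i]
        df = pd.concat([self.sites, pd.DataFrame(cols, index=self.sites.index)], axis=1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CpGCountTable":
        df = pd.read_csv(path, sep="\t")
        meta = ["chrom", "pos0", "strand"]
        samples = []
        for col in df.columns:
            if col.endswith(":C"):
                samples.append(col[:-2])
        C = df[[f"{s}:C" for s in samples]].to_numpy(dtype=np.int64)
        T = df[[f"{s}:T" for s in samples]].to_numpy(dtype=np.int64)
        return cls(df[meta].copy(), C, T, samples)


@dataclass
class MethylRegion:
    """A maximal run of contiguous CpG sites sharing a methylation status."""

    region_id: str
    chrom: str
    start: int
    end: int  # 0-based half-open
    status: str
    site_idx: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.site_idx = np.asarray(self.site_idx, dtype=int)
        if self.site_idx.size == 0:
            raise ValueError("region with zero member sites")
        if self.status not in (STATUS_METHYLATED, STATUS_UNMETHYLATED):
            raise ValueError(f"invalid region status {self.status!r}")


def filter_sites(
    table: CpGCountTable,
    healthy_ids: list[str],
    min_cov: float = 3.0,
    blacklist=None,
    sex_chroms=DEFAULT_SEX_CHROMS,
    coverage_agg: str = "mean",
) -> CpGCountTable:
    """Drop low-coverage, blacklisted and sex-chromosome CpG sites.

    Coverage is aggregated across the healthy samples; ``coverage_agg`` is
    either ``"mean"`` (default convention) or ``"all"`` (every healthy sample
    must individually reach ``min_cov``).
    """
    if not healthy_ids:
        raise ValueError("healthy sample set must be non-empty")
    idx = table.sample_index(healthy_ids)
    cov = table.coverage()[:, idx]
    if coverage_agg == "mean":
        keep = cov.mean(axis=1) >= min_cov
    elif coverage_agg == "all":
        keep = (cov >= min_cov).all(axis=1)
    else:
        raise ValueError(f"unknown coverage_agg {coverage_agg!r}")

    chroms = table.sites["chrom"].to_numpy()
    keep &= ~np.isin(chroms, list(sex_chroms))

    if blacklist:
        pos0 = table.sites["pos0"].to_numpy()
        bl = np.zeros(table.n_sites, dtype=bool)
        for chrom, start, end in blacklist:
            if start >= end:
                raise ValueError(f"blacklist interval with start >= end: {chrom}:{start}-{end}")
            bl |= (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        keep &= ~bl

    return table.subset_sites(keep)


def classify_cpg_status(
    table: CpGCountTable,
    healthy_ids: list[str],
    pct: float = 10.0,
    beta_cut: float = 0.5,
) -> np.ndarray:
    """Three-way methylation status per site from mean healthy beta.

    Unmethylated: strictly below the ``pct`` percentile of per-site mean
    healthy beta AND below ``beta_cut``. Methylated: strictly above the
    ``100 - pct`` percentile AND above ``beta_cut``. Everything else,
    including ties with the percentile cutpoints, is neutral.
    """
    if not (0 < pct < 50):
        raise ValueError("pct must lie in (0, 50)")
    if not healthy_ids:
        raise ValueError("healthy sample set must be non-empty")
    idx = table.sample_index(healthy_ids)
    beta = table.beta()[:, idx]
    with np.errstate(invalid="ignore"):
        mean_beta = np.nanmean(beta, axis=1)

    defined = ~np.isnan(mean_beta)
    status = np.full(table.n_sites, STATUS_NEUTRAL, dtype=object)
    if defined.sum() == 0:
        return status
    lo = np.percentile(mean_beta[defined], pct)
    hi = np.percentile(mean_beta[defined], 100 - pct)
    status[defined & (mean_beta < lo) & (mean_beta < beta_cut)] = STATUS_UNMETHYLATED
    status[defined & (mean_beta > hi) & (mean_beta > beta_cut)] = STATUS_METHYLATED
    return status


def build_regions(
    status: np.ndarray,
    sites: pd.DataFrame,
    min_cpg: int = 3,
) -> list[MethylRegion]:
    """Run-length-encode non-neutral statuses into regions.

    Runs are maximal stretches of identical non-neutral status, split at
    chromosome boundaries; runs shorter than ``min_cpg`` are dropped.
    """
    if len(status) != len(sites):
        raise ValueError("status vector not aligned with sites")
    chroms = sites["chrom"].to_numpy()
    pos0 = sites["pos0"].to_numpy()
    order_ok = True
    for c in pd.unique(chroms):
        p = pos0[chroms == c]
        if np.any(np.diff(p) <= 0):
            order_ok = False
            break
    if not order_ok:
        raise ValueError("sites must be sorted by (chrom, pos0)")

    regions: list[MethylRegion] = []
    n = len(status)
    i = 0
    while i < n:
        st = status[i]
        if st == STATUS_NEUTRAL:
            i += 1
            continue
        j = i
        while j + 1 < n and status[j + 1] == st and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_cpg:
            rid = f"r{len(regions):06d}_{chroms[i]}_{pos0[i]}"
            regions.append(MethylRegion(
                region_id=rid, chrom=chroms[i],
                start=int(pos0[i]), end=int(pos0[j]) + 1,
                status=st, site_idx=np.arange(i, j + 1),
            ))
        i = j + 1
    return regions


def compute_amf(table: CpGCountTable, regions: list[MethylRegion]) -> pd.DataFrame:
    """Samples x regions AMF matrix.

    AMF of a region is the unweighted mean of per-site C/(C+T) over the
    region's covered member sites; NaN when no member site is covered.
    """
    beta = table.beta()
    out = np.empty((len(table.samples), len(regions)))
    for k, reg in enumerate(regions):
        sub = beta[reg.site_idx, :]
        covered = (~np.isnan(sub)).sum(axis=0)
        total = np.nansum(sub, axis=0)
        out[:, k] = np.where(covered > 0, total / np.where(covered > 0, covered, 1), np.nan)
    return pd.DataFrame(out, index=list(table.samples),
                        columns=[r.region_id for r in regions])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


MARKER_COLUMNS = ["region_id", "comparison", "direction", "p_value", "q_value", "target"]


def select_dmrs(
    amf: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fdr: float = 0.05,
    comparison: str = "cfdna-cancer-vs-healthy",
    target: str = "",
) -> tuple[pd.DataFrame, list[str]]:
    """Welch-t differential regions between two sample groups of an AMF matrix.

    Returns (markers, skipped_region_ids). Regions with fewer than two
    defined AMF values in either group are skipped, not failed. Direction is
    ``hyper`` when mean(group_a) > mean(group_b), else ``hypo``. q-values are
    BH-adjusted across the tested regions of this comparison only.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = amf.loc[list(group_a)].to_numpy(dtype=float)
    b = amf.loc[list(group_b)].to_numpy(dtype=float)

    na = (~np.isnan(a)).sum(axis=0)
    nb = (~np.isnan(b)).sum(axis=0)
    testable = (na >= 2) & (nb >= 2)
    skipped = [c for c, t in zip(amf.columns, testable) if not t]
    if not testable.any():
        return pd.DataFrame(columns=MARKER_COLUMNS), skipped

    at = a[:, testable]
    bt = b[:, testable]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(at, bt, axis=0, equal_var=False, nan_policy="omit")
        pvals = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups -> undefined t; treat as null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_fdr(pvals)

    mean_a = np.nanmean(at, axis=0)
    mean_b = np.nanmean(bt, axis=0)
    direction = np.where(mean_a > mean_b, "hyper", "hypo")

    cols = np.asarray(amf.columns)[testable]
    keep = qvals < fdr
    markers = pd.DataFrame({
        "region_id": cols[keep],
        "comparison": comparison,
        "direction": direction[keep],
        "p_value": pvals[keep],
        "q_value": qvals[keep],
        "target": target,
    })
    return markers.reset_index(drop=True), skipped


def concordance_filter(tissue_markers: pd.DataFrame, cfdna_markers: pd.DataFrame) -> pd.DataFrame:
    """Keep cfDNA markers whose direction agrees with the tissue marker for
    the same region and target. Records from the cfDNA set are returned."""
    if tissue_markers.empty or cfdna_markers.empty:
        return cfdna_markers.iloc[0:0].copy()
    key = tissue_markers[["region_id", "target", "direction"]].drop_duplicates()
    merged = cfdna_markers.merge(key, on=["region_id", "target", "direction"], how="inner")
    return merged.reset_index(drop=True)
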