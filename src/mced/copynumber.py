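"""Bin-level copy-ratio analysis: healthy-median reference normalization,
2-sigma alteration calling, prevalence-rule marker selection with a
healthy-exclusion step (guards against clonal-hematopoiesis-like signal),
and the marker-frequency CSD score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CopyRatioMatrix",
    "CNVMarkerSet",
    "normalize_bins",
    "call_alterations",
    "select_cnv_markers",
    "cnv_csd_score",
]

GAIN, LOSS, NONE = 1, -1, 0
_PSEUDO = 0.5  # pseudocount on depth-scaled counts; keeps log2 ratios finite


@dataclass
class CopyRatioMatrix:
    """Samples x bins log2 copy ratios with healthy reference statistics."""

    ratios: pd.DataFrame  # samples x bins
    healthy_mean: pd.Series
    healthy_sd: pd.Series
    reference_ids: list[str]
    dropped_bins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratios.to_numpy()).all():
            raise ValueError("non-finite copy ratios")


@dataclass
class CNVMarkerSet:
    """Retained (bin, direction) markers plus the selection configuration."""

    markers: pd.DataFrame  # bin_id, direction, healthy_freq, freq:<type>...
    alpha_pct: float
    beta_pct: float
    k_sigma: float
    excluded_bins: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)


def normalize_bins(counts: pd.DataFrame, healthy_ids: list[str]) -> CopyRatioMatrix:
    """log2(depth-normalized count / healthy median) per bin.

    ``counts`` is samples x bins, non-negative. Each sample is scaled to the
    cohort-median total depth; the reference is the per-bin median over the
    healthy samples. Bins with healthy median 0 are dropped (recorded).
    """
    if len(healthy_ids) < 3:
        raise ValueError("need at least 3 healthy reference samples")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative bin counts")
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        bad = [counts.index[i] for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"all-zero samples: {bad[:5]}")

    scaled = arr / totals[:, None] * np.median(totals)
    scaled_df = pd.DataFrame(scaled, index=counts.index, columns=counts.columns)
    ref_median = scaled_df.loc[list(healthy_ids)].median(axis=0)

    keep = ref_median > 0
    dropped = [str(b) for b in counts.columns[~keep]]
    scaled_df = scaled_df.loc[:, keep]
    ref_median = ref_median[keep]

    ratios = np.log2((scaled_df + _PSEUDO).div(ref_median + _PSEUDO, axis=1))
    healthy = ratios.loc[list(healthy_ids)]
    return CopyRatioMatrix(
        ratios=ratios,
        healthy_mean=healthy.mean(axis=0),
        healthy_sd=healthy.std(axis=0, ddof=0),
        reference_ids=list(healthy_ids),
        dropped_bins=dropped,
    )


def call_alterations(ratios: CopyRatioMatrix, k_sigma: float = 2.0) -> pd.DataFrame:
    """Per-sample per-bin calls: +1 gain if ratio > mean + k*sigma, -1 loss if
    ratio < mean - k*sigma, else 0. Strict inequalities; zero-sigma bins call
    on strict deviation from the mean."""
    r = ratios.ratios.to_numpy()
    mean = ratios.healthy_mean.to_numpy()
    sd = ratios.healthy_sd.to_numpy()
    upper = mean + k_sigma * sd
    lower = mean - k_sigma * sd
    calls = np.zeros(r.shape, dtype=np.int8)
    calls[r > upper] = GAIN
    calls[r < lower] = LOSS
    return pd.DataFrame(calls, index=ratios.ratios.index, columns=ratios.ratios.columns)


def select_cnv_markers(
    calls: pd.DataFrame,
    labels: pd.Series,
    alpha_pct: float = 5.0,
    beta_pct: float = 20.0,
    include_losses: bool = True,
    k_sigma: float = 2.0,
    healthy_exclusion: bool = True,
) -> CNVMarkerSet:
    """Prevalence-rule marker selection on training-split calls.

    First, bins altered (in either direction) in more than ``alpha_pct`` % of
    healthy samples are excluded outright. Among the remaining bins, a
    (bin, direction) pair becomes a marker when its healthy frequency is
    below ``alpha_pct`` % and its frequency in at least one cancer type
    exceeds ``beta_pct`` %.

    ``healthy_exclusion=False`` disables both healthy-frequency conditions
    (selection on cancer prevalence alone); it exists to quantify the benefit
    of the exclusion rule against clonal-hematopoiesis-like confounders.
    """
    # beta_pct = 100 is allowed and vacuous (no frequency can exceed it)
    if not (0 < alpha_pct < 100) or not (0 < beta_pct <= 100):
        raise ValueError("alpha_pct must lie in (0, 100), beta_pct in (0, 100]")
    labels = labels.loc[calls.index]
    healthy = calls.loc[labels == "healthy"]
    if healthy.empty:
        raise ValueError("no healthy samples among calls")
    cancer_types = sorted(set(labels) - {"healthy"})

    altered_any = (healthy.to_numpy() != NONE).mean(axis=0) * 100
    excluded = (altered_any > alpha_pct) if healthy_exclusion else np.zeros(
        calls.shape[1], dtype=bool)
    excluded_bins = [str(b) for b in calls.columns[excluded]]
    bins_kept = calls.columns[~excluded]

    records = []
    directions = [("gain", GAIN)] + ([("loss", LOSS)] if include_losses else [])
    for name, code in directions:
        h_freq = (healthy[bins_kept] == code).mean(axis=0) * 100
        type_freqs = {
            t: (calls.loc[labels == t, bins_kept] == code).mean(axis=0) * 100
            for t in cancer_types
        }
        max_cancer = pd.concat(type_freqs, axis=1).max(axis=1) if type_freqs else h_freq * 0
        keep = max_cancer > beta_pct
        if healthy_exclusion:
            keep &= h_freq < alpha_pct
        for b in bins_kept[keep]:
            rec = {"bin_id": str(b), "direction": name, "healthy_freq": h_freq[b]}
            for t in cancer_types:
                rec[f"freq:{t}"] = type_freqs[t][b]
            records.append(rec)

    markers = pd.DataFrame(records, columns=(
        ["bin_id", "direction", "healthy_freq"] + [f"freq:{t}" for t in cancer_types]
    ))
    out = CNVMarkerSet(markers, alpha_pct, beta_pct, k_sigma, excluded_bins)
    # post-exclusion invariant, asserted on every run
    if healthy_exclusion and not markers.empty and (markers["healthy_freq"] >= alpha_pct).any():
        raise AssertionError("retained marker violates the healthy-exclusion rule")
    return out


def cnv_csd_score(sample_calls: pd.Series, markers: CNVMarkerSet) -> float:
    """Fraction of marker (bin, direction) pairs detected in one sample."""
    if len(markers) == 0:
        raise ValueError("empty CNV marker set")
    codes = {"gain": GAIN, "loss": LOSS}
    hit = 0
    for bin_id, direction in zip(markers.markers["bin_id"], markers.markers["direction"]):
        if int(sample_calls.get(bin_id, NONE)) == codes[direction]:
            hit += 1
    return hit / len(markers)


def cnv_csd_scores(calls: pd.DataFrame, markers: CNVMarkerSet) -> pd.Series:
    """Vectorized ``cnv_csd_score`` over all rows of a call matrix."""
    if len(markers) == 0:
        raise ValueError("empty CNV marker set")
    codes = {"gain": GAIN, "loss": LOSS}
    hits = np.zeros(len(calls), dtype=float)
    for bin_id, direction in zip(markers.markers["bin_id"], markers.markers["direction"]):
        if bin_id in calls.columns:
            hits += (calls[bin_id].to_numpy() == codes[direction])
    return pd.Series(hits / len(markers), index=calls.index)
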