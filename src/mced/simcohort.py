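"""Seeded synthetic multimodal cfDNA cohort generator.

Produces healthy and eight-cancer cohorts (stages I-IV) whose methylation,
copy-number and fragment-length signals are stage-dependent admixtures of a
healthy background and a tumor component, weighted by a per-sample tumor
fraction (TF). Everything downstream of the assay is testable against the
planted ground truth.

Signal model
------------
* Methylation: per-site expected beta is ``(1-TF) * beta_healthy +
  TF * beta_tumor``; observed counts are beta-binomial around that mean at a
  Poisson-drawn coverage.
* Copy number: bin counts are Poisson with a multiplicative shift
  ``(1-TF) + TF * 2**(+/- segment_effect)`` at the type's altered segments.
  An optional fraction of healthy samples carries recurrent gains at fixed
  bins (a clonal-hematopoiesis-like confounder).
* Fragments: lengths are a two-component discretized-normal mixture with
  tumor weight TF; the tumor mode is shorter than the healthy mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fragmentome import FragmentHistogramSet
from .methylome import CpGCountTable

__all__ = [
    "CANCER_TYPES",
    "STAGES",
    "TISSUE_TYPES",
    "SimConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_tissue_panel",
    "draw_tumor_fraction",
]

CANCER_TYPES = (
    "breast", "colorectal", "gastric", "liver",
    "lung", "ovarian", "pancreatic", "prostate",
)
STAGES = ("I", "II", "III", "IV")
# cancer types with matched tumor / adjacent-normal tissue available
TISSUE_TYPES = ("colorectal", "liver", "lung")

# per-label (age_mean, age_sd, male_fraction); healthy split into <50 / >=50
DEFAULT_AGE_SEX = {
    "healthy_young": (41.6, 6.9, 0.443),
    "healthy_old": (59.2, 6.8, 0.307),
    "breast": (53.0, 11.8, 0.0),
    "colorectal": (62.0, 9.4, 0.629),
    "gastric": (59.7, 12.7, 0.564),
    "liver": (60.5, 11.4, 0.735),
    "lung": (65.9, 11.3, 0.692),
    "ovarian": (54.3, 13.8, 0.0),
    "pancreatic": (63.9, 10.4, 0.592),
    "prostate": (69.9, 7.5, 1.0),
}

DEFAULT_TF_BY_STAGE = {
    "I": (0.08, 0.02),
    "II": (0.12, 0.03),
    "III": (0.16, 0.04),
    "IV": (0.22, 0.05),
}


@dataclass
class SimConfig:
    n_healthy: int = 50
    n_per_cancer_per_stage: int = 5
    n_cpg_sites: int = 20_000
    n_cnv_bins: int = 200
    n_fsr_windows: int = 100
    coverage_mean: float = 30.0
    tf_by_stage: dict = field(default_factory=lambda: dict(DEFAULT_TF_BY_STAGE))
    dmr_effect: float = 0.6
    cnv_segment_effect: float = 0.6
    frag_healthy_mode: int = 166
    frag_tumor_mode: int = 145
    frag_sd: float = 12.0
    frag_mode_jitter_sd: float = 3.0
    frag_sd_jitter_sd: float = 2.0
    frag_bg_short_mean: float = 0.05
    frag_bg_short_sd: float = 0.04
    chip_rate: float = 0.0
    chip_effect_tf: float = 0.25
    n_chip_bins: int = 10
    age_sex_model: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SEX))
    seed: int = 0
    # noise / structure knobs (no counterpart in the assay description)
    bb_concentration: float = 50.0
    n_dmr_per_cancer: int = 12
    n_segments_per_cancer: int = 3
    segment_bins: int = 8
    block_size: int = 5
    extreme_block_frac: float = 0.06
    fragments_per_window: int = 250
    reads_per_bin_mean: float = 500.0
    n_tissue_per_cancer: int = 8
    healthy_young_frac: float = 0.4
    train_fraction: float = 0.6
    n_chroms: int = 5

    def validate(self) -> None:
        counts = [self.n_healthy, self.n_per_cancer_per_stage, self.n_cpg_sites,
                  self.n_cnv_bins, self.n_fsr_windows, self.n_tissue_per_cancer,
                  self.block_size, self.n_chroms]
        if any(c <= 0 for c in counts):
            raise ValueError("configuration error: all counts must be positive")
        if self.coverage_mean <= 0 or self.fragments_per_window <= 0:
            raise ValueError("configuration error: non-positive rates")
        if not (0.0 <= self.chip_rate <= 1.0):
            raise ValueError("configuration error: chip_rate outside [0, 1]")
        means = [self.tf_by_stage[s][0] for s in STAGES]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("configuration error: stage TF means must be non-decreasing I->IV")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth: per-sample TF, per-type DMR regions and CNV segments."""

    tf: pd.Series  # per sample (0 for healthy)
    beta_healthy: np.ndarray  # per-site baseline methylation
    dmr_regions: dict  # type -> list of {block, sites, direction}
    cnv_segments: dict  # type -> list of {bins, direction}
    chip_bins: list
    chip_carriers: list

    def dmr_region_keys(self, cancer_type: str) -> set[tuple[str, int]]:
        """(chrom, first site pos0) keys identifying planted regions."""
        return {(r["chrom"], r["start_pos0"]) for r in self.dmr_regions[cancer_type]}

    def all_dmr_site_idx(self) -> np.ndarray:
        idx = [r["sites"] for regs in self.dmr_regions.values() for r in regs]
        return np.unique(np.concatenate(idx)) if idx else np.array([], dtype=int)

    def to_json(self, path) -> None:
        payload = {
            "tf": self.tf.to_dict(),
            "dmr_regions": {
                t: [{**r, "sites": [int(i) for i in r["sites"]]} for r in regs]
                for t, regs in self.dmr_regions.items()
            },
            "cnv_segments": {
                t: [{**s, "bins": [int(b) for b in s["bins"]]} for s in segs]
                for t, segs in self.cnv_segments.items()
            },
            "chip_bins": list(self.chip_bins),
            "chip_carriers": list(self.chip_carriers),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def draw_tumor_fraction(stage: str, config: SimConfig, rng: np.random.Generator) -> float:
    """One TF draw from the stage's normal(mean, sd), truncated into [0, 1]."""
    if stage not in config.tf_by_stage:
        raise ValueError(f"unknown stage {stage!r}")
    mean, sd = config.tf_by_stage[stage]
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


# ---------------------------------------------------------------- internals

def _site_grid(config: SimConfig) -> pd.DataFrame:
    per_chrom = int(np.ceil(config.n_cpg_sites / config.n_chroms))
    chroms, pos = [], []
    remaining = config.n_cpg_sites
    for c in range(config.n_chroms):
        n = min(per_chrom, remaining)
        if n <= 0:
            break
        chroms.extend([f"chr{c + 1}"] * n)
        pos.extend((100 * np.arange(n) + 1000).tolist())
        remaining -= n
    return pd.DataFrame({"chrom": chroms, "pos0": pos, "strand": "+"})


def _blocks(sites: pd.DataFrame, block_size: int) -> list[np.ndarray]:
    """Contiguous within-chromosome site-index blocks of ~block_size CpGs."""
    blocks = []
    for _, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), block_size):
            chunk = idx[start:start + block_size]
            if len(chunk) >= 3:  # keep blocks large enough to survive min_cpg
                blocks.append(chunk)
    return blocks


def _plant_methylation(config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator):
    """Baseline healthy betas by block plus per-type tumor-shifted DMR blocks."""
    n = len(sites)
    blocks = _blocks(sites, config.block_size)
    n_blocks = len(blocks)
    n_extreme = max(1, int(round(config.extreme_block_frac * n_blocks)))

    # same-status extreme blocks must not be adjacent, or their runs would
    # merge into one diluted region; cross-status adjacency is harmless
    perm = rng.permutation(n_blocks)
    high_blocks, low_blocks = [], []
    used_high, used_low = set(), set()
    for b in perm:
        b = int(b)
        if (len(high_blocks) < n_extreme and b not in used_low
                and (b - 1) not in used_high and (b + 1) not in used_high):
            high_blocks.append(b)
            used_high.add(b)
        elif (len(low_blocks) < n_extreme and b not in used_high
                and (b - 1) not in used_low and (b + 1) not in used_low):
            low_blocks.append(b)
            used_low.add(b)
        if len(high_blocks) == n_extreme and len(low_blocks) == n_extreme:
            break
    high_blocks = np.array(high_blocks)
    low_blocks = np.array(low_blocks)

    beta_healthy = rng.uniform(0.35, 0.65, size=n)
    for b in high_blocks:
        beta_healthy[blocks[b]] = rng.uniform(0.82, 0.95) + rng.normal(0, 0.01, len(blocks[b]))
    for b in low_blocks:
        beta_healthy[blocks[b]] = rng.uniform(0.05, 0.18) + rng.normal(0, 0.01, len(blocks[b]))
    beta_healthy = np.clip(beta_healthy, 0.02, 0.98)

    # per cancer type: half hypo-shifted high blocks, half hyper-shifted low blocks
    n_each = config.n_dmr_per_cancer // 2
    need = n_each * len(CANCER_TYPES)
    if need > len(high_blocks) or need > len(low_blocks):
        raise ValueError("configuration error: too few extreme blocks to plant DMRs; "
                         "increase n_cpg_sites or extreme_block_frac")
    hi_pool = rng.permutation(high_blocks)
    lo_pool = rng.permutation(low_blocks)

    chrom = sites["chrom"].to_numpy()
    pos0 = sites["pos0"].to_numpy()
    beta_tumor = {}
    dmr_regions = {}
    for k, ctype in enumerate(CANCER_TYPES):
        bt = beta_healthy.copy()
        regs = []
        for b in hi_pool[k * n_each:(k + 1) * n_each]:
            s = blocks[b]
            bt[s] = np.clip(bt[s] - config.dmr_effect, 0.02, 0.98)
            regs.append({"block": int(b), "sites": s, "direction": "hypo",
                         "chrom": str(chrom[s[0]]), "start_pos0": int(pos0[s[0]]),
                         "pos0_list": [int(p) for p in pos0[s]]})
        for b in lo_pool[k * n_each:(k + 1) * n_each]:
            s = blocks[b]
            bt[s] = np.clip(bt[s] + config.dmr_effect, 0.02, 0.98)
            regs.append({"block": int(b), "sites": s, "direction": "hyper",
                         "chrom": str(chrom[s[0]]), "start_pos0": int(pos0[s[0]]),
                         "pos0_list": [int(p) for p in pos0[s]]})
        beta_tumor[ctype] = bt
        dmr_regions[ctype] = regs
    return beta_healthy, beta_tumor, dmr_regions


def _methylation_counts(mu: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """Beta-binomial counts around per-site/sample mean ``mu`` (sites x samples)."""
    cov = rng.poisson(config.coverage_mean, size=mu.shape)
    c = config.bb_concentration
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    p = rng.beta(mu * c, (1 - mu) * c)
    C = rng.binomial(cov, p)
    return C.astype(np.int64), (cov - C).astype(np.int64)


def _plant_cnv(config: SimConfig, rng: np.random.Generator):
    n_bins = config.n_cnv_bins
    seg_len = config.segment_bins
    n_segs = config.n_segments_per_cancer
    starts = rng.permutation(n_bins // seg_len)
    need = n_segs * len(CANCER_TYPES)
    if need > len(starts):
        raise ValueError("configuration error: too few CNV bins for the planted segments")
    segments = {}
    k = 0
    for ctype in CANCER_TYPES:
        segs = []
        for j in range(n_segs):
            s = starts[k] * seg_len
            direction = "loss" if j == n_segs - 1 and n_segs > 1 else "gain"
            segs.append({"bins": np.arange(s, min(s + seg_len, n_bins)), "direction": direction})
            k += 1
        segments[ctype] = segs
    # CHIP-like gains sit inside a genuinely cancer-gained segment: without
    # the healthy-exclusion rule these bins become markers and carrier
    # healthy samples pick up spurious score
    chip_bins = segments[CANCER_TYPES[0]][0]["bins"][:config.n_chip_bins]
    return segments, chip_bins


def _sample_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_young = int(round(config.healthy_young_frac * config.n_healthy))
    for i in range(config.n_healthy):
        group = "healthy_young" if i < n_young else "healthy_old"
        mean, sd, male = config.age_sex_model[group]
        age = float(rng.normal(mean, sd))
        age = float(np.clip(age, 25, 49)) if group == "healthy_young" else float(np.clip(age, 50, 90))
        rows.append({"sample_id": f"H{i:04d}", "label": "healthy", "stage": "NA",
                     "age": round(age, 1), "sex": "M" if rng.random() < male else "F",
                     "true_tf": 0.0})
    for ctype in CANCER_TYPES:
        mean, sd, male = config.age_sex_model[ctype]
        for stage in STAGES:
            for j in range(config.n_per_cancer_per_stage):
                age = float(np.clip(rng.normal(mean, sd), 30, 95))
                tf = draw_tumor_fraction(stage, config, rng)
                rows.append({"sample_id": f"C_{ctype[:4]}_{stage}_{j:03d}",
                             "label": ctype, "stage": stage, "age": round(age, 1),
                             "sex": "M" if rng.random() < male else "F",
                             "true_tf": tf})
    return pd.DataFrame(rows)


def _fragment_histograms(sheet: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator) -> FragmentHistogramSet:
    lengths = np.arange(50, 401)
    n_len = len(lengths)
    windows = [f"w{k:04d}" for k in range(config.n_fsr_windows)]
    counts = np.zeros((len(sheet), config.n_fsr_windows, n_len), dtype=np.int64)
    mode_gap = config.frag_healthy_mode - config.frag_tumor_mode
    for si, tf in enumerate(sheet["true_tf"].to_numpy()):
        per_window = rng.poisson(config.fragments_per_window, size=config.n_fsr_windows)
        total = int(per_window.sum())
        if total == 0:
            continue
        # per-sample biological baseline: individuals differ in their typical
        # fragment length, so cohort-level signal is not trivially separable
        sample_mode = rng.normal(config.frag_healthy_mode, config.frag_mode_jitter_sd)
        sample_sd = max(6.0, rng.normal(config.frag_sd, config.frag_sd_jitter_sd))
        # individuals carry a variable load of short (apoptotic-like)
        # fragments even without tumor; TF adds on top of that background
        bg = float(np.clip(rng.normal(config.frag_bg_short_mean, config.frag_bg_short_sd),
                           0.0, 0.5))
        w_short = min(bg + max(tf, 0.0), 1.0)
        n_short = rng.binomial(total, w_short)
        modes = np.full(total, sample_mode, dtype=float)
        if n_short:
            short_pick = rng.choice(total, size=n_short, replace=False)
            modes[short_pick] = sample_mode - mode_gap
        frag = np.rint(rng.normal(modes, sample_sd)).astype(int)
        frag = np.clip(frag, 50, 400)
        window_of = np.repeat(np.arange(config.n_fsr_windows), per_window)
        np.add.at(counts[si], (window_of, frag - 50), 1)
    return FragmentHistogramSet(counts, lengths, sheet["sample_id"].tolist(), windows)


def _qc_metrics(sheet: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(sheet)
    return pd.DataFrame({
        "sample_id": sheet["sample_id"],
        "mapping_rate": np.clip(rng.normal(0.92, 0.02, n), 0.85, 0.99).round(4),
        "duplication_rate": np.clip(rng.normal(0.12, 0.03, n), 0.02, 0.22).round(4),
        "conversion_efficiency": np.clip(rng.normal(0.996, 0.001, n), 0.992, 0.9999).round(5),
    })


# ---------------------------------------------------------------- public API

def simulate_cohort(config: SimConfig):
    """Generate one synthetic cohort.

    Returns ``(sheet, cpg, bins, frags, truth)``: the sample sheet (with a
    stratified train/test split and QC columns handled downstream), the wide
    CpG count table, the samples x bins read-count table, the fragment
    histograms and the planted ground truth. Identical config and seed give
    identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sites = _site_grid(config)
    beta_healthy, beta_tumor, dmr_regions = _plant_methylation(config, sites, rng)
    cnv_segments, chip_bins = _plant_cnv(config, rng)
    sheet = _sample_frame(config, rng)
    n_samples = len(sheet)

    # methylation expected betas: (1-TF) * healthy + TF * tumor profile
    mu = np.tile(beta_healthy[:, None], (1, n_samples))
    for j, (label, tf) in enumerate(zip(sheet["label"], sheet["true_tf"])):
        if label != "healthy" and tf > 0:
            mu[:, j] = (1 - tf) * beta_healthy + tf * beta_tumor[label]
    C, T = _methylation_counts(mu, config, rng)
    cpg = CpGCountTable(sites, C, T, sheet["sample_id"].tolist())

    # copy-number bin counts
    bin_bias = rng.uniform(0.5, 1.5, size=config.n_cnv_bins)
    chip_carriers = []
    rates = np.tile(bin_bias * config.reads_per_bin_mean, (n_samples, 1))
    for j, (label, tf) in enumerate(zip(sheet["label"], sheet["true_tf"])):
        if label != "healthy" and tf > 0:
            for seg in cnv_segments[label]:
                eff = config.cnv_segment_effect if seg["direction"] == "gain" else -config.cnv_segment_effect
                mult = (1 - tf) + tf * 2.0 ** eff
                rates[j, seg["bins"]] *= mult
        elif label == "healthy" and rng.random() < config.chip_rate:
            chip_carriers.append(sheet["sample_id"].iloc[j])
            mult = 1 + config.chip_effect_tf * (2.0 ** config.cnv_segment_effect - 1)
            rates[j, chip_bins] *= mult
    bin_counts = rng.poisson(rates)
    bins = pd.DataFrame(bin_counts, index=sheet["sample_id"].tolist(),
                        columns=[f"bin{b:04d}" for b in range(config.n_cnv_bins)])

    frags = _fragment_histograms(sheet, config, rng)
    qc = _qc_metrics(sheet, rng)
    sheet = sheet.merge(qc, on="sample_id")

    from .io import stratified_split  # late import avoids a cycle
    sheet = stratified_split(sheet, ratio=config.train_fraction, seed=config.seed)

    truth = GroundTruth(
        tf=pd.Series(sheet["true_tf"].to_numpy(), index=sheet["sample_id"].to_numpy()),
        beta_healthy=beta_healthy,
        dmr_regions=dmr_regions,
        cnv_segments=cnv_segments,
        chip_bins=[int(b) for b in chip_bins],
        chip_carriers=chip_carriers,
    )
    return sheet, cpg, bins, frags, truth


def simulate_tissue_panel(config: SimConfig, truth: GroundTruth):
    """Matched tumor / adjacent-normal tissue methylation for the types with
    tissue available. Tumor tissue is the pure (TF=1) tumor profile.

    Returns (tissue_sheet, tissue_cpg); the count table shares the cohort's
    site grid.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    sites = _site_grid(config)
    # rebuild the per-type tumor profiles from the planted truth
    beta_tumor = {}
    for ctype in TISSUE_TYPES:
        bt = truth.beta_healthy.copy()
        for reg in truth.dmr_regions[ctype]:
            s = np.asarray(reg["sites"], dtype=int)
            shift = -config.dmr_effect if reg["direction"] == "hypo" else config.dmr_effect
            bt[s] = np.clip(bt[s] + shift, 0.02, 0.98)
        beta_tumor[ctype] = bt

    ids, labels, roles, mus = [], [], [], []
    for ctype in TISSUE_TYPES:
        for j in range(config.n_tissue_per_cancer):
            ids.append(f"T_{ctype[:4]}_tum_{j:03d}")
            labels.append(ctype)
            roles.append("tumor")
            mus.append(beta_tumor[ctype])
            ids.append(f"T_{ctype[:4]}_adj_{j:03d}")
            labels.append(ctype)
            roles.append("adjacent_normal")
            mus.append(truth.beta_healthy)
    mu = np.stack(mus, axis=1)
    C, T = _methylation_counts(mu, config, rng)
    tissue_cpg = CpGCountTable(sites, C, T, ids)
    tissue_sheet = pd.DataFrame({"sample_id": ids, "target": labels, "role": roles})
    return tissue_sheet, tissue_cpg
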