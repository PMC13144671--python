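"""Fragment-length features: per-window short/long fragment size ratio (FSR)
and the global 5-bp fragment size distribution (FSD), with train-anchored
standardization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FragmentHistogramSet",
    "classify_fragment",
    "classify_fragment_array",
    "compute_fsr",
    "compute_fsd",
    "Standardizer",
    "standardize",
    "histograms_from_bam",
]

SHORT_LO, SHORT_HI = 80, 150   # short: > 80 and < 150 bp
LONG_LO, LONG_HI = 150, 220    # long:  > 150 and < 220 bp
FSD_LO, FSD_HI, FSD_WIDTH = 80, 220, 5


@dataclass
class FragmentHistogramSet:
    """Integer fragment-length counts per (sample, window).

    ``counts`` has shape (n_samples, n_windows, n_lengths) over the 1-bp
    grid ``lengths``. The pooled histogram over windows feeds FSD.
    """

    counts: np.ndarray
    lengths: np.ndarray
    samples: list[str]
    windows: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("negative fragment counts")
        if (self.lengths <= 0).any():
            raise ValueError("fragment lengths must be positive")
        if self.counts.shape != (len(self.samples), len(self.windows), len(self.lengths)):
            raise ValueError("counts not aligned with samples/windows/lengths")

    def pooled(self) -> np.ndarray:
        """(n_samples, n_lengths) histogram summed over windows."""
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        s_idx, w_idx, l_idx = np.nonzero(self.counts)
        df = pd.DataFrame({
            "sample_id": np.asarray(self.samples, dtype=object)[s_idx],
            "window_id": np.asarray(self.windows, dtype=object)[w_idx],
            "length": self.lengths[l_idx],
            "count": self.counts[s_idx, w_idx, l_idx],
        })
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FragmentHistogramSet":
        df = pd.read_csv(path, sep="\t")
        return cls.from_long(df)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FragmentHistogramSet":
        samples = sorted(df["sample_id"].unique().tolist())
        windows = sorted(df["window_id"].unique().tolist())
        lo, hi = int(df["length"].min()), int(df["length"].max())
        lengths = np.arange(lo, hi + 1)
        counts = np.zeros((len(samples), len(windows), len(lengths)), dtype=np.int64)
        s_map = {s: i for i, s in enumerate(samples)}
        w_map = {w: i for i, w in enumerate(windows)}
        si = df["sample_id"].map(s_map).to_numpy()
        wi = df["window_id"].map(w_map).to_numpy()
        li = df["length"].to_numpy(dtype=int) - lo
        np.add.at(counts, (si, wi, li), df["count"].to_numpy(dtype=np.int64))
        return cls(counts, lengths, samples, windows)


def classify_fragment(length: int) -> str:
    """Classify one fragment length as short, long or neither.

    Boundaries are exclusive on both sides: 80, 150 and 220 bp all map to
    ``neither``.
    """
    if length <= 0:
        raise ValueError("fragment length must be positive")
    if SHORT_LO < length < SHORT_HI:
        return "short"
    if LONG_LO < length < LONG_HI:
        return "long"
    return "neither"


def classify_fragment_array(lengths: np.ndarray) -> np.ndarray:
    lengths = np.asarray(lengths)
    if (lengths <= 0).any():
        raise ValueError("fragment length must be positive")
    out = np.full(lengths.shape, "neither", dtype=object)
    out[(lengths > SHORT_LO) & (lengths < SHORT_HI)] = "short"
    out[(lengths > LONG_LO) & (lengths < LONG_HI)] = "long"
    return out


def compute_fsr(histograms: FragmentHistogramSet) -> pd.DataFrame:
    """Per (sample, window) short/long ratio; NaN where no long fragments."""
    lengths = histograms.lengths
    short = (lengths > SHORT_LO) & (lengths < SHORT_HI)
    long_ = (lengths > LONG_LO) & (lengths < LONG_HI)
    n_short = histograms.counts[:, :, short].sum(axis=2).astype(float)
    n_long = histograms.counts[:, :, long_].sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsr = np.where(n_long > 0, n_short / np.where(n_long > 0, n_long, 1), np.nan)
    return pd.DataFrame(fsr, index=list(histograms.samples),
                        columns=[f"fsr:{w}" for w in histograms.windows])


def compute_fsd(
    histograms: FragmentHistogramSet,
    lo: int = FSD_LO,
    hi: int = FSD_HI,
    width: int = FSD_WIDTH,
) -> pd.DataFrame:
    """Pooled fragment-size distribution in ``width``-bp bins over [lo, hi).

    Per sample, proportions of in-range fragments per bin; rows sum to 1.
    Raises if a sample has no fragment in range.
    """
    if (hi - lo) % width != 0:
        raise ValueError("bin width must evenly divide the range")
    pooled = histograms.pooled()
    lengths = histograms.lengths
    in_range = (lengths >= lo) & (lengths < hi)
    n_bins = (hi - lo) // width
    bin_of = (lengths[in_range] - lo) // width

    binned = np.zeros((pooled.shape[0], n_bins), dtype=float)
    np.add.at(binned.T, bin_of, pooled[:, in_range].T)
    totals = binned.sum(axis=1)
    if (totals == 0).any():
        bad = [histograms.samples[i] for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"no in-range fragments for samples: {bad[:5]}")
    props = binned / totals[:, None]
    cols = [f"fsd:{lo + i * width}" for i in range(n_bins)]
    return pd.DataFrame(props, index=list(histograms.samples), columns=cols)


class Standardizer:
    """Per-feature (x - train_mean) / train_sd; zero-sd features map to 0."""

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Standardizer":
        if train.empty:
            raise ValueError("training matrix must be non-empty")
        self.mean_ = train.mean(axis=0)
        self.sd_ = train.std(axis=0, ddof=0)
        return self

    def transform(self, x: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("standardizer applied before fitting")
        if list(x.columns) != list(self.mean_.index):
            raise ValueError("feature columns do not match the fitted ones")
        sd = self.sd_.replace(0.0, np.nan)
        out = (x - self.mean_) / sd
        return out.fillna(0.0)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.to_dict(), "sd": self.sd_.to_dict()}


def standardize(train: pd.DataFrame, apply_to: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    scaler = Standardizer().fit(train)
    return scaler.transform(apply_to), scaler


def histograms_from_bam(path, windows=None, min_len: int = 1, max_len: int = 1000) -> FragmentHistogramSet:
    """Optional BAM ingestion: absolute template lengths of properly paired
    primary alignments, pooled into a single window per file."""
    import pysam  # optional dependency, only needed on this path

    counts: dict[int, int] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if (not read.is_proper_pair or read.is_secondary or
                    read.is_supplementary or read.is_read2):
                continue
            tlen = abs(read.template_length)
            if min_len <= tlen <= max_len:
                counts[tlen] = counts.get(tlen, 0) + 1
    if not counts:
        raise ValueError(f"no usable fragments in {path}")
    lengths = np.arange(min(counts), max(counts) + 1)
    arr = np.zeros((1, 1, len(lengths)), dtype=np.int64)
    for length, n in counts.items():
        arr[0, 0, length - lengths[0]] = n
    return FragmentHistogramSet(arr, lengths, [str(path)], ["pooled"])
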