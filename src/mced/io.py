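"""File formats, the sequencing-QC gate, stratified splitting, run manifests
and the train/test leakage audit.

Coordinates are 0-based half-open everywhere; BED files are read natively.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "validate_sample_sheet",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_bed",
    "qc_gate",
    "stratified_split",
    "sha256_file",
    "Manifest",
    "audit_no_leakage",
]

LABELS = (
    "healthy", "breast", "colorectal", "gastric", "liver",
    "lung", "ovarian", "pancreatic", "prostate",
)
STAGES = ("I", "II", "III", "IV", "NA")

QC_MIN_MAPPING = 0.80
QC_MAX_DUPLICATION = 0.25
QC_MIN_CONVERSION = 0.99


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    required = {"sample_id", "label", "stage", "age", "sex"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids")
    bad = set(sheet["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    bad_stage = set(sheet["stage"].astype(str)) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")
    healthy = sheet[sheet["label"] == "healthy"]
    if (healthy["stage"].astype(str) != "NA").any():
        raise ValueError("healthy samples must have stage NA")
    if not set(sheet["sex"]) <= {"F", "M"}:
        raise ValueError("sex must be F or M")


def read_sample_sheet(path) -> pd.DataFrame:
    # keep_default_na=False so the literal stage "NA" survives the round trip
    sheet = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    for col in ("age", "true_tf", "mapping_rate", "duplication_rate",
                "conversion_efficiency"):
        if col in sheet.columns:
            sheet[col] = pd.to_numeric(sheet[col])
    validate_sample_sheet(sheet)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader: (chrom, start, end) triples, 0-based half-open."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED interval with start >= end: {line!r}")
            intervals.append((chrom, start, end))
    return intervals


def qc_gate(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pass/fail per sample against the sequencing-QC thresholds.

    Pass requires mapping_rate > 0.80, duplication_rate < 0.25 and
    conversion_efficiency > 0.99, all strict. Returns the input with
    ``qc_pass`` and ``qc_fail_reason`` columns appended.
    """
    fields = ["mapping_rate", "duplication_rate", "conversion_efficiency"]
    for f in ["sample_id"] + fields:
        if f not in metrics.columns:
            raise ValueError(f"QC metrics missing column {f!r}")
    for f in fields:
        bad = metrics[metrics[f].isna()]
        if not bad.empty:
            raise ValueError(f"missing QC metric {f!r} for sample "
                             f"{bad['sample_id'].iloc[0]!r}")

    out = metrics.copy()
    reasons = []
    for _, row in out.iterrows():
        fail = []
        if not row["mapping_rate"] > QC_MIN_MAPPING:
            fail.append("mapping_rate")
        if not row["duplication_rate"] < QC_MAX_DUPLICATION:
            fail.append("duplication_rate")
        if not row["conversion_efficiency"] > QC_MIN_CONVERSION:
            fail.append("conversion_efficiency")
        reasons.append(",".join(fail))
    out["qc_fail_reason"] = reasons
    out["qc_pass"] = out["qc_fail_reason"] == ""
    return out


def stratified_split(
    sheet: pd.DataFrame,
    ratio: float = 0.6,
    strata: tuple = ("label", "stage", "sex"),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign a ``split`` column (train/test) per stratum at ``ratio``.

    Per stratum of size n, round(n * ratio) samples go to train (half-up
    rounding); singleton strata go to train. Deterministic for a given seed.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sheet = sheet.copy()
    split = pd.Series("train", index=sheet.index, dtype=object)
    grouped = sheet.groupby(list(strata), sort=True, dropna=False)
    for _, grp in grouped:
        n = len(grp)
        if n == 1:
            continue  # singleton -> train
        n_train = int(np.floor(n * ratio + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # keep both sides non-empty
        order = rng.permutation(n)
        test_rows = grp.index.to_numpy()[order[n_train:]]
        split.loc[test_rows] = "test"
    sheet["split"] = split
    return sheet


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-run provenance: seed, config, stage outputs and their checksums."""

    def __init__(self, outdir, seed: int | None = None, config: dict | None = None):
        self.outdir = Path(outdir)
        self.path = self.outdir / "manifest.json"
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            from . import __version__
            self.data = {"version": __version__, "seed": seed,
                         "config": config or {}, "stages": {}}
        if seed is not None:
            self.data["seed"] = seed
        if config is not None:
            self.data["config"] = config

    def record_stage(self, stage: str, outputs: list[str], **extra) -> None:
        entry = {"outputs": {}}
        for name in outputs:
            p = self.outdir / name
            entry["outputs"][name] = sha256_file(p) if p.exists() else None
        entry.update(extra)
        self.data["stages"][stage] = entry
        self.save()

    def save(self) -> None:
        self.outdir.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, default=str)


def audit_no_leakage(fitted_training_ids: dict[str, list[str]], sheet: pd.DataFrame) -> None:
    """Assert that no test sample id appears in any fitted artifact's
    recorded training provenance. Raises on violation."""
    test_ids = set(sheet.loc[sheet["split"] == "test", "sample_id"])
    for artifact, ids in fitted_training_ids.items():
        leaked = test_ids & set(ids)
        if leaked:
            raise AssertionError(
                f"leakage: artifact {artifact!r} trained on test samples {sorted(leaked)[:5]}"
            )
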