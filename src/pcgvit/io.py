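"""Dataset manifests, challenge-layout loaders, and experiment configs.

All loaders produce the same manifest schema — one row per recording with
(record_id, subject_id, path, label) — so the rest of the pipeline never
cares whether data came from the synthetic generator, a PhysioNet-2016
style directory (per-subset REFERENCE.csv, ±1 labels, no patient ids), or
a PhysioNet-2022 style directory (per-patient metadata text files, one WAV
per auscultation location).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .features import HeartSoundRecord, read_wav

BINARY_LABELS = ("normal", "abnormal")
THREE_CLASS_LABELS = ("present", "unknown", "absent")


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class DatasetManifest:
    """Validated recording table plus its class mode."""

    table: pd.DataFrame  # columns: record_id, subject_id, path, label
    class_mode: str

    @property
    def labels(self) -> tuple[str, ...]:
        return BINARY_LABELS if self.class_mode == "binary" else THREE_CLASS_LABELS

    def __len__(self) -> int:
        return len(self.table)


def _validate(table: pd.DataFrame, class_mode: str, root: Path) -> DatasetManifest:
    allowed = set(BINARY_LABELS if class_mode == "binary" else THREE_CLASS_LABELS)
    required = ["record_id", "subject_id", "path", "label"]
    for col in required:
        if col not in table.columns:
            raise DataError(f"manifest missing required column {col!r}")
    if table["record_id"].duplicated().any():
        dup = table.loc[table["record_id"].duplicated(), "record_id"].iloc[0]
        raise DataError(f"duplicate record_id {dup!r}")
    for i, row in table.iterrows():
        if row["label"] not in allowed:
            raise DataError(f"row {i} ({row['record_id']}): label {row['label']!r} "
                            f"not valid for class_mode={class_mode!r}")
        p = root / row["path"]
        if not p.exists():
            raise DataError(f"row {i} ({row['record_id']}): file {p} does not exist")
    table = table.copy()
    table["path"] = [str(root / p) for p in table["path"]]
    return DatasetManifest(table=table.reset_index(drop=True), class_mode=class_mode)


def load_manifest(path, class_mode: str = "binary") -> DatasetManifest:
    """Load and validate a manifest CSV (paths relative to the CSV)."""
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    return _validate(table, class_mode, path.parent)


def load_physionet2016(root) -> DatasetManifest:
    """Load a PhysioNet-2016 style directory: WAVs + REFERENCE.csv.

    REFERENCE.csv rows are ``record_name,label`` with label −1 (normal) or
    1 (abnormal).  The corpus ships no patient identifiers, so the record
    name doubles as subject id (one recording ≈ one subject) — a known
    limitation of subject-wise splitting on this layout.
    """
    root = Path(root)
    ref = root / "REFERENCE.csv"
    if not ref.exists():
        raise DataError(f"missing reference file {ref}")
    table = pd.read_csv(ref, header=None, names=["record_id", "raw_label"], dtype=str)
    mapping = {"-1": "normal", "1": "abnormal"}
    rows = []
    for i, row in table.iterrows():
        if row["raw_label"] not in mapping:
            raise DataError(f"row {i}: unknown reference label {row['raw_label']!r}")
        wav = root / f"{row['record_id']}.wav"
        if not wav.exists():
            raise DataError(f"row {i}: missing WAV {wav}")
        rows.append({"record_id": row["record_id"], "subject_id": row["record_id"],
                     "path": wav.name, "label": mapping[row["raw_label"]]})
    return _validate(pd.DataFrame(rows), "binary", root)


def load_physionet2022(root) -> DatasetManifest:
    """Load a PhysioNet-2022 style directory.

    Each patient has a ``<pid>.txt`` metadata file whose ``#Murmur:`` line
    carries Present/Absent/Unknown, plus one WAV per recorded auscultation
    location named ``<pid>_<LOC>.wav``.  The murmur label propagates to all
    of that patient's recordings and the patient id is the subject id.
    """
    root = Path(root)
    meta_files = sorted(root.glob("*.txt"))
    if not meta_files:
        raise DataError(f"no patient metadata files in {root}")
    claimed: set[str] = set()
    rows = []
    for meta in meta_files:
        pid = meta.stem
        murmur = None
        for line in meta.read_text().splitlines():
            if line.startswith("#Murmur:"):
                murmur = line.split(":", 1)[1].strip().lower()
        if murmur not in THREE_CLASS_LABELS:
            raise DataError(f"{meta}: missing or invalid '#Murmur:' line")
        wavs = sorted(root.glob(f"{pid}_*.wav"))
        if not wavs:
            raise DataError(f"patient {pid}: metadata present but no recordings")
        for wav in wavs:
            claimed.add(wav.name)
            rows.append({"record_id": wav.stem, "subject_id": pid,
                         "path": wav.name, "label": murmur})
    stray = {w.name for w in root.glob("*.wav")} - claimed
    if stray:
        raise DataError(f"recordings without patient metadata: {sorted(stray)}")
    return _validate(pd.DataFrame(rows), "three_class", root)


def load_records(manifest: DatasetManifest, target_rate: int = 2000) -> list[HeartSoundRecord]:
    """Read every WAV in a manifest into HeartSoundRecord objects."""
    records = []
    for _, row in manifest.table.iterrows():
        samples, rate = read_wav(row["path"], target_rate=target_rate)
        records.append(HeartSoundRecord(record_id=row["record_id"],
                                        subject_id=row["subject_id"],
                                        samples=samples, rate=rate,
                                        label=row["label"]))
    return records


# -- experiment config and results --------------------------------------------

def load_config(path) -> dict:
    """Read a YAML experiment config (features/model/training/split sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} is not a mapping")
    return cfg


def save_results(results: pd.DataFrame, summary: pd.DataFrame, out_dir) -> None:
    """Per-fold metrics as CSV plus a JSON summary of means and sds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "fold_metrics.csv", index=False)
    flat = {f"{metric}_{stat}": summary[(metric, stat)].to_dict()
            for metric, stat in summary.columns}
    pd.Series(flat, dtype=object).to_json(out_dir / "summary.json", indent=2)
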