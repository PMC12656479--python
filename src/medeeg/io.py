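"""Readers/writers: EDF, BrainVision, the internal cohort container, tables.

EDF and BrainVision *reading* delegate to mne.  EDF *writing* is a minimal
EDF implementation (16-bit samples, 1-second records) sufficient for
round-tripping simulated cohorts through standard tools.  The internal
container is a directory of one ``.npy`` array per session plus a
``manifest.csv``; it round-trips bit-exactly.

Presentation tables round half-up to one decimal; a full-precision companion
CSV is always written alongside.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, TASKS
from .design import TestResult
from .stats import StudySummary, dip_test, paired_ttest, summarize

_MANIFEST_COLUMNS = ("file", "subject_id", "task", "session_index", "fs",
                     "n_channels", "duration")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write one recording as a 16-bit EDF file (1-second data records).

    Requires an integer sampling rate and a whole number of seconds of data.
    Samples are quantized to the per-channel physical range; the maximum
    round-trip error is one quantization step,
    (phys_max - phys_min) / (2^16 - 1).
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = n_samp // fs

    data = recording.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(f"{recording.subject_id} X X X", 80))
        f.write(_edf_field(
            f"Startdate 01-JAN-2000 {recording.task} "
            f"session{recording.session_index}", 80))
        f.write(_edf_field(now.strftime("%d.%m.%y"), 8))
        f.write(_edf_field(now.strftime("%H.%M.%S"), 8))
        f.write(_edf_field(256 * (n_ch + 1), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))
        f.write(_edf_field(n_ch, 4))
        for name in recording.channel_names:
            f.write(_edf_field(name[:16], 16))
        for _ in range(n_ch):
            f.write(_edf_field("", 80))       # transducer
        for _ in range(n_ch):
            f.write(_edf_field("uV", 8))      # physical dimension
        for v in pmin:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in pmax:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_edf_field(dmin, 8))
        for _ in range(n_ch):
            f.write(_edf_field(dmax, 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 80))       # prefiltering
        for _ in range(n_ch):
            f.write(_edf_field(fs, 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 32))
        for rec in range(n_records):
            block = digital[:, rec * fs:(rec + 1) * fs]
            f.write(block.tobytes())


def edf_quantization_step(recording: EEGRecording) -> np.ndarray:
    """Per-channel worst-case EDF round-trip error in microvolts."""
    pmin = recording.data.min(axis=1)
    pmax = recording.data.max(axis=1)
    rng = np.where(pmax - pmin > 0, pmax - pmin, 2.0)
    return rng / 65535.0


def _parse_identity(path: Path) -> tuple[str, str, int]:
    """Recover (subject, task, session) from our file naming convention."""
    stem = path.stem
    parts = stem.split("_")
    if len(parts) >= 3 and parts[-2] in TASKS and parts[-1].startswith("s"):
        return "_".join(parts[:-2]), parts[-2], int(parts[-1][1:])
    return stem, "NONMED", 1


def _session_filename(rec: EEGRecording, ext: str) -> str:
    return f"{rec.subject_id}_{rec.task}_s{rec.session_index}{ext}"


def read_recording(path: str | Path, fmt: str | None = None,
                   subject_id: str | None = None, task: str | None = None,
                   session_index: int | None = None) -> EEGRecording:
    """Read one recording from EDF, BrainVision (.vhdr) or internal .npy.

    Identity fields default to what the file name encodes
    (``<subject>_<TASK>_s<index>``). Data is returned in microvolts; files
    with no unit information are assumed to be microvolts (warned).
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = {".edf": "edf", ".vhdr": "brainvision", ".npy": "internal"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    sid, tsk, sess = _parse_identity(path)
    sid = subject_id if subject_id is not None else sid
    tsk = task if task is not None else tsk
    sess = session_index if session_index is not None else sess

    if fmt == "internal":
        data = np.load(path)
        raise_if = None
    elif fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        return EEGRecording(subject_id=sid, task=tsk, session_index=sess,
                            data=data, fs=float(raw.info["sfreq"]),
                            channel_names=list(raw.ch_names))
    elif fmt == "brainvision":
        for suffix in (".vhdr", ".eeg", ".vmrk"):
            member = path.with_suffix(suffix)
            if not member.exists():
                raise FileNotFoundError(
                    f"BrainVision set incomplete: missing {member.name}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6
        return EEGRecording(subject_id=sid, task=tsk, session_index=sess,
                            data=data, fs=float(raw.info["sfreq"]),
                            channel_names=list(raw.ch_names))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    # internal container stores raw microvolt arrays; fs must come from the
    # manifest — a bare .npy read assumes nothing
    warnings.warn("bare .npy read: assuming 128 Hz and microvolts; prefer "
                  "read_cohort with a manifest", stacklevel=2)
    return EEGRecording(subject_id=sid, task=tsk, session_index=sess,
                        data=data, fs=128.0)


# ---------------------------------------------------------------------------
# Internal cohort container
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[EEGRecording], outdir: str | Path,
                 fmt: str = "internal", force: bool = False) -> Path:
    """Write a cohort as one file per session plus ``manifest.csv``.

    ``fmt`` is "internal" (.npy, bit-exact) or "edf" (16-bit quantized).
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    seen = set()
    rows = []
    for rec in cohort:
        if rec.key() in seen:
            raise ValueError(f"duplicate session {rec.key()} in cohort")
        seen.add(rec.key())
        if fmt == "internal":
            fname = _session_filename(rec, ".npy")
            np.save(outdir / fname, rec.data)
        elif fmt == "edf":
            fname = _session_filename(rec, ".edf")
            write_edf(rec, outdir / fname)
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
        rows.append((fname, rec.subject_id, rec.task, rec.session_index,
                     rec.fs, rec.n_channels, rec.duration))
    with open(outdir / "manifest.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_MANIFEST_COLUMNS)
        w.writerows(rows)
    return outdir / "manifest.csv"


def read_cohort(indir: str | Path) -> list[EEGRecording]:
    """Load a cohort written by :func:`write_cohort` via its manifest."""
    indir = Path(indir)
    manifest = indir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {indir}")
    cohort = []
    with open(manifest, newline="") as f:
        for row in csv.DictReader(f):
            path = indir / row["file"]
            if not path.exists():
                raise FileNotFoundError(f"manifest entry missing on disk: {path}")
            fs = float(row["fs"])
            if path.suffix == ".npy":
                data = np.load(path)
                expected = int(round(float(row["duration"]) * fs))
                if data.shape != (int(row["n_channels"]), expected):
                    raise ValueError(
                        f"{path.name}: data shape {data.shape} does not match "
                        f"manifest ({row['n_channels']} ch x {expected} samples)")
                rec = EEGRecording(
                    subject_id=row["subject_id"], task=row["task"],
                    session_index=int(row["session_index"]), data=data, fs=fs)
            else:
                rec = read_recording(
                    path, subject_id=row["subject_id"], task=row["task"],
                    session_index=int(row["session_index"]))
            cohort.append(rec)
    return cohort


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 1) -> float:
    """Presentation rounding: 56.09 -> 56.1, 0.25 -> 0.3 (one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy frame: one row per test (the raw layer under the summary tables)."""
    return pd.DataFrame([{
        "task": r.meditation_task, "pipeline": r.pipeline,
        "train_size": r.train_size, "experiment": r.experiment_id,
        "split": r.split_id, "test_pair": r.test_pair,
        "accuracy": r.accuracy, "seed": r.seed,
    } for r in results])


def _cell_summary_frames(frame: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One study cell -> (presentation table, full-precision table)."""
    pipelines = sorted(frame["pipeline"].unique())
    pretty = {}
    full = {}
    summaries: dict[str, StudySummary] = {}
    for pipe in pipelines:
        sub = frame[frame["pipeline"] == pipe]
        res = [TestResult(accuracy=a, pipeline=pipe,
                          train_size=int(sub["train_size"].iloc[0]),
                          meditation_task=str(sub["task"].iloc[0]),
                          experiment_id=int(e), split_id=0, test_pair=0, seed=0)
               for a, e in zip(sub["accuracy"], sub["experiment"])]
        summaries[pipe] = summarize(res)
    experiments = sorted({e for s in summaries.values()
                          for e in s.experiment_means})
    for pipe, s in summaries.items():
        col = [f"{round_half_up(s.experiment_means[e]):.1f} ± "
               f"{round_half_up(s.experiment_sds[e]):.1f}"
               for e in experiments]
        col += [f"{round_half_up(s.mean_all):.1f} ± {round_half_up(s.sd_all):.1f}",
                f"{round_half_up(s.mean_bottom50):.1f} ± "
                f"{round_half_up(s.sd_bottom50):.1f}",
                f"{round_half_up(s.mean_top50):.1f} ± "
                f"{round_half_up(s.sd_top50):.1f}"]
        pretty[pipe] = col
        full[f"{pipe}_mean"] = [s.experiment_means[e] for e in experiments] + [
            s.mean_all, s.mean_bottom50, s.mean_top50]
        full[f"{pipe}_sd"] = [s.experiment_sds[e] for e in experiments] + [
            s.sd_all, s.sd_bottom50, s.sd_top50]
    index = [str(e + 1) for e in experiments] + [
        "Mean Accuracy (All Tests)", "Mean Accuracy (Bottom 50%)",
        "Mean Accuracy (Top 50%)"]
    return (pd.DataFrame(pretty, index=index),
            pd.DataFrame(full, index=index))


def write_summary_tables(results: list[TestResult],
                         outdir: str | Path) -> list[Path]:
    """Write per-cell summary tables plus t-test and dip-test analogues.

    One table per (meditation task, train size) cell: per-experiment rows and
    the three summary rows, per pipeline.  Pipeline t-tests need all six
    cells' all-test means; the dip test runs per train size on the pooled
    accuracies.  Partial studies produce the available tables and a warning.
    """
    if not results:
        raise ValueError("no results to tabulate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    written = []

    all_means: dict[str, dict[tuple[str, int], float]] = {}
    for (task, tsize), cell in frame.groupby(["task", "train_size"]):
        pretty, full = _cell_summary_frames(cell)
        base = outdir / f"summary_{task}_{tsize}pairs_train"
        pretty.to_csv(base.with_suffix(".csv"), index_label="Experiment No.")
        full.to_csv(base.parent / (base.name + "_fullprec.csv"),
                    index_label="Experiment No.")
        written += [base.with_suffix(".csv"),
                    base.parent / (base.name + "_fullprec.csv")]
        for pipe in cell["pipeline"].unique():
            sub = cell[cell["pipeline"] == pipe]
            all_means.setdefault(pipe, {})[(task, int(tsize))] = float(
                sub["accuracy"].mean())

    # pipeline contrasts on the per-cell all-test means
    pipes = sorted(all_means)
    cells = sorted(set.intersection(*(set(v) for v in all_means.values())))
    if len(pipes) >= 2 and len(cells) >= 2:
        rows = []
        for i in range(len(pipes)):
            for j in range(i + 1, len(pipes)):
                a = [all_means[pipes[i]][c] for c in cells]
                b = [all_means[pipes[j]][c] for c in cells]
                tt = paired_ttest(a, b)
                rows.append({"comparison": f"{pipes[i]} vs {pipes[j]}",
                             "t": round_half_up(tt.t, 2), "df": tt.df,
                             "p": round_half_up(tt.p, 3)})
        p = outdir / "pipeline_ttests.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    else:
        warnings.warn("fewer than 2 pipelines x 2 cells: t-tests skipped",
                      stacklevel=2)

    rows = []
    for tsize, sub in frame.groupby("train_size"):
        acc = sub["accuracy"].to_numpy()
        if len(acc) < 4 or np.ptp(acc) == 0:
            warnings.warn(f"train_size {tsize}: too few/degenerate accuracies "
                          "for the dip test", stacklevel=2)
            continue
        d = dip_test(acc, n_boot=2000, seed=0)
        rows.append({"session_pairs": int(tsize) + 1, "n_tests": d.n,
                     "dip": round(d.dip, 4), "p": round(d.p, 4)})
    if rows:
        p = outdir / "dip_tests.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    return written
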