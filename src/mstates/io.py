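"""Readers and writers for the pipeline's on-disk surfaces.

Formats:

* **matrix**: plain TSV, one row per sample, one column per channel,
  preceded by ``# rate_hz=<float>`` (and optional ``# reference=``)
  header lines and a channel-name column header;
* **EDF**: standard 16-bit European Data Format (written natively,
  read through :mod:`mne`);
* **montage**: whitespace-delimited ``name x y z`` files (``.xyz`` /
  ``.sfp`` dialects, optional count header line);
* templates / labels / segments as TSV with JSON sidecars;
* ground truth and config echoes as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LabelSequence, Montage, Recording, Segment, TemplateSet


class FormatError(ValueError):
    """A file did not parse as the expected dialect."""


# ---------------------------------------------------------------------------
# matrix format


def write_matrix(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={rec.sfreq!r}\n")
        fh.write(f"# reference={rec.reference}\n")
        fh.write("\t".join(rec.montage.channel_names) + "\n")
        np.savetxt(fh, rec.data, fmt="%.17g", delimiter="\t")


def read_matrix(path: str | Path, montage: Montage | None = None) -> Recording:
    path = Path(path)
    sfreq = None
    reference = "vertex"
    names = None
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            header_lines += 1
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("rate_hz="):
                    sfreq = float(body.split("=", 1)[1])
                elif body.startswith("reference="):
                    reference = body.split("=", 1)[1]
            else:
                names = line.split("\t")
                break
    if sfreq is None:
        raise FormatError(f"{path}: missing '# rate_hz=' header line")
    if not names:
        raise FormatError(f"{path}: missing channel-name header row")
    data = np.loadtxt(path, skiprows=header_lines, delimiter="\t", ndmin=2)
    if data.shape[1] != len(names):
        raise FormatError(
            f"{path}: {data.shape[1]} data columns for {len(names)} channel names"
        )
    if montage is None:
        montage = _nominal_montage(names)
    elif list(montage.channel_names) != names:
        raise FormatError(f"{path}: channel names do not match the montage")
    return Recording(data=data, sfreq=sfreq, montage=montage, reference=reference)


def _nominal_montage(names: list[str]) -> Montage:
    """Placeholder positions when no coordinate file accompanies the data."""
    from .simulate import make_montage

    m = make_montage(len(names), seed=0)
    return Montage(channel_names=tuple(names), positions=m.positions)


# ---------------------------------------------------------------------------
# montage files


def read_montage(path: str | Path) -> Montage:
    """Read ``name x y z`` (or ``x y z name``) coordinate files."""
    path = Path(path)
    names: list[str] = []
    coords: list[list[float]] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        tokens = raw.split()
        if not tokens or raw.lstrip().startswith("#"):
            continue
        if len(tokens) < 4:
            if ln == 1:  # count header line of some .xyz dialects
                continue
            raise FormatError(f"{path}:{ln}: expected 'name x y z', got {raw!r}")
        try:
            coords.append([float(t) for t in tokens[1:4]])
            names.append(tokens[0])
        except ValueError:
            try:
                coords.append([float(t) for t in tokens[0:3]])
                names.append(tokens[3])
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: unparseable coordinates") from err
    if len(names) < 2:
        raise FormatError(f"{path}: fewer than 2 channels")
    return Montage(channel_names=tuple(names), positions=np.asarray(coords))


def write_montage(montage: Montage, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, (x, y, z) in zip(montage.channel_names, montage.positions):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


# ---------------------------------------------------------------------------
# EDF


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a minimal 16-bit EDF file (one data record per second).

    Physical ranges are per-channel data extrema, so quantization error
    is bounded by (max - min) / 65535 per channel.  A trailing partial
    second is padded with the channel's final value; the true sample
    count is recoverable from the matrix/JSON sidecars.
    """
    path = Path(path)
    if rec.sfreq != int(rec.sfreq):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rec.sfreq)  # samples per record (1 s records)
    n = rec.n_samples
    n_records = int(np.ceil(n / spr))
    n_ch = rec.n_channels
    data = rec.data
    pad = n_records * spr - n
    if pad:
        data = np.vstack([data, np.repeat(data[-1:, :], pad, axis=0)])

    pmin = data.min(axis=0)
    pmax = data.max(axis=0)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    def pad_field(value: str, width: int) -> bytes:
        return value.encode("ascii")[:width].ljust(width)

    with path.open("wb") as fh:
        fh.write(pad_field("0", 8))  # version
        fh.write(pad_field("X X X X", 80))  # patient id (anonymous)
        fh.write(pad_field("Startdate X X X X", 80))  # recording id
        fh.write(pad_field("01.01.00", 8))
        fh.write(pad_field("00.00.00", 8))
        fh.write(pad_field(str(256 * (1 + n_ch)), 8))
        fh.write(pad_field("", 44))
        fh.write(pad_field(str(n_records), 8))
        fh.write(pad_field("1", 8))  # record duration, seconds
        fh.write(pad_field(str(n_ch), 4))
        for name in rec.montage.channel_names:
            fh.write(pad_field(f"EEG {name}", 16))
        fh.write(b" " * 80 * n_ch)  # transducer
        for _ in range(n_ch):
            fh.write(pad_field("uV", 8))
        for v in pmin:
            fh.write(pad_field(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(pad_field(f"{v:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(pad_field(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(pad_field(str(dmax), 8))
        fh.write(b" " * 80 * n_ch)  # prefiltering
        for _ in range(n_ch):
            fh.write(pad_field(str(spr), 8))
        fh.write(b" " * 32 * n_ch)  # reserved
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr]  # (spr, n_ch)
            fh.write(block.T.tobytes())


def read_edf(path: str | Path, montage: Montage | None = None) -> Recording:
    """Read an EDF file into a Recording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # mne returns volts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    if montage is None:
        montage = _nominal_montage(names)
    elif list(montage.channel_names) != names:
        raise FormatError(f"{path}: channel names do not match the montage")
    return Recording(data=data, sfreq=float(raw.info["sfreq"]), montage=montage)


def read_eeg(path: str | Path, fmt: str | None = None, montage: Montage | None = None) -> Recording:
    """Dispatch on format (``edf`` or ``matrix``; inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        return read_edf(path, montage=montage)
    if fmt == "matrix":
        return read_matrix(path, montage=montage)
    raise ValueError(f"unknown EEG format {fmt!r}")


# ---------------------------------------------------------------------------
# templates, labels, segments, ground truth


def write_templates(templates: TemplateSet, montage: Montage, path: str | Path, sidecar: dict | None = None) -> None:
    """Templates as TSV (channels x classes) plus a JSON sidecar."""
    path = Path(path)
    names = templates.names or tuple(
        f"class_{i + 1}" for i in range(templates.n_templates)
    )
    df = pd.DataFrame(
        templates.maps.T, index=list(montage.channel_names), columns=list(names)
    )
    df.to_csv(path, sep="\t", index_label="channel", float_format="%.10g")
    meta = {
        "level": templates.level,
        "n_templates": templates.n_templates,
        "gev_total": templates.gev_total,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_templates(path: str | Path) -> tuple[TemplateSet, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="channel")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ts = TemplateSet(
        maps=df.to_numpy().T,
        level=meta.get("level", "group"),
        names=tuple(df.columns),
        gev_total=meta.get("gev_total"),
    )
    return ts, list(df.index)


def write_labels(seq: LabelSequence, path: str | Path, sidecar: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_index": np.arange(seq.n_samples),
            "label": seq.labels,
            "correlation": np.round(seq.correlations, 6),
            "excluded": seq.excluded.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {"sfreq": seq.sfreq, "smoothing_converged": seq.smoothing_converged}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_labels(path: str | Path) -> LabelSequence:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LabelSequence(
        labels=df["label"].to_numpy(),
        correlations=df["correlation"].to_numpy(),
        sfreq=float(meta["sfreq"]),
        excluded=df["excluded"].to_numpy().astype(bool),
        smoothing_converged=bool(meta.get("smoothing_converged", True)),
    )


def write_segments(segments: list[Segment], path: str | Path) -> None:
    """BED-like TSV: half-open 0-based sample coordinates."""
    df = pd.DataFrame(
        [
            {
                "start": s.start,
                "end": s.end,
                "class": s.label,
                "duration_ms": round(s.duration_ms, 6),
                "truncated": int(s.truncated),
            }
            for s in segments
        ],
        columns=["start", "end", "class", "duration_ms", "truncated"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path: str | Path) -> None:
    from dataclasses import asdict

    payload = {
        "labels": truth.labels.tolist(),
        "dwell_times_ms": truth.dwell_times_ms,
        "artifact_samples": list(truth.artifact_samples),
        "config": asdict(truth.config) if truth.config is not None else None,
        "templates": truth.templates.maps.tolist() if truth.templates is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# cohort manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """CSV with columns subject_id, group, eeg_path[, montage_path]."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "eeg_path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty manifest")
    if df["subject_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject ids")
    return df
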