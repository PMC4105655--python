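"""WAV, CSV and YAML I/O, the run configuration, and the comparison report."""

from __future__ import annotations

import logging
import wave
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .deconvolve import TransferFunction
from .errors import FormatError, ParameterError
from .sweep import SampledSignal, SweepSpec
from .tubes import PiriformGeometry
from .waveguide import AreaFunction, SideBranch

__all__ = [
    "read_wav", "write_wav", "write_tf_csv", "read_tf_csv",
    "read_geometry_table", "read_area_csv", "read_branches_yaml",
    "formant_report", "export_report", "RunConfig",
]

log = logging.getLogger("sweeptract")

_INT_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31,
              np.dtype(np.uint8): 2 ** 7}


def read_wav(path) -> SampledSignal:
    """Read a mono WAV file into floats in [-1, 1).

    Supports float32/float64 and 8/16/24/32-bit PCM (24-bit arrives as
    left-justified int32).  Multi-channel files keep only the first channel.
    """
    try:
        fs, data = wavfile.read(path)
    except (ValueError, EOFError) as exc:
        raise FormatError(f"cannot parse WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype in _INT_SCALE:
        scale = _INT_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            data = data.astype(np.float64) - 128.0
        data = np.asarray(data, dtype=np.float64) / scale
    return SampledSignal(np.asarray(data, dtype=np.float64), float(fs))


def write_wav(sig: SampledSignal, path, bit_depth: str | int = "float32") -> None:
    """Write a mono WAV file as float32 ('float32') or 16/24-bit PCM."""
    fs = int(round(sig.fs))
    x = sig.samples
    if bit_depth == "float32":
        wavfile.write(path, fs, x.astype(np.float32))
    elif bit_depth == 16:
        ints = np.clip(np.round(x * 2 ** 15), -2 ** 15, 2 ** 15 - 1)
        wavfile.write(path, fs, ints.astype(np.int16))
    elif bit_depth == 24:
        ints = np.clip(np.round(x * 2 ** 23), -2 ** 23, 2 ** 23 - 1)
        ints = ints.astype(np.int64) & 0xFFFFFF
        raw = np.zeros((ints.size, 3), dtype=np.uint8)
        raw[:, 0] = ints & 0xFF
        raw[:, 1] = (ints >> 8) & 0xFF
        raw[:, 2] = (ints >> 16) & 0xFF
        with wave.open(str(path), "wb") as w:
            w.setnchannels(1)
            w.setsampwidth(3)
            w.setframerate(fs)
            w.writeframes(raw.tobytes())
    else:
        raise ParameterError(f"unsupported bit depth {bit_depth!r}")


def write_tf_csv(tf: TransferFunction, path) -> None:
    """Write a transfer function as CSV (freq_hz, mag_db[, re, im])."""
    cols = {"freq_hz": tf.freqs, "mag_db": tf.magnitude_db}
    if not tf.is_db:
        cols["re"] = np.real(tf.values)
        cols["im"] = np.imag(tf.values)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_tf_csv(path) -> TransferFunction:
    df = pd.read_csv(path)
    if "re" in df.columns and "im" in df.columns:
        return TransferFunction(df["freq_hz"].to_numpy(),
                                df["re"].to_numpy() + 1j * df["im"].to_numpy())
    return TransferFunction(df["freq_hz"].to_numpy(),
                            df["mag_db"].to_numpy(), is_db=True)


def read_geometry_table(path) -> list[PiriformGeometry]:
    """Read piriform geometries from CSV or YAML (label, L_mm, VTV, PV)."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        rows = yaml.safe_load(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    try:
        return [
            PiriformGeometry(L_sinus=float(r["L_mm"]), PV=float(r["PV"]),
                             VTV=float(r["VTV"]), label=str(r.get("label", "")))
            for r in rows
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(
            f"{path}: expected columns label, L_mm, VTV, PV") from exc


def read_area_csv(path) -> AreaFunction:
    """Read an area function from CSV (x_mm, area_mm2)."""
    df = pd.read_csv(path)
    try:
        return AreaFunction(df["x_mm"].to_numpy(), df["area_mm2"].to_numpy())
    except KeyError as exc:
        raise FormatError(f"{path}: expected columns x_mm, area_mm2") from exc


def read_branches_yaml(path) -> list[SideBranch]:
    """Read side branches from YAML: list of {attach_x, length, area[, closed_end]}."""
    rows = yaml.safe_load(Path(path).read_text())
    if isinstance(rows, dict):
        rows = [rows]
    return [
        SideBranch(attach_x=float(r["attach_x"]), length=float(r["length"]),
                   area=float(r["area"]),
                   closed_end=bool(r.get("closed_end", True)))
        for r in rows
    ]


def formant_report(numerical_hz, experimental_hz, labels=None) -> pd.DataFrame:
    """Per-formant comparison with signed relative differences.

    ``rel_diff_pct = 100 * (exp - num) / exp`` — the experimental value is
    the denominator and the sign is experimental minus numerical.
    """
    num = np.asarray(numerical_hz, dtype=np.float64)
    exp = np.asarray(experimental_hz, dtype=np.float64)
    if num.size != exp.size:
        raise ParameterError("numerical and experimental lists differ in length")
    labels = list(labels) if labels is not None \
        else [f"F{i + 1}" for i in range(num.size)]
    return pd.DataFrame({
        "formant": labels,
        "num_hz": num,
        "exp_hz": exp,
        "rel_diff_pct": 100.0 * (exp - num) / exp,
    })


def export_report(tfs: dict, formants: pd.DataFrame | None,
                  troughs=None, out_dir=".") -> list[Path]:
    """Write spectra and the formant comparison table to CSV files.

    ``tfs`` maps names to :class:`TransferFunction`; ``formants`` is a frame
    from :func:`formant_report` (a ``mean_abs_rel_diff_pct`` summary row is
    appended); ``troughs`` is an optional mapping of names to trough
    frequencies.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tf in tfs.items():
        p = out_dir / f"tf_{name}.csv"
        write_tf_csv(tf, p)
        written.append(p)
    if formants is not None:
        p = out_dir / "formant_comparison.csv"
        formants.to_csv(p, index=False)
        summary = pd.DataFrame({
            "mean_abs_rel_diff_pct": [formants["rel_diff_pct"].abs().mean()]})
        ps = out_dir / "formant_comparison_summary.csv"
        summary.to_csv(ps, index=False)
        written += [p, ps]
    if troughs:
        rows = [{"name": k, "trough_hz": f}
                for k, fl in troughs.items() for f in np.atleast_1d(fl)]
        p = out_dir / "troughs.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    return written


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run, serialised beside outputs."""

    sweep: SweepSpec = field(default_factory=SweepSpec)
    repeats: int = 3
    temperature_c: float = 5.0
    window_threshold_db: float = 60.0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["sweep"] = asdict(self.sweep)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sweep = SweepSpec(**doc.pop("sweep", {}))
        return cls(sweep=sweep, **doc)
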