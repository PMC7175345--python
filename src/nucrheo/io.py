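"""File formats, unit handling and run configuration.

Trace files are plain TSV with a ``#``-prefixed metadata block followed
by a two-column table::

    # kind: aspiration
    # delta_P: 1 kPa
    # R_p: 3 um
    # phi: 2
    # condition: WT
    # replicate: 0
    t [s]\tL_p [um]
    0.1\t0.477
    ...

Metadata values and column headers may carry units (Pa/kPa, m/um/nm,
s/ms, N/uN/nN); everything is converted to the internal convention
(s, um, kPa, uN) on read.  Results are written as tidy TSV tables with
JSON mirrors and a run manifest recording config, seed and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import CreepFitResult
from .rheometry import AspirationTrace, IndentationTrace

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_trace", "write_trace", "write_results", "read_results"]

# conversion factors into internal units
_UNIT_FACTORS = {
    "s": 1.0, "ms": 1e-3, "min": 60.0,
    "um": 1.0, "µm": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6,
    "kPa": 1.0, "Pa": 1e-3, "MPa": 1e3,
    "uN": 1.0, "µN": 1.0, "nN": 1e-3, "N": 1e6, "mN": 1e3,
    "": 1.0,
}

_META_KEYS_ASPIRATION = {"delta_P", "R_p"}
_META_KEYS_INDENTATION = {"f", "R", "h"}


def _convert(value: float, unit: str, context: str) -> float:
    try:
        return value * _UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r} for {context}") from None


def _parse_meta_value(raw: str, key: str) -> float | str:
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([A-Za-zµ]*)\s*", raw)
    if m:
        try:
            return _convert(float(m.group(1)), m.group(2), key)
        except ValueError:
            if m.group(2):
                raise
    return raw.strip()


def _parse_header_cell(cell: str) -> tuple[str, str]:
    m = re.fullmatch(r"\s*(\w+)\s*(?:\[([^\]]*)\])?\s*", cell)
    if not m:
        raise ValueError(f"cannot parse column header {cell!r}")
    return m.group(1), m.group(2) or ""


def read_trace(path: str | Path, kind: str | None = None):
    """Read an aspiration or indentation trace file.

    ``kind`` (aspiration | indentation) defaults to the file's
    ``kind`` metadata entry.  Missing metadata keys and non-monotone
    time are rejected with informative errors.
    """
    path = Path(path)
    meta: dict[str, float | str] = {}
    rows: list[str] = []
    header: str | None = None
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip()[1:].strip()
            if ":" in body:
                key, raw = body.split(":", 1)
                meta[key.strip()] = _parse_meta_value(raw, key.strip())
            continue
        if header is None:
            header = line
        else:
            rows.append(line)
    if header is None or not rows:
        raise ValueError(f"{path}: no tabular data found")
    kind = str(kind or meta.get("kind", "")).lower()
    if kind not in {"aspiration", "indentation"}:
        raise ValueError(f"{path}: trace kind missing or unknown ({kind!r})")

    names, units = zip(*(_parse_header_cell(c) for c in re.split(r"[\t,]", header)))
    data = np.array([[float(x) for x in re.split(r"[\t,]", r)] for r in rows])
    cols = {n: _convert(data[:, i], units[i], n) for i, n in enumerate(names)}

    if "t" not in cols:
        raise ValueError(f"{path}: missing time column 't'")
    t = cols["t"]
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at data row {bad[0] + 1}")

    required = _META_KEYS_ASPIRATION if kind == "aspiration" else _META_KEYS_INDENTATION
    missing = sorted(k for k in required if k not in meta)
    if missing:
        raise ValueError(f"{path}: missing metadata key(s): {missing}")

    common = dict(condition=str(meta.get("condition", "")),
                  replicate=meta.get("replicate", 0))
    if kind == "aspiration":
        if "L_p" not in cols:
            raise ValueError(f"{path}: missing aspirated-length column 'L_p'")
        return AspirationTrace(
            t=t, L_p=cols["L_p"], delta_P=float(meta["delta_P"]),
            R_p=float(meta["R_p"]), phi=float(meta.get("phi", 2.0)), **common,
        )
    if "delta" not in cols:
        raise ValueError(f"{path}: missing depth column 'delta'")
    return IndentationTrace(
        t=t, delta=cols["delta"], f=float(meta["f"]), R=float(meta["R"]),
        h=float(meta["h"]), ramp=float(meta.get("ramp", 0.0)), **common,
    )


def write_trace(trace, path: str | Path) -> Path:
    """Write a trace in the canonical TSV format (internal units)."""
    path = Path(path)
    lines = []
    if isinstance(trace, AspirationTrace):
        lines += [
            "# kind: aspiration",
            f"# delta_P: {trace.delta_P} kPa",
            f"# R_p: {trace.R_p} um",
            f"# phi: {trace.phi}",
        ]
        cols = ("t [s]", "L_p [um]")
        data = np.column_stack([trace.t, trace.L_p])
    elif isinstance(trace, IndentationTrace):
        lines += [
            "# kind: indentation",
            f"# f: {trace.f} uN",
            f"# R: {trace.R} um",
            f"# h: {trace.h} um",
            f"# ramp: {trace.ramp} s",
        ]
        cols = ("t [s]", "delta [um]")
        data = np.column_stack([trace.t, trace.delta])
    else:
        raise TypeError(f"unsupported trace type {type(trace).__name__}")
    lines += [f"# condition: {trace.condition}", f"# replicate: {trace.replicate}"]
    lines.append("\t".join(cols))
    lines += ["\t".join(format(v, ".10g") for v in row) for row in data]
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML without loss."""

    phi_convention: str = "numerator"
    chi_warn: float = 1.0
    chi_max: float = 3.0
    fit_bounds: tuple[float, float] = (1e-4, 1e4)
    noise_cv: float = 0.05
    fs: float = 10.0
    duration: float = 12.0
    n_replicates: int = 15
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["fit_bounds"] = list(self.fit_bounds)
        d["contrasts"] = [list(c) for c in self.contrasts]
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["fit_bounds"] = tuple(d.get("fit_bounds", (1e-4, 1e4)))
        d["contrasts"] = [tuple(c) for c in d.get("contrasts", [])]
        return cls(**d)


def _fit_record(res: CreepFitResult) -> dict:
    rec = {
        "condition": res.curve.condition,
        "replicate": res.curve.replicate,
        "model": res.model_id,
        "r_squared": res.r_squared,
        "converged": res.converged,
        "n_points": res.n_points,
        "aic": res.aic,
    }
    for name, value in res.params.items():
        lo, hi = res.ci95[name]
        rec[name] = value
        rec[f"{name}_ci_lo"] = lo
        rec[f"{name}_ci_hi"] = hi
    if res.derived is not None:
        rec.update(tau=res.derived.tau, k_ST=res.derived.k_ST, alpha=res.derived.alpha)
    return rec


def write_results(
    fits: Sequence[CreepFitResult],
    out_dir: str | Path,
    associations: dict[str, pd.DataFrame] | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write fit results (TSV + JSON mirror), association tables and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    records = [_fit_record(r) for r in fits]
    cols = list(records[0]) if records else [
        "condition", "replicate", "model", "r_squared", "converged", "n_points", "aic"]
    table = pd.DataFrame(records, columns=cols)
    written["fits_tsv"] = out / "fits.tsv"
    table.to_csv(written["fits_tsv"], sep="\t", index=False)
    written["fits_json"] = out / "fits.json"
    written["fits_json"].write_text(json.dumps(records, indent=1, default=float))

    for name, frame in (associations or {}).items():
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        written[name] = p

    import nucrheo

    manifest = {
        "package": "nucrheo",
        "version": getattr(nucrheo, "__version__", "unknown"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_fits": len(records),
        "config": dataclasses.asdict(config) if config else None,
    }
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=1, default=str))
    return written


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a fits table written by :func:`write_results`."""
    return pd.read_csv(Path(path), sep="\t")
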