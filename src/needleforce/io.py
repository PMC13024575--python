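"""Curve file format, run configuration, and config hashing.

Curve files are plain comma-separated text with '#'-prefixed ``key=value``
metadata header lines, a column header ``t_s,depth_mm,force_N,phase`` and
full ``repr`` float precision, so a write/read round trip reproduces every
array bit-exactly. Units are fixed by the column names (seconds,
millimetres, newtons).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np

from .curve import PHASE_INSERTION, PHASE_RETRACTION, ForceCurve

__all__ = ["read_curve", "write_curve", "ParseError", "ConfigError",
           "load_config", "config_hash", "CURVE_COLUMNS"]

CURVE_COLUMNS = ("t_s", "depth_mm", "force_N", "phase")
_PHASES = {PHASE_INSERTION, PHASE_RETRACTION}


class ParseError(ValueError):
    """A curve file is malformed; the message names the offending line."""


class ConfigError(ValueError):
    """A run configuration fails schema validation."""


def write_curve(curve: ForceCurve, path) -> None:
    """Write a curve as commented CSV with lossless float precision."""
    with open(path, "w") as fh:
        for key, val in curve.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(",".join(CURVE_COLUMNS) + "\n")
        for t, d, f, ph in zip(curve.t, curve.depth, curve.force,
                               curve.phase):
            fh.write(f"{float(t)!r},{float(d)!r},{float(f)!r},{ph}\n")


def read_curve(path) -> ForceCurve:
    """Read a curve file, validating structure row by row.

    Malformed rows (wrong column count, unparsable or non-finite numbers,
    negative or non-increasing time, unknown phase labels) raise
    :class:`ParseError` naming the 1-based line number. Header metadata is
    preserved verbatim as strings.
    """
    meta = {}
    t, depth, force, phase = [], [], [], []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val
                continue
            if not header_seen:
                cols = tuple(c.strip() for c in line.split(","))
                if cols != CURVE_COLUMNS:
                    raise ParseError(
                        f"{path}: line {lineno}: expected header "
                        f"{','.join(CURVE_COLUMNS)}, got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, "
                    f"got {len(parts)}")
            try:
                tv, dv, fv = (float(parts[0]), float(parts[1]),
                              float(parts[2]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: unparsable number: {exc}")
            if not (np.isfinite(tv) and np.isfinite(dv) and np.isfinite(fv)):
                raise ParseError(
                    f"{path}: line {lineno}: non-finite value")
            if tv < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative time {tv}")
            if t and tv <= t[-1]:
                raise ParseError(
                    f"{path}: line {lineno}: time not strictly increasing "
                    f"({tv} after {t[-1]})")
            ph = parts[3].strip()
            if ph not in _PHASES:
                raise ParseError(
                    f"{path}: line {lineno}: unknown phase {ph!r}")
            t.append(tv)
            depth.append(dv)
            force.append(fv)
            phase.append(ph)
    if not header_seen:
        raise ParseError(f"{path}: missing column header line")
    if not t:
        raise ParseError(f"{path}: no data rows")
    return ForceCurve(np.array(t), np.array(depth), np.array(force),
                      np.array(phase, dtype=object), meta)


# ---------------------------------------------------------------------------
# run configuration

_ALLOWED_TOP = {"tissue", "protocol", "perturbation", "fit", "stats",
                "seed", "output_dir", "noise_sd", "sample_rate"}
_ALLOWED_TISSUE = {"preset", "f_max", "lam", "k0", "alpha", "mu0",
                   "gamma_w0", "label"}
_ALLOWED_PROTOCOL = {"speed", "angle_deg", "max_depth", "retraction_speed",
                     "speeds", "angles", "reps"}
_ALLOWED_PERTURB = {"amplitude", "frequency", "duration", "dt", "coupling"}
_ALLOWED_FIT = {"mu0", "max_iter", "multi_start"}
_ALLOWED_STATS = {"factor", "response", "alpha"}


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {name!r} "
            f"(allowed: {sorted(allowed)})")


def load_config(path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown keys are rejected outright so silent typos cannot change a
    run's meaning.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    _check_keys(cfg, _ALLOWED_TOP, "top level")
    for key, allowed in (("tissue", _ALLOWED_TISSUE),
                         ("protocol", _ALLOWED_PROTOCOL),
                         ("perturbation", _ALLOWED_PERTURB),
                         ("fit", _ALLOWED_FIT),
                         ("stats", _ALLOWED_STATS)):
        block = cfg.get(key)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"{path}: {key!r} must be a mapping")
        _check_keys(block, allowed, key)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash identifying a configuration."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
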