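"""Recording, serialization, rendering and run summaries — the externally
visible surface of a run.

Population averages include molecules bound in complexes, which keeps the
recorded means continuous across complex formation and dissociation
events.  Means of an extinct species are recorded as missing (empty CSV
fields), never as zero, because zero is a legal attribute value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import _kernel as K
from .engine import TIMESERIES_COLUMNS, RunResult, WorldState


@dataclass
class TimeSeriesRow:
    """Per-step counts and attribute statistics over the whole population."""

    step: int
    time: float
    n_R_free: int
    n_P_free: int
    n_RR_complexes: int
    n_RP_complexes: int
    n_R_total: int
    n_P_total: int
    mean_a_R: float
    std_a_R: float
    mean_l_R: float
    std_l_R: float
    mean_a_P: float
    std_a_P: float
    mean_l_P: float
    std_l_P: float


def record(state: WorldState) -> TimeSeriesRow:
    """Exact counts and arithmetic means over all living molecules of each
    species, including those bound in complexes.

    Performs a full scan over the object-level views, independent of the
    kernel's incremental accumulators, so it doubles as a recount oracle.
    """
    free = state.free_molecules()
    cplx = state.complexes()
    a_vals = {"replicase": [], "parasite": []}
    l_vals = {"replicase": [], "parasite": []}
    n_rr = n_rp = 0
    for m in free:
        a_vals[m.species].append(m.a)
        l_vals[m.species].append(m.l)
    for c in cplx:
        for m in (c.catalyst, c.template):
            a_vals[m.species].append(m.a)
            l_vals[m.species].append(m.l)
        if c.template.species == "replicase":
            n_rr += 1
        else:
            n_rp += 1

    def stats(vals):
        if not vals:
            return float("nan"), float("nan")
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std())

    ma_r, sa_r = stats(a_vals["replicase"])
    ml_r, sl_r = stats(l_vals["replicase"])
    ma_p, sa_p = stats(a_vals["parasite"])
    ml_p, sl_p = stats(l_vals["parasite"])
    n_rf = sum(1 for m in free if m.species == "replicase")
    n_pf = len(free) - n_rf
    return TimeSeriesRow(
        step=state.step_count, time=state.time,
        n_R_free=n_rf, n_P_free=n_pf,
        n_RR_complexes=n_rr, n_RP_complexes=n_rp,
        n_R_total=n_rf + 2 * n_rr + n_rp, n_P_total=n_pf + n_rp,
        mean_a_R=ma_r, std_a_R=sa_r, mean_l_R=ml_r, std_l_R=sl_r,
        mean_a_P=ma_p, std_a_P=sa_p, mean_l_P=ml_p, std_l_P=sl_p)


def write_timeseries(rows, path) -> None:
    """Write the time series as header-first CSV in the fixed column order,
    full float precision, missing means as empty fields."""
    if isinstance(rows, pd.DataFrame):
        df = rows[TIMESERIES_COLUMNS]
    else:
        df = pd.DataFrame([asdict(r) for r in rows], columns=TIMESERIES_COLUMNS)
    df.to_csv(path, index=False, float_format=None)


class TimeSeriesParseError(ValueError):
    """Malformed time-series CSV; the message names the offending line."""


def read_timeseries(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_timeseries` output."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TimeSeriesParseError(f"{path}: {exc}") from exc
    if list(df.columns) != TIMESERIES_COLUMNS:
        raise TimeSeriesParseError(
            f"{path}: expected columns {TIMESERIES_COLUMNS}, got {list(df.columns)}")
    for col in TIMESERIES_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TimeSeriesParseError(
                f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


#: rendering styles: species base colors, intensity scaled by an attribute
_STYLE_ATTRS = ("a", "l")


def render_frame(state: WorldState, scale: float = 4.0,
                 attribute: str = "a") -> Image.Image:
    """Draw the world: free molecules as circles, complexes as two
    overlapping circles, replicases blue and parasites red with intensity
    mapped from the chosen attribute.  Deterministic for a given state."""
    if attribute not in _STYLE_ATTRS:
        raise ValueError(f"attribute must be one of {_STYLE_ATTRS}")
    w = max(1, int(round(state.geom.width * scale)))
    h = max(1, int(round(state.geom.height * scale)))
    img = Image.new("RGB", (w, h), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    r_px = state.kin.radius * scale

    def circle(x, y, species, value):
        shade = int(round(80 + 175 * value))
        color = (0, 60, shade) if species == "replicase" else (shade, 40, 0)
        cx, cy = x * scale, y * scale
        draw.ellipse((cx - r_px, cy - r_px, cx + r_px, cy + r_px), fill=color)

    for m in state.free_molecules():
        circle(m.x, m.y, m.species, getattr(m, attribute))
    for c in state.complexes():
        # two overlapping circles, offset along x by half a radius
        off = state.kin.radius / 2.0
        circle((c.x - off) % state.geom.width, c.y, c.catalyst.species,
               getattr(c.catalyst, attribute))
        circle((c.x + off) % state.geom.width, c.y, c.template.species,
               getattr(c.template, attribute))
    return img


def summary_schema() -> dict:
    """The JSON schema the run summary must satisfy (shipped in-package)."""
    with resources.files("rpsim.schema").joinpath(
            "run_summary.schema.json").open("rb") as fh:
        return json.load(fh)


def validate_summary(summary: dict, schema: dict | None = None) -> None:
    """Structural validation of a run summary against the shipped schema
    (a minimal checker covering the subset the schema uses: required keys,
    primitive types, enums and nested objects)."""
    if schema is None:
        schema = summary_schema()
    _validate_node(summary, schema, "$")


_TYPES = {"object": dict, "string": str, "integer": int,
          "number": (int, float), "boolean": bool, "null": type(None)}


def _validate_node(value, schema: dict, path: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        expected = _TYPES[typ]
        if typ == "integer" and isinstance(value, bool):
            raise ValueError(f"{path}: expected integer, got bool")
        if not isinstance(value, expected):
            raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
    if "enum" in schema and value not in schema["enum"]:
        raise ValueError(f"{path}: {value!r} not in {schema['enum']}")
    if typ == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{path}.{key}")


def run_summary(result: RunResult, config, seed: int) -> dict:
    """Condensed, JSON-serializable account of one finished run."""
    from .scenarios import config_to_toml, detect_stabilization

    ts = result.timeseries
    window = max(2, min(10000, len(ts) // 2))
    stab = {}
    for col in ("mean_a_R", "mean_l_R", "mean_a_P", "mean_l_P"):
        series = ts[col].to_numpy()
        if np.isnan(series).any():
            stab[col] = None
        else:
            idx = detect_stabilization(series, window=window, tol=1e-6)
            stab[col] = None if idx is None else int(ts["step"].iloc[idx])
    return {
        "config_toml": config_to_toml(config),
        "seed": int(seed),
        "outcome": result.outcome,
        "final_step": int(result.final_step),
        "wall_steps": int(len(ts) - 1),
        "stabilization_step": stab,
        "final_counts": {
            "replicases": int(ts["n_R_total"].iloc[-1]),
            "parasites": int(ts["n_P_total"].iloc[-1]),
        },
        "events": {k: int(v) for k, v in vars(result.events).items()},
    }
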