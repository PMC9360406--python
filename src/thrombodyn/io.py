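"""File I/O, run configuration and the batch analysis pipeline.

Curve files are delimited text.  The default "long" dialect has one row
per sample point::

    sample_id,reagent,tm,replicate,time_min,thrombin_nM

A "wide" reader (one time column, one thrombin column per sample) is
also provided since instrument exports vary.  Factor tables are CSV with
columns sample_id, at_pct, a2m_uM, fib_gL and optional covariates.
Run configurations load from YAML/JSON and are serialized verbatim into
every output for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curve_model import (
    LagRule,
    ThrombinCurve,
    average_replicates,
    compute_tg_parameters,
    etp_inhibition,
    resample_uniform,
)
from .cohort_stats import compare_groups, reference_range
from .inactivation import PlasmaFactors, RateModel, thrombin_decay_capacity
from .prothrombin_conversion import ExtractionOptions, analyze_curve

__all__ = [
    "RunConfig",
    "read_curves",
    "read_wide_curves",
    "write_curves",
    "read_factors",
    "run_pipeline",
]

log = logging.getLogger("thrombodyn")

LONG_COLUMNS = ["sample_id", "reagent", "tm", "replicate", "time_min", "thrombin_nM"]


@dataclass
class RunConfig:
    """Batch-run configuration; fully serialized into every output."""

    curves_path: str = ""
    factors_path: str = ""
    out_dir: str = "td_out"
    dialect: str = "long"  # or "wide"
    delimiter: str = ","
    dt: float = 0.05  # uniform resampling step, min
    lag_threshold_nM: float = 2.0
    lag_peak_fraction: float = 0.05
    smooth_window_min: float = 0.5
    polyorder: int = 3
    tail_extend: bool = True
    tail_halflives: float = 10.0
    seed: int = 0
    group_compare: bool = False  # men / women±OC comparison if covariates present
    rate_model: dict = field(default_factory=lambda: RateModel().to_dict())

    def lag_rule(self) -> LagRule:
        return LagRule(self.lag_threshold_nM, self.lag_peak_fraction)

    def extraction_options(self) -> ExtractionOptions:
        return ExtractionOptions(
            smooth_window_min=self.smooth_window_min,
            polyorder=self.polyorder,
            tail_extend=self.tail_extend,
            tail_halflives=self.tail_halflives,
        )

    def model(self) -> RateModel:
        return RateModel.from_dict(self.rate_model)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_curves(path: str | Path, delimiter: str = ",") -> tuple[list[ThrombinCurve], dict]:
    """Parse a long-format curve file into ThrombinCurve objects.

    Malformed rows (non-numeric time/thrombin) are logged and skipped;
    a missing time column or duplicate (sample, condition, replicate,
    time) keys are hard errors.  Returns (curves, report).
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve file {path} missing columns {missing}")
    n_raw = len(df)
    for col in ("time_min", "thrombin_nM"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    bad = df[["time_min", "thrombin_nM", "replicate"]].isna().any(axis=1)
    skipped = int(bad.sum())
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    df = df[~bad].copy()
    df["tm"] = df["tm"].astype(str).str.lower().isin(["1", "true", "yes", "tm"])
    key_cols = ["sample_id", "reagent", "tm", "replicate", "time_min"]
    if df.duplicated(key_cols).any():
        dup = df[df.duplicated(key_cols)].iloc[0]
        raise ValueError(
            "duplicate (sample, condition, replicate, time) key: "
            f"{tuple(dup[key_cols])}"
        )
    curves = []
    for (sid, reagent, tm, rep), grp in df.groupby(
        ["sample_id", "reagent", "tm", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        curves.append(
            ThrombinCurve(
                time=grp["time_min"].to_numpy(),
                thrombin=grp["thrombin_nM"].to_numpy(),
                sample_id=str(sid),
                reagent=str(reagent),
                tm_present=bool(tm),
                replicate=int(rep),
            )
        )
    report = {"rows": n_raw, "skipped_rows": skipped, "curves": len(curves)}
    return curves, report


def read_wide_curves(
    path: str | Path,
    reagent: str = "thrombo",
    tm_present: bool = False,
    delimiter: str = ",",
) -> tuple[list[ThrombinCurve], dict]:
    """Wide dialect: a ``time_min`` column plus one thrombin column per
    sample; condition metadata supplied by the caller."""
    df = pd.read_csv(path, delimiter=delimiter)
    if "time_min" not in df.columns:
        raise ValueError(f"wide curve file {path} missing 'time_min' column")
    t = pd.to_numeric(df["time_min"], errors="coerce").to_numpy()
    curves = []
    for col in df.columns:
        if col == "time_min":
            continue
        y = pd.to_numeric(df[col], errors="coerce").to_numpy()
        ok = np.isfinite(t) & np.isfinite(y)
        curves.append(
            ThrombinCurve(
                time=t[ok],
                thrombin=y[ok],
                sample_id=str(col),
                reagent=reagent,
                tm_present=tm_present,
            )
        )
    return curves, {"rows": len(df), "curves": len(curves)}


def write_curves(curves: list[ThrombinCurve], path: str | Path, delimiter: str = ",") -> None:
    """Write curves in the long dialect (inverse of :func:`read_curves`)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "reagent": c.reagent,
                    "tm": c.tm_present,
                    "replicate": c.replicate,
                    "time_min": c.time,
                    "thrombin_nM": c.thrombin,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=delimiter, index=False)


def read_factors(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read the per-sample plasma-factor table, indexed by sample_id."""
    df = pd.read_csv(path, delimiter=delimiter)
    needed = {"sample_id", "at_pct", "a2m_uM", "fib_gL"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"factor table {path} missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in factor table")
    return df.set_index("sample_id")


TD_PARAMS = ["pc_tot", "pc_max", "t_at", "t_a2m", "tdc"]
TG_PARAMS = ["lag_time", "peak", "time_to_peak", "etp", "velocity_index"]


def analyze_cohort(
    curves: list[ThrombinCurve],
    factors_df: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-sample x per-condition TG + TD parameter table.

    Replicates are averaged after resampling; samples without a factor
    row are skipped with a warning.
    """
    model = config.model()
    lag_rule = config.lag_rule()
    opts = config.extraction_options()

    grouped: dict[tuple, list[ThrombinCurve]] = {}
    for c in curves:
        grouped.setdefault(c.condition_key(), []).append(c)

    rows = []
    for (sid, reagent, tm), reps in sorted(grouped.items()):
        if sid not in factors_df.index:
            log.warning("sample %s has curves but no factor row; skipped", sid)
            continue
        frow = factors_df.loc[sid]
        factors = PlasmaFactors(
            at_pct=float(frow["at_pct"]),
            a2m_uM=float(frow["a2m_uM"]),
            fib_gL=float(frow["fib_gL"]),
        )
        reps = [resample_uniform(c, config.dt) for c in reps]
        curve = average_replicates(reps, config.dt) if len(reps) > 1 else reps[0]
        tg = compute_tg_parameters(curve, lag_rule)
        td = analyze_curve(curve, factors, model, opts)
        log.info(
            "sample=%s reagent=%s tm=%s clipped=%.3f tail=%.1fnM truncated=%s",
            sid, reagent, tm, td.clipped_mass_frac, td.tail_added_nM, tg.truncated,
        )
        row = {
            "sample_id": sid,
            "reagent": reagent,
            "tm": tm,
            "condition": f"{reagent}_tm" if tm else reagent,
            "lag_time": tg.lag_time,
            "peak": tg.peak,
            "time_to_peak": tg.time_to_peak,
            "etp": tg.etp,
            "velocity_index": tg.velocity_index,
            **td.to_dict(),
        }
        rows.append(row)
    if not rows:
        raise ValueError("empty join: no curve sample_id matches the factor table")
    out = pd.DataFrame(rows)

    # ETP inhibition from the ±TM pair of the same reagent
    inhib = []
    for _, r in out.iterrows():
        val = np.nan
        if r["tm"]:
            ref = out[
                (out["sample_id"] == r["sample_id"])
                & (out["reagent"] == r["reagent"])
                & (~out["tm"])
            ]
            if len(ref) == 1 and ref["etp"].iloc[0] > 0:
                val = etp_inhibition(float(ref["etp"].iloc[0]), float(r["etp"]))
        inhib.append(val)
    out["etp_inhibition_pct"] = inhib
    return out


def summarize_cohort(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) per condition for every TG/TD parameter."""
    rows = []
    params = TG_PARAMS + TD_PARAMS + ["etp_inhibition_pct"]
    for cond, grp in per_sample.groupby("condition"):
        for p in params:
            x = grp[p].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            rows.append(
                {"condition": cond, "parameter": p, "median": med,
                 "iqr_low": q1, "iqr_high": q3, "n": x.size}
            )
    return pd.DataFrame(rows)


def reference_ranges_table(per_sample: pd.DataFrame, params=None) -> pd.DataFrame:
    """Reference-range (2.5th/97.5th percentile) table per condition."""
    params = params or TD_PARAMS
    rows = []
    for cond, grp in per_sample.groupby("condition"):
        for p in params:
            x = grp[p].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size < 2:
                continue
            rr = reference_range(x)
            rows.append({"condition": cond, "parameter": p, **rr.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Batch analysis: read curves and factors, analyze every sample and
    condition, write result tables with embedded provenance.

    Returns {"per_sample", "summary", "reference_ranges", "comparisons"}.
    """
    if config.dialect == "long":
        curves, report = read_curves(config.curves_path, config.delimiter)
    elif config.dialect == "wide":
        curves, report = read_wide_curves(config.curves_path, delimiter=config.delimiter)
    else:
        raise ValueError(f"unknown dialect {config.dialect!r}")
    factors_df = read_factors(config.factors_path, config.delimiter)
    log.info("read %d curves (%d rows skipped), %d factor rows",
             report["curves"], report.get("skipped_rows", 0), len(factors_df))

    per_sample = analyze_cohort(curves, factors_df, config)
    summary = summarize_cohort(per_sample)
    ranges = reference_ranges_table(per_sample)

    comparisons = {}
    if config.group_compare and {"sex", "oc_use"} <= set(factors_df.columns):
        labels = _group_labels(factors_df)
        merged = per_sample.join(labels, on="sample_id")
        for cond, grp in merged.groupby("condition"):
            for p in TD_PARAMS:
                x = grp[p].to_numpy(dtype=float)
                ok = np.isfinite(x)
                if ok.sum() < 6 or grp["group"][ok].nunique() < 2:
                    continue
                try:
                    rep = compare_groups(x[ok], grp["group"][ok].to_numpy())
                except ValueError:
                    continue
                comparisons[f"{cond}:{p}"] = rep.to_dict()

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config.to_dict(), "version": __version__,
                  "input_report": report}
    header = f"# thrombodyn {__version__} config={json.dumps(config.to_dict(), sort_keys=True)}\n"
    for name, df in [("per_sample", per_sample), ("summary", summary),
                     ("reference_ranges", ranges)]:
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump({**provenance, "comparisons": comparisons}, fh, indent=2, default=str)

    return {"per_sample": per_sample, "summary": summary,
            "reference_ranges": ranges, "comparisons": comparisons,
            "provenance": provenance}


def _group_labels(factors_df: pd.DataFrame) -> pd.Series:
    """men / women_no_oc / women_oc labels from covariates."""
    def lab(row):
        if str(row["sex"]).upper().startswith("M"):
            return "men"
        return "women_oc" if bool(row["oc_use"]) else "women_no_oc"

    return pd.Series(factors_df.apply(lab, axis=1), name="group")
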