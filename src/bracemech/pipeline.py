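"""Stage orchestration: dataset -> slopes -> contributions -> statistics.

Each stage is a pure function over plain tables so the command-line
interface stays a thin shell and pipeline composition equals manual
stage-by-stage invocation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as bstats
from .contribution import BeamGeometry, contribution_result, contribution_table
from .errors import BraceMechError, ContiguityError, DegenerateFitError, NoCycleError
from .slopes import METHODS, extract_slope
from .trace_io import PlantRecord, RemovalSeries

__all__ = ["extract_slopes_table", "contributions_from_slopes", "stats_report"]


def extract_slopes_table(
    series_list: list[RemovalSeries],
    method: str = "full",
    fallback_to_full: bool = True,
    seed: int | None = 0,
    min_run: int = 10,
    min_span_m: float = 0.02,
) -> pd.DataFrame:
    """One row per (plant, test): all three methods' slopes where computable.

    The ``slope`` column holds the selected method's estimate (with the
    standard full-trace fallback when the cycle parser fails);
    ``fallback`` flags rows where that happened and ``failed`` rows where
    even the full fit was impossible — failures are flagged, never
    dropped, so downstream exclusions stay visible.
    """
    rows = []
    for series in series_list:
        for lab, trace in sorted(series.traces.items()):
            row: dict = {"plant_id": series.plant.plant_id, "test_label": lab,
                         "failed": False, "fallback": False}
            for m in METHODS:
                try:
                    est = extract_slope(trace, m, fallback_to_full=False, seed=seed,
                                        min_run=min_run, min_span_m=min_span_m)
                    row[f"slope_{m}"] = est.slope_N_per_m
                except (NoCycleError, DegenerateFitError):
                    row[f"slope_{m}"] = np.nan
            try:
                est = extract_slope(trace, method, fallback_to_full=fallback_to_full,
                                    seed=seed, min_run=min_run, min_span_m=min_span_m)
                row["slope"] = est.slope_N_per_m
                row["r_squared"] = est.r_squared
                row["fallback"] = est.fallback
            except BraceMechError:
                row["slope"] = np.nan
                row["r_squared"] = np.nan
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def contributions_from_slopes(
    slopes: pd.DataFrame,
    plants: list[PlantRecord] | None = None,
    direction: str = "divide",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-plant contribution table from a slopes table.

    Plants whose labels are not contiguous, or whose slopes are missing
    or non-positive where the ratios need them, are reported in the
    returned problem map instead of silently disappearing. The
    beam-length correction runs only for plants with a recorded
    attachment height.
    """
    plant_map = {p.plant_id: p for p in plants} if plants else {}
    results, problems = [], {}
    for pid, grp in slopes.groupby("plant_id", sort=True):
        usable = grp[~grp["failed"]] if "failed" in grp else grp
        series = dict(zip(usable["test_label"], usable["slope"]))
        if any(not np.isfinite(v) for v in series.values()):
            problems[pid] = "missing slope estimate"
            continue
        rec = plant_map.get(pid)
        geometry = None
        if rec is not None and rec.attachment_height_m is not None:
            geometry = BeamGeometry(0.64, rec.attachment_height_m)
        try:
            results.append(contribution_result(pid, series, geometry, direction))
        except BraceMechError as exc:
            problems[pid] = str(exc)
    return contribution_table(results, plants), problems


def stats_report(
    contributions: pd.DataFrame,
    repeat_slopes: pd.DataFrame | None = None,
    line_means: pd.DataFrame | None = None,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> dict:
    """Standard statistics block over a contribution table.

    Includes the removal ANOVA analogue (per-whorl ratio comparison with
    Tukey HSD), the contribution-vs-whorl-count correlation, the
    whorl1-vs-overall correlation, and — when a repeat-test slope table
    is supplied — repeatability.
    """
    report: dict = {}
    whorl_cols = [c for c in contributions.columns if c.startswith("whorl")
                  and c != "whorls_in_soil"]
    groups = {c: contributions[c].dropna().to_numpy() for c in whorl_cols}
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) >= 2:
        f, p = bstats.one_way_anova(groups)
        report["whorl_anova"] = {"F": f, "p": p}
        report["whorl_tukey"] = bstats.tukey_hsd(groups)
        report["whorl_means"] = {k: float(v.mean()) for k, v in groups.items()}
    ok = contributions.dropna(subset=["ratio"])
    if ok["whorls_in_soil"].nunique() > 1 and len(ok) >= 3:
        r, p = bstats.pearson(ok["ratio"], ok["whorls_in_soil"])
        report["ratio_vs_whorls"] = {"r": r, "p": p}
    if "whorl1" in contributions:
        both = contributions.dropna(subset=["ratio", "whorl1"])
        if len(both) >= 3 and both["whorl1"].nunique() > 1:
            r, p = bstats.pearson(both["whorl1"], both["ratio"])
            report["whorl1_vs_ratio"] = {"r": r, "p": p}
    if repeat_slopes is not None:
        rep = bstats.repeatability(
            repeat_slopes["slope"], repeat_slopes["plant_id"], seed=seed
        )
        report["repeatability"] = rep
    if line_means is not None:
        report["line_regression"] = bstats.two_predictor_regression(
            line_means["fd_slope"], line_means["dts"], line_means["ph"]
        )
    report["alpha"] = alpha
    report["seed"] = seed
    return report
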