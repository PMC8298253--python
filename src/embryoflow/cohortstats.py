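"""Cohort assembly and hypothesis testing.

The testing protocol mirrors the source study: Shapiro-Wilk normality
check on each sample, then a one-tailed two-sample t-test in a stated
direction (equal-variance by default, Welch by configuration). No
multiple-testing correction is applied; the report footer states this.
"""
from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(RuntimeError):
    pass


REQUIRED_COLUMNS = ("embryo_id", "group", "stage", "structure",
                    "metric", "value")
GROUPS = ("control", "LAL")


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 50.

    Identical values are degenerate for the test (zero variance) and
    raise, per the documented convention.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 50:
        raise StatsError(
            f"Shapiro-Wilk supported for 3 <= n <= 50 (got {len(x)})")
    if np.ptp(x) == 0:
        raise StatsError("all values identical; W undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def ttest_one_tailed(a: Sequence[float], b: Sequence[float],
                     direction: str = "a>b",
                     equal_var: bool = True) -> Tuple[float, float]:
    """Two-sample t-test with a one-tailed p in the stated direction.

    ``direction`` is ``"a>b"`` or ``"a<b"``. Equal-variance (pooled)
    by default; ``equal_var=False`` selects the Welch variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise StatsError("zero variance in both samples")
    if direction not in ("a>b", "a<b"):
        raise StatsError("direction must be 'a>b' or 'a<b'")
    alt = "greater" if direction == "a>b" else "less"
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alt)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CohortTable:
    """Per-embryo metric rows feeding the statistics stage."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS
                   if c not in self.frame.columns]
        if missing:
            raise StatsError(f"table missing columns {missing}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise StatsError(f"unknown groups {sorted(bad)}")
        dup = self.frame.duplicated(
            subset=["embryo_id", "group", "stage", "structure", "metric"])
        if dup.any():
            raise StatsError("duplicate (embryo, metric) rows")

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "CohortTable":
        return cls(pd.DataFrame(list(rows)))

    @classmethod
    def from_csv(cls, text_or_path) -> "CohortTable":
        return cls(pd.read_csv(text_or_path))

    def to_csv(self) -> str:
        return self.frame.to_csv(index=False)


def build_report(table: CohortTable,
                 directions: Optional[Dict[str, str]] = None,
                 equal_var: bool = True,
                 alpha: Tuple[float, float] = (0.05, 0.01)) -> dict:
    """Per (stage, structure, metric) group comparison tables.

    ``directions`` maps metric name to the tested direction for the
    control-vs-LAL comparison (``"control>LAL"`` or ``"control<LAL"``);
    metrics without an entry are tested two ways and the smaller-p
    direction reported, flagged ``direction_assumed``. A pure function
    of its inputs: identical tables yield byte-identical JSON.
    """
    df = table.frame.sort_values(
        ["stage", "structure", "metric", "group", "embryo_id"])
    rows: List[dict] = []
    for (stage, structure, metric), sub in df.groupby(
            ["stage", "structure", "metric"], sort=True):
        entry: dict = {"stage": stage, "structure": structure,
                       "metric": metric}
        samples = {}
        for g in GROUPS:
            vals = sub.loc[sub["group"] == g, "value"].to_numpy(float)
            if len(vals):
                entry[g] = {"n": int(len(vals)),
                            "mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=1))
                            if len(vals) > 1 else 0.0}
                samples[g] = vals
        if set(samples) != set(GROUPS):
            warnings.warn(
                f"metric {metric!r} at {stage}/{structure} missing a "
                "group; test skipped")
            rows.append(entry)
            continue
        a, b = samples["control"], samples["LAL"]
        for g, vals in samples.items():
            try:
                w, p = shapiro_wilk(vals)
                entry[g]["shapiro_w"] = w
                entry[g]["shapiro_p"] = p
                entry[g]["normal"] = bool(p > 0.05)
            except StatsError as exc:
                entry[g]["shapiro_note"] = str(exc)
        direction = (directions or {}).get(metric)
        assumed = direction is None
        if assumed:
            cand = {}
            for d in ("control>LAL", "control<LAL"):
                dd = "a>b" if d == "control>LAL" else "a<b"
                cand[d] = ttest_one_tailed(a, b, dd, equal_var=equal_var)
            direction = min(cand, key=lambda d: cand[d][1])
            t, p = cand[direction]
        else:
            dd = "a>b" if direction == "control>LAL" else "a<b"
            t, p = ttest_one_tailed(a, b, dd, equal_var=equal_var)
        entry["test"] = {
            "direction": direction, "t": t, "p_one_tailed": p,
            "equal_var": equal_var, "direction_assumed": assumed,
            "stars": ("**" if p < alpha[1] else
                      "*" if p < alpha[0] else ""),
        }
        rows.append(entry)
    return {
        "rows": rows,
        "footer": ("One-tailed two-sample t-tests "
                   f"({'pooled' if equal_var else 'Welch'} variance); "
                   "Shapiro-Wilk normality checked per sample; no "
                   "multiple-testing correction applied."),
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: dict) -> str:
    """Plain-text comparison table (one row per metric)."""
    buf = io.StringIO()
    hdr = (f"{'stage':6} {'structure':10} {'metric':24} "
           f"{'control':>18} {'LAL':>18} {'p':>9} sig")
    buf.write(hdr + "\n" + "-" * len(hdr) + "\n")
    for r in report["rows"]:
        def ms(g):
            if g not in r:
                return "-"
            return f"{r[g]['mean']:.3g} ± {r[g]['sd']:.3g}"
        t = r.get("test", {})
        buf.write(f"{r['stage']:6} {r['structure']:10} {r['metric']:24} "
                  f"{ms('control'):>18} {ms('LAL'):>18} "
                  f"{t.get('p_one_tailed', float('nan')):>9.4f} "
                  f"{t.get('stars', ''):3}\n")
    buf.write(report["footer"] + "\n")
    return buf.getvalue()
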