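"""Biological-validation statistics and printed-table fixtures.

Carries the in-repo fixtures of the study's printed validation tables
(autophagy activity, metabolite concentrations, flux/mitochondrial
readouts, and the post-exercise time course) and the statistics applied
to them: paired t-tests, one-way ANOVA, and the percent-change /
fold-ratio arithmetic on printed group means.

The printed t/ANOVA outputs themselves require per-sample data that is
not available, so ``run_validation_report`` recomputes them only when
per-sample (synthetic) data is supplied and otherwise flags them as not
recomputable from printed means alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import OmicsDataset

TABLE_FILES = {
    "T3": "table3_autophagy_activity.tsv",
    "T4": "table4_metabolite_concentrations.tsv",
    "T7": "table7_flux_mito_function.tsv",
    "T8": "table8_time_course.tsv",
}

_TINY = float(np.finfo(np.float64).tiny)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class PrintedTableFixture:
    table_id: str
    values: pd.DataFrame
    units: pd.Series


def load_table(table_id: str) -> PrintedTableFixture:
    """Load one printed-table fixture shipped with the package."""
    if table_id not in TABLE_FILES:
        raise StatsError(f"unknown table id {table_id!r}; have {list(TABLE_FILES)}")
    ref = resources.files("cardiovae") / "tables" / TABLE_FILES[table_id]
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    units = raw.iloc[0].drop(raw.columns[0])
    body = raw.iloc[1:].reset_index(drop=True)
    for c in body.columns:
        try:
            body[c] = pd.to_numeric(body[c])
        except (ValueError, TypeError):
            pass
    return PrintedTableFixture(table_id=table_id, values=body, units=units)


def load_all_tables() -> dict[str, PrintedTableFixture]:
    return {tid: load_table(tid) for tid in TABLE_FILES}


# ---------------------------------------------------------------------------
# tests


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple[str, ...] = ()
    flag: str | None = None


def paired_t_test(
    a: Sequence[float], b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Two-sided paired t-test on the differences d = a - b.

    t = mean(d) / (sd(d)/sqrt(n)) with sd using the n-1 denominator;
    p from Student's t with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise StatsError("paired vectors must have equal length")
    n = a.size
    if n < 2:
        raise StatsError("paired t-test requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult("paired t-test", 0.0, (n - 1,), 1.0, labels)
        return TestResult(
            "paired t-test", float(np.sign(d.mean()) * np.inf), (n - 1,),
            _TINY, labels, flag="zero-variance nonzero differences",
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult("paired t-test", float(t), (n - 1,), max(p, _TINY), labels)


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> TestResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise StatsError("ANOVA requires at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise StatsError("every group needs at least 2 observations")
    if labels is None:
        labels = tuple(f"g{i + 1}" for i in range(len(arrs)))
    ns = np.array([a.size for a in arrs])
    n_total = int(ns.sum())
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("one-way ANOVA", 0.0, (df_b, df_w), 1.0,
                              tuple(labels), flag="degenerate: no variance at all")
        return TestResult("one-way ANOVA", float(np.inf), (df_b, df_w), _TINY,
                          tuple(labels), flag="zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult("one-way ANOVA", float(f), (df_b, df_w),
                      max(p, _TINY), tuple(labels))


# ---------------------------------------------------------------------------
# arithmetic on printed means


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference."""
    if reference == 0:
        raise StatsError("percent change undefined for reference = 0")
    return 100.0 * (value - reference) / reference


def fold_ratio(value: float, reference: float) -> float:
    """value / reference."""
    if reference == 0:
        raise StatsError("fold ratio undefined for reference = 0")
    return value / reference


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class ValidationReport:
    changes: pd.DataFrame
    anova: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Validation report", "=" * 17, ""]
        if self.changes.empty:
            lines.append("(no printed-mean comparisons)")
        else:
            lines.append(self.changes.to_string(index=False,
                                                float_format="%.4g"))
        if self.anova is not None and not self.anova.empty:
            lines += ["", "One-way ANOVA on per-sample data:",
                      self.anova.to_string(index=False, float_format="%.4g")]
        lines += [""] + [f"note: {n}" for n in self.notes]
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.changes.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
        path.with_suffix(".txt").write_text(self.to_text())


def _table8_changes(fix: PrintedTableFixture) -> list[dict]:
    rows = []
    v = fix.values
    measures = [c[: -len("_mean")] for c in v.columns if c.endswith("_mean")]
    for t in sorted(v["time_h"].unique()):
        at_t = v[v["time_h"] == t].set_index("group")
        if not {"A", "D"}.issubset(at_t.index):
            continue
        for m in measures:
            ref = float(at_t.loc["A", f"{m}_mean"])
            val = float(at_t.loc["D", f"{m}_mean"])
            rows.append({
                "table": "T8", "time_h": t, "measure": m,
                "group": "D", "reference": "A",
                "value": val, "reference_value": ref,
                "percent_change": percent_change(ref, val),
                "fold_ratio": fold_ratio(val, ref),
            })
    return rows


def _group_table_changes(fix: PrintedTableFixture) -> list[dict]:
    rows = []
    v = fix.values.set_index("group")
    if "A" not in v.index:
        return rows
    for m in v.columns:
        ref = float(v.loc["A", m])
        for g in v.index:
            if g == "A" or ref == 0:
                continue
            val = float(v.loc[g, m])
            rows.append({
                "table": fix.table_id, "time_h": np.nan, "measure": m,
                "group": g, "reference": "A",
                "value": val, "reference_value": ref,
                "percent_change": percent_change(ref, val),
                "fold_ratio": fold_ratio(val, ref),
            })
    return rows


def run_validation_report(
    fixtures: dict[str, PrintedTableFixture] | None = None,
    dataset: OmicsDataset | None = None,
) -> ValidationReport:
    """All percent-change / fold computations derivable from printed group
    means, plus one-way ANOVA per feature when per-sample data exists.

    Passing ``fixtures={}`` yields an empty report; passing a synthetic
    ``OmicsDataset`` adds recomputed ANOVA F and p per feature.
    """
    if fixtures is None:
        fixtures = load_all_tables()
    rows: list[dict] = []
    notes: list[str] = []
    for tid, fix in fixtures.items():
        if tid == "T8":
            rows.extend(_table8_changes(fix))
        elif "group" in fix.values.columns:
            rows.extend(_group_table_changes(fix))
        else:
            raise StatsError(f"malformed fixture {tid}: no 'group' column")
    if fixtures:
        notes.append(
            "printed paired-t / ANOVA outputs require per-sample data and are "
            "not recomputable from printed means alone"
        )

    anova_df = None
    if dataset is not None:
        arecs = []
        for name in list(dataset.x.columns) + list(dataset.y.columns):
            mat = dataset.x if name in dataset.x.columns else dataset.y
            vecs, labs = [], []
            for g in sorted(set(dataset.group)):
                vecs.append(mat.loc[dataset.group == g, name].to_numpy())
                labs.append(g)
            res = one_way_anova(vecs, labs)
            arecs.append({
                "feature": name, "F": res.statistic,
                "df_between": res.df[0], "df_within": res.df[1],
                "p_value": res.p_value,
            })
        anova_df = pd.DataFrame(arecs)
        notes.append(
            f"{len(arecs)} ANOVA tests performed on per-sample data; "
            "no multiple-testing correction applied"
        )

    cols = ["table", "time_h", "measure", "group", "reference",
            "value", "reference_value", "percent_change", "fold_ratio"]
    changes = pd.DataFrame(rows, columns=cols)
    return ValidationReport(changes=changes, anova=anova_df, notes=notes)
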