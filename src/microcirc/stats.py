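"""Paired statistics for per-subject FCD tables.

Study designs in this area measure the same subjects at a healthy
baseline and again under an intervention (here: controlled hemorrhage),
so the natural analysis is a paired t-test on the per-subject FCD
differences, plus Bland-Altman agreement when two instruments measure
the same quantity.

The package ships two small per-subject tables from a nine-swine
sublingual SDF study as packaged CSV fixtures: one produced by the
fully automated analyzer re-implemented here, one by a semi-automated
commercial tool with manual editing, each with area-based FCD (%) and
length-based FCD (mm/mm^2) at baseline and during hemorrhage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateTestError, ParameterError, ShapeError

#: packaged per-subject FCD tables (nine swine, baseline vs hemorrhage)
AUTOMATED_TABLE = "fcd_automated.csv"
SEMIAUTOMATED_TABLE = "fcd_semiautomated.csv"


@dataclass
class PairedMeasurements:
    subject_ids: list
    baseline: np.ndarray
    condition: np.ndarray

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype=np.float64)
        if len(self.subject_ids) != len(self.baseline) or \
                len(self.baseline) != len(self.condition):
            raise ShapeError("subject/baseline/condition lengths differ")
        if len(self.baseline) < 2:
            raise ParameterError("need at least 2 paired measurements")

    @property
    def n(self) -> int:
        return len(self.baseline)


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    mean_diff: float
    sd_diff: float


def summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ParameterError("summary needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1))


def paired_t(pm: PairedMeasurements) -> TTestResult:
    """Two-sided paired t-test on baseline - condition differences."""
    d = pm.baseline - pm.condition
    mean_d, sd_d = summary(d)
    if sd_d == 0:
        raise DegenerateTestError("paired differences have zero variance")
    n = pm.n
    t = mean_d / (sd_d / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p_two_sided=p,
                       mean_diff=mean_d, sd_diff=sd_d)


def bland_altman(a, b):
    """Bland-Altman agreement of two measurement series.

    Returns ``(bias, lower_loa, upper_loa, points)`` where points is an
    (n, 2) array of per-pair ((a+b)/2, a-b) for plotting.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ShapeError("bland_altman needs two equal-length vectors (n >= 2)")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lower = bias - 1.96 * sd
    upper = bias + 1.96 * sd
    points = np.column_stack([(a + b) / 2.0, diff])
    return bias, lower, upper, points


def load_table(which_or_path) -> pd.DataFrame:
    """Load a per-subject FCD table.

    ``which_or_path`` is one of the packaged table names
    (:data:`AUTOMATED_TABLE`, :data:`SEMIAUTOMATED_TABLE`) or a CSV
    path with the same columns: subject, baseline_area, baseline_length,
    hemorrhage_area, hemorrhage_length.
    """
    name = str(which_or_path)
    if name in (AUTOMATED_TABLE, SEMIAUTOMATED_TABLE):
        with (resources.files("microcirc") / "data" / name).open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(name)


def paired_from_table(table: pd.DataFrame, measure: str = "area"
                      ) -> PairedMeasurements:
    """Extract the baseline/hemorrhage pairs for one FCD measure."""
    if measure not in ("area", "length"):
        raise ParameterError("measure must be 'area' or 'length'")
    return PairedMeasurements(
        subject_ids=list(table["subject"]),
        baseline=table[f"baseline_{measure}"].to_numpy(),
        condition=table[f"hemorrhage_{measure}"].to_numpy(),
    )


def analyze_table(which_or_path, measure: str = "area") -> dict:
    """Summaries + paired t-test of one table, as a flat dict."""
    pm = paired_from_table(load_table(which_or_path), measure)
    mb, sb = summary(pm.baseline)
    mc, sc = summary(pm.condition)
    tt = paired_t(pm)
    return {
        "mean_baseline": mb, "sd_baseline": sb,
        "mean_condition": mc, "sd_condition": sc,
        "mean_diff": tt.mean_diff, "t": tt.t, "df": tt.df, "p": tt.p_two_sided,
    }
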