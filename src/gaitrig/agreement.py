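"""Agreement statistics between two gait-measurement systems.

Implements the paired-comparison summary used to validate a markerless
system against an optical reference: Pearson correlation, the
Bland–Altman quantities (bias = mean difference, reproducibility
coefficient RPC = 1.96·SD of the differences, coefficient of variation
CV = SD of the differences as a percentage of the grand mean), and the
intraclass correlation for absolute agreement with single measures,
ICC(A,1), from the two-way ANOVA decomposition (McGraw & Wong):

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k/n·(MS_C − MS_E))

with rows = steps or subjects, columns = the k = 2 systems.  ICC values
are labelled poor / fair / good / excellent.

Comparisons run at three levels of detail: single steps per side,
per-subject averages per side, and per-subject averages pooled over
sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements", "AgreementStats",
    "pair_steps", "bland_altman", "icc_a1", "classify_icc", "pearson",
    "agreement_stats", "agreement_table", "bland_altman_plot_data",
]

ICC_CATEGORIES = (          # half-open intervals covering [0, 1]
    (0.40, "poor"), (0.60, "fair"), (0.75, "good"), (np.inf, "excellent"))


@dataclass
class PairedMeasurements:
    """Matched (system A, system B) values for one parameter at one level."""

    parameter: str
    units: str
    level: str                      # single | subject_avg_side | subject_avg_pooled
    values_a: np.ndarray
    values_b: np.ndarray
    keys: list = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, float)
        self.values_b = np.asarray(self.values_b, float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired value arrays must be 1-D and equal length")
        if np.isnan(self.values_a).any() or np.isnan(self.values_b).any():
            raise ValueError("pairs must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass
class AgreementStats:
    parameter: str
    units: str
    level: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    pearson_r: float
    pearson_p: float
    bias: float
    sd_diff: float
    rpc: float
    cv_percent: float
    icc_a1: float
    icc_category: str
    flags: list = field(default_factory=list)


def pair_steps(params_a: pd.DataFrame, params_b: pd.DataFrame,
               parameter: str, units: str = "cm", level: str = "single",
               foot: str | None = None,
               max_time_offset: float = 0.2) -> PairedMeasurements:
    """Pair per-step values of one parameter across two systems.

    Both inputs use the long gait-parameter schema (columns
    ``recording_id, foot, parameter, value, time``).  Within each shared
    recording (and foot, if given) the steps are paired by chronological
    rank when the counts match; otherwise by greedy nearest-event-time
    matching within ``max_time_offset`` seconds, dropping (and counting)
    the unmatched ones.
    """
    sel_a = params_a[params_a["parameter"] == parameter]
    sel_b = params_b[params_b["parameter"] == parameter]
    if foot is not None:
        sel_a = sel_a[sel_a["foot"] == foot]
        sel_b = sel_b[sel_b["foot"] == foot]
    shared = sorted(set(sel_a["recording_id"]) & set(sel_b["recording_id"]),
                    key=str)
    if not shared:
        raise ValueError("systems share no recordings")
    va, vb, keys, dropped = [], [], [], 0
    for rec in shared:
        a = sel_a[sel_a["recording_id"] == rec].sort_values("time")
        b = sel_b[sel_b["recording_id"] == rec].sort_values("time")
        if len(a) == len(b):
            va += list(a["value"])
            vb += list(b["value"])
            keys += [(rec, f) for f in a["foot"]]
        else:
            ta, tb = a["time"].to_numpy(), b["time"].to_numpy()
            used_b: set[int] = set()
            for i, t in enumerate(ta):
                cand = [(abs(t - tb[j]), j) for j in range(len(tb))
                        if j not in used_b and abs(t - tb[j]) <= max_time_offset]
                if not cand:
                    dropped += 1
                    continue
                _, j = min(cand)
                used_b.add(j)
                va.append(a["value"].iloc[i])
                vb.append(b["value"].iloc[j])
                keys.append((rec, a["foot"].iloc[i]))
            dropped += len(tb) - len(used_b)
    return PairedMeasurements(parameter, units, level, np.array(va),
                              np.array(vb), keys, n_dropped=dropped)


def bland_altman(pairs: PairedMeasurements) -> dict:
    """Bias, reproducibility coefficient and coefficient of variation.

    ``d_i = A_i − B_i``; bias = mean(d); RPC = 1.96·sd(d) with the n−1
    sample SD; CV = sd(d) divided by the grand mean of the pairwise means
    ``(A_i + B_i)/2``, in percent.  A grand mean of zero leaves the CV
    undefined (flagged NaN).
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.values_a - pairs.values_b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    grand = float(np.mean((pairs.values_a + pairs.values_b) / 2.0))
    if np.isclose(grand, 0.0):
        cv = float("nan")
    else:
        cv = sd / grand * 100.0
    return {"bias": bias, "sd_diff": sd, "rpc": 1.96 * sd, "cv_percent": cv}


def icc_a1(pairs: PairedMeasurements) -> float:
    """ICC(A,1): two-way, absolute agreement, single measures, k = 2.

    Rows are the paired units (steps or subjects), columns the systems.
    Zero total variance leaves the coefficient undefined (NaN).
    """
    y = np.column_stack([pairs.values_a, pairs.values_b])
    n, k = y.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 rows")
    grand = y.mean()
    if np.isclose(((y - grand) ** 2).sum(), 0.0):
        return float("nan")
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
    if np.isclose(denom, 0.0):
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def classify_icc(value: float) -> str:
    """Absolute-agreement label: [0,0.4) poor, [0.4,0.6) fair,
    [0.6,0.75) good, [0.75,1] excellent; negatives report as poor."""
    if np.isnan(value):
        return "undefined"
    if value > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if value < 0.0:
        return "poor (negative)"
    for upper, label in ICC_CATEGORIES:
        if value < upper:
            return label
    return "excellent"


def pearson(pairs: PairedMeasurements) -> dict:
    """Sample correlation with the two-sided t-test p-value (n−2 df)."""
    if pairs.n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.isclose(np.var(pairs.values_a), 0.0) or np.isclose(
            np.var(pairs.values_b), 0.0):
        raise ValueError("zero variance in one system")
    r, p = stats.pearsonr(pairs.values_a, pairs.values_b)
    return {"r": float(r), "p": float(p)}


def agreement_stats(pairs: PairedMeasurements) -> AgreementStats:
    ba = bland_altman(pairs)
    flags = []
    if np.isnan(ba["cv_percent"]):
        flags.append("cv undefined (zero grand mean)")
    try:
        pe = pearson(pairs)
    except ValueError as err:
        pe = {"r": float("nan"), "p": float("nan")}
        flags.append(f"pearson: {err}")
    icc = icc_a1(pairs)
    if np.isnan(icc):
        flags.append("icc undefined (zero variance)")
    if icc < 0:
        flags.append("negative icc reported as poor")
    return AgreementStats(
        parameter=pairs.parameter, units=pairs.units, level=pairs.level,
        n=pairs.n,
        mean_a=float(np.mean(pairs.values_a)),
        sd_a=float(np.std(pairs.values_a, ddof=1)),
        mean_b=float(np.mean(pairs.values_b)),
        sd_b=float(np.std(pairs.values_b, ddof=1)),
        pearson_r=pe["r"], pearson_p=pe["p"],
        bias=ba["bias"], sd_diff=ba["sd_diff"], rpc=ba["rpc"],
        cv_percent=ba["cv_percent"],
        icc_a1=icc, icc_category=classify_icc(icc), flags=flags)


# ---------------------------------------------------------------------------
# Table assembly

_SPATIAL = ("stride_length", "step_length", "step_width")
_LABELS = {"stride_length": "stride length", "step_length": "step length",
           "step_width": "step width", "step_time": "step time",
           "walking_speed": "Walking Speed"}
_UNITS = {"stride_length": "cm", "step_length": "cm", "step_width": "cm",
          "step_time": "s", "walking_speed": "cm/s"}


def _subject_of(recording_id) -> str:
    """Recording ids are '<subject>/<trial>' or plain subject labels."""
    s = str(recording_id)
    return s.split("/", 1)[0]


def _subject_means(table: pd.DataFrame, parameter: str,
                   foot: str | None) -> pd.Series:
    sel = table[table["parameter"] == parameter]
    if foot is not None:
        sel = sel[sel["foot"] == foot]
    subj = sel["recording_id"].map(_subject_of)
    return sel.groupby(subj)["value"].mean()


def _paired_subject_means(ta: pd.DataFrame, tb: pd.DataFrame, parameter: str,
                          foot: str | None, level: str) -> PairedMeasurements:
    ma = _subject_means(ta, parameter, foot)
    mb = _subject_means(tb, parameter, foot)
    shared = sorted(set(ma.index) & set(mb.index))
    if not shared:
        raise ValueError("no shared subjects")
    return PairedMeasurements(parameter, _UNITS[parameter], level,
                              ma[shared].to_numpy(), mb[shared].to_numpy(),
                              keys=shared)


def agreement_table(params_a: pd.DataFrame, params_b: pd.DataFrame,
                    include_temporal: bool = True,
                    max_time_offset: float = 0.2) -> pd.DataFrame:
    """Full agreement table across parameters, sides and detail levels.

    Row layout follows the validation-study convention: single
    steps/strides per side, per-subject averages per side ("AV ... L/R"),
    and per-subject averages pooled over sides ("AV ... AVG"); walking
    speed only at the pooled-average level.
    """
    rows = []
    spatial = _SPATIAL + (("step_time",) if include_temporal else ())
    if include_temporal:
        speed = _paired_subject_means(params_a, params_b, "walking_speed",
                                      None, "subject_avg_pooled")
        rows.append(("AV Walking Speed (cm/s)", agreement_stats(speed)))
    for parameter in spatial:
        label = _LABELS[parameter]
        unit = _UNITS[parameter]
        for foot in ("L", "R"):
            pairs = pair_steps(params_a, params_b, parameter, unit, "single",
                               foot=foot, max_time_offset=max_time_offset)
            rows.append((f"{label} {foot} ({unit})", agreement_stats(pairs)))
        for foot in ("L", "R"):
            pairs = _paired_subject_means(params_a, params_b, parameter,
                                          foot, "subject_avg_side")
            rows.append((f"AV {label} {foot} ({unit})", agreement_stats(pairs)))
        pairs = _paired_subject_means(params_a, params_b, parameter, None,
                                      "subject_avg_pooled")
        rows.append((f"AV {label} AVG ({unit})", agreement_stats(pairs)))

    out = pd.DataFrame([{
        "row": name, "parameter": st.parameter, "level": st.level,
        "mean_a": st.mean_a, "sd_a": st.sd_a,
        "mean_b": st.mean_b, "sd_b": st.sd_b,
        "r": st.pearson_r, "p": st.pearson_p, "n": st.n,
        "bias": st.bias, "rpc": st.rpc, "cv_percent": st.cv_percent,
        "icc_a1": st.icc_a1, "icc_category": st.icc_category,
        "flags": "; ".join(st.flags),
    } for name, st in rows])
    return out


def render_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering in the published column order."""
    hdr = (f"{'Parameter':34s} {'A Mean±SD':>16s} {'B Mean±SD':>16s} "
           f"{'R':>6s} {'P':>7s} {'N':>5s} {'Bias':>7s} {'RPC':>7s} "
           f"{'CV(%)':>7s} {'ICC(A,1)':>9s}  Category")
    lines = [hdr, "-" * len(hdr)]
    for _, r in table.iterrows():
        p = "<0.001" if r["p"] < 0.001 else f"{r['p']:.3f}"
        lines.append(
            f"{r['row']:34s} {r['mean_a']:8.2f} ±{r['sd_a']:5.2f} "
            f"{r['mean_b']:8.2f} ±{r['sd_b']:5.2f} {r['r']:6.3f} {p:>7s} "
            f"{r['n']:5d} {r['bias']:7.2f} {r['rpc']:7.2f} "
            f"{r['cv_percent']:7.2f} {r['icc_a1']:9.3f}  {r['icc_category']}")
    return "\n".join(lines)


def load_parameter_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a gait-parameter CSV, optionally renaming foreign columns.

    ``column_map`` maps the file's column names onto the canonical schema
    (``recording_id, system, sides_used, foot, parameter, value, time``), so
    externally deposited parameter tables can be ingested without editing.
    Missing optional columns (``system, sides_used, time``) are filled with
    placeholders; the required ones must be present after mapping.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"recording_id", "foot", "parameter", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns: {sorted(missing)}")
    for col, default in (("system", "unknown"), ("sides_used", "n/a"),
                         ("time", np.nan)):
        if col not in df.columns:
            df[col] = default
    return df[["recording_id", "system", "sides_used", "foot", "parameter",
               "value", "time"]]


def bland_altman_plot_data(pairs: PairedMeasurements) -> pd.DataFrame:
    """Mean-vs-difference pairs with the bias and ±RPC limit lines."""
    ba = bland_altman(pairs)
    return pd.DataFrame({
        "mean": (pairs.values_a + pairs.values_b) / 2.0,
        "difference": pairs.values_a - pairs.values_b,
        "bias": ba["bias"],
        "upper_limit": ba["bias"] + ba["rpc"],
        "lower_limit": ba["bias"] - ba["rpc"],
    })
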