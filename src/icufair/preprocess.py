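"""ICU event-table preprocessing: cohort selection, cleaning, filtering,
hourly aggregation, imputation and tabular summarization.

The pipeline turns a long-format event table (stay, feature, time, value) into

* an hourly tensor of shape ``(N, T, F)`` — one row per ICU stay, T hourly
  bins anchored at the first record within 6 h before admission, F features
  partitioned into temporal / demographic / admission / comorbidity blocks —
  and
* a tabular summary of shape ``(N, F')`` replacing each temporal series by its
  min/max/mean (plus a sum for features flagged for it) while static features
  pass through once.

With the default feature layout (122 temporal, 5 demographic, 4 admission,
33 comorbidity, one sum-flagged temporal feature) F = 164 and F' = 409.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecError",
    "FeatureDef",
    "FeatureSpec",
    "StayRecord",
    "FeatureMatrix",
    "TabularSummary",
    "default_spec",
    "select_cohort",
    "clean_events",
    "filter_stays",
    "build_matrix",
    "train_feature_means",
    "impute",
    "summarize_tabular",
]

BLOCKS = ("temporal", "demographic", "admission", "comorbidity")
_RANGE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)\s*$")


class SpecError(ValueError):
    """Raised when events refer to features the spec does not cover, or vice versa."""


@dataclass(frozen=True)
class FeatureDef:
    id: str
    block: str
    name: str = ""
    kind: str = "numeric"  # numeric | categorical
    unit_factors: Mapping[str, float] = field(default_factory=dict)
    summaries: tuple[str, ...] = ("min", "max", "mean")  # temporal features only

    def __post_init__(self):
        if self.block not in BLOCKS:
            raise SpecError(f"feature {self.id!r}: unknown block {self.block!r}")
        if self.kind not in ("numeric", "categorical"):
            raise SpecError(f"feature {self.id!r}: unknown kind {self.kind!r}")


class FeatureSpec:
    """Ordered feature dictionary; order defines the (N, T, F) column layout."""

    def __init__(self, features: Sequence[FeatureDef]):
        self.features = list(features)
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise SpecError("duplicate feature ids in spec")
        self._index = {f.id: i for i, f in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, fid: str) -> bool:
        return fid in self._index

    def __getitem__(self, fid: str) -> FeatureDef:
        return self.features[self._index[fid]]

    def column(self, fid: str) -> int:
        return self._index[fid]

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    def block_ids(self, block: str) -> list[str]:
        return [f.id for f in self.features if f.block == block]

    @property
    def temporal_ids(self) -> list[str]:
        return self.block_ids("temporal")

    @property
    def static_ids(self) -> list[str]:
        return [f.id for f in self.features if f.block != "temporal"]


def default_spec(
    counts: Mapping[str, int] | None = None,
    sum_features: Iterable[str] = ("temp_000",),
) -> FeatureSpec:
    """A cohort-shaped default spec matching the synthetic generator's naming.

    122/5/4/33 features by default; ``sum_features`` temporal ids additionally
    get a 'sum' summary column (one by default, giving F' = 409).
    """
    counts = dict(counts or {"temporal": 122, "demographic": 5, "admission": 4, "comorbidity": 33})
    sum_set = set(sum_features)
    feats: list[FeatureDef] = []
    for i in range(counts.get("temporal", 0)):
        fid = f"temp_{i:03d}"
        summ = ("min", "max", "mean", "sum") if fid in sum_set else ("min", "max", "mean")
        feats.append(FeatureDef(fid, "temporal", summaries=summ))
    demo_names = ("age", "ethnicity", "gender", "marital_status", "insurance")
    n_demo = counts.get("demographic", 0)
    for i in range(n_demo):
        fid = demo_names[i] if i < len(demo_names) else f"demo_extra_{i - len(demo_names)}"
        feats.append(FeatureDef(fid, "demographic"))
    for i in range(counts.get("admission", 0)):
        feats.append(FeatureDef(f"adm_{i}", "admission"))
    for i in range(counts.get("comorbidity", 0)):
        feats.append(FeatureDef(f"com_{i:02d}", "comorbidity"))
    return FeatureSpec(feats)


@dataclass
class StayRecord:
    stay_id: str
    patient_id: str
    age_at_admission: float
    stay_order: int
    icu_duration: float
    admission_time: float = 0.0
    mortality_label: int = 0


@dataclass
class FeatureMatrix:
    """Hourly (N, T, F) array; NaN marks missing cells before imputation."""

    values: np.ndarray
    stay_ids: list[str]
    spec: FeatureSpec
    anchors: dict[str, float]
    encodings: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class TabularSummary:
    """(N, F') summary; ``columns`` holds (feature_id, summary_kind) per column."""

    values: np.ndarray
    stay_ids: list[str]
    columns: list[tuple[str, str]]

    def column_index(self, feature_id: str, kind: str) -> int:
        return self.columns.index((feature_id, kind))


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def select_cohort(
    stays: Sequence[StayRecord],
    min_age: float = 15.0,
    duration_bounds: tuple[float, float] = (12.0, 240.0),
) -> list[StayRecord]:
    """Keep first-known ICU stays of adults with plausible stay length.

    Rules: age at admission >= ``min_age`` years, ``stay_order == 1`` (the
    patient's first known ICU stay) and ICU duration within
    ``duration_bounds`` hours inclusive (12 h to 10 days by default).
    """
    lo, hi = duration_bounds
    if not lo < hi:
        raise ValueError("duration_bounds must satisfy low < high")
    return [
        s
        for s in stays
        if s.age_at_admission >= min_age and s.stay_order == 1 and lo <= s.icu_duration <= hi
    ]


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _parse_value(v) -> tuple[float | None, str | None]:
    """Return (numeric value, categorical token); range tokens -> midpoint."""
    if isinstance(v, (int, float, np.integer, np.floating)):
        x = float(v)
        return (x, None) if np.isfinite(x) else (None, None)
    s = str(v).strip()
    try:
        return float(s), None
    except ValueError:
        pass
    m = _RANGE_RE.match(s)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0, None
    return None, s


def clean_events(events: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Convert units, parse range tokens, and collapse duplicate keys.

    Duplicate (stay, feature, time) rows collapse to their mean for numeric
    features and to the first-appearing value for categorical ones.  Range
    tokens like ``"2-4"`` become their midpoint.  Unparsable values are
    dropped and counted in a ``UserWarning``.
    """
    unknown = set(events["feature_id"]) - set(spec.ids)
    if unknown:
        raise SpecError(f"events contain feature ids missing from the spec: {sorted(unknown)[:5]}")

    df = events.copy()
    numeric = np.empty(len(df), dtype=float)
    numeric.fill(np.nan)
    cat = np.full(len(df), None, dtype=object)
    bad = 0
    has_categorical = any(fdef.kind == "categorical" for fdef in spec.features)
    units = df["unit"].to_numpy(dtype=object) if "unit" in df.columns else None
    if pd.api.types.is_numeric_dtype(df["value"]) and not has_categorical and units is None:
        # fast path: plain numeric events, nothing to parse or convert
        vals = df["value"].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        numeric[finite] = vals[finite]
        bad = int((~finite).sum())
        return _collapse_clean(df, spec, numeric, cat, bad)
    values = df["value"].to_numpy(dtype=object)
    fids = df["feature_id"].to_numpy(dtype=object)
    for i, v in enumerate(values):
        num, tok = _parse_value(v)
        fdef = spec[fids[i]]
        if fdef.kind == "categorical":
            cat[i] = tok if tok is not None else (None if num is None else str(v))
            if cat[i] is None:
                bad += 1
            continue
        if num is None:
            bad += 1
            continue
        if units is not None and units[i] is not None and not (
            isinstance(units[i], float) and np.isnan(units[i])
        ):
            num *= fdef.unit_factors.get(str(units[i]), 1.0)
        numeric[i] = num
    return _collapse_clean(df, spec, numeric, cat, bad)


def _collapse_clean(
    df: pd.DataFrame, spec: FeatureSpec, numeric: np.ndarray, cat: np.ndarray, bad: int
) -> pd.DataFrame:
    if bad:
        import warnings

        warnings.warn(f"clean_events: dropped {bad} unparsable value(s)", stacklevel=2)

    df = df.assign(_num=numeric, _cat=cat)
    keep = ~(np.isnan(numeric) & pd.isna(cat))
    df = df.loc[keep]

    is_cat = df["feature_id"].map(lambda f: spec[f].kind == "categorical")
    keys = ["stay_id", "feature_id", "time_hours"]
    num_df = df.loc[~is_cat]
    if num_df.duplicated(subset=keys).any():
        num_part = num_df.groupby(keys, sort=False, as_index=False)["_num"].mean()
    else:  # nothing to collapse
        num_part = num_df[keys + ["_num"]].copy()
    num_part = num_part.rename(columns={"_num": "value"})
    cat_part = df.loc[is_cat].groupby(["stay_id", "feature_id", "time_hours"], sort=False, as_index=False)[
        "_cat"
    ].first()
    cat_part = cat_part.rename(columns={"_cat": "value"})
    parts = [p for p in (num_part, cat_part) if len(p)]
    if not parts:
        return pd.DataFrame(columns=["stay_id", "feature_id", "time_hours", "value"])
    out = pd.concat(parts, ignore_index=True) if len(parts) > 1 else parts[0]
    return out.sort_values(["stay_id", "feature_id", "time_hours"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# filtering and anchoring
# ---------------------------------------------------------------------------

def _anchors(events: pd.DataFrame, lookback: float) -> pd.Series:
    """Per-stay anchor: earliest event time at or after -lookback hours."""
    eligible = events.loc[events["time_hours"] >= -lookback]
    return eligible.groupby("stay_id")["time_hours"].min()


def filter_stays(
    events: pd.DataFrame,
    stays: Sequence[StayRecord],
    min_cov: float = 24.0,
    max_cov: float = 240.0,
    lookback: float = 6.0,
) -> list[StayRecord]:
    """Keep stays whose event span from the anchor covers [min_cov, max_cov] hours."""
    anchors = _anchors(events, lookback)
    last = events.loc[events["time_hours"] >= -lookback].groupby("stay_id")["time_hours"].max()
    kept = []
    for s in stays:
        if s.stay_id not in anchors.index:
            continue  # no events after anchoring; excluded
        span = last[s.stay_id] - anchors[s.stay_id]
        if min_cov <= span <= max_cov:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# hourly matrix
# ---------------------------------------------------------------------------

def build_matrix(
    events: pd.DataFrame,
    stays: Sequence[StayRecord] | Sequence[str],
    spec: FeatureSpec,
    t_hours: int = 24,
    lookback: float = 6.0,
) -> FeatureMatrix:
    """Bin cleaned events into hourly windows from each stay's anchor.

    Events with time in ``[anchor + h, anchor + h + 1)`` land in hour ``h``;
    multiple values per bin are averaged; events at or beyond
    ``anchor + t_hours`` are dropped; empty bins are NaN.  Static features
    (demographic/admission/comorbidity) broadcast their value across all T
    steps.  Categorical features are label-encoded; the encoding dictionary is
    stored on the returned matrix.
    """
    stay_ids = [s.stay_id if isinstance(s, StayRecord) else str(s) for s in stays]
    n = len(stay_ids)
    f = len(spec)
    row_of = {sid: i for i, sid in enumerate(stay_ids)}
    col_of = {fid: j for j, fid in enumerate(spec.ids)}

    df = events.loc[events["stay_id"].isin(row_of)].copy()
    anchors = _anchors(df, lookback)

    # label-encode categorical values (first appearance order)
    encodings: dict[str, dict[str, int]] = {}
    cat_ids = [fdef.id for fdef in spec.features if fdef.kind == "categorical"]
    if cat_ids:
        is_cat = df["feature_id"].isin(cat_ids)
        vals = df.loc[is_cat, "value"].astype(object)
        for fid in cat_ids:
            toks = df.loc[df["feature_id"] == fid, "value"].astype(str)
            mapping: dict[str, int] = {}
            for tok in toks:
                if tok not in mapping:
                    mapping[tok] = len(mapping)
            encodings[fid] = mapping
        df.loc[is_cat, "value"] = [
            encodings[fid][str(v)] for fid, v in zip(df.loc[is_cat, "feature_id"], vals)
        ]
    df["value"] = df["value"].astype(float)

    values = np.full((n, t_hours, f), np.nan)

    temporal = set(spec.temporal_ids)
    is_temp = df["feature_id"].isin(temporal).to_numpy()
    tmp = df.loc[is_temp]
    if len(tmp):
        anchor_vec = tmp["stay_id"].map(anchors).to_numpy(dtype=float)
        rel = tmp["time_hours"].to_numpy(dtype=float) - anchor_vec
        bins = np.floor(rel).astype(int)
        ok = (bins >= 0) & (bins < t_hours)
        rows = tmp["stay_id"].map(row_of).to_numpy()[ok]
        cols = tmp["feature_id"].map(col_of).to_numpy()[ok]
        flat = (rows * t_hours + bins[ok]) * f + cols
        vals = tmp["value"].to_numpy(dtype=float)[ok]
        order = np.argsort(flat, kind="stable")
        flat, vals = flat[order], vals[order]
        uniq, start = np.unique(flat, return_index=True)
        sums = np.add.reduceat(vals, start)
        counts = np.diff(np.append(start, len(vals)))
        values.reshape(-1)[uniq] = sums / counts

    static = df.loc[~is_temp]
    if len(static):
        first = static.groupby(["stay_id", "feature_id"], sort=False)["value"].first()
        srows = first.index.get_level_values(0).map(row_of).to_numpy()
        scols = first.index.get_level_values(1).map(col_of).to_numpy()
        values[srows[:, None], np.arange(t_hours)[None, :], scols[:, None]] = first.to_numpy(
            dtype=float
        )[:, None]

    anchor_map = {sid: float(anchors.get(sid, 0.0)) for sid in stay_ids}
    return FeatureMatrix(values=values, stay_ids=stay_ids, spec=spec, anchors=anchor_map, encodings=encodings)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def train_feature_means(matrix: FeatureMatrix, train_rows: Sequence[int]) -> np.ndarray:
    """Per-feature mean of observed cells over the training rows only."""
    sub = matrix.values[np.asarray(train_rows, dtype=int)]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(sub.reshape(-1, sub.shape[-1]), axis=0)
    return np.where(np.isfinite(means), means, 0.0)


def _ffill(values: np.ndarray) -> np.ndarray:
    n, t, f = values.shape
    out = values.copy()
    idx = np.where(np.isnan(out), 0, np.arange(t)[None, :, None])
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(out, idx, axis=1)


def impute(matrix: FeatureMatrix, train_means: np.ndarray) -> FeatureMatrix:
    """Forward- then backward-fill along time; all-missing series get the train mean."""
    if len(train_means) != len(matrix.spec):
        raise SpecError(
            f"train_means covers {len(train_means)} features, spec has {len(matrix.spec)}"
        )
    v = _ffill(matrix.values)
    v = _ffill(v[:, ::-1, :])[:, ::-1, :]
    still = np.isnan(v)
    if still.any():
        fill = np.broadcast_to(np.asarray(train_means)[None, None, :], v.shape)
        v = np.where(still, fill, v)
    return FeatureMatrix(
        values=v,
        stay_ids=list(matrix.stay_ids),
        spec=matrix.spec,
        anchors=dict(matrix.anchors),
        encodings=dict(matrix.encodings),
    )


# ---------------------------------------------------------------------------
# tabular summary
# ---------------------------------------------------------------------------

_SUMMARY_ORDER = ("min", "max", "mean", "sum")


def summarize_tabular(matrix: FeatureMatrix, spec: FeatureSpec | None = None) -> TabularSummary:
    """Replace each temporal series by its configured summaries; statics pass through."""
    spec = spec or matrix.spec
    v = matrix.values
    if np.isnan(v).any():
        raise ValueError("summarize_tabular expects an imputed matrix (no missing cells)")
    cols: list[tuple[str, str]] = []
    arrays: list[np.ndarray] = []
    for fdef in spec.features:
        j = spec.column(fdef.id)
        series = v[:, :, j]
        if fdef.block == "temporal":
            for kind in _SUMMARY_ORDER:
                if kind not in fdef.summaries:
                    continue
                agg = {"min": series.min, "max": series.max, "mean": series.mean, "sum": series.sum}[
                    kind
                ](axis=1)
                cols.append((fdef.id, kind))
                arrays.append(agg)
        else:
            cols.append((fdef.id, "value"))
            arrays.append(series[:, 0])
    return TabularSummary(values=np.column_stack(arrays), stay_ids=list(matrix.stay_ids), columns=cols)
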