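"""Domain types, file I/O and detection-history engineering.

Camera-trap records arrive as one row per trigger (station, species,
timestamp).  This module turns them into the inputs occupancy models need:

* a temporal-independence filter (triggers of the same species at the same
  station within a 30-min window of the previously *retained* trigger are
  treated as a continuation of one detection event),
* occasion binning into sites x occasions detection histories in {0, 1, NA},
* a grazing-season occasion covariate,
* covariate standardization, contrast coding and collinearity screening
  (pairwise Pearson |r| <= 0.5 and VIF < 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

#: The four focal ungulate species of the analysis.
FOCAL_SPECIES = ["red_deer", "roe_deer", "wild_boar", "cattle"]

#: Continuous habitat covariates (standardized to mean 0, SD 1).
CONTINUOUS_COVARIATES = ["Dtr", "Ele", "Slo", "Lon", "Lat"]

#: Categorical habitat covariates and their contrast codes.
CATEGORICAL_LEVELS: dict[str, dict[str, int]] = {
    "Dtw": {"le100": 1, "gt100": -1},          # distance-to-water class
    "Vt": {"mixed": 1, "coniferous": -1},      # vegetation type
    "Asp": {"sunny": 1, "shady": -1, "flat": 0},  # aspect class
    "Td": {"dense": 1, "sparse": -1},          # tree-density class
}

ALL_COVARIATES = CONTINUOUS_COVARIATES + list(CATEGORICAL_LEVELS)

#: Default ecological priority used to break collinearity ties: covariates
#: earlier in the list are preferred when a correlated pair must lose one.
DEFAULT_PRIORITY = ["Dtr", "Ele", "Slo", "Dtw", "Vt", "Asp", "Td", "Lon", "Lat"]


@dataclass
class Station:
    """A camera station: location, deployment window and habitat covariates."""

    id: str
    x: float
    y: float
    deploy_start: date
    deploy_end: date
    covariates: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deploy_start >= self.deploy_end:
            raise ValueError(
                f"station {self.id}: deploy_start must precede deploy_end"
            )


@dataclass(frozen=True)
class DetectionEvent:
    """A single independent camera trigger."""

    station_id: str
    species: str
    timestamp: datetime


@dataclass
class DetectionHistory:
    """Sites x occasions detection matrix for one species.

    Entries are 1 (detected during the occasion), 0 (station active, no
    detection) or NaN (station inactive for the entire occasion).
    """

    matrix: pd.DataFrame                # index station_id, columns occ_001..occ_T
    occasions: pd.DataFrame             # columns start, end (dates), n_days
    occasion_length_days: int = 10

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, na_rep="")


@dataclass
class CovariateScreenReport:
    """Outcome of the collinearity screen."""

    pearson: pd.DataFrame
    vif: pd.Series
    kept: list[str]
    dropped: list[tuple[str, str]]      # (covariate, reason)


# ---------------------------------------------------------------------------
# I/O

def read_stations(path) -> pd.DataFrame:
    """Read the station table.

    Expected columns: ``station_id, x, y, deploy_start, deploy_end`` plus the
    nine habitat covariates.  Returns a frame indexed by station_id with
    parsed dates.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    for col in ("deploy_start", "deploy_end"):
        df[col] = pd.to_datetime(df[col])
    bad = df["deploy_start"] >= df["deploy_end"]
    if bad.any():
        sid = df.loc[bad, "station_id"].iloc[0]
        raise ValueError(f"station {sid}: deploy_start must precede deploy_end")
    return df.set_index("station_id", drop=False)


def read_events(path, stations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a detection-event table and validate it.

    Parameters
    ----------
    path
        CSV with columns ``station_id, species, timestamp`` (ISO-8601).
    stations
        Optional station table from :func:`read_stations`.  When given, each
        event must reference a known station and fall inside its deployment
        window; violations raise with the offending row number.

    Returns
    -------
    DataFrame sorted by timestamp.  Unknown species labels are kept as-is.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "species": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(
            f"row {row + 2}: malformed timestamp {df['timestamp'].iloc[row]!r}"
        )
    df["timestamp"] = ts
    if stations is not None:
        unknown = ~df["station_id"].isin(stations.index)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise ValueError(
                f"row {row + 2}: unknown station {df['station_id'].iloc[row]!r}"
            )
        start = stations.loc[df["station_id"], "deploy_start"].to_numpy()
        end = stations.loc[df["station_id"], "deploy_end"].to_numpy()
        tsv = df["timestamp"].to_numpy()
        outside = (tsv < start) | (tsv > end)
        if outside.any():
            row = int(np.flatnonzero(outside)[0])
            raise ValueError(
                f"row {row + 2}: timestamp outside deployment window of "
                f"station {df['station_id'].iloc[row]!r}"
            )
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Independence filter and rare-species exclusion

def filter_independent(events: pd.DataFrame, window_minutes: float = 30) -> pd.DataFrame:
    """Keep only temporally independent detections.

    Per (station, species), a trigger is retained iff at least
    ``window_minutes`` elapsed since the previously *retained* trigger;
    everything closer is a continuation of that event.  Anchoring on the
    retained event makes the filter idempotent.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    window = pd.Timedelta(minutes=window_minutes)
    keep = np.zeros(len(events), dtype=bool)
    order = events.sort_values("timestamp", kind="mergesort")
    for _, grp in order.groupby(["station_id", "species"], sort=False):
        last = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= window:
                keep[idx] = True
                last = ts
    return events.loc[keep].sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def exclude_rare_species(events: pd.DataFrame, min_detections: int) -> pd.DataFrame:
    """Drop species with fewer than ``min_detections`` independent detections."""
    if min_detections < 0:
        raise ValueError("min_detections must be >= 0")
    counts = events["species"].value_counts()
    keep = counts.index[counts >= min_detections]
    return events[events["species"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Occasion binning

def _occasion_grid(survey_start, survey_end, occasion_days: int) -> pd.DataFrame:
    if occasion_days <= 0:
        raise ValueError("occasion_days must be positive")
    start = pd.Timestamp(survey_start)
    end = pd.Timestamp(survey_end)
    span_days = (end - start) / pd.Timedelta(days=1)
    n_occ = math.ceil(span_days / occasion_days)
    rows = []
    for k in range(n_occ):
        occ_start = start + pd.Timedelta(days=k * occasion_days)
        occ_end = min(occ_start + pd.Timedelta(days=occasion_days), end)
        n_days = (occ_end - occ_start) / pd.Timedelta(days=1)
        if n_days < 1:  # trailing sliver shorter than one day
            continue
        rows.append({"start": occ_start, "end": occ_end, "n_days": n_days})
    return pd.DataFrame(rows)


def build_history(
    events: pd.DataFrame,
    stations: pd.DataFrame,
    survey_start,
    survey_end,
    occasion_days: int = 10,
    species: list[str] | None = None,
) -> dict[str, DetectionHistory]:
    """Bin independence-filtered events into detection histories.

    Occasions partition ``[survey_start, survey_end)`` into consecutive
    ``occasion_days`` blocks anchored at the shared survey start, so occasion
    indices align across stations.  An entry is 1 if the species was detected
    at least once in the block, 0 if the station was active on at least one
    day of the block without a detection, and NA if the station was inactive
    for the entire block.
    """
    occasions = _occasion_grid(survey_start, survey_end, occasion_days)
    if species is None:
        species = sorted(events["species"].unique())
    station_ids = list(stations.index)
    cols = [f"occ_{k + 1:03d}" for k in range(len(occasions))]

    # NA pattern depends only on deployment, identical across species
    active = np.zeros((len(station_ids), len(occasions)), dtype=bool)
    for i, sid in enumerate(station_ids):
        dep_s = stations.loc[sid, "deploy_start"]
        dep_e = stations.loc[sid, "deploy_end"]
        for k in range(len(occasions)):
            occ_s, occ_e = occasions.loc[k, "start"], occasions.loc[k, "end"]
            active[i, k] = (dep_s < occ_e) and (dep_e > occ_s)

    histories: dict[str, DetectionHistory] = {}
    occ_starts = occasions["start"].to_numpy()
    for sp in species:
        sub = events[events["species"] == sp]
        mat = np.where(active, 0.0, np.nan)
        if len(sub):
            occ_idx = (
                np.searchsorted(occ_starts, sub["timestamp"].to_numpy(), side="right") - 1
            )
            within = (occ_idx >= 0) & (
                sub["timestamp"].to_numpy()
                < occasions["end"].to_numpy()[np.clip(occ_idx, 0, None)]
            )
            row_pos = {sid: i for i, sid in enumerate(station_ids)}
            for sid, k, ok in zip(sub["station_id"], occ_idx, within):
                if ok and sid in row_pos:
                    mat[row_pos[sid], k] = 1.0
        histories[sp] = DetectionHistory(
            matrix=pd.DataFrame(mat, index=station_ids, columns=cols),
            occasions=occasions,
            occasion_length_days=occasion_days,
        )
    return histories


def grazing_covariate(
    occasions: pd.DataFrame,
    season_start: tuple[int, int] = (5, 1),
    season_end: tuple[int, int] = (9, 30),
) -> np.ndarray:
    """Occasion-level grazing-season flag.

    An occasion is flagged 1 iff the majority of its days fall inside the
    May 1 - Sep 30 grazing season (month/day bounds configurable).
    """
    flags = np.zeros(len(occasions), dtype=int)
    for k in range(len(occasions)):
        days = pd.date_range(
            occasions.loc[k, "start"],
            occasions.loc[k, "end"] - pd.Timedelta(days=1),
            freq="D",
        )
        md = [(d.month, d.day) for d in days]
        inside = sum(season_start <= x <= season_end for x in md)
        if inside * 2 > len(days):
            flags[k] = 1
    return flags


# ---------------------------------------------------------------------------
# Covariate preparation and screening

def code_covariates(stations: pd.DataFrame) -> pd.DataFrame:
    """Standardize continuous covariates and contrast-code categoricals.

    Continuous columns come out with sample mean 0 and SD 1; categorical
    columns are coded with the fixed {1, -1, 0} contrasts of
    :data:`CATEGORICAL_LEVELS`.
    """
    if len(stations) < 2:
        raise ValueError("need at least two stations")
    out = {}
    for cov in CONTINUOUS_COVARIATES:
        if cov not in stations.columns:
            continue
        v = stations[cov].astype(float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {cov} has zero variance")
        out[cov] = (v - v.mean()) / sd
    for cov, levels in CATEGORICAL_LEVELS.items():
        if cov not in stations.columns:
            continue
        vals = stations[cov].astype(str)
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValueError(f"covariate {cov}: unknown levels {sorted(unknown)}")
        out[cov] = vals.map(levels).astype(float)
    return pd.DataFrame(out, index=stations.index)


def _vif_series(design: pd.DataFrame) -> pd.Series:
    if design.shape[1] < 2:
        return pd.Series(1.0, index=design.columns)
    X = np.column_stack([np.ones(len(design)), design.to_numpy()])
    vals = [variance_inflation_factor(X, j + 1) for j in range(design.shape[1])]
    return pd.Series(vals, index=design.columns)


def prepare_design(
    stations: pd.DataFrame,
    priority: list[str] | None = None,
    r_threshold: float = 0.5,
    vif_threshold: float = 3.0,
) -> tuple[pd.DataFrame, CovariateScreenReport]:
    """Build the screened occupancy design matrix.

    Screening proceeds as in standard occupancy practice: iteratively drop
    the lower-priority member of any covariate pair with Pearson
    ``|r| > r_threshold``; then drop low-priority covariates until every VIF
    is below ``vif_threshold``; finally re-verify the correlation condition.
    ``priority`` breaks ties (earlier = more ecologically meaningful); it
    defaults to :data:`DEFAULT_PRIORITY`.
    """
    design = code_covariates(stations)
    if priority is None:
        priority = DEFAULT_PRIORITY
    rank = {c: priority.index(c) if c in priority else len(priority) + i
            for i, c in enumerate(design.columns)}
    pearson_full = design.corr()
    kept = list(design.columns)
    dropped: list[tuple[str, str]] = []

    # stage 1: pairwise correlation screen
    while True:
        corr = design[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.to_numpy().max() <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        loser = a if rank[a] > rank[b] else b
        winner = b if loser == a else a
        kept.remove(loser)
        dropped.append((loser, f"|r|={corr.loc[a, b]:.3f} with {winner} > {r_threshold}"))

    # stage 2: VIF screen
    while True:
        vif = _vif_series(design[kept])
        high = vif[vif >= vif_threshold]
        if high.empty:
            break
        loser = max(high.index, key=lambda c: rank[c])
        kept.remove(loser)
        dropped.append((loser, f"VIF={vif[loser]:.2f} >= {vif_threshold}"))

    # re-verify correlations among survivors
    corr = design[kept].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    assert corr.to_numpy().max() <= r_threshold, "screen left correlated covariates"

    report = CovariateScreenReport(
        pearson=pearson_full,
        vif=_vif_series(design[kept]),
        kept=kept,
        dropped=dropped,
    )
    return design[kept], report


def write_history(history: DetectionHistory, matrix_path, occasions_path) -> None:
    """Write a detection history plus its occasion sidecar (dates and Time flag)."""
    history.to_csv(matrix_path)
    side = history.occasions.copy()
    side["Time"] = grazing_covariate(history.occasions)
    side.to_csv(occasions_path, index=False)
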