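"""Spatiotemporal avoidance tests.

At stations where a species pair co-occurs, the shortest interval between
any detection of one species and any detection of the other (the minimum
time-to-encounter) summarizes fine-scale temporal partitioning.  The
observed median of these per-station minima is compared against a
randomization null in the spirit of the multi-response permutation
procedure: detection days of one species are redrawn uniformly over the
station's active deployment days (times of day preserved) and the median
recomputed, 1000 times.  An observed median larger than the null indicates
avoidance (separation in time); smaller indicates aggregation.

A companion bootstrap checks spatial confounding: the mean nearest-station
distance between the two species' station sets is compared with the same
statistic under random reassignment of presence labels across stations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

_DAY = pd.Timedelta(days=1)


@dataclass
class EncounterRecord:
    """Minimum time-to-encounter for one pair at one station."""

    station_id: str
    pair: tuple[str, str]
    min_encounter_days: float


@dataclass
class EncounterTestResult:
    """Randomization test of the median minimum time-to-encounter."""

    pair: tuple[str, str]
    n_cooccurring_stations: int
    cooccurrence_pct: float
    observed_median_days: float
    expected_median_days: float
    null_medians: np.ndarray
    p: float


@dataclass
class DistanceNullResult:
    """Bootstrap test of the mean minimum interspecific distance."""

    pair: tuple[str, str]
    observed_mean_min_distance: float
    expected_mean: float
    null_means: np.ndarray
    p: float


def _pair_events(events: pd.DataFrame, pair: tuple[str, str]):
    a = events[events["species"] == pair[0]]
    b = events[events["species"] == pair[1]]
    return a, b


def min_encounter_times(
    events: pd.DataFrame, pair: tuple[str, str]
) -> list[EncounterRecord]:
    """Per-station minimum |t_A - t_B| in (fractional) days.

    One record per station where both species of the pair were detected;
    the minimum runs over the full cross product of detection times, so the
    result is symmetric in the pair.
    """
    a, b = _pair_events(events, pair)
    shared = sorted(set(a["station_id"]) & set(b["station_id"]))
    records = []
    for sid in shared:
        ta = a.loc[a["station_id"] == sid, "timestamp"].to_numpy()
        tb = b.loc[b["station_id"] == sid, "timestamp"].to_numpy()
        diff = np.abs(ta[:, None] - tb[None, :]) / np.timedelta64(1, "s")
        records.append(
            EncounterRecord(
                station_id=sid,
                pair=pair,
                min_encounter_days=float(diff.min() / 86400.0),
            )
        )
    return records


def _median(values: np.ndarray) -> float:
    """Sample median; with an even count, the midpoint of the two central
    values."""
    return float(np.median(values))


def encounter_randomization(
    events: pd.DataFrame,
    pair: tuple[str, str],
    stations: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    analysis_station_count: int | None = None,
) -> EncounterTestResult:
    """Randomization test of the median minimum time-to-encounter.

    The null keeps the first species' detections fixed and, for each
    co-occurring station, redraws the calendar day of each of the second
    species' detections uniformly over that station's active days (the time
    of day is preserved).  p is the plain proportion of the ``n_sim``
    simulated medians strictly greater than the observed median, so p near
    1 indicates aggregation and p near 0 indicates avoidance stronger than
    chance.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    obs_records = min_encounter_times(events, pair)
    if not obs_records:
        raise ValueError(f"no co-occurring stations for pair {pair}")
    observed = _median(np.array([r.min_encounter_days for r in obs_records]))

    a, b = _pair_events(events, pair)
    shared = [r.station_id for r in obs_records]
    rng = np.random.default_rng(seed)

    # per shared station: fixed species-A seconds, species-B time-of-day
    # seconds, and the station's active day count
    prep = []
    for sid in shared:
        ta = a.loc[a["station_id"] == sid, "timestamp"]
        tb = b.loc[b["station_id"] == sid, "timestamp"]
        dep_start = pd.Timestamp(stations.loc[sid, "deploy_start"]).normalize()
        dep_end = pd.Timestamp(stations.loc[sid, "deploy_end"])
        n_days = max(int(np.ceil((dep_end - dep_start) / _DAY)), 1)
        ta_sec = (ta - dep_start) / pd.Timedelta(seconds=1)
        tod_b = (tb - tb.dt.normalize()) / pd.Timedelta(seconds=1)
        prep.append((ta_sec.to_numpy(), tod_b.to_numpy(), n_days))

    null_medians = np.empty(n_sim)
    for s in range(n_sim):
        mins = np.empty(len(prep))
        for i, (ta_sec, tod_b, n_days) in enumerate(prep):
            days = rng.integers(0, n_days, size=len(tod_b))
            tb_sec = days * 86400.0 + tod_b
            mins[i] = np.abs(ta_sec[:, None] - tb_sec[None, :]).min() / 86400.0
        null_medians[s] = _median(mins)

    denom = analysis_station_count or len(stations)
    return EncounterTestResult(
        pair=pair,
        n_cooccurring_stations=len(shared),
        cooccurrence_pct=round(100.0 * len(shared) / denom, 2),
        observed_median_days=observed,
        expected_median_days=float(null_medians.mean()),
        null_medians=null_medians,
        p=float(np.mean(null_medians > observed)),
    )


def cooccurrence_summary(
    events: pd.DataFrame,
    analysis_station_count: int,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise co-occurrence counts and percentages.

    ``analysis_station_count`` is the denominator (the stations that
    recorded any target species); percentages are reported to 2 dp.
    """
    if analysis_station_count <= 0:
        raise ValueError("analysis_station_count must be positive")
    if species is None:
        species = sorted(events["species"].unique())
    by_species = {
        sp: set(events.loc[events["species"] == sp, "station_id"]) for sp in species
    }
    rows = []
    for a, b in combinations(species, 2):
        n = len(by_species[a] & by_species[b])
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "n_cooccurring": n,
                "pct": round(100.0 * n / analysis_station_count, 2),
            }
        )
    return pd.DataFrame(rows)


def distance_null(
    stations: pd.DataFrame,
    events: pd.DataFrame,
    pair: tuple[str, str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> DistanceNullResult:
    """Bootstrap test of the mean minimum interspecific distance.

    Observed statistic: for each station holding species A, the Euclidean
    distance (metres, planar coordinates) to the nearest station holding
    species B, averaged — and symmetrically for B to A, the two directions
    averaged.  The null reassigns each species' presence labels uniformly at
    random across all analysis stations, preserving station counts; p is
    the proportion of null means <= the observed mean (small p: the two
    species sit closer together than random placement).
    """
    a, b = _pair_events(events, pair)
    sites_a = sorted(set(a["station_id"]))
    sites_b = sorted(set(b["station_id"]))
    if not sites_a or not sites_b:
        raise ValueError(f"each species of {pair} needs at least one station")

    xy = stations[["x", "y"]].astype(float)
    coords = xy.to_numpy()
    ids = list(stations.index)
    pos = {sid: i for i, sid in enumerate(ids)}

    def stat(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        d = np.hypot(
            coords[idx_a, 0][:, None] - coords[idx_b, 0][None, :],
            coords[idx_a, 1][:, None] - coords[idx_b, 1][None, :],
        )
        return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())

    ia = np.array([pos[s] for s in sites_a])
    ib = np.array([pos[s] for s in sites_b])
    observed = stat(ia, ib)

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_boot)
    for k in range(n_boot):
        ra = rng.choice(len(ids), size=len(ia), replace=False)
        rb = rng.choice(len(ids), size=len(ib), replace=False)
        null_means[k] = stat(ra, rb)

    return DistanceNullResult(
        pair=pair,
        observed_mean_min_distance=float(observed),
        expected_mean=float(null_means.mean()),
        null_means=null_means,
        p=float(np.mean(null_means <= observed)),
    )


def write_interaction_results(
    encounter_results: list[EncounterTestResult],
    distance_results: list[DistanceNullResult],
    path,
) -> None:
    """Combined pair-level table: co-occurrence, encounter test, distance
    test."""
    dist_by_pair = {r.pair: r for r in distance_results}
    rows = []
    for r in encounter_results:
        d = dist_by_pair.get(r.pair)
        rows.append(
            {
                "species_a": r.pair[0],
                "species_b": r.pair[1],
                "n_cooccurring": r.n_cooccurring_stations,
                "pct": r.cooccurrence_pct,
                "observed_median_days": r.observed_median_days,
                "expected_median_days": r.expected_median_days,
                "p_encounter": r.p,
                "observed_mean_distance": d.observed_mean_min_distance if d else np.nan,
                "expected_mean_distance": d.expected_mean if d else np.nan,
                "p_distance": d.p if d else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
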