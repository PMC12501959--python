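"""Seeded generator of synthetic camera-trap surveys.

Emulates the survey structure the rest of the package assumes: stations on
jittered transects (minimum inter-station spacing 400 m), a roughly
year-long deployment, four focal species whose joint occupancy follows the
multivariate-Bernoulli interaction model on habitat covariates, imperfect
daily detection with a higher rate during the May-September grazing season,
clustered repeat triggers within the 30-min independence window, and
species-specific circular activity (bimodal crepuscular for the wild
ungulates, unimodal midday for cattle).

The emitted CSVs use exactly the dialects :mod:`camtrap_cooccur.data_model`
reads, and the generating parameters are written to a truth file so
recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from camtrap_cooccur.data_model import (
    CATEGORICAL_LEVELS,
    code_covariates,
    read_stations,
)
from camtrap_cooccur.occupancy_multi import NaturalParams, joint_psi

TWO_PI = 2.0 * np.pi


@dataclass
class SpeciesConfig:
    """Generative parameters for one species."""

    name: str
    psi_intercept: float
    psi_effects: dict[str, float]          # on the standardized covariate scale
    p_daily_intercept: float               # logit of the per-day detection prob
    p_time_effect: float                   # added on grazing-season days
    activity: list[tuple[float, float, float]]  # (weight, mean hour, kappa)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic survey."""

    n_stations: int = 39
    n_transects: int = 15
    survey_start: str = "2022-06-15"
    survey_days: int = 360
    occasion_days: int = 10
    min_spacing_m: float = 400.0
    station_spacing_m: float = 500.0
    transect_spacing_m: float = 1000.0
    dropout_prob: float = 0.15             # fraction of stations failing early
    repeat_trigger_rate: float = 0.8       # Poisson mean of extra triggers
    grazing_season: tuple[tuple[int, int], tuple[int, int]] = ((5, 1), (9, 30))
    categorical_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Dtw": {"le100": 0.4, "gt100": 0.6},
            "Vt": {"mixed": 0.5, "coniferous": 0.5},
            "Asp": {"sunny": 0.4, "shady": 0.4, "flat": 0.2},
            "Td": {"dense": 0.5, "sparse": 0.5},
        }
    )
    species: list[SpeciesConfig] = field(default_factory=lambda: default_species())
    gamma: dict[tuple[str, str], float] = field(
        default_factory=lambda: default_gamma()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, value in self.gamma.items():
            rev = (pair[1], pair[0])
            if rev in self.gamma and self.gamma[rev] != value:
                raise ValueError(f"gamma asymmetric for pair {pair}")
        for probs in self.categorical_probs.values():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("categorical level probabilities must sum to 1")

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def gamma_matrix(self) -> np.ndarray:
        names = self.species_names
        g = np.zeros((len(names), len(names)))
        for (a, b), v in self.gamma.items():
            i, j = names.index(a), names.index(b)
            g[i, j] = g[j, i] = v
        return g


def default_species() -> list[SpeciesConfig]:
    """Default regime: crepuscular wild ungulates whose occupancy tracks
    elevation/aspect/cover, a diurnal low-elevation grazer, and detection
    rates that rise in the grazing season."""
    crepuscular = [(0.5, 8.5, 3.0), (0.5, 21.0, 3.0)]
    return [
        SpeciesConfig(
            name="red_deer",
            psi_intercept=0.5,
            psi_effects={"Ele": 0.6, "Asp": 1.0, "Td": 1.0},
            p_daily_intercept=-3.0,
            p_time_effect=0.7,
            activity=crepuscular,
        ),
        SpeciesConfig(
            name="roe_deer",
            psi_intercept=0.5,
            psi_effects={"Ele": 1.0, "Asp": 1.2, "Slo": 0.5},
            p_daily_intercept=-4.0,
            p_time_effect=1.0,
            activity=crepuscular,
        ),
        SpeciesConfig(
            name="wild_boar",
            psi_intercept=0.0,
            psi_effects={"Ele": -1.0, "Dtw": 1.0},
            p_daily_intercept=-4.0,
            p_time_effect=1.5,
            activity=crepuscular,
        ),
        SpeciesConfig(
            name="cattle",
            psi_intercept=0.5,
            psi_effects={"Ele": -1.2},
            p_daily_intercept=-6.0,
            p_time_effect=3.5,
            activity=[(1.0, 12.5, 3.0)],
        ),
    ]


def default_gamma() -> dict[tuple[str, str], float]:
    """Pairwise interaction intercepts: strong cattle avoidance by the deer,
    weaker for wild boar, mild structure among the wild species."""
    return {
        ("red_deer", "roe_deer"): -0.5,
        ("red_deer", "wild_boar"): 0.3,
        ("red_deer", "cattle"): -2.5,
        ("roe_deer", "wild_boar"): -0.3,
        ("roe_deer", "cattle"): -2.5,
        ("wild_boar", "cattle"): -0.8,
    }


# ---------------------------------------------------------------------------

def simulate_stations(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the station table: jittered transect layout plus covariates.

    Longitude and latitude are generated collinear with elevation (the
    mountain-gradient situation that gets them screened out downstream).
    """
    n, nt = config.n_stations, config.n_transects
    if config.station_spacing_m - 100.0 < config.min_spacing_m:
        raise ValueError(
            "station_spacing_m too small to guarantee the minimum spacing"
        )
    xs, ys, transects = [], [], []
    per = int(np.ceil(n / nt))
    k = 0
    for t in range(nt):
        for j in range(per):
            if k >= n:
                break
            xs.append(j * config.station_spacing_m + rng.uniform(-50, 50))
            ys.append(t * config.transect_spacing_m + rng.uniform(-100, 100))
            transects.append(t + 1)
            k += 1
    xs, ys = np.asarray(xs), np.asarray(ys)
    if n > 1:
        d = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
        np.fill_diagonal(d, np.inf)
        if d.min() <= config.min_spacing_m:
            raise ValueError("layout violates the minimum inter-station spacing")

    ele_z = rng.normal(size=n)
    rows = {
        "station_id": [f"ST{i + 1:03d}" for i in range(n)],
        "x": xs,
        "y": ys,
        "transect": transects,
        "Dtr": np.maximum(rng.normal(800, 400, size=n), 10.0),
        "Ele": 1600 + 150 * ele_z,
        "Slo": np.clip(rng.normal(20, 8, size=n), 0, 55),
        "Lon": 87.2 + 0.12 * (0.8 * ele_z + 0.6 * rng.normal(size=n)),
        "Lat": 48.6 + 0.10 * (0.8 * ele_z + 0.6 * rng.normal(size=n)),
    }
    for cov, probs in config.categorical_probs.items():
        levels = list(CATEGORICAL_LEVELS[cov])
        p = [probs[lv] for lv in levels]
        rows[cov] = rng.choice(levels, size=n, p=p)

    start = pd.Timestamp(config.survey_start)
    end = start + pd.Timedelta(days=config.survey_days)
    dep_end = []
    for i in range(n):
        if rng.uniform() < config.dropout_prob:
            frac = rng.uniform(0.5, 0.9)
            dep_end.append(start + pd.Timedelta(days=round(config.survey_days * frac)))
        else:
            dep_end.append(end)
    rows["deploy_start"] = [start] * n
    rows["deploy_end"] = dep_end
    df = pd.DataFrame(rows)
    return df.set_index("station_id", drop=False)


def simulate_occupancy_states(
    config: SimConfig, stations: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw latent presence vectors per station from the joint occupancy
    distribution implied by the true natural parameters."""
    design = code_covariates(stations)
    names = config.species_names
    gamma = config.gamma_matrix()
    beta = []
    covs_per_species = []
    for sp in config.species:
        covs = list(sp.psi_effects)
        covs_per_species.append(covs)
        beta.append(np.array([sp.psi_intercept] + [sp.psi_effects[c] for c in covs]))
    params = NaturalParams(beta=beta, gamma=gamma)

    z = np.zeros((len(stations), len(names)), dtype=int)
    for i, sid in enumerate(stations.index):
        x = [
            np.concatenate([[1.0], design.loc[sid, covs].to_numpy(dtype=float)])
            for covs in covs_per_species
        ]
        states, probs = joint_psi(params, x)
        z[i] = states[rng.choice(len(states), p=probs)]
    return pd.DataFrame(z, index=stations.index, columns=names)


def _sample_activity_times(
    spec: SpeciesConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Seconds since midnight drawn from the species' von Mises mixture."""
    weights = np.array([w for w, _, _ in spec.activity])
    comp = rng.choice(len(weights), size=size, p=weights / weights.sum())
    out = np.empty(size)
    for c, (_, mean_hour, kappa) in enumerate(spec.activity):
        m = comp == c
        mu = mean_hour / 24.0 * TWO_PI
        out[m] = rng.vonmises(mu - np.pi, kappa, size=m.sum()) + np.pi
    return (out % TWO_PI) / TWO_PI * 86400.0


def _in_season(day: pd.Timestamp, season) -> bool:
    (m0, d0), (m1, d1) = season
    return (m0, d0) <= (day.month, day.day) <= (m1, d1)


def simulate_events(
    config: SimConfig,
    stations: pd.DataFrame,
    z: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate triggers for occupied station-species.

    Detection is simulated daily (logit p = intercept + time-effect on
    grazing-season days) so one event stream feeds both the occasion-binned
    occupancy analyses and the timestamp-level temporal analyses.  Each
    detection may spawn extra triggers within 30 min to exercise the
    independence filter.
    """
    records = []
    for sid in stations.index:
        dep_start = pd.Timestamp(stations.loc[sid, "deploy_start"])
        dep_end = pd.Timestamp(stations.loc[sid, "deploy_end"])
        n_days = int((dep_end - dep_start) / pd.Timedelta(days=1))
        days = pd.date_range(dep_start, periods=n_days, freq="D")
        season_flag = np.array(
            [_in_season(d, config.grazing_season) for d in days], dtype=float
        )
        for sp in config.species:
            if z.loc[sid, sp.name] == 0:
                continue
            eta = sp.p_daily_intercept + sp.p_time_effect * season_flag
            p_day = 1.0 / (1.0 + np.exp(-eta))
            hits = np.flatnonzero(rng.uniform(size=n_days) < p_day)
            if hits.size == 0:
                continue
            tods = _sample_activity_times(sp, hits.size, rng)
            for d_idx, tod in zip(hits, tods):
                ts = days[d_idx] + pd.Timedelta(seconds=round(float(tod)))
                ts = min(ts, dep_end - pd.Timedelta(seconds=1))
                records.append((sid, sp.name, ts))
                for _ in range(rng.poisson(config.repeat_trigger_rate)):
                    extra = ts + pd.Timedelta(minutes=float(rng.uniform(1, 25)))
                    if extra < dep_end:
                        records.append((sid, sp.name, extra))
    events = pd.DataFrame(records, columns=["station_id", "species", "timestamp"])
    return events.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def simulate_survey(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full draw: (stations, latent states, events) from one seed."""
    rng = np.random.default_rng(config.seed)
    stations = simulate_stations(config, rng)
    z = simulate_occupancy_states(config, stations, rng)
    events = simulate_events(config, stations, z, rng)
    return stations, z, events


def truth_record(config: SimConfig) -> dict:
    """The generating parameters as a plain dict (for the truth file)."""
    d = asdict(config)
    d["gamma"] = {f"{a}|{b}": float(v) for (a, b), v in config.gamma.items()}
    d["grazing_season"] = [list(x) for x in config.grazing_season]
    for sp in d["species"]:
        sp["activity"] = [list(c) for c in sp["activity"]]
    return d


def config_from_truth(d: dict) -> SimConfig:
    """Rebuild a SimConfig from a truth record (round-trip of
    :func:`truth_record`)."""
    d = dict(d)
    d.pop("latent_states", None)
    d["gamma"] = {
        tuple(k.split("|")): float(v) for k, v in d["gamma"].items()
    }
    d["grazing_season"] = tuple(tuple(x) for x in d["grazing_season"])
    d["species"] = [
        SpeciesConfig(
            name=sp["name"],
            psi_intercept=sp["psi_intercept"],
            psi_effects=dict(sp["psi_effects"]),
            p_daily_intercept=sp["p_daily_intercept"],
            p_time_effect=sp["p_time_effect"],
            activity=[tuple(c) for c in sp["activity"]],
        )
        for sp in d["species"]
    ]
    return SimConfig(**d)


def end_to_end_fixture(
    config: SimConfig, outdir
) -> tuple[Path, Path, Path]:
    """Write stations.csv, events.csv and truth.yaml for one simulated
    survey; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stations, z, events = simulate_survey(config)

    st_path = outdir / "stations.csv"
    out = stations.drop(columns=["transect"]).copy()
    out["deploy_start"] = pd.to_datetime(out["deploy_start"]).dt.strftime("%Y-%m-%d")
    out["deploy_end"] = pd.to_datetime(out["deploy_end"]).dt.strftime("%Y-%m-%d")
    out.to_csv(st_path, index=False)

    ev_path = outdir / "events.csv"
    ev = events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(ev_path, index=False)

    truth_path = outdir / "truth.yaml"
    truth = truth_record(config)
    truth["latent_states"] = {sid: z.loc[sid].tolist() for sid in z.index}
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)

    # the written table must read back through the standard reader
    read_stations(st_path)
    return st_path, ev_path, truth_path
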