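"""Simulation studies validating the estimators.

Self-contained harnesses that exercise the package's own methods against
known generative truth: parameter recovery for the multi-species occupancy
model, bias of the Dhat4 overlap estimator against the numerically
integrated true overlap, and type-I-error calibration of the three
randomization/bootstrap tests.  Both the test suite and the results-
reproduction script drive these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from camtrap_cooccur import activity as act
from camtrap_cooccur import data_model as dm
from camtrap_cooccur import interactions as ia
from camtrap_cooccur import occupancy_multi as om
from camtrap_cooccur import synthetic_data as sd
from camtrap_cooccur.data_model import DetectionHistory


def _occasion_grid(n_occasions: int, start: str) -> pd.DataFrame:
    occ = pd.DataFrame(
        {"start": pd.date_range(start, periods=n_occasions, freq="10D")}
    )
    occ["end"] = occ["start"] + pd.Timedelta(days=10)
    occ["n_days"] = 10.0
    return occ


def simulate_occupancy_dataset(
    config: sd.SimConfig,
    n_occasions: int,
    seed: int,
    p_intercept: float = -0.85,
    p_time: float = 0.8,
):
    """Draw one occasion-level dataset from the generative occupancy model.

    Stations, covariates and latent presence come from the synthetic-survey
    generator; detection is drawn directly at the occasion scale with
    logit p = p_intercept + p_time * Time (mid-range probabilities).
    Returns (histories, design, occasion covariates, packed true params).
    """
    rng = np.random.default_rng(seed)
    stations = sd.simulate_stations(config, rng)
    z = sd.simulate_occupancy_states(config, stations, rng)
    design = dm.code_covariates(stations)

    occ = _occasion_grid(n_occasions, config.survey_start)
    time_flag = dm.grazing_covariate(occ, *config.grazing_season)
    p = 1.0 / (1.0 + np.exp(-(p_intercept + p_time * time_flag)))

    histories = {}
    cols = [f"occ_{t + 1:03d}" for t in range(n_occasions)]
    for sp in config.species:
        y = (rng.uniform(size=(len(stations), n_occasions)) < p) & (
            z[sp.name].to_numpy()[:, None] == 1
        )
        histories[sp.name] = DetectionHistory(
            matrix=pd.DataFrame(y.astype(float), index=stations.index, columns=cols),
            occasions=occ,
        )
    truth = om.pack_params(
        [
            np.array([sp.psi_intercept] + list(sp.psi_effects.values()))
            for sp in config.species
        ],
        config.gamma_matrix(),
        [np.array([p_intercept, p_time])] * len(config.species),
    )
    occ_cov = pd.DataFrame({"Time": time_flag})
    return histories, design, occ_cov, truth


def recovery_study(
    n_replicates: int = 20,
    n_sites: int = 500,
    n_occasions: int = 36,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the multi-species fit over seeded replicates.

    Each replicate simulates a survey from the default generative regime,
    fits the interaction model with the true per-species covariate sets, and
    scores every occupancy coefficient and interaction intercept against
    truth at 3 Wald SE.  Returns the pooled fraction within 3 SE.
    """
    within = []
    for rep in range(n_replicates):
        config = sd.SimConfig(
            n_stations=n_sites, n_transects=max(15, n_sites // 25),
            dropout_prob=0.0, seed=seed,
        )
        hists, design, occ_cov, truth = simulate_occupancy_dataset(
            config, n_occasions, seed=int(np.random.default_rng([seed, rep]).integers(2 ** 31)),
        )
        winners = {sp.name: tuple(sp.psi_effects) for sp in config.species}
        fit = om.fit_multi(winners, hists, design, occ_cov, n_starts=1, seed=rep)
        n_occ_params = sum(1 + len(sp.psi_effects) for sp in config.species)
        n_gamma = len(config.species) * (len(config.species) - 1) // 2
        sl = slice(0, n_occ_params + n_gamma)  # score beta and gamma
        ok = np.abs(fit.params[sl] - truth[sl]) < 3 * fit.se[sl]
        within.append(ok)
    pooled = np.concatenate(within)
    return {
        "fraction_within_3se": float(pooled.mean()),
        "n_parameters_scored": int(pooled.size),
        "n_replicates": n_replicates,
    }


def delta4_bias_study(
    n_replicates: int = 50,
    n: int = 1000,
    seed: int = 0,
) -> dict:
    """Bias of Dhat4 against the numerically integrated true overlap.

    Samples come from the generator's default activity regimes (bimodal
    crepuscular vs unimodal midday); the truth is the grid integral of
    min(f1, f2) of the generating mixtures.
    """
    species = sd.default_species()
    crep = species[0].activity
    cattle = species[-1].activity
    hour = lambda h: h / 24.0 * 2 * np.pi  # noqa: E731

    def mixture_pdf(theta, comps):
        from scipy.stats import vonmises

        w = np.array([c[0] for c in comps])
        w = w / w.sum()
        return sum(
            wi * vonmises.pdf(theta, kappa, loc=hour(mu))
            for wi, (_, mu, kappa) in zip(w, comps)
        )

    theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    truth = float(
        np.minimum(mixture_pdf(theta, crep), mixture_pdf(theta, cattle)).sum()
        * 2 * np.pi / len(theta)
    )
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        a = sd._sample_activity_times(species[0], n, rng) / 86400 * 2 * np.pi
        b = sd._sample_activity_times(species[-1], n, rng) / 86400 * 2 * np.pi
        estimates.append(act.overlap_delta(a, b, "dhat4"))
    return {
        "true_overlap": truth,
        "mean_estimate": float(np.mean(estimates)),
        "abs_bias": float(abs(np.mean(estimates) - truth)),
        "n_replicates": n_replicates,
    }


def _calibration_fraction(p_values: np.ndarray) -> dict:
    return {
        "fraction_p_below_05": float(np.mean(np.asarray(p_values) < 0.05)),
        "n_replicates": len(p_values),
    }


def encounter_null_calibration(
    n_replicates: int = 200,
    n_sim: int = 199,
    n_stations: int = 8,
    deploy_days: int = 60,
    seed: int = 0,
) -> dict:
    """Type-I error of the encounter randomization under its own null.

    Both species' detections are placed independently and uniformly over
    each station's deployment, exactly the exchangeable situation the
    randomization assumes; the p-value should be uniform.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp("2022-06-01")
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i}" for i in range(n_stations)],
            "x": np.arange(n_stations) * 500.0,
            "y": 0.0,
            "deploy_start": start,
            "deploy_end": start + pd.Timedelta(days=deploy_days),
        }
    ).set_index("station_id", drop=False)
    pvals = []
    for _ in range(n_replicates):
        rows = []
        for sid in stations.index:
            for species in ("a", "b"):
                for _ in range(int(rng.integers(2, 6))):
                    t = start + pd.Timedelta(
                        days=int(rng.integers(0, deploy_days)),
                        seconds=float(rng.uniform(0, 86400)),
                    )
                    rows.append({"station_id": sid, "species": species, "timestamp": t})
        events = pd.DataFrame(rows)
        res = ia.encounter_randomization(
            events, ("a", "b"), stations, n_sim=n_sim,
            seed=int(rng.integers(2 ** 31)),
        )
        pvals.append(res.p)
    return _calibration_fraction(np.array(pvals))


def distance_null_calibration(
    n_replicates: int = 200,
    n_boot: int = 199,
    n_stations: int = 30,
    seed: int = 0,
) -> dict:
    """Type-I error of the distance bootstrap when presence labels really
    are random across stations."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        stations = pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(n_stations)],
                "x": rng.uniform(0, 10000, n_stations),
                "y": rng.uniform(0, 10000, n_stations),
                "deploy_start": pd.Timestamp("2022-06-01"),
                "deploy_end": pd.Timestamp("2022-07-01"),
            }
        ).set_index("station_id", drop=False)
        ids = rng.permutation(n_stations)
        rows = [
            {"station_id": f"S{i}", "species": "a",
             "timestamp": pd.Timestamp("2022-06-05")}
            for i in ids[:10]
        ] + [
            {"station_id": f"S{i}", "species": "b",
             "timestamp": pd.Timestamp("2022-06-06")}
            for i in rng.permutation(n_stations)[:12]
        ]
        res = ia.distance_null(
            stations, pd.DataFrame(rows), ("a", "b"), n_boot=n_boot,
            seed=int(rng.integers(2 ** 31)),
        )
        pvals.append(res.p)
    return _calibration_fraction(np.array(pvals))


def overlap_null_calibration(
    n_replicates: int = 200,
    n_perm: int = 199,
    n: int = 50,
    seed: int = 0,
) -> dict:
    """Type-I error of the overlap permutation test when both samples share
    one von Mises activity distribution."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        a = (rng.vonmises(0.0, 1.0, size=n)) % (2 * np.pi)
        b = (rng.vonmises(0.0, 1.0, size=n)) % (2 * np.pi)
        pvals.append(
            act.overlap_randomization_test(
                a, b, n_perm=n_perm, seed=int(rng.integers(2 ** 31))
            )
        )
    return _calibration_fraction(np.array(pvals))
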