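"""Simulation studies validating the estimators against known truth.

Runs the package's evaluation harnesses at reduced scale (the full-scale
versions back the acceptance checks): parameter recovery for the
multi-species model, Dhat4 bias against the numerically integrated true
overlap, and type-I-error calibration of the three randomization tests.
"""

import json
from pathlib import Path

from camtrap_cooccur import evaluation as ev


def main() -> None:
    out = {}
    out["recovery"] = ev.recovery_study(n_replicates=5, n_sites=300, seed=1)
    out["dhat4"] = ev.delta4_bias_study(n_replicates=20, n=1000, seed=1)
    out["encounter_null"] = ev.encounter_null_calibration(n_replicates=100, seed=1)
    out["distance_null"] = ev.distance_null_calibration(n_replicates=100, seed=1)
    out["overlap_null"] = ev.overlap_null_calibration(n_replicates=100, seed=1)

    Path("results").mkdir(exist_ok=True)
    with open("results/validation.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
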